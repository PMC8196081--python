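# Methods

This note documents the models, the synthetic-cohort generator, the
numerical choices and the known limitations of `copydist`.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Similarity from copying profiles

A copying profile is the vector $f^i_k$ of proportions of individual *i*'s
genome matched to donor group *k* by a Li–Stephens-style haplotype-copying
model.  Genetic similarity is $1-\mathrm{TVD}_{ij}$ with
$\mathrm{TVD}_{ij}=\frac12\sum_k|f^i_k-f^j_k|$.  TVD is a metric on the
probability simplex (symmetry, identity, triangle inequality — property
tested).  Two aggregation conventions exist: TVD of group-mean profiles, or
the mean of pairwise $1-\mathrm{TVD}_{ij}$ over cross-individual pairs.
They differ in general; the pipeline uses the **pairwise-mean convention**
throughout, which is the convention compatible with the permutation tests
(each permutation only re-indexes a precomputed pairwise matrix).

Two panels are carried in parallel.  The *internal* panel's donors include
the sampled groups themselves, so endogamy (inflated self-group copying) and
recent local intermixing move it; the *external* panel only sees non-local
donors and reflects differential outside ancestry.  `compare_panels` aligns
the two group-level matrices and reports the Pearson correlation of the
individual-level off-diagonals.

The equalized-panel consistency check is implemented by down-weighting donor
columns by donor sample size and renormalizing (`equalize_panel`), an
approximation of repainting every recipient against equal donor counts;
repainting itself requires the painting model and is out of scope.

## Exchangeability permutation tests

To test whether groups A and B have exchangeable ancestry profiles, each of
`n_perm` permutations draws $\lfloor n_X/2\rfloor$ individuals without
replacement from each group into a mixed group C ($n_X=\min(n_A,n_B)$; when
$n_X$ is odd one further not-yet-sampled individual joins from A with
probability 1/2, else from B), and compares C's mean pairwise similarity
with that of $n_X$ individuals drawn without replacement from Y ∈ {A, B}.
The one-sided p for Y is the proportion of permutations with
mean(C) ≥ mean(Y); ties count toward the null.  p values are plain
proportions (may be exactly 0) with the Monte-Carlo standard error
$\sqrt{p(1-p)/n_{\text{perm}}}$ attached; an optional $(b+1)/(n+1)$
correction is available but off by default.  Default `n_perm` is 100,000;
tests and examples use reduced counts.

For language classifications spanning more than two ethnic/occupation
labels, all means (including in the mixed group) use only cross-label pairs,
so strong within-ethnicity similarity cannot masquerade as
within-classification similarity.  The reported classification-level p is
min(p_A, p_B).  **Caveat:** the min of two dependent p values is
anti-conservative as a test in itself (its null rejection rate at 0.05 is
roughly double nominal); both per-side values are therefore exposed in
`PermutationResult.components`, and calibration guarantees apply to the
per-side p.

The A_max competition test shuffles the members of A_max ∪ B into
pseudo-groups of the original sizes and compares
sim(A, pseudo-A_max) − sim(A, pseudo-B) against the observed difference
(exceedance with ≥).  The religion variant applies the group-pair test to
religion-defined subgroups within one group and skips (with a logged
notice) when fewer than five individuals or fewer than two usable
categories are present.

## Spatial decay models

Distances are haversine great-circle km on a sphere of radius **6371.0 km**
(the radius is a documented constant; no ellipsoidal correction).  Elevation
differences are absolute meters.  Two model forms are used:

- exponential, $G=\alpha+\beta e^{-\lambda d}+e$, for the internal-panel
  distance trend;
- linear, $G=\gamma+\delta x+\varepsilon$, for the external-panel distance
  trend and for elevation under either panel.  When $x=h$, pairs with
  $h \ge 2500$ m are excluded (the cutoff and the 100 m elevation bins are
  interpreted in **meters**; treating them as kilometers would exclude
  nothing and bin nothing).

The $\lambda$ search runs Nelder–Mead over $\log\lambda$ (positivity by
construction), initialized at 0.01/km.  By default $(\alpha,\beta)$ are
profiled out exactly by OLS at each candidate $\lambda$, which makes the
search the joint least-squares (Gaussian-MLE) solution; a literal two-stage
variant that fixes $\alpha=0,\beta=1$ during the search is available as
`two_stage=True`.  The profiled default was chosen because the two-stage
variant anchors $\lambda$ to the raw similarity scale and cannot recover
$\lambda$ when the true $(\alpha, \beta)$ are far from $(0, 1)$ — parameter
recovery is a stated requirement of the pipeline.  Non-convergence raises an
error carrying the best $\lambda$ found.

Residual adjustment follows a fixed chain: to test geography after
elevation, $G$ is replaced by the residuals of the linear fit $G\sim h$ and
$d$ by the residuals $\kappa$ of $d\sim h$, shifted so $\min\kappa=0$
(keeping the 25 km near-bin rule meaningful); to test elevation after
geography, $G$ is replaced by the residuals of the exponential fit
$G\sim d$ and $h$ by the residuals of $h\sim d$.  Adjustment fits use all
supplied pairs; the 2500 m exclusion applies to the elevation *fit*, not to
the adjustment regressions.

### Permutation schemes

Significance permutes **birthplace records** — latitude, longitude and
elevation move together as one record — while similarity stays attached to
the individual; in stratified runs the non-fixed factor labels travel with
the record, permuted only within strata of the fixed factor (singleton
strata stay in place, logged).  One permutation per replicate serves both
the geographic and elevation statistics.  Three exceedance rules, matching
the analysis each belongs to:

- **near_bin** (internal-panel geography): permutation counts when its mean
  G over pairs with permuted distance < 25 km is ≥ the observed mean;
- **slope** (linear analyses): permutation counts when its fitted δ is ≤
  the observed δ (more negative = more extreme);
- **fitted_grid** (factor-restricted external-geography and elevation
  analyses): permutation counts when *any* fitted value on a fixed grid of
  bin centers (48 over [12.5, 1187.5] km, 25 over [50, 2450] m; bins
  left-closed right-open) is ≥ the observed fitted value at that center.

The any-bin rule is a union rule: it is valid (never anti-conservative) but
not exactly calibrated; in its single-bin reduction it is an exact scalar
exceedance test, which is how its calibration is verified.  Factor tests
restrict all pairs — real and permuted — to those sharing the factor;
religion recorded as "Traditional" is treated as missing for the shared-
religion factor (practices vary across groups), and missing factor values
never match.

The final p per target is the **maximum** over the admissible permutation
schemes (free plus each fixed factor), excluding: the scheme fixing the
tested factor itself (zero effective permutations); the schemes fixing
group label or first language when testing geographic or elevation distance
(those permutations barely move birthplaces, since co-ethnics live
together); and the schemes fixing group and first language when testing
group, first language or language group (the two factors are nearly
collinear with the targets).

## Cultural scores and association

The unweighted score between two groups counts traits (out of the table's
trait list) whose states match as Y–Y or N–N; U never contributes.  The
weighted score gives a Y–Y match on a trait with H practicing groups a
contribution 1/H (N–N: 1/Z), so ubiquitous practices count less; summed
over all pairs a trait contributes exactly C(H,2)/H (conservation property,
tested).

Mantel tests permute one matrix's rows and columns jointly and use the
exceedance rule r ≥ r_obs on off-diagonal Pearson correlation; the partial
variant takes the first-order partial correlation given the third matrix
(equivalently, correlation of residuals after regressing both off-diagonal
vectors on the third's).  Per-trait category tests compare mean pairwise
group similarity within category X vs Y under label permutation (default
10,000), skipping categories of fewer than two groups.  No multiple-testing
correction is applied across traits or contrasts, matching the reported
analysis; this is a deliberate presentation choice, not an oversight.

The adjusted similarity G* removes spatial structure using only
**cross-language-branch pairs** for every fit in the chain (G on d,
exponential; h on d; the G-residuals on the h-residuals), so the correction
is not confounded with shared linguistic classification; deviations are
group-pair mean G* minus the mean over that branch pairing (they sum to
zero within each branch pairing by construction).

The intermixing test flags a group pair when at least one cross-individual
pairing has mean MRCA segment length (total cM / segment count) at least
2.5 cM above the **median over all cross-group pairings** in the table.
A per-pair median was considered and rejected: a uniformly elevated pair
would raise its own reference and never be flagged, defeating the purpose
of detecting recently intermixed pairs.  Significance resamples same-size
group subsets (default 10,000) and counts subsets with at least as many
flagged pairs.

## Relatedness pruning

A pair from populations (i, k) is flagged when PI_HAT > 0.15 **and**
PI_HAT exceeds the minimum of the four thresholds
$X+3\max(0.02,S)$ and $Y+3\max(0.02,D)$ for both populations, where
X/Y/S/D are the mean/median/sample SD (n−1)/unscaled MAD of
within-population PI_HAT values, computed once on the full table (not
recomputed during removal).  Populations with ≤ 2 sampled individuals have
no meaningful spread; any pair above 0.15 containing one of their members
is flagged directly.  Removal is greedy: repeatedly delete the individual
in the most surviving pairs, breaking ties by lexicographically smallest id
(a documented determinism choice).  Greedy removal is a valid vertex cover
but **not** guaranteed minimal — an 11-pair counterexample exists where it
removes one individual more than necessary — so the suite asserts the
cover property and the ≥-minimum bound, with equality only where it
provably holds.  After pruning, surviving pairs at PI_HAT ≥ 0.2 trigger a
logged warning (a soft expectation in study-like cohorts, not a guarantee).

## The synthetic-cohort generator

The generator produces exactly the structure the analyses assume, on an
explicit donor-feature basis where $1-\mathrm{TVD}$ equals shared mass:

- one **pool** donor (mass α = 0.50) shared by everyone;
- one **self** donor per group (the remainder mass);
- one **overlap** donor per group pair carrying
  $m_{ab}=\beta e^{-\lambda d_{ab}} + \max(0, a_h + \delta_h h_{ab})$
  with defaults β = 0.10, λ = 0.01/km, $a_h$ = 0.005, $\delta_h$ = −2·10⁻⁶/m
  (the elevation term reaches zero exactly at the 2500 m cutoff).

Between-group expected similarity is therefore **exactly**
$\alpha + m_{ab}$ — the planted decay is not approximate.  Individual
variation has two parts: a private "close kin" donor with mass
ζ ~ |N(0, 0.072²)| taken from the self donor, making within-group
similarity $1-\max(\zeta_i,\zeta_j)$ with mean ≈ 0.90 (the order of real
within-group copying similarity) without touching cross-group pairs; and a
small pool↔self shift η ~ N(0, 0.025²) that perturbs each cross-group
similarity by $\min(\eta_i,\eta_j)$ — constant mean, pair-level SD ≈ 0.02 —
so decay-parameter recovery is unbiased.

Geography: group centroids sit on a jittered grid of nodes spanning a
10°×10° box (≈ Ethiopia), **two groups per node 30–80 km apart**, because
real ethnic groups often neighbour each other at tens of km while the
cohort spans > 1000 km; the paired layout is what makes the short range of
the decay identifiable.  Individual birthplaces jitter 0.02° (~2 km) around
the centroid and elevations (uniform 500–3000 m per group) jitter ±30 m.
Default cohort size is 30 groups × 10 individuals.

Planted effects, all internal-panel unless noted:

- **endogamy** moves center mass ε from pool to self (default planted
  strength 0.15), lowering that group's cross-group internal similarity by
  ≈ ε while the external panel is untouched;
- **admixture edges** mix the target's center toward the source by the
  mixing fraction *linearly in both panels* (so the L1 gap shrinks exactly
  by that fraction) and add 40/generations cM to the pair's mean MRCA
  segment draws (Gamma totals over Poisson segment counts around a 0.6 cM
  base — exponential-family segment lengths whose mean encodes recency);
- **trait cliques** add a shared overlap donor (default 0.04) and +4 cM
  segments among practicing groups;
- **religion splits** shift mass to religion-specific donors within one
  group (default 0.12), creating religion-stratified substructure;
- **planted relatives** raise a configured fraction of within-group PI_HAT
  pairs to U(0.25, 0.45) over a |N(0.02, 0.01)| background.

Feasibility is validated: every group's self-donor mass must exceed
3·SD(η) + 2·SD(ζ) so noise clipping stays rare; infeasible configurations
raise with a actionable message rather than silently rescaling.

**What the generator does not emulate:** linkage and coalescent noise,
donor-panel competition effects, genuine painting uncertainty, spatially
autocorrelated elevation, unequal group sizes by default, and any
correlation between language classification and ancestry beyond geography
(language classes are assigned by map quadrant).  Passing tests therefore
demonstrate the statistical machinery's correctness and calibration on data
with the assumed structure — not that real painted data satisfy that
structure.

### Recovery conventions

Parameter-recovery checks fit **cross-group pairs**: within-group pairs are
governed by the kin/endogamy model, not the spatial kernel, exactly as
short-distance same-group pairs in real data reflect endogamy rather than
isolation by distance.  The elevation-slope check adjusts geography out
first (the pipeline's own `elev_after_geo` chain) and judges recovery
against a delete-one-group jackknife CI, because elevation is a group-level
attribute: with 30 groups the honest effective sample is the group set, and
naive pair-level CIs under-cover badly.

## Problem sizes and defaults in the test suite

The suite runs the generator at 30×10 for recovery checks and 6–16 groups
for permutation-heavy checks; permutation counts are reduced to 99–2,000
(defaults in the API remain 100,000 / 10,000).  Null calibration uses 200
fresh replicates per engine against the exact binomial 95% interval at
α = 0.05, with a fixed two-stage retry rule whose false-alarm rate is 0.25%
per engine while retaining > 90% power against a genuinely inflated engine.

## Known limitations

- The fitted-grid (any-bin) rule is conservative by construction; its p
  values are valid but not uniform under the null.
- min(p_A, p_B) summaries (language classification tests) are
  anti-conservative; use the per-side components for calibrated inference.
- `equalize_panel` approximates equal-donor-count repainting by column
  re-weighting; it cannot reproduce painting-competition effects.
- Greedy pruning can exceed the minimum possible number of removals.
- The proximity-score null permutes cluster positions uniformly on the
  circle; if admixture sources were constrained by factors other than
  geography, this null does not model them.
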