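# Methods

## Fatty-acid nomenclature and classification

Labels follow the `C:D[ωN]` shorthand: chain length, number of double
bonds, and — for unsaturated FA — the position of the first double bond
from the methyl end. The parser accepts `w`, `ω` and `n-` for the omega
token, tolerates internal whitespace, and recognises `i`/`ai` (and the `a`
shorthand) for iso/anteiso branching; the canonical form is ASCII (`22:6w3`)
so labels survive CSV headers. An unsaturated FA without an omega position
parses but is flagged `omega_unknown`; such FA contribute to class sums but
are excluded (with a warning) from Σω3/Σω6.

Classification partitions FA into SFA, MUFA, PUFA and OBCFA, with OBCFA
(odd chain length or any branching) taking precedence over the
unsaturation classes so that the partition is exact. 18:1w7 is assigned to
OBCFA through an override registry rather than hard-coded logic, because
its membership in the bacterial-marker group is a convention, not a
structural fact; users can extend the registry with a two-column CSV.
LCPUFA is defined as chain ≥ 20 with ≥ 2 double bonds — EPA (20:5w3)
counts, consistent with how the term is used for crustacean nutrition.

## Compositional handling

Profiles are stored in percent (0–100), matching how FA tables are
printed; transforms convert to fractions internally. Raw peak areas are
closed per sample over the non-excluded FA, with the unmethylated 19:0
internal standard excluded by default at the I/O layer (it parses like any
FA; exclusion is a data-processing concern, not a grammar one). Incoming
tables whose rows deviate from 100 by more than 0.5 percentage points are
re-closed with a warning; smaller deviations are re-closed silently. The
arcsine square-root transform y = asin(√(p/100)) operates on fractions so
its codomain is the standard [0, π/2].

## Trophic-modification coefficients

For each treatment and FA, all consumer/food replicate pairs are divided
(the full Cartesian product — "all permutations" in the QFASA sense), and
the coefficient is the symmetric 10% trimmed mean: sort, drop
floor(0.10·n) values from each tail, average the rest. At n = 25 this
drops 2 per tail. Ratios with a zero food proportion are excluded before
trimming and reported as `n_dropped`; propagating infinities would let one
trace FA absent from one food replicate destroy the whole coefficient. The
standard error is sd/√n over the finite ratio set (the error bars shown
with log₁₀-ranked coefficient plots are not otherwise defined in the
literature this follows). Ranking is by descending coefficient within
treatment by default, with a pooled scope available for cross-treatment
displays. Ratios are computed on raw percent, not transformed values —
ratios of arcsine-transformed proportions have no interpretation.

Closure makes only coefficient *ratios* identifiable: if tissue is
t ∝ c ⊙ f re-closed, the observable ratio for FA i is cᵢ/Σⱼcⱼfⱼ. The
generator therefore records both the applied coefficients and these
post-closure expected ratios, and recovery is assessed against the latter.

## PERMANOVA

One-way sums of squares use the inter-point identities
SS_total = (1/n)Σ_{i<j}d² and SS_within = Σ_g(1/n_g)Σ_{i<j∈g}d², avoiding
explicit centroids. p-values use the (1+count)/(1+n_perm) estimator so
p is never zero; when the number of distinct relabelings is at most
n_perm, the null set is enumerated exactly and the exact p reported along
with the enumeration size. Permutations are unrestricted permutations of
raw observations. A group pattern with zero within-group variance yields
pseudo-F = +inf with the p-value still taken from permutations.

The two-way crossed design uses the Gower-centered inner-product matrix
G = −½ J D² J and hat-matrix projections of a sum-to-zero-coded model
matrix; each term's SS is tr((H_full − H_reduced)G) with the term's columns
dropped from the reduced model — marginal (type-III) sums of squares,
which coincide with the sequential partition when the design is balanced
(verified against a classical ANOVA oracle). Degrees of freedom are
computed from matrix ranks, so aliasing is handled naturally: when one
factor is a pure replicate of the other, the interaction has SS 0 and
df 0. Any other empty-cell pattern raises, since marginal main-effect
tests are then undefined. Each term is tested against the residual mean
square under permutation of the rows/columns of G.

Pairwise post-hoc comparisons report t = √(pseudo-F) on each group pair.
The optional Monte-Carlo p resamples 10 000 draws with replacement from
the permuted t distribution and takes the continuity-corrected tail
proportion — a documented stand-in for proprietary asymptotic-expansion
p-values in commercial software, useful when the exact permutation set is
too small to resolve small p.

Distances are Euclidean on either arcsine-√-transformed values (default)
or raw percent; pseudo-F is invariant to affine rescaling but not to the
transform itself, so both choices are exposed.

## NMDS

SMACOF majorization with monotone (primary-tie / weak) disparities:
configuration distances are PAVA-regressed on the rank order of the input
dissimilarities, ties broken by current distance, and the configuration is
updated by the Guttman transform. Stress is Kruskal stress-1,
√(Σ(d−d̂)²/Σd²). One metric start (classical scaling on the doubly
centered squared distances) plus `n_starts` seeded random starts;
convergence is a stress change below `tol` (default 1e-9) within
`max_iter` (300). The best configuration is centered and rotated to
principal axes. Centroid-shift vectors (food → consumer) are computed in
any coordinate space — the ordination for display, or the full
transformed-FA space for an ordination-free, reproducible magnitude.

## Univariate comparisons

One-way ANOVA on transformed proportions with Tukey HSD via the
studentized-range distribution (Tukey–Kramer for unequal n, as group sizes
of 4–7 are typical here). Compact letters come from the interval sweep
over means sorted descending: each maximal run of consecutively ranked,
pairwise non-significant groups shares a letter. Indices that are already
ratios (Σω3/Σω6) are analysed untransformed.

## Synthetic data generator

The generator emulates a feeding assay: a 42-FA baseline registry
(dominated by 16:0 at 26.4%, 20:5w3 at 16.6%, 18:0 at 13.2%, 22:6w3 at
11.4% and 18:1w9 at 7.0%, with class sums ≈ 43/12/35/10 for
SFA/MUFA/PUFA/OBCFA) is perturbed per treatment by a log-normal factor
(σ = 0.3) to produce distinct food means; consumer means apply the
treatment's coefficient vector under closure; replicates are Dirichlet
draws around each mean. Dirichlet noise was chosen because it respects
closure and non-negativity with a single concentration parameter.

Concentrations default to 2000 for consumers and 13600 for foods. Both
are derived from printed replicate spreads in the motivating system: crab
DHA 14.3 ± 0.7% implies SD ≈ 0.75 points at p = 0.143 (concentration
≈ 2000), while food pellets subsampled from one homogenized stock show
14.3 ± 0.3% (≈ 13600). The default coefficient pattern enriches 18:1w9,
18:1w7 and the abundant (≥1%) LCPUFA except 22:5w3 (coefficients 1.5–1.6)
and mildly dilutes the rest (0.7–0.85), mirroring the observed retention
pattern.

The factorial wild-survey generator (3 locations × 2 months, n = 4 per
cell by default) applies multiplicative per-FA effects per level; with no
effects every cell shares one mean, giving an exchangeable null used for
type-I-error calibration.

What the generator does **not** emulate: chromatographic co-elution and
identification error, compositional correlation structure beyond what
closure plus Dirichlet induces, between-individual variation in the
modification coefficients themselves, and growth/survival outcomes.
Passing recovery tests therefore demonstrate estimator correctness under
a well-specified replicate model, not robustness to instrument artefacts.

## Problem sizes and numerical choices

Simulation-based checks use 1000 replicates for type-I-error calibration
(exact enumeration of a 4/5 two-group design — unbalanced because a
balanced 4/4 split's exact null cannot attain p near 0.05) and 100
simulated assays for coefficient recovery; both finish in seconds while
giving Monte-Carlo error well inside the asserted bands. Permutation
counts default to 9999. Floating-point ties in permutation counting use a
relative tolerance of 1e-12 in favour of the null. The trimmed-mean count
uses floor; the plausible alternatives (10% total rather than per tail;
rounding rather than flooring at n = 25) are conventions the
implementation deliberately fixes, since the trimmed-mean literature this
follows removes a fraction per tail.

## Known limitations

- Type-III permutation tests permute raw observations; restricted
  (residual) permutation schemes are not implemented.
- The Monte-Carlo pairwise p is a resampling construction, not the
  asymptotic expansion used by commercial PERMANOVA software; the two
  agree in rank but not necessarily in the extreme tail.
- Coefficient recovery for trace FA (< 0.3% of total) is noisy at
  realistic replicate dispersions; the recovery guarantee is about the
  median FA, not every FA.
- Only Euclidean distances are provided; the biomarker workflow this
  package supports does not use Bray–Curtis or other dissimilarities.
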