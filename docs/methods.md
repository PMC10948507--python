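# Methods

This note documents the models, conventions, and numerical choices behind
`salicore`, and what the synthetic-data generator does and does not emulate.

## Trait derivation

Growth rates are linear interval means over fixed measurement days (DAS =
days after starting the stress treatment): shoot growth rate
GR = mean((h₇ − h₂)/5, (h₁₇ − h₂)/15) cm/day, leaf expansion rate
LER = mean((L₇ − L₂)/5, (L₁₂ − L₂)/10) cm/day, and leaf gain
NIL = leaves₁₇ − leaves₁. The salt tolerance index of a growth trait is
STI = stress/control, with the salt-injury index SII = 1 − STI.

Replicates are averaged per genotype × treatment *before* the ratio is
formed (ratio of means). This is robust to single-replicate zero controls;
a genotype whose control mean is non-positive gets a missing ratio for that
trait and an entry in the exclusion report rather than an infinite index.
Genotypes missing a whole treatment arm are excluded with a warning.

Water content defaults to the fresh-mass basis (fresh − dry)/fresh × 100.
Published seedling panels report water-content scales that no single
convention reproduces (shoot means near 15% are far below what fresh-basis
water content of living tissue usually gives), so the formula is
configurable (`fresh_basis` | `dry_basis`) and the default is an explicit
assumption rather than a claim.

Trait directions: larger Sen, SNC, RNC, SN/RN, SKC and RKC indicate *less*
tolerant material; the remaining eight traits point the other way. The map
is user-overridable (`directions.yaml`) because the protective role of K⁺
retention is debatable — the default follows the assignment used when the
14-trait membership evaluation was introduced for these species.

## Dose–response

Mean SII (averaged over pilot genotypes with equal weights) is regressed on
NaCl concentration by ordinary least squares; the 50%-injury concentration
is the line's inverse at SII = 0.5. All supplied concentration points enter
the fit, including a 0 mM control (SII ≡ 0 by construction) when present —
whether to include it is a judgment call; excluding it simply means passing
four points instead of five. The screening recommendation takes the
candidate level minimizing mean absolute distance to the per-trait
50%-injury concentrations, breaking ties toward the level with the largest
senescence-score variance (diversity of response is what makes a level
informative for screening). Nonlinear (logistic/4PL) dose–response models
are out of scope.

## Membership scoring and classification

Membership values are min–max normalized per trait over the supplied table
(so D is invariant to any increasing affine rescaling of a trait column),
flipped for negative-direction traits; D is the unweighted mean over
traits. A zero-range trait is uninformative and is set to membership 0.5
with a warning instead of failing the whole table.

Grades come from agglomerative clustering of the one-dimensional D values
(Euclidean distance, complete linkage by default; single/average/ward
selectable) with the tree cut at height 0.12. Linkage is configurable
because cluster counts at a fixed cut depend on it; complete linkage is the
package default as the most common conservative choice for tight grade
bands. If the cut yields more than five clusters, the two clusters with
closest mean D are merged until five remain, preserving the five-grade
taxonomy; fewer clusters are spread over the grade scale by rank
(3 clusters → HST/MST/HSS), and a degenerate single cluster is labelled
MST. Grade mean D is strictly decreasing from HST to HSS by construction.

## Predictive model

`fit_tolerance_model` regresses D on trait columns by OLS (statsmodels).
The default fixed predictor set is the seven-trait combination
(SNC, RNIL, RWC, RGR, RKC, Sen, RNC) of the bundled reference model, which
guarantees the published model structure is reproducible; a forward
stepwise mode (largest partial F, entry p < 0.05) is provided for model
discovery, with the entry rule stated as this package's convention. The
design condition number is reported and a collinearity warning attached
above 10⁸. Predictions report full precision and a 4-decimal rounding,
matching the precision at which reference Y values are printed.

The reference coefficients, their standard errors and the 15-genotype
verification rows ship as text fixtures (`src/salicore/data/`); the test
suite confirms every verification prediction agrees with its printed Y
value within the 0.0005 rounding tolerance.

## Core selection

With all 14 traits numeric, Gower distance is the range-normalized
Manhattan distance averaged over traits, so d ∈ [0, 1]; zero-range traits
are dropped with a warning. Objectives: E-NE (mean distance from each core
entry to its nearest other entry, maximized) and A-NE (mean distance from
every accession to its nearest entry, minimized), combined as
0.5·E-NE − 0.5·A-NE on the raw Gower scale. Both objectives already live on
the same [0, 1] scale, so no internal renormalization is applied; an
optional min–max normalization against random-subset baselines can be
layered on by callers who need it. Core size is round-half-up of
fraction × N (0.20 of 318 → 64).

The search is parallel tempering over k-subsets: 4 replicas on a geometric
temperature ladder (10⁻⁴ to 5×10⁻², chosen to bracket typical objective
deltas of 10⁻³ on Gower-scaled instances), one-swap moves with Metropolis
acceptance, periodic adjacent-replica exchange, and termination after a
patience of 5,000 consecutive proposed moves without improving the best
objective. Patience-based termination (rather than a wall-clock budget)
makes the result a pure function of the seed. The temperature schedule is
this package's own; no equivalence with other core-selection software's
internals is claimed. `exhaustive_core` enumerates all subsets (budget
C(N,k) ≤ 10⁶, lexicographic tie-break) and serves as the independent
optimum oracle in tests; on 10-genotype instances with k = 3 the tempered
search attains the enumerated optimum in ≥ 95% of seeded runs.

## Core validation

Metric conventions (several circulate in the core-collection literature):

- MD% = |mean_core − mean_entire| / mean_entire × 100 (entire-set mean as
  denominator);
- CR% = range_core/range_entire × 100 — never above 100 for a true subset;
- VR% = CV_core/CV_entire × 100;
- **VD% = |CV_core − CV_entire| / CV_core × 100**, a CV difference rather
  than a variance ratio. This definition is stated prominently because it
  is the one consistent with the bundled benchmark table, where every
  (VR, VD) pair satisfies VD = (VR − 100)/VR × 100 whenever the core is the
  more variable set.

Shannon–Weaver diversity defaults to distinct-value classes in natural log,
bounded by ln(sample size) — the scheme under which a panel of n mostly
unique values approaches ln n (ln 318 = 5.76, ln 64 = 4.16, matching the
bands the benchmark reports); an equal-width fixed-bin scheme is available
for conventional use. Ties are counted as shared classes.

The mean comparison uses the studentized-range (Newman–Keuls) statistic
with two groups, q = |t|·√2 on the pooled t — algebraically a pooled
two-sample t-test, implemented through `scipy.stats.studentized_range`.
Levene's test uses the Brown–Forsythe median-centered variant; the Wilcoxon
rank-sum test is exact up to n = 25 per sample and uses the
continuity-corrected normal approximation beyond. PCA is an
eigendecomposition of the correlation matrix of within-set standardized
traits, components ordered by eigenvalue with each component's
largest-magnitude loading made positive.

## Synthetic data

`simulate_trait_table` draws from a Gaussian copula: correlated standard
normals (default correlation: the eight strongest published pairs, e.g.
SWC–RWC +0.73, Sen–SNC +0.66, Sen–RNIL −0.52, zeros elsewhere, repaired to
the nearest PSD matrix by eigenvalue clipping) pushed through skew-normal
marginals (shape |a| = 4, sign from the trait's reported skew) solved to
hit each trait's published mean and CV, then truncated to the published
min–max range via the truncated CDF. Kurtosis is not matched, and only the
skew *sign* is targeted. The default marginals are the 14-trait moments of
a 318-genotype seedling screen (e.g. SNC mean 126.00 mg/g, CV 0.21).

What this emulates: realistic trait scales, dispersion, bounded ranges,
mild skew, and the sign structure of the strongest trait correlations.
What it does not: genotype relatedness, replicate-level measurement error
(except in `simulate_raw_trial`), species substructure, and the full
correlation matrix — the PSD repair attenuates the planted coefficients
somewhat (e.g. a target of 0.66 realizes near 0.58 at n = 300). Passing
tests therefore demonstrate correctness of the *pipeline* under a faithful
statistical caricature, not recovery of any particular real panel's
results; published per-trait results that depend on the raw data (class
counts, per-trait benchmark metrics, the 144.5/153.7 mM half-injury fits)
are correspondingly validated through identities and parameter-recovery
simulations rather than re-derivation.

`simulate_raw_trial` plants known stress/control ratios and reconstructs
consistent height/leaf time series with multiplicative replicate noise, so
assembly recovers the planted ratios exactly at zero noise.
`simulate_clustered_panel` places cluster centroids at equal spacings with
jitter capped so that, *after* Gower's range normalization, centroids stay
at least `separation` apart and within-cluster spread stays below
`separation/4`.

## Problem sizes and determinism

Test and acceptance runs use n = 300–318 synthetic panels for scoring and
recovery checks, 10-genotype instances for exhaustive-oracle comparisons,
and 50–100 seed replicates for Monte-Carlo recovery — sizes at which every
statistical check is stable under the pinned seeds. All generators and the
core search are pure functions of (inputs, seed); pipeline reruns with the
same config and seed are bit-identical, and the run manifest records input
checksums, the seed, and aggregated warnings.

## Known limitations

- Gower distance supports numeric (interval) traits only; categorical
  support would require the general Gower formulation.
- The stepwise entry rule and the complete-linkage default are conventions,
  not re-derivations of how the reference model/grades were originally
  obtained.
- SWC/RWC formula ambiguity (above) means absolute water-content values are
  convention-dependent; ratios and memberships are unaffected within a
  convention.
- The membership min/max are computed over whatever table is supplied, so D
  values are panel-relative; scoring a new genotype against an old panel
  requires re-using that panel's min/max (not yet automated).
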