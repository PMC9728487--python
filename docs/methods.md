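# Methods

## The problem

A washed *E. coli* culture suddenly deprived of carbon loses viability
exponentially, and the decay constant — the death rate, per day — depends
strongly on how the cells grew beforehand. Because slowing growth
reorganizes most of the proteome, almost every protein correlates or
anticorrelates with survival in any single perturbation, and no single
comparison can say which proteins matter. The approach implemented here
combines many growth perturbations: a protein that rises whenever survival
improves, across catabolic limitation, anabolic limitation, ribosome
limitation, rich medium and stationary phase, accumulates evidence that no
single condition could provide.

## Data model

Conditions are organized in a three-level hierarchy: a **perturbation**
(one biological axis, labelled C, A, R, L, S) contains one or more
**datasets** (a group of conditions measured together, e.g. one
repository's carbon-source series), and a dataset contains **conditions**,
each carrying a death rate (per day) and a pre-starvation growth rate
(per hour). Within a dataset, all C(n,2) condition pairs are compared,
each oriented from the higher-death to the lower-death condition, so a
positive fold change always means "more abundant where survival is
better". Ties in death rate are broken lexicographically on the condition
id and logged.

## Differential stage

Peptide intensities are rolled up to protein level as the log2 of the sum
of present peptide intensities per sample; a protein-sample cell with no
present peptide stays absent rather than zero. Data quantified against a
heavy spike-in channel are first converted to pseudo-intensities:
(light / heavy) × the median of that peptide's heavy intensities over all
samples, dropping measurements whose heavy partner is missing or
non-positive.

Each ordered pair is then tested per protein. The default test is a
**moderated two-sample test**: the per-protein pooled variance is shrunk
toward a prior estimated across all proteins by empirical Bayes (the
Smyth 2004 moment estimators for the prior degrees of freedom d0 and scale
s0²), and the statistic is referred to a t distribution with d + d0
degrees of freedom (a normal when the observed variance spread is
chi-squared-pure and d0 is infinite). Moderation matters here for a
specific reason: the scoring layer transforms each p-value back into a
normal quantile and then adds those quantiles assuming unit variances and
a covariance of 0.5 between pairs sharing a condition. An unmoderated
Welch t at 3-4 replicates, pushed through that transform, produces
Z-values with sd ≈ 0.97 and pair-to-pair covariance ≈ 0.44 rather than
0.5, quietly mis-normalizing every merged score. With variance shrinkage
the effective degrees of freedom are large and the transform is calibrated
(covariance ≈ 0.49-0.50, merged sd ≈ 1.00 in the star design; see
`scripts/acceptance.py`). A plain Welch t-test remains available via
`method="welch"` (with a median-variance floor for degenerate exact ties);
it is useful for sensitivity analysis, not as the default.

P-values are clamped to (1e-15, 1], capping |Z| near 8; the inverse-normal
transform diverges as p → 0 and a single saturated test should not
dominate a merged score. A pair statistic is emitted only when both
conditions have at least `min_replicates = 2` present values (a
two-sample test is undefined below that).

## Scoring stage

For each protein and pair, Z = sgn(log2FC) · Φ⁻¹(1 − p/2) (the input p is
two-sided by default; `tail="one"` switches to Φ⁻¹(1 − p)). Z is exactly 0
when FC = 0 or p = 1. The |Z| ≥ 1.28 significance threshold used in
pairwise classification corresponds to a one-sided p of 0.1.

Merging proceeds in three Stouffer-type steps, each a sum of Z-values
divided by the standard deviation of that sum:

1. **pairs → dataset**: σ_C is the square root of the summed covariance
   matrix over the *present* pairs. The default rule assigns 1 to an
   identical pair, 0.5 to pairs sharing one condition in the same role
   (α=γ XOR β=δ) and 0 otherwise. The `signed` variant additionally
   assigns −0.5 when the shared condition appears in opposite roles
   (β=γ or α=δ); that is the exact covariance of standardized mean
   differences, and it is what makes chain designs (c1c2, c2c3, …)
   exactly unit-variance. The default rule treats opposite-role sharing
   as independent, so under chain designs the merged sd deviates slightly
   from 1; the star design (all pairs against one reference) is exact
   under both rules. Both rules are exposed; the default reproduces the
   published procedure, and the signed matrix is PSD-checked.
2. **datasets → perturbation**: datasets are independent, σ_D = √(number
   of datasets present).
3. **perturbations → Survival score**: σ_P = √(n_P) over the
   perturbations actually measured for that protein; n_P is reported next
   to the score. Missing levels never contribute to the numerator or the
   denominator, which keeps the score defined for sparsely measured
   proteins at the cost of larger weight on whatever was measured.

## Enrichment stage

The background is restricted to proteins scored in at least 3 of the 5
perturbations (k configurable) — sparsely measured proteins have unstable
scores. Gene sets come from GMT files or from an OBO ontology plus GAF
annotations, propagating each annotation to every ancestor reachable via
is_a / part_of (the subgraph is checked to be acyclic; obsolete terms and
NOT-qualified annotations are skipped). Enrichment is a two-sample
Kolmogorov-Smirnov test of member scores against non-member scores —
two-sample because the quantity of interest is the difference between a
set and the background of all proteins — one-sided toward higher scores
by default, with scipy's exact small-sample p where applicable. Sets with
fewer than 5 scored members are not tested (KS is degenerate there).
Benjamini-Hochberg correction is applied per namespace family (processes
and compartments separately, mirroring how such results are usually
listed); ΔSurvival score is the member median minus the background
median.

## Phenotype stage

Death rates are the negative slope of an OLS fit of ln(CFU/ml) against
time, using points within the first 10 days of starvation and stopping at
the first measurement below 10⁷ CFU/ml (that point and all later points
are excluded — after the initial exponential phase mutant takeover
stabilizes viability and later points are uninformative). Replicates are
fit jointly as repeated observations. The growth-death relation
death = a·exp(b·growth) is fit by OLS of ln(death) on growth; R² is
computed in log space (defined as 0 when the death rates are constant).

## Abundance stage

Mass estimate = synthesis-rate proxy × molecular weight, in arbitrary
proxy units — only mass *fractions* are interpreted. Condition-specific
masses scale the reference estimate by linear fold changes; proteins
without a fold change carry the reference mass by default (the reference
proteome is the baseline) or can be omitted. A set's mass fraction is its
summed mass over the summed mass of all quantified proteins.

## Synthetic data

The generator emulates the statistical structure the pipeline consumes,
with known ground truth:

* log2 intensity of peptide k, protein i, condition c, replicate r is
  μ_i + b_k + θ_i·s(c) + ε, with μ_i ~ N(24, 2) (typical MS log2
  intensities), peptide offsets b_k ~ N(0, 1), replicate noise
  ε ~ N(0, 0.5), and θ_i = 1 log2-unit for the 100 planted proteins of
  2000 (0 otherwise). Defaults are the conditions at which recovery is
  assessed; all are configurable.
* the survival covariate s(c) is −log(death rate), min-max rescaled to
  [0, 1] within each perturbation, so planted abundance decreases
  monotonically in death rate and the largest planted fold change within
  a dataset is exactly θ.
* peptide counts per protein are 1 + Poisson(mean − 1) with mean 3;
  values are reported on the linear scale.
* missingness is logistic dropout in log2 intensity (width 1 log2-unit),
  with the midpoint solved so the expected overall missing fraction
  matches `missing_rate` (default 0.1); low intensities drop
  preferentially, as in low-coverage proteomes.
* the spike-in variant adds a heavy channel whose expected level depends
  on the peptide but not the condition, present wherever the light value
  is.
* condition hierarchies draw death rates log-uniformly in
  (0.05, 1.6)/day — a plausible span for sudden carbon starvation after
  fast vs slow growth; the published conditions do not pin this range
  numerically, so it is the package's choice — and derive growth rates
  from death = 0.04/day · exp(3 h · growth) for nutrient-class
  perturbations and the mirrored decreasing relation for ribosome
  limitation, reproducing the two exponential branches of the
  growth-death plane. The fastest-growing condition of each dataset is
  flagged as the glucose-like reference.
* viability series decay as n0·exp(−death rate·t) with mean-unbiased
  lognormal counting noise of a given CV.
* gene sets: one set holding exactly the planted proteins plus uniform
  decoy sets. Decoys are drawn from a seed stream decoupled from the
  peptide generator's (callers often reuse one seed, and the generator's
  first draw is the planted-id choice — an identically seeded stream
  would clone the planted set into decoy #1).

All randomness flows from explicitly passed seeds through
`numpy.random.default_rng`; identical configs give byte-identical output
files.

What the generator does **not** emulate: instrument artifacts (retention
time, charge states, match-between-runs), shared peptides between
proteins, correlated biological regulation between non-planted proteins,
dataset-specific batch effects, or the long-term stationary phase after
the exponential death regime. Passing tests therefore demonstrate that
the statistics are implemented and calibrated as specified — not that the
pipeline is robust to every pathology of real repository data.

## Problem sizes and numerical choices

Calibration checks (`scripts/acceptance.py`, `tests/test_acceptance.py`)
use 6,000-12,000 null proteins at 4 replicates — enough that the Monte
Carlo error of a covariance estimate (~0.013) is small against the ±0.05
bands being checked. Recovery checks use 10 independent seeds of a
2,000-measurement study (400 proteins, 7 datasets, 3 conditions each, 4
replicates, 10% missingness) at the planted effect of 1 log2-unit and
noise sd 0.5, requiring the planted median Survival score to exceed the
null 99th percentile and the planted set to reach FDR < 0.05 while ≥95%
of decoy sets do not. The Monte-Carlo oracle for the signed covariance
rule uses 200,000 draws (relative sd error ~0.2% against the 2% band).

Known limitations: the default covariance rule under-corrects chain
designs (see above); the moderated test assumes peptide-level noise is
roughly log-normal; the GO closure treats is_a and part_of identically
and ignores other relation types; protein inference from shared peptides
is out of scope (each peptide maps to one protein id).
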