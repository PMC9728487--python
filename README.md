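# survscore

Score every protein for its correlation with bacterial starvation
survival across growth perturbations.

When *E. coli* is washed into carbon-free medium, viability decays
exponentially at a death rate set by the prior growth condition. Because
slowing growth reorganizes most of the proteome, almost every protein
correlates with survival in any one comparison. `survscore` implements
the statistical machinery to combine *many* perturbations — catabolic
limitation, anabolic limitation, ribosome limitation, rich medium,
stationary phase — into one composite per-protein **Survival score**,
for proteomicists and microbial physiologists who want to rank candidate
survival genes from label-free peptide-intensity data.

## The score

For each ordered condition pair αβ (α the higher-death condition) the
differential stage yields a fold change and p-value per protein, turned
into a signed Z-value

    Z_αβ = sgn(log2FC) · Φ⁻¹(1 − p/2)

so positive Z means "more abundant where survival is better". Z-values
are merged upward, each step dividing a sum by the standard deviation of
that sum:

    Z_i^D = Σ_αβ Z_αβ / σ_C      σ_C² = Σ cov(αβ, γδ)   (pairs of a dataset)
    Z_j^P = Σ_i Z_i^D / √n_D                            (datasets of a perturbation)
    Z^S   = Σ_j Z_j^P / √n_P                            (perturbations; the Survival score)

with cov = 1 for an identical pair, 0.5 for pairs sharing one condition
in the same role, 0 otherwise (a `signed` variant adds −0.5 for
opposite-role sharing). Missing pairs, datasets or perturbations drop out
of both numerator and denominator, so sparsely measured proteins still
get a score, with `n_P` reported alongside. Downstream, gene sets are
tested for a shift of member scores toward higher values (two-sample KS,
signed scores, BH-FDR), death rates are fit by log-linear OLS over the
first 10 days and above 10⁷ CFU/ml, and set mass fractions are computed
from synthesis-rate × molecular-weight proxies.

The differential stand-in is a moderated two-sample test (empirical-Bayes
variance shrinkage); `docs/methods.md` explains why moderation is what
keeps the merging arithmetic calibrated at 3-4 replicates, and documents
every stage, default and limitation.

## Worked example

The `analysis/` scripts run the whole study on synthetic data with known
ground truth (100 planted survival proteins of 2,000, effect +1
log2-unit per unit of survival covariate, 4 replicates, 10% missing
values, 7 datasets over 5 perturbations):

```
python analysis/01_simulate.py
python analysis/02_differential.py
python analysis/03_survival_scores.py
python analysis/04_enrichment.py
python analysis/05_death_rates.py
python analysis/06_mass_fractions.py
```

which prints, among other things:

```
41298 (protein, pair) stats over 7 datasets -> results/pair_stats.tsv
scored 1997 proteins -> results/survival_scores.tsv
median Survival score: planted 6.64 vs null 0.01 (null 99th pct 2.14)
background: 1988 proteins with n_P >= 3
  planted_survival n=100 delta=+6.57 p=2.99e-166 FDR=1.23e-164
1 of 41 sets at FDR < 0.05 -> results/enrichment.tsv
fit 21 conditions; median |rate error| 0.025/day at counting-noise CV 0.2
nutrient-class relation: death = 0.040/day * exp(3.00 h * growth), R^2 = 1.000
```

Read: planted proteins score far above the null distribution (median 6.64
against a null 99th percentile of 2.14); of 41 gene sets only the planted
one is significant after FDR correction; death rates recovered from noisy
viability counts are accurate to ~0.03/day; and the fitted growth-death
relation returns the generating parameters. The same stages are available
as a CLI (`survscore simulate|diffexp|score|enrich|deathrate|growthdeath|massfrac|run`)
for real peptide tables (native TSV or MaxQuant `peptides.txt` columns),
condition metadata, GMT or OBO+GAF gene sets, and viability CSVs.

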