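"""Synthetic proteomics and viability data with known ground truth.

Emulates the statistical structure of multi-repository label-free
proteomics over a perturbation -> dataset -> condition hierarchy:
replicated log-normal peptide intensities, a subset of "planted" proteins
whose abundance rises monotonically with starvation survival (i.e. falls
with death rate), intensity-dependent missingness, an optional heavy
spike-in channel, gene sets containing the planted proteins, and
exponentially decaying viability counts.  Everything is driven by one
seeded generator so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .enrichment import GeneSet
from .hierarchy import Condition, ConditionHierarchy
from .phenotype import ViabilitySeries

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "generate_condition_hierarchy",
    "simulate_peptide_matrix",
    "simulate_spikein_matrix",
    "simulate_viability_series",
    "emit_gene_sets",
]

# growth-death phenomenology: death = A_NUTRIENT * exp(B_SLOPE * growth)
# for nutrient-class perturbations, death = A_STRESS * exp(-B_SLOPE * growth)
# for proteome-stress ones (ribosome limitation).
A_NUTRIENT = 0.04  # per day
A_STRESS = 2.0  # per day
B_SLOPE = 3.0  # hours

STRESS_PERTURBATIONS = frozenset({"R", "O"})


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic peptide generator.

    effect_size is the log2 change of a planted protein per unit of the
    survival covariate s(c) in [0, 1]; replicate_noise_sd and
    peptide_offset_sd are in log2 units.
    """

    hierarchy: ConditionHierarchy
    seed: int = 0
    n_proteins: int = 2000
    n_planted: int = 100
    effect_size: float = 1.0
    mean_peptides_per_protein: float = 3.0
    n_replicates: int = 4
    replicate_noise_sd: float = 0.5
    peptide_offset_sd: float = 1.0
    base_log2_mean: float = 24.0
    base_log2_sd: float = 2.0
    missing_rate: float = 0.1
    dropout_scale: float = 1.0  # logistic width of the dropout curve, log2 units
    spikein: bool = False

    def __post_init__(self) -> None:
        if self.n_planted > self.n_proteins:
            raise ValueError("n_planted must not exceed n_proteins")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("n_proteins and n_replicates must be >= 1")
        if self.mean_peptides_per_protein < 1:
            raise ValueError("mean_peptides_per_protein must be >= 1")
        for name in ("replicate_noise_sd", "peptide_offset_sd", "base_log2_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError("missing_rate must lie in [0, 1]")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted: ids, per-protein effects, true means."""

    planted_ids: frozenset[str]
    effects: pd.Series  # log2 units per unit covariate; 0 for non-planted
    condition_means: pd.DataFrame  # protein x condition, true mean log2 level

    def __post_init__(self) -> None:
        eff = self.effects
        planted = eff.index.isin(self.planted_ids)
        if not (eff[planted] > 0).all():
            raise ValueError("planted proteins must have strictly positive effect")
        if not (eff[~planted] == 0).all():
            raise ValueError("non-planted proteins must have effect exactly 0")


def generate_condition_hierarchy(
    n_perturbations: int,
    datasets_per_perturbation: int | list[int],
    conditions_per_dataset: int | list[int],
    death_rate_range: tuple[float, float] = (0.05, 1.6),
    seed: int = 0,
    labels: list[str] | None = None,
) -> ConditionHierarchy:
    """Random but reproducible perturbation -> dataset -> condition tree.

    Death rates are drawn log-uniformly in ``death_rate_range``; growth
    rates follow the exponential growth-death relation (increasing with
    death rate for nutrient-class perturbations, decreasing for the
    ribosome-limitation class).  The fastest-growing condition of each
    dataset is flagged as the glucose-like reference.
    """
    if n_perturbations < 1:
        raise ValueError("n_perturbations must be >= 1")
    lo, hi = death_rate_range
    if not (0 < lo <= hi):
        raise ValueError("death_rate_range must be positive and ordered")

    if labels is None:
        labels = (
            list("CARLS")[:n_perturbations]
            if n_perturbations <= 5
            else [f"P{i + 1}" for i in range(n_perturbations)]
        )
    if len(labels) != n_perturbations:
        raise ValueError("labels length must equal n_perturbations")

    if isinstance(datasets_per_perturbation, int):
        datasets_per_perturbation = [datasets_per_perturbation] * n_perturbations
    if len(datasets_per_perturbation) != n_perturbations:
        raise ValueError("datasets_per_perturbation length mismatch")
    if any(n < 1 for n in datasets_per_perturbation):
        raise ValueError("dataset counts must be >= 1")

    n_datasets = sum(datasets_per_perturbation)
    if isinstance(conditions_per_dataset, int):
        conditions_per_dataset = [conditions_per_dataset] * n_datasets
    if len(conditions_per_dataset) != n_datasets:
        raise ValueError("conditions_per_dataset length mismatch")
    if any(n < 1 for n in conditions_per_dataset):
        raise ValueError("condition counts must be >= 1")

    rng = np.random.default_rng(seed)
    conds: list[Condition] = []
    ds_cursor = 0
    for pert, n_ds in zip(labels, datasets_per_perturbation):
        stress = pert in STRESS_PERTURBATIONS
        for d in range(n_ds):
            n_c = conditions_per_dataset[ds_cursor]
            ds_cursor += 1
            dataset_id = f"{pert}_d{d + 1}"
            drs = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_c))
            if stress:
                growth = np.log(A_STRESS / drs) / B_SLOPE
            else:
                growth = np.log(drs / A_NUTRIENT) / B_SLOPE
            ref = int(np.argmax(growth))
            for k in range(n_c):
                conds.append(
                    Condition(
                        condition_id=f"{dataset_id}_c{k + 1}",
                        dataset_id=dataset_id,
                        perturbation=pert,
                        death_rate=float(drs[k]),
                        growth_rate=float(growth[k]),
                        is_reference=(k == ref),
                    )
                )
    return ConditionHierarchy(conds)


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def _sample_log2_core(config: SimulationConfig, rng: np.random.Generator):
    """Shared sampling: returns (row index, protein index array, true log2
    means per protein x condition, peptide offsets, condition ids)."""
    h = config.hierarchy
    cond_ids = [c.condition_id for c in h.conditions]
    s = h.survival_covariate().reindex(cond_ids).to_numpy()

    proteins = _protein_ids(config.n_proteins)
    planted = rng.choice(config.n_proteins, size=config.n_planted, replace=False)
    effects = np.zeros(config.n_proteins)
    effects[planted] = config.effect_size
    if config.n_planted and config.effect_size <= 0:
        raise ValueError("planted proteins require a strictly positive effect_size")

    n_pep = 1 + rng.poisson(config.mean_peptides_per_protein - 1.0, config.n_proteins)
    prot_idx = np.repeat(np.arange(config.n_proteins), n_pep)
    pep_ids = [
        f"{proteins[i]}_pep{k + 1}"
        for i, m in enumerate(n_pep)
        for k in range(m)
    ]
    mu = rng.normal(config.base_log2_mean, config.base_log2_sd, config.n_proteins)
    b = rng.normal(0.0, config.peptide_offset_sd, prot_idx.size)

    # protein-level true mean log2 per condition
    cond_means = mu[:, None] + np.outer(effects, s)

    rows = pd.MultiIndex.from_arrays(
        [pep_ids, [proteins[i] for i in prot_idx]], names=["peptide", "protein"]
    )
    truth = GroundTruth(
        planted_ids=frozenset(proteins[i] for i in planted),
        effects=pd.Series(effects, index=pd.Index(proteins, name="protein")),
        condition_means=pd.DataFrame(
            cond_means, index=pd.Index(proteins, name="protein"), columns=cond_ids
        ),
    )
    return rows, prot_idx, cond_means, b, cond_ids, truth


def _dropout_mask(
    log2_values: np.ndarray, rate: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask of entries to drop; low intensities drop preferentially.

    P(drop | x) = sigmoid((x0 - x) / scale) with x0 chosen so the expected
    overall dropout fraction equals ``rate``.
    """
    if rate <= 0:
        return np.zeros(log2_values.shape, dtype=bool)
    if rate >= 1:
        return np.ones(log2_values.shape, dtype=bool)
    flat = log2_values.ravel()

    def mean_drop(x0: float) -> float:
        return float(expit((x0 - flat) / scale).mean()) - rate

    lo, hi = flat.min() - 60 * scale, flat.max() + 60 * scale
    x0 = brentq(mean_drop, lo, hi)
    return rng.random(log2_values.shape) < expit((x0 - log2_values) / scale)


def simulate_peptide_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Replicated peptide intensities on the linear scale, plus ground truth.

    log2 intensity of peptide k of protein i in condition c, replicate r is
    mu_i + b_k + theta_i * s(c) + eps with eps ~ N(0, replicate_noise_sd).
    A fraction ``missing_rate`` of entries is absent, preferentially at low
    intensity (logistic dropout).
    """
    rng = np.random.default_rng(config.seed)
    rows, prot_idx, cond_means, b, cond_ids, truth = _sample_log2_core(config, rng)

    n_pep, n_cond, n_rep = prot_idx.size, len(cond_ids), config.n_replicates
    log2 = (
        cond_means[prot_idx][:, :, None]
        + b[:, None, None]
        + rng.normal(0.0, config.replicate_noise_sd, (n_pep, n_cond, n_rep))
    )
    values = np.exp2(log2)
    drop = _dropout_mask(log2, config.missing_rate, config.dropout_scale, rng)
    values[drop] = np.nan

    cols = pd.MultiIndex.from_product(
        [cond_ids, range(1, n_rep + 1)], names=["condition", "replicate"]
    )
    table = pd.DataFrame(values.reshape(n_pep, -1), index=rows, columns=cols)
    return table, truth


def simulate_spikein_matrix(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Light intensities paired with a condition-independent heavy channel.

    The heavy channel mimics a uniformly mixed isotope-labelled reference:
    its expected level depends on the peptide (mu_i + b_k) but not on the
    condition, and a heavy value is present wherever the light one is.
    """
    if not config.spikein:
        raise ValueError("spikein matrix requested but config.spikein is False")
    rng = np.random.default_rng(config.seed)
    rows, prot_idx, cond_means, b, cond_ids, truth = _sample_log2_core(config, rng)

    n_pep, n_cond, n_rep = prot_idx.size, len(cond_ids), config.n_replicates
    light_log2 = (
        cond_means[prot_idx][:, :, None]
        + b[:, None, None]
        + rng.normal(0.0, config.replicate_noise_sd, (n_pep, n_cond, n_rep))
    )
    base = cond_means[prot_idx].mean(axis=1)  # condition-averaged true level
    heavy_log2 = (
        base[:, None, None]
        + b[:, None, None]
        + rng.normal(0.0, config.replicate_noise_sd, (n_pep, n_cond, n_rep))
    )
    light = np.exp2(light_log2)
    heavy = np.exp2(heavy_log2)
    drop = _dropout_mask(light_log2, config.missing_rate, config.dropout_scale, rng)
    light[drop] = np.nan
    heavy[drop] = np.nan

    cols = pd.MultiIndex.from_product(
        [cond_ids, range(1, n_rep + 1), ["light", "heavy"]],
        names=["condition", "replicate", "channel"],
    )
    stacked = np.stack([light, heavy], axis=-1).reshape(n_pep, -1)
    table = pd.DataFrame(stacked, index=rows, columns=cols)
    return table, truth


def simulate_viability_series(
    death_rate: float,
    n0: float,
    days: list[float] | np.ndarray,
    noise_cv: float = 0.0,
    seed: int = 0,
    condition_id: str = "sim",
    replicate: str = "r1",
) -> ViabilitySeries:
    """CFU/ml decaying as n0 * exp(-death_rate * t) with lognormal noise.

    noise_cv is the coefficient of variation of the multiplicative counting
    noise; the lognormal is mean-unbiased so E[count] equals the decay curve.
    """
    days = np.asarray(days, dtype=float)
    if death_rate < 0:
        raise ValueError("death_rate must be >= 0")
    if n0 <= 0:
        raise ValueError("n0 must be > 0")
    if (days < 0).any():
        raise ValueError("days must be non-negative")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    expected = n0 * np.exp(-death_rate * days)
    if noise_cv > 0:
        sigma2 = math.log(1.0 + noise_cv**2)
        rng = np.random.default_rng(seed)
        noise = np.exp(rng.normal(-sigma2 / 2.0, math.sqrt(sigma2), days.size))
        counts = expected * noise
    else:
        counts = expected
    return ViabilitySeries(
        condition_id=condition_id,
        replicate=replicate,
        times=days,
        cfu=counts,
    )


def emit_gene_sets(
    truth: GroundTruth,
    n_decoy_sets: int,
    set_size: int,
    seed: int = 0,
) -> list[GeneSet]:
    """One set holding exactly the planted proteins plus uniform decoy sets."""
    if set_size < 1:
        raise ValueError("set_size must be >= 1")
    universe = list(truth.effects.index)
    if set_size > len(universe):
        raise ValueError("set_size exceeds the number of simulated proteins")
    if n_decoy_sets < 0:
        raise ValueError("n_decoy_sets must be >= 0")
    # separate stream from the peptide generator: callers often reuse the
    # simulation seed, and the first draw there already picked the planted
    # ids, so an identically seeded stream would clone the planted set
    rng = np.random.default_rng((seed, 0x675E75))
    sets = [
        GeneSet(
            set_id="planted_survival",
            name="planted survival proteins",
            namespace="custom",
            members=frozenset(truth.planted_ids),
        )
    ]
    width = max(3, len(str(n_decoy_sets)))
    for i in range(n_decoy_sets):
        members = rng.choice(len(universe), size=set_size, replace=False)
        sets.append(
            GeneSet(
                set_id=f"decoy_{i + 1:0{width}d}",
                name=f"decoy set {i + 1}",
                namespace="custom",
                members=frozenset(universe[j] for j in members),
            )
        )
    return sets
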