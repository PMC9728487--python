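"""Covariance-corrected hierarchical merging of Z-values into Survival scores.

Each protein's differential results are converted to signed Z-values
(sign from the fold change, magnitude from the p-value through the inverse
normal CDF) and merged upward in three Stouffer-type steps:

* condition pairs -> dataset: sum of pair Z divided by sigma_C, the square
  root of the summed covariance matrix of the pairs.  Two pairs drawn from
  the same conditions are correlated: the covariance is 1 for an identical
  pair, 0.5 when the pairs share one condition in the same role, and 0
  otherwise (the printed rule).  The ``signed`` variant additionally
  assigns -0.5 when the shared condition appears in opposite roles, which
  is the exact covariance of standardized mean differences and keeps chain
  designs unit-variance.
* datasets -> perturbation: datasets are independent, so sigma_D is the
  square root of the number of datasets present.
* perturbations -> Survival score: likewise, sigma_P = sqrt(n_P) over the
  perturbations actually measured; missing perturbations contribute
  neither to the sum nor to sigma_P.

Positive Survival scores mean abundance rises where starvation survival
is longer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .hierarchy import enumerate_ordered_pairs

__all__ = [
    "enumerate_ordered_pairs",
    "z_from_pair",
    "pair_covariance",
    "covariance_matrix",
    "merge_pairs_to_dataset",
    "merge_datasets_to_perturbation",
    "merge_to_survival_score",
    "score_proteins",
    "classify_pairwise",
    "ZTable",
]

DEFAULT_THRESHOLD = 1.28  # |Z| cut-off corresponding to one-sided P = 0.1


def z_from_pair(
    log2fc,
    pvalue,
    tail: str = "two",
    p_floor: float = 1e-15,
):
    """Signed Z-value of a differential observation (vectorized).

    |Z| is the upper quantile of the standard normal at the observed
    p-value — Phi^-1(1 - p/2) when the input p is two-sided (default),
    Phi^-1(1 - p) when it is one-sided — and the sign comes from the fold
    change.  Z is exactly 0 when the fold change is 0 or p = 1.
    """
    if tail not in ("two", "one"):
        raise ValueError(f"unknown tail convention {tail!r}")
    fc = np.asarray(log2fc, dtype=float)
    p = np.asarray(pvalue, dtype=float)
    if not np.all((p > 0) & (p <= 1)):
        raise ValueError("p-values must lie in (0, 1]")
    if not np.all(np.isfinite(fc)):
        raise ValueError("fold changes must be finite")
    p_eff = np.clip(p, p_floor, 1.0)
    q = p_eff / 2.0 if tail == "two" else p_eff
    mag = stats.norm.isf(q)
    mag = np.maximum(mag, 0.0)  # one-sided p > 0.5 carries no excess signal
    z = np.sign(fc) * mag
    z = np.where(p == 1.0, 0.0, z)
    if z.ndim == 0:
        return float(z)
    return z


def pair_covariance(
    pair1: tuple[str, str],
    pair2: tuple[str, str],
    rule: str = "paper",
    dataset1: str | None = None,
    dataset2: str | None = None,
) -> float:
    """Covariance between the Z-values of two ordered condition pairs.

    paper rule: 1 if the pairs are identical, 0.5 if they share exactly one
    condition in the same role (alpha=gamma XOR beta=delta), 0 otherwise.
    signed rule: additionally -0.5 per condition shared in opposite roles
    (beta=gamma or alpha=delta), the exact value for standardized mean
    differences.
    """
    if dataset1 is not None and dataset2 is not None and dataset1 != dataset2:
        raise ValueError(
            f"pairs from different datasets: {dataset1!r} vs {dataset2!r}"
        )
    if rule not in ("paper", "signed"):
        raise ValueError(f"unknown covariance rule {rule!r}")
    a1, b1 = pair1
    a2, b2 = pair2
    same = 0.5 * (float(a1 == a2) + float(b1 == b2))
    if rule == "paper":
        return same
    opposite = 0.5 * (float(b1 == a2) + float(a1 == b2))
    return same - opposite


def covariance_matrix(
    pairs: list[tuple[str, str]], rule: str = "paper"
) -> np.ndarray:
    """Covariance matrix over a dataset's ordered pairs under ``rule``.

    The signed variant is checked for positive semi-definiteness.
    """
    n = len(pairs)
    cov = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            cov[i, j] = cov[j, i] = pair_covariance(pairs[i], pairs[j], rule)
    if rule == "signed" and n:
        eig = np.linalg.eigvalsh(cov)
        if eig.min() < -1e-9:
            raise ValueError(
                f"signed covariance matrix not PSD for pairs {pairs} "
                f"(min eigenvalue {eig.min():.3g})"
            )
    return cov


def merge_pairs_to_dataset(
    pair_z: dict[tuple[str, str], float], rule: str = "paper"
) -> float:
    """Merge one protein's pair Z-values within a dataset: sum(Z) / sigma_C.

    Only present pairs enter both the sum and the covariance matrix.
    """
    if not pair_z:
        raise ValueError("need at least one pair Z-value")
    pairs = list(pair_z)
    var = float(covariance_matrix(pairs, rule).sum())
    if var <= 0:
        raise ValueError(
            f"non-positive merged variance ({var:.3g}) for pair set {pairs}"
        )
    return float(sum(pair_z.values()) / math.sqrt(var))


def merge_datasets_to_perturbation(dataset_z: list[float] | np.ndarray) -> float:
    """Merge dataset Z-values of one perturbation: sum / sqrt(n present)."""
    z = np.asarray(dataset_z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("need at least one dataset Z-value")
    return float(z.sum() / math.sqrt(z.size))


def merge_to_survival_score(
    perturbation_z: list[float] | np.ndarray,
) -> tuple[float, int]:
    """Merge perturbation Z-values into the Survival score, with n_P.

    Missing perturbations are excluded from both the sum and sigma_P.
    """
    z = np.asarray(perturbation_z, dtype=float)
    z = z[np.isfinite(z)]
    if z.size == 0:
        raise ValueError("no perturbation Z-values present; score is absent")
    return float(z.sum() / math.sqrt(z.size)), int(z.size)


@dataclass
class ZTable:
    """Per-protein Z-values at every level of the merging hierarchy."""

    pair_z: pd.DataFrame  # long: protein_id, dataset_id, pair, z
    dataset_z: pd.DataFrame  # long: protein_id, perturbation, dataset_id, z
    perturbation_z: pd.DataFrame  # wide: protein_id x perturbation
    scores: pd.DataFrame  # protein_id -> survival_score, n_perturbations

    def table(self) -> pd.DataFrame:
        """Wide export: one Z column per perturbation, n_perturbations,
        survival_score; absent values stay empty."""
        out = self.perturbation_z.copy()
        out.columns = [f"Z_{p}" for p in out.columns]
        out["n_perturbations"] = self.scores["n_perturbations"]
        out["survival_score"] = self.scores["survival_score"]
        return out.sort_index()


def _merge_dataset_block(
    zmat: np.ndarray, pairs: list[tuple[str, str]], rule: str
) -> np.ndarray:
    """Vectorized Eq-2 merge for one dataset.

    zmat is proteins x pairs with NaN for absent stats; sigma_C is computed
    once per distinct presence pattern.
    """
    cov = covariance_matrix(pairs, rule)
    present = np.isfinite(zmat)
    out = np.full(zmat.shape[0], np.nan)
    patterns, inverse = np.unique(present, axis=0, return_inverse=True)
    for k, pat in enumerate(patterns):
        if not pat.any():
            continue
        var = float(cov[np.ix_(pat, pat)].sum())
        if var <= 0:
            sel = [p for p, m in zip(pairs, pat) if m]
            raise ValueError(
                f"non-positive merged variance ({var:.3g}) for pair set {sel}"
            )
        rows = inverse == k
        out[rows] = np.nansum(zmat[rows][:, pat], axis=1) / math.sqrt(var)
    return out


def score_proteins(
    pair_stats: pd.DataFrame,
    rule: str = "paper",
    tail: str = "two",
    p_floor: float = 1e-15,
) -> ZTable:
    """Full merging pipeline from a long pair-stat table to Survival scores.

    ``pair_stats`` needs columns protein_id, perturbation, dataset_id,
    cond_high_death, cond_low_death, log2fc, pvalue (the differential
    stage's output).  Absent combinations are simply skipped at every
    level, per the missing-data rule.
    """
    required = {
        "protein_id",
        "perturbation",
        "dataset_id",
        "cond_high_death",
        "cond_low_death",
        "log2fc",
        "pvalue",
    }
    missing = required - set(pair_stats.columns)
    if missing:
        raise ValueError(f"pair_stats missing columns: {sorted(missing)}")
    df = pair_stats.copy()
    df["z"] = z_from_pair(
        df["log2fc"].to_numpy(), df["pvalue"].to_numpy(), tail=tail, p_floor=p_floor
    )

    ds_records = []
    for (pert, ds), grp in df.groupby(["perturbation", "dataset_id"], sort=True):
        wide = grp.pivot_table(
            index="protein_id",
            columns=["cond_high_death", "cond_low_death"],
            values="z",
            aggfunc="first",
        )
        pairs = [tuple(c) for c in wide.columns]
        merged = _merge_dataset_block(wide.to_numpy(dtype=float), pairs, rule)
        ds_records.append(
            pd.DataFrame(
                {
                    "protein_id": wide.index,
                    "perturbation": pert,
                    "dataset_id": ds,
                    "z": merged,
                }
            )
        )
    dataset_z = (
        pd.concat(ds_records, ignore_index=True)
        if ds_records
        else pd.DataFrame(columns=["protein_id", "perturbation", "dataset_id", "z"])
    )
    dataset_z = dataset_z.dropna(subset=["z"])

    # datasets -> perturbations (independent: sigma = sqrt(n present))
    grp = dataset_z.groupby(["protein_id", "perturbation"])["z"]
    pert_long = (grp.sum() / np.sqrt(grp.count())).rename("z").reset_index()
    perturbation_z = pert_long.pivot(
        index="protein_id", columns="perturbation", values="z"
    )

    # perturbations -> Survival score
    n_p = perturbation_z.notna().sum(axis=1)
    with np.errstate(invalid="ignore"):
        surv = perturbation_z.sum(axis=1, skipna=True) / np.sqrt(n_p)
    scores = pd.DataFrame(
        {"survival_score": surv, "n_perturbations": n_p.astype(int)}
    )
    scores = scores[scores["n_perturbations"] > 0]

    pair_long = df[
        [
            "protein_id",
            "perturbation",
            "dataset_id",
            "cond_high_death",
            "cond_low_death",
            "z",
        ]
    ].copy()
    return ZTable(
        pair_z=pair_long,
        dataset_z=dataset_z,
        perturbation_z=perturbation_z,
        scores=scores,
    )


def classify_pairwise(
    z_a: pd.Series,
    z_b: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
) -> tuple[pd.Series, dict[str, float]]:
    """Quadrant classification of two Z-value columns.

    Proteins significant in both columns (|Z| >= threshold) and agreeing in
    sign are ``correlated``; significant with opposite signs,
    ``anticorrelated``; anything else ``insignificant``.  Only proteins
    measured in both columns enter the fractions, which sum to 1.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    a, b = z_a.align(z_b, join="inner")
    both = a.notna() & b.notna()
    a, b = a[both], b[both]
    sig = (a.abs() >= threshold) & (b.abs() >= threshold)
    same_sign = np.sign(a) == np.sign(b)
    cats = pd.Series("insignificant", index=a.index, dtype=object)
    cats[sig & same_sign] = "correlated"
    cats[sig & ~same_sign] = "anticorrelated"
    n = len(cats)
    fractions = {
        k: (float((cats == k).sum()) / n if n else float("nan"))
        for k in ("correlated", "anticorrelated", "insignificant")
    }
    return cats, fractions
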