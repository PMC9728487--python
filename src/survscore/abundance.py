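"""Absolute protein mass estimates and gene-set mass fractions.

Protein synthesis rates (a copy-number proxy from ribosome profiling of a
reference condition) times molecular weight give a mass estimate per
protein; fold changes against the reference carry the estimate to other
conditions; a gene set's mass fraction is its summed mass over the summed
mass of all quantified proteins.  Masses are in arbitrary proxy units —
only fractions are interpreted.
"""

from __future__ import annotations

import logging

import pandas as pd

from .enrichment import GeneSet

logger = logging.getLogger(__name__)


def absolute_mass_estimates(
    synthesis_rates: pd.Series,
    molecular_weights: pd.Series,
) -> pd.Series:
    """mass = synthesis rate x molecular weight, joined on protein id.

    Proteins missing from either table are omitted (count logged);
    non-positive rates or weights reject the record.
    """
    rates = synthesis_rates.dropna()
    mws = molecular_weights.dropna()
    common = rates.index.intersection(mws.index)
    n_lost = len(rates.index.union(mws.index)) - len(common)
    if len(common) == 0:
        raise ValueError("no protein ids shared between rates and weights")
    if n_lost:
        logger.info("%d proteins present in only one table; omitted", n_lost)
    r = rates.loc[common]
    w = mws.loc[common]
    bad = (r <= 0) | (w <= 0)
    if bad.any():
        logger.warning("rejected %d records with non-positive rate or MW", int(bad.sum()))
    mass = (r * w)[~bad]
    mass.name = "mass"
    return mass.sort_index()


def scale_by_fold_change(
    masses: pd.Series,
    fold_changes: pd.Series,
    missing_policy: str = "carry",
) -> pd.Series:
    """Condition-specific masses: mass_c = mass_ref x FC_c (linear scale).

    Proteins without a fold change either carry the reference mass
    (``missing_policy='carry'``, the default — the reference proteome is the
    baseline) or are omitted (``'omit'``).
    """
    if missing_policy not in ("carry", "omit"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    fc = fold_changes.dropna()
    if (fc <= 0).any():
        raise ValueError("fold changes must be > 0 on the linear scale")
    fc_full = fc.reindex(masses.index)
    if missing_policy == "carry":
        fc_full = fc_full.fillna(1.0)
    scaled = (masses * fc_full).dropna()
    scaled.name = "mass"
    return scaled


def gene_set_mass_fraction(masses: pd.Series, gene_set: GeneSet) -> float:
    """Fraction of total proteome mass carried by the set's members."""
    total = float(masses.sum())
    if total <= 0:
        raise ValueError("total mass must be > 0")
    in_set = masses.index.isin(gene_set.members)
    if not in_set.any():
        logger.warning("gene set %s has no quantified members", gene_set.set_id)
        return 0.0
    return float(masses[in_set].sum()) / total
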