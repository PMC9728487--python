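"""End-to-end pipeline driver: simulate (optional) -> differential ->
score -> enrich (-> death rates, mass fractions when inputs are given).

Every output table carries a provenance header with the tool version, the
seed and the options that produced it, and all writers emit deterministic
row order, so one config plus one seed reproduces byte-identical results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import abundance as ab
from . import differential as de
from . import enrichment as en
from . import io as sio
from . import phenotype as ph
from . import scoring as sc
from . import synthetic as syn

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    outdir: str = "survscore_out"
    seed: int = 0
    # inputs; any left None and not simulated is skipped
    peptides: str | None = None
    peptide_dialect: str = "native"
    conditions: str | None = None
    gmt: str | None = None
    obo: str | None = None
    gaf: str | None = None
    viability: str | None = None
    synthesis_rates: str | None = None
    molecular_weights: str | None = None
    # stage options
    simulate: dict | None = None  # SimulationConfig overrides; None = use files
    diff_method: str = "moderated"
    min_replicates: int = 2
    covariance_rule: str = "paper"
    tail: str = "two"
    p_floor: float = 1e-15
    threshold: float = sc.DEFAULT_THRESHOLD
    min_k: int = 3
    min_set_size: int = 5
    enrich_side: str = "greater"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate_paths(self) -> None:
        if self.simulate is None:
            for name in ("peptides", "conditions"):
                p = getattr(self, name)
                if p is None:
                    raise ValueError(f"{name} path required unless simulating")
        for name in (
            "peptides",
            "conditions",
            "gmt",
            "obo",
            "gaf",
            "viability",
            "synthesis_rates",
            "molecular_weights",
        ):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ValueError(f"input path for {name} does not exist: {p}")


def default_hierarchy(seed: int = 0) -> "syn.ConditionHierarchy":
    """The five-perturbation layout of the study: catabolic limitation with
    three datasets, one dataset each for A, R, L and stationary phase."""
    return syn.generate_condition_hierarchy(
        n_perturbations=5,
        datasets_per_perturbation=[3, 1, 1, 1, 1],
        conditions_per_dataset=3,
        seed=seed,
    )


def simulate_bundle(config: PipelineConfig) -> dict[str, Path]:
    """Write a complete synthetic fixture bundle into outdir/fixtures."""
    outdir = Path(config.outdir) / "fixtures"
    outdir.mkdir(parents=True, exist_ok=True)
    overrides = dict(config.simulate or {})
    seed = int(overrides.pop("seed", config.seed))
    hierarchy = default_hierarchy(seed)
    n_decoys = int(overrides.pop("n_decoy_sets", 25))
    sim = syn.SimulationConfig(hierarchy=hierarchy, seed=seed, **overrides)
    table, truth = syn.simulate_peptide_matrix(sim)
    sets = syn.emit_gene_sets(
        truth, n_decoy_sets=n_decoys, set_size=sim.n_planted, seed=seed
    )
    series = [
        syn.simulate_viability_series(
            c.death_rate,
            n0=1e9,
            days=list(range(0, 11)),
            noise_cv=0.2,
            seed=seed + i,
            condition_id=c.condition_id,
            replicate="r1",
        )
        for i, c in enumerate(hierarchy.conditions)
    ]
    meta = {"seed": seed}
    paths = {
        "peptides": outdir / "peptides.tsv",
        "conditions": outdir / "conditions.tsv",
        "gmt": outdir / "gene_sets.gmt",
        "viability": outdir / "viability.csv",
        "truth": outdir / "ground_truth.tsv",
    }
    sio.write_peptide_table(table, paths["peptides"], meta=meta)
    sio.write_condition_table(hierarchy, paths["conditions"], meta=meta)
    sio.write_gmt(sets, paths["gmt"])
    sio.write_viability_csv(series, paths["viability"])
    truth_df = truth.effects.rename("true_effect").to_frame()
    truth_df["planted"] = truth_df.index.isin(truth.planted_ids).astype(int)
    truth_df.index.name = "protein_id"
    sio.write_scores(truth_df, paths["truth"], meta=meta)
    return paths


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute all stages for which inputs exist; returns output paths."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        fixture_paths = simulate_bundle(config)
        config.peptides = str(fixture_paths["peptides"])
        config.conditions = str(fixture_paths["conditions"])
        if config.gmt is None:
            config.gmt = str(fixture_paths["gmt"])
        if config.viability is None:
            config.viability = str(fixture_paths["viability"])
    config.validate_paths()

    meta = {
        "seed": config.seed,
        "covariance": config.covariance_rule,
        "tail": config.tail,
        "diff_method": config.diff_method,
    }
    outputs: dict[str, Path] = {}

    logger.info("stage: differential")
    table = sio.read_peptide_table(config.peptides, dialect=config.peptide_dialect)
    hierarchy = sio.read_condition_table(config.conditions)
    if "channel" in (table.columns.names or []):
        table = de.spikein_pseudo_intensities(table)
    abund = de.protein_rollup(table)
    pair_stats = de.all_pair_stats(
        abund,
        hierarchy,
        min_replicates=config.min_replicates,
        method=config.diff_method,
        p_floor=config.p_floor,
    )
    outputs["pair_stats"] = outdir / "pair_stats.tsv"
    sio.write_pair_stats(pair_stats, outputs["pair_stats"], meta=meta)

    logger.info("stage: scoring")
    ztab = sc.score_proteins(
        pair_stats, rule=config.covariance_rule, tail=config.tail, p_floor=config.p_floor
    )
    score_table = ztab.table()
    score_table.index.name = "protein_id"
    outputs["scores"] = outdir / "survival_scores.tsv"
    sio.write_scores(score_table, outputs["scores"], meta=meta)

    sets = None
    if config.gmt or (config.obo and config.gaf):
        logger.info("stage: enrichment")
        sets = sio.read_annotation_files(gmt=config.gmt, obo=config.obo, gaf=config.gaf)
        background = en.filter_min_perturbations(
            score_table.rename(columns={"survival_score": "survival_score"}),
            k=config.min_k,
        )
        enr = en.enrich_gene_sets(
            sets,
            background,
            side=config.enrich_side,
            min_size=config.min_set_size,
        )
        outputs["enrichment"] = outdir / "enrichment.tsv"
        sio.write_enrichment(enr, outputs["enrichment"], meta=meta)

    if config.viability:
        logger.info("stage: death rates")
        series = sio.read_viability_csv(config.viability)
        rows = []
        by_cond: dict[str, list] = {}
        for s in series:
            by_cond.setdefault(s.condition_id, []).append(s)
        for cond, ss in sorted(by_cond.items()):
            fit = ph.fit_death_rate(ss)
            rows.append(
                {
                    "condition_id": cond,
                    "death_rate_per_day": fit.death_rate,
                    "intercept_ln_cfu": fit.intercept,
                    "n_points": fit.n_points,
                    "r_squared": fit.r_squared,
                }
            )
        fits = pd.DataFrame(rows)
        outputs["death_rates"] = outdir / "death_rates.tsv"
        sio._write_tsv(fits, outputs["death_rates"], meta, index=False)
        # growth-death relation over the hierarchy's nutrient-class conditions
        hframe = hierarchy.to_frame()
        nutrient = hframe[~hframe["perturbation"].isin(syn.STRESS_PERTURBATIONS)]
        if len(nutrient) >= 3:
            gd = ph.fit_growth_death_exponential(
                nutrient["growth_rate_per_h"], nutrient["death_rate_per_day"]
            )
            gd_df = pd.DataFrame(
                [
                    {
                        "amplitude_per_day": gd.amplitude,
                        "slope_hours": gd.slope,
                        "r_squared": gd.r_squared,
                    }
                ]
            )
            outputs["growth_death"] = outdir / "growth_death_fit.tsv"
            sio._write_tsv(gd_df, outputs["growth_death"], meta, index=False)

    if config.synthesis_rates and config.molecular_weights:
        logger.info("stage: mass fractions")
        rates = pd.read_csv(
            config.synthesis_rates, sep="\t", comment="#", index_col=0
        ).iloc[:, 0]
        mws = pd.read_csv(
            config.molecular_weights, sep="\t", comment="#", index_col=0
        ).iloc[:, 0]
        masses = ab.absolute_mass_estimates(rates, mws)
        frac_rows = []
        for gs in sets or []:
            frac_rows.append(
                {
                    "set_id": gs.set_id,
                    "mass_fraction": ab.gene_set_mass_fraction(masses, gs),
                }
            )
        outputs["mass_fractions"] = outdir / "mass_fractions.tsv"
        sio._write_tsv(pd.DataFrame(frac_rows), outputs["mass_fractions"], meta, False)

    logger.info("pipeline complete: %s", sorted(outputs))
    return outputs
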