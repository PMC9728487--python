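"""Abundance stage: absolute mass estimates from synthetic synthesis-rate
proxies and molecular weights, scaled to each condition by the generator's
true fold changes, and gene-set mass fractions per condition.

Reads results/fixtures/, writes results/mass_fractions.tsv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from survscore import abundance as ab
from survscore import io as sio

OUT = Path(__file__).resolve().parent.parent / "results"
SEED = 20260926


def main() -> None:
    fixtures = OUT / "fixtures"
    if not fixtures.exists():
        sys.exit("run analysis/01_simulate.py first")
    truth = sio.read_scores(fixtures / "ground_truth.tsv")
    hierarchy = sio.read_condition_table(fixtures / "conditions.tsv")
    sets = sio.read_gmt(fixtures / "gene_sets.gmt")
    planted = next(s for s in sets if s.set_id == "planted_survival")

    # synthetic synthesis rates (lognormal copies/time) and weights (Da)
    rng = np.random.default_rng(SEED)
    proteins = truth.index
    rates = pd.Series(rng.lognormal(5.0, 1.5, len(proteins)), index=proteins)
    mws = pd.Series(rng.uniform(10_000, 150_000, len(proteins)), index=proteins)
    masses = ab.absolute_mass_estimates(rates, mws)

    # condition fold changes implied by the planted effects: the covariate
    # moves planted proteins by effect * s(c) log2-units from the reference
    s = hierarchy.survival_covariate()
    ref = {c.dataset_id: c.condition_id for c in hierarchy.conditions if c.is_reference}
    rows = []
    for cond in hierarchy.conditions:
        ds_ref = ref[cond.dataset_id]
        delta_s = s[cond.condition_id] - s[ds_ref]
        fc = pd.Series(
            np.exp2(truth["true_effect"].to_numpy() * delta_s), index=proteins
        )
        cond_masses = ab.scale_by_fold_change(masses, fc)
        rows.append(
            {
                "condition_id": cond.condition_id,
                "death_rate_per_day": cond.death_rate,
                "planted_mass_fraction": ab.gene_set_mass_fraction(
                    cond_masses, planted
                ),
            }
        )
    frac = pd.DataFrame(rows).sort_values("death_rate_per_day")
    sio._write_tsv(frac, OUT / "mass_fractions.tsv", {"seed": SEED}, False)
    print(
        "planted-set mass fraction ranges from "
        f"{frac['planted_mass_fraction'].min():.3f} (fast death) to "
        f"{frac['planted_mass_fraction'].max():.3f} (slow death) "
        "-> mass_fractions.tsv"
    )


if __name__ == "__main__":
    sys.exit(main())
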