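import numpy as np
import pandas as pd
import pytest

from survscore.hierarchy import Condition, ConditionHierarchy
from survscore.synthetic import SimulationConfig, generate_condition_hierarchy


def single_dataset_hierarchy(death_rates: dict[str, float]) -> ConditionHierarchy:
    """One perturbation, one dataset, conditions with the given death rates."""
    return ConditionHierarchy(
        [
            Condition(
                condition_id=cid,
                dataset_id="D1",
                perturbation="C",
                death_rate=dr,
                growth_rate=1.0,
                is_reference=(i == 0),
            )
            for i, (cid, dr) in enumerate(death_rates.items())
        ]
    )


@pytest.fixture
def carls_hierarchy():
    """Layout mirroring the study: C with three datasets, A/R/L/S one each."""
    return generate_condition_hierarchy(
        n_perturbations=5,
        datasets_per_perturbation=[3, 1, 1, 1, 1],
        conditions_per_dataset=3,
        seed=7,
    )


@pytest.fixture
def chain3_hierarchy():
    return single_dataset_hierarchy({"c1": 0.5, "c2": 0.3, "c3": 0.1})


def make_abundances(data: dict[str, dict[str, list[float]]]) -> pd.DataFrame:
    """Protein-level log2 abundance frame from {protein: {condition: reps}}."""
    records = {}
    for prot, conds in data.items():
        row = {}
        for cond, reps in conds.items():
            for r, v in enumerate(reps, start=1):
                row[(cond, r)] = v
        records[prot] = row
    df = pd.DataFrame.from_dict(records, orient="index")
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["condition", "replicate"])
    df.index.name = "protein"
    return df.astype(float)


def null_peptide_config(hierarchy, n_proteins=5000, seed=0, **kw):
    """Null (no planted structure) complete-data simulation config."""
    defaults = dict(
        hierarchy=hierarchy,
        seed=seed,
        n_proteins=n_proteins,
        n_planted=0,
        effect_size=0.0,
        n_replicates=4,
        replicate_noise_sd=0.5,
        missing_rate=0.0,
    )
    defaults.update(kw)
    return SimulationConfig(**defaults)
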