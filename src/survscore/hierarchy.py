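"""Growth-condition hierarchy: perturbations -> datasets -> conditions.

Each condition is one pre-starvation growth environment carrying the
death rate measured after carbon runs out (per day) and the growth rate
during the preceding exponential phase (per hour).  Conditions measured
together form a dataset; datasets probing the same kind of physiological
perturbation (catabolic limitation, anabolic limitation, ribosome
limitation, rich medium, stationary phase) form a perturbation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Condition:
    condition_id: str
    dataset_id: str
    perturbation: str
    death_rate: float  # per day, >= 0
    growth_rate: float  # per hour
    is_reference: bool = False

    def __post_init__(self) -> None:
        if self.death_rate < 0:
            raise ValueError(
                f"condition {self.condition_id!r}: death rate must be >= 0, "
                f"got {self.death_rate}"
            )


@dataclass
class ConditionHierarchy:
    """Validated container for the perturbation -> dataset -> condition tree."""

    conditions: list[Condition] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        dataset_pert: dict[str, str] = {}
        for c in self.conditions:
            if c.condition_id in seen:
                raise ValueError(f"duplicate condition id {c.condition_id!r}")
            seen.add(c.condition_id)
            prev = dataset_pert.setdefault(c.dataset_id, c.perturbation)
            if prev != c.perturbation:
                raise ValueError(
                    f"dataset {c.dataset_id!r} spans perturbations "
                    f"{prev!r} and {c.perturbation!r}"
                )

    # -- lookups ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.conditions)

    @property
    def perturbations(self) -> list[str]:
        out: list[str] = []
        for c in self.conditions:
            if c.perturbation not in out:
                out.append(c.perturbation)
        return out

    @property
    def dataset_ids(self) -> list[str]:
        out: list[str] = []
        for c in self.conditions:
            if c.dataset_id not in out:
                out.append(c.dataset_id)
        return out

    def datasets_of(self, perturbation: str) -> list[str]:
        return [
            d
            for d in self.dataset_ids
            if self.perturbation_of_dataset(d) == perturbation
        ]

    def perturbation_of_dataset(self, dataset_id: str) -> str:
        for c in self.conditions:
            if c.dataset_id == dataset_id:
                return c.perturbation
        raise KeyError(dataset_id)

    def conditions_of(self, dataset_id: str) -> list[Condition]:
        return [c for c in self.conditions if c.dataset_id == dataset_id]

    def condition(self, condition_id: str) -> Condition:
        for c in self.conditions:
            if c.condition_id == condition_id:
                return c
        raise KeyError(condition_id)

    def death_rates(self) -> dict[str, float]:
        return {c.condition_id: c.death_rate for c in self.conditions}

    # -- survival covariate ---------------------------------------------

    def survival_covariate(self) -> pd.Series:
        """Per-condition survival covariate s(c) in [0, 1].

        s(c) = -log(death rate), min-max rescaled within each perturbation,
        so s increases as conditions become longer-lived.  A perturbation
        whose conditions all share one death rate gets the neutral 0.5.
        """
        rows = {}
        for pert in self.perturbations:
            conds = [c for c in self.conditions if c.perturbation == pert]
            raw = np.array([-np.log(max(c.death_rate, 1e-12)) for c in conds])
            span = raw.max() - raw.min()
            scaled = (raw - raw.min()) / span if span > 0 else np.full_like(raw, 0.5)
            for c, s in zip(conds, scaled):
                rows[c.condition_id] = s
        return pd.Series(rows, name="survival_covariate")

    # -- frame conversion -------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_id": [c.condition_id for c in self.conditions],
                "dataset_id": [c.dataset_id for c in self.conditions],
                "perturbation": [c.perturbation for c in self.conditions],
                "growth_rate_per_h": [c.growth_rate for c in self.conditions],
                "death_rate_per_day": [c.death_rate for c in self.conditions],
                "is_reference": [int(c.is_reference) for c in self.conditions],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ConditionHierarchy":
        required = {
            "condition_id",
            "dataset_id",
            "perturbation",
            "growth_rate_per_h",
            "death_rate_per_day",
            "is_reference",
        }
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"condition table missing columns: {sorted(missing)}")
        conds = [
            Condition(
                condition_id=str(r.condition_id),
                dataset_id=str(r.dataset_id),
                perturbation=str(r.perturbation),
                death_rate=float(r.death_rate_per_day),
                growth_rate=float(r.growth_rate_per_h),
                is_reference=bool(int(r.is_reference)),
            )
            for r in df.itertuples(index=False)
        ]
        return cls(conds)


def enumerate_ordered_pairs(
    death_rates: dict[str, float],
) -> list[tuple[str, str]]:
    """All C(n,2) condition pairs, each oriented high-death -> low-death.

    Conditions are ranked by death rate (descending); every combination is
    compared in an increasing manner, adjacent comparisons first, so three
    conditions give [(c1,c2), (c2,c3), (c1,c3)].  Ties in death rate are
    broken lexicographically on the condition id and logged.
    """
    if len(death_rates) < 2:
        raise ValueError("need at least 2 conditions to form a pair")
    for cid, dr in death_rates.items():
        if not np.isfinite(dr):
            raise ValueError(f"non-finite death rate for condition {cid!r}")
    by_rate: dict[float, list[str]] = {}
    for cid, dr in death_rates.items():
        by_rate.setdefault(dr, []).append(cid)
    for dr, ids in by_rate.items():
        if len(ids) > 1:
            logger.warning(
                "death-rate tie at %g among %s; breaking lexicographically",
                dr,
                sorted(ids),
            )
    ranked = sorted(death_rates, key=lambda cid: (-death_rates[cid], cid))
    idx = {cid: i for i, cid in enumerate(ranked)}
    pairs = list(itertools.combinations(ranked, 2))
    pairs.sort(key=lambda p: (idx[p[1]] - idx[p[0]], idx[p[0]]))
    return pairs
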