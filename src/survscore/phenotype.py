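"""Death-rate estimation from viability time series and the exponential
growth-death relation.

Viability of a washed, suddenly starved culture decays exponentially, so
the death rate is the negative slope of an ordinary least-squares fit of
ln(CFU/ml) against time.  The fit uses the first ``window_days`` days and
stops at the first measurement below the viability floor (after long
starvation mutants take over and the decay is no longer exponential, so
late points are uninformative about the initial death rate).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_WINDOW_DAYS = 10.0
DEFAULT_FLOOR = 1e7  # CFU/ml


@dataclass
class ViabilitySeries:
    """One replicate's CFU/ml counts over days of starvation."""

    condition_id: str
    replicate: str
    times: np.ndarray  # days, strictly increasing
    cfu: np.ndarray  # CFU/ml, > 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.cfu = np.asarray(self.cfu, dtype=float)
        if self.times.shape != self.cfu.shape:
            raise ValueError("times and cfu must have equal length")
        if (self.times < 0).any():
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if (self.cfu <= 0).any():
            raise ValueError("viability counts must be > 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "condition_id": self.condition_id,
                "replicate": self.replicate,
                "time_days": self.times,
                "cfu_per_ml": self.cfu,
            }
        )


@dataclass(frozen=True)
class DeathRateFit:
    death_rate: float  # per day; positive = exponential decay
    intercept: float  # ln CFU/ml at t = 0
    n_points: int
    r_squared: float
    window_days: float
    floor: float


@dataclass(frozen=True)
class GrowthDeathFit:
    """death = amplitude * exp(slope * growth); R^2 in log space."""

    amplitude: float  # per day
    slope: float  # hours
    r_squared: float


def _truncate(series: ViabilitySeries, window_days: float, floor: float):
    """Apply the fitting window: keep t <= window and stop at the first
    point below the floor (that point and everything after is excluded)."""
    t, v = series.times, series.cfu
    below = np.nonzero(v < floor)[0]
    if below.size:
        t, v = t[: below[0]], v[: below[0]]
    keep = t <= window_days
    return t[keep], v[keep]


def fit_death_rate(
    series: ViabilitySeries | list[ViabilitySeries],
    window_days: float = DEFAULT_WINDOW_DAYS,
    floor: float = DEFAULT_FLOOR,
) -> DeathRateFit:
    """OLS fit of ln(viability) vs time; death rate is the negative slope.

    Several replicates may be passed; they are fit jointly as repeated
    observations.  Raises when fewer than two usable points survive the
    truncation rules.
    """
    series_list = [series] if isinstance(series, ViabilitySeries) else list(series)
    if not series_list:
        raise ValueError("no viability series given")
    ts, vs = [], []
    for s in series_list:
        t, v = _truncate(s, window_days, floor)
        ts.append(t)
        vs.append(v)
    t = np.concatenate(ts)
    v = np.concatenate(vs)
    label = ", ".join(
        f"{s.condition_id}/{s.replicate}" for s in series_list
    )
    if t.size < 2 or np.unique(t).size < 2:
        raise ValueError(
            f"viability series [{label}]: fewer than 2 usable points after "
            f"applying window <= {window_days} d and floor >= {floor:g} CFU/ml"
        )
    res = stats.linregress(t, np.log(v))
    return DeathRateFit(
        death_rate=float(-res.slope),
        intercept=float(res.intercept),
        n_points=int(t.size),
        r_squared=float(res.rvalue**2),
        window_days=window_days,
        floor=floor,
    )


def fit_growth_death_exponential(
    growth_rates,
    death_rates,
) -> GrowthDeathFit:
    """Fit death = a * exp(b * growth) by OLS of ln(death) on growth."""
    g = np.asarray(growth_rates, dtype=float)
    d = np.asarray(death_rates, dtype=float)
    if g.shape != d.shape:
        raise ValueError("growth and death arrays must match in length")
    if g.size < 3:
        raise ValueError("need at least 3 (growth, death) points")
    if (d <= 0).any():
        raise ValueError("death rates must be > 0 for a log-space fit")
    y = np.log(d)
    slope, intercept = np.polyfit(g, y, 1)
    resid = y - (intercept + slope * g)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if ss_tot == 0 else 1.0 - float((resid**2).sum()) / ss_tot
    return GrowthDeathFit(
        amplitude=float(np.exp(intercept)),
        slope=float(slope),
        r_squared=max(0.0, r2),
    )
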