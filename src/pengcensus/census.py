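"""Calibration of automated counts and archipelago-wide abundance estimation.

Automated UAV counts are calibrated against manual validation counts with a
per-site simple linear regression (manual ~ detected); per-island counts
carry N-class precision labels whose relative half-widths are propagated by
Monte Carlo to an archipelago-wide 95% confidence interval.  The regional
baseline (the management subarea's abundance excluding this archipelago) is
a fixed published figure used to express the archipelago's share.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .field_counts import PrecisionClass

__all__ = [
    "CalibrationModel",
    "SiteCount",
    "CensusEstimate",
    "RegionalBaseline",
    "fit_calibration",
    "apply_calibration",
    "sum_census",
    "propagate_error",
    "regional_share",
    "load_table1",
]

SPECIES = ("adeliae", "papua", "antarctica", "atriceps")


@dataclass(frozen=True)
class CalibrationModel:
    """Per-site linear map from detected counts to estimated true nests."""

    site_id: str
    slope: float
    intercept: float
    residual_scale: float       # sqrt(RSS / (n - 2)), nests
    n_plots: int
    x_mean: float = 0.0         # mean detected count over validation plots
    sxx: float = 1.0            # sum of squared deviations of detected counts

    def __post_init__(self):
        if self.n_plots < 2:
            raise ValueError("calibration needs at least two validation plots")
        if self.residual_scale < 0:
            raise ValueError("residual scale must be non-negative")


@dataclass(frozen=True)
class SiteCount:
    """One island x species census record (mirrors a census-table row)."""

    island_id: str
    species: str
    count: int
    precision: PrecisionClass
    method: str = "ground"      # ground | photo | uav

    def __post_init__(self):
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.method not in ("ground", "photo", "uav"):
            raise ValueError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class CensusEstimate:
    """Archipelago total with a Monte-Carlo 95% confidence interval."""

    total: int
    ci_low: int
    ci_high: int
    level: float = 0.95
    n_reps: int = 0
    seed: int | None = None
    error_interpretation: str = "normal95"

    def __post_init__(self):
        if not (self.ci_low <= self.total <= self.ci_high):
            raise ValueError("CI must contain the point estimate")


@dataclass(frozen=True)
class RegionalBaseline:
    """Published abundance of the surrounding subarea, excluding this survey."""

    label: str = "CCAMLR 48.1 excluding Danger Islands"
    pairs: int = 606526
    ci: tuple[int, int] = (322477, 990402)


# ---------------------------------------------------------------------------
# Calibration (simple linear regression of manual on detected)
# ---------------------------------------------------------------------------

def fit_calibration(plots, site_id: str = "") -> CalibrationModel:
    """OLS of manual validation counts on detected counts for one site.

    ``plots`` is a sequence of (detected, manual) pairs.  The residual
    scale uses n-2 degrees of freedom and is defined as 0 when n=2 (an
    exact two-point line).
    """
    arr = np.asarray(list(plots), dtype=float).reshape(-1, 2)
    n = len(arr)
    if n < 2:
        raise ValueError("need at least two validation plots")
    x, y = arr[:, 0], arr[:, 1]
    sxx = float(np.sum((x - x.mean()) ** 2))
    if sxx == 0:
        raise ValueError("degenerate design: detected counts all equal")
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (slope * x + intercept)
    rss = float(np.sum(resid**2))
    scale = math.sqrt(rss / (n - 2)) if n > 2 else 0.0
    return CalibrationModel(site_id, slope, intercept, scale, n,
                            float(x.mean()), sxx)


def apply_calibration(
    model: CalibrationModel, detected_total: int
) -> tuple[int, float]:
    """Map a detected count to (estimated nests, relative uncertainty).

    The relative uncertainty is the half-width of the t-based prediction
    interval at the detected value divided by the estimate; it feeds the
    N-class assignment of automated counts.
    """
    if detected_total < 0:
        raise ValueError("detected_total must be non-negative")
    raw = model.slope * detected_total + model.intercept
    if raw <= 0 and detected_total > 0:
        warnings.warn(
            f"calibrated estimate {raw:.1f} non-positive for "
            f"{detected_total} detections; forcing 0"
        )
    est = max(0, int(round(raw)))
    if model.n_plots > 2 and model.residual_scale > 0:
        tcrit = stats.t.ppf(0.975, model.n_plots - 2)
        half = tcrit * model.residual_scale * math.sqrt(
            1 + 1 / model.n_plots
            + (detected_total - model.x_mean) ** 2 / model.sxx
        )
    else:
        half = 0.0
    rel = half / est if est > 0 else (math.inf if half > 0 else 0.0)
    return est, rel


# ---------------------------------------------------------------------------
# Aggregation and error propagation
# ---------------------------------------------------------------------------

def load_table1() -> list[SiteCount]:
    """The packaged census-summary table as SiteCount records."""
    with resources.files("pengcensus.data").joinpath(
        "table1_census.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return [
        SiteCount(r.island, r.species, int(r.count),
                  PrecisionClass.from_label(r.precision), r.method)
        for r in df.itertuples()
    ]


def _one_per_island(site_counts, species: str) -> list[SiteCount]:
    rows = [s for s in site_counts if s.species == species]
    seen = set()
    for s in rows:
        key = (s.island_id, s.species)
        if key in seen:
            raise ValueError(f"duplicate record for {key}")
        seen.add(key)
    return rows

def sum_census(site_counts, species: str = "adeliae") -> int:
    """Integer sum of per-island counts for one species."""
    return int(sum(s.count for s in _one_per_island(site_counts, species)))


def propagate_error(
    site_counts,
    interpretation: str = "normal95",
    n_reps: int = 100_000,
    seed: int = 0,
    species: str = "adeliae",
    half_width_override: dict[str, float] | None = None,
) -> CensusEstimate:
    """Monte-Carlo propagation of per-island N-class errors to a 95% CI.

    Per replicate each island's count is drawn independently with its
    class's relative half-width h: under ``normal95`` the half-width is
    read as 1.96 standard deviations of a normal (sd = h*count/1.96); under
    ``uniform`` as the half-width of a uniform on [count(1-h), count(1+h)].
    Draws are truncated at zero.  The CI is the empirical 2.5/97.5
    percentile range of the replicate totals; the point estimate stays the
    deterministic sum.

    ``half_width_override`` maps precision labels to replacement relative
    half-widths (e.g. ``{"N1": 0.0}`` for a degenerate sensitivity mode).
    """
    if n_reps < 1000:
        raise ValueError("n_reps must be at least 1000")
    if interpretation not in ("normal95", "uniform"):
        raise ValueError(f"unknown error interpretation {interpretation!r}")
    rows = _one_per_island(site_counts, species)
    total = sum(s.count for s in rows)
    rng = np.random.default_rng(seed)
    counts = np.array([s.count for s in rows], dtype=float)
    override = half_width_override or {}
    hw = np.array([
        override.get(s.precision.label, s.precision.half_width) for s in rows
    ])
    if interpretation == "normal95":
        sd = hw * counts / 1.96
        draws = rng.normal(counts, sd, size=(n_reps, len(rows)))
    else:
        lo = counts * (1 - hw)
        hi = counts * (1 + hw)
        draws = rng.uniform(lo, hi, size=(n_reps, len(rows)))
    draws = np.clip(draws, 0.0, None)
    totals = draws.sum(axis=1)
    lo_q, hi_q = np.percentile(totals, [2.5, 97.5])
    return CensusEstimate(
        int(total), int(round(lo_q)), int(round(hi_q)),
        0.95, n_reps, seed if isinstance(seed, int) else None, interpretation,
    )


def regional_share(total: int, baseline: RegionalBaseline | None = None) -> float:
    """Percent of the regional population held by the surveyed archipelago.

    Returns the unrounded percentage 100*T/(T+baseline); round for the
    headline presentation value.
    """
    if total < 0:
        raise ValueError("total must be non-negative")
    baseline = baseline or RegionalBaseline()
    if total == 0:
        return 0.0
    return 100.0 * total / (total + baseline.pairs)
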