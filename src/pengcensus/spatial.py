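"""Nearest-neighbour spatial filtering of nest detections.

Colonially nesting penguins are strongly clustered: within a sub-colony the
nearest-neighbour (NN) distance is short and tightly distributed, while
detector false positives (rocks, shadows, lone walking birds) form an
approximately spatially random field whose NN distances are much larger.
The filter exploits this: a detection is retained iff at least ``m`` other
detections lie within radius ``r`` of it, with ``r`` chosen from the
empirical NN-distance distribution.

The filter is applied in a single pass against the *original* detection
set.  Iterating it to a fixed point would progressively erode colony
edges, so the pipeline never does; see the methods note.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial import cKDTree

from .detection import DetectionSet

__all__ = ["FilterRule", "nn_distances", "fit_filter_rule", "apply_filter"]

DEFAULT_RADIUS = 1.5     # metres; fallback when a data-driven fit degenerates
DEFAULT_MIN_NEIGHBORS = 2


@dataclass(frozen=True)
class FilterRule:
    """Retention rule: keep a point iff >= min_neighbors others within radius."""

    radius: float
    min_neighbors: int = DEFAULT_MIN_NEIGHBORS
    method: str = "fixed"            # fixed | quantile | mixture-crossover

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.min_neighbors < 1:
            raise ValueError("min_neighbors must be at least 1")

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "FilterRule":
        return cls(**json.loads(text))


def _points(detections) -> np.ndarray:
    if isinstance(detections, DetectionSet):
        return detections.points
    return np.asarray(detections, dtype=float).reshape(-1, 2)


def nn_distances(points, k: int = 1) -> np.ndarray:
    """Distance from each point to its k-th nearest other point (metres)."""
    pts = _points(points)
    if len(pts) < k + 1:
        raise ValueError(f"need at least {k + 1} points for k={k}")
    tree = cKDTree(pts)
    d, _ = tree.query(pts, k=k + 1)
    return d[:, k]


def fit_filter_rule(
    detections,
    method: str = "mixture-crossover",
    params: dict | None = None,
    seed: int = 0,
) -> FilterRule:
    """Choose a filter rule from the detections' NN-distance distribution.

    Methods
    -------
    fixed
        Pass-through: ``params`` supplies ``radius`` (and optionally
        ``min_neighbors``) verbatim.
    quantile
        radius = the q-th percentile (default q=90, linear interpolation)
        of the k-NN distances (default k=1).
    mixture-crossover
        View the log k-NN-distance distribution as a two-component mixture:
        a structured short-distance (colony) component and a long-distance
        component from the sparse, spatially random false-positive field.
        The two modes are located on a kernel-smoothed density and the
        radius is placed at their log-midpoint (geometric mean) — the
        density crossover point when the two log-scale components have
        comparable spread.  By default k equals ``min_neighbors`` so the
        fitted distances measure exactly the neighbourhood statistic the
        retention rule thresholds.  Degenerate fits (no second mode, or all
        distances identical) fall back to the fixed default with a warning.
    """
    params = dict(params or {})
    m = int(params.pop("min_neighbors", DEFAULT_MIN_NEIGHBORS))
    if method == "fixed":
        return FilterRule(float(params["radius"]), m, "fixed")

    k = int(params.pop("k", m if method == "mixture-crossover" else 1))
    pts = _points(detections)
    if method == "mixture-crossover" and len(pts) < 10:
        raise ValueError("mixture-crossover fitting needs >= 10 detections")
    d = nn_distances(pts, k=k)

    if np.ptp(d) == 0:
        warnings.warn("degenerate NN-distance distribution (all identical); "
                      "falling back to fixed default rule")
        return FilterRule(DEFAULT_RADIUS, m, "fixed")

    if method == "quantile":
        q = float(params.pop("q", 90.0))
        r = float(np.percentile(d, q))
        return FilterRule(r, m, "quantile")

    if method == "mixture-crossover":
        r = _mixture_crossover(d)
        if r is None:
            warnings.warn("mixture components not separated; "
                          "falling back to fixed default rule")
            return FilterRule(DEFAULT_RADIUS, m, "fixed")
        return FilterRule(r, m, "mixture-crossover")

    raise ValueError(f"unknown rule-fitting method {method!r}")


MIN_MODE_SEPARATION = 0.5   # log-distance units; ~1.65x in distance


def _mixture_crossover(d: np.ndarray) -> float | None:
    """Crossover radius between the two modes of the log-distance density.

    The colony mode is the global maximum of a Gaussian-KDE-smoothed
    density of log distances; the unstructured mode is the highest local
    maximum at least ``MIN_MODE_SEPARATION`` log units beyond it.  Returns
    the geometric mean of the two mode positions, or None when no second
    mode exists (detections of one class only).
    """
    from scipy.stats import gaussian_kde

    logd = np.log(np.clip(d, 1e-9, None))
    kde = gaussian_kde(logd)
    grid = np.linspace(logd.min(), logd.max(), 512)
    dens = kde(grid)
    i_main = int(np.argmax(dens))
    interior = np.arange(1, len(grid) - 1)
    local_max = interior[(dens[interior] > dens[interior - 1])
                         & (dens[interior] >= dens[interior + 1])]
    far = [i for i in local_max if grid[i] > grid[i_main] + MIN_MODE_SEPARATION]
    if not far:
        return None
    i_second = far[int(np.argmax(dens[far]))]
    return float(np.exp(0.5 * (grid[i_main] + grid[i_second])))


def apply_filter(detections, rule: FilterRule) -> tuple[DetectionSet, DetectionSet]:
    """Split detections into (retained, rejected) under the rule.

    Neighbourhoods are evaluated against the full, unfiltered input in a
    single pass: a point is retained iff at least ``rule.min_neighbors``
    *other* input points lie within ``rule.radius`` of it.  The two outputs
    partition the input exactly.
    """
    if isinstance(detections, DetectionSet):
        pts, scores = detections.points, detections.scores
        raster_id, settings = detections.raster_id, dict(detections.settings)
    else:
        pts = _points(detections)
        scores = np.zeros(len(pts))
        raster_id, settings = "", {}
    settings["filter_rule"] = asdict(rule)
    if len(pts) == 0:
        empty = DetectionSet(np.empty((0, 2)), np.empty(0), raster_id, settings)
        return empty, empty
    tree = cKDTree(pts)
    counts = np.array(tree.query_ball_point(pts, rule.radius,
                                            return_length=True)) - 1
    keep = counts >= rule.min_neighbors
    retained = DetectionSet(pts[keep], scores[keep], raster_id, settings)
    rejected = DetectionSet(pts[~keep], scores[~keep], raster_id, settings)
    return retained, rejected
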