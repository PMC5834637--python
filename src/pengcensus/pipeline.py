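"""End-to-end survey orchestration.

Composes the stages — simulate colony + imagery, detect candidates, apply
the nearest-neighbour filter, calibrate against manual validation plots,
and aggregate the archipelago census with error propagation — into
reproducible, seeded runs driven by a flat configuration mapping.

A single run seed fans out to independent per-stage substreams (derived by
hashing seed + stage name) so any stage can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as pio
from .census import (CensusEstimate, RegionalBaseline, SiteCount,
                     apply_calibration, fit_calibration, load_table1,
                     propagate_error, regional_share, sum_census)
from .detection import DetectionSet, detect_on_tiles
from .field_counts import classify_precision, protocol_count
from .spatial import FilterRule, apply_filter, fit_filter_rule
from .synthetic import (BlobParams, ColonyLayout, ObserverModel, Orthomosaic,
                        generate_colony_layout, render_orthomosaic,
                        simulate_observer_count)

__all__ = [
    "DEFAULT_CONFIG",
    "IslandSurveyResult",
    "RunManifest",
    "stage_seed",
    "config_hash",
    "validate_config",
    "survey_island",
    "match_detections",
    "run_pipeline",
]


DEFAULT_CONFIG: dict = {
    "mode": "simulate",            # simulate | fixture
    "seed": 1,
    "output_dir": "results/run",
    "islands": {
        "n_islands": 2,
        "n_subcolonies": 8,
        "nests_per_subcolony": 150,
        "cluster_radius": 3.0,
        "hardcore": 0.7,
        "extent_width": 200.0,
        "extent_height": 160.0,
    },
    "render": {
        "gsd": 0.05,
        "artifact_intensity": 0.005,
        "noise_sd": 0.05,
    },
    "detect": {
        "tile_size": 512,
        "threshold": 0.25,
        "blob_scale": 0.15,
        "merge_radius": 0.35,
    },
    "filter": {
        "method": "mixture-crossover",
        "min_neighbors": 2,
        "radius": None,          # used only by method=fixed
    },
    "observer": {
        "cv": 0.03,
        "bias": 1.0,
    },
    "calibration": {
        "manual_cv": 0.02,
        "grid_size": 15.0,
    },
    "census": {
        "interpretation": "normal95",
        "n_reps": 20000,
    },
}


def stage_seed(seed: int, stage: str) -> int:
    """Derive an independent, reproducible substream seed for one stage."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def config_hash(config: dict) -> str:
    """Hash of the run parameters (the output location is not a parameter)."""
    params = {k: v for k, v in config.items() if k != "output_dir"}
    return hashlib.sha256(
        json.dumps(params, sort_keys=True).encode()
    ).hexdigest()[:16]


def validate_config(config: dict) -> list[str]:
    """Return a list of problems; empty means the config is valid."""
    problems: list[str] = []
    known = set(DEFAULT_CONFIG)
    for key in config:
        if key not in known:
            problems.append(f"unknown key: {key}")
    mode = config.get("mode", "simulate")
    if mode not in ("simulate", "fixture"):
        problems.append(f"mode must be simulate|fixture, got {mode!r}")
    for block_name, block in config.items():
        if block_name in ("mode", "seed", "output_dir"):
            continue
        defaults = DEFAULT_CONFIG.get(block_name)
        if not isinstance(defaults, dict):
            continue
        for key in block:
            if key not in defaults:
                problems.append(f"unknown key: {block_name}.{key}")

    def get(block, key):
        return config.get(block, {}).get(key, DEFAULT_CONFIG[block][key])

    if get("detect", "tile_size") < 32:
        problems.append("detect.tile_size below minimum 32")
    if get("detect", "threshold") < 0:
        problems.append("detect.threshold must be non-negative")
    if get("observer", "cv") < 0:
        problems.append("observer.cv must be non-negative")
    if get("observer", "bias") <= 0:
        problems.append("observer.bias must be positive")
    if get("render", "gsd") <= 0:
        problems.append("render.gsd must be positive")
    if get("render", "artifact_intensity") < 0:
        problems.append("render.artifact_intensity must be non-negative")
    if get("islands", "hardcore") >= get("islands", "cluster_radius"):
        problems.append("islands.hardcore must be below islands.cluster_radius")
    if get("census", "n_reps") < 1000:
        problems.append("census.n_reps must be at least 1000")
    if get("census", "interpretation") not in ("normal95", "uniform"):
        problems.append("census.interpretation must be normal95|uniform")
    if get("calibration", "manual_cv") < 0:
        problems.append("calibration.manual_cv must be non-negative")
    return problems


def _merged(config: dict | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v)
           for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        if isinstance(v, dict) and isinstance(cfg.get(k), dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


# ---------------------------------------------------------------------------
# Single-island survey chain
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IslandSurveyResult:
    """Outcome of the detect -> filter -> calibrate chain on one island."""

    island_id: str
    true_count: int
    n_detected: int
    n_retained: int
    n_rejected: int
    estimate: int
    rel_uncertainty: float
    rule: FilterRule
    calibration: object
    retained: DetectionSet

    @property
    def relative_error(self) -> float:
        if self.true_count == 0:
            return 0.0 if self.estimate == 0 else float("inf")
        return (self.estimate - self.true_count) / self.true_count


def match_detections(
    detections: np.ndarray, truth: np.ndarray, radius: float = 0.5
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detections to truth points.

    Pairs are matched in order of increasing distance up to ``radius``.
    Returns (matched, missed_truth, unmatched_detections).
    """
    from scipy.spatial import cKDTree

    det = np.asarray(detections, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    if len(det) == 0 or len(tru) == 0:
        return 0, len(tru), len(det)
    tree = cKDTree(tru)
    pairs = []
    dists, idx = tree.query(det, k=min(4, len(tru)),
                            distance_upper_bound=radius)
    dists = np.atleast_2d(dists)
    idx = np.atleast_2d(idx)
    for i in range(len(det)):
        for d, j in zip(dists[i], idx[i]):
            if np.isfinite(d):
                pairs.append((d, i, j))
    pairs.sort()
    used_det: set[int] = set()
    used_tru: set[int] = set()
    for d, i, j in pairs:
        if i not in used_det and j not in used_tru:
            used_det.add(i)
            used_tru.add(j)
    matched = len(used_det)
    return matched, len(tru) - matched, len(det) - matched


def _plot_counts(points: np.ndarray, x0: float, y0: float, size: float) -> int:
    if len(points) == 0:
        return 0
    inside = ((points[:, 0] >= x0) & (points[:, 0] < x0 + size)
              & (points[:, 1] >= y0) & (points[:, 1] < y0 + size))
    return int(inside.sum())


def survey_island(
    layout: ColonyLayout,
    ortho: Orthomosaic,
    config: dict | None = None,
    seed: int = 0,
) -> IslandSurveyResult:
    """Run detect -> filter -> calibrate on one rendered island.

    Validation plots combine (a) one square quadrat per visible
    sub-colony, centred on the sub-colony and wide enough (six cluster
    radii) to include its sparse edge, and (b) a regular grid of smaller
    quadrats over the occupied extent, plus one empty background plot for
    intercept leverage.  Each plot contributes a (detected, manual)
    calibration pair, the manual count being an observer count of the
    true nests in the plot.  Sampling whole sub-colonies including their
    edges means the regression also corrects for edge nests lost to the
    spatial filter, while the grid plots widen the leverage of the fit.
    The calibrated island estimate and its prediction-interval relative
    uncertainty are returned alongside the filter diagnostics.
    """
    cfg = _merged(config)
    rng = np.random.default_rng(stage_seed(seed, f"survey:{layout.island_id}"))

    det = detect_on_tiles(
        ortho,
        tile_size=cfg["detect"]["tile_size"],
        threshold=cfg["detect"]["threshold"],
        blob_scale=cfg["detect"]["blob_scale"],
        merge_radius=cfg["detect"]["merge_radius"],
    )
    filter_params = {"min_neighbors": cfg["filter"]["min_neighbors"]}
    if cfg["filter"].get("radius") is not None:
        filter_params["radius"] = cfg["filter"]["radius"]
    rule = fit_filter_rule(
        det, method=cfg["filter"]["method"], params=filter_params,
        seed=stage_seed(seed, "filter"),
    )
    retained, rejected = apply_filter(det, rule)

    # Calibration plots: whole-sub-colony quadrats (edges included) plus a
    # grid of smaller quadrats over the occupied extent and one empty
    # background plot.
    size = 6.0 * cfg["islands"]["cluster_radius"]
    grid_size = cfg["calibration"]["grid_size"]
    manual_cv = cfg["calibration"]["manual_cv"]
    xmin, ymin, xmax, ymax = layout.extent.bounds
    plots: list[tuple[float, float, float]] = []
    for sc in np.unique(layout.subcolony_id):
        cx, cy = layout.nests[layout.subcolony_id == sc].mean(axis=0)
        plots.append((cx - size / 2, cy - size / 2, size))
    n_empty = 0
    for x0 in np.arange(xmin, xmax, grid_size):
        for y0 in np.arange(ymin, ymax, grid_size):
            if _plot_counts(retained.points, x0, y0, grid_size) == 0:
                if n_empty >= 1:
                    continue
                n_empty += 1
            plots.append((x0, y0, grid_size))
    observer = ObserverModel(cv=manual_cv, bias=1.0)
    pairs = []
    for (x0, y0, s) in plots:
        detected = _plot_counts(retained.points, x0, y0, s)
        true_in_plot = _plot_counts(layout.nests, x0, y0, s)
        manual = simulate_observer_count(true_in_plot, observer, rng)
        pairs.append((detected, manual))
    model = fit_calibration(pairs, site_id=layout.island_id)
    estimate, rel = apply_calibration(model, len(retained))

    return IslandSurveyResult(
        layout.island_id, layout.n_nests, len(det), len(retained),
        len(rejected), estimate, rel, rule, model, retained,
    )


# ---------------------------------------------------------------------------
# Full pipeline run
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    """Provenance record of one pipeline run."""

    config_hash: str
    stages: dict = field(default_factory=dict)
    summary_path: str = ""

    def record(self, stage: str, outputs: list[str], seconds: float) -> None:
        self.stages[stage] = {"outputs": outputs,
                              "seconds": round(seconds, 3)}


def run_pipeline(config: dict | None = None) -> RunManifest:
    """Execute the configured survey end to end and write all artifacts.

    In ``simulate`` mode: generate islands, render imagery, detect, filter,
    calibrate, then aggregate the archipelago census (Monte-Carlo CI and
    regional share).  In ``fixture`` mode: skip imagery and aggregate the
    packaged census table directly.  Identical config + seed reproduces a
    byte-identical census summary.
    """
    cfg = _merged(config)
    problems = validate_config(cfg)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    seed = cfg["seed"]
    out = Path(cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash(cfg))

    site_counts: list[SiteCount] = []
    island_rows = []
    if cfg["mode"] == "simulate":
        isl = cfg["islands"]
        for i in range(isl["n_islands"]):
            t0 = time.perf_counter()
            island_id = f"island{i:02d}"
            lay_seed = stage_seed(seed, f"layout:{island_id}")
            layout = generate_colony_layout(
                (0, 0, isl["extent_width"], isl["extent_height"]),
                isl["n_subcolonies"], isl["nests_per_subcolony"],
                isl["cluster_radius"], isl["hardcore"],
                seed=lay_seed, island_id=island_id,
            )
            ortho, artifacts = render_orthomosaic(
                layout, gsd=cfg["render"]["gsd"],
                artifact_intensity=cfg["render"]["artifact_intensity"],
                noise_sd=cfg["render"]["noise_sd"],
                seed=stage_seed(seed, f"render:{island_id}"),
            )
            truth_csv = out / f"{island_id}_truth.csv"
            pio.write_layout_csv(truth_csv, layout, artifacts)
            raster_tif = out / f"{island_id}.tif"
            pio.write_raster(raster_tif, ortho)
            manifest.record(f"simulate:{island_id}",
                            [str(truth_csv), str(raster_tif)],
                            time.perf_counter() - t0)

            t0 = time.perf_counter()
            result = survey_island(layout, ortho, cfg, seed=seed)
            det_csv = out / f"{island_id}_retained.csv"
            pio.write_detections_csv(det_csv, result.retained)
            rule_json = out / f"{island_id}_rule.json"
            rule_json.write_text(result.rule.to_json())
            manifest.record(f"survey:{island_id}",
                            [str(det_csv), str(rule_json)],
                            time.perf_counter() - t0)

            precision = classify_precision(min(0.10, max(result.rel_uncertainty,
                                                         0.0)))
            site_counts.append(SiteCount(island_id, "adeliae",
                                         result.estimate, precision, "uav"))
            island_rows.append({
                "island": island_id, "true": result.true_count,
                "detected": result.n_detected, "retained": result.n_retained,
                "estimate": result.estimate,
                "relative_error": result.relative_error,
                "precision": precision.label,
            })
    else:
        site_counts = load_table1()
        island_rows = [
            {"island": s.island_id, "estimate": s.count,
             "precision": s.precision.label, "method": s.method}
            for s in site_counts if s.species == "adeliae"
        ]

    t0 = time.perf_counter()
    total = sum_census(site_counts, "adeliae")
    est = propagate_error(
        site_counts, cfg["census"]["interpretation"],
        cfg["census"]["n_reps"], seed=stage_seed(seed, "census"),
    )
    share = regional_share(total) if cfg["mode"] == "fixture" else None
    summary = {
        "mode": cfg["mode"],
        "seed": seed,
        "config_hash": manifest.config_hash,
        "total": est.total,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "level": est.level,
        "n_reps": est.n_reps,
        "error_interpretation": est.error_interpretation,
        "islands": island_rows,
    }
    if share is not None:
        summary["regional_share_pct"] = round(share)
        summary["regional_share_pct_exact"] = round(share, 2)
    summary_path = out / "census_summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
    manifest.record("census", [str(summary_path)], time.perf_counter() - t0)
    manifest.summary_path = str(summary_path)
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2, sort_keys=True)
    )
    return manifest
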