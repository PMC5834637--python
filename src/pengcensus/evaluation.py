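"""Study-level evaluation experiments.

These functions run the headline experiments of the analysis — the
published-table aggregation, error-propagation plausibility, confidence
interval coverage, end-to-end count recovery on synthetic islands, the
spatial-filter confusion rates and the cross-calibration round trip — so
tests, the analysis drivers and the acceptance script share one
implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .census import SiteCount, load_table1, propagate_error, regional_share, sum_census
from .detection import detect_on_tiles
from .field_counts import PrecisionClass
from .pipeline import match_detections, stage_seed, survey_island
from .spatial import apply_filter, fit_filter_rule
from .synthetic import generate_colony_layout, generate_scene_pair, render_orthomosaic
from .landsat import apply_offsets, estimate_offsets

STUDY_EXTENT = (0.0, 0.0, 200.0, 160.0)
STUDY_LAYOUT = dict(n_subcolonies=8, nests_per_subcolony=150,
                    cluster_radius=3.0, hardcore=0.7)

# Per-island truth magnitudes and precision labels used for the synthetic
# coverage experiment: one archipelago of nine islands spanning the same
# orders of magnitude as the study system.
COVERAGE_TRUTH = (284535, 94951, 12000, 5804, 0, 21071, 292363, 40803, 0)
COVERAGE_CLASSES = ("N2", "N2", "N4", "N1", "N1", "N2", "N2", "N1", "N1")


def make_study_island(seed: int, island_id: str | None = None):
    """One rendered study island: (layout, orthomosaic, artifact truth)."""
    layout = generate_colony_layout(
        STUDY_EXTENT, seed=seed,
        island_id=island_id or f"island{seed:02d}", **STUDY_LAYOUT,
    )
    ortho, artifacts = render_orthomosaic(layout, seed=seed + 100)
    return layout, ortho, artifacts


def ci_coverage(
    n_archipelagos: int = 400,
    n_reps: int = 2000,
    interpretation: str = "normal95",
    seed: int = 0,
) -> float:
    """Fraction of synthetic archipelagos whose 95% CI covers the truth.

    Per archipelago, each island's observed count is its true count plus
    an error drawn per the stated interpretation of its precision class;
    the Monte-Carlo CI is then computed from the observed counts alone.
    """
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_archipelagos):
        sites = []
        true_total = 0
        for i, (truth, label) in enumerate(zip(COVERAGE_TRUTH,
                                               COVERAGE_CLASSES)):
            prec = PrecisionClass.from_label(label)
            if interpretation == "normal95":
                obs = rng.normal(truth, prec.half_width * truth / 1.96)
            else:
                obs = rng.uniform(truth * (1 - prec.half_width),
                                  truth * (1 + prec.half_width))
            obs = max(0.0, obs)
            sites.append(SiteCount(f"i{i}", "adeliae", int(round(obs)), prec))
            true_total += truth
        est = propagate_error(sites, interpretation, n_reps,
                              seed=int(rng.integers(2**31)))
        covered += est.ci_low <= true_total <= est.ci_high
    return covered / n_archipelagos


@dataclass(frozen=True)
class RecoveryResult:
    """Per-island end-to-end recovery outcomes."""

    true_counts: list[int]
    estimates: list[int]

    @property
    def relative_errors(self) -> np.ndarray:
        t = np.asarray(self.true_counts, float)
        e = np.asarray(self.estimates, float)
        return (e - t) / t

    @property
    def mean_abs_relative_error(self) -> float:
        return float(np.mean(np.abs(self.relative_errors)))

    @property
    def max_abs_relative_error(self) -> float:
        return float(np.max(np.abs(self.relative_errors)))


def end_to_end_recovery(n_islands: int = 10, seed: int = 0) -> RecoveryResult:
    """Recover island nest counts through detect -> filter -> calibrate."""
    truths, estimates = [], []
    for i in range(n_islands):
        island_seed = stage_seed(seed, f"recovery:{i}") % (2**31 - 10)
        layout, ortho, _ = make_study_island(island_seed, f"island{i:02d}")
        res = survey_island(layout, ortho, seed=island_seed)
        truths.append(res.true_count)
        estimates.append(res.estimate)
    return RecoveryResult(truths, estimates)


@dataclass(frozen=True)
class FilterEvaluation:
    """Spatial-filter confusion rates on one labelled island."""

    n_nest_detections: int
    n_artifact_detections: int
    artifact_rejection_rate: float
    nest_rejection_rate: float
    detection_recall: float
    radius: float


def evaluate_filter(seed: int = 0) -> FilterEvaluation:
    """Label detections by nearest truth point and score the default rule."""
    layout, ortho, artifacts = make_study_island(seed)
    det = detect_on_tiles(ortho)
    rule = fit_filter_rule(det)
    retained, rejected = apply_filter(det, rule)

    d_nest, _ = cKDTree(layout.nests).query(det.points)
    d_art, _ = cKDTree(artifacts).query(det.points)
    is_artifact = d_art < d_nest
    tree = cKDTree(det.points)
    neighbor_counts = np.array(
        tree.query_ball_point(det.points, rule.radius, return_length=True)
    ) - 1
    keep = neighbor_counts >= rule.min_neighbors
    assert keep.sum() == len(retained)

    matched, _, _ = match_detections(det.points, layout.nests, 0.5)
    return FilterEvaluation(
        int((~is_artifact).sum()), int(is_artifact.sum()),
        float(1 - keep[is_artifact].mean()),
        float(1 - keep[~is_artifact].mean()),
        matched / layout.n_nests,
        rule.radius,
    )


def cross_calibration_residuals(seed: int = 0, size: int = 64,
                                noise_sd: float = 0.01) -> dict[str, float]:
    """Offset-recovery errors and post-adjustment residual band differences."""
    spectra = {"guano": {"green": 0.18, "red": 0.22, "nir": 0.30},
               "non_guano": {"green": 0.08, "red": 0.09, "nir": 0.12}}
    offsets = {"green": 0.02, "red": -0.015, "nir": 0.03}
    truth = np.zeros((size, size), bool)
    truth[: size // 3] = True
    ref, off = generate_scene_pair(truth, spectra, offsets,
                                   noise_sd=noise_sd, seed=seed)
    est = estimate_offsets(off, ref)
    adj = apply_offsets(off, est)
    recovery_err = max(abs(est.offsets[b] - offsets[b]) for b in offsets)
    residual = max(abs(float((adj.bands[b] - ref.bands[b]).mean()))
                   for b in offsets)
    return {"offset_recovery_max_error": recovery_err,
            "post_adjustment_max_residual": residual,
            "standard_error": noise_sd * np.sqrt(2) / size}


def published_census_summary(n_reps: int = 100_000, seed: int = 0) -> dict:
    """Aggregate the packaged census table: total, CI, regional share."""
    sites = load_table1()
    total = sum_census(sites, "adeliae")
    est = propagate_error(sites, "normal95", n_reps, seed)
    share = regional_share(total)
    return {
        "total": total,
        "ci_low": est.ci_low,
        "ci_high": est.ci_high,
        "half_width": (est.ci_high - est.ci_low) / 2,
        "share_pct": share,
        "share_pct_rounded": round(share),
        "chinstrap_total": sum_census(sites, "antarctica"),
    }
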