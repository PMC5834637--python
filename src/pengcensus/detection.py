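"""Candidate nest detection on orthomosaics.

The detector honours the I/O contract of a neural point detector — tiles of
512 x 512 pixels in, scored point detections out — but the operator itself
is a classical difference-of-Gaussians (DoG) blob detector with local-maxima
extraction.  It is deliberately tuned for high recall: spatially
unstructured false positives are tolerated here and removed downstream by
the nearest-neighbour spatial filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.feature import peak_local_max

from .synthetic import Orthomosaic

__all__ = [
    "Tile",
    "DetectionSet",
    "tile_raster",
    "detect_candidates",
    "detect_on_tiles",
    "merge_tile_detections",
]

DOG_SIGMA_RATIO = 1.6


@dataclass(frozen=True)
class Tile:
    """One pixel block of a parent raster; tiles partition the raster."""

    pixels: np.ndarray
    row_off: int
    col_off: int
    parent_id: str

    def __post_init__(self):
        if self.row_off < 0 or self.col_off < 0:
            raise ValueError("tile offsets must be non-negative")


@dataclass(frozen=True)
class DetectionSet:
    """Scored point detections in world coordinates (metres)."""

    points: np.ndarray              # (n, 2) x, y metres
    scores: np.ndarray              # (n,) in [0, 1]
    raster_id: str = ""
    settings: dict = field(default_factory=dict)

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        sc = np.asarray(self.scores, dtype=float).reshape(-1)
        if len(sc) != len(pts):
            raise ValueError("one score per point required")
        if len(sc) and (sc.min() < 0 or sc.max() > 1):
            raise ValueError("scores must lie in [0, 1]")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "scores", sc)

    def __len__(self) -> int:
        return len(self.points)


def tile_raster(ortho: Orthomosaic, tile_size: int = 512) -> list[Tile]:
    """Partition a raster into tiles; trailing tiles may be smaller.

    Concatenating the tiles reconstructs the raster exactly, so pixel sums
    are conserved; tile count is ceil(rows/size) * ceil(cols/size).
    """
    if tile_size < 32:
        raise ValueError("tile_size must be at least 32 pixels")
    rows, cols = ortho.pixels.shape[:2]
    if rows == 0 or cols == 0:
        raise ValueError("cannot tile an empty raster")
    tiles = []
    for r0 in range(0, rows, tile_size):
        for c0 in range(0, cols, tile_size):
            block = ortho.pixels[r0:r0 + tile_size, c0:c0 + tile_size]
            tiles.append(Tile(block, r0, c0, ortho.island_id))
    return tiles


def _dog_response(img: np.ndarray, sigma_px: float) -> np.ndarray:
    g1 = ndimage.gaussian_filter(img, sigma_px, mode="reflect")
    g2 = ndimage.gaussian_filter(img, DOG_SIGMA_RATIO * sigma_px, mode="reflect")
    return g1 - g2


def _reference_peak(sigma_px: float) -> float:
    """DoG peak response to a unit-amplitude Gaussian blob of scale sigma_px.

    Closed form: filtering a Gaussian blob of scale s with a Gaussian of
    scale t gives amplitude s^2/(s^2+t^2) at the centre.
    """
    s2 = sigma_px * sigma_px
    r1 = s2 / (s2 + s2)
    r2 = s2 / (s2 + (DOG_SIGMA_RATIO * sigma_px) ** 2)
    return r1 - r2


def _refine_peaks(resp: np.ndarray, peaks: np.ndarray) -> np.ndarray:
    """Sub-pixel peak positions by centre-of-mass over a 3x3 window."""
    refined = peaks.astype(float).copy()
    rows, cols = resp.shape
    for i, (r, c) in enumerate(peaks):
        if 0 < r < rows - 1 and 0 < c < cols - 1:
            w = resp[r - 1:r + 2, c - 1:c + 2]
            w = np.clip(w - w.min(), 0, None)
            tot = w.sum()
            if tot > 0:
                rr, cc = np.mgrid[-1:2, -1:2]
                refined[i, 0] = r + (w * rr).sum() / tot
                refined[i, 1] = c + (w * cc).sum() / tot
    return refined


def detect_candidates(
    ortho: Orthomosaic,
    threshold: float = 0.25,
    blob_scale: float = 0.15,
) -> DetectionSet:
    """Detect blob-like candidates on a full raster.

    ``blob_scale`` is the expected Gaussian scale (sigma) of a nest blob in
    metres; ``threshold`` is a cutoff on the DoG response normalised so that
    an isolated unit-amplitude blob scores 1.  One point is returned per
    accepted local maximum, with its normalised response (clipped to [0, 1])
    as the score.  An empty set is a valid result.
    """
    sigma_px = blob_scale / ortho.gsd
    if sigma_px < 1.0:
        raise ValueError(
            f"blob_scale={blob_scale} m is below one pixel at gsd={ortho.gsd}"
        )
    img = ortho.pixels if ortho.pixels.ndim == 2 else ortho.pixels.mean(axis=2)
    resp = _dog_response(img, sigma_px) / _reference_peak(sigma_px)
    min_dist = max(1, int(round(sigma_px)))
    peaks = peak_local_max(resp, min_distance=min_dist,
                           threshold_abs=threshold, exclude_border=False)
    if len(peaks) == 0:
        return DetectionSet(np.empty((0, 2)), np.empty(0), ortho.island_id,
                            {"threshold": threshold, "blob_scale": blob_scale})
    scores = np.clip(resp[peaks[:, 0], peaks[:, 1]], 0.0, 1.0)
    sub = _refine_peaks(resp, peaks)
    x, y = ortho.pixel_to_world(sub[:, 0], sub[:, 1])
    return DetectionSet(
        np.column_stack([x, y]), scores, ortho.island_id,
        {"threshold": threshold, "blob_scale": blob_scale},
    )


def detect_on_tiles(
    ortho: Orthomosaic,
    tile_size: int = 512,
    threshold: float = 0.25,
    blob_scale: float = 0.15,
    merge_radius: float = 0.35,
) -> DetectionSet:
    """Tile, detect per tile, and merge seam duplicates.

    Each tile is processed with a read-only halo from the parent raster wide
    enough (4 outer DoG scales) that its filter response equals the
    full-raster response; only peaks whose centres fall inside the tile core
    are kept, so up to sub-pixel refinement at seams the result matches
    detection on the untiled raster.
    """
    sigma_px = blob_scale / ortho.gsd
    if sigma_px < 1.0:
        raise ValueError("blob_scale below one pixel at this gsd")
    halo = int(math.ceil(4 * DOG_SIGMA_RATIO * sigma_px))
    rows, cols = ortho.pixels.shape[:2]
    per_tile: list[DetectionSet] = []
    for tile in tile_raster(ortho, tile_size):
        r0, c0 = tile.row_off, tile.col_off
        r1 = r0 + tile.pixels.shape[0]
        c1 = c0 + tile.pixels.shape[1]
        hr0, hc0 = max(0, r0 - halo), max(0, c0 - halo)
        hr1, hc1 = min(rows, r1 + halo), min(cols, c1 + halo)
        block = ortho.pixels[hr0:hr1, hc0:hc1]
        sub = Orthomosaic(block, ortho.gsd,
                          ortho.pixel_to_world(hr0 - 0.5, hc0 - 0.5),
                          ortho.island_id)
        det = detect_candidates(sub, threshold, blob_scale)
        if len(det) == 0:
            per_tile.append(det)
            continue
        prow, pcol = ortho.world_to_pixel(det.points[:, 0], det.points[:, 1])
        keep = ((prow >= r0 - 0.5) & (prow < r1 - 0.5)
                & (pcol >= c0 - 0.5) & (pcol < c1 - 0.5))
        per_tile.append(DetectionSet(det.points[keep], det.scores[keep],
                                     ortho.island_id, det.settings))
    return merge_tile_detections(per_tile, merge_radius)


def merge_tile_detections(
    sets: list[DetectionSet],
    merge_radius: float = 0.35,
) -> DetectionSet:
    """Merge near-duplicate points across tile seams.

    Points closer than ``merge_radius`` are collapsed to their
    score-weighted centroid (merged score = maximum).  Merging is iterated
    to a fixed point so the operation is idempotent; the output never has
    more points than the input.
    """
    if not sets:
        return DetectionSet(np.empty((0, 2)), np.empty(0))
    ids = {s.raster_id for s in sets}
    if len(ids) > 1:
        raise ValueError(f"mismatched parent raster ids: {sorted(ids)}")
    pts = np.vstack([s.points for s in sets]) if sets else np.empty((0, 2))
    scores = np.concatenate([s.scores for s in sets])
    settings = dict(sets[0].settings)
    settings["merge_radius"] = merge_radius
    raster_id = sets[0].raster_id

    while len(pts) > 1:
        tree = cKDTree(pts)
        pairs = tree.query_pairs(merge_radius, output_type="ndarray")
        if len(pairs) == 0:
            break
        # union-find over the pair graph
        parent = np.arange(len(pts))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for a, b in pairs:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
        roots = np.array([find(i) for i in range(len(pts))])
        new_pts, new_scores = [], []
        for r in np.unique(roots):
            members = roots == r
            w = scores[members]
            w = w if w.sum() > 0 else np.ones(members.sum())
            new_pts.append(np.average(pts[members], axis=0, weights=w))
            new_scores.append(scores[members].max())
        pts = np.asarray(new_pts).reshape(-1, 2)
        scores = np.asarray(new_scores)
    return DetectionSet(pts, scores, raster_id, settings)
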