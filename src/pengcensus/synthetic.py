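"""Synthetic study-system generator.

Everything the census pipeline consumes can be generated here with seeded
reproducibility: colony layouts (clustered nest point patterns with
short-range regular spacing inside sub-colonies), orthomosaic-like rasters
with confusable artifacts, observer counting error for the triple-count
ground protocol, and paired multispectral scenes from two "sensors" that
differ by per-band additive offsets.

Coordinate conventions
----------------------
World coordinates are metres with y increasing north.  Raster indices are
row-major and 0-based, row 0 at the northern edge; world<->pixel conversion
uses the pixel-centre convention (the centre of pixel (0, 0) sits half a
pixel inside the raster origin).
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from shapely.geometry import Point, Polygon, box

__all__ = [
    "ColonyLayout",
    "Orthomosaic",
    "ObserverModel",
    "MultispectralScene",
    "BlobParams",
    "InfeasibleLayoutError",
    "generate_colony_layout",
    "render_orthomosaic",
    "simulate_observer_count",
    "generate_scene_pair",
]


class InfeasibleLayoutError(RuntimeError):
    """Requested nest packing cannot be realised inside the extent."""


def _as_polygon(extent) -> Polygon:
    """Accept a (xmin, ymin, xmax, ymax) tuple or a shapely Polygon."""
    if isinstance(extent, Polygon):
        return extent
    xmin, ymin, xmax, ymax = extent
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("extent must have positive width and height")
    return box(xmin, ymin, xmax, ymax)


@dataclass(frozen=True)
class ColonyLayout:
    """A set of nest points (metres) with sub-colony labels inside an extent."""

    island_id: str
    nests: np.ndarray            # (n, 2) float array of x, y in metres
    subcolony_id: np.ndarray     # (n,) int array
    extent: Polygon
    hardcore: float = 0.0

    def __post_init__(self):
        nests = np.asarray(self.nests, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "nests", nests)
        object.__setattr__(
            self, "subcolony_id", np.asarray(self.subcolony_id, dtype=int)
        )
        if len(self.subcolony_id) != len(nests):
            raise ValueError("every nest needs a subcolony label")
        if not np.all(np.isfinite(nests)):
            raise ValueError("nest coordinates must be finite")

    @property
    def n_nests(self) -> int:
        return len(self.nests)

    def min_pairwise_distance(self) -> float:
        """Brute-force all-pairs minimum distance (for invariant checks)."""
        if self.n_nests < 2:
            return math.inf
        d = self.nests[:, None, :] - self.nests[None, :, :]
        dist = np.hypot(d[..., 0], d[..., 1])
        np.fill_diagonal(dist, np.inf)
        return float(dist.min())


@dataclass(frozen=True)
class Orthomosaic:
    """Georeferenced top-down raster: each pixel maps to gsd x gsd metres.

    ``origin`` is the world coordinate of the *outer corner* of pixel (0, 0),
    i.e. the north-west corner of the raster.
    """

    pixels: np.ndarray          # (rows, cols) or (rows, cols, bands)
    gsd: float                  # metres / pixel
    origin: tuple[float, float]
    island_id: str = ""

    def __post_init__(self):
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")
        px = np.asarray(self.pixels, dtype=float)
        if not np.all(np.isfinite(px)):
            raise ValueError("pixel values must be finite")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.pixels.shape

    def world_to_pixel(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Return fractional (row, col) of world coordinates (pixel-centre)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = (x - self.origin[0]) / self.gsd - 0.5
        row = (self.origin[1] - y) / self.gsd - 0.5
        return row, col

    def pixel_to_world(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin[0] + (col + 0.5) * self.gsd
        y = self.origin[1] - (row + 0.5) * self.gsd
        return x, y


@dataclass(frozen=True)
class ObserverModel:
    """Error model for one human counter.

    cv is the relative standard deviation of a single count; bias is
    multiplicative (1 = unbiased).
    """

    cv: float = 0.03
    bias: float = 1.0

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be non-negative")
        if self.bias <= 0:
            raise ValueError("bias must be positive")


@dataclass(frozen=True)
class MultispectralScene:
    """Named reflectance bands on a shared grid at a stated cell size."""

    bands: dict[str, np.ndarray]
    sensor_id: str
    cell_size: float = 30.0

    def __post_init__(self):
        shapes = {b.shape for b in self.bands.values()}
        if len(shapes) > 1:
            raise ValueError("all bands must share one shape")
        for name, arr in self.bands.items():
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"band {name!r} has non-finite reflectance")

    @property
    def band_names(self) -> list[str]:
        return list(self.bands)

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.bands.values())).shape


# ---------------------------------------------------------------------------
# Colony layout: hard-core cluster process
# ---------------------------------------------------------------------------

def generate_colony_layout(
    extent,
    n_subcolonies: int,
    nests_per_subcolony: float = 150.0,
    cluster_radius: float = 3.0,
    hardcore: float = 0.7,
    seed: int | np.random.Generator = 0,
    island_id: str = "synthetic",
    attempts_per_nest: int = 2000,
) -> ColonyLayout:
    """Simulate a colony as a cluster process with a hard-core constraint.

    Parent (sub-colony) centres are uniform in the extent; offspring nests are
    displaced isotropically (Gaussian, scale ``cluster_radius``) and accepted
    by dart-throwing only if they fall inside the extent and at least
    ``hardcore`` metres from every previously accepted nest.  The per-parent
    nest count is Poisson with mean ``nests_per_subcolony``.

    Raises :class:`InfeasibleLayoutError` if the dart-throw budget
    (``attempts_per_nest`` draws per requested nest) is exhausted — packing
    failures are explicit, never silent truncation.
    """
    if hardcore < 0:
        raise ValueError("hardcore must be non-negative")
    if hardcore >= cluster_radius:
        raise ValueError("hardcore must be smaller than cluster_radius")
    poly = _as_polygon(extent)
    rng = np.random.default_rng(seed)

    xmin, ymin, xmax, ymax = poly.bounds
    if n_subcolonies == 0:
        return ColonyLayout(island_id, np.empty((0, 2)), np.empty(0, int),
                            poly, hardcore)

    # Parent centres uniform in the polygon (rejection sampling).
    parents = []
    while len(parents) < n_subcolonies:
        px = rng.uniform(xmin, xmax)
        py = rng.uniform(ymin, ymax)
        if poly.contains(Point(px, py)):
            parents.append((px, py))
    parents = np.asarray(parents)

    counts = rng.poisson(nests_per_subcolony, size=n_subcolonies)
    pts: list[tuple[float, float]] = []
    labels: list[int] = []
    h2 = hardcore * hardcore
    # uniform grid hash with cell size = hardcore: any conflicting neighbour
    # lies in the 3x3 cell neighbourhood
    cell = hardcore if hardcore > 0 else 1.0
    grid: dict[tuple[int, int], list[int]] = {}

    def conflicts(x: float, y: float) -> bool:
        if hardcore == 0 or not pts:
            return False
        ci, cj = int(math.floor(x / cell)), int(math.floor(y / cell))
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                for idx in grid.get((ci + di, cj + dj), ()):
                    px, py = pts[idx]
                    if (px - x) ** 2 + (py - y) ** 2 < h2:
                        return True
        return False

    rect = poly.equals(box(*poly.bounds))
    for sc, (cx, cy) in enumerate(parents):
        for _ in range(counts[sc]):
            placed = False
            for _ in range(attempts_per_nest):
                dx, dy = rng.normal(0.0, cluster_radius, size=2)
                x, y = cx + dx, cy + dy
                if rect:
                    if not (xmin <= x <= xmax and ymin <= y <= ymax):
                        continue
                elif not poly.contains(Point(x, y)):
                    continue
                if conflicts(x, y):
                    continue
                key = (int(math.floor(x / cell)), int(math.floor(y / cell)))
                grid.setdefault(key, []).append(len(pts))
                pts.append((x, y))
                labels.append(sc)
                placed = True
                break
            if not placed:
                raise InfeasibleLayoutError(
                    f"could not place nest {len(pts) + 1} of sub-colony {sc} "
                    f"within {attempts_per_nest} attempts; extent too small "
                    f"for the requested intensity at hardcore={hardcore} m"
                )
    nests = np.asarray(pts).reshape(-1, 2)
    return ColonyLayout(island_id, nests, np.asarray(labels, int), poly, hardcore)


# ---------------------------------------------------------------------------
# Orthomosaic rendering
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BlobParams:
    """Appearance of a rendered nest (or artifact) blob.

    sigma is the Gaussian scale in metres; by default artifacts share the
    nest appearance exactly — the worst case for any detector, matching the
    confusability of rocks and shadows with incubating birds.
    """

    sigma: float = 0.15
    amplitude: float = 1.0
    artifact_sigma: float | None = None      # None -> same as nests
    artifact_amplitude: float | None = None

    @property
    def a_sigma(self) -> float:
        return self.sigma if self.artifact_sigma is None else self.artifact_sigma

    @property
    def a_amplitude(self) -> float:
        return (self.amplitude if self.artifact_amplitude is None
                else self.artifact_amplitude)


def _add_blobs(img: np.ndarray, ortho: Orthomosaic, points: np.ndarray,
               sigma_m: float, amplitude: float) -> None:
    """Accumulate isotropic Gaussian blobs at world positions in-place."""
    if len(points) == 0:
        return
    sigma_px = sigma_m / ortho.gsd
    half = max(1, int(math.ceil(4 * sigma_px)))
    rows, cols = img.shape
    prow, pcol = ortho.world_to_pixel(points[:, 0], points[:, 1])
    for r0, c0 in zip(np.atleast_1d(prow), np.atleast_1d(pcol)):
        r_lo = max(0, int(math.floor(r0)) - half)
        r_hi = min(rows, int(math.ceil(r0)) + half + 1)
        c_lo = max(0, int(math.floor(c0)) - half)
        c_hi = min(cols, int(math.ceil(c0)) + half + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        rr = np.arange(r_lo, r_hi)[:, None]
        cc = np.arange(c_lo, c_hi)[None, :]
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        img[r_lo:r_hi, c_lo:c_hi] += amplitude * np.exp(-d2 / (2 * sigma_px**2))


def render_orthomosaic(
    layout: ColonyLayout,
    gsd: float = 0.05,
    artifact_intensity: float = 0.005,
    blob_params: BlobParams | None = None,
    noise_sd: float = 0.05,
    seed: int | np.random.Generator = 0,
    pad: float = 2.0,
) -> tuple[Orthomosaic, np.ndarray]:
    """Render a layout to an orthomosaic-like raster plus artifact truth.

    Nests become compact bright Gaussian blobs at their world positions.
    Artifacts ("rocks and shadows") come from a homogeneous Poisson process
    over the extent with, by default, the identical blob appearance, so they
    are spatially unstructured but visually confusable.  Additive Gaussian
    pixel noise is applied last.

    Returns (orthomosaic, artifact_points) where artifact_points is an
    (m, 2) array of world coordinates — the ground truth the spatial-filter
    evaluation needs.
    """
    if gsd <= 0:
        raise ValueError("gsd must be positive")
    bp = blob_params or BlobParams()
    if 2 * bp.sigma < gsd:
        raise ValueError(
            f"blob diameter {2 * bp.sigma:.3f} m is below one pixel at "
            f"gsd={gsd} m/px; lower the gsd (finer pixels) or enlarge the blob"
        )
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = layout.extent.bounds
    xmin, ymin, xmax, ymax = xmin - pad, ymin - pad, xmax + pad, ymax + pad
    cols = int(math.ceil((xmax - xmin) / gsd))
    rows = int(math.ceil((ymax - ymin) / gsd))
    ortho = Orthomosaic(np.zeros((rows, cols)), gsd, (xmin, ymax),
                        layout.island_id)
    img = ortho.pixels

    _add_blobs(img, ortho, layout.nests, bp.sigma, bp.amplitude)

    # Homogeneous Poisson artifact field over the (unpadded) extent.
    area = layout.extent.area
    n_art = rng.poisson(artifact_intensity * area)
    arts: list[tuple[float, float]] = []
    exmin, eymin, exmax, eymax = layout.extent.bounds
    while len(arts) < n_art:
        x = rng.uniform(exmin, exmax)
        y = rng.uniform(eymin, eymax)
        if layout.extent.contains(Point(x, y)):
            arts.append((x, y))
    artifact_points = np.asarray(arts).reshape(-1, 2)
    _add_blobs(img, ortho, artifact_points, bp.a_sigma, bp.a_amplitude)

    if noise_sd > 0:
        img += rng.normal(0.0, noise_sd, size=img.shape)
    return ortho, artifact_points


# ---------------------------------------------------------------------------
# Observer error
# ---------------------------------------------------------------------------

def simulate_observer_count(
    true_count: int,
    observer: ObserverModel,
    seed: int | np.random.Generator = 0,
) -> int:
    """One human count: mean bias*true, relative sd cv, non-negative integer.

    The draw is normal on the count scale, truncated at zero and rounded.
    """
    if true_count < 0:
        raise ValueError("true_count must be non-negative")
    rng = np.random.default_rng(seed)
    mean = observer.bias * true_count
    if observer.cv == 0:
        return int(round(mean))
    draw = rng.normal(mean, observer.cv * mean)
    return int(round(max(0.0, draw)))


# ---------------------------------------------------------------------------
# Paired multispectral scenes
# ---------------------------------------------------------------------------

def generate_scene_pair(
    guano_truth: np.ndarray,
    spectra: dict[str, dict[str, float]],
    sensor_offsets: dict[str, float],
    noise_sd: float = 0.01,
    seed: int | np.random.Generator = 0,
    cell_size: float = 30.0,
) -> tuple[MultispectralScene, MultispectralScene]:
    """Generate (reference, offset) scenes of the same guano truth.

    ``spectra`` maps class name ("guano", "non_guano") to per-band mean
    reflectance.  The reference scene is class mean + noise; the offset
    scene is the same class structure plus a per-band additive constant
    (emulating inter-sensor radiometric differences) plus independent noise.
    """
    truth = np.asarray(guano_truth, dtype=bool)
    if set(spectra) != {"guano", "non_guano"}:
        raise ValueError("spectra must define classes 'guano' and 'non_guano'")
    bands_g = set(spectra["guano"])
    bands_n = set(spectra["non_guano"])
    if bands_g != bands_n:
        raise ValueError("class spectra must share identical band names")
    if set(sensor_offsets) != bands_g:
        raise ValueError(
            f"offset band names {sorted(sensor_offsets)} do not match "
            f"spectra band names {sorted(bands_g)}"
        )
    rng = np.random.default_rng(seed)
    ref_bands: dict[str, np.ndarray] = {}
    off_bands: dict[str, np.ndarray] = {}
    for band in sorted(bands_g):
        base = np.where(truth, spectra["guano"][band], spectra["non_guano"][band])
        base = base.astype(float)
        noise_ref = rng.normal(0, noise_sd, truth.shape) if noise_sd > 0 else 0.0
        noise_off = rng.normal(0, noise_sd, truth.shape) if noise_sd > 0 else 0.0
        ref_bands[band] = base + noise_ref
        off_bands[band] = base + sensor_offsets[band] + noise_off
    ref = MultispectralScene(ref_bands, sensor_id="reference", cell_size=cell_size)
    off = MultispectralScene(off_bands, sensor_id="offset", cell_size=cell_size)
    return ref, off
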