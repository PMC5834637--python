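"""Cross-sensor calibration and guano-area change analysis.

Scenes from different satellite sensors are made comparable by estimating
the per-band mean difference against a reference sensor over comparable
pixels and subtracting it.  Guano (colony) pixels are then classified by a
pluggable classifier — the default is a nearest-class-mean discriminant on
the reflectance vector, configured from class spectra — and fine-scale
classifications (e.g. polygons digitised from historical aerial photos) are
reduced to a coarse grid (30 m cells by default) so colony areas can be
compared across epochs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box
from skimage.measure import block_reduce

from .synthetic import MultispectralScene

__all__ = [
    "SensorOffsets",
    "GuanoMask",
    "NearestClassMean",
    "estimate_offsets",
    "apply_offsets",
    "classify_guano",
    "reduce_to_grid",
    "compare_epochs",
]


@dataclass(frozen=True)
class SensorOffsets:
    """Per-band additive differences of a sensor against the reference."""

    reference_sensor: str
    offsets: dict[str, float]


@dataclass(frozen=True)
class GuanoMask:
    """Boolean guano raster at a stated cell size, labelled by epoch."""

    mask: np.ndarray
    cell_size: float = 30.0
    epoch: str = ""

    def __post_init__(self):
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        object.__setattr__(self, "mask", np.asarray(self.mask, dtype=bool))

    @property
    def area_m2(self) -> float:
        return float(self.mask.sum()) * self.cell_size**2


def _check_bands(a_bands, b_bands):
    if set(a_bands) != set(b_bands):
        raise ValueError(
            f"band mismatch: {sorted(a_bands)} vs {sorted(b_bands)}"
        )


def estimate_offsets(
    scene: MultispectralScene,
    reference: MultispectralScene,
    mask: np.ndarray | None = None,
) -> SensorOffsets:
    """Per-band mean difference of a scene against the reference sensor.

    ``mask`` selects the comparable pixels (default: all).  offset[b] =
    mean(scene[b] - reference[b]) over the mask.
    """
    _check_bands(scene.band_names, reference.band_names)
    if mask is None:
        mask = np.ones(scene.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("comparable-pixel mask is empty")
    offsets = {
        b: float(np.mean(scene.bands[b][mask] - reference.bands[b][mask]))
        for b in scene.band_names
    }
    return SensorOffsets(reference.sensor_id, offsets)


def apply_offsets(
    scene: MultispectralScene, offsets: SensorOffsets
) -> MultispectralScene:
    """Shift each band by -offset so the scene matches the reference sensor."""
    _check_bands(scene.band_names, offsets.offsets)
    bands = {
        b: scene.bands[b] - offsets.offsets[b] for b in scene.band_names
    }
    return MultispectralScene(bands, scene.sensor_id, scene.cell_size)


class NearestClassMean:
    """Two-class discriminant: assign each pixel to the closest class mean.

    With equal class covariances and priors this is the linear-discriminant
    decision rule on the reflectance vector.  Configure with class spectra
    mapping {"guano": {band: mean}, "non_guano": {band: mean}}.
    """

    def __init__(self, spectra: dict[str, dict[str, float]]):
        if set(spectra) != {"guano", "non_guano"}:
            raise ValueError("spectra must define 'guano' and 'non_guano'")
        _check_bands(spectra["guano"], spectra["non_guano"])
        self.spectra = spectra

    def __call__(self, scene: MultispectralScene) -> np.ndarray:
        _check_bands(scene.band_names, self.spectra["guano"])
        bands = sorted(scene.band_names)
        stack = np.stack([scene.bands[b] for b in bands], axis=-1)
        mu_g = np.array([self.spectra["guano"][b] for b in bands])
        mu_n = np.array([self.spectra["non_guano"][b] for b in bands])
        d_g = ((stack - mu_g) ** 2).sum(axis=-1)
        d_n = ((stack - mu_n) ** 2).sum(axis=-1)
        return d_g < d_n


def classify_guano(
    scene: MultispectralScene,
    classifier=None,
    spectra: dict[str, dict[str, float]] | None = None,
    epoch: str = "",
) -> GuanoMask:
    """Classify guano pixels with a pluggable classifier.

    Either pass a ``classifier`` callable (scene -> boolean array) or class
    ``spectra`` for the default nearest-class-mean discriminant.  The
    result is deterministic for fixed inputs.
    """
    if classifier is None:
        if spectra is None:
            raise ValueError(
                "untrained classifier: provide a classifier or class spectra"
            )
        classifier = NearestClassMean(spectra)
    mask = np.asarray(classifier(scene), dtype=bool)
    if mask.shape != scene.shape:
        raise ValueError("classifier output shape does not match the scene")
    return GuanoMask(mask, scene.cell_size, epoch)


def reduce_to_grid(
    source,
    cell_size: float = 30.0,
    threshold: float = 0.5,
    fine_cell_size: float | None = None,
    bounds: tuple[float, float, float, float] | None = None,
    epoch: str = "",
) -> GuanoMask:
    """Reduce polygons or a fine mask to a coarse grid by covered fraction.

    A coarse cell is guano iff the covered fraction is >= ``threshold``
    (default 0.5, majority rule — approximately area-preserving).

    ``source`` may be a shapely Polygon/MultiPolygon (or list of Polygons),
    in which case the grid is anchored at multiples of ``cell_size`` over
    ``bounds`` (default: the geometry envelope), or a fine boolean mask
    together with its ``fine_cell_size``, which must divide ``cell_size``
    evenly.  Reducing a mask already on the target grid is the identity.
    """
    if isinstance(source, np.ndarray) or isinstance(source, GuanoMask):
        if isinstance(source, GuanoMask):
            fine_cell_size = source.cell_size
            fine = source.mask
        else:
            if fine_cell_size is None:
                raise ValueError("fine_cell_size required for mask input")
            fine = np.asarray(source, dtype=bool)
        factor = cell_size / fine_cell_size
        if abs(factor - round(factor)) > 1e-9:
            raise ValueError(
                f"cell_size {cell_size} must be an integer multiple of the "
                f"fine cell size {fine_cell_size}"
            )
        factor = int(round(factor))
        frac = block_reduce(fine.astype(float), (factor, factor), np.mean)
        return GuanoMask(frac >= threshold, cell_size, epoch)

    polys = source if isinstance(source, (list, tuple)) else [source]
    geoms = []
    for p in polys:
        if hasattr(p, "geoms"):
            geoms.extend(p.geoms)
        else:
            geoms.append(p)
    for g in geoms:
        if not g.is_valid or not np.all(np.isfinite(np.asarray(g.bounds))):
            raise ValueError("non-finite or invalid geometry")
    xmin = min(g.bounds[0] for g in geoms)
    ymin = min(g.bounds[1] for g in geoms)
    xmax = max(g.bounds[2] for g in geoms)
    ymax = max(g.bounds[3] for g in geoms)
    if bounds is not None:
        xmin, ymin, xmax, ymax = bounds
    # snap grid origin to multiples of cell_size so gridding is canonical
    x0 = math.floor(xmin / cell_size) * cell_size
    y0 = math.floor(ymin / cell_size) * cell_size
    ncols = int(math.ceil((xmax - x0) / cell_size)) or 1
    nrows = int(math.ceil((ymax - y0) / cell_size)) or 1
    out = np.zeros((nrows, ncols), dtype=bool)
    cell_area = cell_size * cell_size
    for i in range(nrows):
        # row 0 at the top (north), consistent with raster convention
        cy_hi = y0 + (nrows - i) * cell_size
        for j in range(ncols):
            cell = box(x0 + j * cell_size, cy_hi - cell_size,
                       x0 + (j + 1) * cell_size, cy_hi)
            covered = sum(g.intersection(cell).area for g in geoms)
            out[i, j] = covered / cell_area >= threshold
    return GuanoMask(out, cell_size, epoch)


def compare_epochs(masks: list[GuanoMask]) -> dict[str, pd.DataFrame]:
    """Area per epoch plus pairwise change statistics on a common grid.

    Returns {"areas": per-epoch area table, "changes": consecutive-pair
    table with gained/lost/stable cell counts and area ratios}.  For any
    pair, gained - lost equals the difference in guano cell counts.
    """
    if len(masks) == 0:
        raise ValueError("need at least one mask")
    shape = masks[0].mask.shape
    cell = masks[0].cell_size
    for m in masks:
        if m.mask.shape != shape or m.cell_size != cell:
            raise ValueError("masks are not on a common grid")
    areas = pd.DataFrame({
        "epoch": [m.epoch for m in masks],
        "cells": [int(m.mask.sum()) for m in masks],
        "area_m2": [m.area_m2 for m in masks],
    })
    rows = []
    for a, b in zip(masks[:-1], masks[1:]):
        gained = int((b.mask & ~a.mask).sum())
        lost = int((a.mask & ~b.mask).sum())
        stable = int((a.mask & b.mask).sum())
        na, nb = int(a.mask.sum()), int(b.mask.sum())
        rows.append({
            "epoch_a": a.epoch, "epoch_b": b.epoch,
            "gained": gained, "lost": lost, "stable": stable,
            "area_ratio": (nb / na) if na else math.inf if nb else 1.0,
        })
    changes = pd.DataFrame(rows, columns=["epoch_a", "epoch_b", "gained",
                                          "lost", "stable", "area_ratio"])
    return {"areas": areas, "changes": changes}
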