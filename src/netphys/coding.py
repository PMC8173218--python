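"""Sparse-coding counts and empirical receptive-field mapping.

The sparse-coding measure is simply the number of units in a channel's
spatial map with strictly positive activation.  The empirical receptive
field (ERF) of a channel localizes the part of the theoretical receptive
field that actually drives it under preferred stimuli: per image, the
channel's activation map is bilinearly up-sampled to the input size,
each unit's mean up-sampled activation within its (clipped) theoretical
receptive field is computed, the winning unit's box is cropped, and the
crops are averaged across images on a common size x size canvas.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .activations import (
    ActivationDataset,
    RFGeometry,
    unit_rf_bounds,
    unit_rf_box_unclipped,
)

__all__ = [
    "EmpiricalRF",
    "count_active_units",
    "upsample_map",
    "empirical_rf",
    "erf_half_max_area",
]


def count_active_units(spatial_map) -> int:
    """Number of units with strictly positive activation."""
    return int(np.count_nonzero(np.asarray(spatial_map) > 0))


def upsample_map(spatial_map, input_size: tuple[int, int]) -> np.ndarray:
    """Bilinear up-sampling of an activation map to the input-image size.

    Uses the half-pixel-center convention (edge values extended); a
    constant map up-samples to the same constant.
    """
    m = np.asarray(spatial_map, dtype=float)
    if m.ndim != 2:
        raise ValueError("spatial map must be 2-d")
    H, W = input_size
    if H < m.shape[0] or W < m.shape[1]:
        raise ValueError("target size must be at least the source size")
    if (H, W) == m.shape:
        return m.copy()
    return resize(m, (H, W), order=1, mode="edge", anti_aliasing=False,
                  preserve_range=True)


@dataclass
class EmpiricalRF:
    """Average cropped up-sampled activation around per-image winning units.

    ``map`` is a geometry.size x geometry.size canvas; boundary crops are
    placed at their within-box offset and averaged with per-pixel counts,
    so edge images do not shrink the field.  ``counts`` records how many
    images contributed to each canvas pixel.
    """

    map: np.ndarray
    counts: np.ndarray
    winner_units: list
    geometry: RFGeometry
    n_images_used: int
    skipped_images: list = field(default_factory=list)

    def centroid(self) -> tuple[float, float]:
        """Activation-weighted centroid (row, col) of the ERF canvas."""
        m = self.map
        total = m.sum()
        if total <= 0:
            raise ValueError("empty ERF map")
        rr, cc = np.mgrid[0 : m.shape[0], 0 : m.shape[1]]
        return float((rr * m).sum() / total), float((cc * m).sum() / total)


def _box_means(up: np.ndarray, geom: RFGeometry, grid: tuple[int, int]) -> np.ndarray:
    """Mean up-sampled activation within every unit's clipped RF box.

    Summed-area table makes each box mean O(1).
    """
    H, W = up.shape
    sat = np.zeros((H + 1, W + 1))
    sat[1:, 1:] = up.cumsum(0).cumsum(1)
    gh, gw = grid
    means = np.empty((gh, gw))
    for r in range(gh):
        for c in range(gw):
            r0, r1, c0, c1 = unit_rf_bounds(geom, (r, c), (H, W), grid_shape=grid)
            area = (r1 - r0) * (c1 - c0)
            if area <= 0:
                means[r, c] = -np.inf  # box entirely off-image
                continue
            s = sat[r1, c1] - sat[r0, c1] - sat[r1, c0] + sat[r0, c0]
            means[r, c] = s / area
    return means


def empirical_rf(dataset: ActivationDataset, channel: int, geom: RFGeometry,
                 input_size: tuple[int, int]) -> EmpiricalRF:
    """Empirical receptive field of one channel over a stimulus set.

    Per image: up-sample the channel map to ``input_size``, pick the unit
    whose clipped theoretical RF box has the highest mean up-sampled
    activation (ties broken by lowest (row, col)), crop that box, and
    accumulate the crop on a ``geom.size``-square canvas aligned to the
    unit center.  All-zero maps have no defined winner and are skipped
    with a warning.
    """
    if not 0 <= channel < dataset.n_channels:
        raise IndexError(f"channel {channel} outside dataset")
    H, W = input_size
    grid = dataset.map_shape
    size = geom.size
    canvas = np.zeros((size, size))
    counts = np.zeros((size, size))
    winners: list = []
    skipped: list = []
    for i in range(dataset.n_images):
        m = dataset.activations[i, channel]
        if not np.any(m > 0):
            warnings.warn(f"image {i}: all-zero map, winner undefined, skipped")
            skipped.append(i)
            winners.append(None)
            continue
        up = upsample_map(m, (H, W))
        means = _box_means(up, geom, grid)
        flat = int(np.argmax(means))  # first occurrence = lowest (row, col)
        unit = (flat // grid[1], flat % grid[1])
        winners.append(unit)
        r0, r1, c0, c1 = unit_rf_bounds(geom, unit, (H, W), grid_shape=grid)
        ur0, _, uc0, _ = unit_rf_box_unclipped(geom, unit)
        orow, ocol = r0 - ur0, c0 - uc0  # offset of the clipped crop in the canvas
        canvas[orow : orow + (r1 - r0), ocol : ocol + (c1 - c0)] += up[r0:r1, c0:c1]
        counts[orow : orow + (r1 - r0), ocol : ocol + (c1 - c0)] += 1
    used = dataset.n_images - len(skipped)
    if used == 0:
        raise ValueError("no image produced a defined winner unit")
    out = np.zeros_like(canvas)
    np.divide(canvas, counts, out=out, where=counts > 0)
    return EmpiricalRF(out, counts, winners, geom, used, skipped)


def erf_half_max_area(erf: EmpiricalRF | np.ndarray, threshold: float = 0.5) -> int:
    """Number of canvas pixels at or above ``threshold`` x the ERF peak.

    A compact size summary of the field: smaller area = more focused RF.
    """
    m = erf.map if isinstance(erf, EmpiricalRF) else np.asarray(erf, dtype=float)
    peak = m.max()
    if peak <= 0:
        return 0
    return int(np.count_nonzero(m >= threshold * peak))
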