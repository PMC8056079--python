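"""Prognostic heatmaps by patch occlusion.

A cubic patch is zeroed in both scans of a pair, the model is re-scored,
and the patch importance is the absolute change in prediction. Scrolling
the patch across the grid in stride steps and taking, per voxel, the
maximum importance over every covering patch yields the heatmap.
Trailing patch positions are clipped at the volume boundary so every
voxel is covered.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .grids import ScanPair, VolumeGrid

DEFAULT_PATCH = 64
DEFAULT_STRIDE = 8


@dataclass
class PrognosticHeatmap:
    importance: np.ndarray
    patch_size: int = DEFAULT_PATCH
    stride: int = DEFAULT_STRIDE

    def __post_init__(self):
        if np.any(self.importance < 0):
            raise ValueError("importance must be non-negative")


def _as_array(volume):
    return volume.intensities if isinstance(volume, VolumeGrid) \
        else np.asarray(volume)


def _clip_roi(roi, shape) -> tuple:
    out = []
    for (a, b), n in zip(roi, shape):
        a2, b2 = max(int(a), 0), min(int(b), n)
        if a2 >= b2:
            return None
        out.append(slice(a2, b2))
    return tuple(out)


def occlude(volume, roi):
    """Copy of ``volume`` with the (z, y, x) box ``roi`` set to zero.

    ``roi`` is ((z0, z1), (y0, y1), (x0, x1)), half-open; it is clipped
    to the volume and must intersect it. The input is untouched.
    """
    arr = _as_array(volume)
    sl = _clip_roi(roi, arr.shape)
    if sl is None:
        raise ValueError(f"ROI {roi} does not intersect the volume")
    out = arr.copy()
    out[sl] = 0.0
    if isinstance(volume, VolumeGrid):
        return volume.with_intensities(out)
    return out


def roi_positions(shape, patch: int, stride: int):
    """All ROI boxes scrolling through the grid: starts at multiples of
    ``stride`` per axis, extents clipped at the boundary."""
    if patch < stride:
        raise ValueError("patch must be >= stride")
    axes = [range(0, n, stride) for n in shape]
    for starts in itertools.product(*axes):
        yield tuple((s, min(s + patch, n)) for s, n in zip(starts, shape))


def prognostic_heatmap(model_fn, pair: ScanPair,
                       patch: int = DEFAULT_PATCH,
                       stride: int = DEFAULT_STRIDE) -> PrognosticHeatmap:
    """Occlusion-sensitivity heatmap for one scan pair.

    ``model_fn(prior, subsequent, t_start, t_delta) -> scalar`` is the
    full prediction path. Both scans are occluded at the same location;
    per-voxel importance is the maximum of |occluded - reference| over
    every patch position covering the voxel.
    """
    prior = _as_array(pair.prior)
    subsequent = _as_array(pair.subsequent)
    t_start = float(pair.days_from_treatment_start)
    t_delta = float(pair.days_between_scans)
    reference = float(model_fn(prior, subsequent, t_start, t_delta))
    heat = np.zeros(subsequent.shape, dtype=np.float64)
    for roi in roi_positions(subsequent.shape, patch, stride):
        sl = tuple(slice(a, b) for a, b in roi)
        occ_p = prior.copy()
        occ_s = subsequent.copy()
        occ_p[sl] = 0.0
        occ_s[sl] = 0.0
        score = float(model_fn(occ_p, occ_s, t_start, t_delta))
        importance = abs(score - reference)
        np.maximum(heat[sl], importance, out=heat[sl])
    return PrognosticHeatmap(importance=heat, patch_size=patch, stride=stride)
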