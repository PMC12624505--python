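"""Peak detection on total ion images.

Pixels above lambda1 * sigma (population SD over all cells, zeros included)
survive thresholding; survivors are clustered with DBSCAN on integer pixel
coordinates; each cluster yields its bounding rectangle, recursively bisected
while its RT1 width exceeds 50 s or its RT2 height exceeds 1 s.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.cluster import DBSCAN

from lifetracer import grid
from lifetracer.tii import TIIGrid


@dataclass(frozen=True)
class DetectionParams:
    lambda1: float = 5.0
    dbscan_min_samples: int = 20
    dbscan_eps: float = 5.0
    split_rt1_max: float = 50.0  # seconds
    split_rt2_max: float = 1.0  # seconds

    def __post_init__(self):
        for name in ("lambda1", "dbscan_min_samples", "dbscan_eps", "split_rt1_max", "split_rt2_max"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class Peak:
    """Rectangular detection on one TII.

    Retention windows are in seconds on the fixed axes; ``irect`` is the
    total intensity of the (thresholded) rectangle.  Pixel-index bounds are
    kept for filter stages that need grid geometry.
    """

    sample_id: str
    mz_bin: int
    rt1_min: float
    rt1_max: float
    rt2_min: float
    rt2_max: float
    apex_rt1: float
    apex_rt2: float
    apex_intensity: float
    irect: float
    row_min: int = 0
    row_max: int = 0
    col_min: int = 0
    col_max: int = 0


def tii_sigma(tii: TIIGrid) -> float:
    """Population standard deviation over every cell, zeros included."""
    return float(np.std(tii.values))


def threshold_tii(tii: TIIGrid, lambda1: float, sigma: float) -> TIIGrid:
    """Zero every pixel with intensity <= lambda1 * sigma (strict > survives)."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    cut = lambda1 * sigma
    values = np.where(tii.values > cut, tii.values, 0.0)
    return TIIGrid(
        sample_id=tii.sample_id,
        mz_bin=tii.mz_bin,
        values=values,
        rt1_axis=tii.rt1_axis,
        rt2_axis=tii.rt2_axis,
    )


def _axis_step(axis: np.ndarray, default: float) -> float:
    return float(axis[1] - axis[0]) if len(axis) > 1 else default


def _split_pixels(
    rows: np.ndarray,
    cols: np.ndarray,
    params: DetectionParams,
    rt1_step: float,
    rt2_step: float,
):
    """Recursively bisect a pixel set while its bbox exceeds the RT limits.

    Splits happen at the geometric midpoint of the offending axis; each split
    strictly shrinks the extent, so recursion terminates.  Yields
    (rows, cols) pixel subsets whose bounding boxes satisfy both limits.
    """
    r0, r1 = int(rows.min()), int(rows.max())
    c0, c1 = int(cols.min()), int(cols.max())
    width_s = (c1 - c0) * rt1_step
    height_s = (r1 - r0) * rt2_step
    if width_s > params.split_rt1_max:
        mid = (c0 + c1) / 2.0
        left = cols <= mid
        yield from _split_pixels(rows[left], cols[left], params, rt1_step, rt2_step)
        yield from _split_pixels(rows[~left], cols[~left], params, rt1_step, rt2_step)
    elif height_s > params.split_rt2_max:
        mid = (r0 + r1) / 2.0
        low = rows <= mid
        yield from _split_pixels(rows[low], cols[low], params, rt1_step, rt2_step)
        yield from _split_pixels(rows[~low], cols[~low], params, rt1_step, rt2_step)
    else:
        yield rows, cols


def _peak_from_box(thresh: TIIGrid, r0: int, r1: int, c0: int, c1: int) -> Peak:
    rect = thresh.values[r0 : r1 + 1, c0 : c1 + 1]
    flat = int(np.argmax(rect))
    ar, ac = np.unravel_index(flat, rect.shape)
    return Peak(
        sample_id=thresh.sample_id,
        mz_bin=thresh.mz_bin,
        rt1_min=float(thresh.rt1_axis[c0]),
        rt1_max=float(thresh.rt1_axis[c1]),
        rt2_min=float(thresh.rt2_axis[r0]),
        rt2_max=float(thresh.rt2_axis[r1]),
        apex_rt1=float(thresh.rt1_axis[c0 + ac]),
        apex_rt2=float(thresh.rt2_axis[r0 + ar]),
        apex_intensity=float(rect[ar, ac]),
        irect=float(rect.sum()),
        row_min=r0,
        row_max=r1,
        col_min=c0,
        col_max=c1,
    )


def cluster_pixels(thresh: TIIGrid, params: DetectionParams) -> list[Peak]:
    """Density-cluster surviving pixels and emit bounding-rectangle peaks.

    Assumes ``thresh`` has already been thresholded; DBSCAN noise pixels are
    discarded, oversized clusters are split recursively.
    """
    rows, cols = np.nonzero(thresh.values)
    if rows.size == 0:
        return []
    coords = np.column_stack([rows, cols]).astype(float)
    labels = DBSCAN(eps=params.dbscan_eps, min_samples=params.dbscan_min_samples).fit_predict(coords)
    rt1_step = _axis_step(thresh.rt1_axis, grid.RT1_STEP)
    rt2_step = _axis_step(thresh.rt2_axis, grid.RT2_STEP)
    peaks: list[Peak] = []
    for lab in np.unique(labels):
        if lab < 0:
            continue
        sel = labels == lab
        for prow, pcol in _split_pixels(rows[sel], cols[sel], params, rt1_step, rt2_step):
            peaks.append(
                _peak_from_box(
                    thresh, int(prow.min()), int(prow.max()), int(pcol.min()), int(pcol.max())
                )
            )
    peaks.sort(key=lambda p: (p.col_min, p.row_min, p.col_max, p.row_max))
    return peaks


def detect_peaks(tii: TIIGrid, params: DetectionParams | None = None) -> list[Peak]:
    """Full single-image detection: sigma, threshold, cluster, split."""
    params = params or DetectionParams()
    sigma = tii_sigma(tii)
    thresh = threshold_tii(tii, params.lambda1, sigma)
    return cluster_pixels(thresh, params)
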