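"""Automatic parameter calibration.

Grid search over (lambda1, lambda2) scores each pair by how many expected
(compound, sample) occurrences from an expert-verified reference set are
recovered by detection + filtering within +/-50 s RT1 and +/-1 s RT2; among
pairs above 90% accuracy the largest lambda1 is taken and, for it, the
median passing lambda2.  Clustering tolerances are then derived from the
cross-sample retention-time dispersion of the matched reference peaks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from lifetracer.errors import CalibrationError, ValidationError
from lifetracer.filters import FilterParams, apply_filter_cascade
from lifetracer.peaks import DetectionParams, Peak, cluster_pixels, threshold_tii, tii_sigma
from lifetracer.raw_io import RawScanTable
from lifetracer.tii import build_tii, quantize_scans

logger = logging.getLogger(__name__)

LAMBDA1_GRID = tuple(range(1, 21))
LAMBDA2_GRID = (1,) + tuple(range(10, 201, 10))

RT1_TOLERANCE = 50.0  # seconds, matching window for reference recovery
RT2_TOLERANCE = 1.0


@dataclass
class ReferenceCompound:
    name: str
    mz_bin: int
    #: sample_id -> (present, rt1, rt2); rt values are the expected apex
    expected: dict[str, tuple[bool, float, float]]

    def __post_init__(self):
        if not any(present for present, _, _ in self.expected.values()):
            raise ValidationError(f"reference compound {self.name!r} has no expected presence")


@dataclass
class CalibrationResult:
    accuracy_surface: dict[tuple[int, int], float]
    selected_lambda1: int
    selected_lambda2: int
    rt1_thrsh: float
    rt2_thrsh: float


def _match_peak(
    peaks: list[Peak], rt1: float, rt2: float
) -> Peak | None:
    """Highest-irect peak whose apex lies within the recovery tolerances."""
    best = None
    for p in peaks:
        if abs(p.apex_rt1 - rt1) <= RT1_TOLERANCE and abs(p.apex_rt2 - rt2) <= RT2_TOLERANCE:
            if best is None or p.irect > best.irect:
                best = p
    return best


def _detect_for_bins(
    raw: RawScanTable,
    bins: list[int],
    lambda1: float,
    detection: DetectionParams,
) -> dict[int, tuple[list[Peak], float, "object"]]:
    """Detection (no filtering) for the given bins; returns peaks, sigma and
    the thresholded grid per bin so multiple lambda2 values can reuse them."""
    out = {}
    params = DetectionParams(
        lambda1=lambda1,
        dbscan_min_samples=detection.dbscan_min_samples,
        dbscan_eps=detection.dbscan_eps,
        split_rt1_max=detection.split_rt1_max,
        split_rt2_max=detection.split_rt2_max,
    )
    for b in bins:
        tii = build_tii(quantize_scans(raw, b), raw.sample_id, b)
        sigma = tii_sigma(tii)
        thresh = threshold_tii(tii, lambda1, sigma)
        out[b] = (cluster_pixels(thresh, params), sigma, thresh)
    return out


def recovery_accuracy(
    lambda1: float,
    lambda2: float,
    refs: list[ReferenceCompound],
    raw_samples: dict[str, RawScanTable],
    detection: DetectionParams | None = None,
    filters: FilterParams | None = None,
) -> float:
    """Fraction of expected (compound, sample) presences recovered.

    Runs detection at lambda1 and the full filter cascade at lambda2 on the
    reference compounds' m/z bins only (a match requires the same bin, so
    the restriction does not change the score).
    """
    if not refs:
        raise ValidationError("empty reference set")
    detection = detection or DetectionParams()
    filters = filters or FilterParams()
    fparams = FilterParams(
        tii_nonzero_max_fraction=filters.tii_nonzero_max_fraction,
        lambda2=lambda2,
        strip_ratio_thresholds=dict(filters.strip_ratio_thresholds),
        band_dilation_px=filters.band_dilation_px,
    )
    total = 0
    hit = 0
    for sample_id, raw in raw_samples.items():
        wanted = sorted({r.mz_bin for r in refs if r.expected.get(sample_id, (False,))[0]})
        detected = _detect_for_bins(raw, wanted, lambda1, detection)
        for ref in refs:
            present, rt1, rt2 = ref.expected.get(sample_id, (False, 0.0, 0.0))
            if not present:
                continue
            total += 1
            peaks, sigma, thresh = detected[ref.mz_bin]
            surviving, _ = apply_filter_cascade(thresh, peaks, sigma, fparams)
            if _match_peak(surviving, rt1, rt2) is not None:
                hit += 1
    if total == 0:
        raise ValidationError("reference set expects no presences")
    return hit / total


def grid_search(
    refs: list[ReferenceCompound],
    raw_samples: dict[str, RawScanTable],
    lambda1_grid=LAMBDA1_GRID,
    lambda2_grid=LAMBDA2_GRID,
    detection: DetectionParams | None = None,
    filters: FilterParams | None = None,
) -> dict[tuple[int, int], float]:
    """Exhaustive accuracy surface over the (lambda1, lambda2) grid.

    Detection depends only on lambda1, so each sample/bin is detected once
    per lambda1 and the filter cascade re-run per lambda2.
    """
    if not refs:
        raise ValidationError("empty reference set")
    detection = detection or DetectionParams()
    filters = filters or FilterParams()
    surface: dict[tuple[int, int], float] = {}
    # expected presences, fixed across the surface
    expected = [
        (ref, sample_id, rt1, rt2)
        for ref in refs
        for sample_id, (present, rt1, rt2) in ref.expected.items()
        if present and sample_id in raw_samples
    ]
    if not expected:
        raise ValidationError("reference set expects no presences in the provided samples")
    for l1 in lambda1_grid:
        per_sample = {
            sid: _detect_for_bins(
                raw,
                sorted({r.mz_bin for r in refs if r.expected.get(sid, (False,))[0]}),
                float(l1),
                detection,
            )
            for sid, raw in raw_samples.items()
        }
        for l2 in lambda2_grid:
            fparams = FilterParams(
                tii_nonzero_max_fraction=filters.tii_nonzero_max_fraction,
                lambda2=float(l2),
                strip_ratio_thresholds=dict(filters.strip_ratio_thresholds),
                band_dilation_px=filters.band_dilation_px,
            )
            hit = 0
            for ref, sid, rt1, rt2 in expected:
                peaks, sigma, thresh = per_sample[sid][ref.mz_bin]
                surviving, _ = apply_filter_cascade(thresh, peaks, sigma, fparams)
                if _match_peak(surviving, rt1, rt2) is not None:
                    hit += 1
            surface[(int(l1), int(l2))] = hit / len(expected)
    return surface


def select_params(
    surface: dict[tuple[int, int], float], min_accuracy: float = 0.90
) -> tuple[int, int]:
    """Pick (lambda1*, lambda2*) from the accuracy surface.

    Among cells with accuracy strictly above ``min_accuracy``: take the
    largest lambda1 present, then the median of its passing lambda2 values
    (lower of the two middles for even counts).
    """
    passing = {k: a for k, a in surface.items() if a > min_accuracy}
    if not passing:
        best = max(surface.values()) if surface else float("nan")
        raise CalibrationError(
            f"no (lambda1, lambda2) reached accuracy > {min_accuracy}; best achieved {best}"
        )
    l1_star = max(l1 for l1, _ in passing)
    l2_values = sorted(l2 for l1, l2 in passing if l1 == l1_star)
    l2_star = l2_values[(len(l2_values) - 1) // 2]  # lower median
    return l1_star, l2_star


def derive_rt_thresholds(
    refs: list[ReferenceCompound],
    detected_peaks: dict[str, list[Peak]],
) -> tuple[float, float]:
    """Clustering tolerances from worst-case reference RT dispersion.

    For each compound, match its expected occurrences to surviving peaks and
    take max-min of the matched apex RT1 (and RT2) across samples; compounds
    matched in fewer than two samples are excluded with a warning.  The
    maxima over compounds are rounded: RT1 up to the whole second, RT2 to
    the nearest 0.1 s, floored at the grid granularity (1 s, 0.1 s).
    """
    disp1: list[float] = []
    disp2: list[float] = []
    for ref in refs:
        rt1s = []
        rt2s = []
        for sample_id, (present, rt1, rt2) in ref.expected.items():
            if not present:
                continue
            match = _match_peak(detected_peaks.get(sample_id, []), rt1, rt2)
            if match is not None:
                rt1s.append(match.apex_rt1)
                rt2s.append(match.apex_rt2)
        if len(rt1s) < 2:
            logger.warning(
                "reference compound %s matched in %d sample(s); excluded from "
                "threshold derivation",
                ref.name,
                len(rt1s),
            )
            continue
        disp1.append(max(rt1s) - min(rt1s))
        disp2.append(max(rt2s) - min(rt2s))
    if not disp1:
        raise CalibrationError("no reference compound was matched in >= 2 samples")
    return round_rt_dispersions(max(disp1), max(disp2))


def round_rt_dispersions(rt1_dispersion: float, rt2_dispersion: float) -> tuple[float, float]:
    """Round worst-case dispersions to thresholds (ceil to 1 s; 0.1 s nearest)."""
    rt1 = max(1.0, float(math.ceil(rt1_dispersion)))
    rt2 = max(0.1, float(np.round(rt2_dispersion, 1)))
    return rt1, rt2


def calibrate(
    refs: list[ReferenceCompound],
    raw_samples: dict[str, RawScanTable],
    min_accuracy: float = 0.90,
    lambda1_grid=LAMBDA1_GRID,
    lambda2_grid=LAMBDA2_GRID,
    detection: DetectionParams | None = None,
    filters: FilterParams | None = None,
) -> CalibrationResult:
    """End-to-end calibration: surface, parameter choice, RT thresholds."""
    detection = detection or DetectionParams()
    filters = filters or FilterParams()
    surface = grid_search(
        refs, raw_samples, lambda1_grid, lambda2_grid, detection, filters
    )
    l1, l2 = select_params(surface, min_accuracy)
    fparams = FilterParams(
        tii_nonzero_max_fraction=filters.tii_nonzero_max_fraction,
        lambda2=float(l2),
        strip_ratio_thresholds=dict(filters.strip_ratio_thresholds),
        band_dilation_px=filters.band_dilation_px,
    )
    surviving: dict[str, list[Peak]] = {}
    for sid, raw in raw_samples.items():
        bins = sorted({r.mz_bin for r in refs if r.expected.get(sid, (False,))[0]})
        surviving[sid] = []
        for b, (peaks, sigma, thresh) in _detect_for_bins(raw, bins, float(l1), detection).items():
            kept, _ = apply_filter_cascade(thresh, peaks, sigma, fparams)
            surviving[sid].extend(kept)
    rt1_thrsh, rt2_thrsh = derive_rt_thresholds(refs, surviving)
    return CalibrationResult(
        accuracy_surface=surface,
        selected_lambda1=l1,
        selected_lambda2=l2,
        rt1_thrsh=rt1_thrsh,
        rt2_thrsh=rt2_thrsh,
    )
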