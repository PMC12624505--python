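"""Conservative denoising cascade applied after detection.

Three explicit stages in fixed order, each only removing peaks:

1. whole-image rejection — discard every peak of a TII whose thresholded
   nonzero-pixel fraction exceeds 10% (noise spread uniformly over the image);
2. local total-intensity rejection — discard peaks with Irect < lambda2*sigma;
3. strip-region rejection — discard peaks sitting inside full-height column
   bands or full-width row bands whose nonzero-pixel ratio exceeds a
   configured threshold (vertical/horizontal instrument streaks).

DBSCAN's noise-point removal during detection acts as the implicit fourth
filter of the cascade.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from lifetracer.errors import ConfigurationError
from lifetracer.peaks import Peak
from lifetracer.tii import TIIGrid

DEFAULT_STRIP_THRESHOLDS = {"vertical": 0.5, "horizontal": 0.5}


@dataclass
class FilterParams:
    tii_nonzero_max_fraction: float = 0.10
    lambda2: float = 100.0
    #: ratio thresholds per band kind ("vertical" = full-height column band,
    #: "horizontal" = full-width row band); mandatory config with documented
    #: defaults since the originally calibrated values are not recoverable.
    strip_ratio_thresholds: dict = field(default_factory=lambda: dict(DEFAULT_STRIP_THRESHOLDS))
    #: peak bands are the peak's own rows/columns dilated by this many pixels
    band_dilation_px: int = 5

    def __post_init__(self):
        if not (0 < self.tii_nonzero_max_fraction <= 1):
            raise ValueError("tii_nonzero_max_fraction must be in (0, 1]")
        if self.lambda2 <= 0:
            raise ValueError("lambda2 must be positive")


def filter_overall_tii(thresh: TIIGrid, max_fraction: float = 0.10) -> bool:
    """Keep/discard decision for a whole thresholded image.

    Returns True (keep) unless strictly more than ``max_fraction`` of the
    pixels are nonzero.
    """
    return thresh.nonzero_fraction() <= max_fraction


def filter_local_intensity(peaks: list[Peak], sigma: float, lambda2: float = 100.0) -> list[Peak]:
    """Keep peaks with irect >= lambda2 * sigma (Irect < lambda2*sigma discarded)."""
    cut = lambda2 * sigma
    return [p for p in peaks if p.irect >= cut]


def filter_strip_regions(
    thresh: TIIGrid, peaks: list[Peak], params: FilterParams
) -> list[Peak]:
    """Discard peaks lying in dense vertical/horizontal strip bands.

    A vertical band is a single full-height grid column (a horizontal band a
    single full-width row) with ratio = nonzero pixels / band pixels.  A peak
    is associated with every band within ``band_dilation_px`` of its extent
    (the density-clustering reach) and is discarded when any such band's
    ratio exceeds the configured threshold for its kind.
    """
    for kind in ("vertical", "horizontal"):
        if kind not in params.strip_ratio_thresholds:
            raise ConfigurationError(f"missing strip ratio threshold for {kind!r} bands")
    v_thr = params.strip_ratio_thresholds["vertical"]
    h_thr = params.strip_ratio_thresholds["horizontal"]
    nz = thresh.values != 0
    n_rows, n_cols = nz.shape
    col_ratio = nz.sum(axis=0) / n_rows  # per-column nonzero fraction
    row_ratio = nz.sum(axis=1) / n_cols
    d = params.band_dilation_px
    out = []
    for p in peaks:
        c0, c1 = max(0, p.col_min - d), min(n_cols - 1, p.col_max + d)
        r0, r1 = max(0, p.row_min - d), min(n_rows - 1, p.row_max + d)
        if col_ratio[c0 : c1 + 1].max() > v_thr or row_ratio[r0 : r1 + 1].max() > h_thr:
            continue
        out.append(p)
    return out


def apply_filter_cascade(
    thresh: TIIGrid,
    peaks: list[Peak],
    sigma: float,
    params: FilterParams | None = None,
) -> tuple[list[Peak], dict]:
    """Run the fixed cascade overall-TII -> local-intensity -> strip-region.

    Returns the surviving peaks plus a per-stage count report.
    """
    params = params or FilterParams()
    report = {"input": len(peaks)}
    if not filter_overall_tii(thresh, params.tii_nonzero_max_fraction):
        report.update(after_overall_tii=0, after_local_intensity=0, after_strip=0)
        return [], report
    report["after_overall_tii"] = len(peaks)
    peaks = filter_local_intensity(peaks, sigma, params.lambda2)
    report["after_local_intensity"] = len(peaks)
    peaks = filter_strip_regions(thresh, peaks, params)
    report["after_strip"] = len(peaks)
    return peaks, report
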