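"""Quantization of scans into integer m/z bins and total ion image (TII)
construction on the fixed retention-time grid.

A TII is a dense 2D intensity array with RT2 on the rows and RT1 on the
columns; every (sample, m/z bin) pair shares the same axes, so pixel
coordinates are directly comparable across images.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from lifetracer import grid
from lifetracer.raw_io import RawScanTable

logger = logging.getLogger(__name__)


@dataclass
class TIIGrid:
    """Total ion image for one (sample, integer m/z bin)."""

    sample_id: str
    mz_bin: int
    values: np.ndarray  # shape (n_rt2, n_rt1), non-negative
    rt1_axis: np.ndarray = field(default_factory=grid.rt1_axis)
    rt2_axis: np.ndarray = field(default_factory=grid.rt2_axis)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def nonzero_fraction(self) -> float:
        return float(np.count_nonzero(self.values)) / self.values.size

    def total_intensity(self) -> float:
        return float(self.values.sum())


def quantize_scans(raw: RawScanTable, mz_bin: int) -> pd.DataFrame:
    """Collect scans with m/z in [v-0.5, v+0.5) and merge same-(RT1, RT2) rows.

    The window is half-open so adjacent bins partition the m/z axis.  Returns
    a frame with columns rt1, rt2, area (areas summed per retention pair);
    empty when no scan falls in the window.
    """
    if not (grid.MZ_BIN_MIN <= mz_bin <= grid.MZ_BIN_MAX):
        raise ValueError(f"mz_bin {mz_bin} outside [{grid.MZ_BIN_MIN}, {grid.MZ_BIN_MAX}]")
    df = raw.df
    mask = (df["mz"].values >= mz_bin - 0.5) & (df["mz"].values < mz_bin + 0.5)
    sub = df.loc[mask, ["rt1", "rt2", "area"]]
    if sub.empty:
        return sub.reset_index(drop=True)
    out = sub.groupby(["rt1", "rt2"], as_index=False, sort=True)["area"].sum()
    return out


def build_tii(entries: pd.DataFrame, sample_id: str, mz_bin: int) -> TIIGrid:
    """Place quantized entries on the fixed grid with zero imputation.

    Each entry snaps to the nearest axis point (ties toward the lower index);
    entries landing on the same cell accumulate.  Entries outside the grid
    are dropped with a warning.
    """
    values = np.zeros((grid.n_rt2(), grid.n_rt1()), dtype=np.float64)
    if len(entries):
        cols = grid.snap_index(entries["rt1"].values, grid.RT1_START, grid.RT1_STEP)
        rows = grid.snap_index(entries["rt2"].values, grid.RT2_START, grid.RT2_STEP)
        ok = (rows >= 0) & (rows < values.shape[0]) & (cols >= 0) & (cols < values.shape[1])
        n_bad = int((~ok).sum())
        if n_bad:
            logger.warning(
                "%s mz_bin=%d: dropped %d entries outside the fixed RT grid",
                sample_id,
                mz_bin,
                n_bad,
            )
        np.add.at(values, (rows[ok], cols[ok]), entries["area"].values[ok])
    return TIIGrid(sample_id=sample_id, mz_bin=mz_bin, values=values)


class TIIStack(Mapping):
    """Lazy mapping m/z bin -> TIIGrid for one sample.

    Grids are materialized on access and not cached (each dense image is
    ~9 MB); :meth:`nonzero_bins` lists the bins that contain any scan so
    pipelines can skip the all-zero images.
    """

    def __init__(self, raw: RawScanTable, mz_bins=None):
        self.raw = raw
        self.mz_bins = list(mz_bins) if mz_bins is not None else list(grid.all_mz_bins())
        self._bin_set = set(self.mz_bins)

    def __getitem__(self, mz_bin: int) -> TIIGrid:
        if mz_bin not in self._bin_set:
            raise KeyError(mz_bin)
        return build_tii(quantize_scans(self.raw, mz_bin), self.raw.sample_id, mz_bin)

    def __iter__(self) -> Iterator[int]:
        return iter(self.mz_bins)

    def __len__(self) -> int:
        return len(self.mz_bins)

    def nonzero_bins(self) -> list[int]:
        bins = np.unique(grid.mz_to_bin(self.raw.df["mz"].values))
        return [int(b) for b in bins if int(b) in self._bin_set]

    def iter_nonzero(self) -> Iterator[tuple[int, TIIGrid]]:
        for b in self.nonzero_bins():
            yield b, self[b]


def tii_stack(raw: RawScanTable, mz_bins=None) -> TIIStack:
    """Build the lazy per-bin image stack (671 bins by default)."""
    return TIIStack(raw, mz_bins=mz_bins)


def export_png(tii: TIIGrid, path, log_scale: bool = True) -> None:
    """Write a heatmap of the image for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vals = np.log1p(tii.values) if log_scale else tii.values
    fig, ax = plt.subplots(figsize=(10, 3))
    ax.imshow(
        vals,
        origin="lower",
        aspect="auto",
        extent=[tii.rt1_axis[0], tii.rt1_axis[-1], tii.rt2_axis[0], tii.rt2_axis[-1]],
        cmap="viridis",
        interpolation="nearest",
    )
    ax.set_xlabel("RT1 (s)")
    ax.set_ylabel("RT2 (s)")
    ax.set_title(f"{tii.sample_id} m/z {tii.mz_bin}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
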