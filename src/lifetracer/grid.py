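"""Fixed retention-time grid geometry shared by every TII.

The instrument samples the first column every 3.5 s over [2200, 11457.568] s
and the second column every 8 ms over [0, 3.504] s.  All total ion images
share the axes defined here, which is what makes cross-sample pixel
coordinates comparable downstream.
"""

from __future__ import annotations

import math

import numpy as np

RT1_START = 2200.0
RT1_STOP = 11457.568
RT1_STEP = 3.5

RT2_START = 0.0
RT2_STOP = 3.504
RT2_STEP = 0.008

# Observed extremes of the instrument's m/z axis; rows outside are dropped.
MZ_MIN = 29.99778
MZ_MAX = 700.02157

MZ_BIN_MIN = 30
MZ_BIN_MAX = 700


def n_rt1() -> int:
    """Number of RT1 axis points (inclusive grid over the stated range)."""
    return int(math.floor((RT1_STOP - RT1_START) / RT1_STEP + 1e-9)) + 1


def n_rt2() -> int:
    """Number of RT2 axis points; the stated range/step give exactly 439."""
    return int(round((RT2_STOP - RT2_START) / RT2_STEP)) + 1


def rt1_axis() -> np.ndarray:
    return RT1_START + RT1_STEP * np.arange(n_rt1())


def rt2_axis() -> np.ndarray:
    return RT2_START + RT2_STEP * np.arange(n_rt2())


def snap_index(values, start: float, step: float) -> np.ndarray:
    """Snap coordinates to the nearest axis index, ties toward the lower index.

    Does not bounds-check; callers mask with the axis length.
    """
    t = (np.asarray(values, dtype=float) - start) / step
    return np.ceil(t - 0.5).astype(np.int64)


def mz_to_bin(mz) -> np.ndarray:
    """Integer m/z bin under the half-open window [v-0.5, v+0.5)."""
    return np.floor(np.asarray(mz, dtype=float) + 0.5).astype(np.int64)


def all_mz_bins() -> range:
    """Every integer m/z bin of the standard stack (671 bins)."""
    return range(MZ_BIN_MIN, MZ_BIN_MAX + 1)
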