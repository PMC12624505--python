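"""Distributional comparison of peak attributes between classes.

Two-sample Kolmogorov-Smirnov (sup-norm ECDF distance) plus a one-sided
Mann-Whitney U test per attribute.  Exact p-values are used for small
samples (< 50 per side), asymptotic approximations otherwise; the MWU uses
normal approximation with tie correction at scale since retention values
are grid-quantized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from lifetracer.errors import ValidationError

#: directions tested per attribute: is the abiotic ("a") distribution
#: shifted this way relative to the biotic one?
DEFAULT_ALTERNATIVES = {"mz": "less", "rt1": "less", "rt2": "greater"}

_EXACT_N = 50


@dataclass
class DistTestResult:
    attribute: str
    ks_stat: float
    ks_p: float
    mwu_stat: float
    mwu_p: float
    direction: str


def compare_distributions(
    values_a, values_b, attribute: str = "", alternative: str = "two-sided"
) -> DistTestResult:
    """KS and MWU comparison of two samples of one peak attribute.

    ``alternative`` applies to the Mann-Whitney test (a vs b); the KS
    statistic is always the two-sided sup distance.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValidationError("both samples must be non-empty")
    small = min(a.size, b.size) < _EXACT_N
    ks = sps.ks_2samp(a, b, method="exact" if small else "asymp")
    mwu = sps.mannwhitneyu(
        a, b, alternative=alternative, method="exact" if small else "asymptotic"
    )
    return DistTestResult(
        attribute=attribute,
        ks_stat=float(ks.statistic),
        ks_p=float(ks.pvalue),
        mwu_stat=float(mwu.statistic),
        mwu_p=float(mwu.pvalue),
        direction=alternative,
    )


def compare_peak_attributes(
    peaks_a, peaks_b, alternatives: dict | None = None
) -> list[DistTestResult]:
    """Compare m/z, RT1 and RT2 apex distributions of two peak populations."""
    alternatives = alternatives or DEFAULT_ALTERNATIVES
    getters = {
        "mz": lambda p: p.mz_bin,
        "rt1": lambda p: p.apex_rt1,
        "rt2": lambda p: p.apex_rt2,
    }
    results = []
    for attr, get in getters.items():
        results.append(
            compare_distributions(
                [get(p) for p in peaks_a],
                [get(p) for p in peaks_b],
                attribute=attr,
                alternative=alternatives.get(attr, "two-sided"),
            )
        )
    return results


def ecdf_plot(values_a, values_b, attribute: str, path) -> None:
    """Overlay the two empirical CDFs for visual inspection."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for vals, label in ((values_a, "abiotic"), (values_b, "biotic")):
        x = np.sort(np.asarray(vals, dtype=float))
        ax.step(x, np.arange(1, x.size + 1) / x.size, where="post", label=label)
    ax.set_xlabel(attribute)
    ax.set_ylabel("ECDF")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
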