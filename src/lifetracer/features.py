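"""Cross-sample peak clustering into features and the binary presence matrix.

A feature groups peaks that share an integer m/z bin and whose apexes lie
within the RT1/RT2 tolerances of the feature's seed peak.  Clustering is
deterministic: peaks are visited by descending irect (ties broken on
retention times then sample id), each joining the best matching existing
feature or seeding a new one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lifetracer.errors import ValidationError
from lifetracer.peaks import Peak
from lifetracer.raw_io import SampleManifest


@dataclass
class Feature:
    feature_id: int
    mz_bin: int
    rt1_center: float  # seed peak apex
    rt2_center: float
    member_peaks: list[tuple[str, Peak]] = field(default_factory=list)

    @property
    def sample_ids(self) -> set[str]:
        return {s for s, _ in self.member_peaks}


@dataclass
class FeatureMatrix:
    """Binary features x samples presence matrix with per-sample labels."""

    df: pd.DataFrame  # index: feature_id, columns: sample_id, values 0/1
    labels: pd.Series  # index: sample_id -> "abiotic" | "biotic"
    feature_index: pd.DataFrame  # feature_id -> mz_bin, rt1_center, rt2_center

    @property
    def n_features(self) -> int:
        return self.df.shape[0]

    @property
    def n_samples(self) -> int:
        return self.df.shape[1]


def cluster_peaks(
    all_peaks: list[Peak],
    rt1_thrsh: float = 50.0,
    rt2_thrsh: float = 0.8,
) -> list[Feature]:
    """Greedy seed-anchored clustering of peaks into features.

    Visit order: descending irect, then apex rt1, rt2, sample_id.  A peak
    joins the feature with equal mz_bin whose seed apex is within both
    tolerances; if several qualify, the smallest combined normalized distance
    (|d_rt1|/rt1_thrsh + |d_rt2|/rt2_thrsh) wins, then the lower feature_id.
    Otherwise the peak seeds a new feature at its own apex.
    """
    order = sorted(
        all_peaks, key=lambda p: (-p.irect, p.apex_rt1, p.apex_rt2, p.sample_id)
    )
    features: list[Feature] = []
    by_bin: dict[int, list[Feature]] = {}
    for peak in order:
        candidates = []
        for feat in by_bin.get(peak.mz_bin, ()):
            d1 = abs(peak.apex_rt1 - feat.rt1_center)
            d2 = abs(peak.apex_rt2 - feat.rt2_center)
            if d1 <= rt1_thrsh and d2 <= rt2_thrsh:
                candidates.append((d1 / rt1_thrsh + d2 / rt2_thrsh, feat.feature_id, feat))
        if candidates:
            _, _, feat = min(candidates, key=lambda t: (t[0], t[1]))
            feat.member_peaks.append((peak.sample_id, peak))
        else:
            feat = Feature(
                feature_id=len(features),
                mz_bin=peak.mz_bin,
                rt1_center=peak.apex_rt1,
                rt2_center=peak.apex_rt2,
                member_peaks=[(peak.sample_id, peak)],
            )
            features.append(feat)
            by_bin.setdefault(peak.mz_bin, []).append(feat)
    return features


def build_matrix(features: list[Feature], manifest: SampleManifest) -> FeatureMatrix:
    """Binary presence matrix: cell = 1 iff the feature has a peak in the sample."""
    sample_ids = manifest.sample_ids
    known = set(sample_ids)
    for feat in features:
        unknown = feat.sample_ids - known
        if unknown:
            raise ValidationError(
                f"feature {feat.feature_id} references samples not in manifest: {sorted(unknown)}"
            )
    data = np.zeros((len(features), len(sample_ids)), dtype=np.int8)
    col = {s: j for j, s in enumerate(sample_ids)}
    for i, feat in enumerate(features):
        for s in feat.sample_ids:
            data[i, col[s]] = 1
    df = pd.DataFrame(data, index=[f.feature_id for f in features], columns=sample_ids)
    labels = pd.Series(manifest.labels, name="label").reindex(sample_ids)
    feature_index = pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in features],
            "mz_bin": [f.mz_bin for f in features],
            "rt1_center": [f.rt1_center for f in features],
            "rt2_center": [f.rt2_center for f in features],
        }
    ).set_index("feature_id")
    return FeatureMatrix(df=df, labels=labels, feature_index=feature_index)
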