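"""Feature groups: collapse coefficient-ranked features into coeluting
fragment-ion families and run the artifact-zeroing robustness check.

Grouping is anchor-greedy: the highest-|coefficient| unassigned feature
anchors a group that absorbs every unassigned feature within the RT
tolerances of the anchor, regardless of m/z; chains are not merged
transitively.  Groups are ranked by the anchor's |coefficient|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lifetracer.classify import FittedClassifier
from lifetracer.errors import ValidationError
from lifetracer.features import Feature, FeatureMatrix


@dataclass
class FeatureGroup:
    group_id: int
    member_features: list[int]  # feature_ids
    representative: int  # anchor feature_id, max |coefficient|
    coefficient: float  # representative's signed weight
    direction: str  # "abiotic" (positive) or "biotic"
    n_samples_shared: int = 0  # samples containing the representative

    def __contains__(self, feature_id: int) -> bool:
        return feature_id in self.member_features


def group_features(
    features: list[Feature],
    coefficients: dict,
    rt1_thrsh: float = 50.0,
    rt2_thrsh: float = 0.8,
) -> list[FeatureGroup]:
    """Anchor-greedy grouping, ranked by representative |coefficient|.

    Ties on |coefficient| anchor the lower feature_id first; the result
    partitions the feature set.
    """
    missing = [f.feature_id for f in features if f.feature_id not in coefficients]
    if missing:
        raise ValidationError(f"features without coefficients: {missing[:5]}")
    remaining = sorted(
        features, key=lambda f: (-abs(coefficients[f.feature_id]), f.feature_id)
    )
    groups: list[FeatureGroup] = []
    assigned: set[int] = set()
    for anchor in remaining:
        if anchor.feature_id in assigned:
            continue
        members = [
            f.feature_id
            for f in remaining
            if f.feature_id not in assigned
            and abs(f.rt1_center - anchor.rt1_center) <= rt1_thrsh
            and abs(f.rt2_center - anchor.rt2_center) <= rt2_thrsh
        ]
        assigned.update(members)
        coef = float(coefficients[anchor.feature_id])
        groups.append(
            FeatureGroup(
                group_id=len(groups),
                member_features=members,
                representative=anchor.feature_id,
                coefficient=coef,
                direction="abiotic" if coef > 0 else "biotic",
            )
        )
    return groups


def filter_shared_groups(
    groups: list[FeatureGroup], matrix: FeatureMatrix, min_samples: int = 2
) -> list[FeatureGroup]:
    """Keep groups whose representative feature appears in >= min_samples
    samples; annotates n_samples_shared on every group along the way."""
    kept = []
    for g in groups:
        g.n_samples_shared = int(matrix.df.loc[g.representative].sum())
        if g.n_samples_shared >= min_samples:
            kept.append(g)
    return kept


def zero_artifact_groups(
    fitted: FittedClassifier,
    artifact_group_ids: list[int],
    groups: list[FeatureGroup],
    matrix: FeatureMatrix,
) -> dict:
    """Robustness check: zero the coefficients of artifact groups' features
    and re-score every sample.

    Returns accuracies before/after and their delta; the fitted model is not
    modified.
    """
    by_id = {g.group_id: g for g in groups}
    unknown = [gid for gid in artifact_group_ids if gid not in by_id]
    if unknown:
        raise ValidationError(f"unknown group id(s): {unknown}")
    y = (matrix.labels.values == "abiotic").astype(int)
    acc_before = float(np.mean(fitted.predict(matrix) == y))
    zeroed = dict(fitted.coefficients)
    for gid in artifact_group_ids:
        for fid in by_id[gid].member_features:
            zeroed[fid] = 0.0
    stripped = FittedClassifier(
        family=fitted.family,
        hyperparameters=fitted.hyperparameters,
        coefficients=zeroed,
        intercept=fitted.intercept,
        feature_ids=fitted.feature_ids,
    )
    acc_after = float(np.mean(stripped.predict(matrix) == y))
    return {
        "accuracy_before": acc_before,
        "accuracy_after": acc_after,
        "delta": acc_after - acc_before,
    }
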