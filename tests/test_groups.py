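import numpy as np
import pytest

from lifetracer.classify import fit_final
from lifetracer.errors import ValidationError
from lifetracer.features import Feature
from lifetracer.groups import filter_shared_groups, group_features, zero_artifact_groups

from .conftest import make_matrix


def feat(fid, rt1, rt2=1.0, mz_bin=100):
    return Feature(feature_id=fid, mz_bin=mz_bin, rt1_center=rt1, rt2_center=rt2)


class TestGroupFeatures:
    def test_three_coeluting_features_one_group(self):
        feats = [feat(0, 3000.0), feat(1, 3020.0, mz_bin=120), feat(2, 3040.0, mz_bin=140)]
        coefs = {0: 2.0, 1: -1.0, 2: 0.5}
        groups = group_features(feats, coefs)
        assert len(groups) == 1
        assert groups[0].representative == 0
        assert groups[0].coefficient == 2.0
        assert sorted(groups[0].member_features) == [0, 1, 2]

    def test_well_separated_features_ordered_by_coef(self):
        feats = [feat(0, 3000.0), feat(1, 5000.0)]
        coefs = {0: 0.5, 1: -2.0}
        groups = group_features(feats, coefs)
        assert [g.representative for g in groups] == [1, 0]
        assert groups[0].direction == "biotic"
        assert groups[1].direction == "abiotic"

    def test_chain_not_transitively_merged(self):
        # A-B within 50 s, B-C within 50 s, A-C not; |A|>|B|>|C|
        a, b, c = feat(0, 3000.0), feat(1, 3040.0), feat(2, 3080.0)
        coefs = {0: 3.0, 1: 2.0, 2: 1.0}
        groups = group_features([a, b, c], coefs)
        assert [sorted(g.member_features) for g in groups] == [[0, 1], [2]]

    def test_grouping_ignores_mz(self):
        feats = [feat(0, 3000.0, mz_bin=100), feat(1, 3001.0, mz_bin=600)]
        groups = group_features(feats, {0: 1.0, 1: 0.5})
        assert len(groups) == 1

    def test_partition_property(self, rng):
        feats = [
            feat(i, float(rng.uniform(3000, 4000)), float(rng.uniform(0.5, 2.5)))
            for i in range(50)
        ]
        coefs = {i: float(rng.normal()) for i in range(50)}
        groups = group_features(feats, coefs)
        seen = [f for g in groups for f in g.member_features]
        assert sorted(seen) == list(range(50))

    def test_representative_has_max_abs_coef(self, rng):
        feats = [
            feat(i, float(rng.uniform(3000, 3500)), float(rng.uniform(0.5, 2.5)))
            for i in range(40)
        ]
        coefs = {i: float(rng.normal()) for i in range(40)}
        for g in group_features(feats, coefs):
            assert all(abs(coefs[g.representative]) >= abs(coefs[f]) for f in g.member_features)

    def test_members_within_tolerance_of_representative(self, rng):
        feats = [
            feat(i, float(rng.uniform(3000, 3500)), float(rng.uniform(0.5, 2.5)))
            for i in range(40)
        ]
        coefs = {i: float(rng.normal()) for i in range(40)}
        by_id = {f.feature_id: f for f in feats}
        for g in group_features(feats, coefs):
            anchor = by_id[g.representative]
            for fid in g.member_features:
                assert abs(by_id[fid].rt1_center - anchor.rt1_center) <= 50.0
                assert abs(by_id[fid].rt2_center - anchor.rt2_center) <= 0.8

    def test_coefficient_tie_anchors_lower_feature_id(self):
        feats = [feat(0, 3000.0), feat(1, 5000.0)]
        groups = group_features(feats, {0: 1.0, 1: -1.0})
        assert groups[0].representative == 0

    def test_brute_force_oracle_random_sets(self):
        """Independent execution of the stated anchor-greedy procedure."""
        for trial in range(100):
            rng = np.random.default_rng(trial)
            n = int(rng.integers(5, 40))
            feats = [
                feat(i, float(rng.uniform(3000, 3800)), float(rng.uniform(0.2, 3.0)))
                for i in range(n)
            ]
            coefs = {i: float(rng.normal()) for i in range(n)}
            got = group_features(feats, coefs)
            # oracle: repeated max-|coef| extraction over an explicit pool
            pool = {f.feature_id: f for f in feats}
            expected = []
            while pool:
                anchor_id = min(pool, key=lambda i: (-abs(coefs[i]), i))
                anchor = pool[anchor_id]
                members = sorted(
                    i
                    for i, f in pool.items()
                    if abs(f.rt1_center - anchor.rt1_center) <= 50.0
                    and abs(f.rt2_center - anchor.rt2_center) <= 0.8
                )
                expected.append((anchor_id, members))
                for i in members:
                    del pool[i]
            assert [(g.representative, sorted(g.member_features)) for g in got] == expected

    def test_missing_coefficient_rejected(self):
        with pytest.raises(ValidationError):
            group_features([feat(0, 3000.0)], {})


class TestSharedGroups:
    def _setup(self):
        feats = [feat(0, 3000.0), feat(1, 5000.0), feat(2, 7000.0)]
        groups = group_features(feats, {0: 3.0, 1: 2.0, 2: 1.0})
        # presence: feature 0 in 3 samples, 1 in 1 sample, 2 in 2 samples
        data = np.array([[1, 1, 1, 0], [0, 0, 1, 0], [1, 0, 0, 1]])
        matrix = make_matrix(data, ["abiotic", "abiotic", "biotic", "biotic"])
        return groups, matrix

    def test_min_two_samples(self):
        groups, matrix = self._setup()
        kept = filter_shared_groups(groups, matrix, min_samples=2)
        assert [g.representative for g in kept] == [0, 2]
        assert kept[0].n_samples_shared == 3

    def test_min_one_is_identity(self):
        groups, matrix = self._setup()
        assert filter_shared_groups(groups, matrix, min_samples=1) == groups


class TestZeroArtifacts:
    def _fitted_setup(self, seed=0):
        """Signal features track the class; artifact features are all-ones
        and RT-disjoint from the signal."""
        rng = np.random.default_rng(seed)
        y = np.array([1] * 8 + [0] * 10)
        signal = [y.copy() for _ in range(3)]
        artifacts = [np.ones(18, dtype=int) for _ in range(2)]
        noise = [rng.integers(0, 2, 18) for _ in range(5)]
        data = np.array(signal + artifacts + noise)
        import pandas as pd

        meta = pd.DataFrame(
            {
                "mz_bin": 100,
                # signal at 3000-3100 s, artifacts far away at 9000 s, noise beyond
                "rt1_center": [3000.0, 3040.0, 3080.0, 9000.0, 9030.0]
                + [6000.0 + 200 * i for i in range(5)],
                "rt2_center": 1.0,
            },
            index=range(10),
        )
        matrix = make_matrix(data, ["abiotic"] * 8 + ["biotic"] * 10, feature_meta=meta)
        feats = [
            feat(i, meta.loc[i, "rt1_center"], meta.loc[i, "rt2_center"]) for i in range(10)
        ]
        fitted = fit_final(matrix)
        groups = group_features(feats, fitted.coefficients)
        return fitted, groups, matrix

    def test_zero_empty_set_delta_zero(self):
        fitted, groups, matrix = self._fitted_setup()
        out = zero_artifact_groups(fitted, [], groups, matrix)
        assert out["delta"] == 0.0

    def test_zero_artifacts_accuracy_unchanged(self):
        fitted, groups, matrix = self._fitted_setup()
        artifact_ids = [
            g.group_id for g in groups if matrix.feature_index.loc[g.representative, "rt1_center"] >= 9000
        ]
        assert artifact_ids
        out = zero_artifact_groups(fitted, artifact_ids, groups, matrix)
        assert out["accuracy_before"] == 1.0
        assert out["delta"] == 0.0

    def test_zero_all_groups_predicts_from_intercept(self):
        fitted, groups, matrix = self._fitted_setup()
        out = zero_artifact_groups(fitted, [g.group_id for g in groups], groups, matrix)
        expected = 1 if fitted.intercept > 0 else 0
        y = (matrix.labels.values == "abiotic").astype(int)
        assert out["accuracy_after"] == pytest.approx(float(np.mean(y == expected)))

    def test_unknown_group_id_rejected(self):
        fitted, groups, matrix = self._fitted_setup()
        with pytest.raises(ValidationError):
            zero_artifact_groups(fitted, [999], groups, matrix)
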