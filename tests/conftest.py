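import numpy as np
import pandas as pd
import pytest

from lifetracer import grid
from lifetracer.features import FeatureMatrix
from lifetracer.raw_io import ManifestEntry, RawScanTable, SampleManifest
from lifetracer.tii import TIIGrid


def make_tii(values, sample_id="S", mz_bin=100, rt1_step=grid.RT1_STEP, rt2_step=grid.RT2_STEP):
    """TIIGrid from a small 2D array with consistently spaced toy axes."""
    values = np.asarray(values, dtype=float)
    n_rows, n_cols = values.shape
    return TIIGrid(
        sample_id=sample_id,
        mz_bin=mz_bin,
        values=values,
        rt1_axis=grid.RT1_START + rt1_step * np.arange(n_cols),
        rt2_axis=grid.RT2_START + rt2_step * np.arange(n_rows),
    )


def make_raw(rows, sample_id="S"):
    """RawScanTable from (rt1, rt2, mz, area) tuples."""
    df = pd.DataFrame(rows, columns=["rt1", "rt2", "mz", "area"])
    df.insert(0, "spectrum", np.arange(len(df)))
    df["tof"] = 120000.0
    df["resolution"] = 10000.0
    return RawScanTable(sample_id=sample_id, df=df[["spectrum", "rt1", "rt2", "tof", "mz", "area", "resolution"]])


def make_matrix(data, labels, feature_meta=None):
    """FeatureMatrix from a features x samples 0/1 array.

    ``labels`` is a list aligned with columns; columns are named s00, s01...
    and rows 0..n-1.
    """
    data = np.asarray(data, dtype=np.int8)
    sample_ids = [f"s{j:02d}" for j in range(data.shape[1])]
    df = pd.DataFrame(data, index=range(data.shape[0]), columns=sample_ids)
    lab = pd.Series(dict(zip(sample_ids, labels)), name="label").reindex(sample_ids)
    if feature_meta is None:
        feature_meta = pd.DataFrame(
            {
                "mz_bin": 100,
                "rt1_center": 3000.0 + 200.0 * np.arange(data.shape[0]),
                "rt2_center": 1.0,
            },
            index=df.index,
        )
    return FeatureMatrix(df=df, labels=lab, feature_index=feature_meta)


def toy_manifest(sample_labels):
    return SampleManifest(
        entries=[ManifestEntry(sample_id=s, label=l, path="") for s, l in sample_labels]
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_synth_dataset():
    """Shared small synthetic dataset: 3+3 samples, 6 clean compounds."""
    from lifetracer import synth

    config = synth.SynthConfig(
        n_abiotic=3,
        n_biotic=3,
        compounds=synth.default_test_compounds(6),
        background_rate=300,
        background_mz_range=(30.0, 45.0),
        seed=7,
    )
    return synth.generate_dataset(config)
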