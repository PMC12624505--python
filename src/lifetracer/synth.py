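"""Synthetic raw scan tables with known ground truth.

Planted compounds are coeluting fragment-ion sets: every fragment m/z of a
compound shares one jittered (RT1, RT2) center and contributes a truncated
isotropic Gaussian intensity blob in pixel units.  Optional diffuse
exponential background scans and dense strip-noise lines emulate the noise
kinds the denoising cascade targets.  Everything is driven by one seed and
is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from lifetracer import grid
from lifetracer.calibrate import ReferenceCompound
from lifetracer.errors import ConfigurationError, ValidationError
from lifetracer.raw_io import ManifestEntry, RawScanTable, SampleManifest, write_manifest, write_raw_scans

_TRUNCATE_SD = 3.0
_MIN_AREA = 1.0


@dataclass
class PlantedCompound:
    name: str
    fragment_mzs: list[int]
    rt1: float
    rt2: float
    amplitude: float = 5000.0
    footprint_sd_px: float = 1.5
    #: probability of presence per class label
    class_affinity: dict = field(default_factory=lambda: {"abiotic": 1.0, "biotic": 1.0})

    def __post_init__(self):
        if not self.fragment_mzs:
            raise ConfigurationError(f"compound {self.name!r} has no fragment m/z values")
        if not (grid.RT1_START <= self.rt1 <= grid.RT1_STOP):
            raise ConfigurationError(f"compound {self.name!r} rt1 {self.rt1} outside grid")
        if not (grid.RT2_START <= self.rt2 <= grid.RT2_STOP):
            raise ConfigurationError(f"compound {self.name!r} rt2 {self.rt2} outside grid")


@dataclass
class StripNoise:
    mz_bin: int
    axis: str  # "vertical" (fixed RT1, spans RT2) or "horizontal"
    position: float  # seconds on the fixed axis
    density: float = 0.8  # fraction of band pixels carrying a scan
    intensity: float = 5000.0


@dataclass
class SynthConfig:
    n_abiotic: int = 8
    n_biotic: int = 10
    compounds: list = field(default_factory=list)
    rt1_jitter_sd: float = 3.0  # seconds
    rt2_jitter_sd: float = 0.01
    background_rate: int = 0  # scans per sample
    background_mz_range: tuple = (30.0, 700.0)
    background_intensity_scale: float = 20.0
    strip_noise: list = field(default_factory=list)
    mz_scatter: float = 0.2  # within-bin m/z jitter of emitted scans
    seed: int = 0

    def __post_init__(self):
        if self.rt1_jitter_sd < 0 or self.rt2_jitter_sd < 0:
            raise ConfigurationError("jitter standard deviations must be >= 0")


@dataclass
class SynthDataset:
    tables: dict  # sample_id -> RawScanTable
    manifest: SampleManifest
    #: {"labels": {sample: label},
    #:  "occurrences": [{sample, compound, fragment_mz, rt1, rt2}]}
    ground_truth: dict
    config: SynthConfig


def _sample_ids(config: SynthConfig) -> list[tuple[str, str]]:
    ids = [(f"A{i + 1:02d}", "abiotic") for i in range(config.n_abiotic)]
    ids += [(f"B{i + 1:02d}", "biotic") for i in range(config.n_biotic)]
    return ids


def _blob_rows(rng, rt1_c: float, rt2_c: float, mz_frag: float, cfg: SynthConfig, amp: float, sd: float):
    """Scan rows for one fragment blob centered at (rt1_c, rt2_c)."""
    rt1_ax, rt2_ax = grid.rt1_axis(), grid.rt2_axis()
    j0 = int(grid.snap_index(rt1_c, grid.RT1_START, grid.RT1_STEP))
    i0 = int(grid.snap_index(rt2_c, grid.RT2_START, grid.RT2_STEP))
    radius = int(np.ceil(_TRUNCATE_SD * sd))
    rows = []
    for di in range(-radius, radius + 1):
        for dj in range(-radius, radius + 1):
            r2 = di * di + dj * dj
            if r2 > (_TRUNCATE_SD * sd) ** 2:
                continue
            i, j = i0 + di, j0 + dj
            if not (0 <= i < rt2_ax.size and 0 <= j < rt1_ax.size):
                continue
            area = amp * np.exp(-r2 / (2.0 * sd * sd))
            if area < _MIN_AREA:
                continue
            mz = mz_frag + rng.uniform(-cfg.mz_scatter, cfg.mz_scatter)
            rows.append((rt1_ax[j], rt2_ax[i], mz, area))
    return rows


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate scan tables, an in-memory manifest and the ground truth."""
    rng = np.random.default_rng(config.seed)
    rt1_ax, rt2_ax = grid.rt1_axis(), grid.rt2_axis()
    tables: dict[str, RawScanTable] = {}
    occurrences = []
    labels = {}
    for sample_id, label in _sample_ids(config):
        labels[sample_id] = label
        rows: list[tuple[float, float, float, float]] = []
        for comp in config.compounds:
            p = float(comp.class_affinity.get(label, 0.0))
            if rng.random() >= p:
                continue
            rt1_c = comp.rt1 + rng.normal(0.0, config.rt1_jitter_sd)
            rt2_c = comp.rt2 + rng.normal(0.0, config.rt2_jitter_sd)
            rt1_c = float(np.clip(rt1_c, grid.RT1_START, grid.RT1_STOP))
            rt2_c = float(np.clip(rt2_c, grid.RT2_START, grid.RT2_STOP))
            for frag in comp.fragment_mzs:
                rows.extend(
                    _blob_rows(rng, rt1_c, rt2_c, float(frag), config, comp.amplitude, comp.footprint_sd_px)
                )
                occurrences.append(
                    {
                        "sample": sample_id,
                        "compound": comp.name,
                        "fragment_mz": int(frag),
                        "rt1": rt1_c,
                        "rt2": rt2_c,
                    }
                )
        if config.background_rate > 0:
            n = int(config.background_rate)
            lo, hi = config.background_mz_range
            bg_rt1 = rng.uniform(grid.RT1_START, grid.RT1_STOP, n)
            bg_rt2 = rng.uniform(grid.RT2_START, grid.RT2_STOP, n)
            bg_mz = rng.uniform(lo, hi, n)
            bg_area = rng.exponential(config.background_intensity_scale, n) + _MIN_AREA
            rows.extend(zip(bg_rt1, bg_rt2, bg_mz, bg_area))
        for strip in config.strip_noise:
            if strip.axis == "vertical":
                j = int(grid.snap_index(strip.position, grid.RT1_START, grid.RT1_STEP))
                hit = rng.random(rt2_ax.size) < strip.density
                for i in np.nonzero(hit)[0]:
                    mz = strip.mz_bin + rng.uniform(-0.4, 0.4)
                    rows.append((rt1_ax[j], rt2_ax[i], mz, strip.intensity * (0.5 + rng.random())))
            elif strip.axis == "horizontal":
                i = int(grid.snap_index(strip.position, grid.RT2_START, grid.RT2_STEP))
                hit = rng.random(rt1_ax.size) < strip.density
                for j in np.nonzero(hit)[0]:
                    mz = strip.mz_bin + rng.uniform(-0.4, 0.4)
                    rows.append((rt1_ax[j], rt2_ax[i], mz, strip.intensity * (0.5 + rng.random())))
            else:
                raise ConfigurationError(f"unknown strip axis {strip.axis!r}")
        df = pd.DataFrame(rows, columns=["rt1", "rt2", "mz", "area"])
        df.insert(0, "spectrum", np.arange(len(df)))
        df["tof"] = 120000.0
        df["resolution"] = 10000.0
        df = df[["spectrum", "rt1", "rt2", "tof", "mz", "area", "resolution"]]
        tables[sample_id] = RawScanTable(sample_id=sample_id, df=df)
    manifest = SampleManifest(
        entries=[ManifestEntry(sample_id=s, label=l, path="") for s, l in _sample_ids(config)]
    )
    truth = {"labels": labels, "occurrences": occurrences}
    return SynthDataset(tables=tables, manifest=manifest, ground_truth=truth, config=config)


def write_dataset(dataset: SynthDataset, out_dir) -> Path:
    """Write scan tables as CSV plus a YAML manifest; returns manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for sample_id, table in dataset.tables.items():
        path = out_dir / f"{sample_id}.csv"
        write_raw_scans(table, path)
        label = dataset.ground_truth["labels"][sample_id]
        entries.append(ManifestEntry(sample_id=sample_id, label=label, path=str(path)))
    manifest = SampleManifest(entries=entries)
    manifest_path = out_dir / "manifest.yaml"
    write_manifest(manifest, manifest_path)
    return manifest_path


def make_reference_set(dataset: SynthDataset, k: int = 6) -> list[ReferenceCompound]:
    """Build a calibration reference set from the first k planted compounds.

    Expected presence/RT entries cover the abiotic samples (with realized,
    jittered retention times from the ground truth); each reference uses the
    compound's first fragment m/z.
    """
    compounds = dataset.config.compounds
    if len(compounds) < k:
        raise ValidationError(f"need >= {k} planted compounds, have {len(compounds)}")
    occ = {
        (o["sample"], o["compound"], o["fragment_mz"]): (o["rt1"], o["rt2"])
        for o in dataset.ground_truth["occurrences"]
    }
    abiotic = [s for s, l in dataset.ground_truth["labels"].items() if l == "abiotic"]
    refs = []
    for comp in compounds[:k]:
        frag = int(comp.fragment_mzs[0])
        expected = {}
        for s in abiotic:
            hit = occ.get((s, comp.name, frag))
            if hit is not None:
                expected[s] = (True, hit[0], hit[1])
            else:
                expected[s] = (False, comp.rt1, comp.rt2)
        refs.append(
            ReferenceCompound(name=comp.name, mz_bin=int(grid.mz_to_bin(frag)), expected=expected)
        )
    return refs


def default_test_compounds(n: int = 6, n_fragments: int = 2, rng=None) -> list[PlantedCompound]:
    """Deterministic well-separated clean compounds spanning the grid."""
    rng = rng or np.random.default_rng(12345)
    rt1s = np.linspace(2600.0, 11000.0, n)
    rt2s = 0.5 + (np.arange(n) % 5) * 0.55
    comps = []
    used_mz = set()
    for i in range(n):
        frags = []
        while len(frags) < n_fragments:
            mz = int(rng.integers(40, 650))
            if mz not in used_mz:
                used_mz.add(mz)
                frags.append(mz)
        comps.append(
            PlantedCompound(
                name=f"compound_{i:02d}",
                fragment_mzs=frags,
                rt1=float(rt1s[i]),
                rt2=float(rt2s[i]),
            )
        )
    return comps
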