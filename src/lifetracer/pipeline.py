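"""End-to-end orchestration: ingest -> TII -> detect -> filter -> features
-> classify -> groups -> stats, driven by one config object (or YAML file)
with the calibrated defaults and a single root seed."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from lifetracer import raw_io
from lifetracer.classify import ModelSpec, fit_final, ninefold_loo_cv, stratified_nested_cv
from lifetracer.errors import LifeTracerError
from lifetracer.features import build_matrix, cluster_peaks
from lifetracer.filters import FilterParams, apply_filter_cascade
from lifetracer.groups import filter_shared_groups, group_features
from lifetracer.peaks import DetectionParams, Peak, cluster_pixels, threshold_tii, tii_sigma
from lifetracer.raw_io import RawScanTable, SampleManifest
from lifetracer.stats import compare_peak_attributes
from lifetracer.tii import tii_stack

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables with the calibrated defaults."""

    manifest: str = ""
    out_dir: str = "lifetracer_out"
    lambda1: float = 5.0
    lambda2: float = 100.0
    eps: float = 5.0
    min_samples: int = 20
    split_rt1_max: float = 50.0
    split_rt2_max: float = 1.0
    tii_nonzero_max_fraction: float = 0.10
    strip_ratio_thresholds: dict = field(
        default_factory=lambda: {"vertical": 0.5, "horizontal": 0.5}
    )
    rt1_thrsh: float = 50.0
    rt2_thrsh: float = 0.8
    C: float = 0.1
    model_family: str = "logreg_l2"
    cv_scheme: str = ""  # "", "ninefold_loo" or "stratified_6x5"
    n_seeds: int = 10
    min_shared_samples: int = 2
    seed: int = 0

    def detection_params(self) -> DetectionParams:
        return DetectionParams(
            lambda1=self.lambda1,
            dbscan_min_samples=self.min_samples,
            dbscan_eps=self.eps,
            split_rt1_max=self.split_rt1_max,
            split_rt2_max=self.split_rt2_max,
        )

    def filter_params(self) -> FilterParams:
        return FilterParams(
            tii_nonzero_max_fraction=self.tii_nonzero_max_fraction,
            lambda2=self.lambda2,
            strip_ratio_thresholds=dict(self.strip_ratio_thresholds),
        )


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    known = {f for f in PipelineConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise LifeTracerError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**doc)


def detect_sample(
    raw: RawScanTable,
    detection: DetectionParams,
    filters: FilterParams,
) -> tuple[list[Peak], dict]:
    """Detection plus filter cascade over every non-empty TII of one sample."""
    stack = tii_stack(raw)
    surviving: list[Peak] = []
    counts = {"detected": 0, "after_filters": 0, "tiis": 0}
    for mz_bin, tii in stack.iter_nonzero():
        sigma = tii_sigma(tii)
        thresh = threshold_tii(tii, detection.lambda1, sigma)
        peaks = cluster_pixels(thresh, detection)
        counts["detected"] += len(peaks)
        kept, _ = apply_filter_cascade(thresh, peaks, sigma, filters)
        counts["after_filters"] += len(kept)
        counts["tiis"] += 1
        surviving.extend(kept)
    return surviving, counts


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    cols = [
        "sample_id",
        "mz_bin",
        "rt1_min",
        "rt1_max",
        "rt2_min",
        "rt2_max",
        "apex_rt1",
        "apex_rt2",
        "apex_intensity",
        "irect",
    ]
    return pd.DataFrame([{c: getattr(p, c) for c in cols} for p in peaks], columns=cols)


def run_pipeline(
    config: PipelineConfig,
    manifest: SampleManifest | None = None,
    tables: dict[str, RawScanTable] | None = None,
) -> dict:
    """Run every stage and write artifacts under ``config.out_dir``.

    ``manifest``/``tables`` may be supplied in memory (e.g. from the
    synthetic generator); otherwise they are read from ``config.manifest``.
    Returns the run report (also written as JSON).
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if manifest is None:
        manifest = raw_io.read_manifest(config.manifest)
    if tables is None:
        tables = {
            e.sample_id: raw_io.read_raw_scans(e.path, e.sample_id) for e in manifest.entries
        }
    raw_io.require_both_labels(manifest)
    detection = config.detection_params()
    filters = config.filter_params()

    report: dict = {"config": asdict(config), "stages": {}}
    all_peaks: list[Peak] = []
    per_sample = {}
    for entry in manifest.entries:
        peaks, counts = detect_sample(tables[entry.sample_id], detection, filters)
        all_peaks.extend(peaks)
        per_sample[entry.sample_id] = counts
        logger.info("%s: %s", entry.sample_id, counts)
    report["stages"]["detection"] = per_sample
    peaks_to_frame(all_peaks).to_csv(out_dir / "peaks.csv", index=False)

    features = cluster_peaks(all_peaks, config.rt1_thrsh, config.rt2_thrsh)
    report["stages"]["features"] = {"n_features": len(features)}

    if not features:
        report["stages"]["note"] = "no features; downstream stages skipped"
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2)
        return report

    matrix = build_matrix(features, manifest)
    matrix.df.to_csv(out_dir / "matrix.csv")
    matrix.feature_index.to_csv(out_dir / "feature_index.csv")

    if config.cv_scheme:
        spec = ModelSpec(config.model_family)
        cv = (
            ninefold_loo_cv(matrix, spec, config.n_seeds)
            if config.cv_scheme == "ninefold_loo"
            else stratified_nested_cv(matrix, spec, n_seeds=config.n_seeds)
        )
        report["stages"]["cv"] = cv.to_dict()

    fitted = fit_final(matrix, ModelSpec(config.model_family, [{"C": config.C}]))
    pd.DataFrame(
        {"feature_id": fitted.feature_ids, "coefficient": [fitted.coefficients[f] for f in fitted.feature_ids]}
    ).to_csv(out_dir / "coefficients.csv", index=False)

    groups = group_features(features, fitted.coefficients, config.rt1_thrsh, config.rt2_thrsh)
    shared = filter_shared_groups(groups, matrix, config.min_shared_samples)
    report["stages"]["groups"] = {"n_groups": len(groups), "n_shared_groups": len(shared)}
    pd.DataFrame(
        [
            {
                "rank": i,
                "group_id": g.group_id,
                "representative": g.representative,
                "coefficient": g.coefficient,
                "direction": g.direction,
                "n_samples_shared": g.n_samples_shared,
                "n_members": len(g.member_features),
            }
            for i, g in enumerate(shared)
        ]
    ).to_csv(out_dir / "groups.csv", index=False)

    labels = manifest.labels
    abiotic_peaks = [p for p in all_peaks if labels[p.sample_id] == "abiotic"]
    biotic_peaks = [p for p in all_peaks if labels[p.sample_id] == "biotic"]
    if abiotic_peaks and biotic_peaks:
        tests = compare_peak_attributes(abiotic_peaks, biotic_peaks)
        report["stages"]["stats"] = [
            {
                "attribute": t.attribute,
                "ks_stat": t.ks_stat,
                "ks_p": t.ks_p,
                "mwu_p": t.mwu_p,
                "direction": t.direction,
            }
            for t in tests
        ]
        pd.DataFrame(report["stages"]["stats"]).to_csv(out_dir / "stats.csv", index=False)

    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
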