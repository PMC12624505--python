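"""Reading, validating and writing raw scan tables and the sample manifest.

A raw scan table is delimited text with one row per ionization scan and
seven named columns (an optional unnamed positional row index is ignored):
spectrum, 1st Time (s), 2nd Time (s), TOF, m/z, Area, Resolution.  Header
matching is case- and spacing-insensitive, and both comma- and tab-delimited
files are accepted (detected from the header line).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
import yaml

from lifetracer import grid
from lifetracer.errors import EmptyTableError, FormatError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column order of the analysis frame
COLUMNS = ["spectrum", "rt1", "rt2", "tof", "mz", "area", "resolution"]

#: headers written by :func:`write_raw_scans`
_WRITE_HEADERS = {
    "spectrum": "spectrum",
    "rt1": "1st Time (s)",
    "rt2": "2nd Time (s)",
    "tof": "TOF",
    "mz": "m/z",
    "area": "Area",
    "resolution": "Resolution",
}

# normalized header -> canonical name; normalization strips everything but
# alphanumerics and lowercases, so "1st Time (s)" -> "1sttimes"
_ALIASES = {
    "spectrum": "spectrum",
    "1sttimes": "rt1",
    "1sttime": "rt1",
    "firsttimes": "rt1",
    "rt1": "rt1",
    "2ndtimes": "rt2",
    "2ndtime": "rt2",
    "secondtimes": "rt2",
    "rt2": "rt2",
    "tof": "tof",
    "mz": "mz",
    "area": "area",
    "i": "area",
    "intensity": "area",
    "resolution": "resolution",
}

VALID_LABELS = ("abiotic", "biotic")


def _normalize(header: str) -> str:
    return re.sub(r"[^0-9a-z]", "", str(header).lower())


@dataclass
class RawScanTable:
    """Long-format table of scans for one sample.

    ``df`` holds the canonical columns :data:`COLUMNS`; ``n_dropped`` counts
    rows removed because m/z, RT1 or RT2 fell outside the documented ranges
    (or the area was non-positive).
    """

    sample_id: str
    df: pd.DataFrame
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    label: str
    path: str


@dataclass
class SampleManifest:
    entries: list[ManifestEntry] = field(default_factory=list)

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    @property
    def labels(self) -> dict[str, str]:
        return {e.sample_id: e.label for e in self.entries}

    def by_label(self, label: str) -> list[ManifestEntry]:
        return [e for e in self.entries if e.label == label]

    def __len__(self) -> int:
        return len(self.entries)


def _detect_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def _in_range_mask(df: pd.DataFrame) -> pd.Series:
    return (
        df["mz"].between(grid.MZ_MIN, grid.MZ_MAX)
        & df["rt1"].between(grid.RT1_START, grid.RT1_STOP)
        & df["rt2"].between(grid.RT2_START, grid.RT2_STOP)
        & (df["area"] > 0)
    )


def read_raw_scans(path, sample_id: str) -> RawScanTable:
    """Read one raw scan table, keeping only in-range rows.

    Rows whose m/z, RT1 or RT2 lie outside the documented instrument ranges
    (or with non-positive area) are dropped, counted and logged — documented
    extremes are treated as observed, not guaranteed, bounds.

    Raises
    ------
    FormatError
        If a required column is missing (names the column).
    EmptyTableError
        If the file has no data rows.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _detect_delimiter(path)
    raw = pd.read_csv(path, sep=sep, float_precision="round_trip")
    rename = {}
    for col in raw.columns:
        canon = _ALIASES.get(_normalize(col))
        if canon is not None and canon not in rename.values():
            rename[col] = canon
    raw = raw.rename(columns=rename)
    for needed, label in [
        ("spectrum", "spectrum"),
        ("rt1", "1st Time (s)"),
        ("rt2", "2nd Time (s)"),
        ("tof", "TOF"),
        ("mz", "m/z"),
        ("area", "Area"),
        ("resolution", "Resolution"),
    ]:
        if needed not in raw.columns:
            raise FormatError(f"{path}: missing required column {label!r}")
    if len(raw) == 0:
        raise EmptyTableError(f"{path}: no data rows")
    df = raw[COLUMNS].copy()
    for col in ("rt1", "rt2", "tof", "mz", "area", "resolution"):
        df[col] = pd.to_numeric(df[col]).astype(np.float64)
    keep = _in_range_mask(df)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.warning(
            "%s: dropped %d of %d rows outside documented m/z, RT or area ranges",
            sample_id,
            n_dropped,
            len(df),
        )
    return RawScanTable(sample_id=sample_id, df=df[keep].reset_index(drop=True), n_dropped=n_dropped)


def write_raw_scans(table: RawScanTable, path) -> None:
    """Write a scan table as CSV with the canonical instrument headers.

    Floats are written with 17 significant digits so re-reading preserves
    the analysis fields (rt1, rt2, mz, area) bit-exactly.
    """
    out = table.df[COLUMNS].rename(columns=_WRITE_HEADERS)
    out.to_csv(path, index=False, float_format="%.17g")


def read_manifest(path) -> SampleManifest:
    """Read and validate the YAML sample manifest.

    The file holds either a top-level ``samples:`` list or a bare list of
    ``{sample_id, label, path}`` mappings with label in {abiotic, biotic}.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if isinstance(doc, dict):
        doc = doc.get("samples")
    if not doc:
        raise ValidationError(f"{path}: manifest lists no samples")
    entries = []
    for item in doc:
        try:
            entry = ManifestEntry(
                sample_id=str(item["sample_id"]),
                label=str(item["label"]),
                path=str(item.get("path", "")),
            )
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"{path}: malformed manifest entry {item!r}") from exc
        if entry.label not in VALID_LABELS:
            raise ValidationError(
                f"{path}: unknown label {entry.label!r} for sample {entry.sample_id!r}"
            )
        entries.append(entry)
    ids = [e.sample_id for e in entries]
    dupes = {s for s in ids if ids.count(s) > 1}
    if dupes:
        raise ValidationError(f"{path}: duplicate sample_id(s): {sorted(dupes)}")
    return SampleManifest(entries=entries)


def write_manifest(manifest: SampleManifest, path) -> None:
    doc = {
        "samples": [
            {"sample_id": e.sample_id, "label": e.label, "path": e.path}
            for e in manifest.entries
        ]
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def require_both_labels(manifest: SampleManifest) -> None:
    """Classification runs need at least one sample of each class."""
    present = {e.label for e in manifest.entries}
    missing = set(VALID_LABELS) - present
    if missing:
        raise ValidationError(f"manifest lacks samples with label(s): {sorted(missing)}")
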