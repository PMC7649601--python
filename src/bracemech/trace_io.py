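"""Reading, writing and assembly of force-rotation traces.

A *trace* is one biomechanics test on one plant: the device rotates the
stalk while a load cell records force, yielding ordered samples of
(rotation in degrees, force in newtons). Tests on the same plant across
sequential brace-root whorl excisions are labelled ``A`` (all whorls
intact), ``B`` (top soil-entering whorl excised), ``C``, ... and grouped
into a :class:`RemovalSeries`.

File formats are deliberately minimal and text-based:

* trace CSV with required header ``index,rotation_deg,force_N`` (an
  optional ``time_s`` column is ignored);
* metadata CSV with one row per plant
  (``plant_id,plot_id,whorls_in_soil,whorls_total,attachment_height_m,group``
  plus one ``file_<LABEL>`` column per test).
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import (
    ContiguityError,
    InsufficientDataError,
    LabelConflictError,
    TraceFormatError,
    TraceParseError,
)

TRACE_COLUMNS = ("index", "rotation_deg", "force_N")

__all__ = [
    "ForceRotationTrace",
    "PlantRecord",
    "RemovalSeries",
    "read_trace_csv",
    "write_trace_csv",
    "read_metadata_csv",
    "write_metadata_csv",
    "assemble_series",
    "load_dataset",
]


@dataclass
class ForceRotationTrace:
    """One device test: ordered (rotation, force) samples plus geometry.

    Parameters
    ----------
    index : ndarray of int
        Ordinal sample numbers, strictly increasing.
    rotation_deg : ndarray of float
        Device rotation in degrees.
    force_N : ndarray of float
        Load-cell force in newtons.
    load_height_m : float
        Height ``h`` of the applied load above the plant base (m), > 0.
    plant_id : str
    test_label : str
        Single uppercase letter; ``A`` = all brace roots intact.
    """

    index: np.ndarray
    rotation_deg: np.ndarray
    force_N: np.ndarray
    load_height_m: float
    plant_id: str = ""
    test_label: str = "A"

    def __post_init__(self) -> None:
        self.index = np.asarray(self.index, dtype=np.int64)
        self.rotation_deg = np.asarray(self.rotation_deg, dtype=float)
        self.force_N = np.asarray(self.force_N, dtype=float)
        n = self.index.size
        if not (n == self.rotation_deg.size == self.force_N.size):
            raise TraceFormatError("index, rotation_deg and force_N must have equal length")
        if n < 2:
            raise InsufficientDataError(f"trace needs at least 2 samples, got {n}")
        if np.any(np.diff(self.index) <= 0):
            raise TraceFormatError("sample index must be strictly increasing")
        if not np.all(np.isfinite(self.rotation_deg)) or not np.all(np.isfinite(self.force_N)):
            raise TraceFormatError("rotation_deg and force_N must be finite")
        if not self.load_height_m > 0:
            raise TraceFormatError(f"load_height_m must be > 0, got {self.load_height_m}")
        if not (len(self.test_label) == 1 and self.test_label in string.ascii_uppercase):
            raise TraceFormatError(f"test_label must be a single uppercase letter, got {self.test_label!r}")

    def __len__(self) -> int:
        return int(self.index.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ForceRotationTrace):
            return NotImplemented
        return (
            np.array_equal(self.index, other.index)
            and np.array_equal(self.rotation_deg, other.rotation_deg)
            and np.array_equal(self.force_N, other.force_N)
            and self.load_height_m == other.load_height_m
            and self.plant_id == other.plant_id
            and self.test_label == other.test_label
        )


@dataclass
class PlantRecord:
    """Per-plant phenotype metadata.

    ``whorls_in_soil`` counts brace-root whorls that enter the soil and
    hence determines the number of removal tests (``whorls_in_soil + 1``).
    ``attachment_height_m`` is the height of the highest soil-entering
    whorl's attachment on the stalk; it may be missing (``None``), in which
    case the beam-length correction is skipped for this plant.
    """

    plant_id: str
    plot_id: str = ""
    whorls_in_soil: int = 0
    whorls_total: int = 0
    attachment_height_m: float | None = None
    group: str = ""

    def __post_init__(self) -> None:
        if self.attachment_height_m is not None and not np.isfinite(self.attachment_height_m):
            self.attachment_height_m = None
        if not 0 <= self.whorls_in_soil <= self.whorls_total:
            raise TraceFormatError(
                f"plant {self.plant_id}: need 0 <= whorls_in_soil <= whorls_total, "
                f"got {self.whorls_in_soil}/{self.whorls_total}"
            )
        if self.attachment_height_m is not None and self.attachment_height_m < 0:
            raise TraceFormatError(f"plant {self.plant_id}: attachment_height_m must be >= 0")


@dataclass
class RemovalSeries:
    """All tests for one plant across sequential whorl excisions."""

    plant: PlantRecord
    traces: dict[str, ForceRotationTrace] = field(default_factory=dict)

    @property
    def labels(self) -> list[str]:
        return sorted(self.traces)

    def validate(self) -> None:
        labels = self.labels
        expected = list(string.ascii_uppercase[: self.plant.whorls_in_soil + 1])
        if labels != expected:
            raise ContiguityError(
                f"plant {self.plant.plant_id}: labels {labels} are not the contiguous "
                f"sequence {expected} implied by whorls_in_soil={self.plant.whorls_in_soil}"
            )


def read_trace_csv(
    path: str | Path,
    load_height_m: float,
    plant_id: str = "",
    test_label: str = "A",
) -> ForceRotationTrace:
    """Read a trace CSV (header ``index,rotation_deg,force_N``).

    Samples are returned in file order; nothing is reordered or filtered.

    Raises
    ------
    TraceFormatError
        Missing or malformed header.
    TraceParseError
        Non-numeric cell (message includes the data row number).
    InsufficientDataError
        Fewer than 2 data rows.
    """
    path = Path(path)
    with open(path, newline="", encoding="utf-8") as fh:
        header = fh.readline().strip()
        cols = [c.strip() for c in header.split(",")]
        extra = [c for c in cols if c not in TRACE_COLUMNS + ("time_s",)]
        if cols[:3] != list(TRACE_COLUMNS) or extra:
            raise TraceFormatError(
                f"{path}: expected header 'index,rotation_deg,force_N', got {header!r}"
            )
        rows = []
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            if len(cells) < 3:
                raise TraceParseError(f"{path}: row {lineno} has {len(cells)} cells, expected >= 3")
            try:
                rows.append((int(cells[0]), float(cells[1]), float(cells[2])))
            except ValueError as exc:
                raise TraceParseError(f"{path}: row {lineno}: {exc}") from None
    if len(rows) < 2:
        raise InsufficientDataError(f"{path}: trace has {len(rows)} data rows, need >= 2")
    idx, rot, force = (np.array(col) for col in zip(*rows))
    return ForceRotationTrace(idx, rot, force, load_height_m, plant_id, test_label)


def write_trace_csv(trace: ForceRotationTrace, path: str | Path) -> None:
    """Write a trace CSV; floats use repr precision so a round trip is lossless."""
    path = Path(path)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for i, r, f in zip(trace.index, trace.rotation_deg, trace.force_N):
            fh.write(f"{int(i)},{float(r)!r},{float(f)!r}\n")


_META_COLUMNS = ["plant_id", "plot_id", "whorls_in_soil", "whorls_total", "attachment_height_m", "group"]


def read_metadata_csv(path: str | Path) -> tuple[list[PlantRecord], dict[str, dict[str, str]]]:
    """Read the plant metadata table.

    Returns the plant records and, per plant, the map test label -> trace
    file reference taken from the ``file_<LABEL>`` columns (empty cells are
    skipped).
    """
    df = pd.read_csv(path, dtype={"plant_id": str, "plot_id": str})
    missing = [c for c in _META_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise TraceFormatError(f"{path}: metadata missing columns {missing}")
    file_cols = {c[len("file_"):]: c for c in df.columns if c.startswith("file_")}
    records: list[PlantRecord] = []
    files: dict[str, dict[str, str]] = {}
    for _, row in df.iterrows():
        a = row.get("attachment_height_m", np.nan)
        rec = PlantRecord(
            plant_id=str(row["plant_id"]),
            plot_id=str(row.get("plot_id", "")),
            whorls_in_soil=int(row["whorls_in_soil"]),
            whorls_total=int(row["whorls_total"]),
            attachment_height_m=None if pd.isna(a) else float(a),
            group="" if pd.isna(row.get("group", "")) else str(row.get("group", "")),
        )
        records.append(rec)
        files[rec.plant_id] = {
            lab: str(row[col]) for lab, col in sorted(file_cols.items()) if not pd.isna(row[col])
        }
    return records, files


def write_metadata_csv(
    records: Iterable[PlantRecord],
    files: Mapping[str, Mapping[str, str]],
    path: str | Path,
) -> None:
    """Write the metadata table (inverse of :func:`read_metadata_csv`)."""
    records = list(records)
    labels = sorted({lab for m in files.values() for lab in m})
    rows = []
    for rec in records:
        row = {
            "plant_id": rec.plant_id,
            "plot_id": rec.plot_id,
            "whorls_in_soil": rec.whorls_in_soil,
            "whorls_total": rec.whorls_total,
            "attachment_height_m": np.nan if rec.attachment_height_m is None else rec.attachment_height_m,
            "group": rec.group,
        }
        for lab in labels:
            row[f"file_{lab}"] = files.get(rec.plant_id, {}).get(lab, "")
        rows.append(row)
    pd.DataFrame(rows, columns=_META_COLUMNS + [f"file_{lab}" for lab in labels]).to_csv(path, index=False)


def assemble_series(
    records: Iterable[PlantRecord],
    traces: Iterable[ForceRotationTrace],
    errors: str = "raise",
) -> list[RemovalSeries] | tuple[list[RemovalSeries], dict[str, str]]:
    """Group traces into one labelled removal series per plant.

    Labels must form a contiguous alphabetic run starting at ``A`` with
    ``whorls_in_soil + 1`` entries. With ``errors="raise"`` the first
    violation raises; with ``errors="report"`` a ``(series, problems)``
    pair is returned where ``problems`` maps plant_id -> description, so
    failing plants are reported rather than silently dropped.
    """
    if errors not in ("raise", "report"):
        raise ValueError("errors must be 'raise' or 'report'")
    by_plant: dict[str, dict[str, ForceRotationTrace]] = {}
    for tr in traces:
        slot = by_plant.setdefault(tr.plant_id, {})
        if tr.test_label in slot:
            msg = f"plant {tr.plant_id}: duplicate test label {tr.test_label!r}"
            if errors == "raise":
                raise LabelConflictError(msg)
            by_plant[tr.plant_id] = {"__conflict__": tr}  # sentinel; reported below
            continue
        slot[tr.test_label] = tr

    series: list[RemovalSeries] = []
    problems: dict[str, str] = {}
    for rec in records:
        plant_traces = by_plant.get(rec.plant_id)
        if not plant_traces:
            continue
        if "__conflict__" in plant_traces:
            problems[rec.plant_id] = "duplicate test label"
            continue
        s = RemovalSeries(plant=rec, traces=plant_traces)
        try:
            s.validate()
        except ContiguityError as exc:
            if errors == "raise":
                raise
            problems[rec.plant_id] = str(exc)
            continue
        series.append(s)
    if errors == "report":
        return series, problems
    return series


def load_dataset(directory: str | Path, load_height_m: float | None = None,
                 errors: str = "raise"):
    """Load a dataset directory (``metadata.csv`` + trace files) into series.

    ``load_height_m`` overrides the per-dataset load height; if omitted a
    ``load_height_m`` column in the metadata is used, else 0.64 m.
    """
    directory = Path(directory)
    meta_path = directory / "metadata.csv"
    df = pd.read_csv(meta_path, nrows=1)
    h_default = 0.64
    if load_height_m is None and "load_height_m" in df.columns:
        h_by_plant = pd.read_csv(meta_path, dtype={"plant_id": str}).set_index("plant_id")["load_height_m"].to_dict()
    else:
        h_by_plant = {}
    records, files = read_metadata_csv(meta_path)
    traces = []
    for rec in records:
        h = load_height_m or h_by_plant.get(rec.plant_id, h_default)
        for lab, fname in files[rec.plant_id].items():
            traces.append(read_trace_csv(directory / fname, h, rec.plant_id, lab))
    return assemble_series(records, traces, errors=errors)
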