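"""Plate CSV reading/writing and result serialization.

The canonical trace format is plain CSV in one of two dialects, matching
what RT-qPCR instruments and microplate readers export:

* wide — first column ``cycle``, one additional column per well;
* long — columns ``well,cycle,fluorescence``, one row per reading.

Malformed files (missing columns, non-numeric cells, duplicate readings,
cycle gaps) are hard errors that name the offending location. Result
serialization is byte-stable for fixed inputs: JSON is written with sorted
keys and fixed separators, TSV floats with 6 significant digits.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError
from .trace import FluorescenceTrace

__all__ = [
    "PlateRun",
    "read_plate_csv",
    "write_plate_csv",
    "read_pairing_csv",
    "write_pairing_csv",
    "write_results",
    "config_hash",
]

_DIALECTS = ("wide", "long")


@dataclass
class PlateRun:
    """A set of co-acquired well traces plus optional tagged→control pairing."""

    traces: dict[str, FluorescenceTrace]
    metadata: dict = field(default_factory=dict)
    pairing: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.traces:
            raise FormatError("plate contains no wells")
        lengths = {len(t) for t in self.traces.values()}
        if len(lengths) > 1:
            raise FormatError(f"wells differ in cycle count: {sorted(lengths)}")
        intervals = {t.sampling_interval for t in self.traces.values()}
        if len(intervals) > 1:
            raise FormatError("wells differ in sampling interval")
        for tagged, control in self.pairing.items():
            for well in (tagged, control):
                if well not in self.traces:
                    raise FormatError(f"pairing references unknown well {well!r}")

    def wells(self) -> list[str]:
        return list(self.traces)


def _numeric(df: pd.DataFrame, col: str, path) -> np.ndarray:
    raw = df[col]
    out = pd.to_numeric(raw, errors="coerce")
    bad = out.isna() & raw.notna() | raw.isna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path}: non-numeric or missing value in column {col!r}, "
            f"data row {row + 1}"
        )
    return out.to_numpy()


def read_plate_csv(path, dialect: str = "wide") -> PlateRun:
    """Parse a plate CSV in the given dialect into a validated PlateRun."""
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # ragged rows etc.
        raise FormatError(f"{path}: {exc}") from exc
    if dialect == "wide":
        if df.columns.empty or df.columns[0] != "cycle":
            raise FormatError(f"{path}: first column must be 'cycle'")
        if df.shape[1] < 2:
            raise FormatError(f"{path}: no well columns present")
        cycles = _numeric(df, "cycle", path)
        if pd.Index(cycles).has_duplicates:
            dup = int(pd.Index(cycles)[pd.Index(cycles).duplicated()][0])
            raise FormatError(f"{path}: duplicate cycle {dup}")
        traces = {}
        for well in df.columns[1:]:
            values = _numeric(df, well, path)
            try:
                traces[well] = FluorescenceTrace(
                    cycles.astype(np.int64), values, label=str(well)
                )
            except ValueError as exc:
                raise FormatError(f"{path}: well {well!r}: {exc}") from exc
        return PlateRun(traces)
    # long dialect
    required = ["well", "cycle", "fluorescence"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    df = df[required]
    dup = df.duplicated(subset=["well", "cycle"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate reading for well {row['well']!r}, "
            f"cycle {row['cycle']}"
        )
    cycles_all = _numeric(df, "cycle", path)
    values_all = _numeric(df, "fluorescence", path)
    traces = {}
    for well, idx in df.groupby("well", sort=False).groups.items():
        pos = df.index.get_indexer(idx)
        order = np.argsort(cycles_all[pos])
        try:
            traces[str(well)] = FluorescenceTrace(
                cycles_all[pos][order].astype(np.int64),
                values_all[pos][order],
                label=str(well),
            )
        except ValueError as exc:
            raise FormatError(f"{path}: well {well!r}: {exc}") from exc
    return PlateRun(traces)


def write_plate_csv(run: PlateRun, path, dialect: str = "wide") -> None:
    """Write a PlateRun back to CSV; lossless round-trip in both dialects."""
    path = Path(path)
    if dialect not in _DIALECTS:
        raise ValueError(f"dialect must be one of {_DIALECTS}")
    wells = run.wells()
    if dialect == "wide":
        first = run.traces[wells[0]]
        data = {"cycle": first.cycles}
        for well in wells:
            data[well] = run.traces[well].intensities
        pd.DataFrame(data).to_csv(path, index=False)
        return
    rows = []
    for well in wells:
        t = run.traces[well]
        rows.extend(
            (well, int(c), float(v)) for c, v in zip(t.cycles, t.intensities)
        )
    pd.DataFrame(rows, columns=["well", "cycle", "fluorescence"]).to_csv(
        path, index=False
    )


def read_pairing_csv(path, run: PlateRun | None = None) -> dict[str, str]:
    """Read a tagged→control pairing table (columns ``tagged,control``)."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("tagged", "control") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    pairing = dict(zip(df["tagged"].astype(str), df["control"].astype(str)))
    if run is not None:
        for well in set(pairing) | set(pairing.values()):
            if well not in run.traces:
                raise FormatError(f"{path}: unknown well {well!r}")
    return pairing


def write_pairing_csv(pairing: dict[str, str], path) -> None:
    pd.DataFrame(
        sorted(pairing.items()), columns=["tagged", "control"]
    ).to_csv(path, index=False)


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(obj, sort_keys=True, separators=(",", ":"), default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _format_cell(v) -> str:
    if isinstance(v, bool) or v is None:
        return {True: "true", False: "false", None: ""}[v]
    if isinstance(v, float):
        return f"{v:.6g}"
    return str(v)


def write_results(
    records: list[dict],
    path,
    format: str = "tsv",
    provenance: dict | None = None,
    columns: list[str] | None = None,
) -> None:
    """Serialize result records with provenance; byte-stable output.

    TSV: one header line (key order of the first record, or ``columns``
    for an empty result set), floats at 6 significant digits, provenance as
    leading ``#`` comment lines. JSON: an object with ``provenance`` and
    ``results`` keys, sorted keys, so that parse → re-serialize is
    byte-identical.
    """
    path = Path(path)
    if format == "json":
        payload = {"provenance": provenance or {}, "results": records}
        path.write_text(
            json.dumps(payload, sort_keys=True, indent=2, allow_nan=False) + "\n"
        )
        return
    if format != "tsv":
        raise ValueError("format must be 'tsv' or 'json'")
    lines = []
    for key in sorted(provenance or {}):
        lines.append(f"# {key}: {(provenance or {})[key]}")
    if columns is None:
        columns = list(records[0]) if records else []
    lines.append("\t".join(columns))
    for rec in records:
        lines.append("\t".join(_format_cell(rec.get(c)) for c in columns))
    path.write_text("\n".join(lines) + "\n")
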