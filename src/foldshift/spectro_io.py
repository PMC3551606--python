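"""Reading and writing the tabular and sequence formats the pipeline touches.

Instrument exports are assumed to be plain two-column text (comma or tab
separated, optional single header line, ``#`` comments).  Temperatures are
kept in degrees Celsius on disk and converted to Kelvin only inside the
thermodynamic computations.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

__all__ = [
    "VariantRecord",
    "RawTrace",
    "TraceError",
    "read_trace",
    "write_trace",
    "read_fasta",
    "write_fasta",
    "read_manifest",
    "write_results_table",
    "read_results_table",
    "RESULT_COLUMNS",
]

#: axis/signal units per trace kind
KIND_UNITS = {"melt": ("degC", "mdeg"), "emission": ("nm", "AU"), "progress": ("s", "AU")}

X_UNITS = frozenset({"degC", "nm", "s"})
Y_UNITS = frozenset({"mdeg", "AU"})

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWY"

#: column order of the per-variant summary table
RESULT_COLUMNS = [
    "variant",
    "pH4_helicity_note",
    "Tm_C",
    "Tm_err",
    "lambda_max_pH4",
    "F_max_pH4",
    "lambda_max_pH6",
    "F_max_pH6",
    "MEWD_nm",
    "residual_activity_pct",
]


class TraceError(ValueError):
    """Raised for malformed or invalid trace/manifest/FASTA content."""


_MUTATION_RE = re.compile(r"^([A-Z])(\d+)([A-Z])$")


@dataclass(frozen=True)
class VariantRecord:
    """A construct identity: name, optional background, and its point mutations.

    Mutations are (wild-type residue, 1-based position, substituted residue)
    triples, e.g. ``("W", 9, "A")`` for W9A.  Names follow the slash
    convention used for stacked mutations, e.g. ``"C72S/W9A"``.
    """

    name: str
    background: str = ""
    mutations: tuple[tuple[str, int, str], ...] = ()

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("variant name must be non-empty")
        positions = [pos for _, pos, _ in self.mutations]
        if any(p <= 0 for p in positions):
            raise ValueError(f"{self.name}: mutation positions must be positive")
        if len(set(positions)) != len(positions):
            raise ValueError(f"{self.name}: duplicate mutation positions")

    @classmethod
    def from_name(cls, name: str, background: str = "") -> "VariantRecord":
        """Parse mutations out of a slash-joined name like ``C72S/W9A``.

        Tokens that do not look like point mutations (e.g. ``WT``) contribute
        no mutation entries.
        """
        muts = []
        for token in name.split("/"):
            m = _MUTATION_RE.match(token.strip())
            if m:
                muts.append((m.group(1), int(m.group(2)), m.group(3)))
        return cls(name=name, background=background, mutations=tuple(muts))


@dataclass
class RawTrace:
    """An ordered two-column numeric trace with declared units and metadata."""

    x: np.ndarray
    y: np.ndarray
    x_unit: str
    y_unit: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x_unit not in X_UNITS or self.y_unit not in Y_UNITS:
            raise TraceError(f"undeclared units ({self.x_unit}, {self.y_unit})")
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise TraceError("x and y must be 1-D arrays of equal length")
        if len(self.x) < 5:
            raise TraceError(f"trace has {len(self.x)} rows; at least 5 required")
        if np.any(np.diff(self.x) == 0):
            raise TraceError("duplicate x values in trace")
        if not np.all(np.diff(self.x) > 0):
            raise TraceError("x axis not strictly increasing")


def _parse_two_columns(path: Path) -> tuple[np.ndarray, np.ndarray]:
    """Parse a two-column numeric table; comma/tab/whitespace delimited.

    An optional single header line is skipped; ``#`` lines and trailing
    blanks are ignored.  A non-numeric cell in the body raises
    :class:`TraceError` naming the offending row.
    """
    text = path.read_text()
    rows: list[tuple[int, str]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        rows.append((lineno, stripped))
    if not rows:
        raise TraceError(f"{path}: no data rows")

    def split(line: str) -> list[str]:
        for sep in (",", "\t"):
            if sep in line:
                return [f.strip() for f in line.split(sep)]
        return line.split()

    def numeric(fields: list[str]) -> bool:
        try:
            [float(f) for f in fields]
            return True
        except ValueError:
            return False

    start = 0
    if not numeric(split(rows[0][1])):
        start = 1  # header line
    xs, ys = [], []
    for lineno, line in rows[start:]:
        fields = split(line)
        if len(fields) < 2:
            raise TraceError(f"{path}: row {lineno} has fewer than two columns")
        try:
            xs.append(float(fields[0]))
            ys.append(float(fields[1]))
        except ValueError as exc:
            raise TraceError(f"{path}: non-numeric cell at row {lineno}: {line!r}") from exc
    if not xs:
        raise TraceError(f"{path}: no numeric rows")
    return np.array(xs), np.array(ys)


def read_trace(path: str | Path, kind: str, meta: dict | None = None) -> RawTrace:
    """Read a two-column trace and validate it into a :class:`RawTrace`.

    ``kind`` sets the units: melt -> (degC, mdeg), emission -> (nm, AU),
    progress -> (s, AU).  Rows are sorted by the x axis; duplicate x values
    or fewer than 5 rows are rejected.
    """
    if kind not in KIND_UNITS:
        raise ValueError(f"unknown trace kind {kind!r}; expected one of {sorted(KIND_UNITS)}")
    path = Path(path)
    x, y = _parse_two_columns(path)
    order = np.argsort(x, kind="stable")
    x_unit, y_unit = KIND_UNITS[kind]
    return RawTrace(x=x[order], y=y[order], x_unit=x_unit, y_unit=y_unit, meta=dict(meta or {}))


def write_trace(trace: RawTrace, path: str | Path, sep: str = "\t") -> None:
    """Write a trace as a two-column text file with a unit header line."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"x_{trace.x_unit}{sep}y_{trace.y_unit}\n")
        for xv, yv in zip(trace.x, trace.y):
            fh.write(f"{xv:.12g}{sep}{yv:.12g}\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs.

    Ids are the header token up to the first whitespace; sequences are
    upper-cased.  Gap (``-``) and stop (``*``) characters are preserved here
    (motif scanning rejects them later); any other non-letter character is a
    validation error naming the record.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        raise TraceError(f"{path}: empty FASTA file")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - set(AA_LETTERS) - set("BJOUXZ-*")
        if bad:
            raise TraceError(f"{path}: record {rec.id!r} has illegal characters {sorted(bad)}")
        records.append((rec.id, seq))
    if not records:
        raise TraceError(f"{path}: no FASTA records")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read the variant manifest TSV.

    Required columns: ``name``; optional: ``background``, ``mutations``
    (semicolon-joined, e.g. ``W9A;Y12A``), ``cycle_id``, ``note`` (a
    user-supplied qualitative label, e.g. the molten-globule-transition
    call).  Returns a DataFrame with a parsed ``record`` column of
    :class:`VariantRecord`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "name" not in df.columns:
        raise TraceError(f"{path}: manifest missing required column 'name'")
    if df["name"].eq("").any():
        raise TraceError(f"{path}: manifest contains an empty variant name")
    if df["name"].duplicated().any():
        dups = df.loc[df["name"].duplicated(), "name"].tolist()
        raise TraceError(f"{path}: duplicate variant names {dups}")
    records = []
    for _, row in df.iterrows():
        muts = []
        for token in str(row.get("mutations", "")).split(";"):
            token = token.strip()
            if not token:
                continue
            m = _MUTATION_RE.match(token)
            if not m:
                raise TraceError(f"{path}: malformed mutation token {token!r} for {row['name']}")
            muts.append((m.group(1), int(m.group(2)), m.group(3)))
        if muts:
            records.append(
                VariantRecord(row["name"], str(row.get("background", "")), tuple(muts))
            )
        else:
            records.append(VariantRecord.from_name(row["name"], str(row.get("background", ""))))
    df = df.copy()
    df["record"] = records
    return df


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float) and np.isnan(value):
        return "NA"
    if isinstance(value, float):
        return f"{value:.10g}"
    s = str(value)
    return s if s else "NA"


def write_results_table(rows: Sequence[dict], path: str | Path) -> None:
    """Write per-variant summaries as a TSV mirroring the published table layout.

    Columns are fixed (:data:`RESULT_COLUMNS`); missing values become "NA".
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(_fmt(row.get(col)) for col in RESULT_COLUMNS) + "\n")


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", na_values=["NA"])
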