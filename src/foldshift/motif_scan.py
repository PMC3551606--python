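"""PROSITE-like scanning of fixed-gap aromatic motifs in protein sequences.

The conserved propeptide aromatic motif of crammer-like inhibitors and
cathepsin propeptides is written ``W-x(2)-[FYW]-x(3)-[FY]-x(3)-Y-x(12)-[FYW]``:
dash-separated tokens where a bare letter is a fixed residue, ``[...]`` a
set of allowed residues, and ``x(n)`` exactly n arbitrary residues (n
defaults to 1 for a bare ``x``).  Gap lengths are exact, not ranges.
All (possibly overlapping) matches are reported with 1-based coordinates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Sequence, Union

import pandas as pd

__all__ = [
    "CRAMMER_AROMATIC_MOTIF",
    "MotifPattern",
    "MotifHit",
    "parse_motif",
    "scan",
    "scan_fasta",
]

#: the conserved propeptide aromatic motif, W X2 (F/Y/W) X3 (F/Y) X3 Y X12 (F/Y/W)
CRAMMER_AROMATIC_MOTIF = "W-x(2)-[FYW]-x(3)-[FY]-x(3)-Y-x(12)-[FYW]"

AA20 = frozenset("ACDEFGHIKLMNPQRSTVWY")

Element = Union[frozenset, int]  # residue set (constrained slot) or exact gap length


class MotifSyntaxError(ValueError):
    """Raised for a malformed motif pattern string."""


@dataclass(frozen=True)
class MotifPattern:
    """A parsed fixed-gap motif: alternating residue-set slots and gaps."""

    elements: tuple[Element, ...]
    source_text: str

    def __post_init__(self) -> None:
        if not self.elements:
            raise MotifSyntaxError("empty motif")
        if not isinstance(self.elements[0], frozenset) or not isinstance(
            self.elements[-1], frozenset
        ):
            raise MotifSyntaxError("motif must start and end with a residue slot")

    @property
    def span(self) -> int:
        """Total length of a match in residues (slots plus gaps)."""
        return sum(1 if isinstance(e, frozenset) else e for e in self.elements)

    @property
    def n_slots(self) -> int:
        return sum(1 for e in self.elements if isinstance(e, frozenset))


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; positions are 1-based and inclusive."""

    sequence_id: str
    start: int
    end: int
    matched_residues: tuple[tuple[int, str], ...]


_SET_RE = re.compile(r"^\[([A-Z]+)\]$")
_GAP_RE = re.compile(r"^x(?:\((\d+)\))?$")


def parse_motif(text: str) -> MotifPattern:
    """Parse a dash-separated PROSITE-like pattern into a :class:`MotifPattern`.

    Tokens: a single residue letter, a bracketed set like ``[FYW]``, or
    ``x(n)`` / ``x`` for exactly n (or one) arbitrary residues.
    """
    if not text or not text.strip():
        raise MotifSyntaxError("empty motif pattern")
    elements: list[Element] = []
    for token in text.strip().split("-"):
        token = token.strip()
        if not token:
            raise MotifSyntaxError(f"empty token in pattern {text!r}")
        gap = _GAP_RE.match(token)
        if gap:
            elements.append(int(gap.group(1) or 1))
            continue
        m = _SET_RE.match(token.upper())
        if m:
            residues = frozenset(m.group(1))
            if not residues <= AA20:
                raise MotifSyntaxError(f"non-amino-acid letters in token {token!r}")
            elements.append(residues)
            continue
        if len(token) == 1 and token.upper() in AA20:
            elements.append(frozenset(token.upper()))
            continue
        raise MotifSyntaxError(f"malformed motif token {token!r}")
    return MotifPattern(elements=tuple(elements), source_text=text.strip())


def scan(pattern: MotifPattern, sequence: str, sequence_id: str = "") -> list[MotifHit]:
    """All exact-gap matches of ``pattern`` in ``sequence``, left to right.

    Matching is case-insensitive; overlapping matches are all reported.
    ``X`` (unknown residue) in the sequence never satisfies a constrained
    slot.  Gapped or stop-containing sequences are rejected: degap first
    (or use :func:`scan_fasta`, which remaps coordinates for you).
    """
    if "-" in sequence or "*" in sequence:
        raise ValueError("sequence contains '-' or '*': degap/strip it before scanning")
    seq = sequence.upper()
    span = pattern.span
    hits: list[MotifHit] = []
    for start in range(0, len(seq) - span + 1):
        pos = start
        matched: list[tuple[int, str]] = []
        ok = True
        for element in pattern.elements:
            if isinstance(element, int):
                pos += element
                continue
            residue = seq[pos]
            if residue not in element:  # 'X' fails every slot by construction
                ok = False
                break
            matched.append((pos + 1, residue))
            pos += 1
        if ok:
            hits.append(
                MotifHit(
                    sequence_id=sequence_id,
                    start=start + 1,
                    end=start + span,
                    matched_residues=tuple(matched),
                )
            )
    return hits


def _degap_map(seq: str) -> tuple[str, list[int]]:
    """Strip '-' and return (degapped sequence, degapped idx -> gapped idx)."""
    degapped = []
    mapping = []
    for i, ch in enumerate(seq):
        if ch != "-":
            degapped.append(ch)
            mapping.append(i)
    return "".join(degapped), mapping


def scan_fasta(
    pattern: MotifPattern, records: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Scan each FASTA record; return one row per hit.

    Alignment input (sequences with ``-``) is degapped before scanning and
    hit coordinates are remapped back to the original gapped columns.
    Duplicate record ids are scanned with a warning.  Columns:
    sequence_id, start, end, matched_residues (";"-joined pos:res pairs).
    """
    seen = set()
    rows = []
    for seq_id, seq in records:
        if seq_id in seen:
            warnings.warn(f"duplicate FASTA id {seq_id!r}; scanning both", stacklevel=2)
        seen.add(seq_id)
        clean = seq.replace("*", "")
        gapped = "-" in clean
        degapped, mapping = _degap_map(clean)
        for hit in scan(pattern, degapped, sequence_id=seq_id):
            if gapped:
                start = mapping[hit.start - 1] + 1
                end = mapping[hit.end - 1] + 1
                matched = tuple((mapping[p - 1] + 1, r) for p, r in hit.matched_residues)
            else:
                start, end, matched = hit.start, hit.end, hit.matched_residues
            rows.append(
                {
                    "sequence_id": seq_id,
                    "start": start,
                    "end": end,
                    "matched_residues": ";".join(f"{p}:{r}" for p, r in matched),
                }
            )
    return pd.DataFrame(rows, columns=["sequence_id", "start", "end", "matched_residues"])
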