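"""Alignment parsing and numeric encoding.

Converts a pre-aligned protein family (aligned FASTA or Clustal-style text
blocks) into the two numeric representations everything downstream consumes:

* a *property wave* per taxon — the residue letters replaced by one measured
  physicochemical value, gaps by 0;
* a *factor matrix* per taxon — an ``m x 5`` matrix of state-space
  coordinates, gaps (and, by default, ambiguity codes) as all-zero rows.

Alignment is external to this package: inputs must already be gapped to a
common length.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TextIO

import numpy as np
from Bio import SeqIO

from .exceptions import AlignmentError, EncodingError
from .tables import AA_LETTERS, AMBIGUOUS_LETTERS, GAP, FactorTable, PropertyTable

_ALLOWED = frozenset(AA_LETTERS) | AMBIGUOUS_LETTERS | {GAP}
#: Characters treated as gap after normalization ('.' and '*' dialects).
_GAP_ALIASES = {".": GAP, "*": GAP}


def normalize_row(row: str) -> str:
    """Uppercase and map '.'/'*' gap dialects to '-'."""
    return "".join(_GAP_ALIASES.get(c, c) for c in row.upper())


@dataclass(frozen=True)
class Alignment:
    """An n x m grid of gapped amino-acid letters with unique taxon labels."""

    taxa: tuple
    rows: tuple

    def __post_init__(self):
        taxa = tuple(self.taxa)
        rows = tuple(normalize_row(r) for r in self.rows)
        if len(taxa) != len(rows):
            raise AlignmentError("taxa and rows differ in count")
        if not rows:
            raise AlignmentError("empty alignment")
        if any(not t for t in taxa):
            raise AlignmentError("empty taxon label")
        if len(set(taxa)) != len(taxa):
            dupes = sorted({t for t in taxa if taxa.count(t) > 1})
            raise AlignmentError(f"duplicate taxon labels: {dupes}")
        m = len(rows[0])
        if m < 1:
            raise AlignmentError("alignment length must be >= 1")
        for t, r in zip(taxa, rows):
            if len(r) != m:
                raise AlignmentError(
                    f"row {t!r} has length {len(r)}, expected {m} (ragged alignment)"
                )
            for j, c in enumerate(r):
                if c not in _ALLOWED:
                    raise AlignmentError(
                        f"illegal character {c!r} in row {t!r} at position {j + 1}"
                    )
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "rows", rows)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def row(self, taxon: str) -> str:
        try:
            return self.rows[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(f"unknown taxon {taxon!r}") from None

    def subset(self, taxa: Iterable[str]) -> "Alignment":
        taxa = list(taxa)
        return Alignment(tuple(taxa), tuple(self.row(t) for t in taxa))

    def to_fasta(self, path_or_handle) -> None:
        handle = path_or_handle
        close = False
        if isinstance(path_or_handle, (str, Path)):
            handle, close = open(path_or_handle, "w"), True
        try:
            for t, r in zip(self.taxa, self.rows):
                handle.write(f">{t}\n{r}\n")
        finally:
            if close:
                handle.close()


@dataclass(frozen=True)
class PropertyWave:
    """One taxon's sequence as a numeric string for one property (gaps -> 0)."""

    taxon: str
    property_name: str
    values: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FactorMatrix:
    """One taxon's sequence as an m x 5 state-space matrix (gaps -> zero rows)."""

    taxon: str
    x: np.ndarray

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        if x.ndim != 2 or x.shape[1] != 5:
            raise AlignmentError(f"factor matrix for {self.taxon!r} must be m x 5, got {x.shape}")
        object.__setattr__(self, "x", x)

    @property
    def length(self) -> int:
        return self.x.shape[0]


# --------------------------------------------------------------------------
# Parsing
# --------------------------------------------------------------------------

def _as_handle(source) -> TextIO:
    if (
        isinstance(source, (str, Path))
        and str(source)
        and "\n" not in str(source)
        and Path(source).exists()
    ):
        return open(source)
    if isinstance(source, str):
        return io.StringIO(source)
    return source


_CONSENSUS_CHARS = set(" .:*\t")


def _parse_clustal_txt(handle: TextIO) -> tuple[list, list]:
    """Tolerant Clustal-style block parser.

    Strips header and consensus/ruler lines, then concatenates each taxon's
    per-block segments in first-seen order.  Trailing cumulative-position
    numbers are ignored.
    """
    order: list = []
    parts: dict = {}
    for line in handle:
        stripped = line.rstrip("\n")
        if not stripped.strip():
            continue
        upper = stripped.upper()
        if upper.startswith(("CLUSTAL", "MUSCLE", "MAFFT", "KALIGN")):
            continue
        # consensus lines carry no label: only conservation symbols
        if set(stripped) <= _CONSENSUS_CHARS:
            continue
        fields = stripped.split()
        if len(fields) < 2:
            continue
        label, seq = fields[0], fields[1]
        if len(fields) >= 3 and not fields[2].isdigit():
            seq = "".join(fields[1:])
        if label not in parts:
            order.append(label)
            parts[label] = []
        parts[label].append(seq)
    if not order:
        raise AlignmentError("no sequence blocks found in clustal-txt input")
    return order, ["".join(parts[t]) for t in order]


def load_alignment(source, format: str = "fasta") -> Alignment:
    """Parse an aligned FASTA file/stream or Clustal-style text into an Alignment.

    Parameters
    ----------
    source : path, text, or open handle
    format : {"fasta", "clustal-txt"}
    """
    handle = _as_handle(source)
    if format == "fasta":
        records = list(SeqIO.parse(handle, "fasta"))
        if not records:
            raise AlignmentError("no FASTA records found")
        return Alignment(tuple(r.id for r in records), tuple(str(r.seq) for r in records))
    if format == "clustal-txt":
        taxa, rows = _parse_clustal_txt(handle)
        return Alignment(tuple(taxa), tuple(rows))
    raise AlignmentError(f"unknown alignment format {format!r}")


# --------------------------------------------------------------------------
# Encoding
# --------------------------------------------------------------------------

def to_property_wave(alignment: Alignment, taxon: str, table: PropertyTable,
                     strict: bool = False) -> PropertyWave:
    """Encode one row as a property wave: ``table[residue]`` per position, 0 at gaps.

    Ambiguity codes (X, B, Z, J, U, O) encode as 0 like gaps unless
    ``strict=True``, in which case they raise :class:`EncodingError`.
    """
    row = alignment.row(taxon)
    values = np.zeros(len(row))
    for j, c in enumerate(row):
        if c == GAP:
            continue
        if c in AMBIGUOUS_LETTERS:
            if strict:
                raise EncodingError(
                    f"ambiguous residue {c!r} at position {j + 1} in {taxon!r} (strict mode)"
                )
            continue
        try:
            values[j] = table[c]
        except KeyError:
            raise EncodingError(
                f"no {table.property_name!r} value for residue {c!r} at position "
                f"{j + 1} in {taxon!r}"
            ) from None
    return PropertyWave(taxon, table.property_name, values)


def to_factor_matrix(alignment: Alignment, taxon: str, table: FactorTable,
                     strict: bool = False) -> FactorMatrix:
    """Encode one row as an m x 5 factor matrix; gaps and ambiguity codes -> zero rows."""
    row = alignment.row(taxon)
    x = np.zeros((len(row), 5))
    for j, c in enumerate(row):
        if c == GAP:
            continue
        if c in AMBIGUOUS_LETTERS:
            if strict:
                raise EncodingError(
                    f"ambiguous residue {c!r} at position {j + 1} in {taxon!r} (strict mode)"
                )
            continue
        try:
            x[j] = table[c]
        except KeyError:
            raise EncodingError(
                f"no factor coordinates for residue {c!r} at position {j + 1} in {taxon!r}"
            ) from None
    return FactorMatrix(taxon, x)


def property_waves(alignment: Alignment, table: PropertyTable, strict: bool = False) -> list:
    """Property waves for every taxon, in alignment order."""
    return [to_property_wave(alignment, t, table, strict) for t in alignment.taxa]


def factor_matrices(alignment: Alignment, table: FactorTable, strict: bool = False) -> list:
    """Factor matrices for every taxon, in alignment order."""
    return [to_factor_matrix(alignment, t, table, strict) for t in alignment.taxa]


#: Gap fraction above which the alignment is flagged: the zero-row gap
#: encoding degrades tree quality when gaps dominate.
GAP_WARN_THRESHOLD = 0.25


def gap_fraction(alignment: Alignment) -> tuple[float, bool]:
    """Fraction of gap characters in the grid, plus a warning flag above 25%."""
    n_gaps = sum(r.count(GAP) for r in alignment.rows)
    frac = n_gaps / (alignment.n_taxa * alignment.length)
    return frac, frac > GAP_WARN_THRESHOLD
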