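"""Strand-specific per-nucleotide coverage tracks and their file formats.

A :class:`CoverageTrack` holds one strand of one library as a dense,
zero-filled vector of non-negative coverage values, one per genomic
position ``1..length``.  Reverse-strand tracks use forward-strand
coordinates throughout — coordinates never flip anywhere in the package.

Two text formats are supported:

* **wiggle** (``variableStep`` / ``fixedStep``, span 1) as produced by
  BAM-to-wiggle converters; positions absent from the file are zero-filled.
* the **grp** dialect: a per-strand table with one line per genomic
  position and one tab-separated column per library.  Body line *k*
  is genomic position *k* (1-based).  Two header lines::

      # genome=<id> strand=<F|R> length=<L>
      # libs=<tab-separated labels>

Values are printed with up to 6 significant digits; integral values are
printed without a decimal point, so a write→read round trip reproduces
values to the printed precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np

from .errors import (
    CoordinateError,
    CrafdValidationError,
    IncompatibleTracksError,
    ParseError,
    StateError,
)

Strand = Literal["F", "R"]

FORWARD: Strand = "F"
REVERSE: Strand = "R"

#: default scale for library-size normalization (reads-per-million style)
DEFAULT_NORM_SCALE = 1e6


def _check_strand(strand: str) -> Strand:
    if strand not in ("F", "R"):
        raise CrafdValidationError(f"strand must be 'F' or 'R', got {strand!r}")
    return strand  # type: ignore[return-value]


@dataclass
class CoverageTrack:
    """Per-nucleotide coverage for one strand of one library.

    Parameters
    ----------
    genome_id
        Replicon identifier (single replicon per run).
    strand
        ``"F"`` (forward) or ``"R"`` (reverse); reverse-strand tracks are
        stored in forward-strand coordinates.
    values
        One non-negative finite value per position ``1..length``;
        position *i* is ``values[i-1]``.
    label
        Library name.
    normalized
        Whether the track has been normalized to library size.
    """

    genome_id: str
    strand: Strand
    values: np.ndarray
    label: str
    normalized: bool = False

    def __post_init__(self) -> None:
        _check_strand(self.strand)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size == 0:
            raise CrafdValidationError("values must be a non-empty 1-D array")
        if not np.all(np.isfinite(v)):
            raise CrafdValidationError("coverage values must be finite")
        if np.any(v < 0):
            raise CrafdValidationError("coverage values must be non-negative")
        self.values = v

    @property
    def length(self) -> int:
        return int(self.values.size)

    def total(self) -> float:
        """Sum of coverage over all positions."""
        return float(self.values.sum())

    def mean(self) -> float:
        return float(self.values.mean())

    def region_mean(self, start: int, end: int) -> float:
        """Mean coverage over the 1-based inclusive interval ``[start, end]``."""
        if not (1 <= start <= end <= self.length):
            raise CoordinateError(
                f"interval [{start}, {end}] outside genome of length {self.length}"
            )
        return float(self.values[start - 1 : end].mean())

    def compatible_with(self, other: "CoverageTrack", check_norm: bool = True) -> None:
        if (
            self.genome_id != other.genome_id
            or self.strand != other.strand
            or self.length != other.length
            or (check_norm and self.normalized != other.normalized)
        ):
            raise IncompatibleTracksError(
                f"tracks {self.label!r} and {other.label!r} differ in "
                "genome, strand, length, or normalization state"
            )


def normalize_to_library_size(
    track: CoverageTrack,
    total_mapped_reads: float,
    scale: float = DEFAULT_NORM_SCALE,
) -> CoverageTrack:
    """Normalize a raw track to library size.

    Every value is multiplied by ``scale / total_mapped_reads`` so mean
    coverage becomes comparable across libraries of different depth.
    Normalization is not idempotent: re-normalizing raises a StateError.
    """
    if track.normalized:
        raise StateError(f"track {track.label!r} is already normalized")
    if not (total_mapped_reads > 0):
        raise CrafdValidationError(
            f"total_mapped_reads must be positive, got {total_mapped_reads}"
        )
    if not (scale > 0):
        raise CrafdValidationError(f"scale must be positive, got {scale}")
    return replace(
        track,
        values=track.values * (scale / total_mapped_reads),
        normalized=True,
    )


def merge_tracks(
    tracks: Sequence[CoverageTrack], reducer: Literal["mean", "sum"] = "mean"
) -> CoverageTrack:
    """Positionwise mean or sum of same-strand tracks (replicate merging)."""
    if len(tracks) == 0:
        raise CrafdValidationError("merge_tracks requires at least one track")
    if reducer not in ("mean", "sum"):
        raise CrafdValidationError(f"unknown reducer {reducer!r}")
    first = tracks[0]
    for t in tracks[1:]:
        first.compatible_with(t)
    stack = np.vstack([t.values for t in tracks])
    values = stack.mean(axis=0) if reducer == "mean" else stack.sum(axis=0)
    return CoverageTrack(
        genome_id=first.genome_id,
        strand=first.strand,
        values=values,
        label="+".join(t.label for t in tracks),
        normalized=first.normalized,
    )


# ---------------------------------------------------------------------------
# wiggle
# ---------------------------------------------------------------------------

def read_wiggle(
    path, genome_length: int, strand: Strand, label: str
) -> CoverageTrack:
    """Read a variableStep/fixedStep wiggle file into a zero-filled track.

    Positions absent from the file hold 0.  Only span 1 is supported.
    A position beyond ``genome_length`` is a coordinate error; any
    malformed line is a parse error naming the line number.
    """
    _check_strand(strand)
    if genome_length < 1:
        raise CrafdValidationError("genome_length must be positive")
    values = np.zeros(genome_length, dtype=float)
    mode: str | None = None  # "variable" | "fixed"
    fixed_pos = 0
    fixed_step = 1

    def _span_ok(fields: dict, lineno: int) -> None:
        span = int(fields.get("span", "1"))
        if span != 1:
            raise ParseError(f"only span=1 wiggle is supported (span={span})", path, lineno)

    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            if line.startswith("variableStep"):
                fields = _wig_decl_fields(line, path, lineno)
                _span_ok(fields, lineno)
                mode = "variable"
                continue
            if line.startswith("fixedStep"):
                fields = _wig_decl_fields(line, path, lineno)
                _span_ok(fields, lineno)
                try:
                    fixed_pos = int(fields["start"])
                    fixed_step = int(fields.get("step", "1"))
                except (KeyError, ValueError) as exc:
                    raise ParseError(f"bad fixedStep declaration: {exc}", path, lineno)
                if fixed_pos < 1 or fixed_step < 1:
                    raise ParseError("fixedStep start and step must be >= 1", path, lineno)
                mode = "fixed"
                continue
            if mode is None:
                raise ParseError("data line before step declaration", path, lineno)
            parts = line.split()
            try:
                if mode == "variable":
                    if len(parts) != 2:
                        raise ValueError("expected '<position> <value>'")
                    pos, val = int(parts[0]), float(parts[1])
                else:
                    if len(parts) != 1:
                        raise ValueError("expected a single value")
                    pos, val = fixed_pos, float(parts[0])
                    fixed_pos += fixed_step
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno)
            if pos < 1 or pos > genome_length:
                raise CoordinateError(
                    f"{path}:{lineno}: position {pos} outside genome of "
                    f"length {genome_length}"
                )
            if not np.isfinite(val) or val < 0:
                raise ParseError(f"invalid coverage value {val}", path, lineno)
            values[pos - 1] = val
    return CoverageTrack(
        genome_id=Path(str(path)).stem, strand=strand, values=values, label=label
    )


def _wig_decl_fields(line: str, path, lineno: int) -> dict:
    fields = {}
    for token in line.split()[1:]:
        if "=" not in token:
            raise ParseError(f"malformed declaration token {token!r}", path, lineno)
        k, v = token.split("=", 1)
        fields[k] = v
    return fields


# ---------------------------------------------------------------------------
# grp
# ---------------------------------------------------------------------------

@dataclass
class GrpFile:
    """A per-strand grp table: length × n_libraries coverage matrix."""

    genome_id: str
    strand: Strand
    column_labels: list[str]
    matrix: np.ndarray  # (length, n_libraries), float

    def __post_init__(self) -> None:
        _check_strand(self.strand)
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2:
            raise CrafdValidationError("grp matrix must be 2-D")
        if m.shape[1] != len(self.column_labels):
            raise CrafdValidationError(
                f"{m.shape[1]} columns but {len(self.column_labels)} labels"
            )
        if not np.all(np.isfinite(m)):
            raise CrafdValidationError("grp values must be finite")
        if np.any(m < 0):
            raise CrafdValidationError("grp values must be non-negative")
        self.matrix = m

    @property
    def length(self) -> int:
        return int(self.matrix.shape[0])

    @classmethod
    def from_tracks(cls, tracks: Sequence[CoverageTrack]) -> "GrpFile":
        if not tracks:
            raise CrafdValidationError("from_tracks requires at least one track")
        first = tracks[0]
        for t in tracks[1:]:
            first.compatible_with(t, check_norm=False)
        return cls(
            genome_id=first.genome_id,
            strand=first.strand,
            column_labels=[t.label for t in tracks],
            matrix=np.column_stack([t.values for t in tracks]),
        )

    def track(self, label: str, normalized: bool = False) -> CoverageTrack:
        """Extract one library column as a CoverageTrack."""
        try:
            idx = self.column_labels.index(label)
        except ValueError:
            raise CrafdValidationError(
                f"library {label!r} not in grp columns {self.column_labels}"
            )
        return CoverageTrack(
            genome_id=self.genome_id,
            strand=self.strand,
            values=self.matrix[:, idx].copy(),
            label=label,
            normalized=normalized,
        )

    def tracks(self, normalized: bool = False) -> list[CoverageTrack]:
        return [self.track(lbl, normalized) for lbl in self.column_labels]


def _format_value(x: float) -> str:
    # integral values print without a decimal point; otherwise 6 sig. digits
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return f"{x:.6g}"


def write_grp(grp: GrpFile, path) -> None:
    """Write the canonical grp text (UTF-8, LF, deterministic bytes)."""
    if any("\t" in lbl or "\n" in lbl for lbl in grp.column_labels):
        raise CrafdValidationError("library labels may not contain tabs or newlines")
    if any(ch.isspace() for ch in grp.genome_id):
        raise CrafdValidationError("genome_id may not contain whitespace")
    with open(path, "wt", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# genome={grp.genome_id} strand={grp.strand} length={grp.length}\n")
        fh.write("# libs=" + "\t".join(grp.column_labels) + "\n")
        for row in grp.matrix:
            fh.write("\t".join(_format_value(x) for x in row) + "\n")


def read_grp(path) -> GrpFile:
    """Read a grp file; body line *k* is genomic position *k*."""
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        libs_line = fh.readline().rstrip("\n")
        meta = {}
        if not header.startswith("# "):
            raise ParseError("missing grp header line", path, 1)
        for token in header[2:].split():
            if "=" not in token:
                raise ParseError(f"malformed header token {token!r}", path, 1)
            k, v = token.split("=", 1)
            meta[k] = v
        for key in ("genome", "strand", "length"):
            if key not in meta:
                raise ParseError(f"grp header missing {key}=", path, 1)
        if not libs_line.startswith("# libs="):
            raise ParseError("second grp line must be '# libs=<labels>'", path, 2)
        labels = libs_line[len("# libs=") :].split("\t")
        if labels == [""]:
            raise ParseError("grp file declares no libraries", path, 2)
        try:
            length = int(meta["length"])
        except ValueError:
            raise ParseError(f"bad length {meta['length']!r}", path, 1)
        strand = meta["strand"]
        if strand not in ("F", "R"):
            raise ParseError(f"strand must be F or R, got {strand!r}", path, 1)

        matrix = np.empty((length, len(labels)), dtype=float)
        n_rows = 0
        for lineno, raw in enumerate(fh, start=3):
            line = raw.rstrip("\n")
            if line == "" and n_rows == length:
                continue
            parts = line.split("\t")
            if len(parts) != len(labels):
                raise ParseError(
                    f"expected {len(labels)} fields, found {len(parts)}", path, lineno
                )
            if n_rows >= length:
                raise ParseError(
                    f"more data lines than declared length {length}", path, lineno
                )
            try:
                row = [float(p) for p in parts]
            except ValueError as exc:
                raise ParseError(str(exc), path, lineno)
            for x in row:
                if not np.isfinite(x):
                    raise ParseError(f"non-finite value {x}", path, lineno)
                if x < 0:
                    raise CrafdValidationError(
                        f"{path}:{lineno}: negative coverage value {x}"
                    )
            matrix[n_rows] = row
            n_rows += 1
        if n_rows != length:
            raise ParseError(
                f"declared length {length} but found {n_rows} data lines", path
            )
    return GrpFile(
        genome_id=meta["genome"], strand=strand, column_labels=labels, matrix=matrix
    )
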