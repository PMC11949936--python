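"""Genomic intervals and the plain-text formats the screen pipeline touches.

Every coordinate inside the package is 0-based, half-open ``[start, end)``.
Coordinates printed by genome browsers (and in most papers) are 1-based
inclusive; they are converted exactly once, at the boundary, by
:func:`parse_region` — ``start - 1`` with the end unchanged.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO

__all__ = [
    "FormatError",
    "GenomicInterval",
    "FeatureAnnotation",
    "parse_region",
    "read_fasta",
    "read_bed",
    "write_bedgraph",
    "read_bedgraph",
    "interval_overlaps",
]

_VALID_BASES = frozenset("ACGTN")


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome or contig name.
    start : int
        0-based inclusive start (bp).
    end : int
        0-based exclusive end (bp).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )

    def length(self) -> int:
        """Interval length in bp (``end - start``)."""
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return interval_overlaps(self, other)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:[{self.start},{self.end})"


def interval_overlaps(a: GenomicInterval, b: GenomicInterval) -> bool:
    """True iff the two half-open intervals share at least one base.

    Adjacent intervals (``a.end == b.start``) do not overlap.
    """
    return a.chrom == b.chrom and a.start < b.end and b.start < a.end


_REGION_RE = re.compile(r"^([^:]+):([\d,]+)-([\d,]+)$")


def parse_region(region: str, one_based: bool = True) -> GenomicInterval:
    """Parse a ``chrom:start-end`` region string into a :class:`GenomicInterval`.

    With ``one_based=True`` (the default, matching genome-browser display)
    the printed inclusive start is converted to 0-based by subtracting 1 and
    the end is kept as-is, so ``chr14:22,541,009-22,564,966`` becomes
    ``[22541008, 22564966)``. Thousands separators are tolerated.
    """
    m = _REGION_RE.match(region.strip())
    if m is None:
        raise FormatError(f"cannot parse region string {region!r}")
    chrom = m.group(1)
    start = int(m.group(2).replace(",", ""))
    end = int(m.group(3).replace(",", ""))
    if one_based:
        start -= 1
    return GenomicInterval(chrom, start, end)


@dataclass
class FeatureAnnotation:
    """Labelled intervals (e.g. exons) kept sorted by ``(chrom, start)``.

    Overlapping intervals are permitted; sorting is enforced on
    construction. ``source`` records where the annotation came from
    (a file path, or ``"synthetic"``).
    """

    intervals: list[tuple[GenomicInterval, str]] = field(default_factory=list)
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.intervals = sorted(
            self.intervals, key=lambda t: (t[0].chrom, t[0].start, t[0].end)
        )

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, query: GenomicInterval) -> list[tuple[GenomicInterval, str]]:
        """All annotated intervals overlapping ``query``."""
        return [t for t in self.intervals if interval_overlaps(t[0], query)]


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into ``{name: uppercase sequence}``.

    Sequences are uppercased and restricted to the alphabet ``ACGTN``.
    An empty file, a file whose first non-blank line is not a header, a
    duplicate record name, or an illegal character raise :class:`FormatError`.
    """
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line
                break
        if not first.startswith(">"):
            raise FormatError(f"{path}: not FASTA (missing '>' header)")
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise FormatError(f"{path}: duplicate record name {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            raise FormatError(
                f"{path}: record {rec.id!r} contains illegal characters "
                f"{sorted(bad)}"
            )
        records[rec.id] = seq
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 80) -> None:
    """Write ``{name: sequence}`` as FASTA with fixed line width."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_bed(path: str | Path) -> FeatureAnnotation:
    """Read a BED3/BED4 file (0-based half-open) into a :class:`FeatureAnnotation`.

    Column 4, when present, becomes the feature label (default ``"feature"``).
    Rows are re-sorted; ``start >= end`` is a :class:`FormatError`.
    """
    path = Path(path)
    out: list[tuple[GenomicInterval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = parts[0], parts[1], parts[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            label = parts[3] if len(parts) >= 4 and parts[3] else "feature"
            out.append((GenomicInterval(chrom, start, end), label))
    return FeatureAnnotation(intervals=out, source=str(path))


def write_bed(ann: FeatureAnnotation, path: str | Path) -> None:
    """Write a :class:`FeatureAnnotation` as BED4."""
    with open(path, "w") as fh:
        for iv, label in ann.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{label}\n")


def write_bedgraph(
    records: Iterable[tuple[GenomicInterval, float]],
    path: str | Path,
    track_name: str = "tilescreen",
) -> None:
    """Write ``(interval, value)`` records as a bedGraph track.

    Records are sorted by ``(chrom, start, end)``; overlapping intervals are
    rejected with an error naming the first collision. Values are printed
    with 6 decimal places (trailing zeros trimmed), so a round trip
    preserves them to 1e-6.
    """
    recs = sorted(records, key=lambda t: (t[0].chrom, t[0].start, t[0].end))
    for prev, cur in zip(recs, recs[1:]):
        if interval_overlaps(prev[0], cur[0]):
            raise ValueError(
                f"overlapping bedGraph intervals: {prev[0]} and {cur[0]}"
            )
    with open(path, "w") as fh:
        fh.write(f'track type=bedGraph name="{track_name}"\n')
        for iv, value in recs:
            v = f"{float(value):.6f}".rstrip("0").rstrip(".")
            if v in ("", "-"):
                v = "0"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{v}\n")


def read_bedgraph(path: str | Path) -> list[tuple[GenomicInterval, float]]:
    """Read a bedGraph track back into ``(interval, value)`` records."""
    out: list[tuple[GenomicInterval, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise FormatError(f"{path}:{lineno}: expected 4 bedGraph columns")
            out.append(
                (GenomicInterval(parts[0], int(parts[1]), int(parts[2])), float(parts[3]))
            )
    return out
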