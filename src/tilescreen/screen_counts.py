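"""Guide counting: from raw screen FASTQ reads to a guides × samples matrix.

Reads carry the 20-nt spacer between two fixed vector anchor sequences
(amplicon structure ``...anchor5 | spacer | anchor3...``). Extraction is
anchor-delimited and exact by default; an optional Hamming-distance-1 rescue
recovers single-substitution sequencing errors, discarding ambiguous reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .genomic_io import FormatError
from .library_design import GuideLibrary, reverse_complement

__all__ = [
    "Sample",
    "SampleSheet",
    "CountMatrix",
    "extract_spacer",
    "count_guides",
    "write_counts",
    "read_counts",
    "read_sample_sheet",
    "write_sample_sheet",
]

CONDITIONS = ("sorted", "baseline")
UNASSIGNED_ROW = "__unassigned__"


@dataclass(frozen=True)
class Sample:
    sample_id: str
    condition: str  # "sorted" (expression-negative edited pool) or "baseline"
    replicate: int
    fastq_r1: str | None = None
    fastq_r2: str | None = None

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(
                f"{self.sample_id}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )


@dataclass
class SampleSheet:
    """Sample metadata: condition (sorted vs baseline) and replicate per sample."""

    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("sample_ids are not unique")
        for cond in CONDITIONS:
            if not any(s.condition == cond for s in self.samples):
                raise ValueError(f"no sample with condition {cond!r}")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def ids_for(self, condition: str) -> list[str]:
        return [s.sample_id for s in self.samples if s.condition == condition]


def read_sample_sheet(path: str | Path, require_fastq: bool = False) -> SampleSheet:
    """Read ``sample_id,condition,replicate,fastq_r1[,fastq_r2]`` CSV."""
    df = pd.read_csv(path, dtype=str)
    required = ["sample_id", "condition", "replicate"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    samples = []
    for row in df.itertuples(index=False):
        r1 = getattr(row, "fastq_r1", None)
        r2 = getattr(row, "fastq_r2", None)
        r1 = None if r1 is None or pd.isna(r1) else str(r1)
        r2 = None if r2 is None or pd.isna(r2) else str(r2)
        if require_fastq and r1 is None:
            raise FormatError(f"{path}: sample {row.sample_id} lacks fastq_r1")
        samples.append(
            Sample(
                sample_id=str(row.sample_id),
                condition=str(row.condition),
                replicate=int(row.replicate),
                fastq_r1=r1,
                fastq_r2=r2,
            )
        )
    return SampleSheet(samples=samples)


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "condition": s.condition,
                "replicate": s.replicate,
                "fastq_r1": s.fastq_r1,
                "fastq_r2": s.fastq_r2,
            }
            for s in sheet.samples
        ]
    ).to_csv(path, index=False)


@dataclass
class CountMatrix:
    """Integer guide × sample counts plus per-sample unassigned-read tallies.

    Invariant: for every sample, assigned + unassigned equals the number of
    reads scanned.
    """

    counts: pd.DataFrame  # index = guide_ids, columns = sample_ids
    unassigned: pd.Series  # index = sample_ids

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.unassigned = self.unassigned.reindex(self.counts.columns).fillna(0).astype(np.int64)
        if (self.counts.to_numpy() < 0).any() or (self.unassigned < 0).any():
            raise ValueError("negative counts are not allowed")

    @property
    def guide_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def total_reads(self) -> pd.Series:
        """Reads scanned per sample (assigned + unassigned)."""
        return self.counts.sum(axis=0) + self.unassigned


def extract_spacer(
    read: str, anchor5: str, anchor3: str = "", spacer_len: int = 20
) -> str | None:
    """Extract the spacer delimited by vector anchors from one read.

    Returns the ``spacer_len`` bases immediately after the first occurrence
    of ``anchor5``, provided ``anchor3`` (when non-empty) follows
    immediately after them; otherwise ``None``.
    """
    if not anchor5:
        raise ValueError("anchor5 must be non-empty")
    i = read.find(anchor5)
    if i < 0:
        return None
    s = i + len(anchor5)
    e = s + spacer_len
    if e > len(read):
        return None
    if anchor3 and not read.startswith(anchor3, e):
        return None
    return read[s:e]


def _mismatch_neighbors(spacer: str) -> "list[str]":
    """All 3·len single-substitution variants of a spacer."""
    out = []
    for i, b in enumerate(spacer):
        for alt in "ACGT":
            if alt != b:
                out.append(spacer[:i] + alt + spacer[i + 1 :])
    return out


def _lookup(
    spacer: str, exact: dict[str, str], max_mismatches: int
) -> str | None:
    hit = exact.get(spacer)
    if hit is not None or max_mismatches == 0:
        return hit
    matches = {g for v in _mismatch_neighbors(spacer) if (g := exact.get(v)) is not None}
    if len(matches) == 1:
        return matches.pop()
    return None  # no match, or ambiguous between >=2 guides


def _iter_fastq(path: str):
    try:
        with pysam.FastxFile(path) as fh:
            for i, rec in enumerate(fh):
                yield rec.sequence.upper()
    except (OSError, ValueError) as exc:
        raise FormatError(f"{path}: cannot parse FASTQ ({exc})") from exc


def count_guides(
    sheet: SampleSheet,
    lib: GuideLibrary,
    anchor5: str,
    anchor3: str = "",
    max_mismatches: int = 0,
    spacer_len: int = 20,
) -> CountMatrix:
    """Count spacer occurrences per sample into a :class:`CountMatrix`.

    Each read contributes to at most one guide. R1 is scanned first; in
    paired-end mode the reverse complement of R2 is scanned only when R1
    yields no spacer (deterministic, read-order independent). Reads whose
    spacer matches no library entry (or matches ambiguously under mismatch
    rescue) are tallied as unassigned.
    """
    spacers = lib.spacers()
    if len(set(spacers)) != len(spacers):
        raise ValueError("library spacers are not unique; deduplicate first")
    if max_mismatches not in (0, 1):
        raise ValueError("max_mismatches must be 0 or 1")
    exact = {g.spacer: g.guide_id for g in lib.guides}
    guide_ids = [g.guide_id for g in lib.guides]
    counts = pd.DataFrame(
        0, index=pd.Index(guide_ids, name="guide_id"), columns=sheet.sample_ids
    )
    unassigned = pd.Series(0, index=sheet.sample_ids)
    for sample in sheet.samples:
        if sample.fastq_r1 is None:
            raise ValueError(f"sample {sample.sample_id} has no FASTQ path")
        tally: dict[str, int] = {}
        n_unassigned = 0
        r1_iter = _iter_fastq(sample.fastq_r1)
        r2_iter = _iter_fastq(sample.fastq_r2) if sample.fastq_r2 else None
        for read1 in r1_iter:
            spacer = extract_spacer(read1, anchor5, anchor3, spacer_len)
            if spacer is None and r2_iter is not None:
                try:
                    read2 = next(r2_iter)
                except StopIteration:
                    raise FormatError(
                        f"{sample.fastq_r2}: fewer records than {sample.fastq_r1}"
                    ) from None
                spacer = extract_spacer(
                    reverse_complement(read2), anchor5, anchor3, spacer_len
                )
            elif r2_iter is not None:
                next(r2_iter, None)  # keep mates in register
            gid = _lookup(spacer, exact, max_mismatches) if spacer else None
            if gid is None:
                n_unassigned += 1
            else:
                tally[gid] = tally.get(gid, 0) + 1
        counts[sample.sample_id] = (
            pd.Series(tally, dtype=np.int64).reindex(guide_ids, fill_value=0).to_numpy()
        )
        unassigned[sample.sample_id] = n_unassigned
    return CountMatrix(counts=counts, unassigned=unassigned)


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    """Write counts CSV (guides as rows, samples as columns).

    The unassigned tallies are stored as a reserved final row
    ``__unassigned__`` so the round trip is lossless.
    """
    out = cm.counts.copy()
    out.loc[UNASSIGNED_ROW] = cm.unassigned
    out.to_csv(path, index_label="guide_id")


def read_counts(
    path: str | Path, sheet: SampleSheet | None = None
) -> CountMatrix:
    """Read a counts CSV back; validates integer cells and sample columns."""
    df = pd.read_csv(path, index_col="guide_id")
    num = df.apply(pd.to_numeric, errors="coerce")
    if num.isna().any().any():
        bad = df[num.isna().any(axis=1)].index[0]
        raise FormatError(f"{path}: non-numeric count in row {bad!r}")
    if not (num == num.round()).all().all():
        raise FormatError(f"{path}: non-integer count value")
    if (num < 0).any().any():
        raise FormatError(f"{path}: negative count value")
    num = num.astype(np.int64)
    if UNASSIGNED_ROW in num.index:
        unassigned = num.loc[UNASSIGNED_ROW]
        num = num.drop(index=UNASSIGNED_ROW)
    else:
        unassigned = pd.Series(0, index=num.columns)
    if sheet is not None and list(num.columns) != sheet.sample_ids:
        raise FormatError(
            f"{path}: sample columns {list(num.columns)} do not match "
            f"sample sheet {sheet.sample_ids}"
        )
    return CountMatrix(counts=num, unassigned=unassigned)
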