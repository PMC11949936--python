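"""In-silico tiling sgRNA library design for SpCas9 (NGG PAM).

Enumerates every 20-nt protospacer adjacent to an NGG PAM on both strands of
a target interval, the way a tiling screen saturates a locus. The predicted
cut site uses the canonical SpCas9 blunt cut between protospacer positions
17 and 18 (3 bp 5' of the PAM), recorded as the 0-based coordinate of the
cleaved bond:

* "+" guides: ``cut_site = spacer_start + 17``
* "−" guides: ``cut_site = spacer_start + 3``
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from .genomic_io import FeatureAnnotation, FormatError, GenomicInterval, interval_overlaps

__all__ = [
    "SgRNA",
    "GuideLibrary",
    "reverse_complement",
    "scan_protospacers",
    "apply_design_filters",
    "annotate_exonic",
    "write_library",
    "read_library",
]

SPACER_LEN = 20
PAM_LEN = 3
PROTOSPACER_SPAN = SPACER_LEN + PAM_LEN  # 23 bp must fit in the interval

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

LIBRARY_COLUMNS = [
    "guide_id",
    "spacer",
    "pam",
    "chrom",
    "spacer_start",
    "spacer_end",
    "strand",
    "cut_site",
    "exonic",
]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string over ``ACGTN``."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SgRNA:
    """One tiling guide: spacer, PAM, genomic placement and predicted cut.

    ``spacer`` is given in guide orientation (5'→3'); for "−" guides it is
    therefore the reverse complement of the reference subsequence spanned by
    ``[spacer_start, spacer_end)``. ``cut_site`` is the 0-based coordinate of
    the bond SpCas9 cleaves.
    """

    guide_id: str
    spacer: str
    pam: str
    chrom: str
    spacer_start: int
    spacer_end: int
    strand: str
    cut_site: int
    exonic: bool = False

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LEN:
            raise ValueError(
                f"{self.guide_id}: spacer length {len(self.spacer)} != {SPACER_LEN}"
            )
        if len(self.pam) != PAM_LEN or self.pam[1:] != "GG":
            raise ValueError(f"{self.guide_id}: PAM {self.pam!r} does not match NGG")
        if self.spacer_end - self.spacer_start != SPACER_LEN:
            raise ValueError(f"{self.guide_id}: spacer span != {SPACER_LEN} bp")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.guide_id}: strand must be '+' or '-'")
        expected = self.spacer_start + (17 if self.strand == "+" else 3)
        if self.cut_site != expected:
            raise ValueError(
                f"{self.guide_id}: cut_site {self.cut_site} inconsistent with "
                f"strand {self.strand} (expected {expected})"
            )

    @property
    def cut_window(self) -> GenomicInterval:
        """±3 bp window around the cleaved bond, used for exon labelling."""
        return GenomicInterval(self.chrom, self.cut_site - 3, self.cut_site + 3)


@dataclass
class GuideLibrary:
    """Ordered guide collection with unique ids, sorted by cut site."""

    guides: list[SgRNA]
    target_interval: GenomicInterval
    design_params: dict = field(default_factory=dict)
    filter_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.guide_id for g in self.guides]
        if len(set(ids)) != len(ids):
            raise ValueError("guide_ids are not unique")
        for g in self.guides:
            if not (self.target_interval.start <= g.cut_site < self.target_interval.end):
                raise ValueError(
                    f"{g.guide_id}: cut_site {g.cut_site} outside target interval"
                )

    def __len__(self) -> int:
        return len(self.guides)

    def __iter__(self):
        return iter(self.guides)

    def by_id(self, guide_id: str) -> SgRNA:
        try:
            return self._index()[guide_id]
        except KeyError:
            raise LookupError(f"unknown guide id {guide_id!r}") from None

    def _index(self) -> dict[str, SgRNA]:
        idx = getattr(self, "_id_index", None)
        if idx is None or len(idx) != len(self.guides):
            idx = {g.guide_id: g for g in self.guides}
            object.__setattr__(self, "_id_index", idx)
        return idx

    def spacers(self) -> list[str]:
        return [g.spacer for g in self.guides]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "guide_id": g.guide_id,
                    "spacer": g.spacer,
                    "pam": g.pam,
                    "chrom": g.chrom,
                    "spacer_start": g.spacer_start,
                    "spacer_end": g.spacer_end,
                    "strand": g.strand,
                    "cut_site": g.cut_site,
                    "exonic": g.exonic,
                }
                for g in self.guides
            ],
            columns=LIBRARY_COLUMNS,
        )


def _assign_ids(guides: list[SgRNA], prefix: str) -> list[SgRNA]:
    width = max(4, len(str(len(guides))))
    return [
        replace(g, guide_id=f"{prefix}-{i:0{width}d}")
        for i, g in enumerate(guides, start=1)
    ]


def scan_protospacers(
    sequence: str,
    interval: GenomicInterval,
    id_prefix: str = "sg",
) -> GuideLibrary:
    """Enumerate all NGG protospacers fully contained in ``interval``.

    ``sequence`` is the chromosome (or contig) sequence the interval indexes
    into, uppercase ACGTN. A guide is emitted only when the full 23-bp
    protospacer+PAM lies inside the interval and contains no ``N``. Guides
    are sorted by ``(cut_site, strand, spacer_start)`` and given zero-padded
    rank ids.
    """
    if interval.end > len(sequence) or interval.start < 0:
        raise IndexError(
            f"interval {interval} outside sequence of length {len(sequence)}"
        )
    if interval.length() < PROTOSPACER_SPAN:
        raise ValueError(
            f"interval length {interval.length()} < {PROTOSPACER_SPAN} bp"
        )
    region = sequence[interval.start : interval.end]
    found: list[SgRNA] = []
    n_sites = interval.length() - PROTOSPACER_SPAN + 1
    for off in range(n_sites):
        window = region[off : off + PROTOSPACER_SPAN]
        if "N" in window:
            continue
        g0 = interval.start + off
        # forward: spacer then NGG
        if window[21] == "G" and window[22] == "G":
            found.append(
                SgRNA(
                    guide_id="tmp",
                    spacer=window[:SPACER_LEN],
                    pam=window[SPACER_LEN:],
                    chrom=interval.chrom,
                    spacer_start=g0,
                    spacer_end=g0 + SPACER_LEN,
                    strand="+",
                    cut_site=g0 + 17,
                )
            )
        # reverse: CCN then spacer on the forward strand
        if window[0] == "C" and window[1] == "C":
            found.append(
                SgRNA(
                    guide_id="tmp",
                    spacer=reverse_complement(window[PAM_LEN:]),
                    pam=reverse_complement(window[:PAM_LEN]),
                    chrom=interval.chrom,
                    spacer_start=g0 + PAM_LEN,
                    spacer_end=g0 + PROTOSPACER_SPAN,
                    strand="-",
                    cut_site=g0 + PAM_LEN + 3,
                )
            )
    found.sort(key=lambda g: (g.cut_site, g.strand, g.spacer_start))
    return GuideLibrary(
        guides=_assign_ids(found, id_prefix),
        target_interval=interval,
        design_params={
            "spacer_len": SPACER_LEN,
            "pam": "NGG",
            "id_prefix": id_prefix,
            "filters": [],
        },
    )


_KNOWN_RULES = {"dedupe", "polyt", "gc_min", "gc_max"}

DEFAULT_FILTER_RULES = {"dedupe": True, "polyt": True}


def apply_design_filters(
    lib: GuideLibrary, rules: dict | None = None
) -> GuideLibrary:
    """Filter a library; survivors keep their original ids.

    Rules (all optional): ``dedupe`` drops later duplicates of an identical
    spacer (first by coordinate order wins); ``polyt`` drops spacers
    containing ``TTTT`` (a U6 Pol III terminator would truncate the guide);
    ``gc_min``/``gc_max`` bound the spacer GC fraction. Unknown rule names
    raise ``KeyError``. A per-rule removal count is attached as
    ``filter_report``.
    """
    rules = dict(DEFAULT_FILTER_RULES if rules is None else rules)
    unknown = set(rules) - _KNOWN_RULES
    if unknown:
        raise KeyError(f"unknown filter rule(s): {sorted(unknown)}")
    report = {rule: 0 for rule in rules}
    kept: list[SgRNA] = []
    seen: set[str] = set()
    for g in lib.guides:
        if rules.get("dedupe") and g.spacer in seen:
            report["dedupe"] += 1
            continue
        if rules.get("polyt") and "TTTT" in g.spacer:
            report["polyt"] += 1
            continue
        gc = (g.spacer.count("G") + g.spacer.count("C")) / len(g.spacer)
        if rules.get("gc_min") is not None and gc < rules["gc_min"]:
            report["gc_min"] += 1
            continue
        if rules.get("gc_max") is not None and gc > rules["gc_max"]:
            report["gc_max"] += 1
            continue
        seen.add(g.spacer)
        kept.append(g)
    params = dict(lib.design_params)
    params["filters"] = sorted(k for k, v in rules.items() if v not in (None, False))
    return GuideLibrary(
        guides=kept,
        target_interval=lib.target_interval,
        design_params=params,
        filter_report=report,
    )


def annotate_exonic(lib: GuideLibrary, ann: FeatureAnnotation) -> GuideLibrary:
    """Label each guide exonic iff its cut window overlaps any annotated interval."""
    out = []
    for g in lib.guides:
        win = g.cut_window
        exonic = any(interval_overlaps(win, iv) for iv, _ in ann.intervals)
        out.append(replace(g, exonic=exonic))
    return GuideLibrary(
        guides=out,
        target_interval=lib.target_interval,
        design_params=dict(lib.design_params),
        filter_report=dict(lib.filter_report),
    )


def write_library(lib: GuideLibrary, path: str | Path) -> None:
    """Serialize the library as CSV with the canonical column set."""
    lib.to_frame().to_csv(path, index=False)


def read_library(
    path: str | Path, target_interval: GenomicInterval | None = None
) -> GuideLibrary:
    """Read a library CSV back; validates columns and per-guide invariants.

    When ``target_interval`` is omitted it is reconstructed as the tight
    hull of the guides' protospacer spans.
    """
    df = pd.read_csv(path, dtype={"spacer": str, "pam": str, "strand": str})
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}")
    guides = []
    for row in df.itertuples(index=False):
        try:
            guides.append(
                SgRNA(
                    guide_id=str(row.guide_id),
                    spacer=str(row.spacer),
                    pam=str(row.pam),
                    chrom=str(row.chrom),
                    spacer_start=int(row.spacer_start),
                    spacer_end=int(row.spacer_end),
                    strand=str(row.strand),
                    cut_site=int(row.cut_site),
                    exonic=bool(row.exonic),
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: {exc}") from exc
    if target_interval is None:
        chroms = {g.chrom for g in guides}
        if len(chroms) != 1:
            raise FormatError(f"{path}: guides span multiple chromosomes {chroms}")
        lo = min(min(g.spacer_start, g.cut_site) for g in guides) - PAM_LEN
        hi = max(max(g.spacer_end, g.cut_site + 1) for g in guides) + PAM_LEN
        target_interval = GenomicInterval(chroms.pop(), max(0, lo), hi)
    return GuideLibrary(guides=guides, target_interval=target_interval)
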