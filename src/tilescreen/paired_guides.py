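"""Dual-guide excision prediction.

Two Cas9 cuts on the same chromosome excise the intervening fragment when
the broken ends religate; the predicted deletion spans the interval between
the two cleaved bonds, so its size is simply the distance between the cut
coordinates. The prediction depends only on cut sites, never on strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .genomic_io import GenomicInterval
from .library_design import GuideLibrary

__all__ = ["ExcisionPrediction", "predict_excision", "excision_report"]


@dataclass(frozen=True)
class ExcisionPrediction:
    """Predicted deletion from a guide pair: interval between the two cut bonds."""

    guide_a: str
    guide_b: str
    chrom: str
    deleted_start: int  # min cut coordinate
    deleted_end: int  # max cut coordinate; size 0 when cuts coincide
    size: int

    @property
    def deleted_interval(self) -> GenomicInterval | None:
        """The excised span ``[min_cut, max_cut)``; ``None`` when empty."""
        if self.size == 0:
            return None
        return GenomicInterval(self.chrom, self.deleted_start, self.deleted_end)


def predict_excision(lib: GuideLibrary, id_a: str, id_b: str) -> ExcisionPrediction:
    """Predict the fragment deleted by cutting with guides ``id_a`` and ``id_b``.

    Symmetric in the two guides; the two cut sites must lie on the same
    chromosome. A coincident pair yields size 0 and an empty interval.
    """
    a = lib.by_id(id_a)
    b = lib.by_id(id_b)
    if a.chrom != b.chrom:
        raise ValueError(
            f"guides {id_a} ({a.chrom}) and {id_b} ({b.chrom}) lie on "
            "different chromosomes"
        )
    lo, hi = sorted((a.cut_site, b.cut_site))
    return ExcisionPrediction(
        guide_a=id_a,
        guide_b=id_b,
        chrom=a.chrom,
        deleted_start=lo,
        deleted_end=hi,
        size=hi - lo,
    )


def excision_report(
    lib: GuideLibrary, pairs: list[tuple[str, str]]
) -> pd.DataFrame:
    """One prediction row per guide pair (duplicates kept as given)."""
    rows = []
    for id_a, id_b in pairs:
        p = predict_excision(lib, id_a, id_b)
        rows.append(
            {
                "guide_a": p.guide_a,
                "guide_b": p.guide_b,
                "chrom": p.chrom,
                "deleted_start": p.deleted_start,
                "deleted_end": p.deleted_end,
                "size_bp": p.size,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["guide_a", "guide_b", "chrom", "deleted_start", "deleted_end", "size_bp"],
    )


def read_pairs(path: str | Path) -> list[tuple[str, str]]:
    """Read a ``guide_a,guide_b`` CSV into a pair list."""
    df = pd.read_csv(path, dtype=str)
    for col in ("guide_a", "guide_b"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    return list(zip(df["guide_a"], df["guide_b"]))
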