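"""Enrichment scoring of a sorted (expression-negative) pool over baseline.

The statistic is the one a tiling knockout screen reads out: guides whose
disruption abolishes the screened phenotype accumulate in the sorted pool.
Per guide the pipeline computes

* condition medians of depth-normalised counts (CPM),
* ``log2fc = log2((median_sorted + pc) / (median_baseline + pc))``,
* a one-sided Welch two-sample t-test (sorted > baseline) across
  replicates, by default on the variance-stabilised ``log2(CPM + 1)`` scale,
* the composite ``score = -log10(p) * log2fc``,

and calls hits with strict thresholds ``log2fc > 1.5`` and ``p < 0.02``.
Hits falling outside annotated exons ("enriched non-exonic") are the
candidate regulatory elements; exonic hits act as positive controls.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genomic_io import GenomicInterval, write_bedgraph
from .library_design import GuideLibrary
from .screen_counts import CountMatrix, SampleSheet

__all__ = [
    "EnrichmentParams",
    "normalize_cpm",
    "guide_statistics",
    "call_hits",
    "score_track",
    "volcano_summary",
]

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = [
    "guide_id",
    "median_sorted",
    "median_baseline",
    "log2fc",
    "p_value",
    "score",
    "volcano_class",
    "is_hit",
    "chrom",
    "cut_site",
    "exonic",
]

#: smallest positive double; the p-value assigned when both groups are
#: constant but the sorted mean exceeds baseline (total ordering, no NaN)
P_FLOOR = sys.float_info.min


@dataclass
class EnrichmentParams:
    """Tunable knobs of the enrichment stage.

    pseudocount
        Added to both condition medians before the ratio (normalised-count
        units); guards zero baselines.
    lfc_threshold, p_threshold
        Strict volcano cut-offs for hit calling (``log2fc > lfc`` and
        ``p < p_thr``).
    scale
        Depth-normalisation target per sample (reads per million).
    fold_change_mode
        ``"median-of-conditions"``: medians first, then one ratio (default);
        ``"median-of-ratios"``: per-replicate-pair ratios first, median after.
    log_transform
        Run the t-test on ``log2(CPM + 1)`` (default) instead of raw CPM.
    """

    pseudocount: float = 1.0
    lfc_threshold: float = 1.5
    p_threshold: float = 0.02
    normalization: str = "cpm"
    scale: float = 1e6
    fold_change_mode: str = "median-of-conditions"
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.lfc_threshold <= 0:
            raise ValueError("lfc_threshold must be positive")
        if not (0 < self.p_threshold < 1):
            raise ValueError("p_threshold must lie in (0, 1)")
        if self.normalization != "cpm":
            raise ValueError("only 'cpm' normalization is supported")
        if self.fold_change_mode not in ("median-of-conditions", "median-of-ratios"):
            raise ValueError(f"unknown fold_change_mode {self.fold_change_mode!r}")


def normalize_cpm(cm: CountMatrix, scale: float = 1e6) -> pd.DataFrame:
    """Scale each sample column to ``scale`` total (counts per million).

    Zeros stay zero; an all-zero sample column is an error naming the sample.
    """
    totals = cm.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"sample {zero.index[0]!r} has no assigned reads")
    return cm.counts / totals * scale


def _welch_one_sided(
    sorted_vals: np.ndarray, baseline_vals: np.ndarray
) -> np.ndarray:
    """Vectorised one-sided Welch t-test p-values (sorted mean > baseline mean).

    Degenerate rows (zero variance in both groups) get p = 1 when the means
    are not larger in the sorted group, else the machine-minimum positive
    double — a total ordering without exceptions.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        res = stats.ttest_ind(
            sorted_vals, baseline_vals, axis=1, equal_var=False, alternative="greater"
        )
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = np.isnan(p)
    if degenerate.any():
        ms = sorted_vals[degenerate].mean(axis=1)
        mb = baseline_vals[degenerate].mean(axis=1)
        p[degenerate] = np.where(ms > mb, P_FLOOR, 1.0)
    return np.clip(p, P_FLOOR, 1.0)


def guide_statistics(
    norm: pd.DataFrame,
    sheet: SampleSheet,
    params: EnrichmentParams | None = None,
    lib: GuideLibrary | None = None,
) -> pd.DataFrame:
    """Per-guide medians, log2 fold enrichment, p-value and score.

    ``norm`` is the CPM matrix (guides × samples). The returned table has
    the canonical column order; ``chrom``/``cut_site``/``exonic`` are carried
    from ``lib`` when given (else left empty / False). Hit calling is done
    separately by :func:`call_hits`.
    """
    params = params or EnrichmentParams()
    sorted_ids = sheet.ids_for("sorted")
    baseline_ids = sheet.ids_for("baseline")
    if len(sorted_ids) < 2 or len(baseline_ids) < 2:
        raise ValueError("need >=2 replicates per condition for the t-test")
    s = norm[sorted_ids].to_numpy(dtype=float)
    b = norm[baseline_ids].to_numpy(dtype=float)
    median_sorted = np.median(s, axis=1)
    median_baseline = np.median(b, axis=1)
    pc = params.pseudocount
    if params.fold_change_mode == "median-of-conditions":
        log2fc = np.log2((median_sorted + pc) / (median_baseline + pc))
    else:
        # replicate-matched ratios (replicate order pairs columns), median after
        k = min(s.shape[1], b.shape[1])
        ratios = (s[:, :k] + pc) / (b[:, :k] + pc)
        log2fc = np.log2(np.median(ratios, axis=1))
    if params.log_transform:
        p = _welch_one_sided(np.log2(s + 1.0), np.log2(b + 1.0))
    else:
        p = _welch_one_sided(s, b)
    score = -np.log10(p) * log2fc
    # BH-FDR is reported for reference only; hit calling thresholds raw p
    q = stats.false_discovery_control(p, method="bh")
    tbl = pd.DataFrame(
        {
            "guide_id": norm.index,
            "median_sorted": median_sorted,
            "median_baseline": median_baseline,
            "log2fc": log2fc,
            "p_value": p,
            "score": score,
            "volcano_class": "non-exonic",
            "is_hit": False,
            "chrom": "",
            "cut_site": -1,
            "exonic": False,
            "q_value": q,
        }
    ).reset_index(drop=True)
    if lib is not None:
        meta = {g.guide_id: g for g in lib.guides}
        missing = [gid for gid in tbl["guide_id"] if gid not in meta]
        if missing:
            raise LookupError(f"guides absent from library: {missing[:5]}")
        tbl["chrom"] = [meta[g].chrom for g in tbl["guide_id"]]
        tbl["cut_site"] = [meta[g].cut_site for g in tbl["guide_id"]]
        tbl["exonic"] = [meta[g].exonic for g in tbl["guide_id"]]
    return call_hits(tbl, params)


def call_hits(tbl: pd.DataFrame, params: EnrichmentParams | None = None) -> pd.DataFrame:
    """Set ``is_hit`` and ``volcano_class`` with strict volcano thresholds.

    ``is_hit`` requires ``log2fc > lfc_threshold`` and ``p < p_threshold``
    (both strict). Classes: ``exonic`` (cut window in an exon, hit or not),
    ``enriched-non-exonic`` (hit outside exons — candidate regulatory
    element) and ``non-exonic`` (everything else).
    """
    params = params or EnrichmentParams()
    tbl = tbl.copy()
    tbl["is_hit"] = (tbl["log2fc"] > params.lfc_threshold) & (
        tbl["p_value"] < params.p_threshold
    )
    exonic = tbl["exonic"].astype(bool)
    tbl["volcano_class"] = np.where(
        exonic, "exonic", np.where(tbl["is_hit"], "enriched-non-exonic", "non-exonic")
    )
    ordered = ENRICHMENT_COLUMNS + [c for c in tbl.columns if c not in ENRICHMENT_COLUMNS]
    return tbl[ordered]


def score_track(tbl: pd.DataFrame, path) -> None:
    """Write the per-guide score as a bedGraph of 1-bp intervals at cut sites.

    Guides sharing a cut coordinate are emitted at the next free 1-bp
    interval in stable table order; each collision is logged.
    """
    records: list[tuple[GenomicInterval, float]] = []
    taken: set[tuple[str, int]] = set()
    for row in tbl.itertuples(index=False):
        if row.cut_site is None or int(row.cut_site) < 0:
            raise ValueError(f"guide {row.guide_id}: missing cut_site")
        pos = int(row.cut_site)
        while (row.chrom, pos) in taken:
            pos += 1
        if pos != int(row.cut_site):
            logger.warning(
                "score_track: cut site collision for %s at %s:%d, emitted at %d",
                row.guide_id, row.chrom, int(row.cut_site), pos,
            )
        taken.add((row.chrom, pos))
        records.append((GenomicInterval(row.chrom, pos, pos + 1), float(row.score)))
    write_bedgraph(records, path, track_name="tilescreen_score")


def volcano_summary(tbl: pd.DataFrame) -> dict:
    """Class counts plus the hit list sorted by descending score.

    Ties in score are broken by guide_id so the ordering is reproducible.
    """
    counts = tbl["volcano_class"].value_counts().to_dict()
    for cls in ("non-exonic", "exonic", "enriched-non-exonic"):
        counts.setdefault(cls, 0)
    hits = (
        tbl[tbl["is_hit"]]
        .sort_values(["score", "guide_id"], ascending=[False, True])
        ["guide_id"]
        .tolist()
    )
    return {
        "n_guides": int(len(tbl)),
        "class_counts": {k: int(v) for k, v in counts.items()},
        "n_hits": int(tbl["is_hit"].sum()),
        "hits": hits,
    }
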