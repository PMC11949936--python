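"""Synthetic screen generator with known ground truth.

Emulates the full data-generating process of a tiling knockout screen read
out by sorting: an i.i.d. target region with synthetic exon blocks, a tiling
guide library over it, overdispersed per-replicate guide counts (triplicate
sorted vs triplicate baseline, negative-binomial noise around log-normal
baseline abundances), amplicon reads embedding each spacer between fixed
vector anchors, and noisy qPCR tables. Every draw is seeded; each pipeline
stage consumes an independent substream of the one seed, so regenerating any
single artifact is reproducible without replaying the others.

What it deliberately does not model: FACS sorting dynamics, infection (MOI)
statistics, population bottlenecks, PCR jackpotting, or Cas9 editing-outcome
spectra. Enriched exonic guides and enriched regulatory-element guides are
simulated identically — the screen measures enrichment, not mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genomic_io import FeatureAnnotation, GenomicInterval
from .library_design import GuideLibrary
from .screen_counts import CountMatrix, Sample, SampleSheet

__all__ = [
    "ScreenSimParams",
    "ScreenSimTruth",
    "SimRegion",
    "DEFAULT_ANCHOR5",
    "DEFAULT_ANCHOR3",
    "simulate_region",
    "simulate_counts",
    "simulate_fastq",
    "simulate_qpcr",
]

# Synthetic vector context flanking the spacer in simulated amplicon reads
# (U6-promoter 3' end / scaffold 5' end as found in common lentiviral guide
# expression cassettes). 20 bp each keeps spurious matches in 250-bp random
# stuffer vanishingly rare, so exact recovery holds at full depth.
DEFAULT_ANCHOR5 = "TATCTTGTGGAAAGGACGAA"
DEFAULT_ANCHOR3 = "GTTTTAGAGCTAGAAATAGC"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CHAR2IDX = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    _CHAR2IDX[_c] = _i

# substream labels: independent generators per stage from one user seed
_STAGE_REGION, _STAGE_COUNTS, _STAGE_FASTQ, _STAGE_QPCR = 1, 2, 3, 4


def _rng(stage: int, seed: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stage,)))


@dataclass
class ScreenSimParams:
    """Study-design parameters of the simulated screen.

    Defaults mirror the screened design: a ~24-kb window, triplicate sorted
    vs triplicate baseline samples at 200 reads per guide, six truly
    enriched non-exonic guides at 8-fold enrichment, 250-bp reads. GC
    content 0.41 matches the human locus scale; the negative-binomial size
    (dispersion) of 10 is a conventional pooled-screen value.
    """

    seed: int = 0
    region_length: int = 24_000
    gc_content: float = 0.41
    n_true_hits: int = 6
    hit_fold_enrichment: float = 8.0
    exon_intervals: list[tuple[int, int]] | None = None
    replicates: int = 3
    mean_coverage: float = 200.0
    dispersion: float = 10.0
    read_error_rate: float = 0.0
    read_length: int = 250
    chrom: str = "chrS"

    def __post_init__(self) -> None:
        if self.region_length < 1_000:
            raise ValueError("region_length must be >= 1000 bp")
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must lie in [0, 1]")
        for name in ("hit_fold_enrichment", "mean_coverage", "dispersion"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.replicates < 1 or self.n_true_hits < 0:
            raise ValueError("replicates >= 1 and n_true_hits >= 0 required")
        if not (0.0 <= self.read_error_rate < 1.0):
            raise ValueError("read_error_rate must lie in [0, 1)")

    def default_exons(self) -> list[tuple[int, int]]:
        """Four exon blocks spread over the region (knockout positive controls).

        Block width scales with the region (250 bp at the default 24 kb, so
        exonic guides stay a small minority, as in a locus-scale tile).
        """
        L = self.region_length
        w = max(50, round(L / 96))
        return [
            (int(L * f), min(int(L * f) + w, L)) for f in (0.30, 0.45, 0.60, 0.75)
        ]


@dataclass
class SimRegion:
    chrom: str
    sequence: str
    interval: GenomicInterval
    annotation: FeatureAnnotation


@dataclass
class ScreenSimTruth:
    """Ground truth of one simulated screen.

    ``fold_enrichment`` covers every guide exactly once (1.0 = unenriched);
    ``hit_guide_ids`` are the planted non-exonic hits the pipeline is meant
    to recover (enriched exonic guides mimic knockout positive controls and
    are listed separately).
    """

    hit_guide_ids: list[str]
    enriched_exonic_ids: list[str]
    fold_enrichment: dict[str, float]
    baseline_abundance: dict[str, float]

    def __post_init__(self) -> None:
        if set(self.hit_guide_ids) & set(self.enriched_exonic_ids):
            raise ValueError("a guide cannot be both a planted hit and exonic")


def simulate_region(params: ScreenSimParams) -> SimRegion:
    """I.i.d. DNA at the requested GC content, with exon blocks as BED-style
    annotation. Deterministic per seed."""
    rng = _rng(_STAGE_REGION, params.seed)
    gc = params.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=params.region_length, p=probs)
    sequence = _BASES[idx].tobytes().decode()
    exons = params.exon_intervals
    if exons is None:
        exons = params.default_exons()
    ann = FeatureAnnotation(
        intervals=[
            (GenomicInterval(params.chrom, s, e), "exon") for s, e in exons
        ],
        source="synthetic",
    )
    return SimRegion(
        chrom=params.chrom,
        sequence=sequence,
        interval=GenomicInterval(params.chrom, 0, params.region_length),
        annotation=ann,
    )


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, size_param: float
) -> np.ndarray:
    """Negative binomial with given mean and size (inverse-dispersion)."""
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    lib: GuideLibrary, params: ScreenSimParams
) -> tuple[CountMatrix, ScreenSimTruth, SampleSheet]:
    """Overdispersed replicate counts with planted enrichment.

    Baseline abundances are log-normal (sigma 0.5) scaled to
    ``mean_coverage`` reads per guide; replicate counts are negative
    binomial around them. In the sorted condition the means of the planted
    non-exonic hits and of every exonic guide are multiplied by
    ``hit_fold_enrichment``, then the whole sorted mean vector is
    renormalised to the baseline target depth (sorting conserves read-out
    depth, not cell abundance) before drawing.
    """
    if len(lib) == 0:
        raise ValueError("library is empty")
    rng = _rng(_STAGE_COUNTS, params.seed)
    guide_ids = [g.guide_id for g in lib.guides]
    exonic = np.array([g.exonic for g in lib.guides], dtype=bool)
    n = len(guide_ids)
    non_exonic_idx = np.flatnonzero(~exonic)
    if params.n_true_hits > len(non_exonic_idx):
        raise ValueError(
            f"n_true_hits={params.n_true_hits} exceeds the "
            f"{len(non_exonic_idx)} non-exonic guides"
        )
    abundance = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    abundance *= params.mean_coverage / abundance.mean()
    hit_idx = np.sort(rng.choice(non_exonic_idx, size=params.n_true_hits, replace=False))
    fold = np.ones(n)
    fold[hit_idx] = params.hit_fold_enrichment
    fold[exonic] = params.hit_fold_enrichment
    target_depth = abundance.sum()
    sorted_mean = abundance * fold
    sorted_mean *= target_depth / sorted_mean.sum()
    cols: dict[str, np.ndarray] = {}
    samples: list[Sample] = []
    for r in range(1, params.replicates + 1):
        sid = f"sorted_{r}"
        cols[sid] = _nb_draw(rng, sorted_mean, params.dispersion)
        samples.append(Sample(sample_id=sid, condition="sorted", replicate=r))
    for r in range(1, params.replicates + 1):
        sid = f"baseline_{r}"
        cols[sid] = _nb_draw(rng, abundance, params.dispersion)
        samples.append(Sample(sample_id=sid, condition="baseline", replicate=r))
    counts = pd.DataFrame(cols, index=pd.Index(guide_ids, name="guide_id"))
    cm = CountMatrix(counts=counts, unassigned=pd.Series(0, index=counts.columns))
    truth = ScreenSimTruth(
        hit_guide_ids=[guide_ids[i] for i in hit_idx],
        enriched_exonic_ids=[guide_ids[i] for i in np.flatnonzero(exonic)],
        fold_enrichment=dict(zip(guide_ids, fold.tolist())),
        baseline_abundance=dict(zip(guide_ids, abundance.tolist())),
    )
    return cm, truth, SampleSheet(samples=samples)


def _write_fastq(path: Path, seqs: np.ndarray, qual_char: str = "I") -> None:
    L = seqs.dtype.itemsize
    qual = qual_char * L
    with open(path, "w") as fh:
        for i, s in enumerate(seqs):
            fh.write(f"@r{i}\n{s.decode()}\n+\n{qual}\n")


def simulate_fastq(
    cm: CountMatrix,
    lib: GuideLibrary,
    out_dir: str | Path,
    params: ScreenSimParams,
    anchor5: str = DEFAULT_ANCHOR5,
    anchor3: str = DEFAULT_ANCHOR3,
) -> SampleSheet:
    """Write one FASTQ per sample: each count unit becomes one read.

    A read is ``anchor5 + spacer + anchor3`` inserted at a random offset in
    random stuffer sequence of ``read_length`` bp, with per-base
    substitution errors at ``read_error_rate``, in shuffled record order.
    Returns a sample sheet whose rows point at the written files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = _rng(_STAGE_FASTQ, params.seed)
    spacer_by_guide = {g.guide_id: g.spacer for g in lib.guides}
    missing = [gid for gid in cm.guide_ids if gid not in spacer_by_guide]
    if missing:
        raise LookupError(f"count matrix guides absent from library: {missing[:5]}")
    cassette_fixed5 = np.frombuffer(anchor5.encode(), dtype=np.uint8)
    cassette_fixed3 = np.frombuffer(anchor3.encode(), dtype=np.uint8)
    L = params.read_length
    cassette_len = len(anchor5) + 20 + len(anchor3)
    if cassette_len > L:
        raise ValueError(f"cassette ({cassette_len} bp) exceeds read length {L}")
    samples = []
    for sid in cm.sample_ids:
        col = cm.counts[sid].to_numpy()
        n = int(col.sum())
        path = out_dir / f"{sid}.fastq"
        if n == 0:
            path.write_text("")
        else:
            spacers = "".join(
                np.repeat([spacer_by_guide[g] for g in cm.guide_ids], col)
            )
            spac = np.frombuffer(spacers.encode(), dtype=np.uint8).reshape(n, 20)
            cassette = np.hstack(
                [
                    np.tile(cassette_fixed5, (n, 1)),
                    spac,
                    np.tile(cassette_fixed3, (n, 1)),
                ]
            )
            reads = rng.integers(0, 4, size=(n, L), dtype=np.uint8)
            offsets = rng.integers(0, L - cassette_len + 1, size=n)
            window = offsets[:, None] + np.arange(cassette_len)[None, :]
            np.put_along_axis(reads, window, _CHAR2IDX[cassette], axis=1)
            if params.read_error_rate > 0:
                err = rng.random((n, L)) < params.read_error_rate
                shift = rng.integers(1, 4, size=(n, L), dtype=np.uint8)
                reads = np.where(err, (reads + shift) % 4, reads)
            reads = reads[rng.permutation(n)]
            seqs = np.ascontiguousarray(_BASES[reads]).view(f"S{L}").ravel()
            _write_fastq(path, seqs)
        samples.append(sid)
    sheet_samples = []
    for sid in cm.sample_ids:
        cond, rep = sid.rsplit("_", 1)
        sheet_samples.append(
            Sample(
                sample_id=sid,
                condition=cond,
                replicate=int(rep),
                fastq_r1=str(out_dir / f"{sid}.fastq"),
            )
        )
    return SampleSheet(samples=sheet_samples)


def simulate_qpcr(
    true_fold: float,
    n_donors: int = 3,
    noise_sd_ct: float = 0.3,
    seed: int = 0,
    reference_ct: float = 20.0,
    control_delta_ct: float = 4.0,
) -> pd.DataFrame:
    """Paired treated/untreated qPCR table with a known true fold change.

    Per donor, the untreated dCt is fixed and the treated dCt is
    ``control_delta_ct - log2(true_fold)`` plus Gaussian Ct noise, so with
    zero noise the recovered 2^-ddCt equals ``true_fold`` exactly.
    """
    if true_fold <= 0:
        raise ValueError("true_fold must be positive")
    rng = _rng(_STAGE_QPCR, seed)
    rows = []
    for d in range(1, n_donors + 1):
        sample = f"donor{d}"
        rows.append(
            {
                "sample": sample,
                "group": "untreated",
                "target_ct": reference_ct + control_delta_ct,
                "reference_ct": reference_ct,
            }
        )
        dct_treated = (
            control_delta_ct - np.log2(true_fold) + rng.normal(0.0, noise_sd_ct)
        )
        rows.append(
            {
                "sample": sample,
                "group": "treated",
                "target_ct": reference_ct + dct_treated,
                "reference_ct": reference_ct,
            }
        )
    return pd.DataFrame(rows, columns=["sample", "group", "target_ct", "reference_ct"])
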