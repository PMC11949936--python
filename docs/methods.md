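# Methods

`tilescreen` analyses pooled, tiled CRISPR/Cas9 knockout screens that map
regulatory elements by sorting: cells carrying one guide each are edited,
the phenotype-negative population (here, loss of a reporter for the screened
gene) is sorted, and guides whose cut disrupts a functional element become
enriched in the sorted pool relative to an untreated baseline. This note
records the model, the conventions, the defaults and why, the numerical
edge-case policies, and what the synthetic generator does and does not show.

## Coordinates and library design

All internal coordinates are 0-based half-open; 1-based inclusive
genome-browser coordinates are converted exactly once at the boundary
(`parse_region`: printed start − 1, end unchanged). The 1-based convention
was chosen for printed coordinates because it is what browsers and papers
display; the two possible readings of a printed boundary pair differ by
1 bp, immaterial at locus scale.

The scanner enumerates every 20-nt protospacer with an NGG PAM on both
strands whose full 23 bp lie inside the target interval. Partially
overhanging protospacers are excluded (unambiguous and conservative), and
any window containing `N` is dropped — an undetermined base cannot be
synthesised or counted reliably. The predicted cut site is the canonical
SpCas9 blunt cut between protospacer positions 17 and 18 (3 bp 5′ of the
PAM), stored as the 0-based coordinate of the cleaved bond: `spacer_start +
17` on "+", `spacer_start + 3` on "−". Guides are ordered by cut site and
given zero-padded rank ids.

Default design filters: deduplication of identical spacers (duplicates are
uncountable in a pooled readout; the first by coordinate wins) and removal
of spacers containing `TTTT`, which terminates U6 Pol III transcription.
GC-content bounds exist but are off by default — a tiling screen wants
coverage more than it wants activity-optimised guides.

A guide is labelled exonic when its ±3 bp cut window overlaps an annotated
exon. The window, rather than the bare cut coordinate, reflects that indels
extend a few bases around the cut.

## Counting

Reads are assigned by anchor-delimited extraction: the 20 bases after the
first occurrence of the 5′ vector anchor, required to be followed
immediately by the 3′ anchor when one is configured. Matching to the
library is an exact dictionary lookup by default; `max_mismatches=1`
rescues single-substitution errors but discards reads matching two or more
guides. Exact matching is the default because rescue policies trade
specificity for sensitivity in ways that depend on library density, and the
conservative choice is reproducible. R1 is always scanned first; R2
(reverse-complemented) only when R1 yields nothing, so counting is
deterministic and independent of read order. Base qualities are ignored —
the anchor+spacer match is itself a strong integrity check at amplicon
read lengths. Anchors are configuration, not constants: amplicon designs
differ between vectors.

Conservation (assigned + unassigned = reads scanned, per sample) is an
enforced invariant, not a convention.

## Enrichment statistic

Per sample, counts are scaled to counts per million (CPM). CPM is the
minimal depth correction compatible with the median/fold-change readout;
nothing downstream assumes more than equal sequencing effort.

Per guide:

* `median_sorted`, `median_baseline` — medians of CPM across the replicates
  of each condition. Medians first, one ratio after (the
  `median-of-ratios` alternative is available via
  `EnrichmentParams.fold_change_mode`; with unpaired samples the
  medians-first order is the natural one).
* `log2fc = log2((median_sorted + 1) / (median_baseline + 1))` — the
  pseudocount of 1 normalised unit guards zero baselines and barely
  perturbs well-covered guides (~200 CPM-scale medians at default depth).
* `p_value` — one-sided two-sample Welch t-test (sorted mean > baseline
  mean) across replicates, computed by default on `log2(CPM + 1)`.
  Welch because there is no reason to assume equal variances between an
  edited, sorted population and an untreated culture; unpaired because the
  samples are not paired. The log scale stabilises the variance of
  overdispersed counts, whose standard deviation otherwise grows linearly
  with the mean: at triplicate sample sizes the raw-scale test loses so
  much power on strongly enriched guides that planted 8-fold effects
  routinely escape detection, while on the log scale the same effects are
  recovered reliably (see the recovery test). Raw-CPM testing remains
  available (`log_transform=False`).
* `score = −log10(p) × log2fc` — the composite used for genome-track
  visualisation; positive iff the guide is enriched.

Hits require `log2fc > 1.5` and `p < 0.02`, both strict, with no
multiple-testing correction — these are screening thresholds for a
validation funnel, not confirmatory inference; a Benjamini–Hochberg
`q_value` column is emitted for reference but never used in calls. Volcano
classes: `exonic` (knockout positive controls, whatever their
significance), `enriched-non-exonic` (hits outside exons — the candidate
regulatory elements), `non-exonic` (the rest).

Degenerate variance: when both groups are constant, p is 1.0 unless the
sorted mean is strictly larger, in which case the smallest positive double
is used; p is clipped into `(0, 1]`. This yields a total ordering with no
NaNs and no exceptions.

The score track writes one 1-bp bedGraph interval per guide at its cut
site; two guides can share a cut coordinate (one per strand), in which case
the later one in table order is emitted at the next free base and the
collision is logged. Track values round-trip to 1e-6.

## Paired-guide excision and qPCR arithmetic

The predicted dual-guide deletion is the interval between the two cleaved
bonds; its size is the difference of the cut coordinates — the quantity a
perfect religation of the two blunt ends removes. It is symmetric in the
pair and independent of either guide's strand. End resection and indels at
the junction are deliberately not modelled.

Relative expression uses the plain `2^−ΔΔCt` form without
amplification-efficiency correction. Technical replicates are averaged on
the Ct scale (Ct is the log-domain quantity); biological replicates are
summarised on the fold-change scale with the sample (n−1) standard
deviation, reported as missing — not zero — for a single replicate.
Treated samples pair with the control-group entry of the same sample name;
a single control sample serves as a common calibrator.

## Synthetic data: what it emulates

The generator reproduces the screen's design parameters as defaults: a
24,000-bp target window, GC 0.41, four exon blocks (~1% of the window
each) acting as knockout positive controls, 6 planted non-exonic hits at
8-fold enrichment, 3 sorted + 3 baseline replicates, 200 reads per guide,
250-bp single-end reads. At these defaults the scanned library holds
~1,800–1,900 guides after filters.

Counts: per-guide baseline abundances are log-normal (σ = 0.5 on the log
scale) scaled to the mean coverage — the skewed representation a cloned
oligo pool actually has — and replicate counts are negative binomial
around them with size (inverse-dispersion) 10, a conventional pooled-screen
overdispersion in the absence of an empirical estimate. Sorted-condition
means are the baseline means times the planted fold for hits and for every
exonic guide (the screen cannot distinguish enrichment mechanisms, only
enrichment), then the whole sorted mean vector is renormalised to the
baseline target depth before drawing — sequencing depth is a property of
the run, not of the selection — which also depletes non-hit guides
slightly, as real sorting does. Renormalising the means rather than the
drawn counts keeps the noise model exactly negative binomial and the
counts integral.

Reads embed `anchor5 + spacer + anchor3` at a uniform random offset in
i.i.d. stuffer sequence, with optional per-base substitution errors and
shuffled record order. The 20-bp default anchors make a spurious anchor
match in 250 bp of random stuffer rare enough that exact recovery holds at
full depth (expected spurious events ≪ 1 across ~2.3 million reads).

All stages draw from independent substreams of a single seed, so any
artifact regenerates without replaying the others, and every simulator is
deterministic per seed.

What passing tests on this generator do **not** show about real screens:
no PCR jackpotting or bottleneck effects, no guide-specific cutting
efficiency, no chromatin-dependent editing outcomes, no contamination
between sorted gates, and i.i.d. sequence rather than real genome
composition (repeats, homopolymers, biased PAM density). Recovery results
here bound what the statistic can do under its own noise model, not what
any particular wet screen achieves.

## Problem sizes in tests

The exact-recovery check runs at the full default depth (6 samples, ~2.2
million reads). Recovery and calibration suites use 10 fixed seeds at the
default 24-kb design; the CLI round-trip tests use a 3-kb mini screen with
a larger planted fold (16×), where the handful of guides per condition
would otherwise make recovery of a 2-guide truth set flaky for
uninteresting small-sample reasons.

## Known limitations

* Normalisation is per-sample CPM only; no control-guide or trimmed-mean
  scaling. With few, strong hits the sorted depth renormalisation slightly
  deflates their measured fold change.
* The t-test at n = 3 vs 3 is underpowered for folds much below ~4 at this
  dispersion; the null calibration shows it runs slightly conservative
  (empirical size ~1.3–1.5% at nominal 2%).
* No off-target or efficiency modelling in design; a tiling screen's
  interpretation layer (clustering of enriched cut sites) is left to the
  genome-browser track.
* Paired-end support is a fallback rescue, not joint mate evidence.
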