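# tilescreen

Analysis toolkit for **tiled pooled CRISPR/Cas9 knockout screens** that map
regulatory elements of a locus. In such a screen, a guide library targets
every SpCas9 site (20-nt protospacer + NGG PAM, both strands) across a
genomic window; cells carrying one guide each are edited, the population
that lost expression of the screened gene is sorted, and guides cutting a
functional element — an exon or an enhancer — become enriched in the sorted
pool relative to an untreated baseline. The package covers the complete
dry-lab half of that experiment and is intended for groups running
locus-scale tiling screens (e.g. dissecting enhancers of the human *TRA* /
T-cell-receptor-α locus) who want a reproducible, scriptable pipeline.

## What it computes

For each guide *g* with sorted/baseline CPM-normalised replicate counts:

- condition medians `m_s(g)`, `m_b(g)` across replicates,
- log2 fold enrichment `LFC(g) = log2((m_s + 1) / (m_b + 1))`,
- one-sided Welch t-test p-value `p(g)` (sorted > baseline, on
  `log2(CPM+1)`),
- composite score `S(g) = −log10 p(g) · LFC(g)`, exported as a
  genome-browser bedGraph track at the predicted cut site
  (`spacer_start + 17` on "+", `spacer_start + 3` on "−": the SpCas9 blunt
  cut 3 bp 5′ of the PAM),
- hit calls with strict thresholds `LFC > 1.5` and `p < 0.02`, classed as
  *exonic* (knockout positive controls) or *enriched non-exonic*
  (candidate regulatory elements).

Around the statistic: NGG protospacer enumeration and library design
filters, anchor-based spacer extraction and guide counting from FASTQ,
dual-guide excision-size prediction (cut-to-cut distance), `2^−ΔΔCt`
qPCR fold-change summaries, and a fully seeded synthetic-screen generator
with known ground truth. See `docs/methods.md` for conventions, defaults
and limitations.

## Worked example

Simulate a complete screen at the standard design (24-kb window, ~1,900
guides after filters, 6 planted non-exonic hits at 8-fold enrichment,
3 sorted + 3 baseline replicates at 200× coverage), then run the pipeline
on it:

```bash
tilescreen simulate --seed 11 --out demo --no-fastq
# 1866 guides, 6 planted hits -> demo

cat > demo/config.yaml <<EOF
library: demo/library.csv
samples: demo/samples.csv
counts: demo/counts.csv
out_dir: demo/results
EOF
tilescreen run --config demo/config.yaml
```

`demo/results/` now holds `enrichment.csv` (one row per guide),
`scores.bedgraph` and `summary.json`. The top *enriched non-exonic* rows:

```
guide_id  cut_site   log2fc  p_value    score
 sg-0256      2737 2.966769 0.000687 9.383648
 sg-1846     21720 2.892934 0.000659 9.202973
 sg-1370     16235 2.747378 0.004271 6.509947
 sg-1034     12321 2.358955 0.004156 5.617408
 sg-1365     16206 2.400610 0.005748 5.378443
```

Each row is a guide whose cut site (`cut_site`, bp into the simulated
window) was over-represented in the sorted pool: `log2fc` is the log2 fold
enrichment of its median normalised count, `p_value` the one-sided Welch
test across triplicates, and `score` their product with −log10. All five
are planted hits from `demo/truth.json` (`sg-0256, sg-1034, sg-1365,
sg-1370, sg-1846`; the sixth, `sg-1908`, fell just below threshold in this
draw — at this design the pipeline recovers ≥ 5 of 6 planted hits with no
false positives in ≥ 9 of 10 seeds). The `exonic` class in `summary.json`
(94 guides here) collects the knockout positive controls.

The same stages are available piecewise (`tilescreen design / count /
score / excise / ddct`) and as library functions
(`tilescreen.scan_protospacers`, `count_guides`, `guide_statistics`, …).

Counting from raw reads instead of a count table: point the sample sheet's
`fastq_r1` column at the read files and omit `counts:` from the config, or
run `tilescreen count --library demo/library.csv --samples demo/samples.csv
--out counts.csv` (anchors configurable with `--anchor5/--anchor3`).

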