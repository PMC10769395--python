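# regulon-forge

Reusable, tested building blocks for characterizing genes repressed by
ETS-family fusion oncoproteins and re-activated regulators downstream of
them:

- **`genomic_io`** — strict readers/writers for FASTA, BED6, ENCODE
  narrowPeak/broadPeak, and tab-delimited DE / expression / survival /
  detection tables (0-based half-open coordinates throughout).
- **`repeats`** — consecutive GGAA/TTCC microsatellite-run profiling in
  fixed windows around peak summits, binned by run multiplicity
  (1/2/3/4/>4), with percentage-of-peaks and runs-per-peak summaries.
- **`annotate`** — strand-aware promoter (−3 kb/+1 kb around the TSS) vs
  distal classification of peaks, flank-based peak→gene assignment, and
  repressive-mark (H3K9me3/H3K27me3) category calling per locus.
- **`targets`** — fold-change/FDR filtering of DE tables, cross-experiment
  intersection, curated-list restriction, and direct-target calling
  (bound ∩ deregulated, split by sign).
- **`cohort`** — Welch tumor-vs-cell-line range screen, correlation
  screening with Benjamini–Hochberg FDR, top-quartile/median concordance,
  Kaplan–Meier + log-rank survival splits, and ΔΔCt qPCR fold changes.
- **`motility`** — greedy nearest-neighbour linking of nucleus detections,
  quality/duration/ROI track filters, per-track total distance and
  movement range (trajectory diameter), trans-well and confluency
  normalizations.
- **`simulate`** — generators for *every* input above with ground-truth
  sidecar tables (planted repeat runs, DE effects, expression shifts,
  correlated gene pairs, hazard ratios, and track path lengths), so the
  whole pipeline is testable without external data.
- **`pipeline`** — one-config orchestration with a checksummed JSON
  manifest; identical seeds give byte-identical outputs.

## CLI

Everything is reachable through the `regulon-forge` entry point:

```sh
# generate a full synthetic input bundle with truth sidecars
regulon-forge simulate --seed 1 --out demo/inputs

# GGAA/TTCC repeat profile of peak summit windows
regulon-forge repeats --peaks demo/inputs/peaks.narrowPeak \
    --genome demo/inputs/genome.fa --window 500 --out demo/profile.tsv

# promoter/distal classification + mark categories
regulon-forge annotate --peaks demo/inputs/peaks.narrowPeak \
    --genes demo/inputs/genes.bed --k9 demo/inputs/h3k9me3.broadPeak \
    --k27 demo/inputs/h3k27me3.broadPeak --out demo/annotate

# DE filtering and direct-target calling
regulon-forge targets --de demo/inputs/de_table.tsv --fc 1.5 --fdr 0.05 \
    --out demo/targets

# correlation screen against a regulator
regulon-forge cohort --matrix demo/inputs/tumors.tsv --regulator reg_0000 \
    --q 0.01 --out demo/correlations.tsv

# survival split + log-rank
regulon-forge survival --table demo/inputs/survival.tsv --out demo/survival.tsv

# track metrics with the quality/duration filters
regulon-forge motility --detections demo/inputs/detections.tsv \
    --min-quality 100 --min-occ 10 --out demo/tracks.tsv

# or the whole thing from one config
regulon-forge run --config examples/run.yaml
```

Every output TSV carries `#`-prefixed header lines recording the
parameters used; `manifest.json` records per-stage SHA-256 checksums.

## Conventions

- Coordinates are 0-based, half-open everywhere; narrowPeak column 10 is
  the summit offset (−1 → absent → interval midpoint used).
- Repeat runs use maximal-run semantics: `(GGAA)3` is one run of n = 3.
- Fold-change thresholds are given on the linear scale, applied
  inclusively on log2; FDR thresholds are strict (`< cutoff`).
- Quality filter is strict (mean quality > 100); duration filter is
  inclusive (≥ 10 points).
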