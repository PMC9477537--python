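# peakshaper

Candidate peak detection and wide-and-deep scoring for genomic coverage
tracks (ChIP-seq / ATAC-seq / DNase-seq style data).

`peakshaper` finds enriched regions on a per-base coverage track with a
multi-scale thresholding scheme — 25 "definitions of enrichment" formed by
rolling means over {100, 200, 400, 800, 1600} bp windows crossed with
fold-over-chromosome-mean thresholds {2, 4, 8, 16, 32} — and extracts
candidate peaks from runs of at least 5 concurring definitions, applying
50 bp / 2 kb size rules with recursive refinement of over-wide runs. Each
candidate is then scored by a three-part model:

- a **shape score** from a small 1-D CNN over a 2000-point, max-normalized
  signal window centered on the region;
- an **enrichment score** from a logistic regression over 11 max-vs-background
  coverage ratios (10–100 kb backgrounds in 10 kb steps, plus chromosome-wide);
- a **peak score** from an MLP combining both scores with the 11 features —
  the probability that the region's signal reflects a real event.

An optional input-control track adds per-region Poisson upper-tail P-values.
A fragment-pileup simulator generates labeled synthetic tracks so training
and evaluation need no external data. Neural components are implemented in
numpy (deterministic, CPU-only); no deep-learning framework is required.

## CLI

```sh
# generate a synthetic track + truth labels + balanced training labels
peakshaper simulate --config cfg.yml --out simdir

# train the three-part scorer; writes a JSON model bundle directory
peakshaper train --track simdir/track.bedgraph --labels simdir/labels.bed \
    --out modeldir --seed 0

# find and score peaks (all candidates are written; --threshold only sets
# the final pass/fail column)
peakshaper call simdir/track.bedgraph --model modeldir --threshold 0.5 \
    --out peaks.bed

# the same with an input control track (adds a P-value column)
peakshaper call-with-input treat.bedgraph --input control.bedgraph \
    --model modeldir --out peaks.bed

# score externally supplied regions, no detection
peakshaper score simdir/track.bedgraph --bed regions.bed --model modeldir \
    --out scored.bed

# precision / recall / selectivity / F1 against peak-noise labeled regions
peakshaper eval --calls peaks.bed --labels simdir/truth.bed --threshold 0.5
```

Every flag can also be supplied from a YAML config file via `--config`;
explicit flags win. `--seed` controls all randomness; `--verbose` logs to
stderr.

Output columns (`call` / `call-with-input`): chrom, start, end, peak_score,
shape_score, enrichment_score, height, [pvalue], pass. Coordinates are
0-based half-open.

## Layout

- `src/peakshaper/coverage_io.py` — bedGraph/bigWig/BED reading, peak writing
- `src/peakshaper/synthetic_data.py` — fragment-pileup simulator + truth labels
- `src/peakshaper/candidate_detection.py` — enrichment map and candidate extraction
- `src/peakshaper/features.py` — signal-window encoding, enrichment ratios, input P-values
- `src/peakshaper/model.py`, `_nn.py` — CNN / logistic regression / MLP scorer
- `src/peakshaper/pipeline.py`, `cli.py`, `evaluation.py` — operating modes, CLI, metrics
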