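# caretile

Analysis toolkit for tiling CRISPR-activation screens and their targeted
single-cell follow-up:

- **simdata** — synthetic inputs with planted ground truth: a tiled guide
  library, negative-binomial screen counts with per-day abundance slopes,
  a targeted single-cell experiment (bimodal guide counts, batch effects,
  planted guide→gene effects), chromatin feature tracks, and region-pair
  interaction score tables.
- **screenstats** — guide scoring against a control-guide normal null,
  a sliding-window random-intercept mixed linear model per 100 bp bin
  (full-ML likelihood-ratio test of the day effect, chi-square df=1),
  direction-aware merging of significant bins within 500 bp into elements,
  and a final per-element −log10 adjusted-p score.
- **teslade** — single-cell perturbation differential expression: Gaussian
  mixture thresholding of guide counts, cell/gene filtering, depth
  normalization with per-run batch regression, and a two-part
  (detection + continuous) hurdle test of each perturbation against a
  distal-guide background (default ≥400 kb), BH-adjusted jointly.
- **featmodels** — RPK summaries of coverage tracks (histone features
  resized to ≥1 kb), per-bin z-scores, cross-validated logistic element
  prediction with a shuffled-label baseline (10×5-fold, 50 models per
  category), per-TF controlled logistic models, and a random forest
  separating top vs bottom regulatory pairs.
- **pairintegrate** — interaction-square score assignment (max score within
  25 kb squares for Capture-C/Hi-C, 5 kb for catalog links, strict >3 /
  inclusive ≥25 thresholds), evidence classification (nb > other > noEF at
  ≤250 bp), linear distance and jumped-gene counts.
- **io / config / pipeline / cli** — plain-text I/O (TSV, BED, bedGraph,
  MatrixMarket with name sidecars), one YAML config, and a deterministic
  five-stage driver with a checksummed run manifest.

## CLI

One entry point with per-stage subcommands:

```sh
caretile run --out runs/demo --seed 1            # full synthetic pipeline
caretile simulate --out runs/demo                # inputs only
caretile screen --counts counts.tsv --samples samples.tsv --library lib.tsv \
    --chrom chrS --region-start 0 --region-end 100000 --out runs/screen
caretile tesla --genes genes.mtx --guides guides.mtx --runs runs.tsv \
    --library lib.tsv --cares cares.tsv --level care --out runs/tesla
caretile features --tracks track_ATAC.bedgraph --cares cares.tsv \
    --chrom chrS --region-start 0 --region-end 100000 --out runs/features
caretile integrate --pairs de.tsv --cares cares.tsv --annotation genes.tsv \
    --chicago chicago.tsv --shaman shaman.tsv --out runs/integrate
```

Defaults follow the published analysis values where one exists (alpha 0.05,
500 bp merge gap, 400 kb background distance, 25 kb/5 kb interaction
squares, 250 bp evidence distance, 10×5-fold CV); see
`caretile.config.PipelineConfig`.

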