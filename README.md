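# rretools

A tested, reusable pipeline for regeneration-responsive element (RRE)
analysis from chromatin-accessibility data:

- **`rretools.synthetic`** — simulator that generates every pipeline input
  with known ground truth: genomes and gene models, peak sets with planted
  emerging peaks, Poisson accessibility count matrices, DE gene lists
  enriched near planted peaks, CNE intervals, and 400 bp sequence sets with
  planted (optionally co-occurring) PWM instances.
- **`rretools.diff_accessibility`** — per-peak two-sided Wilcoxon rank-sum
  testing (midranks, tie-corrected variance, continuity correction), log2
  fold change on group means, detection-fraction filter; a peak passes at
  p < 0.1, avg_log2FC >= 0.25 and max(pct1, pct2) >= 0.025.
- **`rretools.rre_caller`** — emerging-peak calling by subtracting control
  peaks within 100 bp center distance, organ-level set combination with
  dedup, and Venn partitioning of RRE sets via proximity-graph components.
- **`rretools.peak_gene`** — ±50 kb strand-aware gene windows, peak-to-gene
  linking, and hypergeometric upper-tail enrichment computed in log space
  (finite log10 p down to −350 and beyond).
- **`rretools.cnn`** — a fixed 4-conv-layer sequence classifier (59,785
  trainable parameters, implemented in pure NumPy with explicit backprop
  and Adam), chromosome-holdout datasets with 10:1 controls, de novo motif
  extraction from first-layer filters, PWM-vs-PWM matching with a
  column-shuffle null, and motif co-occurrence testing over the third conv
  layer's 90 bp receptive-field windows.
- **`rretools.categorizer`** — log-odds PWM scanning on both strands and
  Sox/Six four-category enhancer partitioning cross-tabulated with linked
  DE genes.

All genomic coordinates are 0-based half-open (BED convention). Input and
output formats are plain text: BED, minimal GTF, FASTA, JASPAR PFMs,
triplet count TSVs, JSON.

## Test

```sh
python -m pytest tests/
```

The suite includes unit tests per module, property tests (oracle
equivalence against brute-force implementations, exhaustive enumeration
for the rank-sum and hypergeometric tests), and `tests/test_acceptance.py`
with one test per acceptance criterion. The CNN recovery tests train real
models and take several minutes on one CPU.

## CLI

Every stage is exposed under a single entry point:

```sh
# generate a fully synthetic dataset with ground truth
rretools simulate --config config.yaml --outdir sim/

# differential accessibility, then RRE calling
rretools diff-peaks --counts sim/counts_SC.tsv --groups sim/groups_SC.tsv --out diff.tsv
rretools call-rres --treated sim/peaks_treated_SC.bed \
    --untreated sim/peaks_control_SC.bed --stats diff.tsv -d 100 --out rres.bed

# Venn partition of per-cell-type RRE sets
rretools venn --sets sc.bed --sets pc.bed --sets hc.bed

# peak-gene linking and enrichment
rretools link --rres rres.bed --genes sim/genes.gtf --sizes sim/genome.sizes \
    --window 50000 --out links.tsv
rretools enrich --links links.tsv --de sim/de_genes.tsv --genes sim/genes.gtf \
    --out enrichment.json

# CNN training, motif extraction, co-occurrence
rretools train --positives sim/positives.fa --controls sim/controls.fa \
    --seed 0 --outdir run/
rretools motifs --weights run/model_weights.npz --positives sim/positives.fa \
    --outdir run/
rretools cooccur --weights run/model_weights.npz --positives sim/positives.fa \
    --controls sim/controls.fa --out cooccurrence.tsv

# Sox/Six categorization
rretools categorize --fasta rres.fa --out categories.tsv
```

`simulate --config` takes a YAML file overriding any `SyntheticConfig`
field (`n_positives: 2000`, `seed: 7`, ...).

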