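# cagegrn

Enhancer calling, transcription-factor binding prediction and TF influence
ranking from CAGE-seq 5'-tag data alone.

Starting from per-position CTSS BED files (stranded 5'-tag counts), the
pipeline:

1. **TPM-normalizes, pools and pre-filters** CTSS signal and builds
   unidirectional tag clusters with a slice-reduce approach (gap ≤ 20 bp,
   same strand); gene expression is the sum of tag clusters per annotated
   gene (`cagegrn.ctss_clustering`).
2. **Calls bidirectional (enhancer) regions**: at each candidate midpoint a
   balance score B = √(0.5·D/T) + √(0.5·U/T) compares minus-strand upstream
   and plus-strand downstream signal in a 201-bp window; midpoints with
   B ≥ 0.95 are merged, filtered by per-sample support, and width-normalized
   to 200 bp (`cagegrn.bidirectional`).
3. **Predicts TF binding** at the 200-bp regions with L2 logistic regression
   on three features per (TF, enhancer): the best motif z-score against a
   GC-matched sampled background, log-transformed quantile-normalized
   bidirectional TPM, and average curated ChIP coverage. Per-TF and general
   (pooled) models are evaluated by held-out-chromosome / held-out-cell-type
   PR AUC (`cagegrn.binding_model`).
4. **Builds TF→gene networks**: distance-weighted binding (flat to 5 kb,
   exponential decay to 100 kb), TF/target expression, and genome-wide motif
   activity are rank-scaled to [0, 1] and averaged into an interaction score;
   the top edges (default 500 000) form the GRN (`cagegrn.grn_inference`).
5. **Ranks TFs by influence** over a source→target state change: a
   differential network (max(0, target − source) per edge) is traversed to
   depth 2 and positive target-gene log2 fold changes are aggregated with a
   depth-discounted best-path rule; time-course influence profiles are
   clustered with seeded k-means and an elbow pick (`cagegrn.influence`).

`cagegrn.fixtures` generates deterministic synthetic genomes, CTSS tags,
motifs, labels and coverage tracks with planted truth tables, so the entire
pipeline is testable offline.

## CLI

```bash
cagegrn fixtures --seed 7 --out-dir fx/                  # synthetic inputs
cagegrn validate fx/genome.fa fx/ctss_rep1.bed fx/motifs.jaspar
cagegrn ctss --ctss fx/ctss_rep1.bed --ctss fx/ctss_rep2.bed \
    --ctss fx/ctss_rep3.bed --annotation fx/genes.bed --out-dir out/ctss
cagegrn enhancers --ctss fx/ctss_rep1.bed --ctss fx/ctss_rep2.bed \
    --ctss fx/ctss_rep3.bed --annotation fx/genes.bed --out-dir out/enh
cagegrn binding --enhancers out/enh/enhancers.bed --genome fx/genome.fa \
    --motifs fx/motifs.jaspar --motif2tf fx/motif2tf.tsv \
    --model model.json --out-dir out/bind
cagegrn network --binding out/bind/binding.tsv --enhancers out/enh/enhancers.bed \
    --expression out/ctss/gene_expression.tsv --annotation fx/genes.bed \
    --out out/grn.tsv
cagegrn influence --source-grn A.tsv --target-grn B.tsv --de de.tsv --out-dir out/inf
cagegrn timecourse --influence t1.tsv --influence t2.tsv --influence t3.tsv \
    --k-range 1:6 --out-dir out/tc
```

All coordinates are 0-based half-open (BED-native) internally. Coverage
tracks are bedGraph; motif collections are JASPAR-format PFMs with an
optional motif→TF mapping TSV. A differential-expression table
(`gene<TAB>log2fc`) can be supplied to `influence`; otherwise a
pseudocounted log2 fold change of pooled gene TPM is available as a
fallback (`cagegrn.influence.simple_log2fc`).

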