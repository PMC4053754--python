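# txdominance

Most protein-coding genes express many annotated transcripts, but in any one
condition the mRNA pool of a gene is typically dominated by a single
transcript. `txdominance` is a pipeline for quantifying that structure from
RNA-seq isoform quantifications: given a GENCODE-style annotation, a
transcript-by-sample FPKM matrix and (optionally) exon/intron/junction count
tables, it

- builds the **study set** (protein-coding genes whose annotated transcripts
  are all ≥ 300 nt, so none would be lost to library size selection);
- computes **gene expression** as the mean FPKM of expressed exons,
  independently of the transcript quantifier;
- calls the **major transcript** per gene and sample (highest FPKM) and
  classifies **x-fold dominance** (major ≥ x · runner-up, x = 2 and 5 by
  default), with threshold sweeps and mRNA-pool mass fractions
  (mitochondrial genes excluded);
- measures **recurrence** of the major transcript across samples and detects
  **switch events**: gene G switches between transcripts I_k and I_l in
  samples S_i, S_j when expression(I_k)/expression(I_l) ≥ x in S_i and
  ≤ 1/x in S_j; a switch is **strong** when the dominant transcripts exceed
  5 FPKM in their samples while the reciprocal ones stay below 1 FPKM;
- validates major calls with **unique splice-junction read support** for
  genes whose transcripts are all junction-identifiable;
- classifies **non-coding majors** by biotype (retained intron, processed
  transcript, NMD) and measures the 3'-positional bias of retained introns;
- ships a **synthetic-data generator** with ground truth (dominant vs
  uniform Dirichlet abundance scenarios, log-normal gene expression, Poisson
  count noise, planted strong switches), so the whole pipeline runs and can
  be benchmarked with no downloads.

## Worked example

```sh
txdominance simulate -o demo_data --n-genes 200 --n-samples 4 \
    --planted-switches 5 --noiseless --seed 7
txdominance report --data-dir demo_data -o demo_out
python - <<'EOF'
import json
s = json.load(open("demo_out/summary.json"))
print("study-set genes:", s["n_genes_study_set"])
print("pool fraction of majors, S01:", round(s["pool_fractions"]["S01"]["major"], 4))
print("transcripts per gene, S01:", round(s["transcripts_per_gene"]["S01"], 3))
print("two-fold switch events:", s["switches"]["fold_2"]["n_events"])
print("junction agreement %:", s["junction_validation"]["pct_agreement"])
EOF
```

prints

```
study-set genes: 200
pool fraction of majors, S01: 0.8
transcripts per gene, S01: 2.865
two-fold switch events: 15
junction agreement %: 100.0
```

Reading the numbers: the generator's dominant scenario gives the designated
major transcript 80 % of each gene's mass, and the pipeline recovers a major
pool fraction of 0.80 exactly (the data are noiseless). Minor transcripts
hold only ~6.7 % of their gene's mass each, so at the 1 FPKM detection gate
an expressed gene shows ≈ 2.9 expressed transcripts on average rather than
all four. The 5 planted strong switches are found in the pairwise scan
(each also appears in weaker form against other sample pairs, hence 15
two-fold events), and junction-read evidence agrees with the
quantification-based major for every fully identifiable gene.

The same pipeline runs on real inputs by passing file paths instead of
`--data-dir` (see `txdominance report --help`): a GTF, a transcript FPKM
TSV, optional exon/intron/junction count TSVs with feature lengths, a
library-size table and sample metadata (condition, compartment, replicate).

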