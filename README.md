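# lincseek

Identification, positional classification and stress-response
characterization of long noncoding RNAs (lncRNAs) from assembled transcript
models, for a polyploid (two-subgenome) plant genome.

The package implements, as tested and reusable components:

- **`annio`** — GTF/FASTA/BED and tool-table (CPC, Pfam, rfam, RepeatMasker)
  readers/writers on a single 0-based half-open coordinate convention, plus
  an interval index used by all positional logic.
- **`lncfilter`** — the five-step filtration of assembled transcripts into
  high-confidence lncRNAs: length screen (≥ 200 nt), expression screen
  (FPKM ≥ 0.5 in ≥ 3 replicates of one condition), removal of same-strand
  mRNA isoform overlaps, a three-frame longest-ORF screen (< 300 nt), and a
  coding-potential decision combining CPC labels and Pfam hits
  (E ≤ 0.001) under a union rule, with an ORF-only fallback mode.
- **`lncclass`** — positional classes with fixed precedence
  (antisense: ≥ 1 bp opposite-strand exon–exon overlap; intronic: full
  containment in a gene span with zero exon overlap; else lincRNA),
  At/Dt/Un subgenome attribution, class/length/exon/ORF summaries and
  repeat-family overlap fractions.
- **`express`** — FPKM, Benjamini–Hochberg adjustment, a negative-binomial
  Wald-style differential-expression test (median-of-ratios normalization,
  moment dispersion shrunk toward a fitted trend), and multi-contrast
  response-pattern categorization (sustained / drought-specific / delayed,
  up and down) for the control → drought → re-watering design.
- **`targets`** — cis targets by 10 kb / 100 kb genomic windows, trans
  targets by Pearson correlation of log2(FPKM+1) profiles (|r| ≥ 0.9),
  intronic-lncRNA/host-gene call concordance, and the small-RNA precursor
  summary from rfam hits (E ≤ 1e-5, best hit per transcript).
- **`synthio`** — a seeded synthetic-data generator that plants ground truth
  for every stage (positional classes, coding flags, response patterns,
  co-expressed pairs, precursor families, repeat densities) and writes all
  pipeline input files; reruns are byte-identical.
- **`report`/`cli`** — an end-to-end driver with a YAML config, per-stage
  logging and a summary report (JSON/TSV/markdown) whose internal identities
  are re-asserted before rendering.

## CLI

```bash
# generate a synthetic dataset with planted truth
lincseek synth --seed 7 --out data/

# five-step identification
lincseek identify --gtf data/transcripts.gtf --ref-gtf data/ref.gtf \
    --fasta data/transcripts.fa --counts data/counts.tsv \
    --design data/design.csv --out out/

# positional classification + summaries
lincseek classify --lnc-gtf out/lncrna.gtf --ref-gtf data/ref.gtf \
    --repeats data/repeats.bed --out out/

# differential expression and response patterns
lincseek de --counts data/counts.tsv --design data/design.csv \
    --gtf data/transcripts.gtf --gtf data/ref.gtf --contrast D:C --out out/d_vs_c.tsv
lincseek patterns --res-a out/d_vs_c.tsv --res-b out/rew_vs_c.tsv --out out/patterns.tsv

# target prediction
lincseek targets --lnc-gtf out/lncrna.gtf --ref-gtf data/ref.gtf --out out/targets.tsv

# everything from one YAML config
lincseek all --config run.yaml
```

A minimal `run.yaml` lists the input paths plus `out_dir`; every threshold
has a documented default and unknown keys are rejected (see
`lincseek.report.RunConfig`).

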