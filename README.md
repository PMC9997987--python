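# methcap

Conversion-aware hybridization-capture bait design and methylation capture
evaluation, with seeded synthetic data so the whole toolkit is testable
offline.

Enzymatic/bisulfite conversion reads unmethylated cytosines as thymines, so
capture baits for methylation sequencing must match *post-conversion*
sequence space. methcap provides:

* **Bait design** (`methcap.bait_design`, `methcap.conversion`) — tile
  fixed-length baits (default 80 nt at 2x density) over target regions,
  enumerate the nine conversion-permutation sequences per candidate
  (original + {all methylated, two complementary random half-methylated
  splits, unmethylated} x {sense, antisense}), and filter on repeat-mask
  fraction (< 25%), GC content (10–80%) and cross-hit counts (<= 10).
* **Specificity screening** (`methcap.specificity`) — a deterministic
  seed-and-extend local-alignment search of every bait variant against the
  unmodified, all-C→T and all-G→A variants of each screening genome, with
  overlapping genome hits merged into single occurrences and a per-candidate
  maximum across all variant pairs. Exact-equivalent to an exhaustive
  Smith–Waterman scan on the fixtures in the test suite.
* **Capture evaluation** (`methcap.capture_eval`) — per-target coverage
  summaries, Bismark-coverage filtering (>= 5x, unique sites), region
  intersection, cross-callset CpG site matching, Pearson correlation,
  unweighted per-region mean methylation, paired t-tests, spike-in
  (unmethylated lambda / CpG-methylated pUC19) conversion reports, and
  random "promoter" region construction.
* **Synthetic data** (`methcap.simulate`) — seeded random genomes,
  promoter-like targets, Beta-regime methylation profiles, and
  Poisson-depth/Binomial-call coverage simulation with configurable
  conversion error and overconversion.
* **Formats** (`methcap.io_formats`) — FASTA (case preserved; lowercase =
  soft mask), BED3/BED6 (0-based half-open), Bismark coverage (1-based,
  counts authoritative), 7-column cytosine context reports, per-base depth
  TSV.

## CLI

One entry point, four subcommands; every run writes a JSON manifest
(parameters, seed, input checksums, version, timestamp). All randomness
derives hierarchically from a single `--seed`, so reruns are byte-identical.

```sh
# synthetic genome + targets + simulated methylation calls
methcap simulate --seed 7 --chrom-length 200000 --n-targets 22 \
    --genome-out g.fa --targets-out t.bed --cov-out a.cov \
    --report-out ctx.tsv --depth-out d.tsv

# tile, permute and filter baits
methcap design --genome g.fa --targets t.bed --seed 7 \
    --out-fasta baits.fa --out-bed baits.bed --report design.tsv

# screen baits against converted genome variants
methcap screen --baits baits.fa --genomes g.fa --report screen.tsv

# coverage/correlation/conversion QC of one or two callsets
methcap eval --cov a.cov --targets t.bed --depth d.tsv \
    --cytosine-report ctx.tsv --out-prefix eval
```

Each subcommand also accepts `--config cfg.yaml`; precedence is
CLI flag > YAML value > built-in default.

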