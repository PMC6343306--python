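# pybsmeth

An integrated bisulfite-sequencing (BS-Seq) toolkit in pure Python:

- **Alignment** — three-letter (C→T / G→A) converted-genome alignment with
  long-seed candidate search (75 bp, up to 5 mismatches + 1 gap, a gap
  costing the same as 1.5 mismatches), banded affine-gap extension
  (match +Q / mismatch −Q at the base's Phred value, gap open 40,
  gap extension 6), mismatch-gated indel detection, soft-clip
  realignment of long clipped tails, and deep-scan paired-end selection.
  Output is SAM with `NM`, `AS` and `XB` (bisulfite space) tags.
- **Methylation calling** — strand-aware per-cytosine pileup with the
  reverse-strand G/A correction (capped corrected ratio when reverse
  coverage ≥ 10, plain C/(C+T) otherwise, and a C→T SNP flag), CpG/CHG/CHH
  context assignment, per-site TSV tables and per-context bedGraph.
- **Region summaries** — sliding-window methylation (default 100 kb / 50 kb,
  per strand), gene meta-profiles (2 kb flanks + length-normalised body),
  the five-category level partition (M / Mh / H / hU / U), and feature
  annotation of cytosines/DMCs.
- **Differential methylation** — Fisher's exact test without replicates, a
  beta-binomial likelihood-ratio test with replicates, window validity
  criteria (≥ m valid sites per sample, each covered by ≥ n reads),
  Benjamini–Hochberg FDR, and significance at q < 0.05 with
  |meth.diff| ≥ 0.6.
- **Simulation + evaluation** — synthetic genomes, methylomes and BS reads
  (conversion, substitution errors capped at 2/read, indels) with full
  truth tables; alignment scoring by the position(±10 bp)/strand/mapq/
  indel-similarity criteria; paired concordance at the 500 bp criterion;
  RRBS in-silico MspI (C^CGG) digestion with 600 bp size selection.

## Command line

```sh
pybsmeth simulate --length 100000 --reads 5000 --seed 1 -o sim
pybsmeth index   -g sim.fa [--rrbs --site C-CGG --maxfrag 600] -o sim
pybsmeth align   -i sim -1 sim.fq [-2 sim_2.fq] [--no-indel] -o out.sam
pybsmeth calmeth -b out.sam -g sim.fa [--mindepth 5 --revcov 10] -o meth
pybsmeth methregion -m meth.meth.tsv -a genes.bed -o regiondir
pybsmeth dmr     -a cond1.meth.tsv -b cond2.meth.tsv [--dmc] -o dmrdir
pybsmeth evaluate --truth sim.truth.tsv --sam out.sam
pybsmeth report  --eval eval.json --meth meth.meth.tsv -o summary
```

All coordinates are 0-based half-open internally; SAM output is 1-based.
The index is persisted as a versioned JSON document
(`<prefix>.idx.json`).

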