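# svref

Structural-variant (SV) detection and false-positive filtering for short-read
paired-end (PE) libraries, built as a fully self-contained pipeline: it ships
its own PE sequencing simulator and synthetic benchmark builder, so every
stage — from rearranged-genome construction to the final high-confidence
call set — runs and is tested without any external data or aligner.

## What it does

- **`rearrange`** — applies an SV plan (deletions, inversions, tandem
  duplications, reciprocal translocations) to a reference FASTA, producing the
  derived genome, a truth set (BEDPE) and a derived→reference coordinate map.
  Germline retroelement and retrogene insertions (shared by tumor and control)
  are supported for false-positive modelling.
- **`simreads`** — simulates an FR paired-end library (chromosome choice
  proportional to length, Gaussian insert sizes, fixed read length), with
  optional perfect/imperfect PCR-duplicate injection, and emits truth
  alignments as SAM via the coordinate map — no aligner needed.  Mapping
  qualities come from a pluggable k-mer-uniqueness model (unique ⇒ 60,
  2 copies ⇒ 3, more ⇒ 0).
- **`tracks`** — per-position mappability from canonical k-mer occurrence
  counts; low-mappability regions as merged 50-bp windows with mean
  uniqueness < 0.5; a breakpoint-mappability metric (% of fully-unique 50-bp
  windows within 265 bp of a breakpoint).
- **`screen`** — pre-detection pair screening: signature classification
  (deletion / short-insert / inversion / translocation) against the library
  model with an 8-SD insert threshold, a both-mates MAPQ ≥ 23 filter, perfect
  (coordinate-identical) and imperfect (≤ 2 bp offset, same orientation,
  transitive) PCR-duplicate removal.
- **`call`** — union-find clustering of discordant pairs (same class,
  chromosomes and orientations, mates within `mean + 8·SD`); calls require
  ≥ 2 supporting pairs and ≥ 3 bp anchoring-region width on both sides.
- **`filter`** — the post-detection cascade with per-stage accounting:
  tumor/control comparison (type-agnostic, a single control pair suffices),
  low-mappability overlap (≥ 85% intra / ≥ 50% inter removes), simple-repeat
  overlap (≥ 50%), RepeatMasker overlap (≥ 80%, interchromosomal calls with
  2–3 pairs only), and size cutoffs (deletions < 600 bp, duplications
  < 300 bp removed).
- **`stats` / `power`** — library statistics (insert moments, MAPQ histogram,
  anomalous-pair categories, relative coverage) and a closed-form Poisson
  detection-probability model validated against the simulator.
- **`fixtures` / `run`** — seed-deterministic synthetic experiments,
  including a 20-SV benchmark (10 large deletions and 5 reciprocal
  translocation pairs across engineered breakpoint-mappability classes from
  10% to 100%), a germline-artifact demo and an imperfect-duplicate demo;
  `run` chains everything end to end.

## CLI quick start

```sh
svref fixtures --preset table1 --seed 7 --out exp/       # synthetic experiment
svref simreads --fasta exp/tumor.fa --ref-fasta exp/ref.fa \
    --liftover exp/tumor.liftover.tsv --n 200000 --seed 7 --out-prefix lib
svref screen --sam lib.truth.sam --out screened.tsv --stats stats.json
svref call --screened screened.tsv --out calls.bedpe
svref filter --calls calls.bedpe --lowmap exp/tracks/low_mappability.bed \
    --out kept.bedpe --report cascade.json

svref run --preset germline-demo --seed 7 --coverage 20 --out demo/   # all-in-one
svref config      # dump every threshold default as YAML
```

Exit codes: 0 ok, 1 usage error, 2 data error.

## Conventions

All internal coordinates are 0-based half-open; the only shift happens at the
SAM boundary.  Insert size means outer fragment span (leftmost read start to
rightmost read end).  Overlap and size cutoffs are inclusive.  All randomness
flows from explicit seeds; same seed, same bytes.
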