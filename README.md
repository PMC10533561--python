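# hybseq

A pipeline for sequencing antibody variable domains (V<sub>L</sub> and
V<sub>H</sub>) from mouse hybridoma cell lines at plate scale, and for
turning the curated sequences into recombinant-antibody reagents. It takes
barcoded paired-end amplicon FASTQ files and a sample sheet, and produces a
flat-file database of IMGT-annotated, replicate-scored variable-domain
sequences plus Gibson-Assembly-ready gene fragments for recombinant mAb
(R-mAb) and scFv expression constructs. A synthetic plate simulator with
full ground truth makes every stage testable without any external data.

It is intended for groups maintaining hybridoma collections who want
archival-quality V-region sequences — with an explicit, reproducible quality
score per sequence — rather than one-off Sanger reads.

## Pipeline

1. **Read processing** — inline-barcode demultiplexing (5-8 nt barcodes,
   longest match wins), chain assignment from the nested constant-region
   primer on R2, TSO/primer removal, N-read removal, 3' quality trimming
   (Phred < 10), overlap merging, and a 385 bp minimum-length filter.
2. **Denoising** — merged reads are collapsed into amplicon sequence
   variants (ASVs) by a greedy abundance-skew absorber (a variant at Hamming
   distance *d* from a parent is absorbed when its count ≤ 2^−(αd+1) of the
   parent's, α = 2); the aberrant Sp2/0 kappa transcript present in every
   hybridoma is removed by reference matching; ASVs below 10% of a sample's
   productive reads are dropped.
3. **Annotation** — translation, anchor-based IMGT numbering (light 1-127,
   heavy 1-128, lettered 111/112 insertions for long CDR3s), FR1-4/CDR1-3
   segmentation, validity filtering (intact FR1/FR4, start codon, no stops,
   no empty region) and trimming to exactly the IMGT span.
4. **Scoring** — each sequence gets a 0-5 star score:
   `TotalScore = 3·ln(MatchScore) + 2·ASV Score`, where
   `ASV Score = ReadPerSequence / ReadsPerPrimerWell` (up to 2 stars) and
   `MatchScore = (BR + 0.75·TR) − (1 − (BR+TR)/TotalSeqs)` summarises
   consistency across biological replicates (BR, other subclones of the same
   parent) and technical replicates (TR, other samples of the same
   subclone); the log term is clamped to [0, 3]. Sequences under 3 stars are
   filtered out; a per-parent census classifies cell lines by the number of
   distinct retained chains.
5. **Design** — curated V regions become synthesis-ready fragments: R-mAb
   V<sub>L</sub>/V<sub>H</sub> fragments with fixed 50 bp vector homology
   overhangs, and scFv inserts (leader−V<sub>H</sub>−linker−V<sub>L</sub>−
   HA−sortase−His6), screened for internal NotI/AscI/BssHII sites.

See `docs/methods.md` for the models, defaults and design decisions.

## Worked example

Simulate a small plate (2 parent hybridomas, 2 subclones each plus one
technical replicate, 100 read pairs per well per chain, 0.1% substitution
error, 30% aberrant-kappa contamination) and run the pipeline:

```
hybseq simulate --seed 1 --clones 2 --depth 100 --error-rate 0.001 --out plate
hybseq run --r1 plate_R1.fastq.gz --r2 plate_R2.fastq.gz \
           --sheet plate_sheet.tsv --out out
```

which prints the per-stage accounting:

```
curated sequences: 10
  total: 1200
  unassigned_barcode: 36
  ...
  merged: 1164
  asvs: 39
  aberrant_removed: 12
  below_fraction: 15
  curated: 12
  retained_after_score: 10
```

1200 read pairs went in; 36 were unassignable (an error in the barcode or
TSO), every merged read passed the length filter, 12 ASVs matched the
aberrant Sp2/0 kappa reference, and 15 low-support error ASVs fell under the
10% filter. The curated database (`out/db.tsv`) holds one row per sample ×
chain × sequence:

```
 mab_id chain  read_per_sequence  asv_score  br  tr  total_seqs  match_score  total_score
SIM/1.1 heavy                 97   1.000000   1   1           3     1.416667     3.044920
SIM/1.1 light                 66   1.000000   1   1           3     1.416667     3.044920
SIM/1.2 heavy                 96   0.979592   2   0           3     1.666667     3.491661
...
```

Sample `SIM/1.1` was sequenced three times (itself, a technical replicate,
and sibling subclone `SIM/1.2`), so its heavy chain has BR = 1, TR = 1,
TotalSeqs = 3, MatchScore = (1 + 0.75) − (1 − 2/3) ≈ 1.417, and a total of
3·ln(1.417) + 2·1.0 ≈ 3.04 stars — just above the 3-star cutoff, as expected
for a sequence seen consistently in every replicate but with few replicates.
`out/census.tsv` summarises the cohort (here: 2 parents, both with exactly
one V<sub>L</sub> and one V<sub>H</sub>).

Fragments for the top-scoring pair:

```
hybseq design rmab --db out/db.tsv --id SIM/1 --out frags.fa
hybseq search --query $(head -2 frags.fa | tail -1 | cut -c51-110) --db out/db.tsv
```

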