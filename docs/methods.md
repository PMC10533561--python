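# Methods

`hybseq` reconstructs antibody variable-domain (V<sub>L</sub>/V<sub>H</sub>)
sequences from plate-scale, barcoded paired-end amplicon sequencing of mouse
hybridoma samples, scores each sequence for read support and replicate
consistency, and turns curated sequences into Gibson-Assembly-ready gene
fragments. This note records the models, parameters and design decisions
behind each stage.

## Amplicon model

Each sequenced molecule is assumed to have the layout

    inline barcode (5-8 nt) | TSO | 5'UTR | leader | V region | constant stub

where the template-switching oligo (TSO) provides the universal forward
priming site, the constant-region stub ends at a nested chain-specific primer
(heavy, kappa or lambda), and the whole amplicon is 500-550 bp. Paired 300 bp
reads from both ends therefore overlap by at least 50 bp. The R2 read starts
at the nested primer, so its prefix identifies the chain; the R1 prefix
carries the well's inline barcode.

The TSO, UTR, leader, constant stubs and nested primers are assay reagents.
They are config values (`AssayConfig`, YAML-serialisable); the bundled
defaults are synthetic sequences constructed for testing, not any vendor's
proprietary oligos.

## Synthetic plates and what they do (and do not) emulate

The simulator builds clones on two synthetic consensus V scaffolds (one
light, one heavy) with fixed framework regions and per-clone randomized CDRs.
The scaffolds are mouse-*like* but are not real germlines, so the repository
ships no third-party database. Fixed scaffold features guarantee the four
conserved anchors (1st-CYS at IMGT 23, TRP 41, 2nd-CYS 104, J-region
[FW]GxG at 118); CDR residues are drawn from an alphabet excluding Cys, Trp,
Phe and Met so randomized loops cannot imitate an anchor.

Study conditions baked into the defaults:

- **depth** 200 read pairs per well per chain — enough that the abundance
  denoiser's error tails are well separated from true sequences at the
  default error rate;
- **error model** independent per-base substitutions per mate (default rate
  10<sup>-3</sup>), Phred qualities centred on −10·log₁₀(rate) with ±3
  seeded jitter; substitutions only by default, so ASV-level ground truth is
  exact (an optional indel rate exists for robustness tests);
- **aberrant contamination**: every light-chain pool contains reads from a
  bundled synthetic stand-in for the Sp2/0 (MOPC-21-derived) aberrant kappa
  transcript — a kappa-like V region frameshifted by a 4 nt deletion in FR3,
  hence non-productive — at a default fraction of 0.3;
- **replicate structure**: wells are laid out as
  `project/parent.subclone` samples, each parent getting two biological
  replicates (subclones) plus one technical replicate of the first subclone
  by default.

Not simulated: PCR chimeras, index hopping, lane-level artifacts, quality-
dependent error profiles, or between-well contamination. Passing the
end-to-end tests therefore demonstrates correctness of the pipeline's logic
under a clean substitution-error model, not robustness to every failure mode
of real flow cells.

## Read processing

Demultiplexing matches barcodes exactly (0 mismatches) by default: inline
barcodes are short and staggered, and mismatch tolerance risks collisions;
the longest matching barcode wins when barcodes nest, and equal-length
double matches are counted unassigned. The TSO must then be found by exact
match within 20 nt of the barcode end — a cheap guard against barcode false
positives. Nested-primer matching on R2 allows 1 mismatch. All three are
configurable.

Cleaning follows the order: chain assignment and primer removal, N-containing
read removal, 3'-end quality trimming (removing the maximal trailing run of
bases below Phred 10 — a run-based trimmer; windowed trimming would also be
defensible, but the run-based rule is simplest and is what the tests pin
down), then overlap merging. Merging scans all offsets for the one
maximizing matched bases, requiring ≥ 20 nt overlap and ≤ 10% mismatches
(the true overlap in this assay is ≥ 50 nt, so these defaults are
conservative). Disagreeing overlap positions take the higher-quality base;
agreeing positions get quality min(q1+q2, 41), a common consensus
convention. Merged sequences shorter than 385 nt are discarded. Per-stage
counters partition the input exactly.

## ASV denoising

A full parametric error-model denoiser is out of scope; the implementation
is a greedy abundance-skew absorber in the UNOISE style. Unique sequences
are visited in decreasing abundance (ties broken lexicographically, making
the result independent of read order); a sequence at Hamming distance *d* ≤ 4
from an accepted ASV is absorbed when its count is ≤ 2^−(α·d+1) of the
parent's current count (α = 2). Counts are conserved. The contract tested is
that true sequences are recovered and error reads absorbed on wells with ≤ 3
true sequences, ≤ 500 reads and substitution rates ≤ 0.005.

Aberrant-kappa removal flags light-chain ASVs whose identity to the
configured aberrant reference is ≥ 0.97 over the shorter sequence (edlib
infix alignment) with a length ratio ≥ 0.90; heavy-chain ASVs are never
flagged. The matching thresholds are configurable because no published
criterion exists for this step. Aberrant ASVs are removed *before* the
read-support filter, so within-sample fractions renormalize over productive
reads only; the ≥ 10% filter then retains ASVs at fraction ≥ 0.10 of the
remaining total (the boundary value 0.10 is retained).

## Annotation

ANARCI-style germline-HMM numbering is replaced by anchor-motif detection
plus the IMGT gap/insertion rules. Anchors are located backwards from the
3'-most J motif ([FW]GxG): FR3 has a fixed 39-residue span, which places the
2nd-CYS; windows derived from the allowed CDR slot counts (CDR1 ≤ 12,
CDR2 ≤ 10) locate TRP-41 and the 1st-CYS, with candidate ties resolved by a
small residue profile (Y-x-C context for the cysteines, typical CDR lengths
per locus). Short CDRs are numbered from both ends of their slot ranges,
leaving IMGT's middle gaps; CDR3 loops longer than 13 residues get lettered
insertions at 111/112, first on the 112 side (112A, then 111A, 112B, ...).
Kappa and lambda both map to the generic light numbering (1-127); heavy ends
at 128.

Validity requires: no zero-length FR/CDR, IMGT positions 1-10 and the last
10 FR4 positions all present, an ATG-encoded Met upstream of position 1, and
no stop codon from that Met through FR4. Trimming extracts exactly the
codons of the IMGT span; entries with identical trimmed nucleotides are
grouped additively (an amino-acid-level grouping option exists, since edge
trimming artifacts can produce nucleotide variants with identical protein
predictions).

On heavily mutated frameworks the anchor method and a germline HMM can
disagree; the acceptance surface here is the simulator's ground truth and
the explicit validity rules, not bit-compatibility with any external tool.

## Scoring

For each sample × chain × trimmed sequence:

    ASV Score  = ReadPerSequence / ReadsPerPrimerWell
    MatchScore = (BR + 0.75·TR) − (1 − (BR + TR)/TotalSeqs)
    TotalScore = 3·ln(MatchScore) + 2·ASV Score

BR/TR count *other* samples (the focal sample is excluded; configurable) of
the same parent containing the identical trimmed sequence, in a different /
the same subclone respectively. `TotalSeqs` is read as the number of
sequenced samples in the parent group for that chain, making
(BR+TR)/TotalSeqs a detection fraction ≤ 1; an alternative reading (total
distinct sequences in the group) is available behind
`AssayConfig.totalseqs_mode` since the defining text supports either.

`3·ln(MatchScore)` is unbounded above and undefined for MatchScore ≤ 0, while
the scheme's stated component maxima are 3 and 2 stars. The match component
is therefore clamped to [0, 3], with MatchScore ≤ 1 contributing 0; this
reproduces the documented 0-5 star range exactly and is verified analytically
and by grid search in the tests. Entries below 3.0 stars are filtered out.

Per-parent chain multiplicity is the mean number of distinct retained
sequences per sample, rounded to the nearest integer with halves away from
zero (the rounding direction for halves is not specified anywhere; away-from-
zero matches the everyday convention). The census classifies parents by
(n<sub>VL</sub>, n<sub>VH</sub>) multiplicities into the standard categories
(no additional chain, one additional V_L only, etc.), with optional
stratification by a categorical covariate such as fusion method.

## Fragment design

R-mAb V fragments are `overhang + trimmed V + overhang` with the four fixed
50 bp homology arms emitted verbatim (golden-file tested). Inserts are
screened for internal NotI/AscI/BssHII sites, which would break the
restriction-based subclass-switching route; `subclass_switch_check` verifies
a plasmid map has exactly one NotI and one BssHII site flanking the
V_L-joining-V_H cassette and reports the excised length.

scFv inserts encode leader − V_H − linker − V_L − HA − sortase − 6xHis − stop
(orientation swappable). Leader (MGWSCIILFLVATATGVHS) and linker
(GGGGSGGGGSGGGGSGGGS) are fixed; the tag protein sequences are canonical
motifs (YPYDVPDYA, LPETGG, HHHHHH) supplied as defaults because the exact
tag DNA is construct-specific — they are flagged as assumptions and
config-overridable, and tags are concatenated directly without junction
residues. Reverse translation uses a fixed one-high-usage-mouse-codon-per-
residue table (CpG-poor, so designed fragments do not acquire NotI/AscI/
BssHII sites spuriously); there is no codon optimization or synthesis-
constraint screening. scFv vector homology arms are required config inputs
with synthetic test defaults.

## Sequence search

`kmer_search` is a seed-and-extend similarity query over the flat-file
database: shared k-mers (default k = 11 nt / 4 aa) seed diagonals, each
diagonal is scored ungapped over the full mutual overlap, and hits are
ranked by identity then span. It is a convenience for querying the database,
not a BLAT port (no gapped or translated search).

## Problem sizes and numerics

The test suite runs plates of 12-96 wells at depths 30-400; the acceptance
script uses a 6-clone, 18-well error-free plate for its end-to-end check and
a 26 620-point grid (BR, TR ∈ 0..10, TotalSeqs ∈ 1..20, fraction ∈
{0, 0.1, ..., 1}) for the score maxima. All randomness flows from explicit
seeds through `numpy.random.default_rng`; pipeline stages themselves are
seed-free and deterministic, with all ties broken lexicographically.

## Known limitations

- The denoiser needs parent counts of roughly ≥ 8 clean reads to absorb
  singleton error reads at distance 1; very shallow wells (depth ≲ 60 at
  error rates ≳ 0.003) can fall below the 10% filter. Real runs at typical
  plate depths are far from this regime.
- Anchor-based numbering assumes the four conserved anchors are present;
  V domains with substitutions *at* an anchor position are rejected rather
  than rescued by profile alignment.
- The aberrant-transcript filter is reference-based; a well contaminated by
  a productive kappa from another well would not be flagged.
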