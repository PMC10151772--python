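# Methods

## Problem and model

A clonal plasma-cell population transcribes one rearranged light-chain gene at
very high level, so in bulk RNA-seq of CD138-enriched marrow the clonal
IGV<sub>L</sub>–IGJ<sub>L</sub> sequence dominates the IGK/IGL clonotype
repertoire. `clonelc` models the downstream decision problem: given a
sample's assembled clonotypes with read counts, decide whether a single clonal
light-chain sequence exists, reconstruct it as completely as possible, and
check it against the germline repertoire and serum free-light-chain (FLC)
chemistry.

All clone fractions are computed over **combined IGK+IGL counts**. This is a
deliberate choice over per-locus denominators: the clonality question is "does
one light-chain clone dominate the sample's light-chain output", and a clone
dominating its own locus but not the light-chain pool (e.g. a strong IGK clone
with equally strong IGL background) should not be called clonal. Counts, not
input reads, are the unit throughout; subcluster ("children") counts are
assumed already folded into each clone's count by the upstream assembler.

## Clonality classification

Evaluation order and thresholds (config keys in parentheses, comparisons match
the printed inequality conventions):

1. major fraction ≥ 0.95 (`cat1_min_fraction`, inclusive) → **Category 1**;
2. else if major fraction > 0.50 (`major_min_fraction`, strict) and an
   eligible same-locus secondary exists (count ≥ 100 inclusive,
   `merge_secondary_min_count`; share > 1 % strict,
   `merge_secondary_min_share`) and the merge succeeds with merged fraction
   ≥ 0.95 → **Category 2**;
3. else if major fraction > 0.50 and the second-largest LC clone's fraction
   < 0.05 (`cat3_max_second`, strict) → **Category 3**;
4. else **Category 4**, with `biclonal_flag` when the top two LC clones have
   distinct CDR3s and each fraction > 0.10 (`biclonal_min_share`, strict).

The merge is attempted *before* the Category 3 test even when the secondary is
below 5 %, because a successful merge recovers a longer sequence — the point
of the merge step; a merge-eligible pair that fails any merge criterion falls
through to the Category 3/4 tests. Samples with no IGK/IGL clones are
Category 4 with `no_clone_flag`. Ties in major-clone selection (equal counts)
break toward the longer longest fragment, then the lexicographically smaller
concatenated sequence, making classification invariant to input order.

A `low_support_flag` (advisory, default threshold 1 000 counts,
`low_support_count`) marks samples whose major clone is so weakly supported
that re-running on ~10× more input reads is recommended. The default sits an
order of magnitude below typically well-supported clones (≥ 10 000 counts)
and an order above the clearly failed regime (tens of counts).

## Identical-clone merge

Assemblers sometimes split one clone into two overlapping clonotypes (reads
seeded on distinct but similar germline genes). Two clones are collapsed only
when their longest fragments share an **ungapped** overlap of ≥ 200 nt
(`merge_min_overlap`) with **zero** mismatches (N counts as a mismatch —
strict identity), the overlap contains the **full CDR3 of both clones**, and
the combined counts reach ≥ 95 % of LC counts
(`merge_min_combined_fraction`). Each failed criterion produces a distinct
refusal reason (`short_overlap`, `mismatch`, `no_cdr3_in_overlap`,
`insufficient_combined_fraction`) for diagnostics.

The overlap search scores every relative placement of the two sequences as
matches − mismatches, taking the best score with ties to the longer overlap
and then the smaller offset. This returns the clean suffix–prefix or
containment overlap when one exists (with its mismatch count, so a
single-substitution near-miss is reported as such rather than hidden), and
degenerates to short chance runs for unrelated sequences; placements shorter
than 16 nt (`min_reportable_overlap`) are reported as "no overlap". Gapped
overlaps are deliberately out of scope: the acceptance rule demands 100 %
identity, so a gap could only ever produce a refusal. Merging is symmetric in
sequence content: swapping the two clones yields the same merged sequence.

## Germline assignment, CDR3, coverage, translation

V, J and C genes are assigned by best-hit **local alignment** (Biopython
`PairwiseAligner`; match +1, mismatch −2, first gap position −4, each further
−1; all configurable). The V call requires ≥ 100 aligned nt at ≥ 85 %
identity, below which the clone is reported unassigned; the J gene is searched
3′ of the V span (≥ 12 nt, ≥ 80 %) and the C gene 3′ of the J span (≥ 20 nt,
≥ 85 %). Score ties break by gene name, keeping calls deterministic. Running
alignments in-process against a user-supplied germline FASTA keeps the tool
free of network services and external aligner binaries.

CDR3 follows the IMGT anchor convention, here taken from the 2nd-CYS codon
through the codon preceding the J F/W-G-X-G anchor: both anchors are germline
offsets (declared in the FASTA header as `cys104=`/`jmotif=` or inferred — V:
last in-frame TGT/TGC within the 3′ 40 nt; J: first F/W-G-X-G codon match)
mapped onto the clone through the alignments, so junctional insertions are
included. A cysteine codon mutated away from TGT/TGC yields a missing,
flagged CDR3; the clone remains classifiable by counts.

Coverage is **complete** iff the V alignment starts at germline V position 0
and the J alignment reaches the final J nucleotide — the same two reference
points used to display clone coverage, tolerant of the 3′ V trimming inherent
to rearrangement. Translation uses the V germline reading frame anchored at
the V span start, drops any trailing partial codon, and reports
`productive=False` when an in-frame stop precedes the J anchor (stops 3′ of
the anchor, e.g. in a partially covered constant region, do not matter).
Coordinates are 0-based half-open internally; human-readable outputs print
sequences, not coordinates.

## Clinical concordance

κ/λ FLC ratio thresholds are strict (> 1.65 → kappa, < 0.26 → lambda;
boundary values are normal — the convention chosen here since boundary
behavior is otherwise unspecified). λ = 0 with measurable κ gives an infinite
ratio (kappa). An abnormal FLC ratio takes precedence over M-protein data;
normal-ratio or FLC-missing cases fall back to the M-protein light-chain type;
cases with neither are *indeterminate* and excluded from the concordance
percentage (missing values are never coerced to zero anywhere in the
parsers). A case whose FLC ratio contradicts the clone is counted discordant
even when the M-protein type matches the clone; the M-protein match is
annotated separately (`mprotein_matches_clone`).

## Synthetic data: what it emulates and what it does not

Germline genes are random stop-free codon sequences with planted anchors —
redistribution-safe stand-ins for licensed reference repertoires (a loader for
real IMGT-style FASTA is the same code path). V genes (294–300 nt) are
rejection-sampled to ≤ 90 % pairwise identity so best-hit assignment is
well-posed; J genes (18–27 nt) carry the F/W-G-X-G motif; C stubs are 99 nt.

A rearrangement is leader + V[0:cys+3] + junction (0–12 nt, multiples of 3 by
default so products are in frame) + J[anchor−3:] + C-prefix. The random
5′UTR/leader (170 nt) puts default full length near 606 nt, matching typical
full-length clones that begin upstream of the coding region. Substitutions at
`mutation_rate` (default 0.01 per nt in cohort simulation) model somatic
hypermutation over the V..J region, sparing ~6 nt guards around the two CDR3
anchors so planted truth remains well-defined.

Samples plant the four categories exactly: category 1 draws the clonal
fraction from U(0.955, 0.99); category 2 emits the true clone as two
fragments with an exact 254 nt CDR3-spanning overlap (the split point keeps
≥ 110 nt of V on the 3′ fragment so it remains germline-callable), counts
split ~60/38 so the secondary passes eligibility; category 3 draws the major
from U(0.60, 0.88) with background capped strictly below 5 %; category 4
plants two distinct-CDR3 clones at ~0.45/0.15–0.35. Polyclonal background
counts are Dirichlet-distributed (α = 3) over ~12 clones, plus a small IGH
component (10–20 % of LC counts) so total-Ig fractions are exercised; default
LC depth is 124 000 counts, a typical per-sample assignment. Clinical records
are generated concordant (serum values drawn so the ratio is clearly
restricted) unless discordance is requested.

Not emulated: assembler chimeras and sequencing error in fragments, realistic
expression-level variation, germline allelic variation, gapped indel SHM, and
read-level transcriptome structure. Passing recovery tests therefore
demonstrates the correctness of the decision logic and sequence operations
under the stated statistical structure, not robustness to assembler artifacts.

## Numerical and degenerate-input choices

* LC fractions sum to 1 within 1e-12 whenever LC counts exist; a zero-LC
  sample is a flagged condition, not an exception.
* All generators and the FASTQ downsampler are byte-deterministic per seed
  (NumPy `default_rng`); downsampling is per read pair, uniform without
  replacement, preserving original pair order.
* Empty input files parse to empty collections; empty curated sets write
  header-only tables and empty FASTA.
* Problem sizes in the test and acceptance runs (200-sample cohorts, 100
  merge seeds, 200 germline clones, 50 round-trip fixtures) were chosen as the
  smallest sizes at which the binomial uncertainty of each recovery rate is
  well inside the asserted bounds.

## Known limitations

* Full-length constant-region recovery is out of scope; only a C-gene hit and
  span are reported.
* The ungapped overlap criterion reproduces the merge acceptance rules but
  not any particular aligner's intermediate alignments.
* Coverage on heavily mutated termini can read "partial" because local
  alignment clips terminal mismatches.
* Heavy-chain (IGH) clones participate only in count accounting; no VDJ
  junction analysis is performed.
* Amyloidogenicity prediction and subclonal phylogeny are non-goals.
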