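# clonelc

Identification of a patient's clonal immunoglobulin **light-chain (IGV<sub>L</sub>–IGJ<sub>L</sub>) sequence** from untargeted RNA-seq of plasma-cell samples.

In plasma cell dyscrasias (multiple myeloma, AL amyloidosis, MGUS) the malignant
plasma-cell clone secretes a single rearranged light chain, and its sequence —
particularly CDR3 and the framework positions diversified by somatic
hypermutation — is patient-specific. `clonelc` starts from **clonotype tables**
(clone id, locus, read counts, assembled nucleotide fragments, as produced by a
MiXCR-style *assemble shotgun* run on a few million reads) and carries out the
downstream analysis needed to call one curated clonal sequence per sample:

1. **Count accounting** — per-locus (IGK/IGL/IGH) totals; clone fractions use
   combined IGK+IGL ("LC") counts as denominator, with subcluster ("children")
   counts already folded into each clone's count.
2. **Clonality categories** — each sample lands in exactly one of four classes:
   * **Category 1** — one clone holds ≥ 95 % of LC counts;
   * **Category 2** — two clones, identical over an ungapped overlap of
     ≥ 200 nt with **zero** mismatches that contains both CDR3s, together hold
     ≥ 95 %; they are merged into one longer sequence;
   * **Category 3** — the major clone holds > 50 % and the runner-up < 5 %;
   * **Category 4** — everything else, flagged *biclonal* when two
     distinct-CDR3 clones each hold > 10 %.
3. **Germline assignment** — best-hit Smith–Waterman local alignment against a
   germline V/J/C repertoire (match +1, mismatch −2, gap −4/−1); CDR3 runs from
   the V 2nd-CYS codon to the codon preceding the J F/W-G-X-G anchor (IMGT
   convention); coverage is *complete* when the clone reaches V position 0 and
   the last J nucleotide.
4. **Clinical concordance** — the serum free-light-chain ratio κ/λ is compared
   to the reference range 0.26–1.65 (> 1.65 → κ-restricted, < 0.26 →
   λ-restricted), with M-protein light-chain type as fallback for
   normal-ratio cases, and matched against the clone's locus.
5. **Cohort validation** — cross-sample exact-match uniqueness at nucleotide
   and protein level, shared-CDR3 groups with difference counts outside CDR3,
   and the category × locus summary table.

A first-class **synthetic-data generator** produces germline repertoires,
rearrangements, whole clonotype tables, clinical records and FASTQ fixtures
with complete ground truth, so every step is testable without access-restricted
patient data. A seeded **paired-FASTQ downsampler** supports the
fixed-read-budget (e.g. 5 M pairs) entry point of the workflow.

## Worked example

```bash
clonelc simulate --n 8 --seed 7 --mix 0.5,0.25,0.125,0.125 --out-dir demo/sim
clonelc analyze --clonotypes demo/sim/clonotypes.tsv \
                --germline  demo/sim/germline.fasta \
                --clinical  demo/sim/clinical.csv \
                --out-dir   demo/out
```

prints

```
wrote 8 simulated samples to demo/sim
analyzed 8 samples; 7 curated clones; outputs in demo/out
concordance: 8/8 (100.0%) of evaluable samples
```

`demo/out/curated_summary.tsv` then holds one row per curated (category 1–3)
clone — the category-4 sample is reported in the category table but not
curated:

```
sample_id  locus  v_gene    j_gene  c_gene  category  clone_fraction  coverage  concordance  cdr3_nt       cdr3_aa ...
SIM0000    IGK    IGKV1-2   IGKJ2   IGKC    1         0.9665          complete  concordant   TGCGTAGCCACG  CVAT
SIM0002    IGL    IGLV2-13  IGLJ1   IGLC1   3         0.7718          complete  concordant   TGCGCAGCAGAC  CAAD
...
```

`clone_fraction` is the share of IGK+IGL counts on the major clone (post-merge
for category 2), `coverage` says whether the sequence spans the full V–J
region, and `concordance` records the match between clone locus and serum FLC
restriction. `curated_nt.fasta` / `curated_aa.fasta` carry the sequences with
`sample|locus|V|J|category|coverage` headers.

Using real MiXCR `exportClones` output only needs a thin column mapping to the
input TSV dialect: `sample_id`, `clone_id`, `locus` (IGK/IGL/IGH), `count`
(cluster total including children), `fragments` (comma-joined targetSequences),
plus optional `v_hint`/`j_hint`/`c_hint`/`cdr3_nt`.

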