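"""Cross-sample uniqueness checks and cohort-level summaries.

Each curated clone sequence is compared with every other by exact text
matching (case-insensitive; N is not a wildcard) at the nucleotide and
protein level, and clones sharing a CDR3 nucleotide sequence while differing
elsewhere are reported with per-pair difference counts outside CDR3. The
category × locus summary mirrors the cohort table of a clonality study:
counts per category per locus, complete-coverage counts alongside, and the
categories 1–3 total as "samples with a single major clone".
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Optional, Sequence

import pandas as pd
from Bio import Align

from .io_formats import LC_LOCI, CuratedRecord


@dataclass
class SharedCdr3Group:
    cdr3_nt: str
    sample_ids: list[str]
    # (sample_a, sample_b) -> count of differing alignment columns outside CDR3
    pair_differences: dict[tuple[str, str], int]


@dataclass
class DuplicateReport:
    nt_duplicate_groups: list[list[str]]
    aa_duplicate_groups: list[list[str]]
    shared_cdr3_groups: list[SharedCdr3Group]


def _groups_by(records: Sequence[CuratedRecord], key) -> list[list[str]]:
    buckets: dict[str, list[str]] = defaultdict(list)
    for r in records:
        k = key(r)
        if k:
            buckets[k.upper()].append(r.sample_id)
    return [ids for _, ids in sorted(buckets.items()) if len(ids) >= 2]


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _cdr3_interval(rec: CuratedRecord) -> Optional[tuple[int, int]]:
    if rec.cdr3_span is not None:
        return rec.cdr3_span
    if rec.cdr3_nt:
        pos = rec.sequence_nt.upper().find(rec.cdr3_nt.upper())
        if pos >= 0:
            return pos, pos + len(rec.cdr3_nt)
    return None


def count_differences_outside_cdr3(rec_a: CuratedRecord, rec_b: CuratedRecord) -> int:
    """Differing columns of a global alignment outside either clone's CDR3.

    A column differs when its two characters mismatch or one is a gap; it is
    counted only when its position on each sequence lies outside that
    sequence's CDR3 interval.
    """
    a = rec_a.sequence_nt.upper()
    b = rec_b.sequence_nt.upper()
    span_a = _cdr3_interval(rec_a) or (len(a), len(a))
    span_b = _cdr3_interval(rec_b) or (len(b), len(b))
    aln = _global_aligner().align(a, b)[0]
    diffs = 0
    ia = ib = 0
    col_a, col_b = aln[0], aln[1]
    for ca, cb in zip(col_a, col_b):
        pos_a, pos_b = ia, ib
        if ca != "-":
            ia += 1
        if cb != "-":
            ib += 1
        if ca == cb:
            continue
        in_a = ca != "-" and span_a[0] <= pos_a < span_a[1]
        in_b = cb != "-" and span_b[0] <= pos_b < span_b[1]
        if not (in_a or in_b):
            diffs += 1
    return diffs


def find_duplicates(records: Sequence[CuratedRecord]) -> DuplicateReport:
    """Exact-match duplicate groups and shared-CDR3 (but distinct) groups.

    Shared-CDR3 groups collect clones with an identical CDR3 nucleotide
    sequence whose full sequences are not all identical; pairs of
    byte-identical sequences belong to the nucleotide duplicate groups and
    are excluded from the pairwise difference annotation.
    """
    nt_groups = _groups_by(records, lambda r: r.sequence_nt)
    aa_groups = _groups_by(records, lambda r: r.sequence_aa)

    shared: list[SharedCdr3Group] = []
    by_cdr3: dict[str, list[CuratedRecord]] = defaultdict(list)
    for r in records:
        if r.cdr3_nt:
            by_cdr3[r.cdr3_nt.upper()].append(r)
    for cdr3, members in sorted(by_cdr3.items()):
        if len(members) < 2:
            continue
        distinct = {m.sequence_nt.upper() for m in members}
        if len(distinct) < 2:
            continue  # all identical: covered by nt duplicate groups
        pair_diffs: dict[tuple[str, str], int] = {}
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ma, mb = members[i], members[j]
                if ma.sequence_nt.upper() == mb.sequence_nt.upper():
                    continue
                pair_diffs[(ma.sample_id, mb.sample_id)] = \
                    count_differences_outside_cdr3(ma, mb)
        shared.append(SharedCdr3Group(
            cdr3_nt=cdr3,
            sample_ids=[m.sample_id for m in members],
            pair_differences=pair_diffs,
        ))
    return DuplicateReport(nt_duplicate_groups=nt_groups,
                           aa_duplicate_groups=aa_groups,
                           shared_cdr3_groups=shared)


@dataclass
class CohortSummary:
    """Category × locus clone counts; complete-coverage counts in parallel."""

    counts: dict[int, dict[str, int]]            # category -> locus -> n
    complete_counts: dict[int, dict[str, int]]   # category -> locus -> n complete coverage
    n_samples: int
    single_major_total: int                      # categories 1-3

    def category_total(self, category: int) -> int:
        return sum(self.counts[category].values())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cat in (1, 2, 3, 4):
            row = {"category": cat}
            for locus in LC_LOCI:
                row[locus] = self.counts[cat][locus]
                row[f"{locus}_complete"] = self.complete_counts[cat][locus]
            row["unassigned"] = self.counts[cat]["unassigned"]
            row["total"] = self.category_total(cat)
            rows.append(row)
        return pd.DataFrame(rows).set_index("category")


def cohort_summary(
    assignments: Sequence[tuple[int, Optional[str]]],
    coverages: Optional[Sequence[Optional[str]]] = None,
) -> CohortSummary:
    """Tabulate category × locus counts over a cohort.

    ``assignments`` holds one ``(category, locus)`` pair per sample (locus
    None when no clone could be assigned); ``coverages`` the matching
    "complete"/"partial"/None coverage calls.
    """
    if coverages is None:
        coverages = [None] * len(assignments)
    counts = {cat: {"IGK": 0, "IGL": 0, "unassigned": 0} for cat in (1, 2, 3, 4)}
    complete = {cat: {"IGK": 0, "IGL": 0} for cat in (1, 2, 3, 4)}
    for (cat, locus), cov in zip(assignments, coverages):
        key = locus if locus in LC_LOCI else "unassigned"
        counts[cat][key] += 1
        if key in LC_LOCI and cov == "complete":
            complete[cat][key] += 1
    single_major = sum(sum(counts[c].values()) for c in (1, 2, 3))
    return CohortSummary(counts=counts, complete_counts=complete,
                         n_samples=len(assignments), single_major_total=single_major)
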