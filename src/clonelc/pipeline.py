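"""End-to-end per-sample and cohort analysis.

Ties the modules together in pipeline order: count accounting → major-clone
selection → category assignment (with the identical-clone merge) → germline
V/J/C assignment, CDR3, coverage and translation → clinical concordance →
curated records and cohort-level validation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

from .clinical_concordance import (
    ConcordanceResult,
    ConcordanceSummary,
    cohort_concordance_summary,
    concordance,
)
from .clonal_analysis import (
    CategoryAssignment,
    ClonotypeTable,
    FractionReport,
    build_table,
    compute_fractions,
    assign_category,
    flag_low_support,
)
from .cohort_validation import CohortSummary, DuplicateReport, cohort_summary, find_duplicates
from .config import DEFAULT_CONFIG, AnalysisConfig
from .io_formats import (
    ClinicalRecordRow,
    ClonotypeRecordRow,
    CuratedRecord,
    GermlineRepertoire,
)
from .sequence_ops import (
    GermlineAssignment,
    assign_germline,
    attempt_merge,
    longest_fragment,
)

logger = logging.getLogger("clonelc")


@dataclass
class SampleResult:
    sample_id: str
    table: ClonotypeTable
    fractions: FractionReport
    assignment: CategoryAssignment
    final_sequence: Optional[str]
    germline: Optional[GermlineAssignment]
    concordance: Optional[ConcordanceResult]
    curated: Optional[CuratedRecord]


def analyze_sample(
    sample_id: str,
    rows: Sequence[ClonotypeRecordRow],
    repertoire: GermlineRepertoire,
    clinical: Optional[ClinicalRecordRow] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> SampleResult:
    """Run the full light-chain pipeline on one sample's clonotype rows.

    Produces a curated record only for categories 1-3 with a successful
    germline assignment, mirroring the deposition rule for single-major-clone
    samples.
    """
    table = build_table(sample_id, rows)
    fractions = compute_fractions(table)

    span_cache: dict[str, Optional[tuple[int, int]]] = {}

    def cdr3_locator(seq: str) -> Optional[tuple[int, int]]:
        if seq not in span_cache:
            ga = assign_germline(seq, repertoire, config=config)
            span_cache[seq] = ga.cdr3_span if ga is not None else None
        return span_cache[seq]

    def merge_attempt(major, secondary, tbl):
        return attempt_merge(major, secondary, tbl, cdr3_locator=cdr3_locator, config=config)

    assignment = assign_category(table, merge_attempt, cdr3_locator=cdr3_locator, config=config)
    assignment = flag_low_support(assignment, config=config)

    final_seq: Optional[str] = None
    if assignment.merged and assignment.merge_result is not None:
        final_seq = assignment.merge_result.merged_sequence
    elif assignment.major_clone is not None:
        final_seq = longest_fragment(assignment.major_clone)

    germline = None
    if final_seq is not None:
        germline = assign_germline(final_seq, repertoire, config=config)

    clone_locus = assignment.major_clone.locus if assignment.major_clone else None
    conc = concordance(clone_locus, clinical, config) if clinical is not None else None

    curated = None
    if assignment.category in (1, 2, 3) and germline is not None and final_seq is not None:
        curated = CuratedRecord(
            sample_id=sample_id,
            locus=clone_locus or "",
            sequence_nt=final_seq,
            sequence_aa=germline.protein,
            v_gene=germline.v_gene,
            j_gene=germline.j_gene,
            c_gene=germline.c_gene,
            category=assignment.category,
            clone_fraction=assignment.major_fraction,
            coverage=germline.coverage,
            cdr3_nt=germline.cdr3_nt,
            cdr3_aa=germline.cdr3_aa,
            cdr3_span=germline.cdr3_span,
            productive=germline.productive,
            concordance_status=conc.status if conc else None,
            amyloidosis=clinical.amyloidosis if clinical else None,
        )

    logger.info(
        "sample %s: category %d%s, major fraction %s, %s",
        sample_id, assignment.category,
        " (merged)" if assignment.merged else "",
        f"{assignment.major_fraction:.3f}" if assignment.major_fraction is not None else "NA",
        f"V={germline.v_gene} J={germline.j_gene}" if germline else "no germline call",
    )
    return SampleResult(
        sample_id=sample_id, table=table, fractions=fractions,
        assignment=assignment, final_sequence=final_seq, germline=germline,
        concordance=conc, curated=curated,
    )


@dataclass
class CohortResult:
    results: list[SampleResult]
    summary: CohortSummary
    duplicates: DuplicateReport
    concordance_summary: Optional[ConcordanceSummary]

    @property
    def curated(self) -> list[CuratedRecord]:
        return [r.curated for r in self.results if r.curated is not None]


def analyze_cohort(
    tables: dict[str, list[ClonotypeRecordRow]],
    repertoire: GermlineRepertoire,
    clinical: Optional[Sequence[ClinicalRecordRow]] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> CohortResult:
    """Analyze every sample, then run cohort-level validation and summaries."""
    clinical_by_id = {c.sample_id: c for c in clinical} if clinical else {}
    results = [
        analyze_sample(sid, rows, repertoire, clinical_by_id.get(sid), config)
        for sid, rows in tables.items()
    ]
    assignments = [
        (r.assignment.category,
         r.assignment.major_clone.locus if r.assignment.major_clone else None)
        for r in results
    ]
    coverages = [r.germline.coverage if r.germline else None for r in results]
    summary = cohort_summary(assignments, coverages)
    curated = [r.curated for r in results if r.curated is not None]
    duplicates = find_duplicates(curated)
    conc_results = [r.concordance for r in results if r.concordance is not None]
    conc_summary = cohort_concordance_summary(conc_results) if conc_results else None
    return CohortResult(results=results, summary=summary, duplicates=duplicates,
                        concordance_summary=conc_summary)
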