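"""Per-sample count accounting and clonality classification.

A sample's clonotype rows are folded into a :class:`ClonotypeTable` with
per-locus totals; the clone with the most light-chain (IGK+IGL) counts is the
candidate monoclonal sequence, and each sample is placed into one of four
categories by the fraction of light-chain counts that clone carries:

1. a single clone holds >= 95% of LC counts;
2. two clones that are sequence-identical over a long overlap together hold
   >= 95% (they are merged into one sequence);
3. the major clone holds > 50% and the runner-up < 5%;
4. anything else, with a biclonal flag when two distinct-CDR3 clones each
   hold > 10%.

All fractions use combined IGK+IGL counts as the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Optional, Sequence

from .config import DEFAULT_CONFIG, AnalysisConfig
from .io_formats import LC_LOCI, LOCI, ClonotypeRecordRow

if TYPE_CHECKING:  # pragma: no cover
    from .sequence_ops import MergeResult

Clonotype = ClonotypeRecordRow  # one assembled clone; rows double as clones


@dataclass
class ClonotypeTable:
    """All clones of one sample plus per-locus count totals."""

    sample_id: str
    clones: list[Clonotype]
    locus_totals: dict[str, int]
    lc_total: int

    @property
    def lc_clones(self) -> list[Clonotype]:
        return [c for c in self.clones if c.locus in LC_LOCI]


def build_table(sample_id: str, rows: Sequence[ClonotypeRecordRow]) -> ClonotypeTable:
    totals = {locus: 0 for locus in LOCI}
    for r in rows:
        totals[r.locus] += r.count
    return ClonotypeTable(
        sample_id=sample_id,
        clones=list(rows),
        locus_totals=totals,
        lc_total=totals["IGK"] + totals["IGL"],
    )


@dataclass
class FractionReport:
    """Per-clone fractions of LC and total-Ig counts, plus locus shares."""

    lc_total: int
    ig_total: int
    lc_fractions: dict[str, float]        # clone_id -> count / lc_total (LC clones only)
    total_ig_fractions: dict[str, float]  # clone_id -> count / (IGK+IGL+IGH)
    locus_shares: dict[str, float]        # locus -> locus total / ig_total
    no_lc_signal: bool = False


def compute_fractions(table: ClonotypeTable) -> FractionReport:
    """Fractions of combined light-chain counts and of total Ig counts.

    A table with no IGK/IGL counts is reported with ``no_lc_signal`` set and
    empty LC fractions rather than raising.
    """
    ig_total = sum(table.locus_totals.values())
    lc_fr: dict[str, float] = {}
    ig_fr: dict[str, float] = {}
    for c in table.clones:
        if ig_total > 0:
            ig_fr[c.clone_id] = c.count / ig_total
        if c.locus in LC_LOCI and table.lc_total > 0:
            lc_fr[c.clone_id] = c.count / table.lc_total
    shares = {
        locus: (table.locus_totals[locus] / ig_total if ig_total else 0.0) for locus in LOCI
    }
    return FractionReport(
        lc_total=table.lc_total,
        ig_total=ig_total,
        lc_fractions=lc_fr,
        total_ig_fractions=ig_fr,
        locus_shares=shares,
        no_lc_signal=table.lc_total == 0,
    )


def _longest_len(clone: Clonotype) -> int:
    return max(len(f) for f in clone.fragments)


def _selection_key(clone: Clonotype) -> tuple:
    # larger count, then longer longest fragment, then lexicographically
    # smaller concatenated sequence: deterministic under any input order
    return (-clone.count, -_longest_len(clone), "".join(clone.fragments))


def select_major_clone(table: ClonotypeTable) -> Optional[Clonotype]:
    """The light-chain clone with the most counts; None when no LC clone exists.

    Ties are broken toward the longer longest fragment, then the
    lexicographically smaller concatenated sequence.
    """
    lc = table.lc_clones
    if not lc:
        return None
    return min(lc, key=_selection_key)


@dataclass
class CategoryAssignment:
    """Clonality category call for one sample."""

    category: int
    major_clone: Optional[Clonotype]
    major_fraction: Optional[float]
    secondary_clone: Optional[Clonotype] = None
    merged: bool = False
    merge_result: Optional["MergeResult"] = None
    biclonal_flag: bool = False
    low_support_flag: bool = False
    no_clone_flag: bool = False
    advisory: Optional[str] = None


Cdr3Locator = Callable[[str], Optional[tuple[int, int]]]


def _clone_cdr3(clone: Clonotype, cdr3_locator: Optional[Cdr3Locator]) -> Optional[str]:
    if clone.cdr3_nt:
        return clone.cdr3_nt
    if cdr3_locator is not None:
        frag = max(clone.fragments, key=len)
        span = cdr3_locator(frag)
        if span is not None:
            return frag[span[0]:span[1]]
    return None


def assign_category(
    table: ClonotypeTable,
    merge_attempt: Callable[[Clonotype, Clonotype, ClonotypeTable], object],
    cdr3_locator: Optional[Cdr3Locator] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> CategoryAssignment:
    """Assign exactly one clonality category to a sample.

    ``merge_attempt(major, secondary, table)`` must return a ``MergeResult``
    on success or a refusal object otherwise (the ``sequence_ops`` contract).
    The merge is attempted before the Category 3 test because a successful
    merge recovers a longer sequence.
    """
    from .sequence_ops import MergeResult  # local import avoids a cycle

    lc = sorted(table.lc_clones, key=_selection_key)
    if not lc or table.lc_total == 0:
        return CategoryAssignment(category=4, major_clone=None, major_fraction=None,
                                  no_clone_flag=True)
    major = lc[0]
    mf = major.count / table.lc_total
    rest = lc[1:]
    second_fraction = rest[0].count / table.lc_total if rest else 0.0

    biclonal = False
    if rest:
        top2 = (major, rest[0])
        f2 = rest[0].count / table.lc_total
        if mf > config.biclonal_min_share and f2 > config.biclonal_min_share:
            cdr3s = [_clone_cdr3(c, cdr3_locator) for c in top2]
            if all(cdr3s) and cdr3s[0] != cdr3s[1]:
                biclonal = True

    if mf >= config.cat1_min_fraction:
        return CategoryAssignment(category=1, major_clone=major, major_fraction=mf)

    if mf > config.major_min_fraction:
        # Category 2: look for an eligible same-locus secondary and try a merge
        eligible = [
            c for c in rest
            if c.locus == major.locus
            and c.count >= config.merge_secondary_min_count
            and c.count > config.merge_secondary_min_share * table.lc_total
        ]
        if eligible:
            secondary = eligible[0]  # largest eligible
            result = merge_attempt(major, secondary, table)
            if isinstance(result, MergeResult):
                merged_fraction = result.combined_count / table.lc_total
                if merged_fraction >= config.cat1_min_fraction:
                    return CategoryAssignment(
                        category=2, major_clone=major, major_fraction=merged_fraction,
                        secondary_clone=secondary, merged=True, merge_result=result,
                    )
        if second_fraction < config.cat3_max_second:
            return CategoryAssignment(category=3, major_clone=major, major_fraction=mf)

    return CategoryAssignment(category=4, major_clone=major, major_fraction=mf,
                              biclonal_flag=biclonal)


def flag_low_support(
    assignment: CategoryAssignment,
    threshold: Optional[int] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> CategoryAssignment:
    """Flag assignments whose major clone has fewer counts than ``threshold``.

    Uses the post-merge combined count when the sample was merged. The flag is
    advisory: the recommended remedy is re-running on ~10x the input reads.
    """
    if assignment.major_clone is None:
        return assignment
    if threshold is None:
        threshold = config.low_support_count
    count = (assignment.merge_result.combined_count
             if assignment.merged and assignment.merge_result is not None
             else assignment.major_clone.count)
    if count < threshold:
        assignment.low_support_flag = True
        assignment.advisory = (
            f"major clone supported by only {count} counts (< {threshold}); "
            "consider re-running on 10x more input reads"
        )
    return assignment
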