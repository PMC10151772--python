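"""Alignment-level operations on clone sequences.

Covers the sequence side of the pipeline: picking the longest assembled
fragment, the ungapped suffix-prefix/containment overlap search behind the
identical-clone merge, best-hit germline V/J/C assignment by local alignment,
IMGT-convention CDR3 extraction (2nd-CYS through the codon preceding the J
F/W-G-X-G anchor), coverage completeness, and translation in the V reading
frame.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Callable, Optional, Sequence, Union

import numpy as np
from Bio import Align
from Bio.Seq import Seq

from .config import DEFAULT_CONFIG, AnalysisConfig
from .io_formats import GermlineGene, GermlineRepertoire

if TYPE_CHECKING:  # pragma: no cover
    from .clonal_analysis import Clonotype, ClonotypeTable


# ---------------------------------------------------------------------------
# fragments
# ---------------------------------------------------------------------------

def longest_fragment(clone: "Clonotype") -> str:
    """The longest assembled fragment of a clone; ties keep the first stored."""
    return max(clone.fragments, key=len)


# ---------------------------------------------------------------------------
# ungapped overlap search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OverlapResult:
    """Best ungapped overlap between two sequences.

    ``offset`` is the start of ``b`` in ``a`` coordinates (may be negative
    when ``b`` extends 5' of ``a``). ``a_span``/``b_span`` delimit the
    overlapping interval on each input.
    """

    offset: int
    length: int
    mismatches: int
    gaps: int
    a_span: tuple[int, int]
    b_span: tuple[int, int]


def find_overlap(
    seq_a: str,
    seq_b: str,
    min_len: Optional[int] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Optional[OverlapResult]:
    """Best ungapped suffix-prefix or containment overlap of two sequences.

    Every relative placement of ``b`` against ``a`` is scored as
    matches − mismatches over the shared interval (an N counts as a
    mismatch); the best-scoring placement wins, ties going to the longer
    overlap and then the smaller offset. Returns ``None`` when the best
    overlap is shorter than ``min_len`` (default 16 nt) — for unrelated
    random sequences the best placement is essentially always a short
    chance run, so this is the "no overlap" condition.
    """
    if not seq_a or not seq_b:
        raise ValueError("both sequences must be non-empty")
    if min_len is None:
        min_len = config.min_reportable_overlap
    a = np.frombuffer(seq_a.upper().encode(), dtype=np.uint8)
    b = np.frombuffer(seq_b.upper().encode(), dtype=np.uint8)
    la, lb = len(a), len(b)
    n_code = ord("N")
    best: Optional[tuple[tuple[int, int, int], int, int, int]] = None
    for off in range(-(lb - 1), la):
        s = max(0, off)
        e = min(la, off + lb)
        length = e - s
        if length <= 0:
            continue
        seg_a = a[s:e]
        seg_b = b[s - off:e - off]
        eq = seg_a == seg_b
        not_n = (seg_a != n_code) & (seg_b != n_code)
        matches = int(np.count_nonzero(eq & not_n))
        mismatches = length - matches
        key = (matches - mismatches, length, -off)
        if best is None or key > best[0]:
            best = (key, off, length, mismatches)
    assert best is not None
    _, off, length, mismatches = best
    if length < min_len:
        return None
    s = max(0, off)
    e = min(la, off + lb)
    return OverlapResult(
        offset=off, length=length, mismatches=mismatches, gaps=0,
        a_span=(s, e), b_span=(s - off, e - off),
    )


# ---------------------------------------------------------------------------
# identical-clone merge
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MergeResult:
    merged_sequence: str
    combined_count: int
    overlap_length: int
    overlap_contains_cdr3: bool
    source_clone_ids: tuple[str, str]


@dataclass(frozen=True)
class MergeRefusal:
    reason: str  # short_overlap | mismatch | no_cdr3_in_overlap | insufficient_combined_fraction
    detail: str = ""


Cdr3Locator = Callable[[str], Optional[tuple[int, int]]]


def _union_sequence(a: str, b: str, offset: int) -> str:
    if offset >= 0:
        merged = a
        if offset + len(b) > len(a):
            merged += b[len(a) - offset:]
        return merged
    merged = b[:-offset] + a
    if offset + len(b) > len(a):
        merged += b[len(a) - offset:]
    return merged


def attempt_merge(
    major: "Clonotype",
    secondary: "Clonotype",
    table: "ClonotypeTable",
    cdr3_locator: Optional[Cdr3Locator] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Union[MergeResult, MergeRefusal]:
    """Collapse two clones into one sequence when they are the same clone.

    Succeeds only when the longest fragments share an ungapped overlap of at
    least 200 nt with zero mismatches, the overlap contains the full CDR3 of
    both clones, and the combined counts reach 95% of the sample's
    light-chain counts. Each failed criterion yields a distinct refusal.
    """
    a = longest_fragment(major)
    b = longest_fragment(secondary)
    ov = find_overlap(a, b, config=config)
    if ov is None or ov.length < config.merge_min_overlap:
        return MergeRefusal("short_overlap",
                            f"best overlap {0 if ov is None else ov.length} nt "
                            f"< {config.merge_min_overlap}")
    if ov.mismatches > 0 or ov.gaps > 0:
        return MergeRefusal("mismatch", f"{ov.mismatches} mismatch(es) in {ov.length} nt overlap")

    def _cdr3_in_overlap(seq: str, span: tuple[int, int], hint: Optional[str]) -> bool:
        # the germline-anchored locator is precise; a cdr3 string hint is the
        # fallback (located by exact search, so only trustworthy when unique)
        if cdr3_locator is not None:
            cspan = cdr3_locator(seq)
            if cspan is not None:
                return span[0] <= cspan[0] and cspan[1] <= span[1]
        if hint:
            pos = seq.find(hint)
            if pos >= 0:
                return span[0] <= pos and pos + len(hint) <= span[1]
        return False

    if not (_cdr3_in_overlap(a, ov.a_span, major.cdr3_nt)
            and _cdr3_in_overlap(b, ov.b_span, secondary.cdr3_nt)):
        return MergeRefusal("no_cdr3_in_overlap",
                            "overlap does not contain the full CDR3 of both clones")

    combined = major.count + secondary.count
    if table.lc_total <= 0 or combined / table.lc_total < config.merge_min_combined_fraction:
        frac = combined / table.lc_total if table.lc_total else 0.0
        return MergeRefusal("insufficient_combined_fraction",
                            f"combined fraction {frac:.3f} < {config.merge_min_combined_fraction}")

    return MergeResult(
        merged_sequence=_union_sequence(a, b, ov.offset),
        combined_count=combined,
        overlap_length=ov.length,
        overlap_contains_cdr3=True,
        source_clone_ids=(major.clone_id, secondary.clone_id),
    )


# ---------------------------------------------------------------------------
# germline best-hit assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneHit:
    """A local alignment of one germline gene to a clone sequence."""

    gene: GermlineGene
    score: float
    t_span: tuple[int, int]   # on the clone sequence
    q_span: tuple[int, int]   # on the germline gene
    blocks: tuple[tuple[tuple[int, int], tuple[int, int]], ...]
    matches: int
    mismatches: int
    gaps: int

    @property
    def aligned_length(self) -> int:
        return self.matches + self.mismatches

    @property
    def identity(self) -> float:
        cols = self.matches + self.mismatches + self.gaps
        return self.matches / cols if cols else 0.0

    def query_to_target(self, q: int) -> Optional[int]:
        """Map a germline coordinate onto the clone; None if in a gap/unaligned."""
        for (ts, _te), (qs, qe) in self.blocks:
            if qs <= q < qe:
                return ts + (q - qs)
        return None


def _make_aligner(config: AnalysisConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = config.align_match
    aligner.mismatch_score = config.align_mismatch
    aligner.open_gap_score = config.align_gap_open
    aligner.extend_gap_score = config.align_gap_extend
    return aligner


def _align_gene(aligner: Align.PairwiseAligner, seq: str, gene: GermlineGene,
                t_offset: int = 0) -> Optional[GeneHit]:
    if not seq:
        return None
    alns = aligner.align(seq, gene.sequence)
    try:
        aln = alns[0]
    except IndexError:
        return None
    t_blocks, q_blocks = aln.aligned
    if len(t_blocks) == 0:
        return None
    blocks = tuple(
        ((int(ts) + t_offset, int(te) + t_offset), (int(qs), int(qe)))
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks)
    )
    matches = mismatches = 0
    for (ts, te), (qs, _qe) in blocks:
        for k in range(te - ts):
            if seq[ts - t_offset + k] == gene.sequence[qs + k]:
                matches += 1
            else:
                mismatches += 1
    gaps = 0
    for i in range(1, len(blocks)):
        gaps += (blocks[i][0][0] - blocks[i - 1][0][1]) + (blocks[i][1][0] - blocks[i - 1][1][1])
    return GeneHit(
        gene=gene, score=float(aln.score),
        t_span=(blocks[0][0][0], blocks[-1][0][1]),
        q_span=(blocks[0][1][0], blocks[-1][1][1]),
        blocks=blocks, matches=matches, mismatches=mismatches, gaps=gaps,
    )


def _best_hit(aligner: Align.PairwiseAligner, seq: str, genes: Sequence[GermlineGene],
              t_offset: int = 0) -> Optional[GeneHit]:
    best: Optional[GeneHit] = None
    for gene in sorted(genes, key=lambda g: g.name):  # name order makes ties deterministic
        hit = _align_gene(aligner, seq, gene, t_offset)
        if hit is None:
            continue
        if best is None or hit.score > best.score:
            best = hit
    return best


@dataclass
class GermlineAssignment:
    """Germline V/J/C call for one clone sequence, with CDR3 and coverage."""

    v_gene: str
    j_gene: Optional[str]
    c_gene: Optional[str]
    v_hit: GeneHit
    j_hit: Optional[GeneHit]
    c_hit: Optional[GeneHit]
    v_mutations: int
    cdr3_nt: Optional[str]
    cdr3_aa: Optional[str]
    cdr3_span: Optional[tuple[int, int]]
    coverage: Optional[str]        # "complete" | "partial"
    protein: Optional[str]
    productive: Optional[bool]

    @property
    def v_span(self) -> tuple[int, int]:
        return self.v_hit.t_span

    @property
    def j_span(self) -> Optional[tuple[int, int]]:
        return self.j_hit.t_span if self.j_hit else None

    @property
    def c_span(self) -> Optional[tuple[int, int]]:
        return self.c_hit.t_span if self.c_hit else None


def extract_cdr3(seq: str, v_hit: GeneHit, j_hit: GeneHit
                 ) -> tuple[Optional[str], Optional[str], Optional[tuple[int, int]]]:
    """CDR3 from the V 2nd-CYS codon through the codon preceding the J anchor.

    Both anchors are germline offsets mapped onto the clone through the
    alignments; junction insertions between V and J are therefore included.
    Returns ``(None, None, None)`` when an anchor cannot be located or the
    cysteine codon has mutated away from TGT/TGC.
    """
    seq = seq.upper()
    cys_q = v_hit.gene.cys104_offset
    jm_q = j_hit.gene.jmotif_offset
    if cys_q is None or jm_q is None:
        return None, None, None
    cys_t = v_hit.query_to_target(cys_q)
    jm_t = j_hit.query_to_target(jm_q)
    if cys_t is None or jm_t is None or jm_t <= cys_t:
        return None, None, None
    if seq[cys_t:cys_t + 3] not in ("TGT", "TGC"):
        return None, None, None
    cdr3_nt = seq[cys_t:jm_t]
    cdr3_aa = str(Seq(cdr3_nt).translate()) if len(cdr3_nt) % 3 == 0 else None
    return cdr3_nt, cdr3_aa, (cys_t, jm_t)


def classify_coverage(v_hit: GeneHit, j_hit: GeneHit) -> str:
    """"complete" when the clone reaches V position 0 and the J gene's end."""
    if v_hit.q_span[0] == 0 and j_hit.q_span[1] == len(j_hit.gene.sequence):
        return "complete"
    return "partial"


def translate_clone(
    seq: str,
    v_hit: GeneHit,
    end: Optional[int] = None,
    j_anchor: Optional[int] = None,
) -> tuple[str, bool]:
    """Translate in the V germline reading frame from the start of the V span.

    The frame is anchored to germline codon boundaries; a trailing partial
    codon is dropped. ``productive`` is False when an in-frame stop occurs
    before ``j_anchor`` (clone coordinate of the J F/W-G-X-G anchor); with no
    anchor given, any stop makes the clone non-productive.
    """
    seq = seq.upper()
    t0, _ = v_hit.t_span
    frame = v_hit.q_span[0] % 3
    start = t0 + ((3 - frame) % 3)
    stop_at = len(seq) if end is None else min(end, len(seq))
    usable = stop_at - start
    if usable < 3:
        raise ValueError("aligned span shorter than one codon")
    region = seq[start:start + usable - usable % 3]
    protein = str(Seq(region).translate())
    limit = j_anchor if j_anchor is not None else start + len(region)
    productive = True
    pos = protein.find("*")
    if pos >= 0 and start + 3 * pos < limit:
        productive = False
    return protein, productive


def assign_germline(
    seq: str,
    repertoire: GermlineRepertoire,
    locus: Optional[str] = None,
    config: AnalysisConfig = DEFAULT_CONFIG,
) -> Optional[GermlineAssignment]:
    """Best-hit germline V/J/C assignment for a clone sequence.

    The V gene is the highest-scoring local alignment among candidate V
    genes; a call requires at least ``v_min_aligned`` aligned nt at
    ``v_min_identity`` identity, otherwise the clone is unassigned (None).
    The J gene is searched 3' of the V span and the C gene 3' of the J span.
    """
    seq = seq.upper()
    v_genes = repertoire.select("V", locus)
    j_genes = repertoire.select("J", locus)
    if not v_genes or not j_genes:
        raise ValueError(f"repertoire has no V or no J genes for locus {locus!r}")
    aligner = _make_aligner(config)
    v_best: Optional[GeneHit] = None
    for gene in sorted(v_genes, key=lambda g: g.name):
        hit = _align_gene(aligner, seq, gene)
        if hit is None or hit.aligned_length < config.v_min_aligned \
                or hit.identity < config.v_min_identity:
            continue
        if v_best is None or hit.score > v_best.score:
            v_best = hit
    if v_best is None:
        return None
    locus = v_best.gene.locus

    j_region_start = v_best.t_span[1]
    j_best = _best_hit(aligner, seq[j_region_start:],
                       repertoire.select("J", locus), t_offset=j_region_start)
    if j_best is not None and (j_best.aligned_length < 12 or j_best.identity < 0.80):
        j_best = None

    c_best = None
    if j_best is not None:
        c_start = j_best.t_span[1]
        c_best = _best_hit(aligner, seq[c_start:],
                           repertoire.select("C", locus), t_offset=c_start)
        if c_best is not None and (c_best.aligned_length < 20 or c_best.identity < 0.85):
            c_best = None

    cdr3_nt = cdr3_aa = None
    cdr3_span = None
    coverage = "partial"
    j_anchor = None
    if j_best is not None:
        cdr3_nt, cdr3_aa, cdr3_span = extract_cdr3(seq, v_best, j_best)
        coverage = classify_coverage(v_best, j_best)
        if j_best.gene.jmotif_offset is not None:
            j_anchor = j_best.query_to_target(j_best.gene.jmotif_offset)

    protein = None
    productive = None
    try:
        trans_end = j_best.t_span[1] if j_best is not None else None
        protein, productive = translate_clone(seq, v_best, end=trans_end, j_anchor=j_anchor)
    except ValueError:
        pass

    return GermlineAssignment(
        v_gene=v_best.gene.name,
        j_gene=j_best.gene.name if j_best else None,
        c_gene=c_best.gene.name if c_best else None,
        v_hit=v_best, j_hit=j_best, c_hit=c_best,
        v_mutations=v_best.mismatches,
        cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa, cdr3_span=cdr3_span,
        coverage=coverage, protein=protein, productive=productive,
    )
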