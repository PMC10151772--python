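"""Synthetic repertoires, rearrangements, clonotype tables and FASTQ fixtures.

Everything the pipeline consumes can be generated here with known truth, so
the whole analysis is testable without access-restricted patient data. The
generator emulates the statistical structure of plasma-cell RNA-seq clonotype
output:

* germline genes are random sequences with planted IMGT-style anchors (a
  2nd-CYS codon near the V 3' end, an F/W-G-X-G motif in each J) rather than
  copies of licensed reference records;
* rearrangements are V[0:cys+3] + junction + J[anchor-3:] + C-prefix behind a
  random 5'UTR/leader, with somatic-hypermutation-style substitutions outside
  a small guard around the CDR3 anchors; full length lands near 606 nt;
* samples plant one of the four clonality categories exactly (dominant clone
  share, split-clone overlap geometry for category 2, Dirichlet-distributed
  polyclonal background, a small IGH component) plus a clinical record that
  is concordant unless discordance is requested.

All generators are byte-deterministic given a seed.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio.Seq import Seq

from .io_formats import (
    ClinicalRecordRow,
    ClonotypeRecordRow,
    GermlineGene,
    GermlineRepertoire,
    write_clinical_csv,
    write_clonotype_table,
    write_germline_fasta,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = sorted(
    a + b + c
    for a in "ACGT" for b in "ACGT" for c in "ACGT"
    if a + b + c not in _STOPS
)
_SENSE_NO_CYS = [c for c in _SENSE_CODONS if c not in ("TGT", "TGC")]
_FW_CODONS = ("TTT", "TTC", "TGG")

DEFAULT_CATEGORY_MIX = (0.74, 0.12, 0.06, 0.08)
DEFAULT_LC_TOTAL = 124_000  # median LC counts per sample in the motivating cohort


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def _random_codons(rng: np.random.Generator, n: int, pool: Sequence[str] = _SENSE_CODONS) -> str:
    idx = rng.integers(0, len(pool), size=n)
    return "".join(pool[i] for i in idx)


def _identity_at_zero(a: str, b: str) -> float:
    n = min(len(a), len(b))
    return sum(1 for x, y in zip(a[:n], b[:n]) if x == y) / n


# ---------------------------------------------------------------------------
# germline repertoire
# ---------------------------------------------------------------------------

def _make_v_sequence(rng: np.random.Generator) -> tuple[str, int]:
    n_codons = int(rng.integers(98, 101))  # 294-300 nt
    cys_codon_idx = n_codons - 3           # cys at len-9, within the 3' 40 nt
    codons = []
    for i in range(n_codons):
        if i == cys_codon_idx:
            codons.append("TGT" if rng.random() < 0.5 else "TGC")
        elif i >= n_codons - 13:
            codons.append(_SENSE_NO_CYS[int(rng.integers(0, len(_SENSE_NO_CYS)))])
        else:
            codons.append(_SENSE_CODONS[int(rng.integers(0, len(_SENSE_CODONS)))])
    seq = "".join(codons)
    return seq, cys_codon_idx * 3


def _make_j_sequence(rng: np.random.Generator) -> tuple[str, int]:
    from .io_formats import _infer_jmotif  # motif-scan is the shared convention

    for _ in range(100):
        jm = int(rng.choice([6, 9]))
        tail = int(rng.choice([0, 3, 6]))
        prefix = _random_bases(rng, jm - 3) + _random_codons(rng, 1)
        anchor = _FW_CODONS[int(rng.integers(0, 3))]
        g1 = "GG" + _random_bases(rng, 1)
        mid = _random_codons(rng, 1)
        g2 = "GG" + _random_bases(rng, 1)
        seq = prefix + anchor + g1 + mid + g2 + _random_codons(rng, tail // 3)
        if _infer_jmotif(seq) == jm:
            return seq, jm
    raise RuntimeError("could not place a unique J anchor motif")


def make_germline_repertoire(
    n_v: int = 30,
    n_j: int = 4,
    locus_mix: tuple[float, float] = (0.5, 0.5),
    seed: int = 0,
    out_path: Optional[str | Path] = None,
    max_pairwise_identity: float = 0.90,
) -> GermlineRepertoire:
    """Generate a synthetic germline repertoire (V/J/C per IGK and IGL).

    V genes (~294-300 nt) carry an in-frame TGT/TGC anchor near the 3' end,
    J genes (~18-24 nt) a planted F/W-G-X-G motif, and each locus gets a
    ~99 nt C stub. V genes are rejection-sampled to pairwise identity at or
    below ``max_pairwise_identity`` so best-hit assignment is well-posed.
    """
    if n_v < 2:
        raise ValueError("n_v must be >= 2")
    if n_j < 1:
        raise ValueError("n_j must be >= 1")
    rng = np.random.default_rng(seed)
    n_v_k = max(1, round(n_v * locus_mix[0])) if locus_mix[0] > 0 else 0
    n_v_k = min(n_v_k, n_v - (1 if locus_mix[1] > 0 else 0))
    n_v_l = n_v - n_v_k
    n_j_k = max(1, round(n_j * locus_mix[0])) if n_v_k else 0
    n_j_k = min(n_j_k, n_j - (1 if n_v_l else 0))
    n_j_l = n_j - n_j_k
    if (n_v_k and not n_j_k) or (n_v_l and not n_j_l):
        raise ValueError("each locus with V genes needs at least one J gene")

    genes: list[GermlineGene] = []
    v_seqs: list[str] = []
    for n_loc, prefix in ((n_v_k, "IGKV1"), (n_v_l, "IGLV2")):
        locus = prefix[:3]
        for i in range(n_loc):
            for attempt in range(50):
                seq, cys = _make_v_sequence(rng)
                if all(_identity_at_zero(seq, other) <= max_pairwise_identity
                       for other in v_seqs):
                    break
            else:
                raise RuntimeError("could not satisfy the V pairwise identity constraint")
            v_seqs.append(seq)
            genes.append(GermlineGene(f"{prefix}-{i + 1}", "V", locus, seq, cys104_offset=cys))
    for locus, n_loc in (("IGK", n_j_k), ("IGL", n_j_l)):
        for i in range(n_loc):
            seq, jm = _make_j_sequence(rng)
            genes.append(GermlineGene(f"{locus}J{i + 1}", "J", locus, seq, jmotif_offset=jm))
    for locus, name in (("IGK", "IGKC"), ("IGL", "IGLC1")):
        if (locus == "IGK" and n_v_k) or (locus == "IGL" and n_v_l):
            genes.append(GermlineGene(name, "C", locus, _random_codons(rng, 33)))

    repertoire = GermlineRepertoire(genes)
    if out_path is not None:
        write_germline_fasta(repertoire, out_path)
    return repertoire


# ---------------------------------------------------------------------------
# single rearrangement
# ---------------------------------------------------------------------------

@dataclass
class RearrangementTruth:
    """A simulated full-length clone sequence with complete ground truth."""

    sequence: str
    locus: str
    v_gene: str
    j_gene: str
    c_gene: Optional[str]
    v_start: int          # clone coordinate of germline V position 0
    j_end: int            # clone coordinate one past the last J nucleotide
    cys_pos: int          # clone coordinate of the CDR3-start cysteine codon
    j_anchor: int         # clone coordinate of the J F/W-G-X-G anchor codon
    junction: str
    cdr3_nt: str
    cdr3_aa: Optional[str]
    protein: str          # V..J translation in the V reading frame
    productive: bool
    n_mutations: int


def simulate_rearrangement(
    v: GermlineGene,
    j: GermlineGene,
    c: Optional[GermlineGene] = None,
    junction_len: Optional[int] = None,
    mutation_rate: float = 0.0,
    seed: int = 0,
    leader_len: int = 170,
    force_stop: bool = False,
) -> RearrangementTruth:
    """Simulate one VJ rearrangement with junctional insertion and mutation.

    The emitted sequence is leader + V[0:cys+3] + junction + J[anchor-3:] +
    C-prefix. Substitutions are applied at ``mutation_rate`` over the V..J
    region, sparing a small guard around the two CDR3 anchors so the junction
    stays locatable. A junction length that is a multiple of 3 (the default
    draw) keeps the product in frame and productive by construction.
    """
    if v.locus != j.locus or (c is not None and c.locus != v.locus):
        raise ValueError("V, J and C genes must come from one locus")
    rng = np.random.default_rng(seed)
    if junction_len is None:
        junction_len = int(rng.choice([0, 3, 6, 9, 12]))
    if not 0 <= junction_len <= 12:
        raise ValueError("junction_len must be in 0..12")
    assert v.cys104_offset is not None and j.jmotif_offset is not None
    cys = v.cys104_offset
    v_used = v.sequence[:cys + 3]
    if junction_len % 3 == 0:
        junction = _random_codons(rng, junction_len // 3)
    else:
        junction = _random_bases(rng, junction_len)
    j_used = j.sequence[j.jmotif_offset - 3:]
    c_prefix = c.sequence if c is not None else ""
    leader = _random_bases(rng, leader_len)

    seq = leader + v_used + junction + j_used + c_prefix
    v_start = leader_len
    cys_pos = leader_len + cys
    j_anchor = leader_len + len(v_used) + junction_len + 3
    j_end = leader_len + len(v_used) + junction_len + len(j_used)

    if force_stop:
        stop_codon_pos = v_start + 3 * ((cys - 30) // 6)  # mid-V, codon-aligned
        seq = seq[:stop_codon_pos] + "TAA" + seq[stop_codon_pos + 3:]

    n_mut = 0
    if mutation_rate > 0:
        guard = set(range(cys_pos - 3, cys_pos + 6)) | set(range(j_anchor - 3, j_anchor + 6))
        arr = bytearray(seq.encode())
        hits = np.nonzero(rng.random(j_end - v_start) < mutation_rate)[0] + v_start
        for pos in hits:
            if int(pos) in guard:
                continue
            old = arr[pos]
            choices = [b for b in b"ACGT" if b != old]
            arr[pos] = choices[int(rng.integers(0, 3))]
            n_mut += 1
        seq = arr.decode()

    cdr3_nt = seq[cys_pos:j_anchor]
    cdr3_aa = str(Seq(cdr3_nt).translate()) if len(cdr3_nt) % 3 == 0 else None
    coding = seq[v_start:j_end]
    coding = coding[:len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate())
    return RearrangementTruth(
        sequence=seq, locus=v.locus, v_gene=v.name, j_gene=j.name,
        c_gene=c.name if c else None,
        v_start=v_start, j_end=j_end, cys_pos=cys_pos, j_anchor=j_anchor,
        junction=junction, cdr3_nt=cdr3_nt, cdr3_aa=cdr3_aa,
        protein=protein, productive="*" not in protein, n_mutations=n_mut,
    )


# ---------------------------------------------------------------------------
# whole samples
# ---------------------------------------------------------------------------

@dataclass
class SampleTruth:
    sample_id: str
    seed: int
    category: int
    locus: str
    clone_sequence: str
    protein: str
    v_gene: str
    j_gene: str
    c_gene: Optional[str]
    cdr3_nt: str
    cdr3_aa: Optional[str]
    cdr3_span: tuple[int, int]     # CDR3 coordinates on clone_sequence (half-open)
    clone_fraction: float          # planted (combined, for category 2) LC fraction
    split: Optional[dict] = None   # {"split_point", "overlap_length"} for category 2
    biclonal: bool = False
    restriction: str = "indeterminate"
    concordance_status: str = "indeterminate"


@dataclass
class SampleSim:
    rows: list[ClonotypeRecordRow]
    clinical: ClinicalRecordRow
    truth: SampleTruth


def _partition_counts(rng: np.random.Generator, total: int, n: int,
                      cap: Optional[int] = None) -> list[int]:
    """Split ``total`` counts over ``n`` background clones (Dirichlet weights),
    summing exactly and respecting a per-clone cap when given."""
    if total <= 0 or n <= 0:
        return []
    if cap is not None and n * cap < total:
        raise ValueError("infeasible background partition: n * cap < total")
    w = rng.dirichlet(np.full(n, 3.0))
    counts = np.floor(w * total).astype(int)
    if cap is not None:
        counts = np.minimum(counts, cap)
    deficit = total - int(counts.sum())
    order = np.argsort(-w)
    i = 0
    while deficit > 0:
        k = order[i % n]
        if cap is None or counts[k] < cap:
            counts[k] += 1
            deficit -= 1
        i += 1
    return [int(c) for c in counts]


def _pick_genes(rng: np.random.Generator, repertoire: GermlineRepertoire, locus: str
                ) -> tuple[GermlineGene, GermlineGene, Optional[GermlineGene]]:
    vs = repertoire.select("V", locus)
    js = repertoire.select("J", locus)
    cs = repertoire.select("C", locus)
    v = vs[int(rng.integers(0, len(vs)))]
    j = js[int(rng.integers(0, len(js)))]
    c = cs[int(rng.integers(0, len(cs)))] if cs else None
    return v, j, c


def _child_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def simulate_sample(
    category: int,
    repertoire: GermlineRepertoire,
    seed: int,
    sample_id: str = "S1",
    clonal_fraction: Optional[float] = None,
    n_background: int = 12,
    lc_total: int = DEFAULT_LC_TOTAL,
    fragmented: bool = False,
    discordant: bool = False,
    mutation_rate: float = 0.01,
    overlap_len: int = 254,
    locus: Optional[str] = None,
) -> SampleSim:
    """Simulate one sample's clonotype table with a planted clonality category.

    Category 1 plants a dominant clone at >= 95% of LC counts; category 2
    emits the true clone as two fragments sharing a CDR3-spanning exact
    overlap (default 254 nt) with counts satisfying the merge eligibility
    rules; category 3 plants a 50-95% major clone with every other clone
    under 5%; category 4 plants two distinct-CDR3 clones each over 10%
    (biclonal). A concordant (or, on request, discordant) clinical record and
    the full ground truth accompany the table.
    """
    if category not in (1, 2, 3, 4):
        raise ValueError("category must be 1..4")
    rng = np.random.default_rng(seed)
    loci = sorted({g.locus for g in repertoire.genes.values() if g.segment == "V"})
    if locus is None:
        locus = loci[int(rng.integers(0, len(loci)))]

    # planted fractions -----------------------------------------------------
    if category == 1:
        f = clonal_fraction if clonal_fraction is not None else float(rng.uniform(0.955, 0.99))
        if f < 0.95:
            raise ValueError(f"category 1 needs clonal_fraction >= 0.95, got {f}")
    elif category == 2:
        f = clonal_fraction if clonal_fraction is not None else float(rng.uniform(0.96, 0.99))
        if f < 0.95:
            raise ValueError(f"category 2 needs combined fraction >= 0.95, got {f}")
    elif category == 3:
        f = clonal_fraction if clonal_fraction is not None else float(rng.uniform(0.60, 0.88))
        if not 0.50 < f < 0.95:
            raise ValueError(f"category 3 needs clonal_fraction in (0.50, 0.95), got {f}")
        needed = math.ceil((1 - f) * lc_total / (math.floor(0.05 * lc_total) - 1))
        if n_background < needed:
            n_background = needed
    else:
        f = clonal_fraction if clonal_fraction is not None else float(rng.uniform(0.40, 0.48))
        if not 0.10 < f <= 0.50:
            raise ValueError(f"category 4 (biclonal) needs clonal_fraction in (0.10, 0.50], got {f}")

    v, j, c = _pick_genes(rng, repertoire, locus)
    major = simulate_rearrangement(v, j, c, mutation_rate=mutation_rate,
                                   seed=_child_seed(rng))
    S = major.sequence

    rows: list[ClonotypeRecordRow] = []
    clone_n = 0

    def add_row(count: int, fragments: list[str], row_locus: str,
                rr: Optional[RearrangementTruth] = None) -> None:
        nonlocal clone_n
        rows.append(ClonotypeRecordRow(
            sample_id=sample_id, clone_id=f"{sample_id}_c{clone_n}",
            locus=row_locus, count=count, fragments=fragments,
            v_hint=rr.v_gene if rr else None,
            j_hint=rr.j_gene if rr else None,
            c_hint=rr.c_gene if rr else None,
            cdr3_nt=rr.cdr3_nt if rr else None,
        ))
        clone_n += 1

    split_info = None
    second_rr = None
    if category == 2:
        # split the true clone into two fragments with an exact, CDR3-spanning
        # overlap; fragment B must retain enough V for a germline call
        p_min = major.j_anchor + 18 - overlap_len
        p_max = min(major.cys_pos - 110, len(S) - overlap_len - 1)
        if p_max < p_min:
            raise ValueError("overlap_len incompatible with the clone geometry")
        p = int(rng.integers(p_min, p_max + 1))
        frag_a = S[:p + overlap_len]
        frag_b = S[p:]
        combined = math.ceil(f * lc_total)
        major_count = round(float(rng.uniform(0.55, 0.70)) * lc_total)
        second_count = combined - major_count
        min_second = max(100, math.floor(0.01 * lc_total) + 1)
        if second_count < min_second:
            raise ValueError("combined fraction leaves no eligible secondary clone")
        add_row(major_count, [frag_a], locus, major)
        add_row(second_count, [frag_b], locus, major)
        planted = combined
        split_info = {"split_point": p, "overlap_length": overlap_len}
    elif category == 4:
        major_count = round(f * lc_total)
        for _ in range(20):
            v2, j2, c2 = _pick_genes(rng, repertoire, locus)
            second_rr = simulate_rearrangement(v2, j2, c2, mutation_rate=mutation_rate,
                                               seed=_child_seed(rng))
            if second_rr.cdr3_nt != major.cdr3_nt:
                break
        assert second_rr is not None
        f2 = float(rng.uniform(0.15, min(0.35, f - 0.02)))
        second_count = round(f2 * lc_total)
        frags = [S[-150:], S] if fragmented else [S]
        add_row(major_count, frags, locus, major)
        add_row(second_count, [second_rr.sequence], locus, second_rr)
        planted = major_count
    else:
        major_count = math.ceil(f * lc_total)
        frags = [S[-150:], S] if fragmented else [S]
        add_row(major_count, frags, locus, major)
        planted = major_count

    # polyclonal background -------------------------------------------------
    background_total = lc_total - sum(r.count for r in rows)
    cap = math.floor(0.05 * lc_total) - 1 if category == 3 else None
    for count in _partition_counts(rng, background_total, n_background, cap=cap):
        if count < 1:
            continue
        vb, jb, cb = _pick_genes(rng, repertoire, locus)
        bg = simulate_rearrangement(vb, jb, cb, mutation_rate=mutation_rate,
                                    seed=_child_seed(rng))
        add_row(count, [bg.sequence], locus, bg)

    # a small IGH component so total-Ig fractions are exercised
    igh_count = int(round(float(rng.uniform(0.10, 0.20)) * lc_total))
    add_row(igh_count, [_random_bases(rng, 400)], "IGH")

    lc_actual = sum(r.count for r in rows if r.locus in ("IGK", "IGL"))

    # clinical record -------------------------------------------------------
    restriction = "kappa" if locus == "IGK" else "lambda"
    if discordant:
        restriction = "lambda" if restriction == "kappa" else "kappa"
    if restriction == "kappa":
        kappa, lam = float(rng.uniform(100, 400)), float(rng.uniform(4, 20))
    else:
        kappa, lam = float(rng.uniform(4, 20)), float(rng.uniform(100, 400))
    clinical = ClinicalRecordRow(
        sample_id=sample_id,
        serum_kappa=round(kappa, 1),
        serum_lambda=round(lam, 1),
        mprotein_lc=restriction if rng.random() < 0.5 else None,
        amyloidosis=bool(rng.random() < 0.02),
    )

    truth = SampleTruth(
        sample_id=sample_id, seed=seed, category=category, locus=locus,
        clone_sequence=S, protein=major.protein,
        v_gene=major.v_gene, j_gene=major.j_gene, c_gene=major.c_gene,
        cdr3_nt=major.cdr3_nt, cdr3_aa=major.cdr3_aa,
        cdr3_span=(major.cys_pos, major.j_anchor),
        clone_fraction=planted / lc_actual,
        split=split_info, biclonal=category == 4,
        restriction=restriction,
        concordance_status="discordant" if discordant else "concordant",
    )
    return SampleSim(rows=rows, clinical=clinical, truth=truth)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortSim:
    repertoire: GermlineRepertoire
    samples: list[SampleSim]

    @property
    def truths(self) -> list[SampleTruth]:
        return [s.truth for s in self.samples]


def _apportion(n: int, mix: Sequence[float]) -> list[int]:
    raw = [n * m for m in mix]
    counts = [int(x) for x in raw]
    order = sorted(range(len(mix)), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in range(n - sum(counts)):
        counts[order[i % len(mix)]] += 1
    return counts


def simulate_cohort(
    n_samples: int,
    category_mix: Sequence[float] = DEFAULT_CATEGORY_MIX,
    discordance_rate: float = 0.0,
    seed: int = 0,
    repertoire: Optional[GermlineRepertoire] = None,
    out_dir: Optional[str | Path] = None,
    lc_total: int = DEFAULT_LC_TOTAL,
    mutation_rate: float = 0.01,
    n_v: int = 30,
    n_j: int = 4,
) -> CohortSim:
    """Simulate a cohort with planted category proportions and clinical data.

    Category counts follow ``category_mix`` by largest-remainder
    apportionment; discordant clinical records are planted at
    ``discordance_rate``. When ``out_dir`` is given, writes clonotypes.tsv,
    germline.fasta, clinical.csv and truth.json there.
    """
    if abs(sum(category_mix) - 1.0) > 1e-9:
        raise ValueError("category_mix must sum to 1")
    rng = np.random.default_rng(seed)
    if repertoire is None:
        repertoire = make_germline_repertoire(n_v=n_v, n_j=n_j, seed=_child_seed(rng))
    counts = _apportion(n_samples, category_mix)
    categories = [cat for cat, k in zip((1, 2, 3, 4), counts) for _ in range(k)]
    categories = [categories[i] for i in rng.permutation(n_samples)]
    discordant = rng.random(n_samples) < discordance_rate

    samples = []
    for i, cat in enumerate(categories):
        samples.append(simulate_sample(
            category=cat, repertoire=repertoire, seed=_child_seed(rng),
            sample_id=f"SIM{i:04d}", lc_total=lc_total,
            mutation_rate=mutation_rate, discordant=bool(discordant[i]),
        ))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        all_rows = [r for s in samples for r in s.rows]
        write_clonotype_table(all_rows, out_dir / "clonotypes.tsv")
        write_germline_fasta(repertoire, out_dir / "germline.fasta")
        write_clinical_csv([s.clinical for s in samples], out_dir / "clinical.csv")
        truth = {s.truth.sample_id: dataclasses.asdict(s.truth) for s in samples}
        (out_dir / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return CohortSim(repertoire=repertoire, samples=samples)


# ---------------------------------------------------------------------------
# FASTQ fixtures
# ---------------------------------------------------------------------------

def simulate_fastq(
    n_pairs: int,
    read_len: int,
    seed: int,
    out_r1: str | Path,
    out_r2: str | Path,
) -> tuple[Path, Path]:
    """Write a synchronized pair of synthetic FASTQ files (fixed read length)."""
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    rng = np.random.default_rng(seed)
    out_r1, out_r2 = Path(out_r1), Path(out_r2)
    qual = "I" * read_len
    with open(out_r1, "w") as f1, open(out_r2, "w") as f2:
        for i in range(n_pairs):
            for mate, fh in ((1, f1), (2, f2)):
                seq = _random_bases(rng, read_len)
                fh.write(f"@pair{i}/{mate}\n{seq}\n+\n{qual}\n")
    return out_r1, out_r2
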