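"""Readers and writers for every external artifact of the pipeline.

Formats handled here:

* clonotype tables — tab-separated, one row per assembled clone, modeled on a
  MiXCR ``exportClones`` export (clone counts already include subcluster
  "children" counts; non-contiguous assemblies appear as comma-joined
  fragments);
* germline reference genes — FASTA with IMGT-style names (IGKV/IGKJ/IGKC and
  IGLV/IGLJ/IGLC prefixes) and optional ``cys104=``/``jmotif=`` anchor offsets
  in the header;
* clinical records — CSV with serum free-light-chain values (mg/L), M-protein
  light-chain type and an amyloidosis flag;
* paired FASTQ — only for seeded downsampling to a fixed number of read pairs;
* curated outputs — nucleotide/protein FASTA plus a per-sample summary TSV.

Parsers never coerce a missing value to zero; missing stays missing.
"""

from __future__ import annotations

import csv
import gzip
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Optional, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

LC_LOCI = ("IGK", "IGL")
LOCI = ("IGK", "IGL", "IGH")

_DNA_RE = re.compile(r"^[ACGTN]+$")
_GENE_RE = re.compile(r"^(IG[KL])([VJC])")


class ClonelcError(Exception):
    """Base class for all package errors."""


class FormatError(ClonelcError):
    """A file does not conform to its expected dialect."""


class RowValidationError(ClonelcError):
    """A single row violates an invariant; carries the 1-based line number."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


# ---------------------------------------------------------------------------
# domain row types
# ---------------------------------------------------------------------------

@dataclass
class ClonotypeRecordRow:
    """One assembled clone from one sample.

    ``count`` is the number of reads assigned to the clone with subcluster
    counts already folded in. ``fragments`` holds the ordered non-contiguous
    nucleotide pieces of the assembly (usually a single full fragment).
    """

    sample_id: str
    clone_id: str
    locus: str
    count: int
    fragments: list[str]
    v_hint: Optional[str] = None
    j_hint: Optional[str] = None
    c_hint: Optional[str] = None
    cdr3_nt: Optional[str] = None

    def __post_init__(self) -> None:
        if self.locus not in LOCI:
            raise RowValidationError(f"invalid locus {self.locus!r} (expected one of {LOCI})")
        if self.count < 0:
            raise RowValidationError(f"negative count {self.count}")
        if not self.fragments:
            raise RowValidationError("clone has no fragments")
        self.fragments = [f.upper() for f in self.fragments]
        for frag in self.fragments:
            if not frag or not _DNA_RE.match(frag):
                raise RowValidationError(f"invalid fragment {frag[:20]!r}...")
        if self.cdr3_nt is not None:
            self.cdr3_nt = self.cdr3_nt.upper()


@dataclass
class GermlineGene:
    """One germline reference gene (V, J or C) of the IGK or IGL locus.

    V genes carry ``cys104_offset``: the 0-based, codon-aligned nucleotide
    offset of the conserved CDR3-start cysteine (IMGT 2nd-CYS). J genes carry
    ``jmotif_offset``: the 0-based offset of the F/W-G-X-G anchor codon.
    """

    name: str
    segment: str
    locus: str
    sequence: str
    cys104_offset: Optional[int] = None
    jmotif_offset: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"gene {self.name}: empty sequence")
        self.sequence = self.sequence.upper()
        m = _GENE_RE.match(self.name)
        if not m or m.group(1) != self.locus or m.group(2) != self.segment:
            raise FormatError(
                f"gene name {self.name!r} inconsistent with segment {self.segment}/locus {self.locus}"
            )
        if self.segment == "V" and self.cys104_offset is None:
            raise FormatError(f"V gene {self.name} lacks a cys104 anchor")
        if self.segment == "J" and self.jmotif_offset is None:
            raise FormatError(f"J gene {self.name} lacks a jmotif anchor")


class GermlineRepertoire:
    """Germline genes keyed by name, with per-locus/segment selection."""

    def __init__(self, genes: Sequence[GermlineGene]):
        self.genes: dict[str, GermlineGene] = {}
        for g in genes:
            if g.name in self.genes:
                raise FormatError(f"duplicate gene name {g.name}")
            self.genes[g.name] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __getitem__(self, name: str) -> GermlineGene:
        return self.genes[name]

    def select(self, segment: str, locus: Optional[str] = None) -> list[GermlineGene]:
        return [
            g for g in self.genes.values()
            if g.segment == segment and (locus is None or g.locus == locus)
        ]


@dataclass
class ClinicalRecordRow:
    """Baseline clinical data for one sample.

    Serum values are mg/L; ``None`` means not measured. ``mprotein_lc`` is the
    light-chain type of any monoclonal protein seen by immunofixation or
    electrophoresis ("kappa", "lambda", "none") or ``None`` when missing.
    """

    sample_id: str
    serum_kappa: Optional[float] = None
    serum_lambda: Optional[float] = None
    mprotein_lc: Optional[str] = None
    amyloidosis: Optional[bool] = None

    def __post_init__(self) -> None:
        for v, name in ((self.serum_kappa, "serum_kappa"), (self.serum_lambda, "serum_lambda")):
            if v is not None and (math.isnan(v) or v < 0):
                raise RowValidationError(f"{name} must be non-negative, got {v}")
        if self.mprotein_lc is not None and self.mprotein_lc not in ("kappa", "lambda", "none"):
            raise RowValidationError(f"unknown mprotein_lc token {self.mprotein_lc!r}")


@dataclass
class CuratedRecord:
    """Final curated light-chain clone for one sample, ready for deposition."""

    sample_id: str
    locus: str
    sequence_nt: str
    sequence_aa: Optional[str]
    v_gene: Optional[str]
    j_gene: Optional[str]
    c_gene: Optional[str]
    category: int
    clone_fraction: Optional[float]
    coverage: Optional[str]            # "complete" | "partial"
    cdr3_nt: Optional[str] = None
    cdr3_aa: Optional[str] = None
    cdr3_span: Optional[tuple[int, int]] = None  # 0-based half-open on sequence_nt
    productive: Optional[bool] = None
    concordance_status: Optional[str] = None
    amyloidosis: Optional[bool] = None

    @property
    def subcategory(self) -> str:
        """Disease subcategory for deposition: AL/MM when amyloidosis is recorded."""
        return "AL/MM" if self.amyloidosis else "MM"


# ---------------------------------------------------------------------------
# clonotype tables (TSV)
# ---------------------------------------------------------------------------

CLONOTYPE_COLUMNS = [
    "sample_id", "clone_id", "locus", "count", "fragments",
    "v_hint", "j_hint", "c_hint", "cdr3_nt",
]
_REQUIRED_CLONOTYPE_COLUMNS = CLONOTYPE_COLUMNS[:5]


def read_clonotype_table(path: str | Path) -> dict[str, list[ClonotypeRecordRow]]:
    """Read a clonotype TSV, returning rows grouped per sample in file order.

    An empty file (header only, or fully empty) yields an empty mapping.
    """
    path = Path(path)
    grouped: dict[str, list[ClonotypeRecordRow]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            return grouped
        missing = [c for c in _REQUIRED_CLONOTYPE_COLUMNS if c not in header]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        idx = {c: header.index(c) for c in header}
        seen: dict[str, set[str]] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c for c in row):
                continue

            def get(col: str) -> Optional[str]:
                i = idx.get(col)
                if i is None or i >= len(row) or row[i] == "":
                    return None
                return row[i]

            try:
                count_txt = get("count")
                rec = ClonotypeRecordRow(
                    sample_id=get("sample_id") or "",
                    clone_id=get("clone_id") or "",
                    locus=get("locus") or "",
                    count=int(count_txt) if count_txt is not None else -1,
                    fragments=(get("fragments") or "").split(","),
                    v_hint=get("v_hint"),
                    j_hint=get("j_hint"),
                    c_hint=get("c_hint"),
                    cdr3_nt=get("cdr3_nt"),
                )
            except RowValidationError as e:
                raise RowValidationError(str(e.args[0]).split(": ", 1)[-1], line=lineno) from e
            except ValueError as e:
                raise RowValidationError(str(e), line=lineno) from e
            ids = seen.setdefault(rec.sample_id, set())
            if rec.clone_id in ids:
                raise RowValidationError(
                    f"duplicate clone_id {rec.clone_id!r} in sample {rec.sample_id!r}", line=lineno
                )
            ids.add(rec.clone_id)
            grouped.setdefault(rec.sample_id, []).append(rec)
    return grouped


def write_clonotype_table(rows: Sequence[ClonotypeRecordRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CLONOTYPE_COLUMNS)
        for r in rows:
            w.writerow([
                r.sample_id, r.clone_id, r.locus, r.count, ",".join(r.fragments),
                r.v_hint or "", r.j_hint or "", r.c_hint or "", r.cdr3_nt or "",
            ])


# ---------------------------------------------------------------------------
# germline FASTA
# ---------------------------------------------------------------------------

_FW_CODONS = ("TTT", "TTC", "TGG")  # Phe / Phe / Trp


def _infer_cys104(seq: str) -> Optional[int]:
    """Last in-frame TGT/TGC codon within the 3' 40 nt (frame of position 0)."""
    start = max(0, len(seq) - 40)
    best = None
    for i in range(0, len(seq) - 2, 3):
        if i >= start and seq[i:i + 3] in ("TGT", "TGC"):
            best = i
    return best


def _infer_jmotif(seq: str) -> Optional[int]:
    """First offset of an F/W-G-X-G codon pattern (any frame)."""
    for i in range(len(seq) - 11):
        if (seq[i:i + 3] in _FW_CODONS
                and seq[i + 3:i + 5] == "GG"
                and seq[i + 9:i + 11] == "GG"):
            return i
    return None


def read_germline_fasta(path: str | Path) -> GermlineRepertoire:
    """Read a germline gene FASTA into a repertoire.

    Headers are ``>NAME [cys104=INT] [jmotif=INT]``; the gene name's prefix
    (IGKV, IGLJ, ...) determines locus and segment. Anchors absent from the
    header are inferred: V genes by scanning for the last in-frame cysteine
    codon near the 3' end, J genes for the first F/W-G-X-G motif.
    """
    genes: list[GermlineGene] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        m = _GENE_RE.match(name)
        if not m:
            raise FormatError(f"unclassifiable gene name {name!r} (need IGK/IGL + V/J/C prefix)")
        locus, segment = m.group(1), m.group(2)
        seq = str(rec.seq).upper()
        tokens = dict(
            t.split("=", 1) for t in rec.description.split()[1:] if "=" in t
        )
        cys = int(tokens["cys104"]) if "cys104" in tokens else None
        jm = int(tokens["jmotif"]) if "jmotif" in tokens else None
        if segment == "V" and cys is None:
            cys = _infer_cys104(seq)
            if cys is None:
                raise FormatError(f"V gene {name}: no cysteine anchor found or declared")
        if segment == "J" and jm is None:
            jm = _infer_jmotif(seq)
            if jm is None:
                raise FormatError(f"J gene {name}: no F/W-G-X-G anchor found or declared")
        genes.append(GermlineGene(name, segment, locus, seq, cys, jm))
    return GermlineRepertoire(genes)


def write_germline_fasta(repertoire: GermlineRepertoire, path: str | Path) -> None:
    records = []
    for g in repertoire.genes.values():
        desc = []
        if g.cys104_offset is not None:
            desc.append(f"cys104={g.cys104_offset}")
        if g.jmotif_offset is not None:
            desc.append(f"jmotif={g.jmotif_offset}")
        records.append(SeqRecord(Seq(g.sequence), id=g.name, description=" ".join(desc)))
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# clinical CSV
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ["sample_id", "serum_kappa", "serum_lambda", "mprotein_lc", "amyloidosis"]

_BOOL_TOKENS = {"1": True, "true": True, "0": False, "false": False}


def read_clinical_csv(path: str | Path) -> list[ClinicalRecordRow]:
    """Read clinical records; empty cells become missing values, never zero."""
    out: list[ClinicalRecordRow] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return out
        missing = [c for c in CLINICAL_COLUMNS[:4] if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s) {missing}")
        for lineno, row in enumerate(reader, start=2):
            try:
                amy_txt = (row.get("amyloidosis") or "").strip().lower()
                out.append(ClinicalRecordRow(
                    sample_id=row["sample_id"],
                    serum_kappa=float(row["serum_kappa"]) if row["serum_kappa"] else None,
                    serum_lambda=float(row["serum_lambda"]) if row["serum_lambda"] else None,
                    mprotein_lc=row["mprotein_lc"] or None,
                    amyloidosis=_BOOL_TOKENS[amy_txt] if amy_txt else None,
                ))
            except RowValidationError as e:
                raise RowValidationError(str(e.args[0]), line=lineno) from e
            except (ValueError, KeyError) as e:
                raise RowValidationError(f"unparsable value ({e})", line=lineno) from e
    return out


def write_clinical_csv(records: Sequence[ClinicalRecordRow], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(CLINICAL_COLUMNS)
        for r in records:
            w.writerow([
                r.sample_id,
                "" if r.serum_kappa is None else repr(r.serum_kappa),
                "" if r.serum_lambda is None else repr(r.serum_lambda),
                r.mprotein_lc or "",
                "" if r.amyloidosis is None else int(r.amyloidosis),
            ])


# ---------------------------------------------------------------------------
# FASTQ downsampling
# ---------------------------------------------------------------------------

def _fastq_open(path: Path, mode: str = "rt") -> IO[str]:
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def _iter_fastq(fh: IO[str]) -> Iterator[tuple[str, str, str, str]]:
    while True:
        head = fh.readline()
        if not head:
            return
        seq = fh.readline()
        plus = fh.readline()
        qual = fh.readline()
        if not qual:
            raise FormatError("truncated FASTQ record")
        yield head, seq, plus, qual


def _count_fastq(path: Path) -> int:
    with _fastq_open(path) as fh:
        return sum(1 for _ in _iter_fastq(fh))


def downsample_fastq(
    r1: str | Path,
    r2: str | Path,
    n_pairs: int,
    seed: int,
    out_r1: Optional[str | Path] = None,
    out_r2: Optional[str | Path] = None,
) -> tuple[Path, Path]:
    """Sample ``n_pairs`` read pairs uniformly without replacement.

    Mates stay synchronized and retain their original relative order; with the
    same seed and inputs the outputs are byte-identical. If ``n_pairs`` is at
    least the number of pairs present, all pairs are emitted unchanged.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    r1, r2 = Path(r1), Path(r2)
    out_r1 = Path(out_r1) if out_r1 else r1.with_name(r1.stem.removesuffix(".fastq") + ".sampled.fastq")
    out_r2 = Path(out_r2) if out_r2 else r2.with_name(r2.stem.removesuffix(".fastq") + ".sampled.fastq")
    n1, n2 = _count_fastq(r1), _count_fastq(r2)
    if n1 != n2:
        raise FormatError(f"mate count mismatch: {r1} has {n1} reads, {r2} has {n2}")
    total = n1
    if n_pairs >= total:
        keep = None  # keep everything
    else:
        rng = np.random.default_rng(seed)
        keep = np.zeros(total, dtype=bool)
        keep[rng.choice(total, size=n_pairs, replace=False)] = True
    for src, dst in ((r1, out_r1), (r2, out_r2)):
        with _fastq_open(src) as fin, open(dst, "w") as fout:
            for i, rec in enumerate(_iter_fastq(fin)):
                if keep is None or keep[i]:
                    fout.writelines(rec)
    return out_r1, out_r2


# ---------------------------------------------------------------------------
# curated outputs
# ---------------------------------------------------------------------------

SUMMARY_COLUMNS = [
    "sample_id", "locus", "v_gene", "j_gene", "c_gene", "category",
    "clone_fraction", "coverage", "concordance", "cdr3_nt", "cdr3_aa",
    "productive", "subcategory",
]


def _curated_header(rec: CuratedRecord) -> str:
    return "|".join([
        rec.sample_id, rec.locus, rec.v_gene or "NA", rec.j_gene or "NA",
        str(rec.category), rec.coverage or "NA",
    ])


def write_curated_outputs(records: Sequence[CuratedRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write curated nucleotide/protein FASTA files and the summary TSV.

    Returns the paths written. An empty record set produces an empty FASTA and
    a header-only TSV.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nt_path = out_dir / "curated_nt.fasta"
    aa_path = out_dir / "curated_aa.fasta"
    tsv_path = out_dir / "curated_summary.tsv"

    with open(nt_path, "w") as fh:
        for r in records:
            fh.write(f">{_curated_header(r)}\n{r.sequence_nt}\n")
    with open(aa_path, "w") as fh:
        for r in records:
            if r.sequence_aa:
                fh.write(f">{_curated_header(r)}\n{r.sequence_aa}\n")
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(SUMMARY_COLUMNS)
        for r in records:
            w.writerow([
                r.sample_id, r.locus, r.v_gene or "", r.j_gene or "", r.c_gene or "",
                r.category,
                "" if r.clone_fraction is None else f"{r.clone_fraction:.4f}",
                r.coverage or "", r.concordance_status or "",
                r.cdr3_nt or "", r.cdr3_aa or "",
                "" if r.productive is None else int(r.productive),
                r.subcategory,
            ])
    return {"nt_fasta": nt_path, "aa_fasta": aa_path, "summary_tsv": tsv_path}
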