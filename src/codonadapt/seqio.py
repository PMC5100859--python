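"""Sequence and annotation input: FASTA/GFF3 reading, CDS validation and extraction.

Coordinates are GFF3-style 1-based inclusive at every public interface.
Validation is deliberately permissive about draft-genome artifacts: codons
containing ambiguity codes and internal stop codons are excluded from
counting but do not discard the gene.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq

IUPAC_NT = set("ACGTRYSWKMBDHVN")
STOPS = {"TAA", "TAG", "TGA"}


class FastaError(ValueError):
    pass


class GffError(ValueError):
    pass


@dataclass
class CodingSequence:
    """A protein-coding DNA sequence tied to its source genome."""

    id: str
    seq: str
    genome: str = ""

    def __post_init__(self) -> None:
        if len(self.seq) < 3:
            raise ValueError(f"{self.id}: CDS shorter than one codon")


@dataclass
class Contig:
    id: str
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """Gene structure on a contig; intervals 1-based inclusive, sorted by start."""

    gene_id: str
    contig_id: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")
        for name, ivs in (("exon", self.exons), ("CDS", self.cds)):
            prev_end = 0
            for start, end in sorted(ivs):
                if end < start:
                    raise ValueError(f"{self.gene_id}: {name} interval end < start")
                if start <= prev_end:
                    raise ValueError(f"{self.gene_id}: overlapping {name} intervals")
                prev_end = end
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)


@dataclass
class ValidationReport:
    """Outcome of CDS validation for one gene."""

    id: str
    status: str  # "ok" or "rejected"
    reason: str = ""
    countable_codons: int = 0
    ambiguous_codons: int = 0
    internal_stops: int = 0
    terminal_stop_removed: bool = False


def _check_sequence(name: str, seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - IUPAC_NT
    if bad:
        raise FastaError(f"record {name!r}: non-nucleotide characters {sorted(bad)}")
    return s


def read_fasta(path: str | os.PathLike, genome: str = "", as_contigs: bool = False):
    """Read a FASTA file into :class:`CodingSequence` (or :class:`Contig`) records.

    Sequences are uppercased and RNA (U) converted to DNA (T).  Raises
    :class:`FastaError` on empty files, duplicate identifiers, or characters
    outside the IUPAC nucleotide alphabet.
    """
    records = []
    seen: set[str] = set()
    label = genome or os.path.splitext(os.path.basename(os.fspath(path)))[0]
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = _check_sequence(rec.id, str(rec.seq))
        if as_contigs:
            if not seq:
                raise FastaError(f"record {rec.id!r} is empty")
            records.append(Contig(id=rec.id, seq=seq))
        else:
            records.append(CodingSequence(id=rec.id, seq=seq, genome=label))
    if not records:
        raise FastaError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def validate_cds(
    cds: CodingSequence, drop_terminal_stop: bool = True
) -> tuple[list[str], ValidationReport]:
    """Split a CDS into countable codons, excluding ambiguous and stop codons.

    Returns the countable codon list plus a :class:`ValidationReport`.  A
    length not divisible by 3, or zero countable codons after filtering,
    yields status ``"rejected"`` and an empty codon list.
    """
    seq = cds.seq
    if len(seq) % 3 != 0:
        return [], ValidationReport(cds.id, "rejected", "length not multiple of 3")
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    terminal_removed = False
    if drop_terminal_stop and codons and codons[-1] in STOPS:
        codons = codons[:-1]
        terminal_removed = True
    countable: list[str] = []
    ambiguous = internal_stops = 0
    for codon in codons:
        if set(codon) - set("ACGT"):
            ambiguous += 1
        elif codon in STOPS:
            internal_stops += 1
        else:
            countable.append(codon)
    if not countable:
        return [], ValidationReport(
            cds.id, "rejected", "no countable codons after filtering",
            ambiguous_codons=ambiguous, internal_stops=internal_stops,
            terminal_stop_removed=terminal_removed,
        )
    return countable, ValidationReport(
        cds.id, "ok", "", len(countable), ambiguous, internal_stops, terminal_removed
    )


def _prescan_gff(path: str | os.PathLike) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GffError(f"{path}:{lineno}: expected 9 tab-separated columns, got {len(cols)}")
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GffError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end < start:
                raise GffError(f"{path}:{lineno}: end < start")


def read_gff(path: str | os.PathLike) -> list[GeneModel]:
    """Parse a GFF3 file into :class:`GeneModel` records.

    gene/mRNA/exon/CDS features are assembled via Parent attributes; exon and
    CDS features attached to an mRNA are assigned to its gene.  Malformed
    lines raise :class:`GffError` with the line number; exon/CDS features
    whose Parent is unknown raise :class:`GffError`.
    """
    import gffutils

    _prescan_gff(path)
    db = gffutils.create_db(
        os.fspath(path), dbfn=":memory:", force=True,
        merge_strategy="create_unique", keep_order=True,
    )
    genes: dict[str, GeneModel] = {}
    parent_of: dict[str, str] = {}  # mRNA id -> gene id
    for g in db.features_of_type("gene"):
        genes[g.id] = GeneModel(gene_id=g.id, contig_id=g.seqid, strand=g.strand)
    for m in db.features_of_type("mRNA"):
        parents = m.attributes.get("Parent", [])
        if parents and parents[0] in genes:
            parent_of[m.id] = parents[0]
        else:
            # mRNA without an annotated gene acts as its own gene record
            genes[m.id] = GeneModel(gene_id=m.id, contig_id=m.seqid, strand=m.strand)
            parent_of[m.id] = m.id
    for ftype, attr in (("exon", "exons"), ("CDS", "cds")):
        for f in db.features_of_type(ftype):
            parents = f.attributes.get("Parent", [])
            if not parents:
                raise GffError(f"{ftype} feature {f.id!r} has no Parent attribute")
            pid = parents[0]
            gid = parent_of.get(pid, pid)
            if gid not in genes:
                raise GffError(f"{ftype} feature {f.id!r} references unknown parent {pid!r}")
            getattr(genes[gid], attr).append((f.start, f.end))
    out = []
    for model in genes.values():
        # re-run interval checks now that exons/CDS are attached
        out.append(
            GeneModel(model.gene_id, model.contig_id, model.strand,
                      exons=model.exons, cds=model.cds)
        )
    return out


def extract_cds(contigs, model: GeneModel, genome: str = "") -> CodingSequence:
    """Concatenate a gene model's CDS intervals into a 5'->3' coding sequence.

    Intervals are concatenated in genomic order and the result is
    reverse-complemented for minus-strand genes so it starts with the 5'
    codon.  Raises :class:`GffError` if the contig is missing or an interval
    falls outside it.
    """
    by_id = {c.id: c for c in contigs}
    if model.contig_id not in by_id:
        raise GffError(f"{model.gene_id}: contig {model.contig_id!r} not found")
    contig = by_id[model.contig_id]
    if not model.cds:
        raise GffError(f"{model.gene_id}: no CDS intervals")
    parts = []
    for start, end in model.cds:
        if start < 1 or end > contig.length:
            raise GffError(
                f"{model.gene_id}: CDS interval [{start}..{end}] outside contig "
                f"{contig.id!r} (length {contig.length})"
            )
        parts.append(contig.seq[start - 1 : end])
    seq = "".join(parts)
    if model.strand == "-":
        seq = str(Seq(seq).reverse_complement())
    return CodingSequence(id=model.gene_id, seq=seq, genome=genome)


def write_validation_report(reports, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tstatus\treason\tcountable_codons\tambiguous_codons\t"
                 "internal_stops\tterminal_stop_removed\n")
        for r in reports:
            fh.write(f"{r.id}\t{r.status}\t{r.reason}\t{r.countable_codons}\t"
                     f"{r.ambiguous_codons}\t{r.internal_stops}\t{r.terminal_stop_removed}\n")
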