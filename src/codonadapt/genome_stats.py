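"""Assembly and annotation summary statistics (contig N50, GC, gene metrics)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqio import Contig, GeneModel


@dataclass
class AssemblyStats:
    total_length: int
    n_contigs: int
    n50: int
    gc: float


@dataclass
class AnnotationStats:
    gene_count: int
    mean_exon_number: float
    mean_gene_length: float
    mean_protein_length: float | None
    cds_fraction: float


def n50(lengths) -> int:
    """Length of the contig at which the descending cumulative sum first
    reaches half the total."""
    lengths = sorted((int(x) for x in lengths), reverse=True)
    if not lengths:
        raise ValueError("no contig lengths")
    half = sum(lengths) / 2.0
    acc = 0
    for length in lengths:
        acc += length
        if acc >= half:
            return length
    raise AssertionError("unreachable")


def assembly_stats(contigs: list[Contig]) -> AssemblyStats:
    """Total length, contig count, N50 and GC of an assembly.

    GC is computed over unambiguous A/C/G/T positions only, so runs of N in
    a draft assembly do not dilute it.
    """
    if not contigs:
        raise ValueError("empty contig set")
    lengths = [c.length for c in contigs]
    gc = acgt = 0
    for c in contigs:
        seq = c.seq
        gc += seq.count("G") + seq.count("C")
        acgt += sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("no unambiguous nucleotides in assembly")
    return AssemblyStats(
        total_length=sum(lengths),
        n_contigs=len(contigs),
        n50=n50(lengths),
        gc=gc / acgt,
    )


def _merged_length(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of 1-based inclusive intervals."""
    if not intervals:
        return 0
    merged = 0
    cur_s, cur_e = None, None
    for s, e in sorted(intervals):
        if cur_e is None or s > cur_e + 1:
            if cur_e is not None:
                merged += cur_e - cur_s + 1
            cur_s, cur_e = s, e
        else:
            cur_e = max(cur_e, e)
    merged += cur_e - cur_s + 1
    return merged


def annotation_stats(
    models: list[GeneModel],
    contigs: list[Contig],
    protein_lengths: list[int] | None = None,
) -> AnnotationStats:
    """Gene-model summary: mean exon number, mean gene span, CDS fraction.

    The CDS fraction uses the merged union of CDS intervals per contig so
    overlapping isoforms are not double-counted.  Mean protein length comes
    from supplied protein lengths when available, else from CDS length / 3
    per gene (terminal stop not subtracted; inputs vary in whether they
    include it).
    """
    if not models:
        raise ValueError("no gene models")
    contig_ids = {c.id for c in contigs}
    dangling = {m.contig_id for m in models} - contig_ids
    if dangling:
        raise ValueError(f"gene models reference unknown contigs: {sorted(dangling)}")
    total_assembly = sum(c.length for c in contigs)
    exon_total = 0
    span_total = 0
    cds_by_contig: dict[str, list[tuple[int, int]]] = {}
    cds_len_per_gene = []
    for m in models:
        ivs = m.exons or m.cds
        exon_total += max(len(m.exons), 1)
        if ivs:
            span_total += max(e for _, e in ivs) - min(s for s, _ in ivs) + 1
        cds_by_contig.setdefault(m.contig_id, []).extend(m.cds)
        cds_len_per_gene.append(sum(e - s + 1 for s, e in m.cds))
    cds_union = sum(_merged_length(ivs) for ivs in cds_by_contig.values())
    if protein_lengths:
        mean_prot = float(np.mean(protein_lengths))
    else:
        coding = [x / 3.0 for x in cds_len_per_gene if x > 0]
        mean_prot = float(np.mean(coding)) if coding else None
    return AnnotationStats(
        gene_count=len(models),
        mean_exon_number=exon_total / len(models),
        mean_gene_length=span_total / len(models),
        mean_protein_length=mean_prot,
        cds_fraction=cds_union / total_assembly,
    )


def stats_table(
    asm: AssemblyStats, ann: AnnotationStats | None = None
) -> pd.DataFrame:
    """Render assembly/annotation statistics as a (metric, value) table,
    with N50/total length in kb/Mb to one decimal."""
    rows = [
        ("Total contigs length (Mb)", round(asm.total_length / 1e6, 1)),
        ("Number of contigs", asm.n_contigs),
        ("Contig N50 (kb)", round(asm.n50 / 1e3, 1)),
        ("GC (%) genome", round(asm.gc * 100, 1)),
    ]
    if ann is not None:
        rows += [
            ("Percentage of CDS (%)", round(ann.cds_fraction * 100, 1)),
            ("Protein-coding gene number", ann.gene_count),
            ("Mean exon number per gene", round(ann.mean_exon_number, 1)),
            ("Mean gene length (bp)", round(ann.mean_gene_length, 1)),
        ]
        if ann.mean_protein_length is not None:
            rows.append(("Mean protein length (amino acid)",
                         round(ann.mean_protein_length, 1)))
    return pd.DataFrame(rows, columns=["metric", "value"])
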