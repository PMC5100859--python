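"""Codon counting, RSCU, composition, and the effective number of codons.

Implements Wright's Nc from per-family codon homozygosities and its
background-corrected analogue Nc', in which the homozygosity is replaced by
a chi-square deviation from codon frequencies expected under the gene's
(or a supplied) position-specific nucleotide composition.  Nc runs from 20
(one codon per amino acid) to 61 (uniform synonymous usage); low values mean
strong bias.

Definitions, for a synonymous family of size k with counts X_i summing to n
(p_i = X_i / n):

    F   = (n * sum p_i^2 - 1) / (n - 1)
    chi2 = sum_i (X_i - n e_i)^2 / (n e_i)        over members with e_i > 0
    F'  = (chi2 + n - k) / (k * (n - 1))
    Nc  = 2 + 9/Fbar_2 + 1/Fbar_3 + 5/Fbar_4 + 3/Fbar_6

where e_i are the expected within-family frequencies and Fbar_k averages the
usable (n >= 2) families of degeneracy class k.  With uniform e the
correction vanishes and F' equals F exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_code import (
    BASES,
    CODON_INDEX,
    CODON_TO_AA,
    CODONS,
    CLASSES,
    DEGENERACY,
    FAMILIES,
    MULTI_FAMILIES,
    SENSE_CODONS,
)
from .seqio import CodingSequence, validate_cds

#: genes with fewer sense codons than this are flagged "short" (not excluded)
SHORT_GENE_CODONS = 30

_SENSE_IDX = np.array([CODON_INDEX[c] for c in SENSE_CODONS])
_FAMILY_IDX = {aa: np.array([CODON_INDEX[c] for c in fam]) for aa, fam in FAMILIES.items()}


@dataclass
class CodonCounts:
    """64-long codon count vector for a gene or a genome aggregate."""

    unit_id: str
    genome: str
    counts: np.ndarray  # length 64, order genetic_code.CODONS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (64,):
            raise ValueError("counts must be a length-64 vector")
        if (self.counts < 0).any():
            raise ValueError("negative codon counts")

    @property
    def total(self) -> int:
        """Total sense-codon count."""
        return int(self.counts[_SENSE_IDX].sum())

    def family_counts(self, aa: str) -> np.ndarray:
        return self.counts[_FAMILY_IDX[aa]]


@dataclass
class RSCUVector:
    """RSCU per sense codon in families with k >= 2; zero-usage families flagged."""

    unit_id: str
    rscu: dict[str, float]
    missing_families: frozenset[str] = frozenset()


@dataclass
class CompositionStats:
    gc: float
    gc1: float
    gc2: float
    gc3: float
    aa_freq: dict[str, float]


@dataclass
class EncResult:
    """Per-gene effective number of codons, plain and composition-corrected."""

    unit_id: str
    nc: float | None
    nc_prime: float | None
    fbar: dict[int, float] = field(default_factory=dict)
    fbar_prime: dict[int, float] = field(default_factory=dict)
    n_families_used: dict[int, int] = field(default_factory=dict)
    n_codons: int = 0
    flags: list[str] = field(default_factory=list)
    reason: str = ""


def count_codons(
    cds: CodingSequence | list[str], genome: str = "", unit_id: str = ""
) -> CodonCounts:
    """Count codons of a validated CDS (or a pre-validated codon list)."""
    if isinstance(cds, CodingSequence):
        codons, report = validate_cds(cds)
        if report.status != "ok":
            raise ValueError(f"{cds.id}: {report.reason}")
        unit_id = unit_id or cds.id
        genome = genome or cds.genome
    else:
        codons = cds
    counts = np.zeros(64, dtype=np.int64)
    for codon in codons:
        counts[CODON_INDEX[codon]] += 1
    return CodonCounts(unit_id=unit_id, genome=genome, counts=counts)


def aggregate_counts(per_gene: list[CodonCounts], unit_id: str = "") -> CodonCounts:
    """Element-wise sum of per-gene counts from a single genome."""
    if not per_gene:
        raise ValueError("cannot aggregate an empty collection")
    genomes = {c.genome for c in per_gene}
    if len(genomes) > 1:
        raise ValueError(f"mixed genome labels in aggregation: {sorted(genomes)}")
    total = np.sum([c.counts for c in per_gene], axis=0)
    genome = per_gene[0].genome
    return CodonCounts(unit_id=unit_id or genome, genome=genome, counts=total)


def rscu(counts: CodonCounts) -> RSCUVector:
    """Relative synonymous codon usage: RSCU_i = k * X_i / family total.

    One-fold families (Met, Trp) and stop codons are excluded.  Families with
    zero usage are reported as missing rather than zero.
    """
    values: dict[str, float] = {}
    missing: set[str] = set()
    for aa in MULTI_FAMILIES:
        fam = FAMILIES[aa]
        x = counts.family_counts(aa)
        t = x.sum()
        if t == 0:
            missing.add(aa)
            continue
        k = len(fam)
        for codon, xi in zip(fam, x):
            values[codon] = k * xi / t
    return RSCUVector(unit_id=counts.unit_id, rscu=values, missing_families=frozenset(missing))


def composition(source: CodingSequence | CodonCounts | list[str]) -> CompositionStats:
    """GC, positional GC1/2/3 and amino-acid frequencies of a coding sequence."""
    if isinstance(source, CodonCounts):
        counts = source
    else:
        counts = count_codons(source)
    n = counts.counts.sum()
    if n == 0:
        raise ValueError("zero counted codons")
    pos_gc = np.zeros(3)
    gc_total = 0
    aa_counts: dict[str, int] = {}
    for codon, idx in CODON_INDEX.items():
        x = counts.counts[idx]
        if x == 0:
            continue
        for p, base in enumerate(codon):
            if base in "GC":
                pos_gc[p] += x
                gc_total += x
        aa = CODON_TO_AA[codon]
        if aa != "*":
            aa_counts[aa] = aa_counts.get(aa, 0) + int(x)
    total_aa = sum(aa_counts.values())
    aa_freq = {aa: c / total_aa for aa, c in sorted(aa_counts.items())}
    return CompositionStats(
        gc=gc_total / (3 * n),
        gc1=pos_gc[0] / n, gc2=pos_gc[1] / n, gc3=pos_gc[2] / n,
        aa_freq=aa_freq,
    )


def gc_fraction(seq: str) -> float:
    """GC over unambiguous A/C/G/T positions only (Ns excluded from both sides)."""
    acgt = sum(seq.count(b) for b in BASES)
    if acgt == 0:
        raise ValueError("no unambiguous nucleotides")
    return (seq.count("G") + seq.count("C")) / acgt


def family_homozygosity(x: np.ndarray) -> float | None:
    """Wright's within-family homozygosity F = (n*sum p^2 - 1)/(n - 1).

    Returns ``None`` ("unusable") for family totals below 2.
    """
    x = np.asarray(x, dtype=float)
    n = x.sum()
    if n < 2:
        return None
    p = x / n
    return float((n * (p ** 2).sum() - 1.0) / (n - 1.0))


def expected_family_frequencies(background: np.ndarray, aa: str) -> np.ndarray | None:
    """Within-family codon frequencies expected under a positional background.

    ``background`` is a 3x4 matrix of nucleotide frequencies (rows = codon
    positions, columns in A,C,G,T order), each row summing to 1.  The
    expected frequency of a codon is the product of its positional
    frequencies, renormalized over the family.  Returns ``None`` when the
    background assigns zero to every family member.
    """
    background = np.asarray(background, dtype=float)
    if background.shape != (3, 4):
        raise ValueError("background must be 3x4 (positions x ACGT)")
    if not np.allclose(background.sum(axis=1), 1.0, atol=1e-8):
        raise ValueError("each background row must sum to 1")
    base_idx = {b: i for i, b in enumerate(BASES)}
    fam = FAMILIES[aa]
    e = np.array(
        [np.prod([background[p, base_idx[c[p]]] for p in range(3)]) for c in fam]
    )
    s = e.sum()
    if s == 0:
        return None
    return e / s


def corrected_homozygosity(x: np.ndarray, expected: np.ndarray) -> float | None:
    """Composition-corrected homozygosity F' = (chi2 + n - k) / (k (n - 1)).

    The chi-square deviation is taken against the expected within-family
    frequencies; with uniform expectations F' reduces exactly to F.
    Returns ``None`` for family totals below 2.
    """
    x = np.asarray(x, dtype=float)
    expected = np.asarray(expected, dtype=float)
    n = x.sum()
    if n < 2:
        return None
    k = len(x)
    mask = expected > 0
    chi2 = float((((x - n * expected) ** 2)[mask] / (n * expected[mask])).sum())
    return (chi2 + n - k) / (k * (n - 1.0))


def wright_combination(fbar: dict[int, float], flags: list[str] | None = None) -> float:
    """Wright's combination Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6.

    ``fbar`` maps degeneracy class -> mean homozygosity.  A missing Ile
    class is imputed as (F2 + F4)/2 and a missing six-fold class by the
    four-fold mean; both imputations are appended to ``flags``.  The result
    is clamped to [20, 61].
    """
    if flags is None:
        flags = []
    f2, f4 = fbar.get(2), fbar.get(4)
    if f2 is None or f4 is None:
        raise ValueError("no usable two-fold or four-fold families")
    f3 = fbar.get(3)
    if f3 is None:
        f3 = (f2 + f4) / 2.0
        fbar[3] = f3
        flags.append("imputed_F3")
    f6 = fbar.get(6)
    if f6 is None:
        f6 = f4
        fbar[6] = f6
        flags.append("imputed_F6")
    value = 2.0 + 9.0 / f2 + 1.0 / f3 + 5.0 / f4 + 3.0 / f6
    return float(min(max(value, 20.0), 61.0))


def nc(counts: CodonCounts) -> EncResult:
    """Wright's effective number of codons for one gene's codon counts."""
    return enc(counts, background=None)


def positional_background(counts: CodonCounts) -> np.ndarray:
    """3x4 positional nucleotide frequencies implied by a codon count vector."""
    freq = np.zeros((3, 4))
    base_idx = {b: i for i, b in enumerate(BASES)}
    for codon, idx in CODON_INDEX.items():
        x = counts.counts[idx]
        if x == 0:
            continue
        for p in range(3):
            freq[p, base_idx[codon[p]]] += x
    total = counts.counts.sum()
    if total == 0:
        raise ValueError("zero counted codons")
    return freq / total


def enc(counts: CodonCounts, background: np.ndarray | str | None = "gene") -> EncResult:
    """Compute Nc and (optionally) Nc' for one gene.

    ``background`` selects the composition correction: ``"gene"`` derives
    positional nucleotide frequencies from the gene itself, a 3x4 array
    supplies an external (e.g. genome-wide) background, and ``None`` skips
    the corrected statistic.  Genes with no usable two-fold or four-fold
    family are excluded with a reason.
    """
    flags: list[str] = []
    n_codons = counts.total
    if n_codons < SHORT_GENE_CODONS:
        flags.append("short")
    if isinstance(background, str):
        if background != "gene":
            raise ValueError(f"unknown background option {background!r}")
        bg = positional_background(counts)
    else:
        bg = background

    per_class_f: dict[int, list[float]] = {k: [] for k in (2, 3, 4, 6)}
    per_class_fp: dict[int, list[float]] = {k: [] for k in (2, 3, 4, 6)}
    for k in (2, 3, 4, 6):
        for aa in CLASSES[k]:
            x = counts.family_counts(aa)
            f = family_homozygosity(x)
            # F = 0 (every observed codon used exactly once) carries no
            # usable bias signal and would blow up 1/Fbar; treat as unusable
            if f is None or f <= 0:
                continue
            per_class_f[k].append(f)
            if bg is not None:
                e = expected_family_frequencies(bg, aa)
                if e is None:
                    continue
                fp = corrected_homozygosity(x, e)
                if fp is not None and fp > 0:
                    per_class_fp[k].append(fp)

    fbar = {k: float(np.mean(v)) for k, v in per_class_f.items() if v}
    n_used = {k: len(v) for k, v in per_class_f.items()}
    try:
        nc_value = wright_combination(fbar, flags)
    except ValueError as exc:
        return EncResult(counts.unit_id, None, None, fbar, {}, n_used,
                         n_codons, flags, reason=str(exc))

    nc_prime_value = None
    fbar_p: dict[int, float] = {}
    if bg is not None:
        fbar_p = {k: float(np.mean(v)) for k, v in per_class_fp.items() if v}
        flags_p: list[str] = []
        try:
            nc_prime_value = wright_combination(fbar_p, flags_p)
        except ValueError:
            nc_prime_value = None
            flags.append("nc_prime_unavailable")
        flags.extend(f"{f}_prime" for f in flags_p)
    return EncResult(counts.unit_id, nc_value, nc_prime_value, fbar, fbar_p,
                     n_used, n_codons, flags)


def gene_metrics_table(
    sequences: list[CodingSequence], background: np.ndarray | str | None = "gene"
) -> pd.DataFrame:
    """Per-gene metrics table: composition, Nc, Nc' and QC flags."""
    rows = []
    for cds in sequences:
        codons, report = validate_cds(cds)
        if report.status != "ok":
            rows.append({"gene": cds.id, "genome": cds.genome, "status": report.reason})
            continue
        counts = count_codons(codons, genome=cds.genome, unit_id=cds.id)
        comp = composition(counts)
        res = enc(counts, background=background)
        rows.append({
            "gene": cds.id, "genome": cds.genome, "status": "ok",
            "n_codons": counts.total,
            "gc": comp.gc, "gc1": comp.gc1, "gc2": comp.gc2, "gc3": comp.gc3,
            "nc": res.nc, "nc_prime": res.nc_prime,
            "flags": ";".join(res.flags) if res.flags else "",
        })
    return pd.DataFrame(rows)


def genome_rscu_table(per_gene: list[CodonCounts], genome: str) -> pd.DataFrame:
    """Pooled-genome RSCU table (codon, amino acid, RSCU)."""
    pooled = aggregate_counts(per_gene, unit_id=genome)
    vec = rscu(pooled)
    rows = [
        {"genome": genome, "codon": c, "amino_acid": CODON_TO_AA[c],
         "rscu": vec.rscu.get(c, float("nan"))}
        for c in CODONS
        if CODON_TO_AA[c] != "*" and DEGENERACY[CODON_TO_AA[c]] >= 2
    ]
    return pd.DataFrame(rows)
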