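"""Synthetic data with the statistical structure the analyses assume.

Three generators, all pure functions of (config, seed):

* coding-sequence sets for several genomes, with a controllable GC3 target
  and a planted preferred codon per synonymous family whose usage rises
  with a per-gene expression covariate — so codon bias correlates
  negatively with Nc exactly the way translational selection would produce;
* random contig sets with known length statistics for assembly-metric
  checks;
* paired transcript/protein fold-change tables with per-pathway Spearman
  correlations planted through a Gaussian copula.

For a gene ranked r (1..M) by expression, the bias weight is
w = w_max * (r - 1) / (M - 1), and within each family the codon
distribution is (1 - w) * q + w * delta(planted codon), where the baseline
q splits the genome's GC3 target evenly among G/C-ending members and
(1 - GC3) among A/T-ending members.  Expression enters only through rank,
matching the rank-based detection statistic downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import FAMILIES, MULTI_FAMILIES
from .seqio import CodingSequence, Contig


@dataclass
class GenomeSimConfig:
    """Study-scale defaults: a handful of genomes on a GC3 gradient, 2000
    genes each, moderate planted bias."""

    n_genomes: int = 5
    genes_per_genome: int = 2000
    length_range: tuple[int, int] = (100, 600)  # body length in codons
    gc3_targets: tuple[float, ...] | None = None  # default: linspace(0.3, 0.8)
    w_max: float = 0.6
    expression_mu: float = 0.0
    expression_sigma: float = 1.0
    aa_weights: dict[str, float] | None = None  # default uniform over 20
    planted: dict[str, dict[str, str]] | None = None  # genome -> aa -> codon
    seed: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_max <= 1.0:
            raise ValueError("w_max must lie in [0, 1]")
        if self.gc3_targets is None:
            self.gc3_targets = tuple(
                np.linspace(0.3, 0.8, self.n_genomes)
            ) if self.n_genomes > 1 else (0.55,)
        if len(self.gc3_targets) != self.n_genomes:
            raise ValueError("need one GC3 target per genome")
        if any(not 0.0 < g < 1.0 for g in self.gc3_targets):
            raise ValueError("GC3 targets must lie in (0, 1)")


def _baseline_q(aa: str, gc3: float) -> np.ndarray:
    fam = FAMILIES[aa]
    gc_end = np.array([c[2] in "GC" for c in fam])
    n_gc, n_at = int(gc_end.sum()), int((~gc_end).sum())
    if n_gc == 0 or n_at == 0:
        return np.full(len(fam), 1.0 / len(fam))
    q = np.where(gc_end, gc3 / n_gc, (1.0 - gc3) / n_at)
    return q / q.sum()


def simulate_genome_set(
    config: GenomeSimConfig,
) -> tuple[dict[str, list[CodingSequence]], pd.DataFrame, pd.DataFrame]:
    """Generate CDS sets for each genome plus planted-truth tables.

    Returns ``(sequences by genome, genome truth, gene truth)`` where the
    genome truth lists the planted codon per family and the gene truth the
    expression value and bias weight per gene.  Sequences carry an ATG
    start and a TAA terminal stop around the sampled body.
    """
    rng = np.random.default_rng(config.seed)
    aas = list(FAMILIES)
    if config.aa_weights is None:
        weights = np.full(len(aas), 1.0 / len(aas))
    else:
        weights = np.array([config.aa_weights.get(a, 0.0) for a in aas], float)
        if weights.sum() <= 0:
            raise ValueError("aa_weights must have positive total")
        weights = weights / weights.sum()

    genomes: dict[str, list[CodingSequence]] = {}
    genome_truth_rows = []
    gene_truth_rows = []
    for gi in range(config.n_genomes):
        label = f"genome{gi + 1:02d}"
        gc3 = float(config.gc3_targets[gi])
        planted: dict[str, str] = {}
        for aa in MULTI_FAMILIES:
            fam = FAMILIES[aa]
            if config.planted and aa in config.planted.get(label, {}):
                codon = config.planted[label][aa]
                if codon not in fam:
                    raise ValueError(f"{codon} is not a {aa} codon")
            else:
                codon = fam[rng.integers(len(fam))]
            planted[aa] = codon
            genome_truth_rows.append(
                {"genome": label, "amino_acid": aa, "planted_codon": codon}
            )
        baseline = {aa: _baseline_q(aa, gc3) for aa in FAMILIES}
        M = config.genes_per_genome
        expr = rng.lognormal(config.expression_mu, config.expression_sigma, M)
        ranks = stats.rankdata(expr)
        w_all = (
            config.w_max * (ranks - 1.0) / (M - 1.0) if M > 1
            else np.full(M, config.w_max)
        )
        lengths = rng.integers(config.length_range[0], config.length_range[1] + 1, M)
        seqs = []
        for m in range(M):
            gene_id = f"{label}_g{m + 1:05d}"
            w = float(w_all[m])
            L = int(lengths[m])
            aa_idx = rng.choice(len(aas), size=L, p=weights)
            codons = np.empty(L, dtype=object)
            for ai in np.unique(aa_idx):
                aa = aas[ai]
                fam = FAMILIES[aa]
                pos = np.where(aa_idx == ai)[0]
                if len(fam) == 1:
                    codons[pos] = fam[0]
                else:
                    p = (1.0 - w) * baseline[aa] + w * np.array(
                        [c == planted[aa] for c in fam], float
                    )
                    picks = rng.choice(len(fam), size=len(pos), p=p)
                    codons[pos] = [fam[j] for j in picks]
            seq = "ATG" + "".join(codons) + "TAA"
            seqs.append(CodingSequence(id=gene_id, seq=seq, genome=label))
            gene_truth_rows.append({
                "genome": label, "gene": gene_id,
                "expression": float(expr[m]), "bias_weight": w,
                "length_codons": L,
            })
        genomes[label] = seqs
    return genomes, pd.DataFrame(genome_truth_rows), pd.DataFrame(gene_truth_rows)


def simulate_contigs(
    n: int,
    length_range: tuple[int, int] = (1000, 50000),
    gc: float = 0.5,
    seed: int = 1,
    lengths: list[int] | None = None,
) -> tuple[list[Contig], dict]:
    """Random contigs with known total length and N50.

    ``lengths`` pins the length multiset exactly; otherwise lengths are
    uniform over ``length_range``.  Base composition is i.i.d. with the
    requested GC fraction.
    """
    from .genome_stats import n50 as _n50

    if n < 1:
        raise ValueError("need at least one contig")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if lengths is None:
        lengths = list(rng.integers(length_range[0], length_range[1] + 1, n))
    elif len(lengths) != n:
        raise ValueError("lengths must have n entries")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    contigs = [
        Contig(id=f"contig{i + 1:04d}",
               seq="".join(bases[rng.choice(4, size=int(L), p=p)]))
        for i, L in enumerate(lengths)
    ]
    expected = {
        "total_length": int(sum(lengths)),
        "n_contigs": n,
        "n50": _n50(lengths),
        "gc_target": gc,
    }
    return contigs, expected


def spearman_to_pearson(rho_s: float) -> float:
    """Bivariate-normal Pearson correlation whose population Spearman is
    ``rho_s``: rho_p = 2 sin(pi rho_s / 6)."""
    return float(2.0 * np.sin(np.pi * rho_s / 6.0))


def simulate_omics_tables(
    n_genes: int = 1000,
    pathway_sizes: dict[str, int] | None = None,
    target_rho: dict[str, float] | None = None,
    deg_fraction: float = 0.3,
    fc_sigma: float = 1.0,
    seed: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Paired transcript/protein tables with planted per-pathway Spearman
    correlations.

    Pathway members' (log2 transcript FC, log2 protein FC) pairs are drawn
    from a bivariate normal whose Pearson correlation is chosen so the
    population Spearman equals the target; genes outside any pathway are
    uncorrelated.  Transcript P values are assigned so that ``deg_fraction``
    of genes pass the 0.001 DEG cutoff.  Returns ``(transcripts, proteins,
    pathway map, truth)``.
    """
    pathway_sizes = pathway_sizes or {"pw1": 200, "pw2": 200}
    target_rho = target_rho or {pid: 0.7 for pid in pathway_sizes}
    if any(s < 1 for s in pathway_sizes.values()):
        raise ValueError("pathway sizes must be positive")
    if any(abs(r) >= 1 for r in target_rho.values()):
        raise ValueError("target Spearman correlations must satisfy |rho| < 1")
    if sum(pathway_sizes.values()) > n_genes:
        raise ValueError("pathways cannot cover more than n_genes genes")
    rng = np.random.default_rng(seed)
    genes = [f"g{i + 1:05d}" for i in range(n_genes)]
    log_t = np.empty(n_genes)
    log_p = np.empty(n_genes)
    pathway_rows = []
    truth_rows = []
    start = 0
    for pid, size in pathway_sizes.items():
        rho_s = float(target_rho.get(pid, 0.0))
        rho_p = spearman_to_pearson(rho_s)
        cov = fc_sigma ** 2 * np.array([[1.0, rho_p], [rho_p, 1.0]])
        draw = rng.multivariate_normal([0.0, 0.0], cov, size=size)
        log_t[start : start + size] = draw[:, 0]
        log_p[start : start + size] = draw[:, 1]
        for g in genes[start : start + size]:
            pathway_rows.append({"pathway_id": pid, "gene_id": g})
        truth_rows.append({"pathway_id": pid, "size": size,
                           "target_rho_spearman": rho_s,
                           "pearson_used": rho_p})
        start += size
    rest = n_genes - start
    if rest:
        log_t[start:] = rng.normal(0.0, fc_sigma, rest)
        log_p[start:] = rng.normal(0.0, fc_sigma, rest)
    n_deg = int(round(deg_fraction * n_genes))
    p_values = np.empty(n_genes)
    deg_idx = rng.choice(n_genes, size=n_deg, replace=False)
    mask = np.zeros(n_genes, bool)
    mask[deg_idx] = True
    p_values[mask] = rng.uniform(0.0, 0.001, n_deg)
    p_values[~mask] = rng.uniform(0.0011, 1.0, n_genes - n_deg)
    transcripts = pd.DataFrame({
        "gene": genes,
        "fpkm_reference": rng.lognormal(2.0, 1.5, n_genes),
        "fold_change": 2.0 ** log_t,
        "p_value": p_values,
        "fdr": stats.false_discovery_control(p_values),
    })
    proteins = pd.DataFrame({
        "gene": genes,
        "fold_change": 2.0 ** log_p,
        "unique_peptides": rng.integers(1, 15, n_genes),
        "fdr": rng.uniform(0.0, 0.02, n_genes),
    })
    return transcripts, proteins, pd.DataFrame(pathway_rows), pd.DataFrame(truth_rows)
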