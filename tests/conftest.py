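import numpy as np
import pytest

from codonadapt.codon_metrics import count_codons
from codonadapt.seqio import validate_cds
from codonadapt.simulate import GenomeSimConfig, simulate_genome_set


def counts_from_seq(seq: str, unit_id: str = "g", genome: str = "sim"):
    """CodonCounts straight from a raw in-frame sequence string."""
    from codonadapt.seqio import CodingSequence

    codons, report = validate_cds(CodingSequence(unit_id, seq, genome))
    assert report.status == "ok", report.reason
    return count_codons(codons, genome=genome, unit_id=unit_id)


def counts_from_family_dict(fam_counts: dict[str, int], unit_id: str = "g"):
    """CodonCounts with explicit per-codon counts, everything else zero."""
    from codonadapt.codon_metrics import CodonCounts
    from codonadapt.genetic_code import CODON_INDEX

    vec = np.zeros(64, dtype=np.int64)
    for codon, x in fam_counts.items():
        vec[CODON_INDEX[codon]] = x
    return CodonCounts(unit_id=unit_id, genome="sim", counts=vec)


@pytest.fixture(scope="session")
def small_genome_set():
    """One simulated genome, 300 genes, moderate planted bias (shared
    read-only across tests)."""
    config = GenomeSimConfig(n_genomes=1, genes_per_genome=300, w_max=0.6, seed=11)
    genomes, genome_truth, gene_truth = simulate_genome_set(config)
    return config, genomes, genome_truth, gene_truth


@pytest.fixture(scope="session")
def small_genome_counts(small_genome_set):
    _, genomes, _, _ = small_genome_set
    out = {}
    for label, seqs in genomes.items():
        out[label] = [
            count_codons(validate_cds(s)[0], genome=label, unit_id=s.id) for s in seqs
        ]
    return out
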