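import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from codonadapt.codon_metrics import (
    aggregate_counts,
    composition,
    corrected_homozygosity,
    count_codons,
    enc,
    expected_family_frequencies,
    family_homozygosity,
    positional_background,
    rscu,
    wright_combination,
)
from codonadapt.genetic_code import (
    CLASSES,
    DEGENERACY,
    FAMILIES,
    INFORMATIVE_CODONS,
    MULTI_FAMILIES,
    SENSE_CODONS,
)
from codonadapt.seqio import CodingSequence, validate_cds

from conftest import counts_from_family_dict, counts_from_seq

UNIFORM_BG = np.full((3, 4), 0.25)


def test_standard_code_family_structure():
    """Degeneracy classes of the standard code partition the 61 sense codons
    as (2, 9, 1, 5, 3) one/two/three/four/six-fold families."""
    assert len(SENSE_CODONS) == 61
    assert tuple(len(CLASSES[k]) for k in (1, 2, 3, 4, 6)) == (2, 9, 1, 5, 3)
    assert sum(DEGENERACY[aa] for aa in FAMILIES) == 61
    assert len(INFORMATIVE_CODONS) == 59
    assert len(MULTI_FAMILIES) == 18


class TestCounting:
    def test_direct_count(self):
        c = counts_from_seq("ATGTTTTTC")
        assert c.total == 3
        assert c.family_counts("F").tolist() == [1, 1]  # TTC, TTT

    def test_terminal_stop_not_counted(self):
        c = counts_from_seq("ATGAAATAA")
        assert c.total == 2

    def test_invalid_cds_raises(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            count_codons(CodingSequence("g", "ATGAA"))

    def test_aggregate_additivity_and_identity(self):
        a = counts_from_seq("ATGAAA", unit_id="a")
        b = counts_from_seq("ATGAAA", unit_id="b")
        agg = aggregate_counts([a, b])
        assert agg.family_counts("K").sum() == 2
        single = aggregate_counts([a])
        assert (single.counts == a.counts).all()

    def test_aggregate_empty_or_mixed_rejected(self):
        with pytest.raises(ValueError):
            aggregate_counts([])
        a = counts_from_seq("ATGAAA", genome="g1")
        b = counts_from_seq("ATGAAA", genome="g2")
        with pytest.raises(ValueError, match="mixed genome"):
            aggregate_counts([a, b])


class TestRscu:
    def test_phe_family_three_one(self):
        c = counts_from_family_dict({"TTT": 3, "TTC": 1})
        v = rscu(c)
        assert v.rscu["TTT"] == pytest.approx(1.5)
        assert v.rscu["TTC"] == pytest.approx(0.5)

    def test_uniform_usage_gives_all_ones(self):
        c = counts_from_family_dict({codon: 2 for codon in INFORMATIVE_CODONS})
        v = rscu(c)
        assert all(x == pytest.approx(1.0) for x in v.rscu.values())

    def test_single_codon_four_fold(self):
        c = counts_from_family_dict({"GGA": 8})
        v = rscu(c)
        assert v.rscu["GGA"] == pytest.approx(4.0)
        assert v.rscu["GGT"] == v.rscu["GGC"] == v.rscu["GGG"] == 0.0

    def test_zero_usage_family_flagged_missing(self):
        c = counts_from_family_dict({"TTT": 3, "TTC": 1})
        v = rscu(c)
        assert "G" in v.missing_families
        assert "GGA" not in v.rscu

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(0, 50), min_size=59, max_size=59))
    def test_family_sums_equal_family_size(self, raw):
        c = counts_from_family_dict(dict(zip(INFORMATIVE_CODONS, raw)))
        v = rscu(c)
        for aa in MULTI_FAMILIES:
            fam = FAMILIES[aa]
            if aa in v.missing_families:
                continue
            assert sum(v.rscu[x] for x in fam) == pytest.approx(len(fam), abs=1e-9)

    def test_aggregate_then_rscu_equals_concatenated_gene(self):
        a = counts_from_seq("ATGTTTGGAGGTTAA", unit_id="a")
        b = counts_from_seq("ATGTTCGGAGGATAA", unit_id="b")
        concat = counts_from_seq("ATGTTTGGAGGTATGTTCGGAGGA", unit_id="ab")
        v1 = rscu(aggregate_counts([a, b]))
        v2 = rscu(concat)
        assert v1.rscu == pytest.approx(v2.rscu)


class TestComposition:
    def test_hand_counted_gc_positions(self):
        stats = composition(counts_from_seq("ATGGCA"))
        assert (stats.gc1, stats.gc2, stats.gc3) == (0.5, 0.5, 0.5)

    def test_all_gc(self):
        stats = composition(counts_from_seq("GGGGGG"))
        assert stats.gc == stats.gc1 == stats.gc2 == stats.gc3 == 1.0

    def test_poly_gly_aa_freq(self):
        stats = composition(counts_from_seq("GGAGGTGGCGGG"))
        assert stats.aa_freq == {"G": 1.0}

    def test_aa_freq_sums_to_one(self):
        stats = composition(counts_from_seq("ATGTTTGGACGATAA"))
        assert sum(stats.aa_freq.values()) == pytest.approx(1.0)


class TestHomozygosity:
    def test_maximal_bias(self):
        assert family_homozygosity(np.array([5, 0])) == pytest.approx(1.0)

    def test_even_counts(self):
        assert family_homozygosity(np.array([2, 2])) == pytest.approx(1 / 3)

    def test_single_observation_unusable(self):
        assert family_homozygosity(np.array([1, 0])) is None

    @settings(max_examples=100, derandomize=True)
    @given(
        st.lists(st.integers(0, 30), min_size=2, max_size=6).filter(
            lambda x: sum(x) >= 2
        ),
        st.integers(0, 5),
    )
    def test_concentration_never_decreases_f(self, counts, _):
        """Moving a count from a smaller to the largest entry (majorization
        step) never decreases F."""
        x = np.array(counts, dtype=int)
        f0 = family_homozygosity(x)
        donors = np.where((x > 0) & (x < x.max()))[0]
        if donors.size == 0:
            return
        y = x.copy()
        y[donors[0]] -= 1
        y[np.argmax(x)] += 1
        f1 = family_homozygosity(y)
        assert f1 >= f0 - 1e-12


class TestCorrectedHomozygosity:
    def test_uniform_expected_reduces_to_f(self):
        x = np.array([2, 2])
        assert corrected_homozygosity(x, np.array([0.5, 0.5])) == pytest.approx(1 / 3)

    def test_fully_biased_uniform_expected(self):
        assert corrected_homozygosity(
            np.array([4, 0]), np.array([0.5, 0.5])
        ) == pytest.approx(1.0)

    def test_skewed_expected_reduces_apparent_bias(self):
        fp = corrected_homozygosity(np.array([4, 0]), np.array([0.8, 0.2]))
        assert fp == pytest.approx(0.5)

    def test_below_two_unusable(self):
        assert corrected_homozygosity(np.array([1, 0]), np.array([0.5, 0.5])) is None

    @settings(max_examples=200, derandomize=True)
    @given(
        st.lists(st.integers(0, 100), min_size=2, max_size=6).filter(
            lambda x: sum(x) >= 2
        )
    )
    def test_identity_with_f_under_uniform(self, counts):
        x = np.array(counts, dtype=float)
        k = len(x)
        f = family_homozygosity(x)
        fp = corrected_homozygosity(x, np.full(k, 1.0 / k))
        assert fp == pytest.approx(f, abs=1e-12)


class TestExpectedFrequencies:
    def test_uniform_background_uniform_expected(self):
        for aa in ("F", "G", "L"):
            e = expected_family_frequencies(UNIFORM_BG, aa)
            assert e == pytest.approx(np.full(len(FAMILIES[aa]), 1 / len(FAMILIES[aa])))

    def test_glu_family_hand_normalization(self):
        bg = np.array([
            [0.25, 0.25, 0.25, 0.25],
            [0.25, 0.25, 0.25, 0.25],
            [0.10, 0.25, 0.40, 0.25],  # f(A)=0.1, f(G)=0.4 at position 3
        ])
        e = expected_family_frequencies(bg, "E")  # GAA, GAG
        assert e == pytest.approx([0.2, 0.8])

    def test_invalid_background_rejected(self):
        with pytest.raises(ValueError):
            expected_family_frequencies(np.ones((3, 4)), "E")


class TestNc:
    def test_formula_lower_bound(self):
        assert wright_combination({2: 1.0, 3: 1.0, 4: 1.0, 6: 1.0}) == 20.0

    def test_formula_plug_in(self):
        assert wright_combination({2: 1.0, 3: 1.0, 4: 0.5, 6: 1.0}) == 25.0

    def test_cap_at_61(self):
        assert wright_combination({2: 0.2, 3: 0.2, 4: 0.2, 6: 0.2}) == 61.0

    def test_imputations_logged(self):
        flags = []
        value = wright_combination({2: 0.5, 4: 0.5}, flags)
        assert value == pytest.approx(2 + 9 / 0.5 + 1 / 0.5 + 5 / 0.5 + 3 / 0.5)
        assert "imputed_F3" in flags and "imputed_F6" in flags

    def test_maximally_biased_gene_nc_20(self):
        # one codon per family, each used many times
        fam_counts = {FAMILIES[aa][0]: 10 for aa in FAMILIES}
        res = enc(counts_from_family_dict(fam_counts), background=UNIFORM_BG)
        assert res.nc == pytest.approx(20.0)
        assert res.nc_prime == pytest.approx(20.0)
        # under the gene's own background the bias is entirely compositional,
        # so the corrected statistic absorbs it: Nc' well above Nc
        res_own = enc(counts_from_family_dict(fam_counts), background="gene")
        assert res_own.nc_prime > res_own.nc

    def test_gene_without_usable_families_excluded_with_reason(self):
        res = enc(counts_from_family_dict({"ATG": 5}))
        assert res.nc is None and "two-fold or four-fold" in res.reason

    def test_uniform_background_gives_nc_prime_equal_nc(self, small_genome_counts):
        for counts in list(small_genome_counts.values())[0][:50]:
            res = enc(counts, background=UNIFORM_BG)
            assert res.nc_prime == pytest.approx(res.nc, abs=1e-9)

    def test_bounds_hold_on_simulated_genes(self, small_genome_counts):
        for counts in list(small_genome_counts.values())[0]:
            res = enc(counts)
            if res.nc is not None:
                assert 20.0 <= res.nc <= 61.0
            if res.nc_prime is not None:
                assert 20.0 <= res.nc_prime <= 61.0

    def test_composition_driven_bias_absorbed_by_correction(self):
        """A strongly GC3-skewed but otherwise unselected gene should look
        less biased after the composition correction (Nc' >= Nc on average)."""
        from codonadapt.simulate import GenomeSimConfig, simulate_genome_set

        config = GenomeSimConfig(
            n_genomes=1, genes_per_genome=100, w_max=0.0,
            gc3_targets=(0.85,), seed=5,
        )
        genomes, _, _ = simulate_genome_set(config)
        diffs = []
        for s in genomes["genome01"]:
            res = enc(count_codons(validate_cds(s)[0], unit_id=s.id))
            if res.nc is not None and res.nc_prime is not None:
                diffs.append(res.nc_prime - res.nc)
        assert np.mean(diffs) > 0

    def test_positional_background_rows_sum_to_one(self, small_genome_counts):
        counts = list(small_genome_counts.values())[0][0]
        bg = positional_background(counts)
        assert bg.sum(axis=1) == pytest.approx([1.0, 1.0, 1.0])
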