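import numpy as np
import pandas as pd
import pytest
from scipy import stats

from codonadapt.codon_metrics import aggregate_counts, rscu
from codonadapt.correspondence import (
    axis_report,
    build_rscu_matrix,
    correspondence_analysis,
    genome_class_table,
)
from codonadapt.genetic_code import INFORMATIVE_CODONS


def brute_force_ca(X, n_axes):
    """Independent oracle: CA column coordinates via eigendecomposition of
    S^T S instead of the SVD of S."""
    X = np.asarray(X, float)
    P = X / X.sum()
    r, c = P.sum(axis=1), P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    evals, evecs = np.linalg.eigh(S.T @ S)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    keep = evals > 1e-12
    evals, evecs = evals[keep], evecs[:, keep]
    s = np.sqrt(evals)
    col = (evecs * s) / np.sqrt(c)[:, None]
    return s[:n_axes], col[:, :n_axes], float(evals.sum())


def random_rscu_vectors(n, seed):
    rng = np.random.default_rng(seed)
    from conftest import counts_from_family_dict

    vecs = []
    for i in range(n):
        counts = dict(zip(INFORMATIVE_CODONS, rng.integers(1, 200, 59)))
        vecs.append(rscu(counts_from_family_dict(counts, unit_id=f"gen{i}")))
    return vecs


class TestBuildMatrix:
    def test_study_layout_shape(self):
        mat = build_rscu_matrix(random_rscu_vectors(15, seed=0))
        assert mat.shape == (15, 59)
        assert list(mat.columns) == list(INFORMATIVE_CODONS)

    def test_identical_genomes_identical_rows(self):
        v = random_rscu_vectors(1, seed=1)[0]
        v2 = type(v)(unit_id="other", rscu=dict(v.rscu), missing_families=v.missing_families)
        mat = build_rscu_matrix([v, v2])
        assert np.allclose(mat.iloc[0], mat.iloc[1])

    def test_single_genome_rejected(self):
        with pytest.raises(ValueError):
            build_rscu_matrix(random_rscu_vectors(1, seed=2))

    def test_missing_family_imputed_as_one(self):
        from codonadapt.codon_metrics import RSCUVector

        v1, v2 = random_rscu_vectors(2, seed=3)
        partial = {c: x for c, x in v1.rscu.items() if not c.startswith("GG")}
        v1 = RSCUVector(unit_id="g1", rscu=partial, missing_families=frozenset({"G"}))
        mat = build_rscu_matrix([v1, v2])
        assert (mat.loc["g1", ["GGA", "GGC", "GGG", "GGT"]] == 1.0).all()


class TestCA:
    def test_matches_brute_force_oracle_on_random_matrices(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            X = rng.uniform(0.1, 5.0, size=(3, 4))
            df = pd.DataFrame(X)
            res = correspondence_analysis(df, n_axes=2)
            s, col, inertia = brute_force_ca(X, 2)
            assert res.singular_values == pytest.approx(s, abs=1e-8)
            assert res.total_inertia == pytest.approx(inertia, abs=1e-8)
            for a in range(res.col_coords.shape[1]):
                got = res.col_coords.iloc[:, a].to_numpy()
                want = col[:, a]
                sign = np.sign(got @ want)
                assert got == pytest.approx(sign * want, abs=1e-8)

    def test_total_inertia_equals_chi2_over_grand_total(self):
        rng = np.random.default_rng(7)
        X = rng.integers(1, 50, size=(5, 8)).astype(float)
        res = correspondence_analysis(pd.DataFrame(X), n_axes=4)
        chi2 = stats.chi2_contingency(X, correction=False)[0]
        assert res.total_inertia == pytest.approx(chi2 / X.sum(), abs=1e-9)

    def test_row_masses_center_coordinates(self):
        rng = np.random.default_rng(8)
        X = rng.uniform(0.5, 3.0, size=(6, 10))
        res = correspondence_analysis(pd.DataFrame(X), n_axes=3)
        r = X.sum(axis=1) / X.sum()
        c = X.sum(axis=0) / X.sum()
        for axis in res.row_coords.columns:
            assert r @ res.row_coords[axis].to_numpy() == pytest.approx(0.0, abs=1e-9)
            assert c @ res.col_coords[axis].to_numpy() == pytest.approx(0.0, abs=1e-9)

    def test_transition_formulas(self):
        """Each row point is the mass-weighted barycenter of column points,
        scaled by the axis's inverse singular value."""
        rng = np.random.default_rng(9)
        X = rng.uniform(0.5, 3.0, size=(5, 7))
        res = correspondence_analysis(pd.DataFrame(X), n_axes=3)
        P = X / X.sum()
        r = P.sum(axis=1)
        profiles = P / r[:, None]
        G = res.col_coords.to_numpy()
        F = res.row_coords.to_numpy()
        recon = profiles @ G / res.singular_values[None, :]
        assert F == pytest.approx(recon, abs=1e-8)

    def test_identical_rows_get_identical_coordinates(self):
        X = np.array([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0], [3.0, 1.0, 1.0]])
        res = correspondence_analysis(pd.DataFrame(X), n_axes=2)
        assert np.allclose(res.row_coords.iloc[0], res.row_coords.iloc[1])

    def test_rank_one_matrix_has_zero_inertia(self):
        X = np.outer([1.0, 2.0, 3.0], [4.0, 5.0, 6.0, 7.0])
        res = correspondence_analysis(pd.DataFrame(X), n_axes=2)
        assert res.total_inertia == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.row_coords, 0.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.uniform(0.5, 3.0, size=(5, 7)),
                         index=[f"g{i}" for i in range(5)])
        perm = [3, 0, 4, 1, 2]
        res1 = correspondence_analysis(X, n_axes=2)
        res2 = correspondence_analysis(X.iloc[perm], n_axes=2)
        assert np.allclose(res1.row_coords.iloc[perm].to_numpy(),
                           res2.row_coords.to_numpy(), atol=1e-10)

    def test_scale_invariance(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.uniform(0.5, 3.0, size=(4, 6)))
        res1 = correspondence_analysis(X, n_axes=2)
        res2 = correspondence_analysis(2.0 * X, n_axes=2)
        assert np.allclose(res1.row_coords, res2.row_coords, atol=1e-10)
        assert np.allclose(res1.col_coords, res2.col_coords, atol=1e-10)

    def test_errors(self):
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame(np.zeros((3, 3))))
        with pytest.raises(ValueError):
            correspondence_analysis(pd.DataFrame(-np.ones((3, 3))))


@pytest.fixture(scope="module")
def gradient_result():
    from codonadapt.codon_metrics import count_codons
    from codonadapt.seqio import validate_cds
    from codonadapt.simulate import GenomeSimConfig, simulate_genome_set

    config = GenomeSimConfig(n_genomes=5, genes_per_genome=200, w_max=0.0, seed=21)
    genomes, _, _ = simulate_genome_set(config)
    vecs = []
    for label, seqs in genomes.items():
        counts = [count_codons(validate_cds(s)[0], genome=label, unit_id=s.id)
                  for s in seqs]
        vecs.append(rscu(aggregate_counts(counts, unit_id=label)))
    return config, correspondence_analysis(build_rscu_matrix(vecs), n_axes=2)


class TestGc3Gradient:
    def test_axis1_orders_genomes_by_gc3(self, gradient_result):
        config, res = gradient_result
        rho = stats.spearmanr(res.row_coords["axis1"], config.gc3_targets).statistic
        assert abs(rho) == pytest.approx(1.0)

    def test_axis1_separates_gc_ending_codons(self, gradient_result):
        _, res = gradient_result
        report = axis_report(res)
        assert abs(report.loc[0, "gc_ending_correlation"]) > 0.8

    def test_report_row_count_and_classes(self, gradient_result):
        _, res = gradient_result
        classes = {g: "psychrophile" for g in res.row_coords.index}
        table = genome_class_table(res, classes)
        assert len(table) == 5 and (table["class"] == "psychrophile").all()
        with pytest.raises(ValueError, match="unknown genome"):
            genome_class_table(res, {"nope": "mesophile"})

    def test_zero_inertia_reports_undefined_correlations(self):
        X = pd.DataFrame(np.full((3, 4), 2.0), columns=["GGA", "GGC", "TTT", "TTA"])
        res = correspondence_analysis(X, n_axes=2)
        report = axis_report(res)
        assert report["gc_ending_correlation"].isna().all()
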