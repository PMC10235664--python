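"""Network core: adjacency, TOM, module detection, eigenproteins, kME.

Oracles are independent brute-force implementations: a triple loop for the
topological overlap, a dense eigendecomposition for the eigenprotein, and
the closed-form t statistic for kME p-values.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from conftest import make_matrix
from protnet import ValidationError, network, preprocess
from protnet.network import (
    NetworkConfig,
    correlation_matrix,
    detect_modules,
    eigenprotein,
    eigenprotein_set,
    mean_abs_within_correlation,
    module_membership,
    scale_free_fit,
    soft_threshold_adjacency,
    topological_overlap,
)


def brute_force_tom(A: np.ndarray) -> np.ndarray:
    """Triple-loop unsigned TOM, written independently of the vectorized path."""
    n = A.shape[0]
    A0 = A.copy()
    np.fill_diagonal(A0, 0.0)
    k = [sum(A0[i, u] for u in range(n)) for i in range(n)]
    T = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            L = sum(A0[i, u] * A0[u, j] for u in range(n) if u not in (i, j))
            T[i, j] = (L + A0[i, j]) / (min(k[i], k[j]) + 1 - A0[i, j])
    return T


def transformed(values: np.ndarray):
    m = preprocess.impute(make_matrix(values))
    return preprocess.inverse_normal_transform(m)


def planted_dissim(seed, n_sub, sizes, n_analytes, noise=1.0, loading=0.55):
    """Full pipeline up to the TOM dissimilarity for a planted-block panel."""
    rng = np.random.default_rng(seed)
    cols, truth = [], []
    for mi, s in enumerate(sizes, 1):
        f = rng.standard_normal(n_sub)
        lams = np.full(s, loading)
        lams[: int(round(0.2 * s))] *= -1
        cols.append(lams * f[:, None] + noise * rng.standard_normal((n_sub, s)))
        truth += [mi] * s
    n_bg = n_analytes - sum(sizes)
    cols.append(rng.standard_normal((n_sub, n_bg)))
    truth += [0] * n_bg
    m = transformed(np.hstack(cols))
    cor = correlation_matrix(m)
    A = soft_threshold_adjacency(cor)
    D = 1.0 - topological_overlap(A)
    return D, cor, np.array(truth), n_sub


class TestCorrelation:
    def test_identical_and_negated_columns(self, rng):
        x = rng.standard_normal(50)
        m = transformed(np.column_stack([x, x + 0.0, -x]))
        C = correlation_matrix(m)
        assert C.iloc[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert C.iloc[0, 2] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_direct_formula(self, rng):
        X = rng.standard_normal((5, 3))
        m = make_matrix(X, stage="transformed")
        C = correlation_matrix(m).to_numpy()
        for i in range(3):
            for j in range(3):
                xi, xj = X[:, i] - X[:, i].mean(), X[:, j] - X[:, j].mean()
                expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
                assert C[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        m = make_matrix(np.column_stack([np.ones(10), np.arange(10.0)]),
                        stage="transformed")
        with pytest.raises(ValidationError, match="zero-variance"):
            correlation_matrix(m)


class TestAdjacency:
    @pytest.mark.parametrize("r, expected", [
        (0.5, 0.0625), (-0.5, 0.0625), (0.0, 0.0), (1.0, 1.0), (-1.0, 1.0),
    ])
    def test_powered_absolute_correlation(self, r, expected):
        C = np.array([[1.0, r], [r, 1.0]])
        A = soft_threshold_adjacency(C, NetworkConfig(beta=4))
        assert A[0, 1] == pytest.approx(expected, abs=1e-15)
        assert A[0, 0] == 1.0

    def test_out_of_range_correlation_rejected(self):
        with pytest.raises(ValidationError):
            soft_threshold_adjacency(np.array([[1.0, 1.2], [1.2, 1.0]]))


class TestScaleFreeFit:
    def _power_law_adjacency(self):
        # complete-graph blocks with one block per connectivity bin;
        # counts follow freq = C / k exactly, so log-log is exactly linear
        ks = np.array([0.02, 0.04, 0.06, 0.08])
        counts = np.array([24, 12, 8, 6])  # 0.48 / k
        blocks = []
        for k, c in zip(ks, counts):
            w = k / (c - 1)
            B = np.full((c, c), w)
            np.fill_diagonal(B, 1.0)
            blocks.append(B)
        n = counts.sum()
        A = np.zeros((n, n))
        pos = 0
        for B in blocks:
            c = B.shape[0]
            A[pos:pos + c, pos:pos + c] = B
            pos += c
        return A

    def test_exact_power_law_gives_r2_near_one(self):
        A = self._power_law_adjacency()
        fit = scale_free_fit(A, n_bins=4)
        assert fit.r_squared >= 0.999
        assert fit.slope == pytest.approx(-1.0, abs=0.01)

    def test_equal_connectivity_is_degenerate(self):
        A = np.full((10, 10), 0.3)
        np.fill_diagonal(A, 1.0)
        with pytest.raises(ValidationError, match="single bin|non-empty"):
            scale_free_fit(A)

    def test_permutation_invariance(self, rng):
        A = rng.uniform(0, 0.2, (30, 30))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        perm = rng.permutation(30)
        fit1 = scale_free_fit(A)
        fit2 = scale_free_fit(A[np.ix_(perm, perm)])
        assert fit1.r_squared == pytest.approx(fit2.r_squared, abs=1e-12)


class TestTopologicalOverlap:
    def test_perfect_triangle(self):
        A = np.ones((3, 3))
        T = topological_overlap(A)
        assert T[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_single_edge_formula(self):
        A = np.eye(3)
        A[0, 1] = A[1, 0] = 0.5
        T = topological_overlap(A)
        # (L + a) / (min(k) + 1 - a) = (0 + .5) / (.5 + 1 - .5)
        assert T[0, 1] == pytest.approx(0.5, abs=1e-12)

    def test_matches_brute_force(self, rng):
        A = rng.uniform(0, 1, (6, 6))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        T = topological_overlap(A)
        np.testing.assert_allclose(T, brute_force_tom(A), atol=1e-12)

    def test_bounds_and_symmetry(self, rng):
        A = rng.uniform(0, 1, (15, 15))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        T = topological_overlap(A)
        assert (T >= 0).all() and (T <= 1).all()
        np.testing.assert_allclose(T, T.T, atol=1e-15)
        np.testing.assert_allclose(np.diag(T), 1.0)


class TestDetectModules:
    def test_recovers_zero_noise_blocks_exactly(self):
        D, cor, truth, n_sub = planted_dissim(
            3, 300, (10, 8), 30, noise=1e-6, loading=0.7
        )
        part = detect_modules(D, cor=cor, n_subjects=n_sub)
        assert adjusted_rand_score(truth, part.assignment.to_numpy()) == 1.0
        assert (part.assignment.to_numpy()[truth == 0] == 0).all()

    def test_independent_analytes_give_no_modules(self):
        for seed in range(5):
            D, cor, truth, n_sub = planted_dissim(seed, 500, (), 60)
            part = detect_modules(D, cor=cor, n_subjects=n_sub)
            assert part.n_modules == 0
            assert (part.assignment == 0).all()

    def test_block_below_min_size_not_returned(self):
        D, cor, truth, n_sub = planted_dissim(11, 400, (4,), 25, noise=1e-6)
        part = detect_modules(D, NetworkConfig(min_module_size=5),
                              cor=cor, n_subjects=n_sub)
        assert (part.assignment.to_numpy()[truth == 1] == 0).all()

    def test_labels_ordered_by_descending_size(self):
        D, cor, truth, n_sub = planted_dissim(5, 500, (8, 15, 10), 45, noise=0.5)
        part = detect_modules(D, cor=cor, n_subjects=n_sub)
        sizes = part.module_sizes
        assert list(sizes.values) == sorted(sizes.values, reverse=True)

    def test_fewer_analytes_than_min_size_warns(self):
        D = np.zeros((3, 3))
        with pytest.warns(UserWarning):
            part = detect_modules(D, NetworkConfig(min_module_size=5))
        assert (part.assignment == 0).all()

    def test_permuting_analytes_permutes_partition(self):
        D, cor, truth, n_sub = planted_dissim(8, 400, (10, 8), 30, noise=0.5)
        part = detect_modules(D, cor=cor, n_subjects=n_sub)
        rng = np.random.default_rng(0)
        perm = rng.permutation(D.shape[0])
        Dp = pd.DataFrame(D.to_numpy()[np.ix_(perm, perm)],
                          index=D.index[perm], columns=D.index[perm])
        part_p = detect_modules(Dp, cor=cor.to_numpy()[np.ix_(perm, perm)],
                                n_subjects=n_sub)
        merged = pd.concat(
            [part.assignment.rename("a"), part_p.assignment.rename("b")], axis=1
        )
        assert adjusted_rand_score(merged["a"], merged["b"]) == 1.0


class TestEigenprotein:
    def test_rank_one_module(self, rng):
        x = rng.standard_normal(100)
        m = make_matrix(np.column_stack([x, x]), stage="transformed")
        scores, ve = eigenprotein(m, ["A000", "A001"])
        assert ve == pytest.approx(1.0, abs=1e-12)
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(scores.to_numpy(), z, atol=1e-10)

    def test_matches_dense_eigendecomposition(self, rng):
        X = rng.standard_normal((60, 7))
        X[:, 1:] += X[:, [0]]  # correlated block
        m = make_matrix(X, stage="transformed")
        scores, ve = eigenprotein(m, list(m.analyte_ids))
        # oracle: leading eigenvector of the correlation matrix
        C = np.corrcoef(X, rowvar=False)
        w, V = np.linalg.eigh(C)
        lead = V[:, np.argmax(w)]
        Z = (X - X.mean(0)) / X.std(0, ddof=1)
        oracle = Z @ lead
        r = np.corrcoef(scores, oracle)[0, 1]
        assert abs(abs(r) - 1.0) < 1e-10
        assert ve == pytest.approx(w.max() / w.sum(), abs=1e-10)

    def test_negated_copies_have_signed_kme(self, rng):
        x = rng.standard_normal(80)
        m = make_matrix(np.column_stack([x, x, -x, -x + 0.0]), stage="transformed")
        part = pd.Series([1, 1, 1, 1], index=m.analyte_ids, name="module")
        eig = eigenprotein_set(m, network.ModulePartition(assignment=part))
        assert eig.variance_explained["M1"] == pytest.approx(1.0, abs=1e-12)
        kme = eig.kme["M1"]
        # orientation: mean correlation positive => majority sign positive
        np.testing.assert_allclose(kme.iloc[:2], 1.0, atol=1e-10)
        np.testing.assert_allclose(kme.iloc[2:], -1.0, atol=1e-10)

    def test_module_too_small(self, rng):
        m = make_matrix(rng.standard_normal((10, 3)), stage="transformed")
        with pytest.raises(ValidationError, match="size >= 2"):
            eigenprotein(m, ["A000"])


class TestModuleMembership:
    def test_identical_analyte_has_unit_kme(self, rng):
        x = rng.standard_normal(200)
        m = make_matrix(np.column_stack([x, x, rng.standard_normal(200)]),
                        stage="transformed")
        part = pd.Series([1, 1, 0], index=m.analyte_ids, name="module")
        eig = eigenprotein_set(m, network.ModulePartition(assignment=part))
        assert eig.kme.loc["A000", "M1"] == pytest.approx(1.0, abs=1e-10)
        assert eig.kme_p.loc["A000", "M1"] < 1e-100

    def test_p_matches_t_formula(self, rng):
        X = rng.standard_normal((40, 5))
        X[:, :3] += X[:, [0]]
        m = make_matrix(X, stage="transformed")
        part = pd.Series([1, 1, 1, 0, 0], index=m.analyte_ids, name="module")
        eig = eigenprotein_set(m, network.ModulePartition(assignment=part))
        n = 40
        for a in m.analyte_ids:
            r = np.corrcoef(m.values[a], eig.scores["M1"])[0, 1]
            t = r * np.sqrt((n - 2) / (1 - r**2))
            p = 2 * stats.t.sf(abs(t), n - 2)
            assert eig.kme_p.loc[a, "M1"] == pytest.approx(p, abs=1e-10)

    def test_null_p_values_are_uniform(self):
        # analyte independent of the scores: p ~ U(0,1) across simulations
        rng = np.random.default_rng(2024)
        n, sims = 1000, 500
        e = rng.standard_normal(n)
        X = rng.standard_normal((n, sims))
        ec = (e - e.mean()) / e.std()
        r = (X - X.mean(0)).T @ ec / n / X.std(0)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(np.abs(t), n - 2)
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_top_kme_analyte_belongs_to_its_module(self, small_cohort):
        _, proteins, _, truth = small_cohort
        m = preprocess.inverse_normal_transform(
            preprocess.impute(filter_first(proteins))
        )
        cor = correlation_matrix(m)
        A = soft_threshold_adjacency(cor)
        D = 1.0 - topological_overlap(A)
        part = detect_modules(D, cor=cor, n_subjects=m.n_subjects)
        eig = eigenprotein_set(m, part)
        for label in part.module_sizes.index:
            col = f"M{label}"
            top = eig.kme[col].abs().idxmax()
            assert part.assignment[top] == label


def filter_first(proteins):
    out, _ = preprocess.filter_by_missingness(proteins)
    return out


class TestMeanAbsWithinCorrelation:
    def test_identical_columns(self, rng):
        x = rng.standard_normal(30)
        m = make_matrix(np.column_stack([x, x, x]), stage="transformed")
        cor = correlation_matrix(m)
        assert mean_abs_within_correlation(cor, list(m.analyte_ids)) == pytest.approx(1.0)

    def test_hand_computed_average(self):
        cor = pd.DataFrame(
            [[1.0, 0.3, -0.3], [0.3, 1.0, 0.6], [-0.3, 0.6, 1.0]],
            index=list("abc"), columns=list("abc"),
        )
        assert mean_abs_within_correlation(cor, list("abc")) == pytest.approx(0.4)

    def test_vanishes_for_independent_columns(self, rng):
        m = make_matrix(rng.standard_normal((20000, 4)), stage="transformed")
        cor = correlation_matrix(m)
        assert mean_abs_within_correlation(cor, list(m.analyte_ids)) < 0.02

    def test_requires_two_analytes(self):
        cor = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        with pytest.raises(ValidationError):
            mean_abs_within_correlation(cor, ["a"])


class TestUnsignedInvariance:
    def test_negating_a_column_changes_nothing(self):
        rng = np.random.default_rng(17)
        raw = []
        for s in (10, 8):
            f = rng.standard_normal(500)
            lams = np.full(s, 0.55)
            lams[: int(round(0.2 * s))] *= -1
            raw.append(lams * f[:, None] + 0.8 * rng.standard_normal((500, s)))
        raw.append(rng.standard_normal((500, 12)))
        X = np.hstack(raw)
        X_neg = X.copy()
        X_neg[:, 0] *= -1.0

        parts, eigs, cors = [], [], []
        for data in (X, X_neg):
            m = transformed(data)
            cor = correlation_matrix(m)
            A = soft_threshold_adjacency(cor)
            D = 1.0 - topological_overlap(A)
            part = detect_modules(D, cor=cor, n_subjects=500)
            parts.append(part)
            eigs.append(eigenprotein_set(m, part))
            cors.append(cor)

        np.testing.assert_allclose(
            np.abs(cors[0].to_numpy()), np.abs(cors[1].to_numpy()), atol=1e-10
        )
        pd.testing.assert_series_equal(parts[0].assignment, parts[1].assignment)
        np.testing.assert_allclose(
            np.abs(eigs[0].kme.to_numpy()), np.abs(eigs[1].kme.to_numpy()), atol=1e-8
        )
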