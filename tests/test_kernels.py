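"""Preprocessing and kernel construction, checked against independent oracles."""

import numpy as np
import pytest
from scipy import stats

from omicsblup.kernels import (
    ConditionedMatrix,
    OmicsMatrix,
    build_conditioned_kernel,
    build_genomic_kernel,
    build_interaction_kernel,
    build_transcript_kernel,
    center_standardize,
    compute_lambda,
    condition_transcripts,
    qc_filter_genotypes,
    rank_z_transform,
)


def geno(values, **kw):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return OmicsMatrix(values, [f"i{r}" for r in range(n)],
                       [f"s{c}" for c in range(m)], "genotype", **kw)


def transcript(values):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    return OmicsMatrix(values, [f"i{r}" for r in range(n)],
                       [f"g{c}" for c in range(m)], "transcript")


class TestOmicsMatrix:
    def test_rejects_duplicate_ids(self):
        with pytest.raises(ValueError, match="duplicate"):
            OmicsMatrix(np.zeros((2, 2)), ["a", "a"], ["x", "y"], "genotype")
        with pytest.raises(ValueError, match="duplicate"):
            OmicsMatrix(np.zeros((2, 2)), ["a", "b"], ["x", "x"], "genotype")

    def test_rejects_out_of_range_dosages(self):
        with pytest.raises(ValueError, match="dosages"):
            geno([[0, 3.0], [1, 1]])

    def test_allows_missing_dosages(self):
        X = geno([[0, np.nan], [2, 1]])
        assert np.isnan(X.values[0, 1])


class TestQCFilter:
    def test_monomorphic_marker_removed(self):
        X = geno([[0, 1], [0, 1], [0, 2]])
        out, rep = qc_filter_genotypes(X, maf_min=0.05)
        assert out.col_ids == ["s1"]
        assert rep.n_removed_maf == 1

    def test_duplicate_column_removed_by_correlation(self):
        col = np.array([0, 1, 2, 1, 0, 2], dtype=float)
        X = geno(np.c_[col, col])
        out, rep = qc_filter_genotypes(X, corr_max=0.80)
        assert out.col_ids == ["s0"]
        assert rep.n_removed_corr == 1

    def test_low_call_rate_removed(self):
        bad = np.array([np.nan] * 7 + [0, 1, 2], dtype=float)
        good = np.arange(10) % 3.0
        X = geno(np.c_[good, bad])
        out, rep = qc_filter_genotypes(X, call_rate_min=0.90)
        assert out.col_ids == ["s0"]
        assert rep.n_removed_callrate == 1

    def test_matches_brute_force_filter(self, rng):
        # independent reimplementation of the three rules in order
        X = geno(rng.integers(0, 3, size=(10, 50)).astype(float))
        V = X.values.copy()
        V[rng.random(V.shape) < 0.05] = np.nan
        X = geno(V)
        maf_min, cr_min, corr_max = 0.05, 0.90, 0.80

        keep = []
        for j in range(V.shape[1]):
            col = V[:, j]
            obs = col[np.isfinite(col)]
            p = obs.mean() / 2 if obs.size else np.nan
            maf = min(p, 1 - p) if np.isfinite(p) else np.nan
            if not (np.isfinite(maf) and maf >= maf_min):
                continue
            if np.isfinite(col).mean() < cr_min:
                continue
            if keep:
                a, b = V[:, keep[-1]], col
                ok = np.isfinite(a) & np.isfinite(b)
                if ok.sum() >= 2 and np.ptp(a[ok]) > 0 and np.ptp(b[ok]) > 0:
                    if abs(np.corrcoef(a[ok], b[ok])[0, 1]) > corr_max:
                        continue
            keep.append(j)

        out, rep = qc_filter_genotypes(X, maf_min, cr_min, corr_max)
        assert out.col_ids == [X.col_ids[j] for j in keep]
        assert rep.n_retained == len(keep)
        assert (rep.n_input - rep.n_removed_maf - rep.n_removed_callrate
                - rep.n_removed_corr) == rep.n_retained

    def test_all_removed_raises(self):
        X = geno([[0, 0], [0, 0], [0, 0]])
        with pytest.raises(ValueError, match="empty matrix after QC"):
            qc_filter_genotypes(X)


class TestRankZ:
    def test_three_value_example(self):
        # ranks (3,1,2) -> normal quantiles of (0.75, 0.25, 0.5)
        X = transcript(np.array([[5.0], [1.0], [3.0]]))
        out = rank_z_transform(X)
        expect = stats.norm.ppf([0.75, 0.25, 0.5])
        np.testing.assert_allclose(out.values[:, 0], expect, atol=1e-10)
        np.testing.assert_allclose(out.values[0, 0], 0.6745, atol=5e-5)

    def test_idempotent(self, rng):
        X = transcript(rng.standard_normal((12, 4)))
        once = rank_z_transform(X)
        twice = rank_z_transform(once)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-12)

    def test_distribution_free(self, rng):
        # any two features share the same sorted set of quantiles
        X = transcript(np.c_[rng.standard_normal(15),
                             rng.exponential(size=15)])
        out = rank_z_transform(X)
        np.testing.assert_allclose(np.sort(out.values[:, 0]),
                                   np.sort(out.values[:, 1]), atol=1e-12)

    def test_all_tied_feature_raises(self):
        X = transcript(np.c_[np.ones(5), np.arange(5.0)])
        with pytest.raises(ValueError, match="g0"):
            rank_z_transform(X)


class TestCenterStandardize:
    def test_two_individual_example(self):
        Z = center_standardize(geno([[0.0], [2.0]]))
        np.testing.assert_allclose(Z.values[:, 0],
                                   [-0.70710678, 0.70710678], atol=1e-8)

    def test_constant_column_dropped(self):
        Z = center_standardize(geno([[1, 0], [1, 1], [1, 2]]))
        assert Z.dropped_features == ["s0"]
        assert Z.values.shape == (3, 1)

    def test_hand_computed_columns(self):
        V = np.array([[1, 2, 0], [0, 0, 2], [2, 1, 1], [1, 1, 1]], dtype=float)
        Z = center_standardize(geno(V))
        for j in range(3):
            mu, sd = V[:, j].mean(), V[:, j].std(ddof=1)
            np.testing.assert_allclose(Z.values[:, j], (V[:, j] - mu) / sd,
                                       atol=1e-12)
        assert np.allclose(Z.values.mean(axis=0), 0, atol=1e-10)
        assert np.allclose(Z.values.std(axis=0, ddof=1), 1, atol=1e-8)

    def test_missing_values_imputed_to_zero(self):
        Z = center_standardize(geno([[0, np.nan], [1, 0], [2, 2]]))
        assert np.isfinite(Z.values).all()
        # imputed cell equals the column mean, hence 0 after centering
        np.testing.assert_allclose(Z.values[0, 1], 0.0, atol=1e-12)

    def test_single_individual_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            center_standardize(geno([[0, 1]]))


class TestCrossproductKernels:
    def test_two_by_two_example(self):
        Z = center_standardize(geno([[0.0], [2.0]]))
        G = build_genomic_kernel(Z)
        np.testing.assert_allclose(G.values, [[0.5, -0.5], [-0.5, 0.5]],
                                   atol=1e-10)
        assert G.component == "g"
        assert G.n_features_used == 1

    def test_row_sums_vanish_for_centered_input(self, rng):
        Z = center_standardize(geno(rng.integers(0, 3, (8, 20)).astype(float)))
        G = build_genomic_kernel(Z)
        np.testing.assert_allclose(G.values @ np.ones(8), 0, atol=1e-10)

    def test_matches_loop_oracle(self, rng):
        Z = center_standardize(geno(rng.integers(0, 3, (6, 30)).astype(float)))
        G = build_genomic_kernel(Z)
        m = Z.n_features
        expect = np.zeros((6, 6))
        for i in range(6):
            for j in range(6):
                expect[i, j] = sum(Z.values[i, l] * Z.values[j, l]
                                   for l in range(m)) / m
        np.testing.assert_allclose(G.values, expect, atol=1e-12)

    def test_transcript_kernel_equals_genomic_on_same_matrix(self, rng):
        X = rng.standard_normal((5, 40))
        W = center_standardize(transcript(X))
        Zlike = center_standardize(transcript(X))
        T = build_transcript_kernel(W)
        G_same = build_transcript_kernel(Zlike)
        np.testing.assert_allclose(T.values, G_same.values, atol=1e-12)
        assert T.component == "t"

    def test_kernels_are_symmetric_psd(self, tiny_kernels):
        _, _, G, T = tiny_kernels
        for K in (G, T):
            assert np.max(np.abs(K.values - K.values.T)) < 1e-10
            ev = np.linalg.eigvalsh(K.values)
            assert ev.min() >= -1e-8 * ev.max()


class TestInteractionKernel:
    def test_identity_times_t_is_diagonal(self, rng):
        n = 5
        ids = [f"i{r}" for r in range(n)]
        from omicsblup.kernels import RelationshipKernel
        G = RelationshipKernel(np.eye(n), "g", ids)
        Tv = rng.standard_normal((n, n)); Tv = Tv @ Tv.T / n
        T = RelationshipKernel(Tv, "t", ids)
        GT = build_interaction_kernel(G, T)
        np.testing.assert_allclose(GT.values, np.diag(np.diag(Tv)), atol=1e-12)
        assert GT.component == "gt"

    def test_elementwise_arithmetic(self):
        from omicsblup.kernels import RelationshipKernel
        K = np.array([[0.5, -0.5], [-0.5, 0.5]])
        G = RelationshipKernel(K, "g", ["a", "b"])
        T = RelationshipKernel(K, "t", ["a", "b"])
        GT = build_interaction_kernel(G, T)
        np.testing.assert_allclose(GT.values, [[0.25, 0.25], [0.25, 0.25]])

    def test_schur_product_stays_psd(self, rng):
        from omicsblup.kernels import RelationshipKernel
        ids = [f"i{r}" for r in range(6)]
        A = rng.standard_normal((6, 8)); B = rng.standard_normal((6, 8))
        G = RelationshipKernel(A @ A.T / 8, "g", ids)
        T = RelationshipKernel(B @ B.T / 8, "t", ids)
        ev = np.linalg.eigvalsh(build_interaction_kernel(G, T).values)
        assert ev.min() >= -1e-10

    def test_id_mismatch_raises(self, rng):
        from omicsblup.kernels import RelationshipKernel
        G = RelationshipKernel(np.eye(3), "g", ["a", "b", "c"])
        T = RelationshipKernel(np.eye(3), "t", ["a", "c", "b"])
        with pytest.raises(ValueError, match="ordering"):
            build_interaction_kernel(G, T)


class TestLambda:
    def test_direct_arithmetic(self):
        assert compute_lambda(0.6, 0.4, 50122) == pytest.approx(75183.0)
        assert compute_lambda(1.0, 1.0, 1) == 1.0
        assert compute_lambda(0.0, 0.4, 100) == 0.0

    def test_degenerate_heritability_raises(self):
        with pytest.raises(ValueError, match="sigma_g2"):
            compute_lambda(0.5, 0.0, 10)


class TestConditioning:
    def test_infinite_lambda_leaves_w_untouched(self, rng):
        W = center_standardize(transcript(rng.standard_normal((6, 3))))
        Z = center_standardize(geno(rng.integers(0, 3, (6, 10)).astype(float)))
        Wc = condition_transcripts(W, Z, 1e12)
        assert np.max(np.abs(Wc.values - W.values)) < 1e-6 * np.max(np.abs(W.values))

    def test_zero_lambda_projects_out_genotype_span(self, rng):
        Z = center_standardize(geno(rng.integers(0, 3, (5, 8)).astype(float)))
        v = rng.standard_normal((Z.n_features, 2))
        W = Z.values @ v  # inside the genotype column space
        from omicsblup.kernels import StandardizedMatrix
        Wm = StandardizedMatrix(W, Z.row_ids, ["a", "b"],
                                np.zeros(2), np.ones(2))
        Wc = condition_transcripts(Wm, Z, 0.0)
        assert np.max(np.abs(Wc.values)) < 1e-8

    def test_m_form_equals_n_form(self, rng):
        Z = center_standardize(geno(rng.integers(0, 3, (5, 8)).astype(float)))
        W = center_standardize(transcript(rng.standard_normal((5, 3))))
        a = condition_transcripts(W, Z, 2.0, method="n").values
        b = condition_transcripts(W, Z, 2.0, method="m").values
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_sum_of_squares_monotone_in_lambda(self, rng):
        Z = center_standardize(geno(rng.integers(0, 3, (8, 12)).astype(float)))
        W = center_standardize(transcript(rng.standard_normal((8, 4))))
        total = (W.values ** 2).sum()
        last = -1.0
        for lam in (0.0, 1.0, 10.0, 100.0, 1e4, 1e8):
            ss = (condition_transcripts(W, Z, lam).values ** 2).sum()
            assert ss >= last - 1e-9
            assert ss <= total + 1e-9
            last = ss
        assert last == pytest.approx(total, rel=1e-6)

    def test_negative_lambda_raises(self, tiny_kernels):
        Z, W, _, _ = tiny_kernels
        with pytest.raises(ValueError, match="non-negative"):
            condition_transcripts(W, Z, -1.0)


class TestConditionedKernel:
    def test_zero_wc_gives_zero_kernel(self):
        Wc = ConditionedMatrix(np.zeros((4, 3)), list("abcd"),
                               list("xyz"), lam=1.0)
        Tc = build_conditioned_kernel(Wc)
        assert np.all(Tc.values == 0)
        assert Tc.component == "tc"

    def test_large_lambda_recovers_unconditioned_kernel(self, rng):
        Z = center_standardize(geno(rng.integers(0, 3, (6, 10)).astype(float)))
        W = center_standardize(transcript(rng.standard_normal((6, 4))))
        T = build_transcript_kernel(W)
        Tc = build_conditioned_kernel(condition_transcripts(W, Z, 1e12))
        np.testing.assert_allclose(Tc.values, T.values, atol=1e-5)

    def test_matches_loop_oracle(self, rng):
        V = rng.standard_normal((5, 3))
        Wc = ConditionedMatrix(V, list("abcde"), list("xyz"), lam=2.0)
        Tc = build_conditioned_kernel(Wc)
        expect = np.zeros((5, 5))
        for i in range(5):
            for j in range(5):
                expect[i, j] = sum(V[i, l] * V[j, l] for l in range(3)) / 3
        np.testing.assert_allclose(Tc.values, expect, atol=1e-12)
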