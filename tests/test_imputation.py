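import numpy as np
import pytest

from conncf import (
    ExpressionTensor,
    ImputationError,
    NCFParams,
    SVDParams,
    drug_similarity,
    funk_svd_fit,
    funk_svd_predict,
    impute_mom,
    impute_ncf,
    impute_tissue_agnostic,
    reshape_tensor,
)
from conncf.imputation import ConvergenceError, default_k_neighbors

from conftest import make_tensor


def tensor_from_blocks(values, observed=None):
    """Build a tensor from an explicit (drugs, cells, genes) array."""
    values = np.asarray(values, dtype=float)
    d, c, g = values.shape
    if observed is None:
        observed = np.ones((d, c), dtype=bool)
    return ExpressionTensor(
        [f"d{i}" for i in range(d)],
        [f"c{j}" for j in range(c)],
        [f"g{k}" for k in range(g)],
        values, observed,
    )


class TestTissueAgnostic:
    def test_median_of_three(self):
        vals = np.zeros((1, 4, 1))
        vals[0, 1:, 0] = [1, 5, 9]
        t = tensor_from_blocks(vals)
        assert impute_tissue_agnostic(t, "d0", "c0")[0] == 5

    def test_even_count_median_is_mean(self):
        vals = np.zeros((1, 3, 1))
        vals[0, 1:, 0] = [2, 4]
        t = tensor_from_blocks(vals)
        assert impute_tissue_agnostic(t, "d0", "c0")[0] == 3

    def test_constant_tensor(self):
        t = tensor_from_blocks(np.full((3, 4, 5), 2.5))
        np.testing.assert_array_equal(
            impute_tissue_agnostic(t, "d0", "c1"), np.full(5, 2.5)
        )

    def test_no_other_cells_is_error(self):
        observed = np.zeros((2, 2), dtype=bool)
        observed[0, 0] = observed[1, 0] = observed[1, 1] = True
        t = tensor_from_blocks(np.ones((2, 2, 1)), observed)
        with pytest.raises(ImputationError, match="not observed in any cell"):
            impute_tissue_agnostic(t, "d0", "c0")


def mom_oracle(tensor, drug, cell):
    """Independent two-pass median implementation."""
    i = tensor.drugs.index(drug)
    j = tensor.cells.index(cell)
    out = []
    for k in range(tensor.n_genes):
        row = [
            tensor.values[i, jj, k]
            for jj in range(tensor.n_cells)
            if jj != j and tensor.observed[i, jj]
        ]
        col = [
            tensor.values[ii, j, k]
            for ii in range(tensor.n_drugs)
            if ii != i and tensor.observed[ii, j]
        ]
        out.append(np.median([np.median(row), np.median(col)]))
    return np.array(out)


class TestMedianOfMedians:
    def test_mean_of_two_medians(self):
        vals = np.zeros((3, 3, 1))
        vals[0, 1:, 0] = [3, 3]  # row median 3
        vals[1:, 0, 0] = [5, 5]  # column median 5
        t = tensor_from_blocks(vals)
        assert impute_mom(t, "d0", "c0")[0] == 4

    def test_identical_medians(self):
        t = tensor_from_blocks(np.full((3, 3, 2), 1.25))
        np.testing.assert_array_equal(impute_mom(t, "d1", "c1"), [1.25, 1.25])

    def test_against_two_pass_oracle(self):
        rng = np.random.default_rng(13)
        t = tensor_from_blocks(rng.normal(size=(3, 3, 1)))
        np.testing.assert_allclose(
            impute_mom(t, "d1", "c2"), mom_oracle(t, "d1", "c2"), atol=1e-12
        )
        t2 = make_tensor(6, 5, 7, seed=2, missing_fraction=0.3)
        d, c = t2.observed_pairs()[0]
        np.testing.assert_allclose(
            impute_mom(t2, d, c), mom_oracle(t2, d, c), atol=1e-12
        )


class TestDrugSimilarity:
    def test_identical_rows(self):
        t = make_tensor(1, 2, 10, seed=5)
        vals = np.vstack([t.values, t.values])
        t2 = tensor_from_blocks(vals)
        sim = drug_similarity(reshape_tensor(t2), NCFParams(min_overlap=3))
        assert sim[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_antipodal_rows(self):
        rng = np.random.default_rng(8)
        row = rng.normal(size=(1, 2, 10))
        t = tensor_from_blocks(np.vstack([row, -row]))
        sim = drug_similarity(reshape_tensor(t), NCFParams(min_overlap=3))
        assert sim[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_proportional_centered_rows(self):
        # rows (2,1,0) and (4,2,0) center to (1,0,-1) and (2,0,-2)
        vals = np.array([[[2.0], [1.0], [0.0]], [[4.0], [2.0], [0.0]]])
        t = tensor_from_blocks(vals)
        sim = drug_similarity(reshape_tensor(t), NCFParams(min_overlap=3))
        assert sim[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_and_bounded(self):
        t = make_tensor(8, 4, 10, seed=3, missing_fraction=0.3)
        sim = drug_similarity(reshape_tensor(t), NCFParams(min_overlap=5))
        defined = np.isfinite(sim)
        np.testing.assert_array_equal(defined, defined.T)
        np.testing.assert_allclose(sim[defined], sim.T[defined], atol=1e-12)
        assert (np.abs(sim[defined]) <= 1 + 1e-12).all()

    def test_small_overlap_masked(self):
        t = make_tensor(3, 2, 4, seed=1)
        sim = drug_similarity(reshape_tensor(t), NCFParams(min_overlap=100))
        assert np.isnan(sim).all()


class TestImputeNCF:
    def test_duplicate_row_oracle(self):
        rng = np.random.default_rng(10)
        base = rng.normal(size=(1, 3, 8))
        dup = base.copy()
        dup[0, 2] = rng.normal(size=8)  # same outside target cell, differs inside
        filler = rng.normal(size=(2, 3, 8))
        t = tensor_from_blocks(np.vstack([base, dup, filler]))
        t = t.mask_pairs([("d0", "c2")])
        pred = impute_ncf(
            reshape_tensor(t), "d0", "c2", NCFParams(k_neighbors=1, min_overlap=3)
        )
        np.testing.assert_allclose(pred, dup[0, 2], atol=1e-12)

    def test_equal_weight_mean(self):
        rng = np.random.default_rng(11)
        shared = rng.normal(size=(1, 2, 3))
        d1 = shared.copy()
        d2 = shared.copy()
        d1[0, 1] = [2.0, 2.0, 2.0]
        d2[0, 1] = [4.0, 4.0, 4.0]
        t = tensor_from_blocks(np.vstack([shared, d1, d2]))
        t = t.mask_pairs([("d0", "c1")])
        pred = impute_ncf(
            reshape_tensor(t), "d0", "c1", NCFParams(k_neighbors=2, min_overlap=2)
        )
        np.testing.assert_allclose(pred, [3.0, 3.0, 3.0], atol=1e-12)

    def test_signed_weight_normalization(self):
        # inject similarities directly: sims (0.5, -0.5), values (4, 4) -> 0
        t = tensor_from_blocks(np.ones((3, 2, 1)))
        t.values[1, 1, 0] = 4.0
        t.values[2, 1, 0] = 4.0
        R = reshape_tensor(t)
        sims = np.array([
            [1.0, 0.5, -0.5],
            [0.5, 1.0, np.nan],
            [-0.5, np.nan, 1.0],
        ])
        pred = impute_ncf(
            R, "d0", "c1", NCFParams(k_neighbors=2, min_overlap=1),
            similarities=sims,
        )
        assert pred[0] == pytest.approx(0.0, abs=1e-12)

    def test_no_eligible_neighbor_is_error(self):
        t = make_tensor(3, 3, 5, seed=6)
        t = t.mask_pairs([("d001", "c01"), ("d002", "c01")])
        with pytest.raises(ImputationError, match="no eligible neighbor"):
            impute_ncf(
                reshape_tensor(t), "d000", "c01", NCFParams(k_neighbors=2, min_overlap=5)
            )

    def test_invariant_to_drug_order(self):
        t = make_tensor(8, 4, 10, seed=14)
        pred = impute_ncf(
            reshape_tensor(t), "d003", "c02", NCFParams(k_neighbors=3, min_overlap=5)
        )
        perm = np.random.default_rng(0).permutation(8)
        t2 = ExpressionTensor(
            [t.drugs[i] for i in perm], t.cells, t.genes,
            t.values[perm], t.observed[perm],
        )
        pred2 = impute_ncf(
            reshape_tensor(t2), "d003", "c02", NCFParams(k_neighbors=3, min_overlap=5)
        )
        np.testing.assert_allclose(pred, pred2, atol=1e-12)

    def test_default_neighborhood_size(self):
        assert default_k_neighbors(450) == 45
        assert default_k_neighbors(1330) == 133
        assert default_k_neighbors(3) == 1


class TestFunkSVD:
    def _rank1_matrix(self, seed=0):
        rng = np.random.default_rng(seed)
        u = rng.normal(size=12)
        v = rng.normal(size=30)
        return np.outer(u, v)

    def _as_reshaped(self, M, observed=None):
        d = M.shape[0]
        g = 5
        c = M.shape[1] // g
        t = tensor_from_blocks(M.reshape(d, c, g), observed)
        return reshape_tensor(t)

    def test_rank1_recovery_vs_dense_svd(self):
        M = self._rank1_matrix()
        R = self._as_reshaped(M)
        params = SVDParams(rank=1, learning_rate=0.02, regularization=0.0,
                           max_epochs=500, tol=1e-9, seed=1)
        model = funk_svd_fit(R, params)
        recon = model.reconstruct()
        rmse = np.sqrt(np.mean((recon - M) ** 2))
        assert rmse < 1e-2
        # against the exact top singular pair
        U, s, Vt = np.linalg.svd(M)
        best = s[0] * np.outer(U[:, 0], Vt[0])
        assert np.sqrt(np.mean((recon - best) ** 2)) < 1e-2

    def test_masked_rank2_beats_column_means(self):
        rng = np.random.default_rng(4)
        M = np.outer(rng.normal(size=15), rng.normal(size=40)) + np.outer(
            rng.normal(size=15), rng.normal(size=40)
        )
        g = 5
        observed = rng.random((15, 40 // g)) > 0.3
        observed[:, 0] = True  # keep every drug trainable
        t = tensor_from_blocks(M.reshape(15, 40 // g, g), observed)
        R = reshape_tensor(t)
        params = SVDParams(rank=2, learning_rate=0.02, regularization=0.0,
                           max_epochs=800, tol=1e-10, seed=2)
        model = funk_svd_fit(R, params)
        recon = model.reconstruct()
        mask = R.column_mask()
        col_means = np.array([
            M[mask[:, j], j].mean() if mask[:, j].any() else 0.0
            for j in range(M.shape[1])
        ])
        held = ~mask
        rmse_svd = np.sqrt(np.mean((recon[held] - M[held]) ** 2))
        rmse_base = np.sqrt(
            np.mean((np.broadcast_to(col_means, M.shape)[held] - M[held]) ** 2)
        )
        assert rmse_svd < rmse_base

    def test_seeded_determinism_is_bit_exact(self):
        R = self._as_reshaped(self._rank1_matrix(3))
        params = SVDParams(rank=2, max_epochs=30, seed=42)
        m1 = funk_svd_fit(R, params)
        m2 = funk_svd_fit(R, params)
        np.testing.assert_array_equal(m1.U, m2.U)
        np.testing.assert_array_equal(m1.V, m2.V)
        assert m1.rmse_trace == m2.rmse_trace

    def test_rmse_trace_non_increasing(self):
        R = self._as_reshaped(self._rank1_matrix(5))
        params = SVDParams(rank=2, learning_rate=0.01, max_epochs=100, tol=1e-4, seed=0)
        model = funk_svd_fit(R, params)
        trace = np.array(model.rmse_trace)
        # monotone descent up to stopping-tolerance-scale jitter near the end
        assert (np.diff(trace) <= params.tol).all()
        assert trace[-1] < trace[0]

    def test_predict_matches_reconstruction(self):
        M = self._rank1_matrix(7)
        R = self._as_reshaped(M)
        params = SVDParams(rank=1, learning_rate=0.02, regularization=0.0,
                           max_epochs=500, tol=1e-9, seed=3)
        model = funk_svd_fit(R, params)
        pred = funk_svd_predict(model, "d2", "c3")
        np.testing.assert_allclose(pred, model.reconstruct()[2, 15:20], atol=1e-12)
        np.testing.assert_allclose(pred, M[2, 15:20], atol=0.1)

    def test_zero_factors_predict_zero(self):
        R = self._as_reshaped(self._rank1_matrix(8))
        model = funk_svd_fit(R, SVDParams(rank=1, max_epochs=1, seed=0))
        model.U[:] = 0
        model.V[:] = 0
        np.testing.assert_array_equal(funk_svd_predict(model, "d0", "c0"), np.zeros(5))

    def test_divergence_raises(self):
        R = self._as_reshaped(self._rank1_matrix(9) * 100)
        with pytest.raises(ConvergenceError, match="learning_rate"):
            funk_svd_fit(R, SVDParams(rank=2, learning_rate=5.0, max_epochs=50, seed=0))
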