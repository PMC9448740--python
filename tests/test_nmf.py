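"""Basis-restricted NMF: recovery, constraints, convergence."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import nnls

from ramandx.errors import ValidationError
from ramandx.nmf import fit_gbr_nmf, reconstruction_error, score_table
from tests.conftest import make_meta


@pytest.fixture(scope="module")
def small_library(library):
    """First five chemicals only — keeps the oracle comparisons cheap."""
    from ramandx.containers import BasisLibrary

    return BasisLibrary(library.axis, library.names[:5], library.spectra[:5])


class TestRecovery:
    def test_noiseless_mixture_recovered_against_nnls_oracle(self, small_library):
        rng = np.random.default_rng(2)
        W0 = rng.lognormal(0.0, 0.4, size=(12, 5))
        X = W0 @ small_library.spectra
        model = fit_gbr_nmf(X, small_library, n_iter=3000, tol=1e-12, seed=0)
        eff = model.effective_scores()
        # per-spectrum oracle: non-negative least squares on the basis
        for i in range(12):
            w_nnls, _ = nnls(small_library.spectra.T, X[i])
            cos = eff[i] @ w_nnls / (np.linalg.norm(eff[i]) * np.linalg.norm(w_nnls))
            assert cos >= 0.99

    def test_single_chemical_concentrates_mass(self, small_library):
        X = np.tile(small_library.spectra[2], (10, 1))
        model = fit_gbr_nmf(X, small_library, n_iter=3000, tol=1e-12, seed=1)
        eff = model.effective_scores()
        frac = eff[:, 2] / eff.sum(axis=1)
        assert np.all(frac >= 0.99)

    def test_group_mask_pins_scores_to_zero(self, small_library):
        rng = np.random.default_rng(3)
        X = rng.lognormal(0.0, 0.3, size=(6, 5)) @ small_library.spectra
        mask = np.ones((6, 5))
        mask[2, 3] = 0
        mask[4, 0] = 0
        model = fit_gbr_nmf(X, small_library, group_mask=mask, n_iter=200, seed=0)
        assert model.W[2, 3] == 0.0
        assert model.W[4, 0] == 0.0

    def test_fixed_rows_never_move(self, small_library):
        rng = np.random.default_rng(4)
        X = rng.lognormal(0.0, 0.3, size=(6, 5)) @ small_library.spectra
        model = fit_gbr_nmf(X, small_library, n_free=2, n_iter=100, seed=0)
        np.testing.assert_array_equal(model.S[:5], small_library.spectra)
        assert model.fixed_mask.tolist() == [True] * 5 + [False] * 2


class TestObjective:
    def test_trace_monotone_non_increasing(self, small_library):
        rng = np.random.default_rng(5)
        X = rng.lognormal(0.0, 0.5, size=(15, 5)) @ small_library.spectra
        X += rng.normal(0.0, 0.01 * X.mean(), X.shape).clip(-X * 0.5)
        model = fit_gbr_nmf(X, small_library, n_iter=500, tol=0.0, seed=0)
        tr = np.asarray(model.objective_trace)
        assert np.all(np.diff(tr) <= 1e-12 + 1e-12 * tr[:-1])

    def test_reduces_to_ordinary_nmf_without_restrictions(self, axis):
        """With no fixed rows or mask, the machinery is plain multiplicative-
        update NMF: an independently coded MU loop from the same start gives
        the same objective."""
        rng = np.random.default_rng(6)
        k, p, n, iters = 3, axis.size, 10, 40
        X = rng.uniform(0.2, 1.0, size=(n, p))

        model = fit_gbr_nmf(
            X, None, n_free=k, n_iter=iters, tol=0.0, seed=9, axis=axis,
            init="random",
        )

        # independent MU loop replaying the package's initialization draws
        rng2 = np.random.default_rng(9)
        S = rng2.uniform(0.1, 1.0, size=(k, p))
        S /= np.trapezoid(S, x=axis, axis=1)[:, None]
        W = rng2.uniform(0.0, 1.0, size=(n, k))
        W *= np.linalg.norm(X) / np.linalg.norm(W @ S)
        A = np.ones(k)
        eps = 1e-12
        for _ in range(iters):
            AS = A[:, None] * S
            W *= (X @ AS.T) / (W @ (AS @ AS.T) + eps)
            num_a = np.einsum("ij,ik,kj->k", X, W, S)
            den_a = ((W.T @ W) * (S @ S.T).T) @ A + eps
            A *= num_a / den_a
            B = W * A[None, :]
            S *= (B.T @ X) / ((B.T @ B) @ S + eps)
        obj = float(np.sum((X - (W * A) @ S) ** 2))
        assert model.objective_trace[-1] == pytest.approx(obj, abs=1e-9)

    def test_sklearn_nmf_reaches_comparable_fit(self, axis):
        """Cross-check against sklearn's multiplicative-update NMF: both
        routes should explain an exactly representable matrix essentially
        perfectly."""
        from sklearn.decomposition import NMF

        from ramandx.containers import BasisLibrary

        rng = np.random.default_rng(7)
        k, p = 4, axis.size
        base = rng.uniform(0.1, 1.0, (k, p))
        lib = BasisLibrary(axis, list("abcd"), base)
        X = rng.uniform(0.5, 2.0, size=(20, k)) @ lib.spectra
        ours = fit_gbr_nmf(X, lib, n_iter=4000, tol=1e-14, seed=0)
        sk = NMF(
            n_components=k, solver="mu", beta_loss="frobenius", init="random",
            max_iter=4000, tol=1e-14, random_state=0,
        )
        Wsk = sk.fit_transform(X)
        err_sk = np.linalg.norm(X - Wsk @ sk.components_) / np.linalg.norm(X)
        assert reconstruction_error(ours, X) < 1e-3
        # sklearn converges more slowly from its own random init; the point
        # is that an independent route also finds a near-exact factorization
        assert err_sk < 5e-3

    def test_determinism(self, small_library):
        rng = np.random.default_rng(8)
        X = rng.lognormal(0.0, 0.3, size=(6, 5)) @ small_library.spectra
        a = fit_gbr_nmf(X, small_library, n_iter=100, seed=42)
        b = fit_gbr_nmf(X, small_library, n_iter=100, seed=42)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.A, b.A)


class TestValidationErrors:
    def test_axis_mismatch(self, small_library, axis):
        from ramandx.containers import SpectrumSet

        other = np.linspace(460.0, 1790.0, axis.size)
        s = SpectrumSet(other, np.ones((1, axis.size)), make_meta(1))
        with pytest.raises(ValidationError):
            fit_gbr_nmf(s, small_library)

    def test_nan_rejected(self, small_library):
        X = np.ones((2, small_library.axis.size))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fit_gbr_nmf(X, small_library)

    def test_zero_row_rejected(self, small_library):
        X = np.ones((2, small_library.axis.size))
        X[1] = 0.0
        with pytest.raises(ValidationError):
            fit_gbr_nmf(X, small_library)


class TestScoreTable:
    def test_shape_and_scale_invariance(self, small_library):
        rng = np.random.default_rng(9)
        X = rng.lognormal(0.0, 0.3, size=(6, 5)) @ small_library.spectra
        model = fit_gbr_nmf(X, small_library, n_iter=100, seed=0)
        table = score_table(model, make_meta(6))
        assert len(table) == 6
        eff = model.effective_scores()
        # rescaling the W/A split leaves effective scores unchanged
        c = 3.7
        model.A = model.A.copy()
        model.W = model.W.copy()
        model.A[2] *= c
        model.W[:, 2] /= c
        np.testing.assert_allclose(model.effective_scores(), eff, rtol=1e-9)

    def test_biopsy_means_match_groupby_oracle(self, small_library):
        rng = np.random.default_rng(10)
        X = rng.lognormal(0.0, 0.3, size=(8, 5)) @ small_library.spectra
        model = fit_gbr_nmf(X, small_library, n_iter=100, seed=0)
        meta = make_meta(8)
        meta.loc[4:, "biopsy_id"] = "b2"
        table = score_table(model, meta)
        eff = model.effective_scores()
        got = table.groupby("biopsy_id")[small_library.names].mean()
        np.testing.assert_allclose(got.loc["b1"], eff[:4].mean(axis=0), rtol=1e-12)
        np.testing.assert_allclose(got.loc["b2"], eff[4:].mean(axis=0), rtol=1e-12)


class TestReconstructionError:
    def test_matches_independent_recomputation(self, small_library):
        rng = np.random.default_rng(11)
        X = rng.lognormal(0.0, 0.3, size=(6, 5)) @ small_library.spectra
        model = fit_gbr_nmf(X, small_library, n_iter=200, seed=0)
        err = reconstruction_error(model, X)
        recon = (model.W * model.A[None, :]) @ model.S
        oracle = np.sqrt(np.sum((X - recon) ** 2)) / np.sqrt(np.sum(X**2))
        assert err == pytest.approx(oracle, rel=1e-12)

    def test_orthogonal_data_poorly_explained(self, axis):
        from ramandx.containers import BasisLibrary

        # basis lives in the low half of the axis, data in the high half
        half = axis.size // 2
        b = np.zeros(axis.size)
        b[:half] = 1.0
        lib = BasisLibrary(axis, ["low"], b[None, :])
        X = np.zeros((3, axis.size))
        X[:, half:] = 1.0
        model = fit_gbr_nmf(X, lib, n_iter=200, seed=0)
        assert reconstruction_error(model, X) > 0.95
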