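"""Basis- and group-restricted non-negative matrix factorization (GBR-NMF).

The processed spectral matrix X (n_spectra × n_points) is decomposed as

    X ≈ W · diag(A) · S,      W, A, S ≥ 0

where the first ``n_fixed`` rows of S are *fixed* to a library of reference
chemical spectra (basis restriction) and any remaining ``n_free`` rows are
learned; A is a per-component scaling vector and W holds the per-spectrum
scores — the relative contribution of each chemical to each spectrum.  An
optional binary group mask pins chosen W entries at zero (group restriction),
e.g. to forbid a chemical for a subset of samples.

The squared Frobenius objective ‖X − W diag(A) S‖²_F is minimized by
Lee–Seung-style multiplicative updates applied to W, A and the free rows of S
only; fixed rows are never touched, masked W entries stay exactly zero, and
the objective is non-increasing across iterations.

Because the W/A scale split is not identifiable, downstream analyses use the
*effective score* W[i, j]·A[j], which is invariant to that split.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .containers import BasisLibrary, SpectrumSet
from .errors import ValidationError

_EPS = 1e-12


@dataclass
class GBRNMFModel:
    """A fitted (or in-progress) GBR-NMF decomposition."""

    axis: np.ndarray
    names: list[str]
    W: np.ndarray | None = None
    A: np.ndarray | None = None
    S: np.ndarray | None = None
    fixed_mask: np.ndarray | None = None
    group_mask: np.ndarray | None = None
    objective_trace: list[float] = field(default_factory=list)
    seed: int = 0
    n_iter: int = 0
    tol: float = 0.0

    @property
    def n_components(self) -> int:
        return len(self.names)

    @property
    def fitted(self) -> bool:
        return self.W is not None

    def effective_scores(self) -> np.ndarray:
        """W·diag(A): the scale-invariant per-spectrum chemical scores."""
        return self.W * self.A[None, :]

    def reconstruct(self) -> np.ndarray:
        return (self.W * self.A[None, :]) @ self.S


def _objective(X, W, A, S) -> float:
    R = X - (W * A[None, :]) @ S
    return float(np.sum(R * R))


def fit_gbr_nmf(
    X: SpectrumSet | np.ndarray,
    lib: BasisLibrary | None,
    n_free: int = 0,
    group_mask: np.ndarray | None = None,
    n_iter: int = 2000,
    tol: float = 1e-8,
    seed: int = 0,
    free_names: list[str] | None = None,
    axis: np.ndarray | None = None,
    init: str = "nnls",
) -> GBRNMFModel:
    """Fit the basis-restricted factorization of X against a fixed library.

    Parameters
    ----------
    X
        Processed spectra (a SpectrumSet on the library axis, or a plain
        non-negative matrix).  Negative residuals left by baseline
        subtraction are clipped at 0 in the working copy only.
    lib
        Reference chemical spectra forming the fixed rows of S.  ``None``
        together with ``n_free > 0`` gives ordinary (unrestricted) NMF.
    n_free
        Number of additional unconstrained components to learn.
    group_mask
        Optional binary (n_spectra × n_components) matrix; W is pinned to 0
        wherever the mask is 0.
    n_iter, tol
        Iteration cap and relative-decrease stopping tolerance.
    seed
        Seeds the random initialization of W and the free rows of S.
    axis
        Required only when ``X`` is a plain matrix and ``lib`` is ``None``.
    init
        ``"nnls"`` (default) warm-starts W at the per-spectrum non-negative
        least-squares solution against the initial S; ``"random"`` uses a
        seeded uniform draw.
    """
    if lib is None and n_free < 1:
        raise ValidationError("without a library at least one free component is needed")
    ref_axis = lib.axis if lib is not None else axis
    if isinstance(X, SpectrumSet):
        if ref_axis is not None and (
            X.n_points != len(ref_axis) or not np.allclose(X.axis, ref_axis)
        ):
            raise ValidationError("spectrum axis does not match the library axis")
        axis = X.axis
        Xm = X.intensities
    else:
        Xm = np.atleast_2d(np.asarray(X, dtype=float))
        if ref_axis is None:
            raise ValidationError("axis is required for matrix input without a library")
        if Xm.shape[1] != len(ref_axis):
            raise ValidationError("matrix width does not match the library axis")
        axis = np.asarray(ref_axis, dtype=float)
    if np.any(~np.isfinite(Xm)):
        raise ValidationError("X contains NaN or infinite values")
    Xm = np.clip(Xm, 0.0, None)
    zero_rows = np.nonzero(Xm.sum(axis=1) == 0)[0]
    if zero_rows.size:
        raise ValidationError(f"all-zero spectrum rows: {zero_rows.tolist()[:10]}")

    n_fixed = lib.n_chemicals if lib is not None else 0
    r = n_fixed + n_free
    n, p = Xm.shape
    rng = np.random.default_rng(seed)

    names = list(lib.names) if lib is not None else []
    if n_free:
        extra = free_names or [f"free_{i + 1}" for i in range(n_free)]
        if len(extra) != n_free:
            raise ValidationError("free_names length must equal n_free")
        names = names + list(extra)

    S = np.empty((r, p))
    if n_fixed:
        S[:n_fixed] = lib.spectra
    if n_free:
        free = rng.uniform(0.1, 1.0, size=(n_free, p))
        free /= np.trapezoid(free, x=axis, axis=1)[:, None]
        S[n_fixed:] = free
    fixed_mask = np.zeros(r, dtype=bool)
    fixed_mask[:n_fixed] = True

    if group_mask is not None:
        group_mask = np.asarray(group_mask)
        if group_mask.shape != (n, r):
            raise ValidationError(
                f"group_mask shape {group_mask.shape} != ({n}, {r})"
            )
        G = (group_mask != 0).astype(float)
    else:
        G = None

    if init == "nnls":
        # With S fixed the W-subproblem is convex and separable by spectrum;
        # warm-starting at the per-spectrum non-negative least-squares
        # solution avoids the zero-locking local minima that multiplicative
        # updates from a random start can fall into.
        W = np.vstack([nnls(S.T, Xm[i])[0] for i in range(n)])
        W = np.maximum(W, _EPS)  # keep every component revivable under MU
    elif init == "random":
        # scale the uniform W init so W S has roughly the column energy of X
        W = rng.uniform(0.0, 1.0, size=(n, r))
        W *= np.linalg.norm(Xm) / max(np.linalg.norm(W @ S), _EPS)
    else:
        raise ValidationError(f"unknown init {init!r}")
    if G is not None:
        W *= G
    A = np.ones(r)

    trace: list[float] = [_objective(Xm, W, A, S)]
    for it in range(n_iter):
        AS = A[:, None] * S                      # diag(A) S, r × p
        # W update
        num = Xm @ AS.T
        den = W @ (AS @ AS.T) + _EPS
        W *= num / den
        if G is not None:
            W *= G
        # A update (diagonal middle factor)
        num_a = np.einsum("ij,ik,kj->k", Xm, W, S)
        WtW = W.T @ W
        SSt = S @ S.T
        den_a = (WtW * SSt.T) @ A + _EPS         # diag(WᵀW diag(A) S Sᵀ)
        A *= num_a / den_a
        # free-S update
        if n_free:
            B = W * A[None, :]
            num_s = B.T @ Xm
            den_s = (B.T @ B) @ S + _EPS
            upd = num_s / den_s
            S[~fixed_mask] *= upd[~fixed_mask]
        obj = _objective(Xm, W, A, S)
        trace.append(obj)
        prev = trace[-2]
        if prev > 0 and (prev - obj) / prev < tol:
            break

    return GBRNMFModel(
        axis=axis,
        names=names,
        W=W,
        A=A,
        S=S,
        fixed_mask=fixed_mask,
        group_mask=group_mask,
        objective_trace=trace,
        seed=seed,
        n_iter=n_iter,
        tol=tol,
    )


def score_table(model: GBRNMFModel, meta: pd.DataFrame) -> pd.DataFrame:
    """Per-spectrum effective chemical scores joined to acquisition metadata.

    Returns a DataFrame with the metadata columns followed by one column per
    chemical holding W[i, j]·A[j].
    """
    if not model.fitted:
        raise ValidationError("model is not fitted")
    eff = model.effective_scores()
    if len(meta) != eff.shape[0]:
        raise ValidationError(
            f"{len(meta)} metadata records for {eff.shape[0]} score rows"
        )
    scores = pd.DataFrame(eff, columns=model.names)
    return pd.concat([meta.reset_index(drop=True), scores], axis=1)


def reconstruction_error(model: GBRNMFModel, X: SpectrumSet | np.ndarray) -> float:
    """Relative Frobenius reconstruction error ‖X − WAS‖_F / ‖X‖_F."""
    if not model.fitted:
        raise ValidationError("model is not fitted")
    Xm = X.intensities if isinstance(X, SpectrumSet) else np.atleast_2d(np.asarray(X))
    Xm = np.clip(Xm, 0.0, None)
    if Xm.shape != model.W.shape[:1] + model.S.shape[1:]:
        raise ValidationError(
            f"X shape {Xm.shape} does not match the fitted model "
            f"({model.W.shape[0]} × {model.S.shape[1]})"
        )
    return float(np.linalg.norm(Xm - model.reconstruct()) / np.linalg.norm(Xm))
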