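"""Trilinear (PARAFAC) and Tucker3 decompositions of EEM cubes.

PARAFAC models each cube element as a sum over F components of
sample-score x excitation-loading x emission-loading,

    x_ijk = sum_f a_if b_jf c_kf + e_ijk,

fitted by alternating least squares (ALS).  Tucker3 generalizes this with a
dense core of interaction weights,

    x_ijk = sum_rst a_ir b_js c_kt g_rst + e_ijk,

fitted by higher-order orthogonal iteration (HOOI) from a truncated
higher-order SVD start.  Both fits are fully deterministic.

Conventions
-----------
* PARAFAC: B and C columns have unit Euclidean norm, all scale carried by A;
  the largest-magnitude element of each B and C column is positive, signs
  compensated in A.  This absorbs the scale/sign indeterminacy so two runs
  from the same initialization are bit-comparable.
* Tucker3: A, B, C have orthonormal columns (magnitudes in the core G), same
  sign convention with signs compensated in G.

Held-out samples are scored by ordinary least squares against the fixed
loadings (:func:`project_scores`) — for a training sample this reproduces its
training score row.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.linalg import khatri_rao, solve, lstsq, svd

from .core import EEMCube


def _unfold(x: np.ndarray, mode: int) -> np.ndarray:
    """Mode-n unfolding: rows = mode-n fibres, remaining axes in order, last fastest."""
    return np.moveaxis(x, mode, 0).reshape(x.shape[mode], -1)


def _leading_left_vectors(M: np.ndarray, r: int) -> np.ndarray:
    """First r left singular vectors, with a deterministic sign convention."""
    U = svd(M, full_matrices=False)[0][:, :r]
    # anchor each vector's largest-|.| element positive
    piv = np.argmax(np.abs(U), axis=0)
    U *= np.sign(U[piv, np.arange(U.shape[1])])
    return U


@dataclass
class ParafacModel:
    """PARAFAC factors and fit diagnostics.

    ``A`` (I x F) holds sample scores, ``B`` (J x F) excitation loadings,
    ``C`` (K x F) emission loadings; ``sse`` is the residual sum of squares.
    """

    F: int
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    sse: float
    total_ss: float
    n_iter: int
    converged: bool

    def reconstruct(self, A: np.ndarray | None = None) -> np.ndarray:
        A = self.A if A is None else A
        return np.einsum("if,jf,kf->ijk", A, self.B, self.C)

    def basis(self) -> np.ndarray:
        """Unfolded regression basis (J*K x F): column f = b_f (x) c_f."""
        return khatri_rao(self.B, self.C)


@dataclass
class Tucker3Model:
    """Orthogonal Tucker3 factors, core array, and fit diagnostics."""

    ranks: tuple[int, int, int]
    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    G: np.ndarray
    sse: float
    total_ss: float
    n_iter: int
    converged: bool

    def reconstruct(self, A: np.ndarray | None = None) -> np.ndarray:
        A = self.A if A is None else A
        return np.einsum("rst,ir,js,kt->ijk", self.G, A, self.B, self.C)

    def basis(self) -> np.ndarray:
        """Unfolded regression basis (J*K x R): sample row ~ basis @ a_i."""
        G1 = _unfold(self.G, 0)                    # (R, S*T)
        return np.kron(self.B, self.C) @ G1.T      # (J*K, R)


def _normalize_parafac(A: np.ndarray, B: np.ndarray, C: np.ndarray):
    """Unit-norm B, C columns; scale into A; largest-|.| elements positive."""
    for M in (B, C):
        norms = np.linalg.norm(M, axis=0)
        norms[norms == 0] = 1.0
        M /= norms
        A *= norms
        piv = np.argmax(np.abs(M), axis=0)
        signs = np.sign(M[piv, np.arange(M.shape[1])])
        signs[signs == 0] = 1.0
        M *= signs
        A *= signs
    return A, B, C


def parafac_fit(
    cube: EEMCube,
    F: int,
    tol: float = 1e-8,
    max_iter: int = 2000,
    init: str = "svd",
    seed: int | None = None,
) -> ParafacModel:
    """Fit an F-component PARAFAC model by alternating least squares.

    ``init="svd"`` (default) starts from the leading singular vectors of each
    mode unfolding — deterministic; ``init="random"`` draws a Gaussian start
    from ``seed``.  Iterates until the relative SSE change drops below ``tol``
    or ``max_iter`` is reached; non-convergence is reported via
    ``converged=False``, not an exception.
    """
    if F < 1:
        raise ValueError("F must be >= 1")
    if not cube.is_complete:
        raise ValueError("PARAFAC requires a complete cube")
    X = cube.intensities
    I, J, K = X.shape
    if F > min(I * J, J * K, I * K):
        raise ValueError(f"F={F} exceeds the attainable rank for shape {X.shape}")
    X0, X1, X2 = _unfold(X, 0), _unfold(X, 1), _unfold(X, 2)
    total_ss = float((X ** 2).sum())

    if init == "svd":
        # pad with deterministic extra directions when a mode is smaller than F
        def init_mode(M, dim):
            r = min(F, min(M.shape))
            U = _leading_left_vectors(M, r)
            if r < F:
                rng = np.random.default_rng(0 if seed is None else seed)
                extra = rng.standard_normal((dim, F - r))
                U = np.hstack([U, extra / np.linalg.norm(extra, axis=0)])
            return U

        A, B, C = init_mode(X0, I), init_mode(X1, J), init_mode(X2, K)
    elif init == "random":
        rng = np.random.default_rng(seed)
        A, B, C = (rng.standard_normal((d, F)) for d in (I, J, K))
    else:
        raise ValueError(f"unknown init {init!r}")

    prev_sse = np.inf
    sse = total_ss
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # A-update: X0 ~= A (B kr C)^T
        gram = (B.T @ B) * (C.T @ C)
        A = lstsq_gram(X0 @ khatri_rao(B, C), gram)
        gram = (A.T @ A) * (C.T @ C)
        B = lstsq_gram(X1 @ khatri_rao(A, C), gram)
        gram = (A.T @ A) * (B.T @ B)
        C = lstsq_gram(X2 @ khatri_rao(A, B), gram)

        # SSE via the factor Grams (avoids forming the full reconstruction)
        AtA, BtB, CtC = A.T @ A, B.T @ B, C.T @ C
        model_ss = float(np.sum(AtA * BtB * CtC))
        inner = float(np.sum((X2 @ khatri_rao(A, B)) * C))
        sse = max(total_ss + model_ss - 2.0 * inner, 0.0)
        if prev_sse < np.inf and abs(prev_sse - sse) <= tol * max(prev_sse, 1e-300):
            converged = True
            break
        prev_sse = sse

    # final A-refresh so scores are the exact LS solution for the final B, C
    # (then project_scores on a training sample reproduces its score row)
    A = lstsq_gram(X0 @ khatri_rao(B, C), (B.T @ B) * (C.T @ C))
    A, B, C = _normalize_parafac(A, B.copy(), C.copy())
    return ParafacModel(F=F, A=A, B=B, C=C, sse=float(sse), total_ss=total_ss,
                        n_iter=it, converged=converged)


def lstsq_gram(XZ: np.ndarray, gram: np.ndarray) -> np.ndarray:
    """Solve M @ gram = XZ for M; pseudo-inverse when the gram is ill-conditioned."""
    if np.linalg.cond(gram) > 1e12:
        return XZ @ np.linalg.pinv(gram)
    return np.linalg.solve(gram, XZ.T).T


def tucker3_fit(
    cube: EEMCube,
    ranks: tuple[int, int, int],
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> Tucker3Model:
    """Fit an orthogonal Tucker3 model by HOOI with truncated HOSVD start."""
    if not cube.is_complete:
        raise ValueError("Tucker3 requires a complete cube")
    X = cube.intensities
    dims = X.shape
    R, S, T = ranks
    if min(ranks) < 1 or any(r > d for r, d in zip(ranks, dims)):
        raise ValueError(f"ranks {ranks} out of bounds for shape {dims}")
    total_ss = float((X ** 2).sum())

    factors = [_leading_left_vectors(_unfold(X, n), ranks[n]) for n in range(3)]
    prev_sse = np.inf
    sse = total_ss
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        for n in range(3):
            Y = X
            for m in range(3):
                if m != n:
                    Y = np.moveaxis(np.tensordot(factors[m].T, Y, axes=(1, m)), 0, m)
            factors[n] = _leading_left_vectors(_unfold(Y, n), ranks[n])
        A, B, C = factors
        G = np.einsum("ijk,ir,js,kt->rst", X, A, B, C, optimize=True)
        sse = max(total_ss - float((G ** 2).sum()), 0.0)  # orthonormal factors
        if prev_sse < np.inf and abs(prev_sse - sse) <= tol * max(prev_sse, 1e-300):
            converged = True
            break
        prev_sse = sse

    # final A-refresh against the converged B, C: A becomes the exact leading
    # subspace for those loadings, so LS projection reproduces training scores
    Y = np.moveaxis(np.tensordot(factors[1].T, X, axes=(1, 1)), 0, 1)
    Y = np.moveaxis(np.tensordot(factors[2].T, Y, axes=(1, 2)), 0, 2)
    factors[0] = _leading_left_vectors(_unfold(Y, 0), R)
    A, B, C = factors
    G = np.einsum("ijk,ir,js,kt->rst", X, A, B, C, optimize=True)
    sse = max(total_ss - float((G ** 2).sum()), 0.0)
    # sign convention: anchor B, C, A columns; compensate in the core
    for n, M in enumerate((A, B, C)):
        piv = np.argmax(np.abs(M), axis=0)
        signs = np.sign(M[piv, np.arange(M.shape[1])])
        signs[signs == 0] = 1.0
        M *= signs
        shape = [1, 1, 1]
        shape[n] = -1
        G *= signs.reshape(shape)
    return Tucker3Model(ranks=(R, S, T), A=A, B=B, C=C, G=G, sse=float(sse),
                        total_ss=total_ss, n_iter=it, converged=converged)


def explained_variance(model: ParafacModel | Tucker3Model, cube: EEMCube | None = None) -> float:
    """Percentage of the cube's total sum of squares captured by the model.

    100 * (1 - SSE / total SS); with ``cube`` given, both terms are recomputed
    on that cube (axes and loadings fixed, scores re-projected are NOT used —
    the cube must be the one the model was fitted on).
    """
    if cube is not None:
        total = float((cube.intensities ** 2).sum())
        resid = cube.intensities - model.reconstruct()
        sse = float((resid ** 2).sum())
    else:
        total, sse = model.total_ss, model.sse
    if total == 0:
        raise ValueError("all-zero cube: explained variance undefined")
    return 100.0 * (1.0 - sse / total)


def project_scores(model: ParafacModel | Tucker3Model, new_cube: EEMCube, train_axes=None) -> np.ndarray:
    """Least-squares scores for held-out samples with loadings (and core) fixed.

    Each sample's unfolded vector is regressed on the model basis:
    ``C (kr) B`` columns for PARAFAC, ``(B (x) C) G_(1)^T`` for Tucker3.
    """
    if not new_cube.is_complete:
        raise ValueError("projection requires a complete cube")
    Z = model.basis()  # (J*K, F or R)
    if Z.shape[0] != new_cube.shape[1] * new_cube.shape[2]:
        raise ValueError("new cube axes do not match the training axes")
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise ValueError("rank-deficient projection basis")
    sol = lstsq(Z, new_cube.unfold().T)[0]
    return sol.T


def congruence(u: np.ndarray, v: np.ndarray) -> float:
    """Tucker congruence (cosine similarity) between two loading vectors."""
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


def match_factors(est: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy optimal matching of estimated to true factor columns by |congruence|.

    Returns (permutation, congruences): ``est[:, perm[f]]`` corresponds to
    ``truth[:, f]`` with the signed congruence reported.
    """
    F = truth.shape[1]
    cos = np.zeros((F, F))
    for a in range(F):
        for b in range(F):
            cos[a, b] = congruence(truth[:, a], est[:, b])
    work = np.abs(cos).copy()
    perm = np.full(F, -1)
    for _ in range(F):
        a, b = np.unravel_index(int(np.argmax(work)), (F, F))
        perm[a] = b
        work[a, :] = -np.inf
        work[:, b] = -np.inf
    return perm, np.array([cos[f, perm[f]] for f in range(F)])


def save_model(model: ParafacModel | Tucker3Model, path: str | Path) -> Path:
    """Serialize a fitted model to an HDF5 container."""
    import h5py

    path = Path(path)
    with h5py.File(path, "w") as h5:
        if isinstance(model, ParafacModel):
            h5.attrs["kind"] = "parafac"
            h5.attrs["F"] = model.F
        else:
            h5.attrs["kind"] = "tucker3"
            h5.attrs["ranks"] = model.ranks
            h5.create_dataset("G", data=model.G)
        for name in ("A", "B", "C"):
            h5.create_dataset(name, data=getattr(model, name))
        h5.attrs["sse"] = model.sse
        h5.attrs["total_ss"] = model.total_ss
        h5.attrs["n_iter"] = model.n_iter
        h5.attrs["converged"] = model.converged
    return path


def load_model(path: str | Path) -> ParafacModel | Tucker3Model:
    import h5py

    with h5py.File(path, "r") as h5:
        common = dict(
            A=h5["A"][:], B=h5["B"][:], C=h5["C"][:],
            sse=float(h5.attrs["sse"]), total_ss=float(h5.attrs["total_ss"]),
            n_iter=int(h5.attrs["n_iter"]), converged=bool(h5.attrs["converged"]),
        )
        if h5.attrs["kind"] == "parafac":
            return ParafacModel(F=int(h5.attrs["F"]), **common)
        return Tucker3Model(ranks=tuple(int(r) for r in h5.attrs["ranks"]), G=h5["G"][:], **common)


def export_loadings_tsv(model: ParafacModel | Tucker3Model, cube_axes, out_dir: str | Path) -> None:
    """Plain-text loadings export: wavelength, factor1..factorN per mode."""
    import pandas as pd

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, M, wl in (
        ("excitation_loadings.tsv", model.B, cube_axes.excitation_nm),
        ("emission_loadings.tsv", model.C, cube_axes.emission_nm),
    ):
        df = pd.DataFrame(M, columns=[f"factor{f+1}" for f in range(M.shape[1])])
        df.insert(0, "wavelength_nm", wl)
        df.to_csv(out / name, sep="\t", index=False)
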