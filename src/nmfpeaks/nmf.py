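"""Non-negative matrix factorization core.

Approximates an observed non-negative spectrum matrix ``Y`` (m x T) by the
product of a basis (mixing) matrix ``A`` (m x r) and a source matrix ``X``
(r x T), minimizing the squared Euclidean divergence

    D(A, X) = || Y - A X ||_F^2

with the ISRA-type multiplicative update rules

    A <- A . (Y X^T) / (A X X^T)
    X <- X . (A^T Y) / (A^T A X)

(element-wise product and division).  Started from any strictly positive
point these updates keep every entry non-negative and never increase the
divergence.  Because the quadratic cost has many local minima the solver
restarts from several seeded random initializations and keeps the best.

Scaling ambiguity is removed as is conventional for spectral unmixing: the
input matrix is normalized to unit Frobenius length (the scale being kept to
restore original intensities) and each column of ``A`` is normalized to unit
l1-norm with the scale transferred to the matching row of ``X``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FactorPair",
    "ConvergenceTrace",
    "ModelOrderResult",
    "DegenerateInputError",
    "NumericalError",
    "preprocess",
    "update_step",
    "factorize",
    "normalize_factors",
    "select_components",
    "DEFAULT_CANDIDATES",
]

DEFAULT_CANDIDATES: tuple[int, ...] = (2, 3, 4, 5, 6, 7)


class DegenerateInputError(ValueError):
    """Input matrix carries no usable signal (all zero / all negative)."""


class NumericalError(RuntimeError):
    """Non-finite values appeared during iteration."""


@dataclass
class FactorPair:
    """Basis matrix A (m x r), source matrix X (r x T) and intensity scale.

    After :func:`normalize_factors` every nonzero column of ``A`` has unit
    l1-norm; ``scale`` is the Frobenius norm removed from the input by
    :func:`preprocess`, so ``scale * A @ X`` approximates the original
    (clipped) spectrum.
    """

    A: np.ndarray
    X: np.ndarray
    scale: float = 1.0

    @property
    def rank(self) -> int:
        return self.A.shape[1]

    def reconstruct(self, restore_scale: bool = True) -> np.ndarray:
        out = self.A @ self.X
        return out * self.scale if restore_scale else out


@dataclass
class ConvergenceTrace:
    residuals: np.ndarray  # D(A, X) after each iteration
    stopped_at: int
    stop_reason: str  # "plateau" | "max_iter" | "tol"

    @property
    def final_residual(self) -> float:
        return float(self.residuals[-1])


@dataclass
class ModelOrderResult:
    candidate_r: list[int]
    final_residuals: dict[int, float]
    chosen_r: int
    traces: dict[int, ConvergenceTrace] = field(default_factory=dict)


def preprocess(Y: np.ndarray) -> tuple[np.ndarray, float]:
    """Clip negatives to zero and normalize to unit Frobenius length.

    Returns ``(Ynorm, scale)`` with ``Ynorm = clip(Y, 0) / scale`` and
    ``scale = ||clip(Y, 0)||_F``.  Negative baseline values carry no signal
    under the non-negativity premise and are clipped rather than shifted.
    """
    Y = np.asarray(Y, dtype=float)
    if not np.all(np.isfinite(Y)):
        raise DegenerateInputError("input matrix contains non-finite values")
    clipped = np.maximum(Y, 0.0)
    scale = float(np.linalg.norm(clipped))
    if scale == 0.0:
        raise DegenerateInputError("input matrix is all zero after clipping")
    return clipped / scale, scale


def update_step(
    Y: np.ndarray, A: np.ndarray, X: np.ndarray, eps: float = 1e-12
) -> tuple[np.ndarray, np.ndarray]:
    """One alternating multiplicative update of (A, X).

    ``eps`` is added to each denominator entry to avoid 0/0; exact zeros in a
    factor stay zero (multiplicative invariance).  The A-rule is applied
    first and the X-rule then uses the updated A.
    """
    if A.shape[1] != X.shape[0] or Y.shape != (A.shape[0], X.shape[1]):
        raise ValueError(
            f"shape mismatch: Y{Y.shape}, A{A.shape}, X{X.shape}"
        )
    A = A * (Y @ X.T) / (A @ (X @ X.T) + eps)
    X = X * (A.T @ Y) / ((A.T @ A) @ X + eps)
    return A, X


def _divergence(Y: np.ndarray, A: np.ndarray, X: np.ndarray) -> float:
    R = Y - A @ X
    return float(np.vdot(R, R).real)


def normalize_factors(A: np.ndarray, X: np.ndarray, scale: float = 1.0) -> FactorPair:
    """Scale each nonzero column of A to unit l1-norm, compensating in X.

    The product ``A @ X`` is unchanged; zero columns of A are left alone.
    """
    A = np.array(A, dtype=float)
    X = np.array(X, dtype=float)
    colsum = A.sum(axis=0)
    nz = colsum > 0
    A[:, nz] = A[:, nz] / colsum[nz]
    X[nz, :] = X[nz, :] * colsum[nz, None]
    return FactorPair(A=A, X=X, scale=float(scale))


def _nndsvd_init(Y: np.ndarray, r: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic SVD-based initialization (NNDSVD).

    Splits each leading singular triplet into its dominant non-negative
    part; zeros are floored to a small positive value so the multiplicative
    updates can still move every entry.  Gives the solver a start aligned
    with the data's leading subspace, which reliably seeds one component
    per resolvable line where random starts often collapse two components
    onto one strong peak and starve a weak one.
    """
    U, s, Vt = np.linalg.svd(Y, full_matrices=False)
    m, T = Y.shape
    r_eff = min(r, s.size)
    A = np.zeros((m, r))
    X = np.zeros((r, T))
    A[:, 0] = np.sqrt(s[0]) * np.abs(U[:, 0])
    X[0] = np.sqrt(s[0]) * np.abs(Vt[0])
    for j in range(1, r_eff):
        u, v = U[:, j], Vt[j]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        npos = np.linalg.norm(up) * np.linalg.norm(vp)
        nneg = np.linalg.norm(un) * np.linalg.norm(vn)
        if npos >= nneg and npos > 0:
            A[:, j] = np.sqrt(s[j] * npos) * up / np.linalg.norm(up)
            X[j] = np.sqrt(s[j] * npos) * vp / np.linalg.norm(vp)
        elif nneg > 0:
            A[:, j] = np.sqrt(s[j] * nneg) * un / np.linalg.norm(un)
            X[j] = np.sqrt(s[j] * nneg) * vn / np.linalg.norm(vn)
    floor = max(float(Y.mean()) * 1e-4, 1e-12)
    A[A < floor] = floor
    X[X < floor] = floor
    return A, X


def _run_once(
    Y: np.ndarray,
    r: int,
    rng: np.random.Generator,
    max_iter: int,
    eps: float,
    plateau_window: int,
    plateau_tol: float,
    tol: float,
    init: str = "random",
) -> tuple[np.ndarray, np.ndarray, ConvergenceTrace]:
    m, T = Y.shape
    if init == "nndsvd":
        A, X = _nndsvd_init(Y, r)
    else:
        A = rng.uniform(0.1, 1.1, size=(m, r))
        X = rng.uniform(0.1, 1.1, size=(r, T))
    residuals = np.empty(max_iter)
    prev = _divergence(Y, A, X)
    stagnant = 0
    stop_reason = "max_iter"
    it = 0
    for it in range(max_iter):
        A = A * (Y @ X.T) / (A @ (X @ X.T) + eps)
        X = X * (A.T @ Y) / ((A.T @ A) @ X + eps)
        d = _divergence(Y, A, X)
        residuals[it] = d
        if not np.isfinite(d):
            raise NumericalError(f"non-finite divergence at iteration {it}")
        if d <= tol:  # residual at the numerical floor
            stop_reason = "tol"
            break
        improvement = (prev - d) / max(d, 1e-300)
        stagnant = stagnant + 1 if improvement < plateau_tol else 0
        prev = d
        if stagnant >= plateau_window:
            stop_reason = "plateau"
            break
    trace = ConvergenceTrace(
        residuals=residuals[: it + 1].copy(), stopped_at=it + 1, stop_reason=stop_reason
    )
    return A, X, trace


def factorize(
    Y: np.ndarray,
    r: int,
    *,
    max_iter: int = 5000,
    eps: float = 1e-12,
    plateau_window: int = 10,
    plateau_tol: float = 1e-8,
    tol: float = 1e-14,
    restarts: int = 5,
    seed: int | None = None,
    scale: float = 1.0,
) -> tuple[FactorPair, ConvergenceTrace]:
    """Factorize a preprocessed (non-negative) matrix at a fixed rank r.

    Runs ``restarts`` multiplicative-update descents — the first from the
    deterministic SVD-based (NNDSVD) start, the rest from strictly positive
    uniform(0.1, 1.1) seeded random starts — and keeps the lowest final
    divergence.  Iteration stops once the relative residual improvement has
    been below ``plateau_tol`` for ``plateau_window`` consecutive iterations,
    at ``max_iter``, or when the divergence reaches the absolute floor
    ``tol``.

    ``scale`` is the intensity scale from :func:`preprocess` and is carried
    into the returned :class:`FactorPair` (the factors themselves describe
    the normalized matrix).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("factorize expects a 2D matrix; see ntf2 for tensors")
    if r < 1:
        raise ValueError(f"rank must be >= 1, got {r}")
    if r > min(Y.shape):
        warnings.warn(
            f"rank {r} exceeds min(Y.shape)={min(Y.shape)}; over-complete "
            "factorization will not be unique",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    best: tuple[float, np.ndarray, np.ndarray, ConvergenceTrace] | None = None
    for i in range(max(1, restarts)):
        A, X, trace = _run_once(
            Y, r, rng, max_iter, eps, plateau_window, plateau_tol, tol,
            init="nndsvd" if i == 0 else "random",
        )
        d = trace.final_residual
        if best is None or d < best[0]:
            best = (d, A, X, trace)
    assert best is not None
    _, A, X, trace = best
    return normalize_factors(A, X, scale), trace


def select_components(
    Y: np.ndarray,
    candidates=DEFAULT_CANDIDATES,
    *,
    tie_tol_abs: float = 1e-5,
    tie_tol_rel: float = 0.02,
    seed: int | None = None,
    **config,
) -> ModelOrderResult:
    """Choose the number of components by the residual-decay sweep.

    Runs :func:`factorize` for each candidate rank with the plateau stopping
    rule and picks the rank achieving the minimum final divergence; ranks
    whose residual is within ``max(tie_tol_abs, tie_tol_rel * min)`` of the
    minimum are treated as ties, broken toward the smallest rank (parsimony).
    ``Y`` is expected preprocessed (unit Frobenius norm), so the absolute tie
    tolerance is on that normalized scale; its default reflects the
    multiplicative solver's own convergence precision on strongly overlapped
    data at the default iteration budget — a residual gap smaller than that
    is not evidence for a larger model.
    """
    candidates = sorted(int(c) for c in candidates)
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    ss = np.random.SeedSequence(seed)
    child_seeds = {
        r: int(s.generate_state(1)[0] % (2**31))
        for r, s in zip(candidates, ss.spawn(len(candidates)))
    }
    residuals: dict[int, float] = {}
    traces: dict[int, ConvergenceTrace] = {}
    for r in candidates:
        _, trace = factorize(Y, r, seed=child_seeds[r], **config)
        residuals[r] = trace.final_residual
        traces[r] = trace
    rmin = min(residuals.values())
    tol = max(tie_tol_abs, tie_tol_rel * rmin)
    chosen = next(r for r in candidates if residuals[r] <= rmin + tol)
    return ModelOrderResult(
        candidate_r=candidates,
        final_residuals=residuals,
        chosen_r=chosen,
        traces=traces,
    )
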