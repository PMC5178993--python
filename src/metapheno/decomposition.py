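"""Construction of metaphenotypes: PCA, cross-validated choice of the
number of components, fastICA, and canonical sign/order resolution.

Both methods factor the standardized trait matrix as ``Xs ~ M @ W``:
rows of ``W`` (k x m) are component loadings on the traits, columns of
``M`` (n x k) are the component scores — the metaphenotypes.  ICA is a
rotation of the k-dimensional PCA-whitened space, so at equal k both
methods share the same reconstruction residual.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConvergenceError, ValidationError


@dataclass
class Decomposition:
    method: str  # "PCA" | "ICA"
    weights: np.ndarray  # k x m
    scores: np.ndarray  # n x k
    explained_variance: np.ndarray  # k, fractions of total Xs variance
    trait_names: list[str]
    component_labels: list[str] = field(default_factory=list)
    center: np.ndarray | None = None
    scale: np.ndarray | None = None

    def __post_init__(self) -> None:
        k, m = self.weights.shape
        if self.scores.shape[1] != k:
            raise ValidationError("scores/weights component counts differ")
        if len(self.trait_names) != m:
            raise ValidationError("trait_names length does not match weights")
        if not self.component_labels:
            self.component_labels = [f"C{i + 1}" for i in range(k)]

    @property
    def k(self) -> int:
        return self.weights.shape[0]


def standardize(X: np.ndarray, trait_names: list[str] | None = None):
    """Center and scale each column to mean 0, sd 1 (ddof=0).

    Returns ``(Xs, center, scale)``.  A zero-variance column is an
    error: it cannot carry information into any component.
    """
    X = np.asarray(X, dtype=float)
    if np.isnan(X).any():
        raise ValidationError("standardize requires a complete matrix (impute first)")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    zero = np.flatnonzero(scale == 0.0)
    if zero.size:
        names = (
            [trait_names[j] for j in zero] if trait_names else list(zero)
        )
        raise ValidationError(f"zero-variance trait(s): {names}")
    return (X - center) / scale, center, scale


def pca(
    Xs: np.ndarray,
    k: int | str = "all",
    trait_names: list[str] | None = None,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
) -> Decomposition:
    """Eigendecomposition of the sample covariance of ``Xs``.

    Rows of the returned weights are the top-k eigenvectors (orthonormal);
    scores are the projections; explained_variance are eigenvalue
    fractions of the total variance.
    """
    Xs = np.asarray(Xs, dtype=float)
    n, m = Xs.shape
    if k == "all":
        k = m
    k = int(k)
    if not 1 <= k <= m:
        raise ValidationError(f"k={k} outside [1, {m}]")
    C = (Xs - Xs.mean(axis=0)).T @ (Xs - Xs.mean(axis=0)) / n
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    W = evecs[:, :k].T
    # canonical eigenvector sign: largest-|entry| coordinate positive
    for i in range(k):
        j = int(np.argmax(np.abs(W[i])))
        if W[i, j] < 0:
            W[i] = -W[i]
    M = Xs @ W.T
    ev = evals[:k] / evals.sum()
    return Decomposition(
        method="PCA",
        weights=W,
        scores=M,
        explained_variance=ev,
        trait_names=list(trait_names) if trait_names else [f"T{j+1}" for j in range(m)],
        center=center,
        scale=scale,
    )


# ---------------------------------------------------------------------------
# Cross-validated choice of k (element-wise / Wold-style PRESS)
# ---------------------------------------------------------------------------

def _empca_reconstruct(
    X: np.ndarray, mask_missing: np.ndarray, k: int, max_iter: int = 60, tol: float = 1e-5
) -> np.ndarray:
    """Rank-k EM-PCA reconstruction treating ``mask_missing`` cells as missing."""
    Xw = X.copy()
    col_means = np.array(
        [
            X[~mask_missing[:, j], j].mean() if (~mask_missing[:, j]).any() else 0.0
            for j in range(X.shape[1])
        ]
    )
    for j in range(X.shape[1]):
        Xw[mask_missing[:, j], j] = col_means[j]
    recon = Xw
    for _ in range(max_iter):
        mu = Xw.mean(axis=0)
        U, s, Vt = np.linalg.svd(Xw - mu, full_matrices=False)
        recon = mu + (U[:, :k] * s[:k]) @ Vt[:k]
        new_vals = recon[mask_missing]
        delta = np.max(np.abs(new_vals - Xw[mask_missing])) if new_vals.size else 0.0
        Xw[mask_missing] = new_vals
        if delta < tol:
            break
    return recon


def choose_k_cv(
    Xs: np.ndarray,
    k_max: int,
    n_folds: int = 5,
    seed: int = 0,
    max_iter: int = 60,
) -> tuple[int, np.ndarray]:
    """Element-wise (Wold-style) cross-validation for the number of components.

    Cells are partitioned at random into ``n_folds`` groups; each group
    in turn is treated as missing and reconstructed by rank-k EM-PCA on
    the remaining cells; squared prediction error accumulates into
    PRESS(k).  Returns the argmin k and the full PRESS curve (index 0
    corresponds to k=1).
    """
    Xs = np.asarray(Xs, dtype=float)
    n, m = Xs.shape
    if not 1 <= k_max <= m - 1:
        raise ValidationError(f"k_max={k_max} must lie in [1, m-1={m - 1}]")
    if n_folds < 2:
        raise ValidationError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    fold = rng.integers(0, n_folds, size=(n, m))
    press = np.zeros(k_max)
    for f in range(n_folds):
        held = fold == f
        # guard: never blank out an entire row or column
        for i in np.flatnonzero(held.all(axis=1)):
            held[i, rng.integers(0, m)] = False
        for j in np.flatnonzero(held.all(axis=0)):
            held[rng.integers(0, n), j] = False
        for k in range(1, k_max + 1):
            recon = _empca_reconstruct(Xs, held, k, max_iter=max_iter)
            press[k - 1] += float(((Xs - recon)[held] ** 2).sum())
    return int(np.argmin(press) + 1), press


# ---------------------------------------------------------------------------
# fastICA (negentropy fixed point, symmetric decorrelation)
# ---------------------------------------------------------------------------

def _g_logcosh(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    gu = np.tanh(u)
    return gu, 1.0 - gu**2


def _g_exp(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.exp(-0.5 * u**2)
    return u * e, (1.0 - u**2) * e

_CONTRASTS = {"logcosh": _g_logcosh, "exp": _g_exp}


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    evals, evecs = np.linalg.eigh(W @ W.T)
    evals = np.clip(evals, 1e-12, None)
    return (evecs * (1.0 / np.sqrt(evals))) @ evecs.T @ W


def fastica(
    Xs: np.ndarray,
    k: int,
    seed: int = 0,
    contrast: str = "logcosh",
    tol: float = 1e-6,
    max_iter: int = 500,
    trait_names: list[str] | None = None,
    center: np.ndarray | None = None,
    scale: np.ndarray | None = None,
    n_restarts: int = 5,
) -> Decomposition:
    """FastICA on the standardized trait matrix.

    PCA-whitens to ``k`` dimensions, then runs the symmetric fixed-point
    iteration maximizing the negentropy approximation E[G(w'z)] with
    G' = tanh (``logcosh``, default) or G'(u) = u exp(-u^2/2) (``exp``).
    On non-convergence the iteration restarts with a perturbed seed, up
    to ``n_restarts`` times.
    """
    Xs = np.asarray(Xs, dtype=float)
    n, m = Xs.shape
    if np.isnan(Xs).any():
        raise ValidationError("fastica requires a complete matrix")
    if not 1 <= k <= m:
        raise ValidationError(f"k={k} outside [1, {m}]")
    if contrast not in _CONTRASTS:
        raise ValidationError(f"unknown contrast {contrast!r}")
    g = _CONTRASTS[contrast]

    Xc = Xs - Xs.mean(axis=0)
    C = Xc.T @ Xc / n
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1][:k]
    d = evals[order]
    if np.any(d <= 1e-12):
        raise ValidationError("covariance is rank-deficient at the requested k")
    E = evecs[:, order]  # m x k
    Z = Xc @ E / np.sqrt(d)  # n x k whitened, unit variance (ddof=0)

    last_err: Exception | None = None
    for attempt in range(n_restarts):
        rng = np.random.default_rng(seed + 1000003 * attempt)
        Wr = _sym_decorrelate(rng.standard_normal((k, k)))
        converged = False
        for _ in range(max_iter):
            U = Z @ Wr.T  # n x k current sources
            gu, gpu = g(U)
            W_new = gu.T @ Z / n - (gpu.mean(axis=0))[:, None] * Wr
            W_new = _sym_decorrelate(W_new)
            lim = float(np.max(np.abs(1.0 - np.abs(np.sum(W_new * Wr, axis=1)))))
            Wr = W_new
            if lim < tol:
                converged = True
                break
        if converged:
            break
        last_err = ConvergenceError(
            f"fastICA did not converge in {max_iter} iterations "
            f"(attempt {attempt + 1}/{n_restarts}, seed {seed})"
        )
    else:
        raise last_err  # type: ignore[misc]

    S = Z @ Wr.T  # n x k, unit variance, independent
    # trait-space weights: Xs_hat = S @ W with W = Wr @ diag(sqrt d) @ E^T
    W = Wr @ (np.sqrt(d)[:, None] * E.T)
    total_var = Xc.var(axis=0, ddof=0).sum()
    ev = (W**2).sum(axis=1) / total_var  # unit-variance sources: var of s_i w_i
    return Decomposition(
        method="ICA",
        weights=W,
        scores=S,
        explained_variance=ev,
        trait_names=list(trait_names) if trait_names else [f"T{j+1}" for j in range(m)],
        center=center,
        scale=scale,
    )


def orient_and_order(d: Decomposition) -> Decomposition:
    """Resolve sign and order indeterminacy.

    Each component is flipped so its largest-|loading| trait loads
    positively; components are sorted by explained variance (descending,
    stable) and relabelled C1..Ck.  Idempotent.
    """
    W = d.weights.copy()
    M = d.scores.copy()
    for i in range(d.k):
        j = int(np.argmax(np.abs(W[i])))
        if W[i, j] < 0:
            W[i] = -W[i]
            M[:, i] = -M[:, i]
    order = np.argsort(-d.explained_variance, kind="mergesort")
    return Decomposition(
        method=d.method,
        weights=W[order],
        scores=M[:, order],
        explained_variance=d.explained_variance[order],
        trait_names=list(d.trait_names),
        component_labels=[f"C{i + 1}" for i in range(d.k)],
        center=d.center,
        scale=d.scale,
    )


def amari_index(W_est: np.ndarray, A_true: np.ndarray) -> float:
    """Amari performance index of an estimated unmixing against a true mixing.

    Zero iff ``W_est @ A_true`` is a scaled permutation; normalized to
    [0, 1]-ish scale by 2k(k-1).
    """
    P = np.abs(W_est @ A_true)
    k = P.shape[0]
    row = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    col = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((row.sum() + col.sum()) / (2.0 * k * (k - 1)))
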