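"""Missing-value imputation of the trait matrix by Bayesian/probabilistic PCA.

EM for probabilistic PCA on the observed cells only, with an
automatic-relevance (per-latent-column Gaussian prior) shrinkage so
superfluous columns collapse toward zero.  Traits are standardized on
their observed cells before fitting and de-standardized afterwards —
the trait panel mixes incompatible units.

The tracked objective is the negative penalized observed-data
log-posterior; every conditional-maximization step is exact, so it is
non-increasing across iterations (asserted in the property tests).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_io import PhenotypeMatrix
from .errors import ValidationError

logger = logging.getLogger(__name__)

_ARD_B = 1e-3  # Gamma(1, b) hyperprior scale on the column precisions


@dataclass
class BpcaModel:
    n_components: int
    loading_matrix: np.ndarray  # m x q, standardized-trait space
    mean_vector: np.ndarray  # m, standardized-trait space
    residual_variance: float
    converged: bool
    n_iterations: int
    trait_names: list[str]
    col_center: np.ndarray
    col_scale: np.ndarray
    alpha: np.ndarray = field(default_factory=lambda: np.empty(0))
    objective_trace: list[float] = field(default_factory=list)
    seed: int = 0


def _estep_row(
    y: np.ndarray,
    obs: np.ndarray,
    W: np.ndarray,
    mu: np.ndarray,
    s2: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and covariance of the latent vector for one row."""
    Wo = W[obs]
    q = W.shape[1]
    M = Wo.T @ Wo + s2 * np.eye(q)
    Minv = np.linalg.inv(M)
    Ex = Minv @ Wo.T @ (y[obs] - mu[obs])
    Sx = s2 * Minv
    return Ex, Sx


def _neg_log_posterior(
    Y: np.ndarray,
    obs: np.ndarray,
    W: np.ndarray,
    mu: np.ndarray,
    s2: float,
    alpha: np.ndarray,
) -> float:
    """Negative of observed-data loglik + ARD prior + Gamma(1, b) hyperprior."""
    ll = 0.0
    n, m = Y.shape
    q = W.shape[1]
    patterns: dict[bytes, list[int]] = {}
    for i in range(n):
        patterns.setdefault(obs[i].tobytes(), []).append(i)
    for key, rows in patterns.items():
        o = np.frombuffer(key, dtype=bool)
        if not o.any():
            continue
        Wo = W[o]
        C = Wo @ Wo.T + s2 * np.eye(int(o.sum()))
        sign, logdet = np.linalg.slogdet(C)
        Cinv = np.linalg.inv(C)
        R = Y[np.ix_(rows, np.flatnonzero(o))] - mu[o]
        quad = np.einsum("ij,jk,ik->i", R, Cinv, R)
        ll += -0.5 * (
            len(rows) * (o.sum() * np.log(2 * np.pi) + logdet) + quad.sum()
        )
    # log p(W | alpha) + log p(alpha), dropping alpha-free constants
    col_ss = (W**2).sum(axis=0)
    lp = float(
        np.sum(0.5 * m * np.log(alpha) - alpha * (0.5 * col_ss + _ARD_B))
    )
    return -(ll + lp)


def fit_bpca(
    X: PhenotypeMatrix,
    q: int | None = None,
    max_iter: int = 500,
    tol: float = 1e-5,
    seed: int = 0,
) -> BpcaModel:
    """Fit the probabilistic-PCA imputation model.

    ``q`` defaults to m - 1; the ARD prior selects the effective
    dimensionality.  Convergence is declared when the largest absolute
    change in the imputed (missing) cells falls below ``tol``.
    """
    Y_raw = np.asarray(X.values, dtype=float)
    n, m = Y_raw.shape
    obs = ~np.isnan(Y_raw)
    if not obs.any(axis=1).all():
        raise ValidationError("every row must have at least one observed value")
    if not obs.any(axis=0).all():
        raise ValidationError("every column must have at least one observed value")
    if q is None:
        q = m - 1
    if q > m - 1:
        raise ValidationError(f"q={q} must be <= m-1={m - 1}")

    # standardize on observed cells
    center = np.array([Y_raw[obs[:, j], j].mean() for j in range(m)])
    scale = np.array([Y_raw[obs[:, j], j].std(ddof=0) for j in range(m)])
    scale[scale == 0.0] = 1.0
    Y = (Y_raw - center) / scale

    if q == 0:
        # degenerate fall-back: column-mean model
        mu = np.array([Y[obs[:, j], j].mean() for j in range(m)])
        return BpcaModel(
            n_components=0,
            loading_matrix=np.zeros((m, 0)),
            mean_vector=mu,
            residual_variance=max(float(np.nanvar(Y)), 1e-12),
            converged=True,
            n_iterations=0,
            trait_names=list(X.trait_names),
            col_center=center,
            col_scale=scale,
            alpha=np.empty(0),
            seed=seed,
        )

    # deterministic init: SVD of the mean-imputed matrix
    Y0 = np.where(obs, Y, 0.0)
    mu = np.array([Y[obs[:, j], j].mean() for j in range(m)])
    U, s, Vt = np.linalg.svd(Y0 - mu, full_matrices=False)
    W = (Vt[:q].T * (s[:q] / np.sqrt(n)))
    s2 = max(float(np.mean((Y0 - mu)[obs] ** 2)) * 0.5, 1e-6)
    alpha = np.full(q, 1.0)

    prev_imputed = np.zeros(np.count_nonzero(~obs))
    converged = False
    objective: list[float] = []
    it = 0
    for it in range(1, max_iter + 1):
        # E-step, grouped by missingness pattern
        Ex = np.zeros((n, q))
        Sxx = np.zeros((q, q))  # sum of E[x x^T]
        patterns: dict[bytes, list[int]] = {}
        for i in range(n):
            patterns.setdefault(obs[i].tobytes(), []).append(i)
        Sx_by_row = np.zeros((n, q, q))
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            Wo = W[o]
            M = Wo.T @ Wo + s2 * np.eye(q)
            Minv = np.linalg.inv(M)
            Sx = s2 * Minv
            R = Y[np.ix_(rows, np.flatnonzero(o))] - mu[o]
            Ex[rows] = R @ Wo @ Minv.T
            Sx_by_row[rows] = Sx
            Sxx += len(rows) * Sx
        Sxx += Ex.T @ Ex

        # CM-step per trait j on rows where j is observed
        W_new = np.zeros_like(W)
        mu_new = np.zeros_like(mu)
        for j in range(m):
            rows = np.flatnonzero(obs[:, j])
            Exj = Ex[rows]
            Sxj = Sx_by_row[rows].sum(axis=0) + Exj.T @ Exj
            nj = rows.size
            A = np.zeros((q + 1, q + 1))
            A[0, 0] = nj
            A[0, 1:] = Exj.sum(axis=0)
            A[1:, 0] = A[0, 1:]
            A[1:, 1:] = Sxj + s2 * np.diag(alpha)
            b = np.zeros(q + 1)
            yj = Y[rows, j]
            b[0] = yj.sum()
            b[1:] = Exj.T @ yj
            sol = np.linalg.solve(A, b)
            mu_new[j] = sol[0]
            W_new[j] = sol[1:]

        # residual variance over observed cells
        total, count = 0.0, 0
        for key, rows in patterns.items():
            o = np.frombuffer(key, dtype=bool)
            cols = np.flatnonzero(o)
            R = Y[np.ix_(rows, cols)] - mu_new[cols] - Ex[rows] @ W_new[cols].T
            Wo = W_new[cols]
            tr = np.einsum("rab,ja,jb->r", Sx_by_row[rows], Wo, Wo)
            total += float((R**2).sum() + tr.sum())
            count += len(rows) * len(cols)
        s2_new = max(total / count, 1e-12)

        # ARD precision update (Gamma(1, b) hyperprior mode)
        col_ss = (W_new**2).sum(axis=0)
        alpha = m / (col_ss + 2.0 * _ARD_B)

        W, mu, s2 = W_new, mu_new, s2_new
        objective.append(_neg_log_posterior(Y, obs, W, mu, s2, alpha))

        # convergence: change in imputed cells
        imputed = np.empty_like(prev_imputed)
        pos = 0
        for i in range(n):
            h = ~obs[i]
            if h.any():
                k = int(h.sum())
                imputed[pos : pos + k] = mu[h] + W[h] @ Ex[i]
                pos += k
        if prev_imputed.size == 0:
            converged = True
            break
        delta = float(np.max(np.abs(imputed - prev_imputed))) if imputed.size else 0.0
        prev_imputed = imputed
        if it > 1 and delta < tol:
            converged = True
            break

    if not converged:
        logger.warning("bPCA EM did not converge in %d iterations", max_iter)
    return BpcaModel(
        n_components=q,
        loading_matrix=W,
        mean_vector=mu,
        residual_variance=s2,
        converged=converged,
        n_iterations=it,
        trait_names=list(X.trait_names),
        col_center=center,
        col_scale=scale,
        alpha=alpha,
        objective_trace=objective,
        seed=seed,
    )


def impute(X: PhenotypeMatrix, model: BpcaModel) -> PhenotypeMatrix:
    """Replace missing cells with posterior expectations; observed cells
    are returned bit-identical."""
    if list(X.trait_names) != list(model.trait_names):
        raise ValidationError("trait names do not match the fitted model")
    Y_raw = np.asarray(X.values, dtype=float)
    obs = ~np.isnan(Y_raw)
    Y = (Y_raw - model.col_center) / model.col_scale
    out = Y_raw.copy()
    W, mu, s2 = model.loading_matrix, model.mean_vector, model.residual_variance
    for i in range(Y.shape[0]):
        h = ~obs[i]
        if not h.any():
            continue
        if obs[i].any() and model.n_components > 0:
            Ex, _ = _estep_row(Y[i], obs[i], W, mu, s2)
            pred = mu[h] + W[h] @ Ex
        else:
            pred = mu[h]
        out[i, h] = pred * model.col_scale[h] + model.col_center[h]
    return PhenotypeMatrix(
        values=out,
        trait_names=list(X.trait_names),
        individual_ids=list(X.individual_ids),
        covariates=X.covariates.copy(),
        covariate_names=list(X.covariate_names),
        family_ids=list(X.family_ids) if X.family_ids is not None else None,
    )


def mean_impute(X: PhenotypeMatrix) -> PhenotypeMatrix:
    """Column-mean imputation baseline (used in RMSE comparisons)."""
    out = np.asarray(X.values, dtype=float).copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        col[np.isnan(col)] = np.nanmean(col)
    return PhenotypeMatrix(
        values=out,
        trait_names=list(X.trait_names),
        individual_ids=list(X.individual_ids),
        covariates=X.covariates.copy(),
        covariate_names=list(X.covariate_names),
        family_ids=list(X.family_ids) if X.family_ids is not None else None,
    )
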