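"""Polygenic variance-components mixed model: heritability and
likelihood-ratio SNP association in extended pedigrees.

Model: y ~ N(X beta, sigma_g^2 * A + sigma_e^2 * I) with A = 2*Phi, the
additive (numerator) relationship matrix.  Fitting eigendecomposes A
once per kinship matrix, then profiles beta and the total variance in
closed form while optimizing the 1-D heritability ratio
h = sigma_g^2 / (sigma_g^2 + sigma_e^2), constrained to [0, 1).

Both nested models of every likelihood-ratio test are fitted by full
maximum likelihood on the same complete-case individuals, so the
fixed-effect (SNP) LRT is valid; the heritability test against
sigma_g^2 = 0 uses the boundary mixture 0.5*chi2_0 + 0.5*chi2_1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .data_io import GenotypeMatrix
from .errors import UndefinedStatisticError, ValidationError
from .genotype_qc import maf as _maf
from .kinship import KinshipMatrix

logger = logging.getLogger(__name__)

_H_MAX = 1.0 - 1e-6


@dataclass
class VarCompFit:
    sigma_g2: float
    sigma_e2: float
    beta: np.ndarray
    loglik: float
    converged: bool
    h2: float
    n_used: int


@dataclass
class HeritabilityResult:
    metaphenotype_label: str
    h2r: float
    p_value: float
    sigma_g2: float
    sigma_e2: float
    lrt_stat: float


@dataclass
class AssocResult:
    snp_id: str
    metaphenotype_label: str
    beta_snp: float
    lrt_stat: float
    p_raw: float
    p_adjusted: float
    n_used: int
    testable: bool = True
    significant: bool = False
    chromosome: str = ""
    position: int = 0
    maf: float = float("nan")


class KinshipEigen:
    """Cached eigendecomposition of the additive relationship matrix."""

    def __init__(self, K: KinshipMatrix):
        A = K.additive
        A = 0.5 * (A + A.T)
        lam, U = np.linalg.eigh(A)
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        self.ids = list(K.individual_ids)
        self.n = len(self.ids)


def _profile_negloglik(
    h: float, lam: np.ndarray, yt: np.ndarray, Xt: np.ndarray
) -> tuple[float, np.ndarray, float]:
    """Negative loglik at heritability ratio h, with beta and total
    variance profiled out.  Returns (nll, beta, sigma_p2)."""
    n = yt.size
    v = h * lam + (1.0 - h)
    w = 1.0 / v
    XtW = Xt * w[:, None]
    XX = Xt.T @ XtW
    Xy = XtW.T @ yt
    try:
        beta = np.linalg.solve(XX, Xy)
    except np.linalg.LinAlgError as exc:
        raise ValidationError("singular fixed-effect design") from exc
    r = yt - Xt @ beta
    s2 = float((w * r**2).sum() / n)
    if s2 <= 0:
        return np.inf, beta, s2
    nll = 0.5 * (
        n * np.log(2.0 * np.pi) + n * np.log(s2) + np.log(v).sum() + n
    )
    return nll, beta, s2


def fit_polygenic(
    y: np.ndarray,
    C: np.ndarray | None,
    K: KinshipMatrix | KinshipEigen,
    snp: np.ndarray | None = None,
) -> VarCompFit:
    """Full-ML fit of the polygenic mixed model.

    ``C`` is the covariate matrix (an intercept is always prepended);
    ``snp`` an optional additively coded genotype column appended as a
    fixed effect.  Individuals with a missing genotype must be removed
    by the caller (see :func:`assoc_snp` for per-SNP complete-case
    handling).
    """
    eig = K if isinstance(K, KinshipEigen) else KinshipEigen(K)
    y = np.asarray(y, dtype=float)
    n = y.size
    if n != eig.n:
        raise ValidationError("y length does not match kinship matrix")
    if np.isnan(y).any():
        raise ValidationError("y must be complete")
    cols = [np.ones(n)]
    if C is not None and np.asarray(C).size:
        C = np.asarray(C, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.append(C)
    if snp is not None:
        g = np.asarray(snp, dtype=float)
        if np.isnan(g).any():
            raise ValidationError("snp column must be complete within this fit")
        cols.append(g[:, None])
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValidationError("singular fixed-effect design")

    yt = eig.U.T @ y
    Xt = eig.U.T @ X
    lam = eig.lam

    def f(h: float) -> float:
        return _profile_negloglik(h, lam, yt, Xt)[0]

    # coarse grid then bounded refinement (deterministic, avoids local dips)
    grid = np.linspace(0.0, _H_MAX, 21)
    vals = np.array([f(h) for h in grid])
    i0 = int(np.argmin(vals))
    lo = grid[max(i0 - 1, 0)]
    hi = grid[min(i0 + 1, grid.size - 1)]
    converged = True
    if lo == hi:
        h_opt = lo
    else:
        res = optimize.minimize_scalar(
            f, bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-8, "maxiter": 200},
        )
        h_opt = float(res.x)
        converged = bool(res.success)
        # the boundary h=0 may beat the interior optimum
        if f(0.0) <= res.fun:
            h_opt = 0.0
    nll, beta, s2 = _profile_negloglik(h_opt, lam, yt, Xt)
    return VarCompFit(
        sigma_g2=h_opt * s2,
        sigma_e2=max((1.0 - h_opt) * s2, 1e-300),
        beta=beta,
        loglik=-nll,
        converged=converged,
        h2=h_opt,
        n_used=n,
    )


def heritability(
    y: np.ndarray,
    C: np.ndarray | None,
    K: KinshipMatrix | KinshipEigen,
    label: str = "",
) -> HeritabilityResult:
    """Heritability estimate with a boundary-corrected LRT against
    sigma_g^2 = 0 (p from the 50:50 mixture of chi2_0 and chi2_1)."""
    eig = K if isinstance(K, KinshipEigen) else KinshipEigen(K)
    fit = fit_polygenic(y, C, eig)
    y = np.asarray(y, dtype=float)
    yt = eig.U.T @ y
    cols = [np.ones(y.size)]
    if C is not None and np.asarray(C).size:
        Ca = np.asarray(C, dtype=float)
        cols.append(Ca if Ca.ndim == 2 else Ca[:, None])
    Xt = eig.U.T @ np.column_stack(cols)
    nll0, _, _ = _profile_negloglik(0.0, eig.lam, yt, Xt)
    lrt = max(2.0 * (fit.loglik - (-nll0)), 0.0)
    p = 0.5 * float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 0.5
    return HeritabilityResult(
        metaphenotype_label=label,
        h2r=fit.h2,
        p_value=p,
        sigma_g2=fit.sigma_g2,
        sigma_e2=fit.sigma_e2,
        lrt_stat=lrt,
    )


def assoc_snp(
    y: np.ndarray,
    C: np.ndarray | None,
    K: KinshipMatrix,
    g: np.ndarray,
    snp_id: str = "",
    label: str = "",
    _cache: dict | None = None,
) -> AssocResult:
    """Likelihood-ratio test of one SNP on one metaphenotype.

    Individuals with a missing genotype are dropped from both nested
    fits (per-SNP complete case).  A SNP monomorphic after missingness
    is flagged untestable.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    obs = ~np.isnan(g)
    distinct = np.unique(g[obs])
    if distinct.size < 2:
        return AssocResult(
            snp_id=snp_id, metaphenotype_label=label, beta_snp=np.nan,
            lrt_stat=np.nan, p_raw=np.nan, p_adjusted=np.nan,
            n_used=int(obs.sum()), testable=False,
        )
    idx = np.flatnonzero(obs)
    key = None
    eig = None
    if _cache is not None:
        key = ("eig", obs.tobytes())
        eig = _cache.get(key)
    if eig is None:
        ids = [K.individual_ids[i] for i in idx]
        eig = KinshipEigen(K.subset(ids))
        if _cache is not None:
            _cache[key] = eig
    ys = y[idx]
    Cs = None
    if C is not None and np.asarray(C).size:
        Ca = np.asarray(C, dtype=float)
        Cs = (Ca if Ca.ndim == 2 else Ca[:, None])[idx]

    null_fit = None
    if _cache is not None:
        nkey = ("null", obs.tobytes(), label)
        null_fit = _cache.get(nkey)
    if null_fit is None:
        null_fit = fit_polygenic(ys, Cs, eig)
        if _cache is not None:
            _cache[nkey] = null_fit
    alt_fit = fit_polygenic(ys, Cs, eig, snp=g[idx])
    lrt = 2.0 * (alt_fit.loglik - null_fit.loglik)
    if lrt < -1e-8:
        logger.warning("negative LRT %.3g for %s/%s; clamping", lrt, snp_id, label)
    lrt = max(lrt, 0.0)
    p = float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0
    return AssocResult(
        snp_id=snp_id,
        metaphenotype_label=label,
        beta_snp=float(alt_fit.beta[-1]),
        lrt_stat=lrt,
        p_raw=p,
        p_adjusted=p,  # filled in by gwas()
        n_used=int(obs.sum()),
    )


def gwas(
    M: np.ndarray,
    G: GenotypeMatrix,
    C: np.ndarray | None,
    K: KinshipMatrix,
    alpha: float = 0.05,
    component_labels: list[str] | None = None,
) -> list[AssocResult]:
    """Association of every (SNP, metaphenotype) pair with a global
    Bonferroni correction: p_adjusted = min(1, p_raw * n_tests), where
    n_tests counts only testable pairs."""
    M = np.asarray(M, dtype=float)
    if M.ndim == 1:
        M = M[:, None]
    n, k = M.shape
    if n != G.n_individuals:
        raise ValidationError("score rows do not match genotype rows")
    if G.individual_ids != K.individual_ids:
        K = K.subset(G.individual_ids)
    labels = component_labels or [f"C{i + 1}" for i in range(k)]
    cache: dict = {}
    results: list[AssocResult] = []
    for j, marker in enumerate(G.markers):
        g = G.values[:, j]
        try:
            snp_maf = _maf(g)
        except UndefinedStatisticError:
            snp_maf = np.nan
        for c in range(k):
            r = assoc_snp(
                M[:, c], C, K, g,
                snp_id=marker.snp_id, label=labels[c], _cache=cache,
            )
            r.chromosome = marker.chromosome
            r.position = marker.position
            r.maf = snp_maf
            results.append(r)
    n_tests = sum(1 for r in results if r.testable)
    for r in results:
        if r.testable:
            r.p_adjusted = min(1.0, r.p_raw * n_tests)
            r.significant = r.p_adjusted <= alpha
    return results


def write_heritability_table(results: list[HeritabilityResult], path) -> None:
    """TSV with significance stars at 0.05 / 0.005 / 0.0005."""
    import pandas as pd

    def stars(p: float) -> str:
        if p < 0.0005:
            return "***"
        if p < 0.005:
            return "**"
        if p < 0.05:
            return "*"
        return ""

    pd.DataFrame(
        {
            "metaphenotype": [r.metaphenotype_label for r in results],
            "h2r": [r.h2r for r in results],
            "sigma_g2": [r.sigma_g2 for r in results],
            "sigma_e2": [r.sigma_e2 for r in results],
            "lrt_stat": [r.lrt_stat for r in results],
            "p_value": [r.p_value for r in results],
            "significance": [stars(r.p_value) for r in results],
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")
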