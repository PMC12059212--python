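"""Random-intercept mixed models for count, binary, and Gaussian responses.

Estimation engine for every model family the pipeline needs:

* Poisson and binomial GLMMs with a log/logit link, an optional exposure
  offset, and one or two random intercepts.  One grouping factor is
  integrated out by adaptive Gauss-Hermite quadrature (default 15 nodes);
  two crossed factors use a Laplace approximation over the joint
  random-effect vector.
* A hurdle model for floater counts during chick rearing: a Bernoulli part
  for the probability of a zero and a zero-truncated Poisson part for the
  positive counts, each with its own random intercept.  The two parts have
  orthogonal likelihoods and are estimated separately.
* Gaussian linear mixed models (REML, via statsmodels MixedLM), used for
  residualization (body condition, brood-size-corrected provisioning rate).

Fixed effects are declared through :class:`ModelSpec` terms: numeric
columns, treatment-coded factors with an explicit reference level, and raw
polynomials on standardized covariates.  Wald type-III chi-square tests and
odds ratios are computed from the fixed-effect covariance block.

The marginal likelihood is maximized by bounded quasi-Newton on
(beta, log sigma) from multiple starts (the GLM fit with sigma in
{0.1, 1.0}), which avoids the sigma = 0 boundary trap.  Non-convergence and
boundary estimates are flagged on the result, never silenced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy import optimize, special, stats

__all__ = [
    "Term",
    "ModelSpec",
    "FitResult",
    "HurdleResult",
    "fit_glm",
    "fit_glmm",
    "fit_hurdle",
    "fit_lmm",
    "wald_type3",
    "odds_ratio",
    "ztpois_logpmf",
]

_LOG_SIGMA_BOUNDS = (-7.0, 3.0)
_BOUNDARY_LOG_SIGMA = -5.0


# ---------------------------------------------------------------------------
# model specification and design matrices
# ---------------------------------------------------------------------------

@dataclass
class Term:
    """One fixed-effect term.

    ``kind='auto'`` resolves to a treatment-coded factor for non-numeric
    columns and a plain numeric covariate otherwise.  ``degree > 1`` expands
    a numeric covariate into a raw polynomial; ``standardize=True`` centers
    and scales it first (mean 0, sd 1).
    """

    column: str
    kind: str = "auto"  # auto | numeric | factor
    ref: str | None = None
    degree: int = 1
    standardize: bool = False


@dataclass
class ModelSpec:
    response: str
    family: str  # poisson | binomial | ztpoisson | gaussian
    terms: list = field(default_factory=list)
    offset: str | None = None  # exposure column; log taken internally
    groups: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.family not in {"poisson", "binomial", "ztpoisson", "gaussian"}:
            raise ValueError(f"unknown family {self.family!r}")
        if len(self.groups) > 2:
            raise ValueError("at most two random-intercept factors supported")
        self.terms = [t if isinstance(t, Term) else Term(t) for t in self.terms]


def build_design(spec: ModelSpec, data: pd.DataFrame
                 ) -> tuple[np.ndarray, list[str], dict[str, slice]]:
    """Fixed-effect design matrix with intercept; returns (X, names, term slices)."""
    cols: list[np.ndarray] = [np.ones(len(data))]
    names: list[str] = ["Intercept"]
    slices: dict[str, slice] = {}
    for term in spec.terms:
        start = len(names)
        col = data[term.column]
        kind = term.kind
        if kind == "auto":
            kind = "numeric" if pd.api.types.is_numeric_dtype(col) else "factor"
        if kind == "factor":
            levels = sorted(col.dropna().astype(str).unique())
            ref = term.ref if term.ref is not None else levels[0]
            if ref not in levels:
                raise ValueError(f"reference level {ref!r} absent from {term.column!r}")
            for lev in levels:
                if lev == ref:
                    continue
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term.column}[{lev}]")
        else:
            x = col.to_numpy(dtype=float)
            if term.standardize:
                x = (x - x.mean()) / x.std(ddof=0)
            for deg in range(1, term.degree + 1):
                cols.append(x ** deg)
                names.append(term.column if deg == 1 else f"{term.column}^{deg}")
        slices[term.column] = slice(start, len(names))
    X = np.column_stack(cols)
    return X, names, slices


# ---------------------------------------------------------------------------
# exponential-family log-likelihood kernels (per observation)
# ---------------------------------------------------------------------------

def ztpois_logpmf(y: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Zero-truncated Poisson log-pmf: p(y | lam, y > 0).

    p(y) = lam^y e^(-lam) / (y! (1 - e^(-lam))), y = 1, 2, ...
    """
    y = np.asarray(y, dtype=float)
    lam = np.asarray(lam, dtype=float)
    return (y * np.log(lam) - lam - special.gammaln(y + 1)
            - np.log(-np.expm1(-lam)))


class _Family:
    name: str

    @staticmethod
    def loglik(y, eta):  # pragma: no cover - interface
        raise NotImplementedError

    @staticmethod
    def d1(y, eta):
        raise NotImplementedError

    @staticmethod
    def d2(y, eta):
        raise NotImplementedError


class _Poisson(_Family):
    name = "poisson"

    @staticmethod
    def loglik(y, eta):
        return y * eta - np.exp(eta) - special.gammaln(y + 1)

    @staticmethod
    def d1(y, eta):
        return y - np.exp(eta)

    @staticmethod
    def d2(y, eta):
        return -np.exp(eta)


class _Binomial(_Family):
    name = "binomial"

    @staticmethod
    def loglik(y, eta):
        # y*eta - log(1 + e^eta), numerically stable
        return y * eta - np.logaddexp(0.0, eta)

    @staticmethod
    def d1(y, eta):
        return y - special.expit(eta)

    @staticmethod
    def d2(y, eta):
        p = special.expit(eta)
        return -p * (1.0 - p)


class _ZTPoisson(_Family):
    name = "ztpoisson"

    @staticmethod
    def loglik(y, eta):
        return ztpois_logpmf(y, np.exp(eta))

    @staticmethod
    def d1(y, eta):
        lam = np.exp(eta)
        mean = lam / (-np.expm1(-lam))  # E[Y] of the truncated distribution
        return y - mean

    @staticmethod
    def d2(y, eta):
        lam = np.exp(eta)
        q = -np.expm1(-lam)  # 1 - e^-lam
        mean = lam / q
        # d mean / d eta = lam * d mean/d lam
        dmean = lam * (q - lam * np.exp(-lam)) / q**2
        return -dmean


_FAMILIES = {"poisson": _Poisson, "binomial": _Binomial, "ztpoisson": _ZTPoisson}


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fixed effects, random-effect variances, and inference metadata."""

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    vcov: np.ndarray  # fixed-effect covariance block
    sigma2: dict[str, float]
    loglik: float
    converged: bool
    boundary: bool
    family: str
    n_obs: int
    term_slices: dict[str, slice]
    message: str = ""

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def coef_se(self, name: str) -> float:
        return float(self.se[self.names.index(name)])

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"term": self.names, "beta": self.beta, "se": self.se})


@dataclass
class HurdleResult:
    zero: FitResult  # P(zero) on the logit scale
    conditional: FitResult  # zero-truncated Poisson rate for positives

    @property
    def loglik(self) -> float:
        return self.zero.loglik + self.conditional.loglik


def wald_type3(fit: FitResult, term: str) -> tuple[float, int, float]:
    """Type-III Wald chi-square for one term's coefficient block.

    chi2 = beta' V^-1 beta over the block; df = block size.
    """
    sl = fit.term_slices[term]
    b = fit.beta[sl]
    V = fit.vcov[sl, sl]
    df = len(b)
    if df == 0:
        raise ValueError(f"term {term!r} has no coefficients")
    try:
        chi2 = float(b @ np.linalg.solve(V, b))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular covariance block for term {term!r}") from exc
    return chi2, df, float(stats.chi2.sf(chi2, df))


def odds_ratio(fit: FitResult, coef: str) -> tuple[float, tuple[float, float]]:
    """Odds ratio and 95% Wald CI for one coefficient of a binomial fit."""
    if fit.family != "binomial":
        raise ValueError("odds ratios require a binomial fit")
    b = fit.coef(coef)
    se = fit.coef_se(coef)
    return float(np.exp(b)), (float(np.exp(b - 1.96 * se)),
                              float(np.exp(b + 1.96 * se)))


# ---------------------------------------------------------------------------
# plain GLM (sigma = 0 limit, starting values, oracles)
# ---------------------------------------------------------------------------

def _glm_newton(fam, y, X, off, max_iter=100, tol=1e-10):
    """Newton-Raphson GLM fit; returns (beta, loglik, cov)."""
    p = X.shape[1]
    beta = np.zeros(p)
    # intercept start at the link of the mean
    mu0 = max(y.mean(), 1e-3)
    if fam.name in ("poisson", "ztpoisson"):
        beta[0] = np.log(mu0) - off.mean()
    elif fam.name == "binomial":
        mu0 = min(max(mu0, 1e-3), 1 - 1e-3)
        beta[0] = special.logit(mu0)
    ll_old = -np.inf
    for _ in range(max_iter):
        eta = X @ beta + off
        l1 = fam.d1(y, eta)
        W = -fam.d2(y, eta)
        g = X.T @ l1
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll = fam.loglik(y, X @ cand + off).sum()
            if np.isfinite(ll) and ll >= ll_old - 1e-12:
                break
            t /= 2
        beta = beta + t * step
        ll = fam.loglik(y, X @ beta + off).sum()
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            ll_old = ll
            break
        ll_old = ll
    eta = X @ beta + off
    W = -fam.d2(y, eta)
    H = (X * W[:, None]).T @ X
    cov = np.linalg.inv(H)
    return beta, float(ll_old), cov


def fit_glm(spec: ModelSpec, data: pd.DataFrame) -> FitResult:
    """Ordinary GLM (no random effects); also the sigma^2 = 0 limit."""
    fam = _FAMILIES[spec.family]
    X, names, slices = build_design(spec, data)
    y = data[spec.response].to_numpy(dtype=float)
    off = _log_offset(spec, data)
    beta, ll, cov = _glm_newton(fam, y, X, off)
    se = np.sqrt(np.diag(cov))
    return FitResult(names, beta, se, cov, {}, ll, True, False,
                     spec.family, len(y), slices)


def _log_offset(spec: ModelSpec, data: pd.DataFrame) -> np.ndarray:
    if spec.offset is None:
        return np.zeros(len(data))
    v = data[spec.offset].to_numpy(dtype=float)
    if np.any(v <= 0):
        raise ValueError("offset variable must be strictly positive")
    return np.log(v)


# ---------------------------------------------------------------------------
# one grouping factor: adaptive Gauss-Hermite quadrature
# ---------------------------------------------------------------------------

def _group_codes(data: pd.DataFrame, col: str) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(data[col], sort=True)
    if (codes < 0).any():
        raise ValueError(f"missing values in grouping factor {col!r}")
    return codes.astype(np.intp), len(uniques)


def _find_modes(fam, y, eta0, gidx, G, sigma2, b0=None, max_iter=50):
    """Per-group modes of loglik_g(b) - b^2/(2 sigma^2), Newton with halving."""
    b = np.zeros(G) if b0 is None else b0.copy()

    def objective(bv):
        l = np.bincount(gidx, weights=fam.loglik(y, eta0 + bv[gidx]), minlength=G)
        return l - bv**2 / (2 * sigma2)

    f = objective(b)
    for _ in range(max_iter):
        eta = eta0 + b[gidx]
        g1 = np.bincount(gidx, weights=fam.d1(y, eta), minlength=G) - b / sigma2
        if np.max(np.abs(g1)) < 1e-11 * (1.0 + np.max(np.abs(f))):
            break
        c = np.bincount(gidx, weights=-fam.d2(y, eta), minlength=G) + 1.0 / sigma2
        step = g1 / c
        t = np.ones(G)
        for _ in range(30):
            fnew = objective(b + t * step)
            bad = fnew < f - 1e-14
            if not bad.any():
                break
            t[bad] /= 2
        b = b + t * step
        f = objective(b)
    eta = eta0 + b[gidx]
    c = np.bincount(gidx, weights=-fam.d2(y, eta), minlength=G) + 1.0 / sigma2
    return b, c


def _agq_loglik(fam, y, eta0, gidx, G, sigma, nodes_t, nodes_w, b0=None):
    """Marginal log-likelihood by adaptive Gauss-Hermite quadrature."""
    sigma2 = sigma**2
    bhat, curv = _find_modes(fam, y, eta0, gidx, G, sigma2, b0=b0)
    s = 1.0 / np.sqrt(curv)  # (G,)
    K = len(nodes_t)
    logf = np.empty((G, K))
    for k in range(K):
        bk = bhat + np.sqrt(2.0) * s * nodes_t[k]
        l = np.bincount(gidx, weights=fam.loglik(y, eta0 + bk[gidx]), minlength=G)
        logf[:, k] = l - bk**2 / (2 * sigma2) + nodes_t[k] ** 2 + np.log(nodes_w[k])
    log_int = special.logsumexp(logf, axis=1) + 0.5 * np.log(2.0) + np.log(s)
    ll = log_int - np.log(sigma) - 0.5 * np.log(2 * np.pi)
    return float(ll.sum()), bhat


# ---------------------------------------------------------------------------
# two crossed factors: Laplace approximation
# ---------------------------------------------------------------------------

def _laplace_loglik(fam, y, eta0, g1idx, G1, g2idx, G2, sig, u0=None):
    """Joint-Laplace marginal log-likelihood for two crossed intercepts."""
    s2 = np.concatenate([np.full(G1, sig[0] ** 2), np.full(G2, sig[1] ** 2)])
    q = G1 + G2
    u = np.zeros(q) if u0 is None else u0.copy()

    def eta_of(uv):
        return eta0 + uv[:G1][g1idx] + uv[G1:][g2idx]

    def objective(uv):
        return fam.loglik(y, eta_of(uv)).sum() - 0.5 * np.sum(uv**2 / s2)

    def hessian(uv):
        W = -fam.d2(y, eta_of(uv))
        D1 = np.bincount(g1idx, weights=W, minlength=G1)
        D2 = np.bincount(g2idx, weights=W, minlength=G2)
        M = np.zeros((G1, G2))
        np.add.at(M, (g1idx, g2idx), W)
        H = np.block([[np.diag(D1), M], [M.T, np.diag(D2)]])
        H[np.diag_indices(q)] += 1.0 / s2
        return H

    f = objective(u)
    for _ in range(200):
        l1 = fam.d1(y, eta_of(u))
        grad = np.concatenate([
            np.bincount(g1idx, weights=l1, minlength=G1),
            np.bincount(g2idx, weights=l1, minlength=G2),
        ]) - u / s2
        if np.max(np.abs(grad)) < 1e-10 * (1.0 + abs(f)):
            break
        H = hessian(u)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, grad, rcond=None)[0]
        t = 1.0
        for _ in range(30):
            fnew = objective(u + t * step)
            if np.isfinite(fnew) and fnew >= f - 1e-14:
                break
            t /= 2
        u = u + t * step
        f = objective(u)
    sign, logdet = np.linalg.slogdet(hessian(u))
    if sign <= 0:
        return -np.inf, u
    ll = f - 0.5 * logdet - G1 * np.log(sig[0]) - G2 * np.log(sig[1])
    return float(ll), u


# ---------------------------------------------------------------------------
# GLMM driver
# ---------------------------------------------------------------------------

def _numeric_hessian(fun, x, h=1e-4):
    n = len(x)
    H = np.empty((n, n))
    hs = h * (1.0 + np.abs(x))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = hs[i]
            ej = np.zeros(n); ej[j] = hs[j]
            fpp = fun(x + ei + ej)
            fpm = fun(x + ei - ej)
            fmp = fun(x - ei + ej)
            fmm = fun(x - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    return H


def fit_glmm(spec: ModelSpec, data: pd.DataFrame, n_nodes: int = 15,
             compute_se: bool = True) -> FitResult:
    """Maximum-likelihood random-intercept GLMM.

    One grouping factor is handled by adaptive Gauss-Hermite quadrature with
    ``n_nodes`` nodes; two grouping factors (crossed) by a joint Laplace
    approximation.  With no grouping factors the fit reduces exactly to the
    ordinary GLM.  Grouping factors with a single observed level are pinned
    at sigma^2 = 0 (flagged as boundary) since the variance is then
    unidentifiable.
    """
    if spec.family == "gaussian":
        raise ValueError("use fit_lmm for gaussian responses")
    fam = _FAMILIES[spec.family]
    data = data.reset_index(drop=True)
    X, names, slices = build_design(spec, data)
    y = data[spec.response].to_numpy(dtype=float)
    off = _log_offset(spec, data)
    p = X.shape[1]

    groups = []
    pinned = []
    for col in spec.groups:
        gidx, G = _group_codes(data, col)
        if G < 2:
            pinned.append(col)
        else:
            groups.append((col, gidx, G))

    glm = fit_glm(spec, data)
    if not groups:
        glm.sigma2 = {col: 0.0 for col in pinned}
        glm.boundary = bool(pinned)
        return glm

    nodes_t, nodes_w = hermgauss(n_nodes)
    n_sig = len(groups)
    state = {"warm": None}

    def nll(theta):
        beta = theta[:p]
        sig = np.exp(theta[p:])
        eta0 = X @ beta + off
        if n_sig == 1:
            _, gidx, G = groups[0]
            ll, warm = _agq_loglik(fam, y, eta0, gidx, G, sig[0],
                                   nodes_t, nodes_w, b0=state["warm"])
        else:
            (_, g1, G1), (_, g2, G2) = groups
            ll, warm = _laplace_loglik(fam, y, eta0, g1, G1, g2, G2, sig,
                                       u0=state["warm"])
        state["warm"] = warm
        return -ll if np.isfinite(ll) else 1e12

    bounds = [(None, None)] * p + [_LOG_SIGMA_BOUNDS] * n_sig
    best = None
    for sig_start in (0.1, 1.0):
        state["warm"] = None
        x0 = np.concatenate([glm.beta, np.full(n_sig, np.log(sig_start))])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            # explicit finite-difference step: the default relative step is
            # smaller than the inner-solver noise floor and stalls the search
            res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                    options={"maxiter": 500, "ftol": 1e-13,
                                             "gtol": 1e-9, "eps": 1e-6})
        if best is None or res.fun < best.fun:
            best = res
    # derivative-free polish: the quadrature/Laplace objective carries tiny
    # inner-solver noise that can stall finite-difference quasi-Newton early
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        polish = optimize.minimize(
            nll, best.x, method="Nelder-Mead",
            options={"maxiter": 300, "xatol": 1e-7, "fatol": 1e-8})
    if polish.fun < best.fun:
        clipped = polish.x.copy()
        clipped[p:] = np.clip(clipped[p:], *_LOG_SIGMA_BOUNDS)
        if np.allclose(clipped, polish.x):
            best = polish
    theta = best.x
    ll = -float(best.fun)
    converged = bool(best.success) or abs(best.fun) < 1e11

    sigma2 = {}
    boundary = bool(pinned)
    for k, (col, _, _) in enumerate(groups):
        sigma2[col] = float(np.exp(theta[p + k]) ** 2)
        if theta[p + k] <= _BOUNDARY_LOG_SIGMA:
            boundary = True
    for col in pinned:
        sigma2[col] = 0.0

    if compute_se:
        state["warm"] = None
        H = _numeric_hessian(nll, theta)
        # variance components at the boundary make H singular; use the
        # pseudo-inverse and keep the beta block
        try:
            cov_full = np.linalg.inv(H)
        except np.linalg.LinAlgError:
            cov_full = np.linalg.pinv(H)
        cov = cov_full[:p, :p]
        diag = np.diag(cov).copy()
        if np.any(diag <= 0):
            cov = np.linalg.pinv(H)[:p, :p]
            diag = np.abs(np.diag(cov))
        se = np.sqrt(np.abs(diag))
    else:
        cov = np.full((p, p), np.nan)
        se = np.full(p, np.nan)

    return FitResult(names, theta[:p], se, cov, sigma2, ll, converged,
                     boundary, spec.family, len(y), slices,
                     message=str(best.message))


def fit_hurdle(spec: ModelSpec, data: pd.DataFrame, n_nodes: int = 15,
               compute_se: bool = True) -> HurdleResult:
    """Hurdle model: logit P(zero) + zero-truncated Poisson for positives.

    ``spec.family`` must be ``'ztpoisson'``; the same fixed-effect terms and
    grouping factors are used in both parts.  The exposure offset enters the
    conditional (count) part only.  Both parts carry their own random
    intercept and are estimated independently.
    """
    if spec.family != "ztpoisson":
        raise ValueError("hurdle spec must use the ztpoisson family")
    y = data[spec.response].to_numpy(dtype=float)
    if (y == 0).all() or (y > 0).all():
        raise ValueError("hurdle model needs both zero and positive counts")

    zero_data = data.copy()
    zero_data["_is_zero"] = (y == 0).astype(float)
    zero_spec = ModelSpec("_is_zero", "binomial", list(spec.terms),
                          offset=None, groups=list(spec.groups))
    zero_fit = fit_glmm(zero_spec, zero_data, n_nodes=n_nodes,
                        compute_se=compute_se)

    pos = data[y > 0].reset_index(drop=True)
    cond_spec = ModelSpec(spec.response, "ztpoisson", list(spec.terms),
                          offset=spec.offset, groups=list(spec.groups))
    cond_fit = fit_glmm(cond_spec, pos, n_nodes=n_nodes, compute_se=compute_se)
    return HurdleResult(zero_fit, cond_fit)


# ---------------------------------------------------------------------------
# Gaussian LMM (REML) with conditional residuals
# ---------------------------------------------------------------------------

def fit_lmm(spec: ModelSpec, data: pd.DataFrame
            ) -> tuple[FitResult, np.ndarray]:
    """Gaussian linear mixed model by REML; returns (fit, conditional residuals).

    Conditional residuals subtract both the fixed-effect prediction and the
    predicted (BLUP) random intercepts.  One grouping factor maps onto the
    MixedLM groups argument; two crossed factors are expressed as variance
    components within a single all-encompassing group.  With all variance
    components estimated at zero the residuals coincide with OLS residuals.
    """
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM

    if spec.family != "gaussian":
        raise ValueError("fit_lmm requires the gaussian family")
    data = data.reset_index(drop=True)
    X, names, slices = build_design(spec, data)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the aliased columns via the QR decomposition's tiny pivots
        _, R = np.linalg.qr(X)
        aliased = [names[j] for j in range(X.shape[1])
                   if abs(R[j, j]) < 1e-8 * abs(R).max()]
        raise ValueError(f"rank-deficient fixed-effect design; aliased: {aliased}")
    y = data[spec.response].to_numpy(dtype=float)

    # a (near-)perfect fixed-effect fit leaves no residual variance for the
    # mixed model's GLS step; the REML problem is then degenerate and the
    # OLS solution is exact
    ols_resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
    degenerate = np.var(y) == 0 or np.var(ols_resid) < 1e-12 * (1 + np.var(y))

    if not spec.groups or degenerate:
        ols = sm.OLS(y, X).fit()
        resid = y - X @ ols.params
        cov = np.asarray(ols.cov_params())
        fit = FitResult(names, np.asarray(ols.params), np.asarray(ols.bse),
                        cov, {}, float(ols.llf), True, False, "gaussian",
                        len(y), slices)
        return fit, resid

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if len(spec.groups) == 1:
            gcol = spec.groups[0]
            model = MixedLM(y, X, groups=data[gcol])
            res = model.fit(reml=True)
            sigma2 = {gcol: float(np.asarray(res.cov_re)[0, 0])}
            re_pred = np.zeros(len(y))
            re = res.random_effects
            for g, grp_idx in data.groupby(gcol).groups.items():
                re_pred[np.asarray(grp_idx)] = float(np.asarray(re[g])[0])
        else:
            exog_vc = {}
            for gcol in spec.groups:
                dummies = pd.get_dummies(data[gcol], dtype=float)
                exog_vc[gcol] = {"all": dummies}
            from statsmodels.regression.mixed_linear_model import VCSpec
            vc_names = list(exog_vc)
            vc_mats = [[exog_vc[g]["all"].to_numpy()] for g in vc_names]
            vc_colnames = [[list(exog_vc[g]["all"].columns)] for g in vc_names]
            vcs = VCSpec(vc_names, vc_colnames, vc_mats)
            groups = np.zeros(len(y))
            model = MixedLM(y, X, groups=groups,
                            exog_re=np.zeros((len(y), 0)), exog_vc=vcs)
            res = model.fit(reml=True)
            sigma2 = {g: float(res.vcomp[k]) for k, g in enumerate(vc_names)}
            re_all = res.random_effects[0.0]
            re_pred = np.zeros(len(y))
            pos0 = 0
            for k, g in enumerate(vc_names):
                ncol = vc_mats[k][0].shape[1]
                u = np.asarray(re_all)[pos0:pos0 + ncol]
                re_pred += vc_mats[k][0] @ u
                pos0 += ncol

    beta = np.asarray(res.fe_params)
    resid = y - X @ beta - re_pred
    cov = np.asarray(res.cov_params())[:len(beta), :len(beta)]
    boundary = any(v <= 1e-10 for v in sigma2.values())
    fit = FitResult(names, beta, np.asarray(res.bse_fe), cov, sigma2,
                    float(res.llf), bool(res.converged), boundary,
                    "gaussian", len(y), slices)
    return fit, resid
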