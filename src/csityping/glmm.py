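"""Generalized linear mixed models with crossed random effects.

Fits GLMMs of the form

    g(E[y]) = X beta + Z b,   b ~ N(0, Sigma(theta))

for the three families this package needs: gamma with identity link
(latencies), binomial with logit link (errors) and gaussian with identity
link (log-latencies).  ``Sigma`` is block diagonal over the levels of one or
more crossed grouping factors (e.g. participants and semantic categories),
each contributing a vector random effect (intercept and slope), optionally
with free correlation.

Estimation follows the standard Laplace-approximation scheme: random
effects are rescaled to spherical coordinates ``b = Lambda(theta) u`` with
``u ~ N(0, I)``; for fixed covariance parameters the joint mode of
``(beta, u)`` is found by penalized iteratively reweighted least squares
(PIRLS, Fisher weights, step-halving to keep the gamma mean positive), and
the profiled Laplace deviance

    -2 log L = -2 sum_i log f(y_i | mu_i) + ||u||^2 + log det(Lt Zt W Z L + I)

is minimized over ``theta`` (and the dispersion parameter, where the family
has one) with a quasi-Newton optimizer.  Fixed-effect standard errors are
Wald, conditional on the estimated covariance parameters, taken from the
fixed-effect block of the inverse of the full penalized information matrix.

For the gaussian/gamma families the response is internally rescaled by its
standard deviation so covariance parameters are O(1) regardless of the
measurement unit; estimates and standard errors are reported on the
original scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit, gammaln
from scipy.stats import norm

__all__ = ["RandomTerm", "GLMMFit", "fit_glmm", "GAMMA_IDENTITY", "BINOMIAL_LOGIT", "GAUSSIAN_IDENTITY"]

_MU_FLOOR = 1e-8


# ---------------------------------------------------------------------------
# families


class _Family:
    name = ""
    has_dispersion = False
    linear = False  # identity link + mu-independent weights: PIRLS is exact

    def loglik(self, y, mu, disp):  # pragma: no cover - interface
        raise NotImplementedError

    def weights(self, mu, disp):
        raise NotImplementedError

    def working_residual(self, y, mu):
        """(y - mu) * g'(mu); identity/logit specializations below."""
        raise NotImplementedError

    def mu_valid(self, mu, y):
        return True

    def init_mu(self, y):
        return y.astype(float)


class _GammaIdentity(_Family):
    """Gamma(shape k, mean mu), identity link; dispersion = log(shape)."""

    name = "gamma(identity)"
    has_dispersion = True

    def loglik(self, y, mu, disp):
        k = math.exp(disp)
        return np.sum(
            k * math.log(k) - gammaln(k) + (k - 1.0) * np.log(y) - k * np.log(mu) - k * y / mu
        )

    def weights(self, mu, disp):
        k = math.exp(disp)
        return k / mu**2

    def working_residual(self, y, mu):
        return y - mu

    def mu_valid(self, mu, y):
        return bool(np.all(mu > _MU_FLOOR))

    def init_disp(self, y, mu):
        # method-of-moments from Pearson residuals
        cv2 = max(np.mean(((y - mu) / mu) ** 2), 1e-3)
        return math.log(1.0 / cv2)


class _BinomialLogit(_Family):
    name = "binomial(logit)"
    has_dispersion = False

    def loglik(self, y, mu, disp):
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu))

    def weights(self, mu, disp):
        return np.clip(mu * (1 - mu), 1e-10, None)

    def working_residual(self, y, mu):
        # (y - mu) g'(mu) with g'(mu) = 1/(mu(1-mu))
        return (y - mu) / np.clip(mu * (1 - mu), 1e-10, None)

    def init_mu(self, y):
        return 0.25 + 0.5 * y.astype(float)


class _GaussianIdentity(_Family):
    """Gaussian, identity link; dispersion = log(sigma)."""

    name = "gaussian(identity)"
    has_dispersion = True
    linear = True

    def loglik(self, y, mu, disp):
        s2 = math.exp(2.0 * disp)
        return -0.5 * np.sum((y - mu) ** 2) / s2 - 0.5 * len(y) * math.log(
            2.0 * math.pi * s2
        )

    def weights(self, mu, disp):
        return np.full(mu.shape, math.exp(-2.0 * disp))

    def working_residual(self, y, mu):
        return y - mu

    def init_disp(self, y, mu):
        return 0.5 * math.log(max(np.var(y - mu), 1e-10))


GAMMA_IDENTITY = _GammaIdentity()
BINOMIAL_LOGIT = _BinomialLogit()
GAUSSIAN_IDENTITY = _GaussianIdentity()

_LINKS = {"gamma(identity)": "identity", "binomial(logit)": "logit", "gaussian(identity)": "identity"}


# ---------------------------------------------------------------------------
# random-effect structure


@dataclass
class RandomTerm:
    """One grouping factor's vector random effect.

    ``design`` holds the within-level covariates (a column of ones for the
    intercept, the centred predictor for the slope).  ``correlated=False``
    fits a diagonal covariance (the ``||`` notation of mixed-model formulas).
    """

    name: str
    codes: np.ndarray  # (n,) integer level codes in [0, n_levels)
    n_levels: int
    design: np.ndarray  # (n, k)
    correlated: bool = True
    column_names: tuple[str, ...] = ()

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.design = np.atleast_2d(np.asarray(self.design, dtype=float))
        if self.design.shape[0] != self.codes.shape[0]:
            raise ValueError("design and codes disagree on n")
        if not self.column_names:
            self.column_names = tuple(
                f"re{i}" for i in range(self.design.shape[1])
            )

    @property
    def k(self) -> int:
        return self.design.shape[1]

    @property
    def n_theta(self) -> int:
        return self.k * (self.k + 1) // 2 if self.correlated else self.k


class _Workspace:
    """Precomputed index structure for the crossed random-effects algebra.

    Every observation touches one level of each grouping factor, so all the
    weighted cross-products the PIRLS step needs reduce to ``np.bincount``
    accumulations over level codes — no sparse matrices required at these
    problem sizes (q of order 100).
    """

    def __init__(self, X: np.ndarray, terms: list[RandomTerm]):
        self.X = X
        self.terms = terms
        self.n, self.p = X.shape
        self.offsets = []
        q = 0
        for t in terms:
            self.offsets.append(q)
            q += t.n_levels * t.k
        self.q = q
        # joint codes for cross-term blocks
        self.cross = {}
        for i in range(len(terms)):
            for j in range(i + 1, len(terms)):
                self.cross[(i, j)] = (
                    terms[i].codes * terms[j].n_levels + terms[j].codes
                )

    def zl_rows(self, lambdas: list[np.ndarray]) -> list[np.ndarray]:
        """Per-term (n, k) row values of Z Lambda."""
        return [t.design @ L.T for t, L in zip(self.terms, lambdas)]

    def zb(self, zl: list[np.ndarray], u: np.ndarray) -> np.ndarray:
        """(Z Lambda) u for spherical coefficients u."""
        out = np.zeros(self.n)
        for t, rows, off in zip(self.terms, zl, self.offsets):
            U = u[off : off + t.n_levels * t.k].reshape(t.n_levels, t.k)
            out += np.einsum("ij,ij->i", rows, U[t.codes])
        return out

    def normal_equations(self, zl, w, z):
        """Dense (p+q) system: blocks of A'WA + ridge(u) and rhs A'Wz."""
        p, q, n = self.p, self.q, self.n
        M = np.zeros((p + q, p + q))
        rhs = np.zeros(p + q)
        Xw = self.X * w[:, None]
        M[:p, :p] = self.X.T @ Xw
        rhs[:p] = Xw.T @ z
        wz = w * z
        for ti, (t, rows, off) in enumerate(zip(self.terms, zl, self.offsets)):
            G, k = t.n_levels, t.k
            for a in range(k):
                col = off + a
                rhs[p + col : p + off + G * k : k] = np.bincount(
                    t.codes, wz * rows[:, a], minlength=G
                )
                for pc in range(p):
                    M[pc, p + col : p + off + G * k : k] = np.bincount(
                        t.codes, w * self.X[:, pc] * rows[:, a], minlength=G
                    )
                for b in range(a, k):
                    vals = np.bincount(t.codes, w * rows[:, a] * rows[:, b], minlength=G)
                    ra = slice(p + off + a, p + off + G * k, k)
                    rb = slice(p + off + b, p + off + G * k, k)
                    idx = np.arange(G)
                    M[p + off + a + k * idx, p + off + b + k * idx] = vals
                    if b != a:
                        M[p + off + b + k * idx, p + off + a + k * idx] = vals
        for (i, j), joint in self.cross.items():
            ti, tj = self.terms[i], self.terms[j]
            offi, offj = self.offsets[i], self.offsets[j]
            Gi, Gj = ti.n_levels, tj.n_levels
            for a in range(ti.k):
                for b in range(tj.k):
                    block = np.bincount(
                        joint, w * zl[i][:, a] * zl[j][:, b], minlength=Gi * Gj
                    ).reshape(Gi, Gj)
                    rs = slice(p + offi + a, p + offi + Gi * ti.k, ti.k)
                    cs = slice(p + offj + b, p + offj + Gj * tj.k, tj.k)
                    M[rs, cs] = block
                    M[cs, rs] = block.T
        M[p:, p:] += np.eye(self.q)
        M[:p, :p] += 0.0
        # symmetrize the fixed/random coupling already set above
        M[p:, :p] = M[:p, p:].T
        return M, rhs


def _lambda_blocks(terms: list[RandomTerm], theta: np.ndarray) -> list[np.ndarray]:
    """Per-term lower-triangular Cholesky factor of the level covariance."""
    out = []
    pos = 0
    for term in terms:
        k = term.k
        L = np.zeros((k, k))
        if term.correlated:
            idx = np.tril_indices(k)
            L[idx] = theta[pos : pos + term.n_theta]
        else:
            np.fill_diagonal(L, theta[pos : pos + k])
        out.append(L)
        pos += term.n_theta
    return out


def _theta_init(terms: list[RandomTerm]) -> tuple[np.ndarray, list[tuple]]:
    """Start values (diag 0.3 on the scaled response) and optimizer bounds."""
    theta, bounds = [], []
    for term in terms:
        k = term.k
        if term.correlated:
            for i in range(k):
                for j in range(i + 1):
                    if i == j:
                        theta.append(0.3)
                        bounds.append((0.0, None))
                    else:
                        theta.append(0.0)
                        bounds.append((None, None))
        else:
            theta.extend([0.3] * k)
            bounds.extend([(0.0, None)] * k)
    return np.asarray(theta), bounds


# ---------------------------------------------------------------------------
# results


@dataclass
class GLMMFit:
    fixef: pd.DataFrame  # estimate, se, ci_low, ci_high, z, p per fixed effect
    family: str
    converged: bool
    message: str
    loglik: float
    n_obs: int
    theta: np.ndarray
    ranef_cov: dict[str, pd.DataFrame]  # per term: sd/corr summary
    dispersion: float | None  # gamma shape or gaussian sigma (original scale)
    structure: str
    reduction_trace: list[str] = field(default_factory=list)
    n_pirls_fail: int = 0

    @property
    def slope(self) -> float:
        return float(self.fixef["estimate"].iloc[-1])

    def wald_table(self) -> pd.DataFrame:
        return self.fixef.copy()


# ---------------------------------------------------------------------------
# fitting


def _pirls(y, ws: _Workspace, theta, disp, family, state, maxiter=80, tol=1e-10):
    """Penalized IRLS for the joint mode of (beta, u) at fixed (theta, disp).

    Returns (beta, u, mu, W, M) with M the final dense normal-equation
    matrix (whose random-effect block is Lt Zt W Z L + I), or None on
    breakdown.  Fisher weights; step-halving keeps the gamma mean positive.
    """
    X, p, q = ws.X, ws.p, ws.q
    lambdas = _lambda_blocks(ws.terms, theta)
    zl = ws.zl_rows(lambdas)

    beta = u = None
    if state.get("beta") is not None and state["beta"].shape == (p,):
        beta = state["beta"].copy()
        u = state["u"].copy()
        eta = X @ beta + ws.zb(zl, u)
        if family.name.startswith("gamma") and not family.mu_valid(eta, y):
            beta = u = None
    if beta is None:
        mu0 = family.init_mu(y)
        eta0 = mu0 if family.name != "binomial(logit)" else np.log(mu0 / (1 - mu0))
        beta, _, _, _ = np.linalg.lstsq(X, eta0, rcond=None)
        u = np.zeros(q)
        eta = X @ beta + ws.zb(zl, u)

    mu = expit(eta) if family.name == "binomial(logit)" else eta
    if family.name.startswith("gamma"):
        mu = np.maximum(mu, _MU_FLOOR)

    def penalized_obj(mu_, u_):
        return -family.loglik(y, mu_, disp) + 0.5 * u_ @ u_

    obj = penalized_obj(mu, u)
    M = None
    for _ in range(maxiter):
        W = family.weights(mu, disp)
        z = eta + family.working_residual(y, mu)
        M, rhs = ws.normal_equations(zl, W, z)
        try:
            c = cho_factor(M, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return None
        sol = cho_solve(c, rhs, check_finite=False)
        beta_new, u_new = sol[:p], sol[p:]

        step = 1.0
        for _half in range(30):
            b_try = beta + step * (beta_new - beta)
            u_try = u + step * (u_new - u)
            eta_try = X @ b_try + ws.zb(zl, u_try)
            mu_try = expit(eta_try) if family.name == "binomial(logit)" else eta_try
            if family.mu_valid(mu_try, y):
                obj_try = penalized_obj(mu_try, u_try)
                if np.isfinite(obj_try) and obj_try <= obj + 1e-8 * (1 + abs(obj)):
                    break
            step *= 0.5
        else:
            return None
        moved = step * (
            np.max(np.abs(beta_new - beta)) + np.max(np.abs(u_new - u), initial=0.0)
        )
        beta, u, eta, mu = b_try, u_try, eta_try, mu_try
        new_obj = penalized_obj(mu, u)
        if family.linear or (
            abs(obj - new_obj) < tol * (1.0 + abs(new_obj)) and moved < 1e-6
        ):
            obj = new_obj
            state["beta"], state["u"] = beta.copy(), u.copy()
            if family.linear:
                return beta, u, mu, family.weights(mu, disp), M
            break
        obj = new_obj
    W = family.weights(mu, disp)
    state["beta"], state["u"] = beta.copy(), u.copy()
    # refresh M at the final weights for the Laplace determinant
    z = eta + family.working_residual(y, mu)
    M, _ = ws.normal_equations(zl, W, z)
    return beta, u, mu, W, M


def _laplace_deviance(y, ws, theta, disp, family, state):
    res = _pirls(y, ws, theta, disp, family, state)
    if res is None:
        return 1e10, None
    beta, u, mu, W, M = res
    S = M[ws.p :, ws.p :]
    sign, logdet = np.linalg.slogdet(S)
    if sign <= 0:
        return 1e10, None
    dev = -2.0 * family.loglik(y, mu, disp) + u @ u + logdet
    return dev, (beta, u, mu, W, M)


def _laplace_deviance_at_beta(y, ws, theta, disp, beta, family, state, maxiter=60):
    """Laplace deviance with beta held fixed (u profiled by Fisher scoring).

    Used for the full-likelihood Wald covariance: the numerical Hessian of
    this function over (beta, theta, dispersion) propagates the uncertainty
    of the covariance parameters into the fixed-effect standard errors,
    which the conditional (profiled) information matrix ignores.
    """
    p = ws.p
    lambdas = _lambda_blocks(ws.terms, theta)
    zl = ws.zl_rows(lambdas)
    offset = ws.X @ beta
    u = state.get("u_fixed")
    if u is None or u.shape != (ws.q,):
        u = np.zeros(ws.q)
    eta = offset + ws.zb(zl, u)
    mu = expit(eta) if family.name == "binomial(logit)" else eta
    if family.name.startswith("gamma") and not family.mu_valid(mu, y):
        u = np.zeros(ws.q)
        eta = offset.copy()
        mu = expit(eta) if family.name == "binomial(logit)" else eta
        if not family.mu_valid(mu, y):
            return 1e10

    def pen(mu_, u_):
        return -family.loglik(y, mu_, disp) + 0.5 * u_ @ u_

    obj = pen(mu, u)
    S = None
    for _ in range(maxiter):
        W = family.weights(mu, disp)
        z = eta + family.working_residual(y, mu) - offset
        M, rhs = ws.normal_equations(zl, W, z)
        S, rhs_u = M[p:, p:], rhs[p:]
        try:
            c = cho_factor(S, lower=True, check_finite=False)
        except np.linalg.LinAlgError:
            return 1e10
        u_new = cho_solve(c, rhs_u, check_finite=False)
        step = 1.0
        for _half in range(30):
            u_try = u + step * (u_new - u)
            eta_try = offset + ws.zb(zl, u_try)
            mu_try = expit(eta_try) if family.name == "binomial(logit)" else eta_try
            if family.mu_valid(mu_try, y):
                obj_try = pen(mu_try, u_try)
                if np.isfinite(obj_try) and obj_try <= obj + 1e-8 * (1 + abs(obj)):
                    break
            step *= 0.5
        else:
            return 1e10
        moved = step * np.max(np.abs(u_new - u), initial=0.0)
        u, eta, mu = u_try, eta_try, mu_try
        new_obj = pen(mu, u)
        done = family.linear or (
            abs(obj - new_obj) < 1e-11 * (1 + abs(new_obj)) and moved < 1e-7
        )
        obj = new_obj
        if done:
            break
    state["u_fixed"] = u.copy()
    W = family.weights(mu, disp)
    z = eta + family.working_residual(y, mu) - offset
    M, _ = ws.normal_equations(zl, W, z)
    sign, logdet = np.linalg.slogdet(M[p:, p:])
    if sign <= 0:
        return 1e10
    return -2.0 * family.loglik(y, mu, disp) + u @ u + logdet


def _full_wald_vcov(y, ws, theta, disp, beta, family, has_disp):
    """Fixed-effect block of 2*inv(Hessian of the Laplace deviance).

    Central-difference Hessian over (beta, theta[, log dispersion]); returns
    None when the Hessian is not usable (e.g. variance parameters on the
    boundary).
    """
    x0 = np.concatenate([beta, theta, [disp]] if has_disp else [beta, theta])
    m = len(x0)
    state: dict = {}

    def f(x):
        b = x[: len(beta)]
        th = x[len(beta) : len(beta) + len(theta)]
        dd = x[-1] if has_disp else 0.0
        return _laplace_deviance_at_beta(y, ws, th, dd, b, family, state)

    h = np.maximum(1e-4, 1e-3 * np.abs(x0))
    f0 = f(x0)
    if not np.isfinite(f0) or f0 >= 1e9:
        return None
    H = np.empty((m, m))
    fp = np.empty(m)
    fm = np.empty(m)
    for i in range(m):
        ei = np.zeros(m)
        ei[i] = h[i]
        fp[i] = f(x0 + ei)
        fm[i] = f(x0 - ei)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / h[i] ** 2
    for i in range(m):
        for j in range(i + 1, m):
            ei = np.zeros(m)
            ej = np.zeros(m)
            ei[i] = h[i]
            ej[j] = h[j]
            fpp = f(x0 + ei + ej)
            fmm = f(x0 - ei - ej)
            H[i, j] = H[j, i] = (
                fpp - fp[i] - fp[j] + 2 * f0 - fm[i] - fm[j] + fmm
            ) / (2 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        return None
    try:
        cov = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    block = cov[: len(beta), : len(beta)]
    if np.any(np.diag(block) <= 0):
        return None
    return block


def fit_glmm(
    y: np.ndarray,
    X: np.ndarray,
    terms: list[RandomTerm],
    family: _Family = GAUSSIAN_IDENTITY,
    fixef_names: tuple[str, ...] = (),
    maxiter: int = 20_000,
    structure_label: str = "",
    se_method: str = "conditional",
) -> GLMMFit:
    """Fit a GLMM by Laplace approximation; see module docstring."""
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if not fixef_names:
        fixef_names = tuple(f"x{i}" for i in range(p))

    # rescale the response for unit-free covariance parameters
    if family.name == "binomial(logit)":
        scale = 1.0
    else:
        scale = float(np.std(y))
        scale = scale if scale > 0 else 1.0
    ys = y / scale

    ws = _Workspace(X, terms)
    theta0, bounds = _theta_init(terms)

    mu0 = family.init_mu(ys)
    if family.has_dispersion:
        disp0 = family.init_disp(ys, np.full(n, np.mean(ys)))
        x0 = np.concatenate([theta0, [disp0]])
        bounds = bounds + [(None, None)]
    else:
        x0 = theta0

    state: dict = {}
    n_theta = len(theta0)

    def objective(x):
        theta = x[:n_theta]
        disp = x[n_theta] if family.has_dispersion else 0.0
        dev, _ = _laplace_deviance(ys, ws, theta, disp, family, state)
        return dev

    opt = optimize.minimize(
        objective,
        x0,
        method="L-BFGS-B",
        bounds=bounds,
        options={
            "maxiter": min(maxiter, 10_000),
            "maxfun": min(maxiter, 100_000),
            "ftol": 1e-11,
            "gtol": 1e-7,
            "eps": 1e-5,
        },
    )
    theta = opt.x[:n_theta]
    disp = opt.x[n_theta] if family.has_dispersion else 0.0
    dev, parts = _laplace_deviance(ys, ws, theta, disp, family, state)
    converged = bool(opt.success) and parts is not None
    message = str(opt.message)
    if parts is None:
        raise RuntimeError(f"GLMM fit failed: {message}")
    beta, u, mu, W, M = parts

    # Wald covariance of beta: fixed-effect block of the inverse penalized
    # information (equals the Schur complement against the ridged RE block)
    try:
        vcov = np.linalg.inv(M)[:p, :p]
        if not np.all(np.isfinite(np.diag(vcov))) or np.any(np.diag(vcov) <= 0):
            raise np.linalg.LinAlgError("non-positive variance")
    except np.linalg.LinAlgError:
        vcov = np.full((p, p), np.nan)
        converged = False
        message += "; singular information matrix"

    if se_method == "full" and converged:
        full = _full_wald_vcov(
            ys, ws, theta, disp, beta, family, family.has_dispersion
        )
        if full is not None:
            # the full-likelihood variance dominates the conditional one;
            # numerical noise must not shrink an SE below the profiled value
            d_cond = np.diag(vcov).copy()
            vcov = full
            fix = np.maximum(np.diag(vcov), d_cond)
            np.fill_diagonal(vcov, fix)

    est = beta * scale
    se = np.sqrt(np.diag(vcov)) * scale
    zval = est / se
    pval = 2.0 * norm.sf(np.abs(zval))
    fixef = pd.DataFrame(
        {
            "term": fixef_names,
            "estimate": est,
            "se": se,
            "ci_low": est - 1.959963984540054 * se,
            "ci_high": est + 1.959963984540054 * se,
            "z": zval,
            "p": pval,
        }
    ).set_index("term")

    ranef_cov = {}
    for term, Lk in zip(terms, _lambda_blocks(terms, theta)):
        cov = (Lk @ Lk.T) * scale**2
        sd = np.sqrt(np.diag(cov))
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = cov / np.outer(sd, sd)
        ranef_cov[term.name] = pd.DataFrame(
            {"sd": sd, **{f"corr_{nm}": corr[:, i] for i, nm in enumerate(term.column_names)}},
            index=list(term.column_names),
        )

    if family.name == "gamma(identity)":
        dispersion = math.exp(disp)  # shape, scale-free
    elif family.name == "gaussian(identity)":
        dispersion = math.exp(disp) * scale  # residual sd, original units
    else:
        dispersion = None

    # log-likelihood on the original scale (Jacobian of y/scale)
    loglik = -0.5 * dev - (0.0 if scale == 1.0 else n * math.log(scale))

    return GLMMFit(
        fixef=fixef,
        family=family.name,
        converged=converged,
        message=message,
        loglik=loglik,
        n_obs=n,
        theta=theta,
        ranef_cov=ranef_cov,
        dispersion=dispersion,
        structure=structure_label
        or " + ".join(
            f"({'corr' if t.correlated else 'diag'}|{t.name})" for t in terms
        ),
    )
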