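"""Survival inference: mixed-effects logistic regression, AIC selection, VIF,
and two-sample permutation tests.

The survival model is a binomial GLMM with a logit link: survival to age 10
regressed on standardized network metrics, sex, and metric-by-sex
interactions, with random intercepts for grouping factors such as mother
identity and weaning-age group.  The marginal likelihood is evaluated with a
Laplace approximation (the same approximation lme4's glmer uses by default):
for candidate fixed effects beta and random-effect SDs, the random-effect
vector is profiled out at its conditional mode and the Gaussian curvature
correction applied.  Wald tests use the fixed-effect block of the joint
penalized Hessian, conditional on the estimated variances.

The permutation test compares two samples by the absolute difference in
means, enumerating all label splits exactly when feasible and falling back
to seeded Monte Carlo with the add-one p estimator otherwise.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

logger = logging.getLogger("calfnet")

#: Fixed-effect set of the default reporting model.
DEFAULT_FIXED = ("eigenvector", "strength", "sex", "eigenvector:sex")
DEFAULT_RANDOM = ("mother_id", "weaning_group")

_SEPARATION_BOUND = 10.0
_EXACT_ENUMERATION_LIMIT = 20000


@dataclass(frozen=True)
class ModelSpec:
    """Fixed and random structure of one candidate survival model.

    Fixed terms name standardized metric columns, ``sex`` (male indicator),
    or ``a:b`` products; interactions require both main effects.
    """

    fixed: tuple = DEFAULT_FIXED
    random: tuple = DEFAULT_RANDOM
    response: str = "survived"

    def __post_init__(self):
        for term in self.fixed:
            if ":" in term:
                a, b = term.split(":", 1)
                if a not in self.fixed or b not in self.fixed:
                    raise ValueError(
                        f"interaction {term!r} requires both main effects in the model"
                    )

    def label(self) -> str:
        return " + ".join(self.fixed) if self.fixed else "1"


@dataclass
class GLMMFit:
    """Fitted survival model: coefficient table, likelihood, variance components."""

    table: pd.DataFrame          # term, estimate, se, z, p
    loglik: float
    aic: float
    random_sd: dict
    fitted: np.ndarray           # per-subject fitted survival probability
    converged: bool
    separation: bool
    spec: ModelSpec
    n_obs: int

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "se"])


def _sigmoid(eta):
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


def _log1pexp(eta):
    return np.logaddexp(0.0, eta)


def _resolve_column(data: pd.DataFrame, term: str) -> np.ndarray:
    if term == "sex":
        if "sex" not in data.columns:
            raise ValueError("data lacks a 'sex' column")
        return (data["sex"].astype(str) == "M").to_numpy(float)
    for cand in (term, f"std_{term}"):
        if cand in data.columns:
            return data[cand].to_numpy(float)
    raise ValueError(f"cannot resolve model term {term!r} in data columns")


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Design matrix (with intercept) and response vector for a model spec."""
    cols = [np.ones(len(data))]
    names = ["intercept"]
    for term in spec.fixed:
        if ":" in term:
            a, b = term.split(":", 1)
            cols.append(_resolve_column(data, a) * _resolve_column(data, b))
        else:
            cols.append(_resolve_column(data, term))
        names.append(term)
    X = np.column_stack(cols)
    y = data[spec.response].astype(float).to_numpy()
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError(f"response {spec.response!r} must be binary")
    return X, y, names


class _RandomStructure:
    """Indicator-coded random intercepts: all linear algebra with the
    (conceptually sparse) Z matrix is done through bincount/add.at on the
    per-factor level codes, never through a dense n x q product."""

    def __init__(self, data: pd.DataFrame, factors):
        self.codes, self.blocks = [], []
        start = 0
        for fac in factors:
            if fac not in data.columns:
                raise ValueError(f"random grouping factor {fac!r} not in data")
            c, uniques = pd.factorize(data[fac].astype(str), sort=True)
            self.codes.append(np.asarray(c))
            self.blocks.append((fac, slice(start, start + len(uniques))))
            start += len(uniques)
        self.q = start
        self.n = len(data)

    def zu(self, u):
        out = np.zeros(self.n)
        for c, (_, sl) in zip(self.codes, self.blocks):
            out += u[sl][c]
        return out

    def zt(self, v):
        """Z' v."""
        out = np.empty(self.q)
        for c, (_, sl) in zip(self.codes, self.blocks):
            out[sl] = np.bincount(c, weights=v, minlength=sl.stop - sl.start)
        return out

    def ztwz(self, w):
        """Dense q x q matrix Z' diag(w) Z assembled blockwise."""
        H = np.zeros((self.q, self.q))
        for a, (ca, (_, sla)) in enumerate(zip(self.codes, self.blocks)):
            ga = sla.stop - sla.start
            idx = np.arange(sla.start, sla.stop)
            H[idx, idx] = np.bincount(ca, weights=w, minlength=ga)
            for cb, (_, slb) in list(zip(self.codes, self.blocks))[a + 1:]:
                cross = np.zeros((ga, slb.stop - slb.start))
                np.add.at(cross, (ca, cb), w)
                H[sla, slb] = cross
                H[slb, sla] = cross.T
        return H

    def ztwx(self, w, X):
        """q x p matrix Z' diag(w) X."""
        out = np.empty((self.q, X.shape[1]))
        for c, (_, sl) in zip(self.codes, self.blocks):
            for j in range(X.shape[1]):
                out[sl, j] = np.bincount(c, weights=w * X[:, j],
                                         minlength=sl.stop - sl.start)
        return out

    def sd_per_u(self, theta):
        sd = np.empty(self.q)
        for (_, sl), th in zip(self.blocks, theta):
            sd[sl] = math.exp(th)
        return sd


def _u_mode(beta, sd_per_u, X, y, rs: _RandomStructure, u0):
    """Newton ascent to the conditional mode of the random effects."""
    u = u0.copy()
    d = sd_per_u ** 2
    Xb = X @ beta

    def penalized(u):
        eta = Xb + rs.zu(u)
        return float(np.sum(y * eta - _log1pexp(eta)) - 0.5 * np.sum(u * u / d))

    f = penalized(u)
    for _ in range(60):
        eta = Xb + rs.zu(u)
        mu = _sigmoid(eta)
        grad = rs.zt(y - mu) - u / d
        if np.max(np.abs(grad)) < 1e-10:
            break
        w = mu * (1.0 - mu)
        H = rs.ztwz(w)
        H[np.diag_indices_from(H)] += 1.0 / d
        step = linalg.cho_solve(linalg.cho_factor(H, lower=True), grad)
        t = 1.0
        for _ in range(30):
            f_new = penalized(u + t * step)
            if f_new >= f - 1e-12:
                break
            t *= 0.5
        u = u + t * step
        f = f_new
    return u, f


def _laplace_loglik(beta, theta, X, y, rs: _RandomStructure, u_state):
    """Laplace marginal log-likelihood for given fixed effects and log-SDs."""
    if rs.q == 0:
        eta = X @ beta
        return float(np.sum(y * eta - _log1pexp(eta)))
    sd_per_u = rs.sd_per_u(theta)
    u, f = _u_mode(beta, sd_per_u, X, y, rs, u_state["u"])
    u_state["u"] = u
    mu = _sigmoid(X @ beta + rs.zu(u))
    w = mu * (1.0 - mu)
    S = rs.ztwz(w)
    S *= sd_per_u[:, None] * sd_per_u[None, :]
    S[np.diag_indices_from(S)] += 1.0
    sign, logdet = np.linalg.slogdet(S)
    return f - 0.5 * logdet


def fit_glmm(data: pd.DataFrame, spec: ModelSpec = ModelSpec(),
             keep_subject_random: bool = False) -> GLMMFit:
    """Fit a binomial logistic GLMM by Laplace-approximated ML.

    One row per subject; continuous predictors are assumed already
    standardized.  A ``subject_id`` random intercept is dropped by default
    with a warning, because a Bernoulli outcome observed once per subject
    cannot identify its variance; pass ``keep_subject_random=True`` to retain
    it.  Zero-variance random terms are handled at the boundary (the fit then
    matches plain logistic regression) rather than erroring.  Apparent
    separation (any |coefficient| beyond 10 on the logit scale) flags the
    fit instead of failing silently.
    """
    random_terms = list(spec.random)
    for unident in ("subject_id",):
        if unident in random_terms and not keep_subject_random:
            logger.warning(
                "dropping %r random intercept: one Bernoulli observation per "
                "subject cannot identify its variance", unident)
            random_terms.remove(unident)

    X, y, names = build_design(data, spec)
    n, p = X.shape
    rs = _RandomStructure(data, random_terms)
    K = len(rs.blocks)
    u_state = {"u": np.zeros(rs.q)}

    # plain-logistic Newton start for the fixed effects
    beta0 = np.zeros(p)
    for _ in range(25):
        mu = _sigmoid(X @ beta0)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        H = (X.T * w) @ X
        g = X.T @ (y - mu)
        try:
            step = linalg.solve(H, g, assume_a="pos")
        except linalg.LinAlgError:
            break
        step = np.clip(step, -5, 5)
        beta0 = beta0 + step
        beta0 = np.clip(beta0, -_SEPARATION_BOUND * 3, _SEPARATION_BOUND * 3)
        if np.max(np.abs(g)) < 1e-9:
            break

    theta_lo, theta_hi = -6.0, 3.0
    x0 = np.concatenate([beta0, np.full(K, math.log(0.3))])
    bounds = [(None, None)] * p + [(theta_lo, theta_hi)] * K

    def nll(params):
        return -_laplace_loglik(params[:p], params[p:], X, y, rs, u_state)

    res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
    beta = res.x[:p]
    theta = res.x[p:]
    loglik = -float(res.fun)
    converged = bool(res.success)
    separation = bool(np.max(np.abs(beta)) > _SEPARATION_BOUND)
    if separation:
        logger.warning("possible separation: max |coefficient| = %.2f",
                       np.max(np.abs(beta)))

    # Wald covariance: fixed-effect block of the joint penalized Hessian
    q = rs.q
    if q:
        sd_per_u = rs.sd_per_u(theta)
        u, _ = _u_mode(beta, sd_per_u, X, y, rs, u_state["u"])
    else:
        u = np.zeros(0)
    eta = X @ beta + (rs.zu(u) if q else 0.0)
    mu = _sigmoid(eta)
    w = np.clip(mu * (1 - mu), 1e-12, None)
    Hbb = (X.T * w) @ X
    if q:
        Hub = rs.ztwx(w, X)
        Huu = rs.ztwz(w)
        Huu[np.diag_indices_from(Huu)] += 1.0 / sd_per_u ** 2
        Hbb = Hbb - Hub.T @ linalg.solve(Huu, Hub, assume_a="pos")
    cov = linalg.inv(Hbb)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2 * stats.norm.sf(np.abs(z))

    k = p + K
    aic = -2 * loglik + 2 * k
    table = pd.DataFrame({"term": names, "estimate": beta, "se": se, "z": z, "p": pvals})
    random_sd = {fac: math.exp(th) for (fac, _), th in zip(rs.blocks, theta)}
    for fac, sd_hat in random_sd.items():
        if sd_hat <= math.exp(theta_lo) * 1.5:
            logger.info("random term %r estimated at the zero-variance boundary", fac)
    return GLMMFit(table=table, loglik=loglik, aic=aic, random_sd=random_sd,
                   fitted=mu, converged=converged, separation=separation,
                   spec=spec, n_obs=n)


def select_model_aic(data: pd.DataFrame, specs, **fit_kwargs):
    """Fit candidate models, pick the minimum-AIC one, and run nested LRTs.

    Ties break to the earliest candidate.  Likelihood-ratio tests are run
    between the chosen model and every candidate nested within it (or nesting
    it); non-nested candidates are skipped with a warning.  Returns
    ``(best_spec, aic_table, fits)`` where the table carries one row per
    candidate with its AIC, log-likelihood, parameter count, and LRT p-value
    against the chosen model.
    """
    specs = list(specs)
    if len(specs) < 2:
        raise ValueError("model selection needs at least 2 candidates")
    fits = [fit_glmm(data, s, **fit_kwargs) for s in specs]
    aics = np.array([f.aic for f in fits])
    best_i = int(np.argmin(np.round(aics, 10)))
    best, best_fit = specs[best_i], fits[best_i]

    rows = []
    for s, f in zip(specs, fits):
        k = len(f.table) + len(f.random_sd)
        lrt_p = np.nan
        if s is not best:
            sub, sup = ((f, best_fit) if set(s.fixed) <= set(best.fixed)
                        else (best_fit, f) if set(best.fixed) <= set(s.fixed)
                        else (None, None))
            if sub is None or set(s.random) != set(best.random):
                logger.warning("LRT skipped for non-nested candidate %r", s.label())
            else:
                df = len(sup.table) - len(sub.table)
                stat = max(0.0, 2 * (sup.loglik - sub.loglik))
                lrt_p = float(stats.chi2.sf(stat, df)) if df > 0 else np.nan
        rows.append({"model": s.label(), "k": k, "loglik": f.loglik,
                     "aic": f.aic, "lrt_p_vs_best": lrt_p,
                     "selected": s is best})
    return best, pd.DataFrame(rows), fits


def compute_vif(X: pd.DataFrame) -> pd.Series:
    """Variance inflation factor 1/(1-R^2) for each predictor column.

    Each column is regressed (with intercept) on all the others.  An exactly
    collinear column is reported as infinite, with the most correlated
    partner named in a warning.
    """
    cols = [c for c in X.columns if X[c].nunique() > 1]
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 non-constant predictors")
    out = {}
    M = X[cols].astype(float).to_numpy()
    for j, col in enumerate(cols):
        yj = M[:, j]
        others = np.delete(M, j, axis=1)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        ss_tot = np.sum((yj - yj.mean()) ** 2)
        r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
        if r2 > 1 - 1e-10:
            partner = max((c for c in cols if c != col),
                          key=lambda c: abs(np.corrcoef(X[c], yj)[0, 1]))
            logger.warning("predictor %r exactly collinear (closest partner %r)",
                           col, partner)
            out[col] = np.inf
        else:
            out[col] = 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


@dataclass
class PermutationResult:
    """Outcome of a two-sample permutation test on the difference in means."""

    observed_statistic: float
    n_permutations: int
    p_value: float
    statistic_kind: str = "abs_mean_difference"
    alternative: str = "two_sided"
    exact: bool = False
    seed: int | None = None


def permutation_test_two_sample(x, y, n_perm: int = 10000, seed=None,
                                exact_limit: int = _EXACT_ENUMERATION_LIMIT) -> PermutationResult:
    """Two-sample permutation test on |mean(x) - mean(y)|.

    When the number of distinct label splits C(nx+ny, nx) is at most
    ``exact_limit`` the null distribution is enumerated exactly; otherwise
    ``n_perm`` seeded Monte Carlo permutations are drawn and the add-one
    estimator p = (b+1)/(m+1) is used, guaranteeing a valid p-value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    nx_, ny_ = len(x), len(y)
    pooled = np.concatenate([x, y])
    total = pooled.sum()
    n = nx_ + ny_
    observed = abs(x.mean() - y.mean())
    n_splits = math.comb(n, nx_)
    eps = 1e-12

    if n_splits <= exact_limit:
        idx = np.fromiter(
            (i for comb in combinations(range(n), nx_) for i in comb),
            dtype=np.intp, count=n_splits * nx_).reshape(n_splits, nx_)
        sx = pooled[idx].sum(axis=1)
        stat = np.abs(sx / nx_ - (total - sx) / ny_)
        b = int(np.sum(stat >= observed - eps))
        return PermutationResult(observed, n_splits, b / n_splits, exact=True, seed=seed)

    rng = np.random.default_rng(seed)
    count = 0
    chunk = max(1, min(n_perm, 50_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        order = np.argsort(rng.random((m, n)), axis=1)[:, :nx_]
        sx = pooled[order].sum(axis=1)
        stat = np.abs(sx / nx_ - (total - sx) / ny_)
        count += int(np.sum(stat >= observed - eps))
        done += m
    p = (count + 1) / (n_perm + 1)
    return PermutationResult(observed, n_perm, p, exact=False, seed=seed)


def sex_survival_chisq(table, correction: bool = False):
    """Pearson chi-squared test of a 2x2 survival-by-sex contingency table.

    Continuity correction is off by default; enable with ``correction=True``.
    Returns ``(statistic, p_value)`` with df = 1.
    """
    t = np.asarray(table, float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of nonnegative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("chi-squared undefined: zero row or column margin")
    res = stats.chi2_contingency(t, correction=correction)
    return float(res.statistic), float(res.pvalue)
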