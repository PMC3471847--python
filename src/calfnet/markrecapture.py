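"""Cormack-Jolly-Seber estimation of resighting probability.

Surveys are binned into multi-year occasions (default 4 years, anchored at
the earliest survey date); an individual is "detected" in an occasion if
sighted on at least one day of the bin.  The constant-(phi, p) CJS model is
fit by maximizing the standard conditional likelihood: for each individual,
the probability of its history after first detection, with the chi recursion
chi_t = (1 - phi) + phi (1 - p) chi_{t+1} absorbing trailing non-detection.
phi is apparent survival per occasion interval and p the per-occasion
resighting probability.  Optimization is on the logit scale; standard errors
come from the observed information via the delta method.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .surveys import DAYS_PER_YEAR

logger = logging.getLogger("calfnet")


@dataclass
class CaptureHistory:
    """Binary detection matrix (individuals x occasions) for CJS fitting."""

    matrix: np.ndarray
    ids: list
    occasion_length_years: float
    first_detection: np.ndarray

    @property
    def n_occasions(self) -> int:
        return self.matrix.shape[1]


@dataclass
class CJSEstimate:
    """Constant-parameter CJS fit: resighting probability and apparent survival."""

    p_detect: float
    se_p: float
    phi: float
    se_phi: float
    loglik: float
    n_individuals: int
    n_occasions: int
    boundary: bool = False


def build_capture_histories(surveys: pd.DataFrame, individuals: pd.DataFrame | None = None,
                            occasion_length_years: float = 4.0,
                            min_sightings: int = 15) -> CaptureHistory:
    """Bin sightings into occasions and assemble capture histories.

    Only individuals with at least ``min_sightings`` survey rows overall are
    included (the well-marked, regularly seen animals the resighting estimate
    describes; set 0 to keep everyone).  Individuals first detected in the
    final occasion are excluded as uninformative for CJS.  A partial final
    bin is retained with a warning.
    """
    df = surveys
    start = df["date"].min()
    span_days = (df["date"].max() - start).days + 1
    bin_days = occasion_length_years * DAYS_PER_YEAR
    n_occ = int(math.ceil(span_days / bin_days))
    if n_occ < 2:
        raise ValueError(
            f"study span {span_days} days < 2 occasions of {occasion_length_years} y")
    if span_days % bin_days:
        logger.warning("final occasion bin is partial (%.1f of %.1f years)",
                       (span_days % bin_days) / DAYS_PER_YEAR, occasion_length_years)

    counts = df["individual_id"].value_counts()
    keep = set(counts.index[counts >= min_sightings])
    sub = df[df["individual_id"].isin(keep)]
    occ = ((sub["date"] - start).dt.days // bin_days).astype(int)

    ids = sorted(keep)
    idx = {i: k for k, i in enumerate(ids)}
    M = np.zeros((len(ids), n_occ), dtype=np.int8)
    M[sub["individual_id"].map(idx).to_numpy(), occ.to_numpy()] = 1

    first = np.argmax(M, axis=1)
    informative = M.any(axis=1) & (first < n_occ - 1)
    n_dropped = int((~informative).sum())
    if n_dropped:
        logger.info("excluded %d individuals first detected in the final occasion",
                    n_dropped)
    M = M[informative]
    ids = [i for i, ok in zip(ids, informative) if ok]
    return CaptureHistory(matrix=M, ids=ids,
                          occasion_length_years=occasion_length_years,
                          first_detection=np.argmax(M, axis=1))


def cjs_loglik(phi: float, p: float, history: CaptureHistory) -> float:
    """Conditional CJS log-likelihood at given (phi, p).

    Between first and last detection each individual contributes
    phi^(l-f) p^d (1-p)^(l-f-d) with d detections after the first; the chi
    recursion chi_t = (1-phi) + phi (1-p) chi_{t+1} absorbs the probability
    of never being seen after the last detection.
    """
    M = history.matrix
    T = history.n_occasions
    first = history.first_detection
    last = T - 1 - np.argmax(M[:, ::-1], axis=1)
    chi = np.ones(T + 1)
    for t in range(T - 1, -1, -1):
        chi[t] = (1 - phi) + phi * (1 - p) * chi[t + 1]

    span = (last - first).astype(float)
    d = M.sum(axis=1).astype(float) - 1.0  # detections after the first

    def xlogy(a, b):
        return np.where(a > 0, a * np.log(np.clip(b, 1e-300, None)), 0.0)

    ll = (xlogy(span, phi) + xlogy(d, p) + xlogy(span - d, 1 - p)
          + np.log(np.clip(chi[last + 1], 1e-300, None)))
    return float(ll.sum())


def fit_cjs(history: CaptureHistory) -> CJSEstimate:
    """Maximum-likelihood constant-(phi, p) CJS fit with observed-information SEs.

    Degenerate data (every animal detected at every occasion after first)
    drive the estimates to the boundary phi = p = 1; the fit is flagged and
    SEs reported as 0 there.
    """
    M = history.matrix
    if M.shape[0] == 0:
        raise ValueError("no informative capture histories")
    if history.n_occasions < 2:
        raise ValueError("CJS needs at least 2 occasions")

    def nll(x):
        phi = _expit(x[0])
        p = _expit(x[1])
        return -cjs_loglik(phi, p, history)

    res = optimize.minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    phi, p = _expit(res.x[0]), _expit(res.x[1])
    loglik = -float(res.fun)

    at_bound = [phi > 1 - 1e-4, p > 1 - 1e-4]
    boundary = any(at_bound)
    if boundary:
        logger.warning("CJS estimate at boundary (phi=%.4f, p=%.4f)", phi, p)
        phi, p = min(phi, 1.0), min(p, 1.0)
    # observed-information SEs for interior parameters; a parameter pinned at
    # the boundary gets SE 0 (its information is one-sided there)
    free = [i for i, b in enumerate(at_bound) if not b]
    se = [0.0, 0.0]
    if free:
        def nll_free(xf):
            full = res.x.copy()
            full[free] = xf
            return -cjs_loglik(_expit(full[0]), _expit(full[1]), history)
        H = _numeric_hessian(nll_free, res.x[free])
        try:
            cov_logit = np.linalg.inv(H)
            for k, i in enumerate(free):
                scale = (phi * (1 - phi)) if i == 0 else (p * (1 - p))
                se[i] = math.sqrt(max(cov_logit[k, k], 0.0)) * scale
        except np.linalg.LinAlgError:
            for i in free:
                se[i] = float("nan")
    se_phi, se_p = se
    return CJSEstimate(p_detect=p, se_p=se_p, phi=phi, se_phi=se_phi,
                       loglik=loglik, n_individuals=M.shape[0],
                       n_occasions=history.n_occasions, boundary=boundary)


def simulate_histories(phi: float, p: float, n_individuals: int, n_occasions: int,
                       seed=None) -> CaptureHistory:
    """Simulate CJS capture histories with all animals released at occasion 0."""
    rng = np.random.default_rng(seed)
    M = np.zeros((n_individuals, n_occasions), dtype=np.int8)
    M[:, 0] = 1
    alive = np.ones(n_individuals, dtype=bool)
    for t in range(1, n_occasions):
        alive &= rng.random(n_individuals) < phi
        M[:, t] = alive & (rng.random(n_individuals) < p)
    return CaptureHistory(matrix=M, ids=[f"I{i:04d}" for i in range(n_individuals)],
                          occasion_length_years=4.0,
                          first_detection=np.zeros(n_individuals, dtype=int))


def _expit(x: float) -> float:
    return 0.5 * (1.0 + math.tanh(0.5 * x))


def _numeric_hessian(f, x, h: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, float)
    k = len(x)
    H = np.zeros((k, k))
    f0 = f(x)
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            if i == j:
                H[i, i] = (f(x + ei) - 2 * f0 + f(x - ei)) / h**2
            else:
                H[i, j] = H[j, i] = (
                    f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
                ) / (4 * h**2)
    return H
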