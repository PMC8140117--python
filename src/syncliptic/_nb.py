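"""Negative-binomial likelihood machinery shared by the peak-enrichment and
differential-expression tests.

Parameterization: variance = mu + phi * mu**2 (phi >= 0 is the dispersion,
phi -> 0 recovers Poisson).  Means enter through natural-log offsets:
E[y_ij] = mu_i * exp(o_ij).
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln

_POISSON_PHI = 1e-10  # below this, use the Poisson limit for stability


def nb_logpmf(y: np.ndarray, mu: np.ndarray, phi: float) -> np.ndarray:
    """Log-probability of NB(mean=mu, var=mu+phi*mu^2); Poisson limit at tiny phi.

    mu = 0 is allowed: the pmf degenerates to a point mass at 0.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    y, mu = np.broadcast_arrays(y, mu)
    out = np.empty(y.shape, dtype=float)
    zero = mu <= 0
    out[zero] = np.where(y[zero] == 0, 0.0, -np.inf)
    pos = ~zero
    yp, mp = y[pos], mu[pos]
    if phi < _POISSON_PHI:
        out[pos] = yp * np.log(mp) - mp - gammaln(yp + 1)
    else:
        r = 1.0 / phi
        pm = phi * mp
        out[pos] = (
            gammaln(yp + r)
            - gammaln(r)
            - gammaln(yp + 1)
            + yp * (np.log(pm) - np.log1p(pm))
            - r * np.log1p(pm)
        )
    return out


def profile_mu(counts: np.ndarray, offsets: np.ndarray, phi: float) -> np.ndarray:
    """Per-row MLE of the shared rate mu given natural-log offsets.

    counts, offsets: arrays of shape (n_units, n_obs).  Rows with all-zero
    counts get mu = 0 (the MLE).  The score in mu is strictly decreasing, so
    the root is unique; we iterate the standard multiplicative IRLS update
    mu <- mu * [sum y/(1+phi*m)] / [sum m/(1+phi*m)] which preserves
    positivity, then polish with damped Newton steps on log mu.
    """
    counts = np.asarray(counts, dtype=float)
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), counts.shape)
    exp_o = np.exp(offsets)
    tot = counts.sum(axis=1)
    mu = np.where(tot > 0, tot / exp_o.sum(axis=1), 0.0)
    if phi < _POISSON_PHI:
        return mu  # Poisson MLE is closed form
    active = mu > 0
    m = mu[:, None] * exp_o
    for _ in range(100):
        denom = 1.0 + phi * m
        num = (counts / denom).sum(axis=1)
        den = (m / denom).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(active, num / den, 1.0)
        mu = mu * ratio
        m = mu[:, None] * exp_o
        if np.all(np.abs(ratio[active] - 1.0) < 1e-13):
            break
    # Newton polish on u = log mu
    for _ in range(6):
        denom = 1.0 + phi * m
        score = ((counts - m) / denom).sum(axis=1)
        hess = -(m * (1.0 + phi * counts) / denom**2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            step = np.where(active & (hess < 0), -score / hess, 0.0)
        step = np.clip(step, -1.0, 1.0)
        mu = np.where(active, mu * np.exp(step), mu)
        m = mu[:, None] * exp_o
    return mu


def loglik_shared(
    counts: np.ndarray, offsets: np.ndarray, phi: float, mu: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise profiled log-likelihood and its maximizing mu."""
    counts = np.asarray(counts, dtype=float)
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), counts.shape)
    if mu is None:
        mu = profile_mu(counts, offsets, phi)
    m = mu[:, None] * np.exp(offsets)
    return nb_logpmf(counts, m, phi).sum(axis=1), mu


def loglik_saturated(counts: np.ndarray, phi: float) -> np.ndarray:
    """Row-wise log-likelihood with fitted mean equal to each observation."""
    counts = np.asarray(counts, dtype=float)
    return nb_logpmf(counts, counts, phi).sum(axis=1)


def _cr_adjustment(mu: np.ndarray, exp_o: np.ndarray, phi: float) -> np.ndarray:
    """Cox-Reid term: 0.5 * log of the Fisher information for log mu."""
    m = mu[:, None] * exp_o
    info = (m / (1.0 + phi * m)).sum(axis=1)
    with np.errstate(divide="ignore"):
        return 0.5 * np.log(info)


def estimate_dispersion_apl(
    counts: np.ndarray,
    offsets: np.ndarray,
    group_cols: list[np.ndarray] | None = None,
    bounds: tuple[float, float] = (1e-8, 10.0),
    tol: float = 1e-6,
) -> tuple[float, bool]:
    """Common dispersion maximizing the Cox-Reid adjusted profile likelihood.

    Each row's mean parameters (one shared rate, or one rate per group when
    ``group_cols`` gives column indices per group) are profiled out at every
    candidate phi.  Rows with a zero total in any profiled block carry no
    information about phi through the adjusted likelihood and are dropped.
    Returns (phi_hat, hit_upper_bound).
    """
    counts = np.asarray(counts, dtype=float)
    offsets = np.broadcast_to(np.asarray(offsets, dtype=float), counts.shape)
    if group_cols is None:
        blocks = [(counts, offsets)]
        keep = counts.sum(axis=1) > 0
    else:
        blocks = [(counts[:, c], offsets[:, c]) for c in group_cols]
        keep = np.ones(counts.shape[0], dtype=bool)
        for b, _ in blocks:
            keep &= b.sum(axis=1) > 0
    blocks = [(b[keep], o[keep]) for b, o in blocks]
    if blocks[0][0].shape[0] == 0:
        raise ValueError("no usable rows for dispersion estimation")

    def neg_apl(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        total = 0.0
        for b, o in blocks:
            ll, mu = loglik_shared(b, o, phi)
            total += ll.sum() - _cr_adjustment(mu, np.exp(o), phi).sum()
        return -total

    res = minimize_scalar(
        neg_apl,
        bounds=(np.log(bounds[0]), np.log(bounds[1])),
        method="bounded",
        options={"xatol": tol},
    )
    phi_hat = float(np.exp(res.x))
    hit_upper = phi_hat > bounds[1] * 0.99
    return phi_hat, hit_upper


def nb_rvs(rng: np.random.Generator, mu: np.ndarray, phi: float) -> np.ndarray:
    """Draw NB(mean=mu, var=mu+phi*mu^2) variates (Poisson when phi ~ 0)."""
    mu = np.asarray(mu, dtype=float)
    if phi < _POISSON_PHI:
        return rng.poisson(mu)
    n = 1.0 / phi
    p = 1.0 / (1.0 + phi * mu)
    return rng.negative_binomial(n, p)
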