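"""MA statistics and normalization for the two-sample CLIP comparison.

The log-ratio M and average log-abundance A of each peak are computed from
offset counts and effective library sizes,

    M = log2[(x + o) / (lib_x + o)] - log2[(y + o) / (lib_y + o)]
    A = [log2(x + o) + log2(y + o)] / 2

with offset o = 1 guarding against division by zero, and lib_x/lib_y the
effective library sizes (reads mapping to the peak universe times the TMM
normalization factor).  Because the raw MA cloud of a compartment-vs-total
comparison is not centred at M = 0 and bends with A, a robust LOESS curve
(span 1/4, locally linear, bisquare-reweighted) is fitted to M ~ A and
subtracted: adjusted M = M - fitted M.  After adjustment the cloud's LOESS
line is flat at zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .io import CountMatrix

log = logging.getLogger(__name__)

Direction = Literal["x_vs_y", "y_vs_x"]


@dataclass
class NormFactors:
    """TMM normalization factors; geometric mean 1 across samples."""

    factors: pd.Series
    lib_size: pd.Series

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    @property
    def effective_lib_size(self) -> pd.Series:
        return self.lib_size * self.factors


def tmm_factors(
    counts: CountMatrix,
    trim_m: float = 0.3,
    trim_a: float = 0.05,
    weighted: bool = True,
) -> NormFactors:
    """Trimmed-mean-of-M-values normalization factors.

    Reference sample: the one whose 75th percentile of counts scaled by
    library size is closest to the mean of those percentiles.  For every
    sample, rows with a zero in either sample are dropped, the extreme
    ``trim_m`` fraction of log-ratios and ``trim_a`` fraction of average
    log-abundances are trimmed on both sides, and the factor is 2 to the
    (optionally precision-weighted) mean of the remaining log2 ratios.
    Factors are rescaled to geometric mean 1.
    """
    X = counts.counts.to_numpy(dtype=float)
    lib = counts.lib_size.to_numpy(dtype=float)
    if X.shape[1] < 2:
        raise ValueError("TMM requires at least two samples")
    if (lib <= 0).any() or (X.sum(axis=0) == 0).any():
        raise ValueError("every sample needs positive counts for TMM")
    f75 = np.quantile(X / lib, 0.75, axis=0)
    ref = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.ones(X.shape[1])
    for i in range(X.shape[1]):
        if i == ref:
            continue
        factors[i] = _tmm_pair(
            X[:, i], X[:, ref], lib[i], lib[ref], trim_m, trim_a, weighted
        )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return NormFactors(
        pd.Series(factors, index=counts.counts.columns), counts.lib_size.copy()
    )


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    trim_m: float,
    trim_a: float,
    weighted: bool,
) -> float:
    usable = (obs > 0) & (ref > 0)
    o, r = obs[usable], ref[usable]
    log_r = np.log2((o / lib_obs) / (r / lib_ref))
    abs_e = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
    # delta-method variance of the log ratio
    v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
    n = log_r.size
    lo_l = np.floor(n * trim_m) + 1
    hi_l = n + 1 - lo_l
    lo_s = np.floor(n * trim_a) + 1
    hi_s = n + 1 - lo_s
    rank_r = rankdata(log_r)
    rank_e = rankdata(abs_e)
    keep = (rank_r >= lo_l) & (rank_r <= hi_l) & (rank_e >= lo_s) & (rank_e <= hi_s)
    if keep.sum() < 10:
        log.warning("TMM: fewer than 10 rows after trimming; factor set to 1")
        return 1.0
    if weighted:
        f = np.sum(log_r[keep] / v[keep]) / np.sum(1.0 / v[keep])
    else:
        f = np.mean(log_r[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0**f)


def compute_ma(
    x,
    y,
    lib_x: float,
    lib_y: float,
    o: float = 1.0,
    direction: Direction = "x_vs_y",
):
    """M and A of counts x, y under effective library sizes lib_x, lib_y.

    ``direction="y_vs_x"`` negates M (the reverse comparison); A is unchanged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if (x < 0).any() or (y < 0).any():
        raise ValueError("counts must be non-negative")
    if lib_x <= 0 or lib_y <= 0 or o <= 0:
        raise ValueError("library sizes and offset must be positive")
    m = np.log2((x + o) / (lib_x + o)) - np.log2((y + o) / (lib_y + o))
    a = 0.5 * (np.log2(x + o) + np.log2(y + o))
    if direction == "y_vs_x":
        m = -m
    elif direction != "x_vs_y":
        raise ValueError(f"unknown direction {direction!r}")
    return m, a


@dataclass
class MAProfile:
    """Per-peak normalization state of one MA comparison."""

    peak_ids: np.ndarray
    x: np.ndarray
    y: np.ndarray
    lib_x: float
    lib_y: float
    M: np.ndarray
    A: np.ndarray
    o: float = 1.0
    direction: Direction = "x_vs_y"
    fitted: np.ndarray | None = None

    @property
    def adjusted_M(self) -> np.ndarray:
        if self.fitted is None:
            raise ValueError("LOESS fit not yet computed; call adjust_m")
        return self.M - self.fitted

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "peak_id": self.peak_ids,
                "x": self.x.astype(int),
                "y": self.y.astype(int),
                "M": self.M,
                "A": self.A,
            }
        )
        if self.fitted is not None:
            df["fitted"] = self.fitted
            df["adjusted_M"] = self.adjusted_M
        return df


def make_ma_profile(
    peak_ids,
    x,
    y,
    lib_x: float,
    lib_y: float,
    o: float = 1.0,
    direction: Direction = "x_vs_y",
) -> MAProfile:
    m, a = compute_ma(x, y, lib_x, lib_y, o=o, direction=direction)
    return MAProfile(
        peak_ids=np.asarray(peak_ids),
        x=np.asarray(x),
        y=np.asarray(y),
        lib_x=float(lib_x),
        lib_y=float(lib_y),
        M=m,
        A=a,
        o=o,
        direction=direction,
    )


def fit_robust_loess(
    A: np.ndarray,
    M: np.ndarray,
    span: float = 0.25,
    degree: int = 1,
    robust_iterations: int = 4,
    delta: float | None = None,
) -> np.ndarray:
    """Robust locally linear regression of M on A; fitted value at every A.

    Tricube weights over the span-nearest neighbours, robustified by
    bisquare reweighting of residuals for ``robust_iterations`` rounds
    (the "symmetric" loess family).  ``delta`` enables linear interpolation
    between fit points closer than that distance (speeds up dense data);
    the default uses 1/1000 of the A range, 0 disables it.
    """
    A = np.asarray(A, dtype=float)
    M = np.asarray(M, dtype=float)
    if A.size != M.size:
        raise ValueError("A and M must have the same length")
    if A.size < 10:
        raise ValueError("need at least 10 points for the LOESS fit")
    if not np.isfinite(A).all():
        raise ValueError("A values must be finite")
    if np.ptp(A) == 0:
        raise ValueError("all A values identical: degenerate abscissa")
    if degree != 1:
        raise NotImplementedError("only locally linear (degree=1) fits are supported")
    if delta is None:
        delta = 0.001 * np.ptp(A)
    return _sm_lowess(
        M,
        A,
        frac=span,
        it=robust_iterations,
        delta=delta,
        return_sorted=False,
    )


def adjust_m(
    profile: MAProfile,
    span: float = 0.25,
    robust_iterations: int = 4,
    delta: float | None = None,
) -> MAProfile:
    """Fit the robust LOESS trend and subtract it: adjusted M = M - fitted."""
    fitted = fit_robust_loess(
        profile.A,
        profile.M,
        span=span,
        robust_iterations=robust_iterations,
        delta=delta,
    )
    return replace(profile, fitted=fitted)
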