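"""Replicate-free compartment-enrichment test for CLIP peaks.

With one compartment (x) and one reference (y) library and no replicates, a
common negative-binomial dispersion phi is estimated from the peaks in the
centre of the raw MA cloud (-3 < M < 1), where genuine compartment-specific
binding is rare.  Each peak is then tested with a likelihood-ratio test of a
shared-rate null against the saturated model, with natural-log offsets
log(effective library size) from which the LOESS-fitted M (converted to
natural log) has been subtracted on the compartment side, so the trend
correction enters the inference.  The statistic is referred to chi-square
with one degree of freedom; p-values are reported unadjusted and peaks
ranked by them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from . import _nb
from .manorm import MAProfile

log = logging.getLogger(__name__)

LN2 = float(np.log(2.0))


@dataclass
class DispersionEstimate:
    phi: float
    n_peaks_used: int
    m_window: tuple[float, float]

    def __post_init__(self) -> None:
        if self.phi < 0:
            raise ValueError("dispersion must be non-negative")
        if self.n_peaks_used <= 0:
            raise ValueError("no peaks used for dispersion estimation")


def center_cloud_mask(
    profile: MAProfile | np.ndarray, lo: float = -3.0, hi: float = 1.0
) -> np.ndarray:
    """Peaks in the centre of the raw MA cloud: lo < M < hi (strict)."""
    if lo >= hi:
        raise ValueError("require lo < hi")
    m = profile.M if isinstance(profile, MAProfile) else np.asarray(profile)
    return (m > lo) & (m < hi)


def estimate_common_dispersion(
    x: np.ndarray,
    y: np.ndarray,
    offset_x: np.ndarray,
    offset_y: np.ndarray,
    bounds: tuple[float, float] = (1e-8, 10.0),
) -> DispersionEstimate:
    """Common dispersion from paired counts by Cox-Reid adjusted profile likelihood.

    Each peak contributes two observations of one underlying rate (its mean
    under the null), which is profiled out at every candidate phi; the
    adjusted likelihoods are summed and maximized over log phi.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 50:
        raise ValueError("need at least 50 peaks to estimate a common dispersion")
    counts = np.column_stack([x, y])
    offsets = np.column_stack(
        [np.broadcast_to(offset_x, x.shape), np.broadcast_to(offset_y, y.shape)]
    )
    phi, hit_upper = _nb.estimate_dispersion_apl(counts, offsets, bounds=bounds)
    if hit_upper:
        log.warning("dispersion optimizer at upper bound (phi=%g)", phi)
    return DispersionEstimate(phi=phi, n_peaks_used=int(x.size), m_window=(np.nan, np.nan))


def peak_lrt(
    x,
    y,
    offset_x,
    offset_y,
    phi: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Likelihood-ratio test of one shared rate vs the saturated model.

    Null: both observations share a rate mu with means mu*exp(offset); mu is
    fitted by maximum likelihood.  Alternative: saturated (fitted mean equals
    each observation; the log-likelihood at mean 0 for a zero count is 0).
    Returns (statistic, p) with p from the chi-square(1) upper tail; a peak
    with x = y = 0 gets statistic 0 and p = 1.
    """
    if phi < 0:
        raise ValueError("dispersion must be non-negative")
    x = np.atleast_1d(np.asarray(x, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    ox = np.broadcast_to(np.asarray(offset_x, dtype=float), x.shape)
    oy = np.broadcast_to(np.asarray(offset_y, dtype=float), y.shape)
    if not (np.isfinite(ox).all() and np.isfinite(oy).all()):
        raise ValueError("offsets must be finite")
    counts = np.column_stack([x, y])
    offsets = np.column_stack([ox, oy])
    ll_null, _ = _nb.loglik_shared(counts, offsets, phi)
    ll_sat = _nb.loglik_saturated(counts, phi)
    stat = np.clip(2.0 * (ll_sat - ll_null), 0.0, None)
    p = chi2.sf(stat, df=1)
    p = np.where(counts.sum(axis=1) == 0, 1.0, p)
    if stat.size == 1:
        return float(stat[0]), float(p[0])
    return stat, p


def peak_offsets(
    lib_x: float,
    lib_y: float,
    fitted_m: np.ndarray,
    apply_to: str = "x",
) -> tuple[np.ndarray, np.ndarray]:
    """Natural-log offsets log(effective library size) with the LOESS correction.

    The fitted M (log2) is converted to natural log and subtracted from the
    compartment sample's offset, so the trend adjustment carries into the
    GLM.  Applying it symmetrically (half to each side) shifts both offsets
    by a common constant and leaves the LRT unchanged.
    """
    fitted_ln = np.asarray(fitted_m, dtype=float) * LN2
    ox = np.full_like(fitted_ln, np.log(lib_x))
    oy = np.full_like(fitted_ln, np.log(lib_y))
    if apply_to == "x":
        ox = ox - fitted_ln
    elif apply_to == "split":
        ox = ox - fitted_ln / 2.0
        oy = oy + fitted_ln / 2.0
    else:
        raise ValueError(f"unknown apply_to {apply_to!r}")
    return ox, oy


def enrichment_table(
    profile: MAProfile,
    phi: float,
) -> pd.DataFrame:
    """Run the per-peak LRT over a LOESS-adjusted MA profile."""
    ox, oy = peak_offsets(profile.lib_x, profile.lib_y, profile.fitted)
    stat, p = peak_lrt(profile.x, profile.y, ox, oy, phi)
    df = profile.to_frame()
    df["offset_x"] = ox
    df["offset_y"] = oy
    df["lrt_stat"] = stat
    df["p"] = p
    return df


def _ranked(results: pd.DataFrame) -> pd.DataFrame:
    out = results.sort_values(["p", "peak_id"], kind="mergesort").reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def select_peaks(results: pd.DataFrame, cutoff: float = 1e-5) -> pd.DataFrame:
    """Peaks with p < cutoff, ranked ascending by (p, peak_id)."""
    out = _ranked(results)
    out["selected"] = out["p"] < cutoff
    return out


def matched_count_cutoff(reverse_p: np.ndarray, n_target: int) -> float:
    """The n_target-th smallest p-value of the reverse comparison.

    Selection then takes the first n_target peaks by (p, peak_id) rank, so
    exactly n_target are chosen even when the boundary p is tied.
    """
    p = np.sort(np.asarray(reverse_p, dtype=float))
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    if n_target > p.size:
        raise ValueError("n_target exceeds the number of peaks")
    return float(p[n_target - 1])


def select_matched_count(results: pd.DataFrame, n_target: int) -> pd.DataFrame:
    """Select exactly n_target peaks by (p, peak_id) rank."""
    if n_target <= 0:
        raise ValueError("n_target must be positive")
    out = _ranked(results)
    out["selected"] = out["rank"] <= n_target
    return out
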