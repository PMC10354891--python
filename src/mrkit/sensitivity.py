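"""Heterogeneity and horizontal-pleiotropy diagnostics.

Three complementary checks on a harmonized instrument set:

* **Cochran's Q** — weighted dispersion of the per-variant Wald ratios
  around the IVW estimate; chi-square with J−1 df under homogeneity.
  Weights are the first-order inverse ratio variances β_X²/se_Y², matching
  the IVW weighting, so Q is identically the weighted residual sum of the
  zero-intercept regression.
* **MR-Egger intercept test** — a two-sided t test (J−2 df) of the Egger
  intercept against zero; a nonzero intercept indicates directional
  pleiotropy.
* **MR-PRESSO global test** — simulation-based: the observed leave-one-out
  weighted residual sum of squares is compared against its parametric null
  distribution (effects redrawn from their reported sampling
  distributions around the leave-one-out fitted values).  The Monte-Carlo
  p-value has resolution 1/(n_sim + 1) and is fully determined by the
  seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import (
    InsufficientInstrumentsError,
    MrEstimate,
    _ivw_point,
    ivw,
    mr_egger,
)
from .harmonize import HarmonizedSet

__all__ = [
    "SensitivityReport",
    "PressoResult",
    "cochran_q",
    "egger_intercept_test",
    "mr_presso_global",
    "leave_one_out",
    "sensitivity_report",
]


@dataclass
class PressoResult:
    rss_obs: float
    pval: float
    n_sim: int
    seed: int
    low_resolution: bool = False


@dataclass
class SensitivityReport:
    """Diagnostics for one exposure → outcome analysis."""

    q_stat: float
    q_pval: float
    egger_intercept: float
    egger_intercept_pval: float
    presso_rss_obs: float
    presso_global_pval: float
    n_sim: int
    seed: int


def cochran_q(hset: HarmonizedSet, theta_ivw: float | None = None) -> tuple[float, float]:
    """Cochran's Q over the Wald ratios and its chi-square (J−1 df) p-value.

    When ``theta_ivw`` is omitted it is recomputed as the fixed-effect IVW
    estimate, against which Q is the exact weighted residual sum.
    """
    j = len(hset)
    if j < 2:
        raise InsufficientInstrumentsError("Cochran's Q needs >= 2 instruments")
    bx, by, sy = hset.beta_exposure, hset.beta_outcome, hset.se_outcome
    if theta_ivw is None:
        theta_ivw, _, _ = _ivw_point(bx, by, sy)
    q = float(np.sum((by - theta_ivw * bx) ** 2 / sy**2))
    p = float(stats.chi2.sf(q, j - 1))
    return q, max(p, np.nextafter(0, 1))


def egger_intercept_test(hset: HarmonizedSet) -> tuple[float, float]:
    """(intercept, two-sided t p-value with J−2 df) against α = 0."""
    _, intercept = mr_egger(hset)
    return intercept.theta, intercept.pval


def leave_one_out(hset: HarmonizedSet, mode: str = "fixed") -> pd.DataFrame:
    """IVW estimate excluding each instrument in turn.

    Returns one row per excluded variant with the re-estimated theta, se,
    p, and a flag marking exclusions that change the sign of the estimate
    relative to the full-set IVW.
    """
    j = len(hset)
    if j < 3:
        raise InsufficientInstrumentsError("leave-one-out needs >= 3 instruments")
    full = ivw(hset, mode=mode)
    rows = []
    for i in range(j):
        keep = [k for k in range(j) if k != i]
        est = ivw(hset.subset(keep), mode=mode)
        rows.append(
            {
                "excluded": hset.pairs[i].variant_id,
                "theta": est.theta,
                "se": est.se,
                "pval": est.pval,
                "sign_change": bool(np.sign(est.theta) != np.sign(full.theta)),
            }
        )
    return pd.DataFrame(rows)


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out zero-intercept WLS slopes, one per excluded index."""
    sxx = np.sum(w * bx**2)
    sxy = np.sum(w * bx * by)
    denom = sxx - w * bx**2
    if np.any(denom <= 0):
        raise InsufficientInstrumentsError(
            "leave-one-out slope unidentified (a single variant carries all weight)"
        )
    return (sxy - w * bx * by) / denom


def mr_presso_global(
    hset: HarmonizedSet, n_sim: int = 2000, seed: int = 0
) -> PressoResult:
    """MR-PRESSO global test for horizontal pleiotropy.

    Observed statistic: RSS_obs = Σ_j w_j (β_Yj − θ̂₍₋ⱼ₎ β_Xj)² with
    w_j = se_Yj⁻² and θ̂₍₋ⱼ₎ the IVW slope excluding variant j.  The null
    distribution is built by redrawing β*_Xj ~ N(β_Xj, se_Xj²) and
    β*_Yj ~ N(θ̂₍₋ⱼ₎ β_Xj, se_Yj²), recomputing the same leave-one-out
    statistic on each replicate.  p = (1 + #{RSS* ≥ RSS_obs}) / (n_sim + 1).

    ``n_sim < 100`` is allowed but flagged ``low_resolution`` (with a
    warning): the p-value floor 1/(n_sim+1) is then coarse.
    """
    j = len(hset)
    if j < 4:
        raise InsufficientInstrumentsError(
            f"MR-PRESSO global test needs >= 4 instruments, got {j}"
        )
    low_res = n_sim < 100
    if low_res:
        warnings.warn(
            f"MR-PRESSO with n_sim={n_sim} has p-value resolution "
            f"{1.0 / (n_sim + 1):.3g}; interpret with caution",
            stacklevel=2,
        )
    bx, sx = hset.beta_exposure, hset.se_exposure
    by, sy = hset.beta_outcome, hset.se_outcome
    w = 1.0 / sy**2

    theta_loo = _loo_slopes(bx, by, w)
    rss_obs = float(np.sum(w * (by - theta_loo * bx) ** 2))

    rng = np.random.default_rng(seed)
    # exposure-side noise uses se_X where available (always present for
    # harmonized pairs); the parametric null centres outcome draws on the
    # leave-one-out fitted values, i.e. "no pleiotropy beyond sampling noise"
    bx_star = rng.normal(bx, sx, size=(n_sim, j))
    by_star = rng.normal(theta_loo * bx, sy, size=(n_sim, j))

    sxx = np.sum(w * bx_star**2, axis=1, keepdims=True)
    sxy = np.sum(w * bx_star * by_star, axis=1, keepdims=True)
    denom = sxx - w * bx_star**2
    theta_loo_star = (sxy - w * bx_star * by_star) / denom
    rss_star = np.sum(w * (by_star - theta_loo_star * bx_star) ** 2, axis=1)

    p = (1.0 + float(np.sum(rss_star >= rss_obs))) / (n_sim + 1.0)
    return PressoResult(rss_obs=rss_obs, pval=p, n_sim=n_sim, seed=seed, low_resolution=low_res)


def sensitivity_report(
    hset: HarmonizedSet,
    theta_ivw: float | None = None,
    n_sim: int = 2000,
    seed: int = 0,
) -> SensitivityReport:
    """All three diagnostics bundled for one analysis (the usual reporting
    surface next to the estimates)."""
    q, p_q = cochran_q(hset, theta_ivw)
    alpha, p_alpha = egger_intercept_test(hset)
    presso = mr_presso_global(hset, n_sim=n_sim, seed=seed)
    return SensitivityReport(
        q_stat=q,
        q_pval=p_q,
        egger_intercept=alpha,
        egger_intercept_pval=p_alpha,
        presso_rss_obs=presso.rss_obs,
        presso_global_pval=presso.pval,
        n_sim=n_sim,
        seed=seed,
    )
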