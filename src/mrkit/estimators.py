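"""Causal-effect estimators for two-sample MR on harmonized summary data.

Given J harmonized instruments with exposure effects β_Xj (SE se_Xj) and
outcome effects β_Yj (SE se_Yj), the per-variant Wald ratio is
θ_j = β_Yj / β_Xj with first-order SE se_Yj / |β_Xj|.  The estimators here
combine the ratios:

* **IVW** — inverse-variance weighted combination, identical to the
  zero-intercept weighted regression of β_Y on β_X with weights se_Y⁻²:
  θ̂ = Σ w β_X β_Y / Σ w β_X².  The fixed-effect SE is (Σ w β_X²)^(-1/2);
  the multiplicative random-effects variant inflates it by
  max(1, √(Q/(J−1))) to absorb over-dispersion.  It is the highest-powered
  estimator but assumes every instrument is valid.
* **MR-Egger** — weighted regression of β_Y on β_X with a free intercept,
  after orienting all instruments to β_X ≥ 0.  The intercept estimates the
  average directional pleiotropic effect; the slope is consistent under the
  InSIDE assumption even when all instruments are pleiotropic, at the cost
  of much lower power.  Inference uses a t distribution with J−2 df.
* **Weighted median** — the weighted median of the Wald ratios, consistent
  when instruments carrying less than half of the weight are invalid.  Its
  SE comes from a seeded parametric bootstrap.

All normal-based estimates satisfy the exact identity
ci = θ ∓ z₀.₉₇₅ · se (t quantile for MR-Egger).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy import stats

from .harmonize import HarmonizedPair, HarmonizedSet

__all__ = [
    "MrEstimate",
    "MethodConfig",
    "UndefinedRatioError",
    "DegenerateDesignError",
    "InsufficientInstrumentsError",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "weighted_median_point",
    "run_all_methods",
    "Z_975",
]

Z_975 = float(stats.norm.ppf(0.975))


class UndefinedRatioError(ValueError):
    """Wald ratio requested for an instrument with β_X = 0."""


class DegenerateDesignError(ValueError):
    """All exposure effects are zero; no slope is identified."""


class InsufficientInstrumentsError(ValueError):
    """Fewer instruments than the method's minimum."""


@dataclass
class MrEstimate:
    """A causal-effect estimate with Wald-type inference.

    ``status`` is ``"ok"`` for computed estimates; methods whose
    preconditions fail inside :func:`run_all_methods` yield placeholder
    entries with a ``not_computed: ...`` status and NaN numerics.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snps: int
    status: str = "ok"

    @property
    def computed(self) -> bool:
        return self.status == "ok"


def _not_computed(method: str, n_snps: int, reason: str) -> MrEstimate:
    nan = float("nan")
    return MrEstimate(method, nan, nan, nan, nan, nan, n_snps, f"not_computed: {reason}")


def _normal_estimate(method: str, theta: float, se: float, n_snps: int) -> MrEstimate:
    z = abs(theta) / se if se > 0 else np.inf
    p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    if theta == 0.0:
        p = 1.0 if se > 0 else p
    return MrEstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - Z_975 * se),
        ci_high=float(theta + Z_975 * se),
        pval=max(p, np.nextafter(0, 1)),
        n_snps=n_snps,
    )


def _t_estimate(method: str, theta: float, se: float, df: int, n_snps: int) -> MrEstimate:
    tq = float(stats.t.ppf(0.975, df))
    tstat = abs(theta) / se if se > 0 else np.inf
    p = float(min(1.0, 2.0 * stats.t.sf(tstat, df)))
    if theta == 0.0 and se > 0:
        p = 1.0
    return MrEstimate(
        method=method,
        theta=float(theta),
        se=float(se),
        ci_low=float(theta - tq * se),
        ci_high=float(theta + tq * se),
        pval=max(p, np.nextafter(0, 1)),
        n_snps=n_snps,
    )


# ---------------------------------------------------------------------------
# Wald ratio
# ---------------------------------------------------------------------------


def wald_ratio(pair: HarmonizedPair, second_order: bool = False) -> MrEstimate:
    """Per-variant causal estimate θ = β_Y / β_X.

    The default SE is the first-order delta-method value se_Y / |β_X|
    (exposure-side noise ignored, the common convention); ``second_order``
    adds the β_Y² se_X² / β_X⁴ term.
    """
    if pair.beta_exposure == 0:
        raise UndefinedRatioError(f"{pair.variant_id}: beta_exposure is zero")
    theta = pair.beta_outcome / pair.beta_exposure
    var = (pair.se_outcome / pair.beta_exposure) ** 2
    if second_order:
        var += (
            pair.beta_outcome**2
            * pair.se_exposure**2
            / pair.beta_exposure**4
        )
    return _normal_estimate("wald_ratio", theta, float(np.sqrt(var)), 1)


# ---------------------------------------------------------------------------
# IVW
# ---------------------------------------------------------------------------


def _ivw_point(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> tuple[float, float, float]:
    """(theta, fixed SE, Q) for the zero-intercept weighted regression."""
    w = 1.0 / sy**2
    sxx = float(np.sum(w * bx**2))
    if sxx == 0.0:
        raise DegenerateDesignError("all exposure effects are zero")
    theta = float(np.sum(w * bx * by)) / sxx
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (by - theta * bx) ** 2))
    return theta, se_fixed, q


def ivw(hset: HarmonizedSet, mode: str = "multiplicative_re") -> MrEstimate:
    """Inverse-variance weighted estimate.

    ``mode`` is ``"fixed"`` or ``"multiplicative_re"`` (the default); the
    latter inflates the fixed-effect SE by max(1, √(Q/(J−1))) so that
    between-instrument heterogeneity widens the interval but can never
    shrink it.  A single-pair set degrades to the Wald ratio.
    """
    if mode not in ("fixed", "multiplicative_re"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    j = len(hset)
    if j == 0:
        raise InsufficientInstrumentsError("empty harmonized set")
    if j == 1:
        est = wald_ratio(hset.pairs[0])
        return replace(est, method="ivw_fixed" if mode == "fixed" else "ivw_re")
    theta, se_fixed, q = _ivw_point(hset.beta_exposure, hset.beta_outcome, hset.se_outcome)
    if mode == "fixed":
        return _normal_estimate("ivw_fixed", theta, se_fixed, j)
    scale = max(1.0, float(np.sqrt(q / (j - 1))))
    return _normal_estimate("ivw_re", theta, se_fixed * scale, j)


# ---------------------------------------------------------------------------
# MR-Egger
# ---------------------------------------------------------------------------


def _egger_fit(
    bx: np.ndarray, by: np.ndarray, sy: np.ndarray
) -> tuple[float, float, float, float, float]:
    """(slope, intercept, se_slope, se_intercept, sigma2) of the weighted
    regression β_Y = α + θ β_X after orienting β_X ≥ 0."""
    sign = np.where(bx < 0, -1.0, 1.0)
    x = bx * sign
    y = by * sign
    w = 1.0 / sy**2
    sw = float(np.sum(w))
    sx = float(np.sum(w * x))
    sxx = float(np.sum(w * x**2))
    sy_ = float(np.sum(w * y))
    sxy = float(np.sum(w * x * y))
    d = sw * sxx - sx**2
    if d <= 0:
        raise DegenerateDesignError("exposure effects carry no spread; slope unidentified")
    slope = (sw * sxy - sx * sy_) / d
    intercept = (sxx * sy_ - sx * sxy) / d
    resid = y - intercept - slope * x
    dof = len(x) - 2
    sigma2 = float(np.sum(w * resid**2)) / dof
    scale = max(1.0, sigma2)
    se_slope = float(np.sqrt(scale * sw / d))
    se_intercept = float(np.sqrt(scale * sxx / d))
    return slope, intercept, se_slope, se_intercept, sigma2


def mr_egger(hset: HarmonizedSet) -> tuple[MrEstimate, MrEstimate]:
    """MR-Egger regression: (slope estimate, intercept estimate).

    Instruments are internally oriented so every β_X ≥ 0 (both effects'
    signs flipped together where needed); the harmonized set is not
    mutated.  SEs carry the multiplicative over-dispersion factor
    max(1, residual variance); p-values and CIs use t with J−2 df.
    """
    j = len(hset)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger needs >= 3 instruments, got {j}")
    slope, intercept, se_slope, se_int, _ = _egger_fit(
        hset.beta_exposure, hset.beta_outcome, hset.se_outcome
    )
    return (
        _t_estimate("egger_slope", slope, se_slope, j - 2, j),
        _t_estimate("egger_intercept", intercept, se_int, j - 2, j),
    )


# ---------------------------------------------------------------------------
# Weighted median
# ---------------------------------------------------------------------------


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative weight.

    With ratios ordered θ_(1) ≤ … ≤ θ_(J) and normalized weights w_j, the
    estimate interpolates θ across s_j = Σ_{k≤j} w_k − w_j/2 at s = 1/2.
    """
    order = np.argsort(ratios, kind="stable")
    th = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    w = w / w.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, th))


def _ratio_weights(hset: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    bx, by, sy = hset.beta_exposure, hset.beta_outcome, hset.se_outcome
    if np.any(bx == 0):
        raise UndefinedRatioError("weighted median undefined with beta_exposure = 0")
    ratios = by / bx
    weights = bx**2 / sy**2  # inverse first-order ratio variance
    return ratios, weights


def weighted_median(
    hset: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MrEstimate:
    """Weighted-median estimate with parametric-bootstrap SE.

    Each bootstrap replicate redraws β_Xj ~ N(β_Xj, se_Xj²) and
    β_Yj ~ N(β_Yj, se_Yj²) and recomputes the weighted median; the SE is
    the standard deviation over ``n_boot`` replicates.  ``seed`` is
    mandatory when bootstrapping (the only stochastic estimator must be
    reproducible).  ``n_boot = 0`` returns the point estimate alone with
    NaN inference — useful inside large simulation studies.
    """
    j = len(hset)
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted median needs >= 3 instruments, got {j}")
    ratios, weights = _ratio_weights(hset)
    point = weighted_median_point(ratios, weights)
    if n_boot == 0:
        nan = float("nan")
        return MrEstimate("weighted_median", point, nan, nan, nan, nan, j)
    if seed is None:
        raise ValueError("weighted_median bootstrap requires an explicit seed")
    rng = np.random.default_rng(seed)
    bx, sx = hset.beta_exposure, hset.se_exposure
    by, sy = hset.beta_outcome, hset.se_outcome
    bx_star = rng.normal(bx, sx, size=(n_boot, j))
    by_star = rng.normal(by, sy, size=(n_boot, j))
    boots = np.empty(n_boot)
    for k in range(n_boot):
        xs = bx_star[k]
        if np.any(xs == 0):  # zero-probability event; keep the draw total
            xs = np.where(xs == 0, np.finfo(float).tiny, xs)
        boots[k] = weighted_median_point(by_star[k] / xs, xs**2 / sy**2)
    se = float(np.std(boots, ddof=1))
    return _normal_estimate("weighted_median", point, se, j)


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass
class MethodConfig:
    """Knobs shared by the estimator battery."""

    ivw_mode: str = "multiplicative_re"
    n_boot: int = 1000
    seed: int = 0
    include_fixed: bool = True

    def __post_init__(self) -> None:
        if self.ivw_mode not in ("fixed", "multiplicative_re"):
            raise ValueError(f"unknown IVW mode {self.ivw_mode!r}")


def run_all_methods(
    hset: HarmonizedSet, config: MethodConfig | None = None
) -> list[MrEstimate]:
    """IVW (configured mode, plus fixed-effect when distinct), weighted
    median, and MR-Egger slope/intercept on one harmonized set.

    Methods whose preconditions fail (e.g. Egger with 2 instruments)
    produce ``not_computed`` placeholder entries rather than raising, so a
    grid of analyses never aborts on a thin instrument set.  Output is
    deterministic given the config seed.
    """
    cfg = config or MethodConfig()
    j = len(hset)
    out: list[MrEstimate] = []

    try:
        out.append(ivw(hset, mode=cfg.ivw_mode))
    except (InsufficientInstrumentsError, DegenerateDesignError, UndefinedRatioError) as e:
        out.append(_not_computed("ivw_re" if cfg.ivw_mode != "fixed" else "ivw_fixed", j, str(e)))
    if cfg.include_fixed and cfg.ivw_mode != "fixed":
        try:
            out.append(ivw(hset, mode="fixed"))
        except (InsufficientInstrumentsError, DegenerateDesignError, UndefinedRatioError) as e:
            out.append(_not_computed("ivw_fixed", j, str(e)))

    try:
        out.append(weighted_median(hset, n_boot=cfg.n_boot, seed=cfg.seed))
    except (InsufficientInstrumentsError, UndefinedRatioError) as e:
        out.append(_not_computed("weighted_median", j, str(e)))

    try:
        slope, intercept = mr_egger(hset)
        out.extend([slope, intercept])
    except (InsufficientInstrumentsError, DegenerateDesignError) as e:
        out.append(_not_computed("egger_slope", j, str(e)))
        out.append(_not_computed("egger_intercept", j, str(e)))

    return out
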