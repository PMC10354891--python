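"""End-to-end orchestration of an exposure × outcome analysis grid.

For each pair the pipeline runs instrument selection → harmonization →
estimation (IVW main, weighted median, MR-Egger) → diagnostics, then
applies two decision rules:

* **nominal significance** — p_IVW < 0.05 *and* all three estimators agree
  in sign (an estimate of exactly zero never counts as agreeing);
* **family-wise significance** — the same direction rule with the IVW
  p-value compared against a Bonferroni threshold α / n_tests, where
  n_tests defaults to the number of pairs actually analyzed and can be
  overridden to match a pre-specified family size.

Per-pair seeds are derived from a master seed and the pair's names, so grid
results are independent of execution order.  A pair failing any stage
yields a structured null row rather than aborting the grid.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .estimators import MethodConfig, MrEstimate, run_all_methods
from .harmonize import DEFAULT_PALINDROME_WINDOW, HarmonizedSet, harmonize
from .instruments import InstrumentSet, SelectionConfig, select_instruments
from .sensitivity import (
    SensitivityReport,
    cochran_q,
    egger_intercept_test,
    mr_presso_global,
)
from .sumstats import LdReference, SummaryDataset, format_ci

__all__ = [
    "PipelineConfig",
    "GridResult",
    "bonferroni_threshold",
    "direction_consistent",
    "classify",
    "analyze_pair",
    "run_grid",
]


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Family-wise error threshold α / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


@dataclass
class PipelineConfig:
    """All knobs of a grid run, flat enough for a YAML file."""

    selection: SelectionConfig = field(default_factory=SelectionConfig)
    palindrome_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW
    drop_all_palindromes: bool = False
    ivw_mode: str = "multiplicative_re"
    n_boot: int = 1000
    n_sim: int = 2000
    alpha: float = 0.05
    family_size_override: int | None = None
    master_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sel_keys = {f for f in SelectionConfig.__dataclass_fields__}
        sel = {k: d.pop(k) for k in list(d) if k in sel_keys}
        if "palindrome_window" in d:
            d["palindrome_window"] = tuple(d["palindrome_window"])
        return cls(selection=SelectionConfig(**sel), **d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def _pair_seed(master_seed: int, exposure_name: str, outcome_name: str) -> int:
    """Stable sub-2³¹ seed for one pair; order-independent reproducibility."""
    digest = hashlib.sha256(
        f"{master_seed}|{exposure_name}|{outcome_name}".encode()
    ).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def direction_consistent(estimates: Sequence[MrEstimate]) -> tuple[bool, str]:
    """Whether IVW, weighted median, and Egger slope share a sign.

    Returns (flag, reason).  Any of the three missing or not computed →
    (False, why); an exactly-zero estimate also fails the rule.
    """
    wanted = {"weighted_median": None, "egger_slope": None}
    ivw_est = None
    for est in estimates:
        if est.method in ("ivw_fixed", "ivw_re") and ivw_est is None:
            ivw_est = est
        elif est.method in wanted and wanted[est.method] is None:
            wanted[est.method] = est
    picked = {"ivw": ivw_est, **wanted}
    for name, est in picked.items():
        if est is None:
            return False, f"{name} estimate missing"
        if not est.computed:
            return False, f"{name} {est.status}"
    signs = {np.sign(est.theta) for est in picked.values()}
    if 0.0 in signs:
        return False, "an estimate is exactly zero"
    return (len(signs) == 1), ("" if len(signs) == 1 else "sign disagreement")


@dataclass
class GridResult:
    """One exposure × outcome cell of the analysis grid."""

    exposure: str
    outcome: str
    n_snps: int
    estimates: list[MrEstimate]
    sensitivity: SensitivityReport | None
    nominal_significant: bool
    direction_consistent: bool
    bonferroni_significant: bool
    n_tests_in_family: int
    status: str = "ok"
    instruments: InstrumentSet | None = None
    note: str = ""

    def main_ivw(self) -> MrEstimate | None:
        for est in self.estimates:
            if est.method in ("ivw_re", "ivw_fixed") and est.computed:
                return est
        return None

    def result_rows(self) -> list[dict]:
        """Flat rows (one per method) in the results-table schema."""
        sens = self.sensitivity
        nan = float("nan")
        shared = {
            "exposure": self.exposure,
            "outcome": self.outcome,
            "n_snps": self.n_snps,
            "q_stat": sens.q_stat if sens else nan,
            "q_pval": sens.q_pval if sens else nan,
            "egger_intercept": sens.egger_intercept if sens else nan,
            "egger_intercept_pval": sens.egger_intercept_pval if sens else nan,
            "presso_global_pval": sens.presso_global_pval if sens else nan,
        }
        rows = []
        estimates = self.estimates or [
            MrEstimate("none", nan, nan, nan, nan, nan, 0, f"not_computed: {self.status}")
        ]
        for est in estimates:
            rows.append(
                {
                    **shared,
                    "method": est.method,
                    "beta": est.theta,
                    "ci_95": format_ci(est.ci_low, est.ci_high),
                    "se": est.se,
                    "pval": est.pval,
                }
            )
        return rows


def classify(
    estimates: Sequence[MrEstimate],
    alpha: float,
    n_tests: int,
    main_ivw_method: str = "ivw_re",
) -> dict:
    """Apply the significance rules to one pair's estimates.

    nominal   ⇔ p_IVW < α and directions consistent
    bonferroni ⇔ p_IVW < α / n_tests and directions consistent
    """
    consistent, reason = direction_consistent(estimates)
    ivw_est = next(
        (e for e in estimates if e.method == main_ivw_method and e.computed), None
    )
    if ivw_est is None:
        ivw_est = next(
            (e for e in estimates if e.method in ("ivw_re", "ivw_fixed") and e.computed),
            None,
        )
    threshold = bonferroni_threshold(alpha, n_tests)
    p = ivw_est.pval if ivw_est is not None else float("nan")
    nominal = bool(ivw_est is not None and p < alpha and consistent)
    bonf = bool(ivw_est is not None and p < threshold and consistent)
    return {
        "nominal_significant": nominal,
        "bonferroni_significant": bonf,
        "direction_consistent": consistent,
        "direction_reason": reason,
        "p_ivw": p,
        "alpha": alpha,
        "bonferroni_threshold": threshold,
        "n_tests": n_tests,
    }


def analyze_pair(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld: LdReference | None,
    annotations: pd.DataFrame | None,
    config: PipelineConfig,
    n_tests: int = 1,
) -> GridResult:
    """Run the full cascade for one exposure → outcome pair."""
    seed = _pair_seed(config.master_seed, exposure.trait_name, outcome.trait_name)
    blank = dict(
        exposure=exposure.trait_name,
        outcome=outcome.trait_name,
        estimates=[],
        sensitivity=None,
        nominal_significant=False,
        direction_consistent=False,
        bonferroni_significant=False,
        n_tests_in_family=n_tests,
    )

    instruments = select_instruments(exposure, outcome, ld, annotations, config.selection)
    if instruments.is_empty:
        return GridResult(
            n_snps=0, status="no_instruments", instruments=instruments, **blank
        )

    hset = harmonize(
        instruments.selected,
        outcome,
        palindrome_eaf_window=config.palindrome_window,
        drop_all_palindromes=config.drop_all_palindromes,
        exposure_name=exposure.trait_name,
        outcome_name=outcome.trait_name,
    )
    if len(hset) == 0:
        return GridResult(
            n_snps=0, status="no_overlapping_variants", instruments=instruments, **blank
        )

    estimates = run_all_methods(
        hset,
        MethodConfig(ivw_mode=config.ivw_mode, n_boot=config.n_boot, seed=seed),
    )

    nan = float("nan")
    try:
        q, p_q = cochran_q(hset)
    except Exception:
        q, p_q = nan, nan
    try:
        intercept, p_int = egger_intercept_test(hset)
    except Exception:
        intercept, p_int = nan, nan
    try:
        presso = mr_presso_global(hset, n_sim=config.n_sim, seed=seed + 1)
        rss, p_presso = presso.rss_obs, presso.pval
    except Exception:
        rss, p_presso = nan, nan
    sens = SensitivityReport(
        q_stat=q,
        q_pval=p_q,
        egger_intercept=intercept,
        egger_intercept_pval=p_int,
        presso_rss_obs=rss,
        presso_global_pval=p_presso,
        n_sim=config.n_sim,
        seed=seed + 1,
    )

    main = "ivw_re" if config.ivw_mode != "fixed" else "ivw_fixed"
    flags = classify(estimates, config.alpha, n_tests, main_ivw_method=main)
    blank.update(
        estimates=estimates,
        sensitivity=sens,
        nominal_significant=flags["nominal_significant"],
        direction_consistent=flags["direction_consistent"],
        bonferroni_significant=flags["bonferroni_significant"],
    )
    return GridResult(
        n_snps=len(hset),
        status="ok",
        instruments=instruments,
        note=flags["direction_reason"],
        **blank,
    )


def run_grid(
    exposures: Sequence[SummaryDataset],
    outcomes: Sequence[SummaryDataset],
    ld: LdReference | None = None,
    annotations: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> list[GridResult]:
    """One :class:`GridResult` per exposure × outcome pair.

    The Bonferroni family size defaults to the number of pairs analyzed;
    ``config.family_size_override`` substitutes a pre-specified family.
    Per-pair failures are recorded in the result's ``status``, never fatal.
    Results are deterministic given the master seed and independent of
    pair ordering.
    """
    cfg = config or PipelineConfig()
    pairs = [(e, o) for e in exposures for o in outcomes]
    if not pairs:
        raise ValueError("need at least one exposure and one outcome")
    n_tests = cfg.family_size_override or len(pairs)
    results = []
    for exposure, outcome in pairs:
        try:
            results.append(
                analyze_pair(exposure, outcome, ld, annotations, cfg, n_tests=n_tests)
            )
        except Exception as exc:  # structured null row preserves grid shape
            results.append(
                GridResult(
                    exposure=exposure.trait_name,
                    outcome=outcome.trait_name,
                    n_snps=0,
                    estimates=[],
                    sensitivity=None,
                    nominal_significant=False,
                    direction_consistent=False,
                    bonferroni_significant=False,
                    n_tests_in_family=n_tests,
                    status=f"error: {exc}",
                )
            )
    return results
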