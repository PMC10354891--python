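"""Synthetic paired GWAS summary statistics with known ground truth.

The generator mirrors the model the two-sample MR estimators assume.  For
each instrument j:

* a true exposure effect γ_j is drawn from a truncated normal
  (|γ_j| ≥ γ_min keeps every instrument detectable) and, by default,
  oriented positive — the convention of reporting effects on the
  exposure-increasing allele;
* a direct (pleiotropic) outcome effect α_j comes from the configured
  pleiotropy law;
* the true outcome effect is Γ_j = θ·γ_j + α_j;
* the *observed* effects add two-sample sampling noise from independent
  substreams: β_Xj ~ N(γ_j, se_Xj²), β_Yj ~ N(Γ_j, se_Yj²), with per-SNP
  SEs drawn from log-normal laws (the exposure GWAS, being much larger,
  gets smaller SEs than the outcome GWAS by default);
* Wald p-values, positions spread far enough apart to be independent
  (unless LD blocks are requested), and allele pairs — including a
  configurable palindromic fraction — complete the records.

Background null SNPs (γ = 0) can be added so that the p-value filter and
F screen of the selection cascade have something to reject.  All
randomness flows from the single seed in the truth object; equal truths
give bitwise-identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedSet
from .sumstats import GwasRecord, LdReference, SummaryDataset

__all__ = [
    "GammaLaw",
    "PleiotropyLaw",
    "SeLaw",
    "LdBlocks",
    "SyntheticTruth",
    "simulate_pair",
    "simulate_grid",
    "simulate_effects",
    "harmonized_from_truth",
    "simulate_ld",
    "simulate_annotations",
    "scenario_suite",
]

_NONPALINDROMIC_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"))
_PALINDROMIC_PAIRS = (("A", "T"), ("C", "G"))


@dataclass(frozen=True)
class GammaLaw:
    """True exposure-effect distribution: N(mu, sigma²) truncated to
    |γ| ≥ min_abs, oriented positive when ``one_sided``."""

    mu: float = 0.0
    sigma: float = 0.08
    min_abs: float = 0.05
    one_sided: bool = True

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        out = np.empty(size)
        need = np.ones(size, dtype=bool)
        while need.any():
            cand = rng.normal(self.mu, self.sigma, size=int(need.sum()))
            ok = np.abs(cand) >= self.min_abs
            idx = np.flatnonzero(need)[ok]
            out[idx] = cand[ok]
            need[idx] = False
        if self.one_sided:
            out = np.abs(out)
        return out


@dataclass(frozen=True)
class PleiotropyLaw:
    """Direct-effect law for α_j.

    kinds:
      - ``none``: α = 0 (all instruments valid);
      - ``balanced``: α ~ N(0, sigma²), independent of γ (InSIDE holds,
        no directional component);
      - ``directional``: α ~ N(mu, sigma²), independent of γ (InSIDE
        holds; biases IVW, not the Egger slope);
      - ``correlated``: α = mu + sigma·(ρ·z_γ + √(1−ρ²)·ε) with z_γ the
        standardized γ — InSIDE violated;
      - ``contaminated``: a fraction of instruments get α ~ N(mu, sigma²),
        the rest are valid (the "some instruments invalid" regime).
    """

    kind: str = "none"
    mu: float = 0.0
    sigma: float = 0.0
    rho: float = 0.0
    frac_invalid: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("none", "balanced", "directional", "correlated", "contaminated"):
            raise ValueError(f"unknown pleiotropy kind {self.kind!r}")
        if not (-1.0 <= self.rho <= 1.0):
            raise ValueError("rho must lie in [-1, 1]")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if not (0.0 <= self.frac_invalid <= 1.0):
            raise ValueError("frac_invalid must lie in [0, 1]")

    def draw(self, rng: np.random.Generator, gamma: np.ndarray) -> np.ndarray:
        j = len(gamma)
        if self.kind == "none":
            return np.zeros(j)
        if self.kind == "balanced":
            return rng.normal(0.0, self.sigma, size=j)
        if self.kind == "directional":
            return rng.normal(self.mu, self.sigma, size=j)
        if self.kind == "correlated":
            sd = gamma.std()
            z = (gamma - gamma.mean()) / (sd if sd > 0 else 1.0)
            eps = rng.normal(size=j)
            return self.mu + self.sigma * (self.rho * z + np.sqrt(1 - self.rho**2) * eps)
        # contaminated
        alpha = np.zeros(j)
        n_invalid = int(round(self.frac_invalid * j))
        idx = rng.choice(j, size=n_invalid, replace=False)
        alpha[idx] = rng.normal(self.mu, self.sigma, size=n_invalid)
        return alpha


@dataclass(frozen=True)
class SeLaw:
    """Per-SNP standard-error law: log-normal around ``median`` with
    log-scale spread ``sigma`` (0 → constant SEs)."""

    median: float = 0.005
    sigma: float = 0.4

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.sigma == 0.0:
            return np.full(size, self.median)
        return rng.lognormal(mean=np.log(self.median), sigma=self.sigma, size=size)


@dataclass(frozen=True)
class LdBlocks:
    """Block-diagonal LD: ``sizes`` partition the instrument list; within a
    block r² = ``r2``, between blocks r² = 0."""

    sizes: tuple[int, ...]
    r2: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("r2 must lie in [0, 1]")


@dataclass
class SyntheticTruth:
    """Generating parameters of one simulated exposure/outcome pair.

    The defaults emulate the situation the package targets: a very large
    exposure GWAS (small se_X) against a mid-sized outcome GWAS (larger
    se_Y), with instrument strengths spanning single digits to tens of
    thousands on the per-SNP F scale so the F screen does real work.
    """

    theta: float = 0.0
    J: int = 30
    gamma_law: GammaLaw = field(default_factory=GammaLaw)
    pleiotropy_law: PleiotropyLaw = field(default_factory=PleiotropyLaw)
    se_x_law: SeLaw = field(default_factory=lambda: SeLaw(median=0.004, sigma=0.3))
    se_y_law: SeLaw = field(default_factory=lambda: SeLaw(median=0.01, sigma=0.4))
    n_null_snps: int = 0
    ld_blocks: LdBlocks | None = None
    palindromic_fraction: float = 0.1
    n_exposure: float = 1_000_000
    n_outcome: float = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.J < 1:
            raise ValueError("J must be >= 1")
        if not (0.0 <= self.palindromic_fraction <= 1.0):
            raise ValueError("palindromic_fraction must lie in [0, 1]")
        if self.ld_blocks is not None and sum(self.ld_blocks.sizes) != self.J:
            raise ValueError("ld_blocks sizes must partition the J instruments")


def _rngs(truth: SyntheticTruth) -> tuple[np.random.Generator, ...]:
    # independent substreams: structure, exposure noise, outcome noise —
    # exposure/outcome draws never share a stream (two-sample design)
    ss = np.random.SeedSequence(truth.seed)
    return tuple(np.random.default_rng(s) for s in ss.spawn(3))


def simulate_effects(
    truth: SyntheticTruth,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Instrument-level arrays (β_X, se_X, β_Y, se_Y, γ, α) for one draw."""
    rng_struct, rng_x, rng_y = _rngs(truth)
    gamma = truth.gamma_law.draw(rng_struct, truth.J)
    alpha = truth.pleiotropy_law.draw(rng_struct, gamma)
    se_x = truth.se_x_law.draw(rng_struct, truth.J)
    se_y = truth.se_y_law.draw(rng_struct, truth.J)
    big_gamma = truth.theta * gamma + alpha
    zero_x = se_x == 0
    zero_y = se_y == 0
    bx = np.where(zero_x, gamma, rng_x.normal(gamma, np.where(zero_x, 1.0, se_x)))
    by = np.where(
        zero_y, big_gamma, rng_y.normal(big_gamma, np.where(zero_y, 1.0, se_y))
    )
    return bx, se_x, by, se_y, gamma, alpha


def harmonized_from_truth(truth: SyntheticTruth) -> HarmonizedSet:
    """One replicate as an already-aligned :class:`HarmonizedSet`.

    Skips the allele bookkeeping — the natural input for estimator-level
    simulation studies where harmonization itself is not under test.
    """
    bx, sx, by, sy, _, _ = simulate_effects(truth)
    sx = np.where(sx > 0, sx, 1e-12)
    sy = np.where(sy > 0, sy, 1e-12)
    return HarmonizedSet.from_arrays(
        bx, sx, by, sy, exposure_name="sim_exposure", outcome_name="sim_outcome"
    )


def _positions(truth: SyntheticTruth, n_total: int) -> tuple[list[str], np.ndarray]:
    """Chromosome labels and positions; LD-block mates sit 10 kb apart,
    everything else 25 Mb apart (outside any clumping window)."""
    chroms: list[str] = []
    pos = np.empty(n_total, dtype=np.int64)
    if truth.ld_blocks is not None:
        blocks: list[int] = list(truth.ld_blocks.sizes)
    else:
        blocks = [1] * truth.J
    blocks = blocks + [1] * (n_total - sum(blocks))
    chrom_cycle = [str(c) for c in range(1, 23)]
    i = 0
    for b, size in enumerate(blocks):
        # blocks sharing a chromosome label sit 25 Mb apart (outside any
        # reasonable clumping window); block mates sit 10 kb apart (inside)
        chroms_label = chrom_cycle[b % len(chrom_cycle)]
        base = 1_000_000 + (b // len(chrom_cycle)) * 25_000_000
        for k in range(size):
            chroms.append(chroms_label)
            pos[i] = base + k * 10_000
            i += 1
    return chroms, pos


def _wald_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, np.abs(beta) / np.where(se > 0, se, 1.0), np.inf)
    p = 2.0 * stats.norm.sf(z)
    return np.clip(p, np.nextafter(0, 1), 1.0)


def simulate_pair(
    truth: SyntheticTruth,
) -> tuple[SummaryDataset, SummaryDataset, pd.DataFrame]:
    """Full exposure and outcome datasets plus the per-SNP truth table.

    Instruments are named ``rs1..rsJ``; background null SNPs (γ = 0)
    ``null1..``.  The truth table records γ_j, α_j, Γ_j and whether the
    variant is a planted instrument.  Deterministic under the truth seed.
    """
    rng_struct, rng_x, rng_y = _rngs(truth)
    j = truth.J
    gamma = truth.gamma_law.draw(rng_struct, j)
    alpha = truth.pleiotropy_law.draw(rng_struct, gamma)
    se_x = truth.se_x_law.draw(rng_struct, j)
    se_y = truth.se_y_law.draw(rng_struct, j)

    n_total = j + truth.n_null_snps
    gamma_all = np.concatenate([gamma, np.zeros(truth.n_null_snps)])
    alpha_all = np.concatenate([alpha, np.zeros(truth.n_null_snps)])
    se_x_all = np.concatenate([se_x, truth.se_x_law.draw(rng_struct, truth.n_null_snps)])
    se_y_all = np.concatenate([se_y, truth.se_y_law.draw(rng_struct, truth.n_null_snps)])
    big_gamma_all = truth.theta * gamma_all + alpha_all

    zero_x = se_x_all == 0
    zero_y = se_y_all == 0
    bx = np.where(zero_x, gamma_all, rng_x.normal(gamma_all, np.where(zero_x, 1.0, se_x_all)))
    by = np.where(zero_y, big_gamma_all, rng_y.normal(big_gamma_all, np.where(zero_y, 1.0, se_y_all)))
    # degenerate-noise draws need a positive se for the record invariant
    se_x_rec = np.where(zero_x, 1e-12, se_x_all)
    se_y_rec = np.where(zero_y, 1e-12, se_y_all)

    ids = [f"rs{i + 1}" for i in range(j)] + [f"null{i + 1}" for i in range(truth.n_null_snps)]
    chroms, pos = _positions(truth, n_total)

    n_pal = int(round(truth.palindromic_fraction * n_total))
    pal_idx = set(rng_struct.choice(n_total, size=n_pal, replace=False).tolist())
    eaf = rng_struct.uniform(0.05, 0.95, size=n_total)

    px = _wald_p(bx, se_x_rec)
    py = _wald_p(by, se_y_rec)

    exp_records: list[GwasRecord] = []
    out_records: list[GwasRecord] = []
    for i in range(n_total):
        if i in pal_idx:
            ea, oa = _PALINDROMIC_PAIRS[i % len(_PALINDROMIC_PAIRS)]
        else:
            ea, oa = _NONPALINDROMIC_PAIRS[i % len(_NONPALINDROMIC_PAIRS)]
        common = dict(
            variant_id=ids[i], chrom=chroms[i], pos=int(pos[i]),
            effect_allele=ea, other_allele=oa, eaf=float(eaf[i]),
        )
        exp_records.append(
            GwasRecord(beta=float(bx[i]), se=float(se_x_rec[i]), pval=float(px[i]),
                       n=truth.n_exposure, **common)
        )
        out_records.append(
            GwasRecord(beta=float(by[i]), se=float(se_y_rec[i]), pval=float(py[i]),
                       n=truth.n_outcome, **common)
        )

    truth_table = pd.DataFrame(
        {
            "variant_id": ids,
            "gamma": gamma_all,
            "alpha": alpha_all,
            "big_gamma": big_gamma_all,
            "is_instrument": [i < j for i in range(n_total)],
        }
    )
    exposure = SummaryDataset("sim_exposure", "exposure", exp_records)
    outcome = SummaryDataset("sim_outcome", "outcome", out_records)
    return exposure, outcome, truth_table


def simulate_grid(
    theta: np.ndarray,
    base: SyntheticTruth | None = None,
    seed: int = 0,
) -> tuple[list[SummaryDataset], list[SummaryDataset]]:
    """Exposure × outcome grid datasets with a known causal-effect matrix.

    ``theta[e, o]`` is the true effect of exposure ``e`` on outcome ``o``.
    Each exposure gets its own variant namespace (``e{e}_rs{j}``); every
    outcome dataset carries records for all namespaces, each generated
    under its own cell of the effect matrix with independent outcome
    noise.  This makes null cells genuinely null — shared variants with
    correlated true effects across cells cannot leak signal.

    Other generating parameters (J, effect and SE laws, pleiotropy) come
    from ``base``; its ``theta`` and ``seed`` fields are ignored.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    n_exp, n_out = theta.shape
    base = base or SyntheticTruth()
    ss = np.random.SeedSequence(seed)
    streams = iter(ss.spawn(n_exp * (1 + n_out)))

    exposures: list[SummaryDataset] = []
    per_exp: list[dict] = []
    for e in range(n_exp):
        rng = np.random.default_rng(next(streams))
        gamma = base.gamma_law.draw(rng, base.J)
        alpha = base.pleiotropy_law.draw(rng, gamma)
        se_x = base.se_x_law.draw(rng, base.J)
        se_y = base.se_y_law.draw(rng, base.J)
        bx = rng.normal(gamma, np.where(se_x > 0, se_x, 1e-12))
        ids = [f"e{e}_rs{j + 1}" for j in range(base.J)]
        chroms, pos = _positions(base, base.J)
        eaf = rng.uniform(0.05, 0.95, size=base.J)
        records = []
        for i in range(base.J):
            ea, oa = _NONPALINDROMIC_PAIRS[i % len(_NONPALINDROMIC_PAIRS)]
            records.append(
                GwasRecord(
                    variant_id=ids[i], chrom=chroms[i],
                    pos=int(pos[i]) + e * 100_000,
                    effect_allele=ea, other_allele=oa, eaf=float(eaf[i]),
                    beta=float(bx[i]), se=float(max(se_x[i], 1e-12)),
                    pval=float(_wald_p(bx[i : i + 1], se_x[i : i + 1])[0]),
                    n=base.n_exposure,
                )
            )
        exposures.append(SummaryDataset(f"exposure_{e}", "exposure", records))
        per_exp.append(
            dict(gamma=gamma, alpha=alpha, se_y=se_y, ids=ids, records=records)
        )

    outcomes: list[SummaryDataset] = []
    for o in range(n_out):
        records = []
        for e in range(n_exp):
            rng = np.random.default_rng(next(streams))
            info = per_exp[e]
            big_gamma = theta[e, o] * info["gamma"] + info["alpha"]
            se_y = info["se_y"]
            by = rng.normal(big_gamma, np.where(se_y > 0, se_y, 1e-12))
            for i, exp_rec in enumerate(info["records"]):
                records.append(
                    GwasRecord(
                        variant_id=exp_rec.variant_id, chrom=exp_rec.chrom,
                        pos=exp_rec.pos, effect_allele=exp_rec.effect_allele,
                        other_allele=exp_rec.other_allele, eaf=exp_rec.eaf,
                        beta=float(by[i]), se=float(max(se_y[i], 1e-12)),
                        pval=float(_wald_p(by[i : i + 1], se_y[i : i + 1])[0]),
                        n=base.n_outcome,
                    )
                )
        outcomes.append(SummaryDataset(f"outcome_{o}", "outcome", records))
    return exposures, outcomes


def simulate_ld(
    variant_ids: Sequence[str],
    positions: Sequence[int] | None,
    ld_blocks: LdBlocks,
    seed: int = 0,
) -> LdReference:
    """Block-diagonal LD reference over ``variant_ids``.

    Block sizes must partition the variant list; within-block r² is the
    configured constant, between-block r² is zero.  (The seed is accepted
    for interface symmetry; the block structure is deterministic.)
    """
    n = len(variant_ids)
    if sum(ld_blocks.sizes) != n:
        raise ValueError("block sizes must partition the variant list")
    r2 = np.zeros((n, n))
    start = 0
    for size in ld_blocks.sizes:
        r2[start : start + size, start : start + size] = ld_blocks.r2
        start += size
    np.fill_diagonal(r2, 1.0)
    pos = (
        {v: int(p) for v, p in zip(variant_ids, positions)}
        if positions is not None
        else None
    )
    return LdReference(variant_ids, r2, pos)


def simulate_annotations(
    variant_ids: Sequence[str],
    confounded_fraction: float,
    categories: Sequence[str],
    seed: int = 0,
) -> pd.DataFrame:
    """Confounder-annotation table flagging a seeded random subset.

    Flagged variants get one annotation in a cycling category with a
    p-value well below genome-wide significance (drawn log-uniform in
    [1e-30, 1e-9]); unflagged variants get no rows.
    """
    if not (0.0 <= confounded_fraction <= 1.0):
        raise ValueError("confounded_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_flag = int(round(confounded_fraction * len(variant_ids)))
    cols = ["variant_id", "trait", "category", "pval"]
    if n_flag == 0 or not categories:
        return pd.DataFrame(columns=cols)
    idx = sorted(rng.choice(len(variant_ids), size=n_flag, replace=False).tolist())
    pvals = 10.0 ** rng.uniform(-30, -9, size=n_flag)
    rows = [
        {
            "variant_id": variant_ids[i],
            "trait": f"confounder_trait_{k + 1}",
            "category": categories[k % len(categories)],
            "pval": float(pvals[k]),
        }
        for k, i in enumerate(idx)
    ]
    return pd.DataFrame(rows, columns=cols)


def scenario_suite(seed: int = 0) -> dict[str, SyntheticTruth]:
    """Canonical generating configurations for estimator validation.

    * ``NULL`` — θ = 0, all instruments valid: calibration of type-I error.
    * ``CAUSAL`` — θ = 0.1, J = 100, all valid: parameter recovery.
    * ``BALANCED_PLEIOTROPY`` — zero-mean direct effects with constant SEs:
      the Egger intercept test's own null.
    * ``DIRECTIONAL_PLEIOTROPY`` — nonzero-mean direct effects, independent
      of instrument strength (InSIDE holds): IVW biased, Egger slope not.
    * ``INSIDE_VIOLATED`` — direct effects correlated with instrument
      strength: even the Egger slope is biased (documented, not asserted).
    * ``MINORITY_INVALID`` — 30% of instruments pleiotropic: the weighted
      median's guarantee applies.
    * ``MAJORITY_INVALID`` — 60% invalid: the median's <50%-invalid
      condition fails; no robustness guarantee.
    """
    return {
        "NULL": SyntheticTruth(theta=0.0, J=30, seed=seed),
        "CAUSAL": SyntheticTruth(theta=0.1, J=100, seed=seed),
        "BALANCED_PLEIOTROPY": SyntheticTruth(
            theta=0.1,
            J=30,
            pleiotropy_law=PleiotropyLaw(kind="balanced", sigma=0.01),
            se_x_law=SeLaw(median=0.003, sigma=0.0),
            se_y_law=SeLaw(median=0.01, sigma=0.0),
            seed=seed,
        ),
        "DIRECTIONAL_PLEIOTROPY": SyntheticTruth(
            theta=0.1,
            J=50,
            pleiotropy_law=PleiotropyLaw(kind="directional", mu=0.02, sigma=0.01),
            seed=seed,
        ),
        "INSIDE_VIOLATED": SyntheticTruth(
            theta=0.1,
            J=50,
            pleiotropy_law=PleiotropyLaw(
                kind="correlated", mu=0.02, sigma=0.01, rho=0.7
            ),
            seed=seed,
        ),
        "MINORITY_INVALID": SyntheticTruth(
            theta=0.1,
            J=50,
            pleiotropy_law=PleiotropyLaw(
                kind="contaminated", mu=0.05, sigma=0.01, frac_invalid=0.3
            ),
            seed=seed,
        ),
        "MAJORITY_INVALID": SyntheticTruth(
            theta=0.1,
            J=50,
            pleiotropy_law=PleiotropyLaw(
                kind="contaminated", mu=0.05, sigma=0.01, frac_invalid=0.6
            ),
            seed=seed,
        ),
    }
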