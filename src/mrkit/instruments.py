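"""Instrument selection from exposure GWAS summary statistics.

The selection cascade mirrors standard two-sample MR practice:

1. association filter at a configurable p-value threshold (strict ``<``),
2. greedy LD clumping (most significant variant indexes each region;
   neighbours within the window at r² ≥ the clumping threshold are dropped),
3. proxy substitution for instruments missing from the outcome dataset
   (best available variant at r² strictly above the proxy threshold),
4. instrument-strength screen on the per-variant F statistic (β/se)²,
   keeping F ≥ the threshold,
5. confounder pruning against an annotation table (a variant is removed iff
   it carries at least one sub-threshold association in a configured
   category).

Every stage records its surviving count in an audit trail, so attrition is
always inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .sumstats import GwasRecord, LdReference, SummaryDataset

__all__ = [
    "SelectionConfig",
    "InstrumentSet",
    "filter_by_pvalue",
    "ld_clump",
    "per_snp_f",
    "find_proxy",
    "confounder_filter",
    "select_instruments",
]

#: Audit stage names in cascade order.
AUDIT_STAGES = (
    "input",
    "post_p_filter",
    "post_clump",
    "post_proxy",
    "post_f",
    "post_confounder",
)


@dataclass
class SelectionConfig:
    """Thresholds governing the selection cascade.

    Defaults correspond to a deliberately relaxed instrument p-value
    threshold of 1e-5 (appropriate when few variants reach genome-wide
    significance), clumping at r² < 0.001 within a ±10 Mb window, proxies at
    r² > 0.8, an F ≥ 10 strength screen, and confounder pruning at
    genome-wide significance (5e-8) in the configured categories.
    """

    p_threshold: float = 1e-5
    clump_r2: float = 0.001
    clump_window_bp: int = 10_000_000
    proxy_r2: float = 0.8
    f_threshold: float = 10.0
    confounder_p_threshold: float = 5e-8
    confounder_categories: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if not (0 <= self.clump_r2 < self.proxy_r2 <= 1):
            raise ValueError("require 0 <= clump_r2 < proxy_r2 <= 1")
        if self.clump_window_bp < 0:
            raise ValueError("clump_window_bp must be >= 0")
        self.confounder_categories = tuple(self.confounder_categories)


@dataclass
class InstrumentSet:
    """Outcome of the selection cascade.

    ``selected`` holds the exposure records actually used as instruments
    (proxies appear under their own ids); ``proxy_map`` maps an original
    clumped variant to the proxy that replaced it; ``audit`` maps stage name
    → surviving count; ``removal_log`` records confounder-driven removals.
    """

    selected: list[GwasRecord]
    f_stats: dict[str, float]
    audit: dict[str, int]
    proxy_map: dict[str, str] = field(default_factory=dict)
    removal_log: pd.DataFrame | None = None
    warnings: list[str] = field(default_factory=list)

    @property
    def variant_ids(self) -> list[str]:
        return [r.variant_id for r in self.selected]

    def __len__(self) -> int:
        return len(self.selected)

    @property
    def is_empty(self) -> bool:
        return not self.selected


def filter_by_pvalue(
    dataset: SummaryDataset | Sequence[GwasRecord], p_threshold: float
) -> list[GwasRecord]:
    """Keep records with ``pval`` strictly below the threshold, in input order."""
    return [r for r in dataset if r.pval < p_threshold]


def per_snp_f(record: GwasRecord) -> float:
    """Single-variant instrument-strength F statistic, (β/se)².

    This is the squared Wald z, the per-variant approximation appropriate
    when only summary statistics are available.
    """
    return (record.beta / record.se) ** 2


def _selection_order(records: Sequence[GwasRecord]) -> list[GwasRecord]:
    # p ascending, then variant_id lexicographic: deterministic regardless of
    # input ordering.
    return sorted(records, key=lambda r: (r.pval, r.variant_id))


def ld_clump(
    variants: Sequence[GwasRecord],
    ld_reference: LdReference | None,
    clump_r2: float = 0.001,
    clump_window_bp: int = 10_000_000,
) -> list[GwasRecord]:
    """Greedy LD clumping.

    Repeatedly take the remaining variant with the smallest p-value as an
    index variant, then discard every remaining variant on the same
    chromosome within ``clump_window_bp`` of it whose r² with it is at or
    above ``clump_r2``.  Variants absent from the LD reference are treated
    as independent (r² unknown → 0).  Output is the list of index variants
    in selection order; no surviving pair on one chromosome within the
    window has r² ≥ ``clump_r2``.
    """
    remaining = _selection_order(variants)
    kept: list[GwasRecord] = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for cand in remaining:
            if cand.chrom == index.chrom and abs(cand.pos - index.pos) <= clump_window_bp:
                r2 = (
                    ld_reference.r2_between(index.variant_id, cand.variant_id)
                    if ld_reference is not None
                    else 0.0
                )
                if r2 >= clump_r2:
                    continue
            survivors.append(cand)
        remaining = survivors
    return kept


def find_proxy(
    missing_variant: str,
    outcome_dataset: SummaryDataset,
    ld_reference: LdReference,
    proxy_r2: float = 0.8,
    exposure_dataset: SummaryDataset | None = None,
) -> str | None:
    """Best-LD substitute for an instrument absent from the outcome dataset.

    Scans outcome-dataset variants (restricted to those also present in the
    exposure dataset when one is supplied, since a usable proxy needs effects
    on both sides), and returns the candidate with maximal r² to
    ``missing_variant`` provided that r² is strictly greater than
    ``proxy_r2``.  Ties are broken by smaller exposure p-value, then by
    lexicographic variant id.  Returns ``None`` when nothing qualifies.
    """
    best: tuple[float, float, str] | None = None  # (-r2, exposure p, id)
    for vid in outcome_dataset.variant_ids:
        if vid == missing_variant:
            continue
        if exposure_dataset is not None and vid not in exposure_dataset:
            continue
        r2 = ld_reference.r2_between(missing_variant, vid)
        if r2 <= proxy_r2:
            continue
        p_exp = (
            exposure_dataset[vid].pval
            if exposure_dataset is not None and vid in exposure_dataset
            else 1.0
        )
        key = (-r2, p_exp, vid)
        if best is None or key < best:
            best = key
    return best[2] if best is not None else None


def confounder_filter(
    variants: Sequence[GwasRecord],
    annotations: pd.DataFrame | None,
    categories: Sequence[str],
    confounder_p_threshold: float = 5e-8,
) -> tuple[list[GwasRecord], pd.DataFrame]:
    """Remove variants carrying a confounder association.

    A variant is removed iff it has at least one annotation whose category is
    in ``categories`` with p strictly below ``confounder_p_threshold``.
    Returns the kept records and a removal log (variant_id, trait, category,
    pval) with one row per triggering annotation.
    """
    log_cols = ["variant_id", "trait", "category", "pval"]
    if annotations is None or len(annotations) == 0 or not categories:
        return list(variants), pd.DataFrame(columns=log_cols)
    cats = set(categories)
    hits = annotations[
        annotations["category"].isin(cats)
        & (annotations["pval"] < confounder_p_threshold)
    ]
    flagged = set(hits["variant_id"])
    kept = [r for r in variants if r.variant_id not in flagged]
    present = {r.variant_id for r in variants}
    log = hits[hits["variant_id"].isin(present)][log_cols].reset_index(drop=True)
    return kept, log


def select_instruments(
    exposure: SummaryDataset,
    outcome: SummaryDataset,
    ld_reference: LdReference | None,
    annotations: pd.DataFrame | None,
    config: SelectionConfig | None = None,
) -> InstrumentSet:
    """Run the full selection cascade (p filter → clump → proxy → F screen →
    confounder pruning) and return the instruments with an audit trail.

    An empty final set is a normal result (``InstrumentSet.is_empty``), not
    an exception.
    """
    cfg = config or SelectionConfig()
    audit: dict[str, int] = {"input": len(exposure)}
    warnings: list[str] = []

    stage1 = filter_by_pvalue(exposure, cfg.p_threshold)
    audit["post_p_filter"] = len(stage1)

    if ld_reference is not None:
        absent = [r.variant_id for r in stage1 if r.variant_id not in ld_reference]
        if absent:
            warnings.append(
                f"{len(absent)} variants absent from LD reference treated as independent"
            )
    stage2 = ld_clump(stage1, ld_reference, cfg.clump_r2, cfg.clump_window_bp)
    audit["post_clump"] = len(stage2)

    # proxy substitution: replace (never add) instruments missing in outcome
    stage3: list[GwasRecord] = []
    proxy_map: dict[str, str] = {}
    chosen = {r.variant_id for r in stage2}
    for rec in stage2:
        if rec.variant_id in outcome:
            stage3.append(rec)
            continue
        proxy = (
            find_proxy(
                rec.variant_id, outcome, ld_reference, cfg.proxy_r2, exposure
            )
            if ld_reference is not None
            else None
        )
        if proxy is not None and proxy not in chosen:
            proxy_map[rec.variant_id] = proxy
            chosen.add(proxy)
            stage3.append(exposure[proxy])
        else:
            warnings.append(
                f"{rec.variant_id}: missing in outcome, no eligible proxy"
            )
    audit["post_proxy"] = len(stage3)

    f_stats_all = {r.variant_id: per_snp_f(r) for r in stage3}
    stage4 = [r for r in stage3 if f_stats_all[r.variant_id] >= cfg.f_threshold]
    audit["post_f"] = len(stage4)

    stage5, removal_log = confounder_filter(
        stage4, annotations, cfg.confounder_categories, cfg.confounder_p_threshold
    )
    audit["post_confounder"] = len(stage5)

    return InstrumentSet(
        selected=stage5,
        f_stats={r.variant_id: f_stats_all[r.variant_id] for r in stage5},
        audit=audit,
        proxy_map=proxy_map,
        removal_log=removal_log,
        warnings=warnings,
    )
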