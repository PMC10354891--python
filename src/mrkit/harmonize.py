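"""Allele harmonization of exposure and outcome summary statistics.

Two GWAS report the same variant relative to whichever allele each chose as
the effect allele, possibly on opposite strands.  Before any MR estimator
can consume the pair, both effects must refer to the same allele:

* identical allele pairs pass through unchanged (``aligned``);
* swapped pairs (EA↔OA) flip the outcome beta's sign and its EAF
  (``flipped``);
* complementary-strand pairs are strand-flipped first, then re-compared;
* palindromic variants (A/T or C/G) cannot be resolved from alleles alone —
  they are aligned by allele-frequency agreement when both frequencies fall
  outside a configurable ambiguity window around 0.5, and dropped otherwise;
* anything irreconcilable is dropped as incompatible.

Drops are statuses, never exceptions, and the drop log is complete: the
number of harmonized pairs plus dropped pairs always equals the size of the
variant-id intersection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .sumstats import GwasRecord, SummaryDataset

__all__ = [
    "HarmonizedPair",
    "HarmonizedSet",
    "harmonize_pair",
    "harmonize",
    "DEFAULT_PALINDROME_WINDOW",
    "is_palindromic",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: EAF ambiguity window around 0.5 inside which a palindrome is dropped.
DEFAULT_PALINDROME_WINDOW: tuple[float, float] = (0.42, 0.58)

KEPT_STATUSES = ("aligned", "flipped", "palindromic_kept")
DROP_STATUSES = ("dropped_palindromic", "dropped_incompatible")


def is_palindromic(a: str, b: str) -> bool:
    """True for A/T and C/G variants (alleles are strand-ambiguous)."""
    return _COMPLEMENT.get(a) == b


@dataclass
class HarmonizedPair:
    """One variant's exposure/outcome effects on a common effect allele."""

    variant_id: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float
    effect_allele: str
    status: str
    eaf_exposure: float | None = None
    eaf_outcome: float | None = None

    @property
    def dropped(self) -> bool:
        return self.status in DROP_STATUSES


class HarmonizedSet:
    """The aligned effect pairs one MR analysis consumes.

    Exposes per-variant arrays (``beta_exposure``, ``se_exposure``,
    ``beta_outcome``, ``se_outcome``) for the estimators; ``pairs`` holds
    only non-dropped pairs and ``drop_log`` the rest.
    """

    def __init__(
        self,
        exposure_name: str,
        outcome_name: str,
        pairs: Iterable[HarmonizedPair],
        drop_log: Iterable[HarmonizedPair] = (),
    ) -> None:
        self.exposure_name = exposure_name
        self.outcome_name = outcome_name
        self.pairs = [p for p in pairs]
        self.drop_log = list(drop_log)
        ids = [p.variant_id for p in self.pairs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate variant_id in harmonized set")
        for p in self.pairs:
            if p.dropped:
                raise ValueError(f"{p.variant_id}: dropped pair among kept pairs")
            if not (p.se_exposure > 0 and p.se_outcome > 0):
                raise ValueError(f"{p.variant_id}: non-positive SE")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_snps(self) -> int:
        return len(self.pairs)

    @property
    def variant_ids(self) -> list[str]:
        return [p.variant_id for p in self.pairs]

    def _array(self, attr: str) -> np.ndarray:
        return np.array([getattr(p, attr) for p in self.pairs], dtype=float)

    @property
    def beta_exposure(self) -> np.ndarray:
        return self._array("beta_exposure")

    @property
    def se_exposure(self) -> np.ndarray:
        return self._array("se_exposure")

    @property
    def beta_outcome(self) -> np.ndarray:
        return self._array("beta_outcome")

    @property
    def se_outcome(self) -> np.ndarray:
        return self._array("se_outcome")

    def subset(self, keep: Sequence[int]) -> "HarmonizedSet":
        return HarmonizedSet(
            self.exposure_name,
            self.outcome_name,
            [self.pairs[i] for i in keep],
        )

    @classmethod
    def from_arrays(
        cls,
        beta_exposure,
        se_exposure,
        beta_outcome,
        se_outcome,
        variant_ids: Sequence[str] | None = None,
        exposure_name: str = "exposure",
        outcome_name: str = "outcome",
    ) -> "HarmonizedSet":
        """Build a set directly from effect arrays (already aligned)."""
        bx = np.asarray(beta_exposure, dtype=float)
        sx = np.asarray(se_exposure, dtype=float)
        by = np.asarray(beta_outcome, dtype=float)
        sy = np.asarray(se_outcome, dtype=float)
        if variant_ids is None:
            variant_ids = [f"snp{i + 1}" for i in range(len(bx))]
        pairs = [
            HarmonizedPair(
                variant_id=vid,
                beta_exposure=float(bx[i]),
                se_exposure=float(sx[i]),
                beta_outcome=float(by[i]),
                se_outcome=float(sy[i]),
                effect_allele="A",
                status="aligned",
            )
            for i, vid in enumerate(variant_ids)
        ]
        return cls(exposure_name, outcome_name, pairs)


def _pair(
    exp: GwasRecord,
    out: GwasRecord,
    status: str,
    beta_outcome: float | None = None,
    eaf_outcome: float | None = None,
) -> HarmonizedPair:
    return HarmonizedPair(
        variant_id=exp.variant_id,
        beta_exposure=exp.beta,
        se_exposure=exp.se,
        beta_outcome=out.beta if beta_outcome is None else beta_outcome,
        se_outcome=out.se,
        effect_allele=exp.effect_allele,
        status=status,
        eaf_exposure=exp.eaf,
        eaf_outcome=out.eaf if eaf_outcome is None else eaf_outcome,
    )


def harmonize_pair(
    exp_record: GwasRecord,
    out_record: GwasRecord,
    palindrome_eaf_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW,
    drop_all_palindromes: bool = False,
) -> HarmonizedPair:
    """Align one outcome record to the exposure record's effect allele.

    The exposure labelling is the reference; the outcome beta/EAF are
    flipped when the outcome reported the other allele.  Strand flipping is
    attempted only after direct and swapped comparisons fail, which avoids
    spurious complement matches.  Palindromic variants are resolved by EAF
    agreement (both frequencies outside ``palindrome_eaf_window``) or
    dropped.
    """
    if exp_record.variant_id != out_record.variant_id:
        raise ValueError("harmonize_pair requires matching variant ids")
    ea_x, oa_x = exp_record.effect_allele, exp_record.other_allele
    ea_y, oa_y = out_record.effect_allele, out_record.other_allele

    if is_palindromic(ea_x, oa_x):
        # outcome alleles must be the same ambiguous pair (the complement of
        # a palindrome is the same allele set, so strand is undecidable)
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return _pair(exp_record, out_record, "dropped_incompatible")
        if drop_all_palindromes:
            return _pair(exp_record, out_record, "dropped_palindromic")
        lo, hi = palindrome_eaf_window
        eaf_x, eaf_y = exp_record.eaf, out_record.eaf
        if eaf_x is None or eaf_y is None:
            return _pair(exp_record, out_record, "dropped_palindromic")
        if lo < eaf_x < hi or lo < eaf_y < hi:
            return _pair(exp_record, out_record, "dropped_palindromic")
        # nominal orientation: outcome EA label equal to exposure EA means
        # frequencies should agree in side; disagreement implies the outcome
        # actually measured the other allele
        eaf_y_oriented = eaf_y if ea_y == ea_x else 1.0 - eaf_y
        beta_y_oriented = out_record.beta if ea_y == ea_x else -out_record.beta
        if (eaf_x < 0.5) == (eaf_y_oriented < 0.5):
            return _pair(
                exp_record,
                out_record,
                "palindromic_kept",
                beta_outcome=beta_y_oriented,
                eaf_outcome=eaf_y_oriented,
            )
        return _pair(
            exp_record,
            out_record,
            "palindromic_kept",
            beta_outcome=-beta_y_oriented,
            eaf_outcome=1.0 - eaf_y_oriented,
        )

    def match(a: str, b: str) -> HarmonizedPair | None:
        if (a, b) == (ea_x, oa_x):
            return _pair(exp_record, out_record, "aligned")
        if (a, b) == (oa_x, ea_x):
            return _pair(
                exp_record,
                out_record,
                "flipped",
                beta_outcome=-out_record.beta,
                eaf_outcome=None
                if out_record.eaf is None
                else 1.0 - out_record.eaf,
            )
        return None

    direct = match(ea_y, oa_y)
    if direct is not None:
        return direct
    flipped_strand = match(_COMPLEMENT.get(ea_y, "?"), _COMPLEMENT.get(oa_y, "?"))
    if flipped_strand is not None:
        return flipped_strand
    return _pair(exp_record, out_record, "dropped_incompatible")


def harmonize(
    exposure_records: SummaryDataset | Sequence[GwasRecord],
    outcome_records: SummaryDataset,
    palindrome_eaf_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW,
    drop_all_palindromes: bool = False,
    exposure_name: str | None = None,
    outcome_name: str | None = None,
) -> HarmonizedSet:
    """Harmonize every variant present on both sides, in variant-id order.

    An empty intersection yields an empty set (with an empty drop log), not
    an error.
    """
    if isinstance(exposure_records, SummaryDataset):
        exp_map = {r.variant_id: r for r in exposure_records}
        exposure_name = exposure_name or exposure_records.trait_name
    else:
        exp_map = {r.variant_id: r for r in exposure_records}
        exposure_name = exposure_name or "exposure"
    outcome_name = outcome_name or getattr(outcome_records, "trait_name", "outcome")

    common = sorted(vid for vid in exp_map if vid in outcome_records)
    kept: list[HarmonizedPair] = []
    dropped: list[HarmonizedPair] = []
    for vid in common:
        pair = harmonize_pair(
            exp_map[vid],
            outcome_records[vid],
            palindrome_eaf_window=palindrome_eaf_window,
            drop_all_palindromes=drop_all_palindromes,
        )
        (dropped if pair.dropped else kept).append(pair)
    return HarmonizedSet(exposure_name, outcome_name, kept, dropped)
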