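"""Reading, validation, and writing of GWAS summary statistics and related tables.

This module owns the on-disk formats the rest of the package consumes:

* per-variant GWAS summary associations (tab-delimited, one trait per file),
* LD references (square r² matrix or long pairwise format),
* confounder-annotation tables (variant → trait, category, p), and
* the flat results table produced by a grid of MR analyses.

Conventions follow GWAS summary-statistics practice: tab-separated values,
``.`` decimal separator, ``NA`` for missing, positions 1-based, alleles on
the forward strand as given.  No strand flipping happens at I/O time; allele
reconciliation is the harmonization step's job.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GwasRecord",
    "SummaryDataset",
    "LdReference",
    "ConfounderAnnotation",
    "SumstatsFormatError",
    "ValidationError",
    "DEFAULT_COLUMN_MAP",
    "read_sumstats",
    "write_sumstats",
    "read_ld",
    "write_ld",
    "read_annotations",
    "write_annotations",
    "write_results",
    "read_results",
    "RESULT_COLUMNS",
]

VALID_ALLELES = frozenset("ACGT")

#: Canonical field name -> default file header.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "variant_id": "SNP",
    "chrom": "CHR",
    "pos": "BP",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

REQUIRED_FIELDS = (
    "variant_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "beta",
    "se",
    "pval",
)
OPTIONAL_FIELDS = ("eaf", "n")


class SumstatsFormatError(ValueError):
    """A file cannot be parsed under the declared format/column map."""


class ValidationError(ValueError):
    """Parsed content violates a dataset invariant (e.g. duplicate variant)."""


@dataclass
class GwasRecord:
    """One variant's summary association for one trait.

    Attributes
    ----------
    variant_id : str
        rsID or ``chr:pos:ref:alt`` style identifier.
    chrom : str
        Chromosome label (kept as a string; no coordinate arithmetic across
        chromosomes is ever performed).
    pos : int
        1-based base-pair position.
    effect_allele, other_allele : str
        Single-nucleotide alleles over {A, C, G, T}; the beta is per copy of
        the effect allele.
    eaf : float | None
        Effect-allele frequency in [0, 1]; optional (some meta-analyses omit
        it).
    beta, se : float
        Effect estimate and its standard error (se > 0).
    pval : float
        Association p-value in (0, 1].
    n : float | None
        Sample size; optional.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    def validate(self) -> None:
        """Raise :class:`ValidationError` if any record invariant fails."""
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.variant_id}: invalid effect allele {self.effect_allele!r}"
            )
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.variant_id}: invalid other allele {self.other_allele!r}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: alleles are identical")
        if not np.isfinite(self.beta):
            raise ValidationError(f"{self.variant_id}: non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            raise ValidationError(f"{self.variant_id}: se must be > 0")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.variant_id}: pval must be in (0, 1]")
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            raise ValidationError(f"{self.variant_id}: eaf must be in [0, 1]")
        if int(self.pos) != self.pos or self.pos < 1:
            raise ValidationError(f"{self.variant_id}: pos must be a positive integer")


class SummaryDataset:
    """An ordered, variant-id-keyed collection of :class:`GwasRecord`.

    ``trait_type`` is either ``"exposure"`` or ``"outcome"``; it only labels
    which side of the MR model the dataset plays.
    """

    def __init__(
        self,
        trait_name: str,
        trait_type: str,
        records: Iterable[GwasRecord],
        n_rejected: int = 0,
    ) -> None:
        if trait_type not in ("exposure", "outcome"):
            raise ValueError(f"trait_type must be exposure|outcome, got {trait_type!r}")
        self.trait_name = trait_name
        self.trait_type = trait_type
        self._records: dict[str, GwasRecord] = {}
        for rec in records:
            if rec.variant_id in self._records:
                raise ValidationError(f"duplicate variant_id {rec.variant_id!r}")
            self._records[rec.variant_id] = rec
        #: number of input rows rejected during parsing (0 for in-memory builds)
        self.n_rejected = n_rejected

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[GwasRecord]:
        return iter(self._records.values())

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._records

    def __getitem__(self, variant_id: str) -> GwasRecord:
        return self._records[variant_id]

    def get(self, variant_id: str) -> GwasRecord | None:
        return self._records.get(variant_id)

    @property
    def variant_ids(self) -> list[str]:
        return list(self._records)

    def subset(self, variant_ids: Sequence[str]) -> "SummaryDataset":
        """A new dataset restricted to ``variant_ids`` (in the given order)."""
        return SummaryDataset(
            self.trait_name,
            self.trait_type,
            [self._records[v] for v in variant_ids],
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "variant_id": r.variant_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in self
        ]
        return pd.DataFrame(rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SummaryDataset):
            return NotImplemented
        return (
            self.trait_name == other.trait_name
            and self.trait_type == other.trait_type
            and list(self._records) == list(other._records)
            and all(
                _records_close(a, b)
                for a, b in zip(self._records.values(), other._records.values())
            )
        )


def _records_close(a: GwasRecord, b: GwasRecord, rtol: float = 1e-12) -> bool:
    def close(x: float | None, y: float | None) -> bool:
        if x is None and y is None:
            return True
        if x is None or y is None:
            return False
        return bool(np.isclose(x, y, rtol=rtol, atol=0.0))

    return (
        a.variant_id == b.variant_id
        and a.chrom == b.chrom
        and a.pos == b.pos
        and a.effect_allele == b.effect_allele
        and a.other_allele == b.other_allele
        and close(a.eaf, b.eaf)
        and close(a.beta, b.beta)
        and close(a.se, b.se)
        and close(a.pval, b.pval)
        and close(a.n, b.n)
    )


@dataclass
class ConfounderAnnotation:
    """A single variant → trait association from a confounder lookup."""

    variant_id: str
    trait: str
    category: str
    pval: float

    def validate(self) -> None:
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.variant_id}: annotation pval not in (0, 1]")


class LdReference:
    """Pairwise squared-correlation (r²) lookup over a set of variants.

    The matrix is symmetric with unit diagonal and entries in [0, 1].
    Variants absent from the reference have unknown LD; callers decide how to
    treat them (the instrument-selection stage treats them as independent).
    """

    def __init__(
        self,
        variant_ids: Sequence[str],
        r2: np.ndarray,
        pos: Mapping[str, int] | None = None,
    ) -> None:
        r2 = np.asarray(r2, dtype=float)
        n = len(variant_ids)
        if r2.shape != (n, n):
            raise ValidationError(f"r2 matrix shape {r2.shape} != ({n}, {n})")
        if len(set(variant_ids)) != n:
            raise ValidationError("duplicate variant ids in LD reference")
        asym = np.abs(r2 - r2.T).max(initial=0.0)
        if asym > 1e-8:
            raise ValidationError(f"r2 matrix asymmetric (max |r2-r2'| = {asym:.3g})")
        r2 = (r2 + r2.T) / 2.0
        if n and (r2.min() < -1e-12 or r2.max() > 1 + 1e-12):
            raise ValidationError("r2 entries must lie in [0, 1]")
        r2 = np.clip(r2, 0.0, 1.0)
        np.fill_diagonal(r2, 1.0)
        self.variant_ids = list(variant_ids)
        self.r2 = r2
        self.pos = dict(pos) if pos is not None else None
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r2_between(self, a: str, b: str, default: float = 0.0) -> float:
        """r² between two variants; ``default`` when either is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return default
        return float(self.r2[ia, ib])


# ---------------------------------------------------------------------------
# Summary statistics I/O
# ---------------------------------------------------------------------------


def _parse_optional_float(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    return float(value)


def read_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    trait_name: str | None = None,
    trait_type: str = "exposure",
) -> SummaryDataset:
    """Read a tab-delimited GWAS summary-statistics file.

    Parameters
    ----------
    path : path-like
        Tab-separated file with a header row.
    column_map : mapping, optional
        Canonical field name → file column header.  Defaults to
        :data:`DEFAULT_COLUMN_MAP`; entries you supply override defaults.
    trait_name : str, optional
        Defaults to the file stem.
    trait_type : str
        ``"exposure"`` or ``"outcome"``.

    Rows that violate record invariants (se ≤ 0, p outside (0,1], bad
    alleles, ...) are rejected — never silently passed — and the count of
    rejections is reported on the returned dataset as ``n_rejected``.

    Raises
    ------
    SumstatsFormatError
        If a required column is missing.
    ValidationError
        If two rows share a variant_id.
    """
    path = Path(path)
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    df = pd.read_csv(
        path,
        sep="\t",
        na_values=["NA"],
        keep_default_na=False,
        dtype=str,
    )
    for fld in REQUIRED_FIELDS:
        if cmap[fld] not in df.columns:
            raise SumstatsFormatError(
                f"{path}: required column {cmap[fld]!r} (field {fld!r}) not found"
            )

    records: list[GwasRecord] = []
    seen: set[str] = set()
    n_rejected = 0
    for row in df.itertuples(index=False):
        rowd = dict(zip(df.columns, row))
        try:
            vid = str(rowd[cmap["variant_id"]])
            rec = GwasRecord(
                variant_id=vid,
                chrom=str(rowd[cmap["chrom"]]),
                pos=int(float(rowd[cmap["pos"]])),
                effect_allele=str(rowd[cmap["effect_allele"]]).upper(),
                other_allele=str(rowd[cmap["other_allele"]]).upper(),
                beta=float(rowd[cmap["beta"]]),
                se=float(rowd[cmap["se"]]),
                pval=float(rowd[cmap["pval"]]),
                eaf=_parse_optional_float(rowd.get(cmap["eaf"]))
                if cmap["eaf"] in df.columns
                else None,
                n=_parse_optional_float(rowd.get(cmap["n"]))
                if cmap["n"] in df.columns
                else None,
            )
            rec.validate()
        except ValidationError:
            n_rejected += 1
            continue
        except (TypeError, ValueError):
            n_rejected += 1
            continue
        if rec.variant_id in seen:
            raise ValidationError(
                f"{path}: duplicate variant_id {rec.variant_id!r}"
            )
        seen.add(rec.variant_id)
        records.append(rec)

    return SummaryDataset(
        trait_name=trait_name if trait_name is not None else path.stem,
        trait_type=trait_type,
        records=records,
        n_rejected=n_rejected,
    )


def write_sumstats(
    dataset: SummaryDataset,
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> None:
    """Write a dataset to a tab-delimited file round-trippable by
    :func:`read_sumstats` (floats at full precision, ``NA`` for missing)."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = dataset.to_frame()
    if df.empty:
        df = pd.DataFrame(columns=list(DEFAULT_COLUMN_MAP))
    df = df.rename(columns=cmap)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# LD reference I/O
# ---------------------------------------------------------------------------

_LONG_HEADERS = {("id1", "id2", "r2"), ("snp1", "snp2", "r2"), ("a", "b", "r2")}


def read_ld(path: str | Path) -> LdReference:
    """Read an LD reference from either supported layout.

    * **Square**: header row = label column + variant ids; each data row is a
      variant id followed by its r² against every variant.
    * **Long**: three columns (id1, id2, r2); pairs are symmetrized and
      absent pairs default to r² = 0.

    Asymmetric square inputs (beyond 1e-8) raise :class:`ValidationError`.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    header = tuple(c.strip().lower() for c in df.columns)
    if len(df.columns) == 3 and (header in _LONG_HEADERS or header[2] in ("r2", "r_2")):
        ids: list[str] = []
        seen: set[str] = set()
        for col in (df.columns[0], df.columns[1]):
            for v in df[col]:
                if v not in seen:
                    seen.add(v)
                    ids.append(v)
        index = {v: i for i, v in enumerate(ids)}
        r2 = np.zeros((len(ids), len(ids)))
        np.fill_diagonal(r2, 1.0)
        for a, b, val in df.itertuples(index=False):
            x = float(val)
            ia, ib = index[a], index[b]
            r2[ia, ib] = x
            r2[ib, ia] = x
        return LdReference(ids, r2)

    # square layout: first column holds row labels
    ids = [str(c) for c in df.columns[1:]]
    row_ids = [str(v) for v in df.iloc[:, 0]]
    if row_ids != ids:
        raise SumstatsFormatError(
            f"{path}: square LD matrix row labels do not match column labels"
        )
    r2 = df.iloc[:, 1:].astype(float).to_numpy()
    return LdReference(ids, r2)


def write_ld(ld: LdReference, path: str | Path, fmt: str = "square") -> None:
    """Write an LD reference (``fmt`` = ``"square"`` or ``"long"``)."""
    if fmt == "square":
        df = pd.DataFrame(ld.r2, columns=ld.variant_ids)
        df.insert(0, "SNP", ld.variant_ids)
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
    elif fmt == "long":
        rows = []
        n = len(ld.variant_ids)
        for i in range(n):
            for j in range(i + 1, n):
                if ld.r2[i, j] != 0.0:
                    rows.append(
                        (ld.variant_ids[i], ld.variant_ids[j], ld.r2[i, j])
                    )
        pd.DataFrame(rows, columns=["id1", "id2", "r2"]).to_csv(
            path, sep="\t", index=False, float_format="%.17g"
        )
    else:
        raise ValueError(f"unknown LD format {fmt!r}")


# ---------------------------------------------------------------------------
# Confounder annotations
# ---------------------------------------------------------------------------

ANNOTATION_COLUMNS = {"SNP": "variant_id", "TRAIT": "trait", "CATEGORY": "category", "P": "pval"}


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Read a confounder-annotation table (columns SNP, TRAIT, CATEGORY, P).

    Returns a DataFrame with canonical columns
    ``variant_id, trait, category, pval``; a stand-in for per-variant
    phenome-wide lookups (e.g. PhenoScanner exports).
    """
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    missing = set(ANNOTATION_COLUMNS) - set(df.columns)
    if missing:
        raise SumstatsFormatError(f"{path}: missing annotation columns {sorted(missing)}")
    df = df.rename(columns=ANNOTATION_COLUMNS)[list(ANNOTATION_COLUMNS.values())]
    df["pval"] = df["pval"].astype(float)
    bad = ~((df["pval"] > 0) & (df["pval"] <= 1))
    if bad.any():
        raise ValidationError(f"{path}: {int(bad.sum())} annotation p-values outside (0, 1]")
    return df


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    out = df.rename(columns={v: k for k, v in ANNOTATION_COLUMNS.items()})
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------

#: Flat schema for one analysis × method row (estimate plus diagnostics).
RESULT_COLUMNS = [
    "exposure",
    "outcome",
    "n_snps",
    "method",
    "beta",
    "ci_95",
    "se",
    "pval",
    "q_stat",
    "q_pval",
    "egger_intercept",
    "egger_intercept_pval",
    "presso_global_pval",
]

_CI_RE = re.compile(r"\(\s*([^,]+),\s*([^)]+)\)")


def format_ci(low: float, high: float) -> str:
    if np.isnan(low) or np.isnan(high):
        return "NA"
    return f"({low:.10g}, {high:.10g})"


def parse_ci(text: str) -> tuple[float, float]:
    if text == "NA":
        return (float("nan"), float("nan"))
    m = _CI_RE.match(text)
    if not m:
        raise SumstatsFormatError(f"malformed CI cell {text!r}")
    return float(m.group(1)), float(m.group(2))


def write_results(grid_results: Sequence, path: str | Path) -> None:
    """Write grid results as a flat TSV, one row per exposure × outcome ×
    method, with the shared diagnostics repeated on each row of a pair.

    ``grid_results`` is a sequence of :class:`mrkit.pipeline.GridResult`.
    Raises ``ValueError`` on an empty input.
    """
    if not grid_results:
        raise ValueError("no results to write")
    rows = []
    for gr in grid_results:
        rows.extend(gr.result_rows())
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read back a results TSV; CI cells are expanded to ci_low/ci_high."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    ci = df["ci_95"].astype(str).map(parse_ci)
    df["ci_low"] = [c[0] for c in ci]
    df["ci_high"] = [c[1] for c in ci]
    return df
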