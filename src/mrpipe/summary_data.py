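"""Data model, validation, and TSV I/O for GWAS summary statistics and LD tables.

The canonical GWAS file dialect is tab-separated with a header row and columns
``snp, effect_allele, other_allele, eaf, beta, se, pval, n, n_case, n_control``
(``eaf``, ``n_case``, ``n_control`` optional).  ``read_gwas`` accepts a
``column_map`` that translates arbitrary source headers onto these names, since
public summary-statistics releases rarely agree on a schema.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, ValidationError

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: canonical column order for GWAS TSV files
GWAS_COLUMNS = (
    "snp", "effect_allele", "other_allele", "eaf",
    "beta", "se", "pval", "n", "n_case", "n_control",
)

MANDATORY_COLUMNS = ("snp", "effect_allele", "other_allele", "beta", "se", "pval", "n")

#: floor applied to p-values printed as 0 by upstream tools
PVAL_FLOOR = 1e-300

RESULT_COLUMNS = (
    "exposure", "outcome", "method", "n_snp", "estimate", "se",
    "or", "ci_low", "ci_high", "pval", "adjusted_for",
)


@dataclass(frozen=True)
class AssociationRecord:
    """One SNP-trait association row.

    ``beta`` is on the trait's native scale (log-OR for binary traits);
    ``eaf`` is the effect-allele frequency, ``nan`` when not reported.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    n: int
    eaf: float = math.nan
    n_case: Optional[int] = None
    n_control: Optional[int] = None

    def validate(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(f"{self.snp_id}: invalid effect allele {self.effect_allele!r}")
        if self.other_allele not in VALID_ALLELES:
            raise ValidationError(f"{self.snp_id}: invalid other allele {self.other_allele!r}")
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not math.isfinite(self.beta):
            raise ValidationError(f"{self.snp_id}: non-finite beta")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: pval must lie in (0, 1], got {self.pval}")
        if not (math.isnan(self.eaf) or 0.0 <= self.eaf <= 1.0):
            raise ValidationError(f"{self.snp_id}: eaf outside [0, 1]: {self.eaf}")
        if self.n <= 0:
            raise ValidationError(f"{self.snp_id}: non-positive sample size {self.n}")
        for name, v in (("n_case", self.n_case), ("n_control", self.n_control)):
            if v is not None and v <= 0:
                raise ValidationError(f"{self.snp_id}: non-positive {name} {v}")

    @property
    def is_palindromic(self) -> bool:
        pair = {self.effect_allele, self.other_allele}
        return pair == {"A", "T"} or pair == {"G", "C"}


@dataclass
class GwasTable:
    """A validated trait-level table of :class:`AssociationRecord`, keyed by snp_id."""

    trait_name: str
    records: dict[str, AssociationRecord] = field(default_factory=dict)
    trait_units: str = ""
    is_binary: bool = False
    sex: str = "both"
    n_dropped: int = 0

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self.records

    def __getitem__(self, snp_id: str) -> AssociationRecord:
        return self.records[snp_id]

    def __iter__(self):
        return iter(self.records.values())

    @property
    def snp_ids(self) -> list[str]:
        return list(self.records)

    def subset(self, snp_ids: Iterable[str]) -> "GwasTable":
        keep = {s: self.records[s] for s in snp_ids if s in self.records}
        return replace(self, records=keep, n_dropped=0)

    def add(self, rec: AssociationRecord) -> None:
        rec.validate()
        if rec.snp_id in self.records:
            raise ValidationError(f"duplicate snp_id {rec.snp_id} in table {self.trait_name}")
        self.records[rec.snp_id] = rec

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "snp": r.snp_id, "effect_allele": r.effect_allele,
                "other_allele": r.other_allele, "eaf": r.eaf, "beta": r.beta,
                "se": r.se, "pval": r.pval, "n": r.n,
                "n_case": r.n_case if r.n_case is not None else np.nan,
                "n_control": r.n_control if r.n_control is not None else np.nan,
            }
            for r in self.records.values()
        ]
        return pd.DataFrame(rows, columns=list(GWAS_COLUMNS))


@dataclass
class LDMatrix:
    """Sparse symmetric pairwise r-squared lookup; absent pairs default to 0."""

    entries: dict[frozenset, float] = field(default_factory=dict)

    def get(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self.entries.get(frozenset((a, b)), 0.0)

    def set(self, a: str, b: str, r2: float) -> None:
        if not (0.0 <= r2 <= 1.0):
            raise ValidationError(f"r2 outside [0, 1] for pair ({a}, {b}): {r2}")
        if a == b:
            if abs(r2 - 1.0) > 1e-9:
                raise ValidationError(f"r2({a},{a}) must be 1, got {r2}")
            return
        key = frozenset((a, b))
        old = self.entries.get(key)
        if old is not None and abs(old - r2) > 1e-9:
            raise ValidationError(f"conflicting duplicate r2 for pair ({a}, {b}): {old} vs {r2}")
        self.entries[key] = r2

    def __len__(self) -> int:
        return len(self.entries)


def _record_from_row(row: Mapping) -> AssociationRecord:
    pval = float(row["pval"])
    if pval == 0.0:
        logger.warning("p-value of 0 for %s floored to %.0e", row["snp"], PVAL_FLOOR)
        pval = PVAL_FLOOR

    def _opt_int(key):
        v = row.get(key)
        if v is None or (isinstance(v, float) and math.isnan(v)):
            return None
        return int(v)

    eaf = row.get("eaf")
    eaf = math.nan if eaf is None else float(eaf)
    rec = AssociationRecord(
        snp_id=str(row["snp"]),
        effect_allele=str(row["effect_allele"]).upper(),
        other_allele=str(row["other_allele"]).upper(),
        eaf=eaf,
        beta=float(row["beta"]),
        se=float(row["se"]),
        pval=pval,
        n=int(row["n"]),
        n_case=_opt_int("n_case"),
        n_control=_opt_int("n_control"),
    )
    rec.validate()
    return rec


def table_from_dataframe(
    df: pd.DataFrame,
    trait_name: str,
    trait_units: str = "",
    is_binary: bool = False,
    sex: str = "both",
) -> GwasTable:
    """Build a validated :class:`GwasTable` from a canonical-column dataframe.

    Rows violating any record invariant are dropped and counted in
    ``table.n_dropped``; duplicated snp_ids raise.
    """
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    table = GwasTable(trait_name=trait_name, trait_units=trait_units,
                      is_binary=is_binary, sex=sex)
    dropped = 0
    for row in df.to_dict("records"):
        try:
            table.add(_record_from_row(row))
        except (ValidationError, ValueError, TypeError) as exc:
            if isinstance(exc, ValidationError) and "duplicate snp_id" in str(exc):
                raise
            dropped += 1
            logger.debug("dropping row %r: %s", row.get("snp"), exc)
    table.n_dropped = dropped
    if dropped:
        logger.info("%s: dropped %d invalid row(s)", trait_name, dropped)
    if len(table) == 0:
        raise EmptyInputError(f"no valid records for trait {trait_name!r}")
    return table


def read_gwas(
    path,
    column_map: Optional[Mapping[str, str]] = None,
    trait_name: str = "",
    trait_units: str = "",
    is_binary: bool = False,
    sex: str = "both",
) -> GwasTable:
    """Read a GWAS summary-statistics TSV into a validated table.

    Parameters
    ----------
    path : path-like
        Tab-separated file with a header row.
    column_map : mapping, optional
        ``{source_header: canonical_name}`` renames applied before validation.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if column_map:
        df = df.rename(columns=dict(column_map))
    name = trait_name or str(path)
    return table_from_dataframe(df, trait_name=name, trait_units=trait_units,
                                is_binary=is_binary, sex=sex)


def write_gwas(table: GwasTable, path) -> None:
    """Write a table in the canonical GWAS TSV dialect (round-trips with read_gwas)."""
    df = table.to_dataframe()
    df.to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")


def read_ld(path) -> LDMatrix:
    """Read a long-format LD TSV (columns snp_a, snp_b, r2) into an :class:`LDMatrix`."""
    df = pd.read_csv(path, sep="\t")
    for col in ("snp_a", "snp_b", "r2"):
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    ld = LDMatrix()
    for a, b, r2 in zip(df["snp_a"], df["snp_b"], df["r2"]):
        ld.set(str(a), str(b), float(r2))
    return ld


def write_ld(ld: LDMatrix, path) -> None:
    rows = sorted((tuple(sorted(k)), v) for k, v in ld.entries.items())
    df = pd.DataFrame(
        [{"snp_a": a, "snp_b": b, "r2": v} for (a, b), v in rows],
        columns=["snp_a", "snp_b", "r2"],
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def results_to_dataframe(results: Sequence) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "exposure": getattr(r, "exposure", None) or "NA",
            "outcome": getattr(r, "outcome", None) or "NA",
            "method": r.method,
            "n_snp": r.n_snp,
            "estimate": r.estimate,
            "se": r.se,
            "or": r.odds_ratio if r.odds_ratio is not None else np.nan,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "pval": r.pval,
            "adjusted_for": getattr(r, "adjusted_for", None) or "none",
        })
    return pd.DataFrame(rows, columns=list(RESULT_COLUMNS))


def write_results(results: Sequence, path) -> None:
    """Serialize MR results as a TSV mirroring the published result-table layout."""
    if not results:
        raise EmptyInputError("no results to write")
    results_to_dataframe(results).to_csv(path, sep="\t", index=False,
                                         float_format="%.17g", na_rep="NA")


def read_results(path) -> pd.DataFrame:
    """Read back a results TSV written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    for col in RESULT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"missing mandatory column {col!r}")
    return df
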