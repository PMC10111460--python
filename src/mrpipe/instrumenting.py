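"""Instrument selection, allele harmonization, greedy LD clumping, and
instrument-strength statistics.

The pipeline order is select -> harmonize -> clump: instruments are chosen at
genome-wide significance in the exposure GWAS, aligned to the outcome GWAS's
allele orientation (with frequency-based strand inference for palindromic
SNPs), and then pruned to pairwise LD r-squared below threshold, keeping the
most significant SNP of each correlated group.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, EmptyInstrumentError, HarmonizationError
from .summary_data import AssociationRecord, GwasTable, LDMatrix

logger = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# harmonization action codes
UNCHANGED = "unchanged"
SIGN_FLIPPED = "sign_flipped"
STRAND_FLIPPED = "strand_flipped"
PALINDROME_INFERRED = "palindrome_inferred"
DROPPED_PALINDROME = "dropped_palindrome"
DROPPED_INCOMPATIBLE = "dropped_incompatible"
DROPPED_MISSING_OUTCOME = "dropped_missing_outcome"

RETAINED_ACTIONS = frozenset({UNCHANGED, SIGN_FLIPPED, STRAND_FLIPPED, PALINDROME_INFERRED})

DEFAULT_P_THRESHOLD = 5e-8
DEFAULT_R2_THRESHOLD = 0.001
DEFAULT_PALINDROME_WINDOW = 0.08


@dataclass
class HarmonizedSet:
    """Per-SNP exposure and outcome effects aligned to a common effect allele.

    Alleles are stored in the exposure orientation; ``actions`` records the
    harmonization decision for every shared SNP, including dropped ones.
    Arrays are parallel and cover only retained SNPs.
    """

    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    eaf_exp: np.ndarray
    eaf_out: np.ndarray
    pval_exp: np.ndarray
    effect_allele: list[str]
    other_allele: list[str]
    actions: dict[str, str]
    exposure_name: str = ""
    outcome_name: str = ""
    outcome_binary: bool = False
    n_exp: int = 0
    n_out: int = 0

    def __post_init__(self):
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise HarmonizationError("duplicate snp_id in harmonized set")

    def __len__(self) -> int:
        return len(self.snp_ids)

    @property
    def action_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for a in self.actions.values():
            counts[a] = counts.get(a, 0) + 1
        return counts

    def restrict(self, snp_ids) -> "HarmonizedSet":
        keep = set(snp_ids)
        idx = [i for i, s in enumerate(self.snp_ids) if s in keep]
        return HarmonizedSet(
            snp_ids=[self.snp_ids[i] for i in idx],
            beta_exp=self.beta_exp[idx], se_exp=self.se_exp[idx],
            beta_out=self.beta_out[idx], se_out=self.se_out[idx],
            eaf_exp=self.eaf_exp[idx], eaf_out=self.eaf_out[idx],
            pval_exp=self.pval_exp[idx],
            effect_allele=[self.effect_allele[i] for i in idx],
            other_allele=[self.other_allele[i] for i in idx],
            actions={s: a for s, a in self.actions.items() if s in keep or a not in RETAINED_ACTIONS},
            exposure_name=self.exposure_name, outcome_name=self.outcome_name,
            outcome_binary=self.outcome_binary, n_exp=self.n_exp, n_out=self.n_out,
        )

    def exposure_table(self) -> GwasTable:
        """Reconstitute the exposure side as a GwasTable (exposure orientation)."""
        t = GwasTable(trait_name=self.exposure_name)
        for i, s in enumerate(self.snp_ids):
            t.add(AssociationRecord(
                snp_id=s, effect_allele=self.effect_allele[i],
                other_allele=self.other_allele[i], eaf=float(self.eaf_exp[i]),
                beta=float(self.beta_exp[i]), se=float(self.se_exp[i]),
                pval=float(self.pval_exp[i]), n=self.n_exp or 1,
            ))
        return t

    def outcome_table(self) -> GwasTable:
        """Reconstitute the harmonized outcome side as a GwasTable."""
        from scipy.stats import norm

        t = GwasTable(trait_name=self.outcome_name, is_binary=self.outcome_binary)
        for i, s in enumerate(self.snp_ids):
            z = self.beta_out[i] / self.se_out[i]
            t.add(AssociationRecord(
                snp_id=s, effect_allele=self.effect_allele[i],
                other_allele=self.other_allele[i], eaf=float(self.eaf_out[i]),
                beta=float(self.beta_out[i]), se=float(self.se_out[i]),
                pval=max(float(2.0 * norm.sf(abs(z))), 1e-300), n=self.n_out or 1,
            ))
        return t


def select_instruments(g: GwasTable, p_threshold: float = DEFAULT_P_THRESHOLD) -> GwasTable:
    """Subset to SNPs with ``pval < p_threshold`` (strict inequality)."""
    keep = [s for s, r in g.records.items() if r.pval < p_threshold]
    if not keep:
        raise EmptyInstrumentError(
            f"no instrument for trait {g.trait_name!r} at p < {p_threshold:g}")
    return g.subset(keep)


def _is_palindromic_pair(a1: str, a2: str) -> bool:
    return {a1, a2} in ({"A", "T"}, {"G", "C"})


def _eaf_informative(eaf: float, window: float) -> bool:
    # strictly outside [0.5 - w, 0.5 + w]; missing eaf is uninformative
    return not math.isnan(eaf) and (eaf < 0.5 - window or eaf > 0.5 + window)


def harmonize(
    exposure: GwasTable,
    outcome: GwasTable,
    palindrome_window: float = DEFAULT_PALINDROME_WINDOW,
) -> HarmonizedSet:
    """Align outcome effects to the exposure's effect-allele orientation.

    For each SNP shared between the tables: identical allele pairs are kept
    (with a sign flip when the orientation is swapped); complementary-strand
    pairs are complemented first; palindromic SNPs are oriented from allele
    frequencies when both frequencies are informative (strictly outside
    ``0.5 +/- palindrome_window``) and dropped otherwise; irreconcilable
    pairs are dropped.  SNPs absent from the outcome are dropped and counted.
    """
    snp_ids: list[str] = []
    bx, sx, by, sy, fx, fy, px = [], [], [], [], [], [], []
    ea_list, oa_list = [], []
    actions: dict[str, str] = {}

    for snp, e in exposure.records.items():
        o = outcome.records.get(snp)
        if o is None:
            actions[snp] = DROPPED_MISSING_OUTCOME
            continue

        ea, oa = e.effect_allele, e.other_allele
        o_ea, o_oa = o.effect_allele, o.other_allele
        beta_out, eaf_out = o.beta, o.eaf

        if _is_palindromic_pair(ea, oa):
            if {o_ea, o_oa} != {ea, oa}:
                actions[snp] = DROPPED_INCOMPATIBLE
                continue
            if not (_eaf_informative(e.eaf, palindrome_window)
                    and _eaf_informative(eaf_out, palindrome_window)):
                actions[snp] = DROPPED_PALINDROME
                continue
            # orientation by minor/major agreement: the strand is unknowable,
            # so align on which side of 0.5 the frequencies fall
            exp_minor = e.eaf < 0.5
            out_minor = eaf_out < 0.5
            if exp_minor != out_minor:
                beta_out = -beta_out
                eaf_out = 1.0 - eaf_out
            action = PALINDROME_INFERRED
        else:
            action = UNCHANGED
            if {o_ea, o_oa} == {COMPLEMENT[ea], COMPLEMENT[oa]} and {o_ea, o_oa} != {ea, oa}:
                o_ea, o_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
                action = STRAND_FLIPPED
            if (o_ea, o_oa) == (ea, oa):
                pass
            elif (o_ea, o_oa) == (oa, ea):
                beta_out = -beta_out
                if not math.isnan(eaf_out):
                    eaf_out = 1.0 - eaf_out
                if action == UNCHANGED:
                    action = SIGN_FLIPPED
            else:
                actions[snp] = DROPPED_INCOMPATIBLE
                continue

        snp_ids.append(snp)
        bx.append(e.beta); sx.append(e.se); by.append(beta_out); sy.append(o.se)
        fx.append(e.eaf); fy.append(eaf_out); px.append(e.pval)
        ea_list.append(ea); oa_list.append(oa)
        actions[snp] = action

    if not snp_ids:
        counts: dict[str, int] = {}
        for a in actions.values():
            counts[a] = counts.get(a, 0) + 1
        raise HarmonizationError(
            f"harmonization of {exposure.trait_name!r} vs {outcome.trait_name!r} "
            f"retained zero SNPs (actions: {counts})", action_counts=counts)

    n_exp = min(r.n for r in exposure.records.values())
    n_out = min(r.n for r in outcome.records.values())
    return HarmonizedSet(
        snp_ids=snp_ids,
        beta_exp=np.asarray(bx, float), se_exp=np.asarray(sx, float),
        beta_out=np.asarray(by, float), se_out=np.asarray(sy, float),
        eaf_exp=np.asarray(fx, float), eaf_out=np.asarray(fy, float),
        pval_exp=np.asarray(px, float),
        effect_allele=ea_list, other_allele=oa_list, actions=actions,
        exposure_name=exposure.trait_name, outcome_name=outcome.trait_name,
        outcome_binary=outcome.is_binary, n_exp=n_exp, n_out=n_out,
    )


def clump(g: GwasTable, ld: LDMatrix, r2_threshold: float = DEFAULT_R2_THRESHOLD) -> GwasTable:
    """Greedy p-value-ordered LD pruning.

    SNPs are visited in ascending p-value order (ties broken lexicographically
    by snp_id); each retained SNP eliminates all not-yet-retained SNPs with
    r-squared >= ``r2_threshold`` against it.  Every retained pair therefore
    satisfies r-squared < threshold.
    """
    if len(g) == 0:
        raise EmptyInstrumentError(f"cannot clump empty table {g.trait_name!r}")
    order = sorted(g.records.values(), key=lambda r: (r.pval, r.snp_id))
    retained: list[str] = []
    removed: set[str] = set()
    for rec in order:
        if rec.snp_id in removed:
            continue
        retained.append(rec.snp_id)
        for other in order:
            if other.snp_id in removed or other.snp_id == rec.snp_id:
                continue
            if ld.get(rec.snp_id, other.snp_id) >= r2_threshold:
                removed.add(other.snp_id)
    return g.subset(retained)


def snp_strength(beta: float, se: float, n: int) -> tuple[float, float]:
    """Per-SNP instrument strength: F = (beta/se)^2, r2 = F / (n - 2 + F)."""
    if se <= 0:
        raise DomainError(f"se must be > 0, got {se}")
    if n <= 2:
        raise DomainError(f"sample size must exceed 2, got {n}")
    f = (beta / se) ** 2
    return f, f / (n - 2 + f)


@dataclass
class StrengthReport:
    """Instrument-strength summary across a set of instruments."""

    per_snp_f: dict[str, float]
    per_snp_r2: dict[str, float]
    total_r2: float
    overall_f: float
    n: int
    k: int


def overall_strength(instruments: GwasTable) -> StrengthReport:
    """Aggregate strength: R2 = sum of per-SNP r2; F = ((n-k-1)/k) * R2/(1-R2).

    When instruments report different sample sizes the minimum is used and a
    warning is logged.
    """
    if len(instruments) == 0:
        raise EmptyInstrumentError(f"no instruments in table {instruments.trait_name!r}")
    ns = {r.n for r in instruments.records.values()}
    n = min(ns)
    if len(ns) > 1:
        logger.warning("%s: heterogeneous sample sizes %s; using minimum %d",
                       instruments.trait_name, sorted(ns), n)
    per_f: dict[str, float] = {}
    per_r2: dict[str, float] = {}
    for snp, r in instruments.records.items():
        f, r2 = snp_strength(r.beta, r.se, n)
        per_f[snp] = f
        per_r2[snp] = r2
    total_r2 = float(sum(per_r2.values()))
    if total_r2 >= 1.0:
        raise DomainError(f"total R2 >= 1 ({total_r2}); degenerate instrument set")
    k = len(instruments)
    overall_f = ((n - k - 1) / k) * (total_r2 / (1.0 - total_r2))
    return StrengthReport(per_snp_f=per_f, per_snp_r2=per_r2, total_r2=total_r2,
                          overall_f=overall_f, n=n, k=k)
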