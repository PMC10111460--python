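"""Multivariable MR, conditional instrument strength, and step-wise mediation.

Multivariable IVW regresses SNP-outcome effects jointly on the SNP-effect
matrix of several exposures (no intercept, inverse-variance weights on the
outcome), estimating each exposure's direct effect conditional on the others.
The instrument set is the union of per-exposure genome-wide-significant SNPs,
harmonized to a common orientation and clumped by the best p-value across
exposures.

Mediation follows a step-wise screen: a nominally significant total effect
(univariable IVW exposure -> outcome) and a nominally significant
exposure -> mediator effect are both required before the multivariable direct
effect is computed.  The indirect effect and proportion mediated are
deliberately not computed; attenuation of the direct relative to the total
effect is reported qualitatively instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

from .errors import (
    EmptyInputError,
    MRError,
    SingularDesignError,
    UnderdeterminedError,
)
from .estimators import Z95, MRResult, ivw
from .instrumenting import (
    DEFAULT_P_THRESHOLD,
    DEFAULT_PALINDROME_WINDOW,
    DEFAULT_R2_THRESHOLD,
    HarmonizedSet,
    clump,
    harmonize,
    select_instruments,
)
from .summary_data import AssociationRecord, GwasTable, LDMatrix

logger = logging.getLogger(__name__)

ATTENUATED_TO_NULL = "attenuated_to_null"
PARTIALLY_ATTENUATED = "partially_attenuated"
UNCHANGED_EFFECT = "unchanged"


@dataclass
class MVMRResult:
    """Joint direct effects of several exposures on one outcome."""

    exposures: list[str]
    outcome: str
    estimates: np.ndarray
    ses: np.ndarray
    ci_lows: np.ndarray
    ci_highs: np.ndarray
    pvals: np.ndarray
    n_snp: int
    conditional_f: dict[str, float]
    q_stat: float
    phi: float
    snp_ids: list[str] = field(default_factory=list)

    def effect(self, exposure: str) -> MRResult:
        """The direct effect of one exposure as an :class:`MRResult`."""
        i = self.exposures.index(exposure)
        others = [e for e in self.exposures if e != exposure]
        return MRResult(
            method="mvmr_ivw", n_snp=self.n_snp,
            estimate=float(self.estimates[i]), se=float(self.ses[i]),
            ci_low=float(self.ci_lows[i]), ci_high=float(self.ci_highs[i]),
            pval=float(self.pvals[i]), exposure=exposure, outcome=self.outcome,
            adjusted_for=",".join(others) if others else "",
        )


@dataclass
class MediationReport:
    """Step-wise mediation outcome for one exposure/mediator/outcome pathway."""

    exposure: str
    outcome: str
    mediator: str
    total: MRResult
    exposure_to_mediator: MRResult
    direct: MRResult
    attenuation: str


def univariable_pipeline(
    exposure: GwasTable,
    outcome: GwasTable,
    ld: LDMatrix,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    palindrome_window: float = DEFAULT_PALINDROME_WINDOW,
) -> tuple[MRResult, HarmonizedSet]:
    """select -> harmonize -> clump -> IVW (Wald ratio when 1 SNP remains)."""
    instruments = select_instruments(exposure, p_threshold)
    h = harmonize(instruments, outcome, palindrome_window)
    clumped = clump(h.exposure_table(), ld, r2_threshold)
    h = h.restrict(clumped.snp_ids)
    return ivw(h), h


def _align_union(
    exposure_tables: Sequence[GwasTable],
    outcome: GwasTable,
    ld: LDMatrix,
    p_threshold: float,
    r2_threshold: float,
    palindrome_window: float,
):
    """Union-instrument construction for MVMR.

    Returns (snp_ids, X, S_exp, y, se_out) with every table aligned to the
    orientation of the first exposure table carrying each SNP.
    """
    union: list[str] = []
    seen: set[str] = set()
    for t in exposure_tables:
        for s, r in t.records.items():
            if r.pval < p_threshold and s not in seen:
                seen.add(s)
                union.append(s)
    if not union:
        raise EmptyInputError("no genome-wide-significant SNP in any exposure")

    # keep SNPs present in every exposure table and the outcome
    shared = [s for s in union
              if all(s in t for t in exposure_tables) and s in outcome]
    if not shared:
        raise EmptyInputError("instrument union empty after cross-table intersection")

    # reference orientation: the first exposure table
    ref = exposure_tables[0].subset(shared)
    aligned_sets: list[HarmonizedSet] = []
    for t in list(exposure_tables[1:]) + [outcome]:
        aligned_sets.append(harmonize(ref, t.subset(shared), palindrome_window))
    kept = set(shared)
    for hs in aligned_sets:
        kept &= set(hs.snp_ids)
    if not kept:
        raise EmptyInputError("no SNP survived harmonization across all tables")

    # clump ranking by the best p-value across contributing exposures
    rank = GwasTable(trait_name="union")
    for s in kept:
        best = min(t[s].pval for t in exposure_tables)
        r = ref[s]
        rank.add(AssociationRecord(
            snp_id=s, effect_allele=r.effect_allele, other_allele=r.other_allele,
            eaf=r.eaf, beta=r.beta, se=r.se, pval=best, n=r.n))
    snp_ids = sorted(clump(rank, ld, r2_threshold).snp_ids)

    k = len(exposure_tables)
    j = len(snp_ids)
    x = np.empty((j, k))
    s_exp = np.empty((j, k))
    x[:, 0] = [ref[s].beta for s in snp_ids]
    s_exp[:, 0] = [ref[s].se for s in snp_ids]
    for col, hs in enumerate(aligned_sets[:-1], start=1):
        pos = {s: i for i, s in enumerate(hs.snp_ids)}
        x[:, col] = [hs.beta_out[pos[s]] for s in snp_ids]
        s_exp[:, col] = [hs.se_out[pos[s]] for s in snp_ids]
    h_out = aligned_sets[-1]
    pos = {s: i for i, s in enumerate(h_out.snp_ids)}
    y = np.array([h_out.beta_out[pos[s]] for s in snp_ids])
    se_out = np.array([h_out.se_out[pos[s]] for s in snp_ids])
    return snp_ids, x, s_exp, y, se_out


def _conditional_f_from_matrices(x: np.ndarray, s_exp: np.ndarray) -> np.ndarray:
    """Conditional F per exposure: weighted residual heterogeneity of each
    exposure's SNP effects after projecting out the co-exposures' effects,
    divided by (J - K + 1).  Cross-trait estimation covariance is taken as 0.
    """
    j, k = x.shape
    fs = np.empty(k)
    for t in range(k):
        y = x[:, t]
        w = 1.0 / s_exp[:, t] ** 2
        others = np.delete(x, t, axis=1)
        if others.shape[1] == 0 or not np.any(others):
            resid = y
        else:
            sw = np.sqrt(w)
            coef, *_ = np.linalg.lstsq(others * sw[:, None], y * sw, rcond=None)
            resid = y - others @ coef
        qx = float(np.sum(w * resid**2))
        fs[t] = qx / (j - k + 1)
    return fs


def mvmr_ivw(
    exposure_tables: Sequence[GwasTable],
    outcome: GwasTable,
    ld: LDMatrix,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    palindrome_window: float = DEFAULT_PALINDROME_WINDOW,
) -> MVMRResult:
    """Multivariable IVW: weighted multiple regression of SNP-outcome effects
    on the exposure-effect matrix, no intercept, weights 1/se_out^2.

    Standard errors carry the multiplicative random-effects inflation
    ``sqrt(max(1, Q / (J - K)))``.  With a single exposure table this reduces
    exactly to univariable IVW.
    """
    if not exposure_tables:
        raise EmptyInputError("at least one exposure table required")
    snp_ids, x, s_exp, y, se_out = _align_union(
        exposure_tables, outcome, ld, p_threshold, r2_threshold, palindrome_window)
    j, k = x.shape
    if j <= k:
        raise UnderdeterminedError(f"{j} SNPs cannot identify {k} direct effects")
    if np.linalg.matrix_rank(x) < k:
        raise SingularDesignError("rank-deficient exposure-effect matrix")
    w = 1.0 / se_out**2
    xtw = x.T * w
    xtwx = xtw @ x
    if np.linalg.cond(xtwx) > 1e12:
        raise SingularDesignError("near-singular weighted design")
    coef = np.linalg.solve(xtwx, xtw @ y)
    resid = y - x @ coef
    q = float(np.sum(w * resid**2))
    phi = q / (j - k)
    cov = np.linalg.inv(xtwx) * max(1.0, phi)
    ses = np.sqrt(np.diag(cov))
    z = coef / ses
    pvals = np.minimum(1.0, np.maximum(2.0 * norm.sf(np.abs(z)), 1e-300))
    fs = _conditional_f_from_matrices(x, s_exp)
    names = [t.trait_name for t in exposure_tables]
    return MVMRResult(
        exposures=names, outcome=outcome.trait_name,
        estimates=coef, ses=ses,
        ci_lows=coef - Z95 * ses, ci_highs=coef + Z95 * ses, pvals=pvals,
        n_snp=j, conditional_f=dict(zip(names, fs)),
        q_stat=q, phi=phi, snp_ids=snp_ids,
    )


def conditional_f(
    exposure_tables: Sequence[GwasTable],
    snp_ids: Optional[Sequence[str]] = None,
    palindrome_window: float = DEFAULT_PALINDROME_WINDOW,
) -> dict[str, float]:
    """Conditional F-statistics on a shared instrument set.

    ``snp_ids`` restricts the set; by default the intersection of all tables
    is used.  Tables are aligned to the first table's orientation.
    """
    if len(exposure_tables) < 2:
        raise EmptyInputError("conditional F needs at least two exposures")
    shared = set(exposure_tables[0].snp_ids)
    for t in exposure_tables[1:]:
        shared &= set(t.snp_ids)
    if snp_ids is not None:
        shared &= set(snp_ids)
    ids = sorted(shared)
    if not ids:
        raise EmptyInputError("empty shared instrument set")
    ref = exposure_tables[0].subset(ids)
    k = len(exposure_tables)
    x = np.empty((len(ids), k))
    s_exp = np.empty((len(ids), k))
    x[:, 0] = [ref[s].beta for s in ids]
    s_exp[:, 0] = [ref[s].se for s in ids]
    for col, t in enumerate(exposure_tables[1:], start=1):
        hs = harmonize(ref, t.subset(ids), palindrome_window)
        pos = {s: i for i, s in enumerate(hs.snp_ids)}
        missing = [s for s in ids if s not in pos]
        if missing:
            raise EmptyInputError(f"SNPs lost in harmonization: {missing[:5]}")
        x[:, col] = [hs.beta_out[pos[s]] for s in ids]
        s_exp[:, col] = [hs.se_out[pos[s]] for s in ids]
    fs = _conditional_f_from_matrices(x, s_exp)
    return dict(zip([t.trait_name for t in exposure_tables], fs))


def _classify_attenuation(total: MRResult, direct: MRResult) -> str:
    smaller = abs(direct.estimate) < abs(total.estimate)
    spans_zero = direct.ci_low < 0.0 < direct.ci_high
    if smaller and spans_zero:
        return ATTENUATED_TO_NULL
    if smaller:
        return PARTIALLY_ATTENUATED
    return UNCHANGED_EFFECT


def mediate(
    exposure: GwasTable,
    outcome: GwasTable,
    mediators: Sequence[GwasTable],
    ld: LDMatrix,
    screen_alpha: float = 0.05,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    r2_threshold: float = DEFAULT_R2_THRESHOLD,
    palindrome_window: float = DEFAULT_PALINDROME_WINDOW,
    failures: Optional[dict] = None,
) -> list[MediationReport]:
    """Step-wise mediation screen.

    Step 1 estimates the total effect (univariable IVW, exposure -> outcome)
    and stops unless nominally significant.  Step 2 screens each
    exposure -> mediator effect at the same threshold.  Step 3 computes the
    mediator-conditional direct effect by multivariable IVW and classifies the
    attenuation of direct vs total.  Pathway failures are recorded in
    ``failures`` (if given) and never abort other pathways.
    """
    if failures is None:
        failures = {}
    try:
        total, _ = univariable_pipeline(
            exposure, outcome, ld, p_threshold, r2_threshold, palindrome_window)
    except MRError as exc:
        failures["__total__"] = str(exc)
        return []
    if total.pval >= screen_alpha:
        logger.info("total effect %s -> %s not significant (p=%.3g); no mediation",
                    exposure.trait_name, outcome.trait_name, total.pval)
        return []
    reports: list[MediationReport] = []
    for med in mediators:
        try:
            em, _ = univariable_pipeline(
                exposure, med, ld, p_threshold, r2_threshold, palindrome_window)
            if em.pval >= screen_alpha:
                logger.info("exposure -> mediator %s not significant (p=%.3g); dropped",
                            med.trait_name, em.pval)
                continue
            mv = mvmr_ivw([exposure, med], outcome, ld,
                          p_threshold, r2_threshold, palindrome_window)
            direct = mv.effect(exposure.trait_name)
            reports.append(MediationReport(
                exposure=exposure.trait_name, outcome=outcome.trait_name,
                mediator=med.trait_name, total=total, exposure_to_mediator=em,
                direct=direct, attenuation=_classify_attenuation(total, direct)))
        except MRError as exc:
            failures[med.trait_name] = str(exc)
            logger.warning("mediation pathway via %s failed: %s", med.trait_name, exc)
    return reports
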