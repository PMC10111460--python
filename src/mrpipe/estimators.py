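"""Univariable two-sample MR estimators and pleiotropy diagnostics.

All estimators operate on a :class:`~mrpipe.instrumenting.HarmonizedSet` and
return :class:`MRResult` (or a wrapper around it).  Inference is normal-theory
throughout: two-sided p-values and 1.96-sigma confidence intervals.  The
inverse-variance-weighted (IVW) estimator uses multiplicative random effects
by default: its fixed-effect standard error is inflated by
``sqrt(max(1, Q / (J - 1)))``, so overdispersion widens the interval but
underdispersion never narrows it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.stats import norm

from .errors import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    SingularDesignError,
    UnitError,
)
from .instrumenting import HarmonizedSet

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass
class MRResult:
    """A causal-effect estimate with normal-theory inference.

    ``estimate`` is per exposure unit on the outcome's native scale (log-OR
    for binary outcomes); ``odds_ratio``/``or_low``/``or_high`` are populated
    by :func:`to_odds_ratio`.  ``q_stat``/``q_pval``/``phi`` carry Cochran
    heterogeneity for IVW.
    """

    method: str
    n_snp: int
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    odds_ratio: Optional[float] = None
    or_low: Optional[float] = None
    or_high: Optional[float] = None
    q_stat: Optional[float] = None
    q_pval: Optional[float] = None
    phi: Optional[float] = None
    exposure: str = ""
    outcome: str = ""
    adjusted_for: str = ""


@dataclass
class EggerResult:
    """MR-Egger regression: causal slope plus directional-pleiotropy intercept."""

    slope: MRResult
    intercept: float
    intercept_se: float
    intercept_pval: float


@dataclass
class PressoResult:
    """Global pleiotropy test, per-SNP outlier flags, outlier-corrected
    estimate and distortion test."""

    global_rss: float
    global_pval: float
    outlier_snps: list
    outlier_pvals: dict
    raw: MRResult
    corrected: MRResult
    distortion_pval: float


def _finish(method: str, n_snp: int, estimate: float, se: float,
            h: Optional[HarmonizedSet] = None, **extra) -> MRResult:
    z = estimate / se
    pval = float(min(1.0, max(2.0 * norm.sf(abs(z)), 1e-300)))
    res = MRResult(
        method=method, n_snp=n_snp, estimate=float(estimate), se=float(se),
        ci_low=float(estimate - Z95 * se), ci_high=float(estimate + Z95 * se),
        pval=pval, **extra,
    )
    if h is not None:
        res.exposure = h.exposure_name
        res.outcome = h.outcome_name
    return res


def wald_ratio(h: HarmonizedSet) -> MRResult:
    """Single-instrument causal estimate beta_out / beta_exp with first-order SE."""
    if len(h) != 1:
        raise InsufficientInstrumentsError(f"wald_ratio requires exactly 1 SNP, got {len(h)}")
    bx, by, sy = float(h.beta_exp[0]), float(h.beta_out[0]), float(h.se_out[0])
    if bx == 0.0:
        raise DegenerateInstrumentError(f"zero exposure effect for {h.snp_ids[0]}")
    return _finish("wald", 1, by / bx, sy / abs(bx), h)


def ivw(h: HarmonizedSet, random_effects: bool = True) -> MRResult:
    """Inverse-variance-weighted estimate: weighted regression of outcome on
    exposure effects through the origin, weights 1/se_out^2.

    With ``random_effects`` (the default) the standard error is multiplied by
    ``sqrt(max(1, phi))`` where ``phi = Q / (J - 1)`` is the multiplicative
    overdispersion of the Wald-ratio residuals.  A single SNP delegates to
    :func:`wald_ratio`.
    """
    j = len(h)
    if j == 0:
        raise InsufficientInstrumentsError("empty harmonized set")
    if j == 1:
        return wald_ratio(h)
    bx, by, sy = h.beta_exp, h.beta_out, h.se_out
    w = 1.0 / sy**2
    denom = float(np.sum(w * bx**2))
    if denom == 0.0:
        raise DegenerateInstrumentError("all exposure effects are zero")
    estimate = float(np.sum(w * bx * by)) / denom
    se_fixed = math.sqrt(1.0 / denom)
    q = float(np.sum(w * (by - estimate * bx) ** 2))
    phi = q / (j - 1)
    se = se_fixed * math.sqrt(max(1.0, phi)) if random_effects else se_fixed
    from scipy.stats import chi2
    q_pval = float(chi2.sf(q, j - 1))
    method = "ivw_mre" if random_effects else "ivw_fe"
    return _finish(method, j, estimate, se, h, q_stat=q, q_pval=q_pval, phi=phi)


def egger(h: HarmonizedSet) -> EggerResult:
    """MR-Egger: weighted regression of outcome on exposure effects with an
    intercept, after orienting every SNP to non-negative exposure effect.

    The intercept estimates the average directional pleiotropic effect under
    the InSIDE assumption; both coefficient SEs are inflated by the
    multiplicative residual overdispersion (floored at 1).
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError(f"MR-Egger requires >= 3 SNPs, got {j}")
    flip = np.sign(h.beta_exp)
    flip[flip == 0] = 1.0
    bx = h.beta_exp * flip
    by = h.beta_out * flip
    w = 1.0 / h.se_out**2

    if np.ptp(bx) == 0.0:
        raise SingularDesignError("all exposure effects identical after orientation")
    x = np.column_stack([np.ones(j), bx])
    xtw = x.T * w
    xtwx = xtw @ x
    if np.linalg.cond(xtwx) > 1e12:
        raise SingularDesignError("singular Egger design")
    coef = np.linalg.solve(xtwx, xtw @ by)
    resid = by - x @ coef
    phi = float(np.sum(w * resid**2)) / (j - 2)
    cov = np.linalg.inv(xtwx) * max(1.0, phi)
    intercept, slope = float(coef[0]), float(coef[1])
    se_int, se_slope = math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])
    slope_res = _finish("egger_slope", j, slope, se_slope, h, phi=phi)
    z = intercept / se_int
    int_pval = float(min(1.0, max(2.0 * norm.sf(abs(z)), 1e-300)))
    return EggerResult(slope=slope_res, intercept=intercept,
                       intercept_se=se_int, intercept_pval=int_pval)


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    return float(np.interp(0.5, s, r))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000,
                    seed: Optional[int] = None) -> MRResult:
    """Weighted median of per-SNP Wald ratios (inverse-variance weights on the
    first-order ratio SEs), with a seeded parametric-bootstrap standard error.

    Consistent when at least half the total weight comes from valid SNPs.
    """
    j = len(h)
    if j < 3:
        raise InsufficientInstrumentsError(f"weighted median requires >= 3 SNPs, got {j}")
    if np.any(h.beta_exp == 0.0):
        raise DegenerateInstrumentError("zero exposure effect yields undefined ratio")
    ratios = h.beta_out / h.beta_exp
    se_ratio = h.se_out / np.abs(h.beta_exp)
    weights = 1.0 / se_ratio**2
    estimate = _weighted_median(ratios, weights)

    rng = np.random.default_rng(seed)
    bx = rng.normal(h.beta_exp, h.se_exp, size=(n_boot, j))
    by = rng.normal(h.beta_out, h.se_out, size=(n_boot, j))
    bx[bx == 0.0] = np.finfo(float).tiny  # guard measure-zero event
    r_b = by / bx
    w_b = (bx / h.se_out) ** 2
    order = np.argsort(r_b, axis=1)
    r_sorted = np.take_along_axis(r_b, order, axis=1)
    w_sorted = np.take_along_axis(w_b, order, axis=1)
    s = (np.cumsum(w_sorted, axis=1) - 0.5 * w_sorted) / np.sum(w_sorted, axis=1, keepdims=True)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        boots[i] = np.interp(0.5, s[i], r_sorted[i])
    se = float(np.std(boots))
    return _finish("weighted_median", j, estimate, se, h)


def _loo_ivw(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW estimates, vectorized over the left-out index.

    ``by`` may be 2-D (n_sim, J) for simulated outcome draws.
    """
    s1 = np.sum(w * bx * by, axis=-1, keepdims=True)
    s2 = np.sum(w * bx**2)
    return (s1 - w * bx * by) / (s2 - w * bx**2)


def mr_presso(h: HarmonizedSet, n_sim: int = 1000, outlier_alpha: float = 0.05,
              seed: Optional[int] = None) -> PressoResult:
    """Residual-sum-of-squares pleiotropy test with outlier correction.

    (1) Global test: observed RSS of leave-one-out IVW residuals against a
    parametric null in which each SNP's outcome effect is redrawn around its
    leave-one-out fitted value with variance se_out^2.  (2) Outlier test:
    per-SNP empirical p of the observed squared residual, Bonferroni-adjusted
    by J; flagged below ``outlier_alpha``.  (3) Corrected estimate: IVW on the
    unflagged SNPs.  (4) Distortion test: the raw-vs-corrected difference
    compared against differences from random same-size subsets.  Empirical
    p-values use the (r+1)/(n+1) estimator.
    """
    j = len(h)
    if j < 4:
        raise InsufficientInstrumentsError(f"MR-PRESSO requires >= 4 SNPs, got {j}")
    rng = np.random.default_rng(seed)
    bx, by, sy = h.beta_exp, h.beta_out, h.se_out
    w = 1.0 / sy**2

    theta_loo = _loo_ivw(bx, by[None, :], w)[0]
    resid_obs = by - theta_loo * bx
    rss_obs = float(np.sum(resid_obs**2))

    expected = theta_loo * bx
    by_sim = expected[None, :] + sy[None, :] * rng.standard_normal((n_sim, j))
    theta_sim = _loo_ivw(bx, by_sim, w)
    resid_sim = by_sim - theta_sim * bx[None, :]
    rss_sim = np.sum(resid_sim**2, axis=1)
    global_pval = float((np.sum(rss_sim >= rss_obs) + 1) / (n_sim + 1))

    per_snp_p = (np.sum(resid_sim**2 >= resid_obs[None, :] ** 2, axis=0) + 1) / (n_sim + 1)
    adj_p = np.minimum(1.0, per_snp_p * j)
    flagged = [h.snp_ids[i] for i in range(j) if adj_p[i] < outlier_alpha]
    outlier_pvals = {h.snp_ids[i]: float(adj_p[i]) for i in range(j)}

    raw = ivw(h)
    if flagged:
        keep = [s for s in h.snp_ids if s not in set(flagged)]
        if len(keep) == 0:
            raise DegenerateInstrumentError("all SNPs flagged as outliers")
        corrected = replace(ivw(h.restrict(keep)), method="presso_corrected")
        m = len(keep)
        diff_obs = abs(raw.estimate - corrected.estimate)
        diffs = np.empty(n_sim)
        idx_all = np.arange(j)
        for b in range(n_sim):
            sub = rng.choice(idx_all, size=m, replace=False)
            den = np.sum(w[sub] * bx[sub] ** 2)
            est = np.sum(w[sub] * bx[sub] * by[sub]) / den if den > 0 else raw.estimate
            diffs[b] = abs(raw.estimate - est)
        distortion_pval = float((np.sum(diffs >= diff_obs) + 1) / (n_sim + 1))
    else:
        corrected = replace(raw, method="presso_corrected")
        distortion_pval = 1.0
    raw = replace(raw, method="presso_raw")
    return PressoResult(global_rss=rss_obs, global_pval=global_pval,
                        outlier_snps=flagged, outlier_pvals=outlier_pvals,
                        raw=raw, corrected=corrected,
                        distortion_pval=distortion_pval)


def to_odds_ratio(r: MRResult, per_unit_decrease: bool = False,
                  outcome_binary: bool = True) -> MRResult:
    """Exponentiate a log-OR result into odds-ratio reporting scale.

    With ``per_unit_decrease`` the estimate is sign-inverted (and the CI
    bounds swapped) first, for "per 1-unit reduction" reporting.
    """
    if not outcome_binary:
        raise UnitError("odds-ratio conversion requires a binary outcome")
    est, lo, hi = r.estimate, r.ci_low, r.ci_high
    if per_unit_decrease:
        est, lo, hi = -est, -hi, -lo
    return replace(r, estimate=est, ci_low=lo, ci_high=hi,
                   odds_ratio=math.exp(est), or_low=math.exp(lo),
                   or_high=math.exp(hi))
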