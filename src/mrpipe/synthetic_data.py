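"""Seeded generator of two-sample GWAS summary statistics.

The generative model mirrors the assumptions of summary-level MR: true
SNP-exposure effects gamma_j, optional pleiotropic direct effects alpha_j on
an invalid subset, an optional mediated path (exposure -> mediator -> outcome),
standard errors scaled by sample size and allele frequency under a
standardized-trait approximation, independent estimation noise in the exposure
and outcome samples (the two-sample regime), and optional representational
corruption (strand complements, effect/other allele swaps, palindromic allele
pairs) for harmonization round-trip tests.  Everything is reproducible from
the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.stats import norm

from .errors import ValidationError
from .instrumenting import COMPLEMENT
from .summary_data import AssociationRecord, GwasTable, LDMatrix

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")]


@dataclass
class PleiotropySpec:
    """Direct (non-exposure-mediated) SNP-outcome effects on an invalid subset."""

    fraction_invalid: float = 0.0
    mu_alpha: float = 0.0
    tau_alpha: float = 0.0
    inside: bool = True  # direct effects independent of instrument strength


@dataclass
class MediatorSpec:
    """Chain scenario: total effect = theta_direct + delta * theta_m.

    ``eta_sd`` is the SD of mediator-specific SNP effects (genetic variation in
    the mediator not transmitted through the exposure).  It must be positive
    for the exposure- and mediator-effect columns to be linearly independent,
    otherwise the multivariable direct effects are unidentified.
    """

    delta: float  # exposure -> mediator
    theta_m: float  # mediator -> outcome
    theta_direct: float  # residual exposure -> outcome
    n_med: int = 150_000
    eta_sd: float = 0.05


@dataclass
class CorruptionSpec:
    """Representation-level corruption of the outcome table."""

    strand_flip_fraction: float = 0.0
    allele_swap_fraction: float = 0.0
    palindrome_fraction: float = 0.0


@dataclass
class LDBlockSpec:
    """Exchangeable correlated blocks of consecutive SNPs with constant r2."""

    block_size: int = 5
    n_blocks: int = 2
    r2: float = 0.5


@dataclass
class SyntheticScenario:
    j: int = 50
    theta: float = 0.0
    n_exp: int = 150_000
    n_out: int = 300_000
    outcome_binary: bool = False
    n_case: Optional[int] = None
    n_control: Optional[int] = None
    gamma_law: str = "signed_uniform"  # or "positive_uniform"
    gamma_range: tuple = (0.03, 0.15)
    maf_range: tuple = (0.05, 0.5)
    pleiotropy: PleiotropySpec = field(default_factory=PleiotropySpec)
    mediator: Optional[MediatorSpec] = None
    corruption: CorruptionSpec = field(default_factory=CorruptionSpec)
    ld_blocks: Optional[LDBlockSpec] = None
    feedback: float = 0.0  # true outcome -> exposure effect for bidirectional tests
    seed: int = 0

    def validate(self) -> None:
        if self.j < 1:
            raise ValidationError("j must be >= 1")
        for name in ("n_exp", "n_out"):
            if getattr(self, name) < 100:
                raise ValidationError(f"{name} must be >= 100")
        for name, v in (
            ("fraction_invalid", self.pleiotropy.fraction_invalid),
            ("strand_flip_fraction", self.corruption.strand_flip_fraction),
            ("allele_swap_fraction", self.corruption.allele_swap_fraction),
            ("palindrome_fraction", self.corruption.palindrome_fraction),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {v}")
        if self.outcome_binary and not (self.n_case and self.n_control):
            raise ValidationError("binary outcome requires n_case and n_control")
        if self.gamma_law not in ("signed_uniform", "positive_uniform"):
            raise ValidationError(f"unknown gamma_law {self.gamma_law!r}")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValidationError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")


@dataclass
class TruthRecord:
    """Ground truth realized by one :func:`generate` call."""

    theta_total: float
    theta_direct: float
    gamma: np.ndarray
    alpha: np.ndarray
    invalid_mask: np.ndarray
    maf: np.ndarray
    corruption_log: dict[str, list]
    delta: float = 0.0
    theta_m: float = 0.0
    eta: Optional[np.ndarray] = None


@dataclass
class GeneratedData:
    exposure: GwasTable
    outcome: GwasTable
    mediator: Optional[GwasTable]
    ld: LDMatrix
    truth: TruthRecord


def _exact_count_mask(rng: np.random.Generator, j: int, fraction: float) -> np.ndarray:
    m = int(round(j * fraction))
    mask = np.zeros(j, dtype=bool)
    if m > 0:
        mask[rng.choice(j, size=m, replace=False)] = True
    return mask


def _se_standardized(n, maf) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _two_sided_p(beta, se) -> np.ndarray:
    return np.maximum(2.0 * norm.sf(np.abs(beta / se)), 1e-300)


def _build_table(name, snp_ids, ea, oa, eaf, beta, se, n, *,
                 is_binary=False, n_case=None, n_control=None) -> GwasTable:
    t = GwasTable(trait_name=name, is_binary=is_binary)
    pvals = _two_sided_p(beta, se)
    for i, s in enumerate(snp_ids):
        t.add(AssociationRecord(
            snp_id=s, effect_allele=ea[i], other_allele=oa[i],
            eaf=float(eaf[i]), beta=float(beta[i]), se=float(se[i]),
            pval=float(pvals[i]), n=int(n),
            n_case=n_case, n_control=n_control))
    return t


def generate(s: SyntheticScenario) -> GeneratedData:
    """Draw one two-sample (optionally three-sample) summary-statistics dataset.

    Returns exposure, outcome and optional mediator tables, an LD matrix
    (empty unless ``ld_blocks`` is set) and the :class:`TruthRecord`.
    """
    s.validate()
    rng = np.random.default_rng(s.seed)
    j = s.j
    snp_ids = [f"rs{i + 1:05d}" for i in range(j)]

    maf = rng.uniform(*s.maf_range, size=j)
    mag = rng.uniform(*s.gamma_range, size=j)
    if s.gamma_law == "signed_uniform":
        gamma = mag * rng.choice([-1.0, 1.0], size=j)
    else:
        gamma = mag

    invalid = _exact_count_mask(rng, j, s.pleiotropy.fraction_invalid)
    alpha = np.zeros(j)
    if invalid.any():
        pl = s.pleiotropy
        alpha[invalid] = rng.normal(pl.mu_alpha, pl.tau_alpha, size=int(invalid.sum()))
        if not pl.inside:
            # violate InSIDE: direct effect tracks instrument strength
            scale = np.abs(gamma[invalid]) / np.mean(np.abs(gamma))
            alpha[invalid] = pl.mu_alpha * scale + rng.normal(0.0, pl.tau_alpha,
                                                              size=int(invalid.sum()))

    eta = np.zeros(j)
    if s.mediator is not None:
        med = s.mediator
        theta_direct = med.theta_direct
        theta_total = med.theta_direct + med.delta * med.theta_m
        if med.eta_sd > 0:
            eta = rng.normal(0.0, med.eta_sd, size=j)
        true_med = med.delta * gamma + eta
        true_out = theta_direct * gamma + med.theta_m * true_med + alpha
    else:
        theta_direct = s.theta
        theta_total = s.theta
        true_out = s.theta * gamma + alpha

    se_exp = _se_standardized(s.n_exp, maf)
    beta_exp = gamma + rng.normal(0.0, se_exp)
    # optional reverse-causal path for bidirectional tests: outcome-associated
    # variation feeds back into the measured exposure effects
    if s.feedback != 0.0:
        beta_exp = beta_exp + s.feedback * true_out

    if s.outcome_binary:
        se_out = np.sqrt(1.0 / s.n_case + 1.0 / s.n_control) / np.sqrt(
            2.0 * maf * (1.0 - maf))
        n_out_eff = s.n_case + s.n_control
    else:
        se_out = _se_standardized(s.n_out, maf)
        n_out_eff = s.n_out
    beta_out = true_out + rng.normal(0.0, se_out)

    # allele assignment; an exact fraction of SNPs gets palindromic pairs
    pal_mask = _exact_count_mask(rng, j, s.corruption.palindrome_fraction)
    ea, oa = [], []
    for i in range(j):
        pool = _PALINDROMIC_PAIRS if pal_mask[i] else _NONPALINDROMIC_PAIRS
        a, b = pool[rng.integers(len(pool))]
        ea.append(a)
        oa.append(b)

    exposure = _build_table(f"exposure_{s.seed}", snp_ids, ea, oa, maf,
                            beta_exp, se_exp, s.n_exp)

    # outcome-side representational corruption
    log: dict[str, list] = {"strand_flip": [], "allele_swap": []}
    o_ea, o_oa = list(ea), list(oa)
    o_beta, o_eaf = beta_out.copy(), maf.copy()
    flip_mask = _exact_count_mask(rng, j, s.corruption.strand_flip_fraction)
    swap_mask = _exact_count_mask(rng, j, s.corruption.allele_swap_fraction)
    for i in range(j):
        if flip_mask[i] and not pal_mask[i]:  # complementing a palindrome is ambiguous
            o_ea[i], o_oa[i] = COMPLEMENT[o_ea[i]], COMPLEMENT[o_oa[i]]
            log["strand_flip"].append(snp_ids[i])
        if swap_mask[i]:
            o_ea[i], o_oa[i] = o_oa[i], o_ea[i]
            o_beta[i] = -o_beta[i]
            o_eaf[i] = 1.0 - o_eaf[i]
            log["allele_swap"].append(snp_ids[i])

    outcome = _build_table(
        f"outcome_{s.seed}", snp_ids, o_ea, o_oa, o_eaf, o_beta, se_out,
        n_out_eff, is_binary=s.outcome_binary,
        n_case=s.n_case, n_control=s.n_control)

    mediator_table = None
    delta = theta_m = 0.0
    if s.mediator is not None:
        med = s.mediator
        delta, theta_m = med.delta, med.theta_m
        se_med = _se_standardized(med.n_med, maf)
        beta_med = med.delta * gamma + eta + rng.normal(0.0, se_med)
        mediator_table = _build_table(f"mediator_{s.seed}", snp_ids, ea, oa, maf,
                                      beta_med, se_med, med.n_med)

    ld = LDMatrix()
    if s.ld_blocks is not None:
        blk = s.ld_blocks
        pos = 0
        for _ in range(blk.n_blocks):
            members = snp_ids[pos:pos + blk.block_size]
            for a_i in range(len(members)):
                for b_i in range(a_i + 1, len(members)):
                    ld.set(members[a_i], members[b_i], blk.r2)
            pos += blk.block_size
            if pos >= j:
                break

    truth = TruthRecord(
        theta_total=theta_total, theta_direct=theta_direct,
        gamma=gamma, alpha=alpha, invalid_mask=invalid, maf=maf,
        corruption_log=log, delta=delta, theta_m=theta_m, eta=eta)
    return GeneratedData(exposure=exposure, outcome=outcome,
                         mediator=mediator_table, ld=ld, truth=truth)


def scenario_presets() -> dict[str, SyntheticScenario]:
    """Named scenarios sized to the study's instrument counts.

    ``afb_like`` (J=18), ``births_like`` (J=9), ``menarche_like`` (J=208) and
    ``menopause_like`` (J=154) emulate the four reproductive-factor exposures
    against binary cardiovascular outcomes; ``mediation_chain`` carries a
    mediated path with total = 0.1 + 0.5 * 0.4 = 0.3; ``null`` has no causal
    effect and no pleiotropy.
    """
    binary = dict(outcome_binary=True, n_case=60_000, n_control=120_000)
    return {
        "afb_like": SyntheticScenario(
            j=18, theta=-0.40, n_exp=131_987, gamma_law="positive_uniform",
            gamma_range=(0.05, 0.15), **binary),
        "births_like": SyntheticScenario(
            j=9, theta=0.64, n_exp=193_953, gamma_law="positive_uniform",
            gamma_range=(0.05, 0.15), **binary),
        "menarche_like": SyntheticScenario(
            j=208, theta=-0.10, n_exp=329_345, gamma_range=(0.04, 0.12), **binary),
        "menopause_like": SyntheticScenario(
            j=154, theta=0.0, n_exp=106_048, gamma_range=(0.05, 0.15), **binary),
        "mediation_chain": SyntheticScenario(
            j=50, n_exp=500_000, n_out=200_000, maf_range=(0.1, 0.5),
            mediator=MediatorSpec(delta=0.5, theta_m=0.4, theta_direct=0.1,
                                  n_med=500_000)),
        "null": SyntheticScenario(j=50, theta=0.0),
    }
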