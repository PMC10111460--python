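import math

import numpy as np
import pytest

from mrpipe.errors import (
    DegenerateInstrumentError,
    InsufficientInstrumentsError,
    SingularDesignError,
    UnitError,
)
from mrpipe.estimators import (
    egger,
    ivw,
    mr_presso,
    to_odds_ratio,
    wald_ratio,
    weighted_median,
)
from mrpipe.instrumenting import harmonize
from mrpipe.synthetic_data import PleiotropySpec, SyntheticScenario, generate

from conftest import make_harmonized


def wls_oracle(bx, by, sy, intercept=False):
    """Independent weighted-least-squares reference via numpy lstsq."""
    bx, by, sy = map(np.asarray, (bx, by, sy))
    sw = 1.0 / sy
    x = np.column_stack([np.ones_like(bx), bx]) if intercept else bx[:, None]
    coef, *_ = np.linalg.lstsq(x * sw[:, None], by * sw, rcond=None)
    return coef


class TestWaldRatio:
    def test_formula(self):
        h = make_harmonized([0.1], [0.05], [0.01], sx=[0.02])
        r = wald_ratio(h)
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1)
        assert r.ci_low == pytest.approx(0.5 - 1.959963984540054 * 0.1)

    def test_zero_outcome_effect(self):
        h = make_harmonized([0.1], [0.0], [0.01], binary=True)
        r = to_odds_ratio(wald_ratio(h))
        assert r.estimate == 0.0
        assert r.odds_ratio == pytest.approx(1.0)

    def test_zero_exposure_effect_rejected(self):
        h = make_harmonized([0.0], [0.05], [0.01])
        with pytest.raises(DegenerateInstrumentError):
            wald_ratio(h)


class TestIVW:
    def test_single_snp_delegates_to_wald(self):
        h = make_harmonized([0.1], [0.05], [0.01], sx=[0.02])
        r = ivw(h)
        w = wald_ratio(h)
        assert r.estimate == w.estimate and r.se == w.se and r.method == "wald"

    def test_three_snp_closed_form_matches_oracle(self):
        bx = [0.10, 0.20, 0.15]
        by = [0.05, 0.08, 0.09]
        sy = [0.01, 0.01, 0.02]
        h = make_harmonized(bx, by, sy)
        r = ivw(h)
        # frozen value from the independent WLS oracle (and hand arithmetic:
        # sum(bx*by/sy^2)/sum(bx^2/sy^2) = 243.75 / 556.25)
        assert r.estimate == pytest.approx(243.75 / 556.25, abs=1e-12)
        assert r.estimate == pytest.approx(float(wls_oracle(bx, by, sy)[0]), abs=1e-12)

    def test_oracle_equivalence_random(self, rng):
        for _ in range(50):
            j = 10
            bx = rng.normal(0.1, 0.05, j)
            by = rng.normal(0.02, 0.05, j)
            sy = rng.uniform(0.005, 0.05, j)
            h = make_harmonized(bx, by, sy)
            assert ivw(h).estimate == pytest.approx(
                float(wls_oracle(bx, by, sy)[0]), abs=1e-10)

    def test_exact_fit_limit(self):
        bx = np.array([0.1, 0.2, 0.3])
        h = make_harmonized(bx, 0.4 * bx, [0.01] * 3)
        r = ivw(h)
        assert r.estimate == pytest.approx(0.4, abs=1e-12)
        assert r.q_stat == pytest.approx(0.0, abs=1e-18)
        assert r.phi == pytest.approx(0.0, abs=1e-18)
        # the multiplicative random-effects floor keeps the fixed-effect SE
        fixed = ivw(h, random_effects=False)
        assert r.se == fixed.se

    def test_random_effects_never_deflate(self, rng):
        for seed in range(20):
            d = generate(SyntheticScenario(j=30, theta=0.1, seed=seed))
            h = harmonize(d.exposure, d.outcome)
            assert ivw(h).se >= ivw(h, random_effects=False).se

    def test_all_zero_exposure_rejected(self):
        h = make_harmonized([0.0, 0.0], [0.01, 0.02], [0.01, 0.01])
        with pytest.raises(DegenerateInstrumentError):
            ivw(h)


class TestEgger:
    def test_exact_linear_fit(self, rng):
        bx = rng.uniform(0.05, 0.3, 10)  # already positive
        by = 0.02 + 0.3 * bx
        h = make_harmonized(bx, by, rng.uniform(0.005, 0.02, 10))
        e = egger(h)
        assert e.intercept == pytest.approx(0.02, abs=1e-10)
        assert e.slope.estimate == pytest.approx(0.3, abs=1e-10)

    def test_matches_wls_oracle_with_orientation(self, rng):
        bx = rng.normal(0.0, 0.1, 12)
        by = rng.normal(0.0, 0.05, 12)
        sy = rng.uniform(0.005, 0.05, 12)
        h = make_harmonized(bx, by, sy)
        e = egger(h)
        flip = np.where(bx < 0, -1.0, 1.0)
        a, b = wls_oracle(bx * flip, by * flip, sy, intercept=True)
        assert e.intercept == pytest.approx(float(a), abs=1e-10)
        assert e.slope.estimate == pytest.approx(float(b), abs=1e-10)

    def test_too_few_snps(self):
        h = make_harmonized([0.1, 0.2], [0.05, 0.1], [0.01, 0.01])
        with pytest.raises(InsufficientInstrumentsError):
            egger(h)

    def test_identical_exposure_effects_singular(self):
        h = make_harmonized([0.1, 0.1, 0.1], [0.05, 0.06, 0.04], [0.01] * 3)
        with pytest.raises(SingularDesignError):
            egger(h)

    def test_intercept_recovers_directional_pleiotropy(self):
        # InSIDE scenario: every SNP carries a direct effect with mean 0.05
        intercepts = []
        for seed in range(200):
            d = generate(SyntheticScenario(
                j=100, theta=0.2, n_exp=500_000, n_out=300_000,
                gamma_law="positive_uniform", gamma_range=(0.02, 0.2),
                pleiotropy=PleiotropySpec(1.0, 0.05, 0.02, True), seed=seed))
            intercepts.append(egger(harmonize(d.exposure, d.outcome)).intercept)
        mean = np.mean(intercepts)
        mc_se = np.std(intercepts) / math.sqrt(len(intercepts))
        assert abs(mean - 0.05) < 3 * mc_se


class TestWeightedMedian:
    def test_symmetric_equal_weights(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.04, 0.05, 0.06])
        h = make_harmonized(bx, by, [0.01] * 3)
        r = weighted_median(h, n_boot=10, seed=0)
        assert r.estimate == pytest.approx(0.5)

    def test_interpolation_formula_oracle(self):
        # one wild ratio among a cluster: estimate stays in the cluster and
        # matches the standardized-cumulative-weight interpolation computed here
        bx = np.full(10, 0.1)
        ratios = np.array([0.45, 0.48, 0.5, 0.5, 0.52, 0.55, 0.47, 0.53, 0.49, 10.0])
        by = ratios * bx
        sy = np.full(10, 0.01)
        h = make_harmonized(bx, by, sy)
        r = weighted_median(h, n_boot=10, seed=0)
        w = (bx / sy) ** 2
        order = np.argsort(ratios)
        s = (np.cumsum(w[order]) - 0.5 * w[order]) / w.sum()
        expected = float(np.interp(0.5, s, ratios[order]))
        assert r.estimate == pytest.approx(expected, abs=1e-12)
        assert 0.45 <= r.estimate <= 0.55

    def test_seeded_determinism(self):
        h = make_harmonized([0.1, 0.2, 0.15, 0.12], [0.05, 0.1, 0.06, 0.07],
                            [0.01] * 4)
        r1 = weighted_median(h, n_boot=200, seed=42)
        r2 = weighted_median(h, n_boot=200, seed=42)
        assert r1.se == r2.se
        r3 = weighted_median(h, n_boot=200, seed=43)
        assert r3.se != r1.se

    def test_zero_exposure_effect_rejected(self):
        h = make_harmonized([0.1, 0.0, 0.2], [0.05, 0.01, 0.1], [0.01] * 3)
        with pytest.raises(DegenerateInstrumentError):
            weighted_median(h, seed=0)


class TestPresso:
    def test_too_few_snps(self):
        h = make_harmonized([0.1] * 3, [0.05] * 3, [0.01] * 3)
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(h, seed=0)

    def test_no_outliers_correction_is_noop(self):
        d = generate(SyntheticScenario(j=20, theta=0.1, seed=3))
        h = harmonize(d.exposure, d.outcome)
        pr = mr_presso(h, n_sim=500, seed=5)
        if not pr.outlier_snps:  # deterministic given seeds: clean null
            assert pr.corrected.estimate == pr.raw.estimate
            assert pr.corrected.n_snp == pr.raw.n_snp
            assert pr.distortion_pval == 1.0
        assert pr.corrected.n_snp == pr.raw.n_snp - len(pr.outlier_snps)

    def test_planted_outlier_flagged_and_corrected(self):
        d = generate(SyntheticScenario(j=20, theta=0.1, seed=12))
        h = harmonize(d.exposure, d.outcome)
        i = int(np.argmax((h.beta_exp / h.se_out) ** 2))
        h.beta_out[i] += 10.0 * h.se_out[i]
        pr = mr_presso(h, n_sim=1000, seed=12)
        assert h.snp_ids[i] in pr.outlier_snps
        assert pr.global_pval < 0.05
        assert abs(pr.corrected.estimate - 0.1) < abs(pr.raw.estimate - 0.1)
        assert pr.corrected.n_snp == 20 - len(pr.outlier_snps)

    def test_seeded_determinism(self):
        d = generate(SyntheticScenario(j=15, theta=0.1, seed=4))
        h = harmonize(d.exposure, d.outcome)
        p1 = mr_presso(h, n_sim=300, seed=9)
        p2 = mr_presso(h, n_sim=300, seed=9)
        assert p1.global_pval == p2.global_pval
        assert p1.global_rss == p2.global_rss

    def test_global_pval_range(self):
        d = generate(SyntheticScenario(j=10, theta=0.0, seed=8))
        h = harmonize(d.exposure, d.outcome)
        pr = mr_presso(h, n_sim=200, seed=1)
        assert 1.0 / 201 <= pr.global_pval <= 1.0


class TestOddsRatio:
    def test_zero_estimate_gives_unit_or(self):
        h = make_harmonized([0.1], [0.0], [0.01], binary=True)
        r = to_odds_ratio(wald_ratio(h))
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.or_low == pytest.approx(1.0 / r.or_high)

    def test_log2_gives_two(self):
        h = make_harmonized([0.1], [math.log(2) * 0.1], [0.01], binary=True)
        r = to_odds_ratio(wald_ratio(h))
        assert r.odds_ratio == pytest.approx(2.0)

    def test_per_unit_decrease_inverts_sign(self):
        h = make_harmonized([0.1], [-0.02], [0.01], binary=True)
        base = wald_ratio(h)  # estimate = -0.2
        r = to_odds_ratio(base, per_unit_decrease=True)
        assert r.estimate == pytest.approx(0.2)
        assert r.odds_ratio == pytest.approx(math.exp(0.2))
        assert r.ci_low == pytest.approx(-base.ci_high)
        assert r.pval == base.pval

    def test_continuous_outcome_rejected(self):
        h = make_harmonized([0.1], [0.05], [0.01])
        with pytest.raises(UnitError):
            to_odds_ratio(wald_ratio(h), outcome_binary=False)


class TestSignFlipInvariance:
    def test_all_estimators_invariant_to_joint_flips(self, rng):
        d = generate(SyntheticScenario(j=20, theta=0.1, seed=21))
        h = harmonize(d.exposure, d.outcome)
        flip = rng.choice([-1.0, 1.0], size=len(h))
        h2 = harmonize(d.exposure, d.outcome)
        h2.beta_exp = h2.beta_exp * flip
        h2.beta_out = h2.beta_out * flip
        assert ivw(h2).estimate == pytest.approx(ivw(h).estimate, abs=1e-12)
        assert weighted_median(h2, n_boot=10, seed=0).estimate == pytest.approx(
            weighted_median(h, n_boot=10, seed=0).estimate, abs=1e-12)
        e1, e2 = egger(h), egger(h2)
        assert e2.slope.estimate == pytest.approx(e1.slope.estimate, abs=1e-12)
        assert e2.intercept == pytest.approx(e1.intercept, abs=1e-12)
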