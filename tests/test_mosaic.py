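"""Exact-binomial mosaic detection: oracle equivalence, power, recovery."""

import math

import numpy as np
import pytest

from vippanel.mosaic import (
    MosaicCallConfig,
    ZygosityCall,
    classify_zygosity,
    critical_alt_reads,
    detection_power,
    estimate_af,
)
from vippanel.mosaic import test_site as run_site_test
from vippanel.synth import PileupSite, simulate_pileup


def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """Brute-force P(X >= k) by direct summation of binomial pmf terms."""
    return sum(
        math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1)
    )


def _site(depth, alt, e=0.001):
    return PileupSite(
        sample_id=0, gene="NLRP3", position=0, depth=depth, alt_reads=alt, per_base_error=e
    )


class TestTestSite:
    @pytest.mark.parametrize("depth", [1, 5, 12, 30])
    @pytest.mark.parametrize("e", [0.001, 0.01, 0.1])
    def test_matches_enumeration_oracle_at_small_depth(self, depth, e):
        config = MosaicCallConfig(per_base_error=e)
        for alt in range(1, depth + 1):
            expected = binom_tail_oracle(alt, depth, e)
            got = run_site_test(_site(depth, alt, e), config).p_value
            assert got == pytest.approx(expected, abs=1e-12)

    def test_printed_mosaic_case_is_detected(self):
        # 13 alternate reads out of 426 against an error floor of 0.1%
        res = run_site_test(_site(426, 13))
        assert res.detected and res.p_value < 1e-10

    def test_single_alt_read_not_significant(self):
        res = run_site_test(_site(426, 1))
        # P(X >= 1) = 1 - 0.999^426 ~ 0.35
        assert res.p_value == pytest.approx(1 - 0.999**426, rel=1e-9)
        assert not res.detected

    def test_zero_alt_reads_p_value_one(self):
        res = run_site_test(_site(426, 0))
        assert res.p_value == 1.0 and not res.detected

    def test_alt_exceeding_depth_rejected(self):
        with pytest.raises(ValueError):
            _site(10, 11)


class TestEstimateAf:
    def test_printed_three_percent_case(self):
        est = estimate_af(_site(426, 13))
        assert est.af_hat == pytest.approx(13 / 426)
        assert round(100 * est.af_hat) == 3
        assert est.ci_low < est.af_hat < est.ci_high

    def test_boundary_cases(self):
        zero = estimate_af(_site(100, 0))
        assert zero.af_hat == 0.0 and zero.ci_low == 0.0
        full = estimate_af(_site(100, 100))
        assert full.af_hat == 1.0 and full.ci_high == 1.0

    def test_recovery_and_ci_coverage_at_printed_depth(self):
        # 1000 seeded replicates at (depth 426, af 3%)
        depth, af, n_reps = 426, 0.03, 1000
        rng = np.random.default_rng(42)
        hats, covered = [], 0
        for _ in range(n_reps):
            site = simulate_pileup(depth, af, 0.001, seed=rng)
            est = estimate_af(site)
            hats.append(est.af_hat)
            covered += est.ci_low <= af <= est.ci_high
        se = math.sqrt(af * (1 - af) / depth / n_reps)
        assert abs(np.mean(hats) - af) < 3 * se
        assert covered / n_reps >= 0.95 - 0.02


class TestClassifyZygosity:
    @pytest.mark.parametrize(
        "af,expected",
        [(0.50, ZygosityCall.HET), (1.0, ZygosityCall.HOM), (0.03, ZygosityCall.MOSAIC),
         (0.30, ZygosityCall.HET), (0.85, ZygosityCall.HOM)],
    )
    def test_bands(self, af, expected):
        assert classify_zygosity(af, detected=True) is expected

    def test_not_detected_is_reference(self):
        assert classify_zygosity(0.02, detected=False) is ZygosityCall.REFERENCE

    def test_hemizygous_call_for_male_x_linked(self):
        call = classify_zygosity(
            0.98, detected=True, patient_sex="M", gene_inheritance="XL"
        )
        assert call is ZygosityCall.HEMI


class TestDetectionPower:
    def test_type_one_error_controlled(self):
        assert detection_power(426, 0.0) <= MosaicCallConfig().alpha

    def test_printed_low_mosaic_has_high_power(self):
        assert detection_power(426, 0.03) >= 0.95

    def test_analytic_and_simulated_agree(self):
        for depth, af in [(163, 0.07), (243, 0.20), (426, 0.03)]:
            analytic = detection_power(depth, af)
            simulated = detection_power(depth, af, mode="simulated", n_reps=500, seed=3)
            mc_se = math.sqrt(max(analytic * (1 - analytic), 1e-4) / 500)
            assert abs(analytic - simulated) <= max(3 * mc_se, 0.02)

    def test_power_monotone_in_fraction(self):
        grid = [0.01, 0.02, 0.03, 0.05, 0.10, 0.20]
        powers = [detection_power(426, af) for af in grid]
        assert all(a <= b + 1e-12 for a, b in zip(powers, powers[1:]))

    def test_power_monotone_in_depth(self):
        # monotone up to the discrete jumps of the critical value: compare
        # depths spaced widely enough that the trend dominates
        depths = [50, 100, 200, 400, 800]
        powers = [detection_power(d, 0.03) for d in depths]
        assert all(a <= b + 1e-9 for a, b in zip(powers, powers[1:]))

    def test_simulated_mode_rejects_bad_reps(self):
        with pytest.raises(ValueError):
            detection_power(100, 0.1, mode="simulated", n_reps=0)

    def test_critical_value_is_exact_boundary(self):
        config = MosaicCallConfig()
        for depth in (55, 163, 243, 426):
            k = critical_alt_reads(depth, config)
            assert binom_tail_oracle(k, depth, config.per_base_error) < config.alpha
            if k > 1:
                assert binom_tail_oracle(k - 1, depth, config.per_base_error) >= config.alpha
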