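"""Synthetic cohort generator: determinism, calibration, spiking, pileups."""

import numpy as np
import pandas as pd
import pytest

from vippanel.synth import (
    SimulationParams,
    build_cohort_from_truth,
    simulate_coverage,
    simulate_pileup,
    spike_deletions,
)


class TestSimulateCoverage:
    def test_deterministic_under_fixed_seed(self, vip1):
        params = SimulationParams(seed=7)
        a = simulate_coverage(vip1, params)
        b = simulate_coverage(vip1, params)
        pd.testing.assert_frame_equal(a, b)

    def test_calibration_fraction_above_30x(self, vip1):
        cov = simulate_coverage(vip1, SimulationParams(seed=0))
        per_region = cov.groupby(["gene", "region_label"])["mean_depth"].mean()
        frac_above = (per_region > 30).mean()
        assert frac_above >= 0.97

    def test_designated_low_fraction_matches_parameter(self, vip1):
        params = SimulationParams(seed=0)
        cov = simulate_coverage(vip1, params)
        per_region = cov.groupby(["gene", "region_label"])["mean_depth"].mean()
        frac_low = (per_region <= 30).mean()
        n_regions = per_region.size
        # designated count is round(f*n); sampling noise can only add the
        # rare well-captured region that dips below threshold
        assert frac_low == pytest.approx(params.low_coverage_fraction, abs=3 / n_regions)

    def test_zero_low_fraction_leaves_no_low_regions(self, vip1):
        cov = simulate_coverage(vip1, SimulationParams(seed=0, low_coverage_fraction=0.0))
        per_region = cov.groupby(["gene", "region_label"])["mean_depth"].mean()
        # at dispersion 0.35 around 200x, a cohort-mean below 30x would be a
        # >5 sigma lognormal excursion: none expected in ~1000 regions
        assert (per_region > 30).all()

    def test_record_invariants(self, vip1):
        cov = simulate_coverage(vip1, SimulationParams(seed=3))
        assert (cov["min_depth"] <= cov["mean_depth"] + 1e-9).all()
        assert (cov.loc[cov["mapped_reads"] == 0, "mean_depth"] == 0).all()
        assert cov["mq0_fraction"].between(0, 1).all()

    def test_mq0_regions_have_high_mq0_fraction(self, vip1):
        cov = simulate_coverage(vip1, SimulationParams(seed=3))
        mq0 = cov[cov["region_class"] == "mq0"]
        assert not mq0.empty
        assert (mq0["mq0_fraction"] > 0.9).all()

    def test_rejects_empty_cohort(self, vip1):
        with pytest.raises(ValueError, match="n_samples"):
            simulate_coverage(vip1, SimulationParams(n_samples=0))


class TestSpikeDeletions:
    def test_whole_gene_spike_zeroes_every_region(self, vip1):
        cov = simulate_coverage(vip1, SimulationParams(seed=1, n_samples=4))
        spiked = spike_deletions(cov, [(2, "SH2D1A")])
        cells = spiked[(spiked["sample_id"] == 2) & (spiked["gene"] == "SH2D1A")]
        assert (cells["mapped_reads"] == 0).all()
        assert (cells["mean_depth"] == 0).all()
        others = spiked[~((spiked["sample_id"] == 2) & (spiked["gene"] == "SH2D1A"))]
        pd.testing.assert_frame_equal(
            others.reset_index(drop=True),
            cov[~((cov["sample_id"] == 2) & (cov["gene"] == "SH2D1A"))].reset_index(drop=True),
        )

    def test_single_region_spike(self, vip1):
        cov = simulate_coverage(vip1, SimulationParams(seed=1, n_samples=4))
        spiked = spike_deletions(cov, [(1, "SH2D1A", ["exon 2"])])
        gene = spiked[(spiked["sample_id"] == 1) & (spiked["gene"] == "SH2D1A")]
        assert (gene.loc[gene["region_label"] == "exon 2", "mapped_reads"] == 0).all()
        assert (gene.loc[gene["region_label"] != "exon 2", "mapped_reads"] > 0).any()

    def test_empty_spec_list_is_identity(self, vip1):
        cov = simulate_coverage(vip1, SimulationParams(seed=1, n_samples=2))
        pd.testing.assert_frame_equal(spike_deletions(cov, []), cov)

    def test_unknown_targets_rejected_listing_offenders(self, vip1):
        cov = simulate_coverage(vip1, SimulationParams(seed=1, n_samples=2))
        with pytest.raises(ValueError) as err:
            spike_deletions(cov, [(99, "SH2D1A"), (1, "NOGENE")])
        assert "99" in str(err.value) and "NOGENE" in str(err.value)


class TestSimulatePileup:
    def test_degenerate_fractions(self):
        assert simulate_pileup(100, 0.0, 0.0, seed=0).alt_reads == 0
        assert simulate_pileup(100, 1.0, 0.0, seed=0).alt_reads == 100

    def test_mean_alt_reads_recovers_true_fraction(self):
        # 1000 replicates at the printed low-mosaic depth/fraction pair
        depth, af = 426, 0.03
        rng = np.random.default_rng(11)
        alts = np.array(
            [simulate_pileup(depth, af, 0.001, seed=rng).alt_reads for _ in range(1000)]
        )
        se = np.sqrt(depth * af * (1 - af) / 1000)
        assert abs(alts.mean() - depth * af) < 3 * se

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            simulate_pileup(0, 0.5)
        with pytest.raises(ValueError):
            simulate_pileup(100, 1.5)
        with pytest.raises(ValueError):
            simulate_pileup(100, 0.5, per_base_error=-0.1)


class TestBuildCohortFromTruth:
    def test_out_of_capture_record_absent_from_variant_table(self, table2_bundle):
        keys = {(v.gene, v.cdna_change) for v in table2_bundle.variants}
        assert ("UNC13D", "c.118-308C>T") not in keys
        # but the record stays in the truth list
        assert any(r.cdna_change == "c.118-308C>T" for r in table2_bundle.truth)

    def test_three_samples_carry_zero_read_regions(self, table2_bundle):
        cov = table2_bundle.coverage
        zero_samples = set(cov.loc[cov["mapped_reads"] == 0, "sample_id"])
        spiked = {
            r.patient_id for r in table2_bundle.truth if r.is_deletion
        }
        assert spiked == {5, 10, 13}
        assert spiked <= zero_samples

    def test_pileup_depths_match_printed_read_depths(self, table2_bundle):
        by_key = {(p.sample_id, p.gene): p for p in table2_bundle.pileups}
        assert by_key[(16, "NLRP3")].depth == 426
        assert by_key[(14, "TNFRSF1A")].depth == 163

    def test_empty_truth_gives_empty_bundle(self, vip1):
        bundle = build_cohort_from_truth([], vip1)
        assert bundle.coverage.empty
        assert bundle.pileups == [] and bundle.variants == []

    def test_deterministic_for_fixed_seed(self, blinded_truth, vip1):
        p = SimulationParams(seed=5)
        a = build_cohort_from_truth(blinded_truth, vip1, p)
        b = build_cohort_from_truth(blinded_truth, vip1, p)
        pd.testing.assert_frame_equal(a.coverage, b.coverage)
        assert [s.alt_reads for s in a.pileups] == [s.alt_reads for s in b.pileups]
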