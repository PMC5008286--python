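"""Generator contracts: determinism, bounds, parameter/correlation recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from imprintscore.cohort_stats import pearson_correlation
from imprintscore.scoring import score_cohort
from imprintscore.synthetic_data import (
    SimulationConfig,
    simulate_clones,
    simulate_cohort,
    simulate_outcomes,
    simulate_triads,
)
from imprintscore.survival import km_estimate, logrank_test


class TestConfig:
    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_per_group=1)
        with pytest.raises(ValueError):
            SimulationConfig(dmr_baseline_sd=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(h19_coupling_r=1.5)
        with pytest.raises(ValueError):
            SimulationConfig(p_meth_dense=1.2)
        with pytest.raises(ValueError):
            SimulationConfig(h0=0.0)
        with pytest.raises(ValueError):
            SimulationConfig(gamma=-0.1)

    def test_study_default_group_sizes(self):
        sizes = SimulationConfig().group_sizes()
        assert sizes == {"normal": 8, "early_onset": 23, "late_onset": 9}


class TestCohort:
    def test_deterministic_given_seed(self, study_config, study_cohort):
        again = simulate_cohort(SimulationConfig(seed=study_config.seed))
        pd.testing.assert_frame_equal(study_cohort, again)
        different = simulate_cohort(SimulationConfig(seed=study_config.seed + 1))
        assert not study_cohort["methylation_pct"].equals(different["methylation_pct"])

    def test_full_locus_panel_per_sample(self, study_cohort):
        per_sample = study_cohort.groupby("sample_id")
        assert (per_sample.size() == 7).all()  # 3 x 14q32 + H19 + MEST + PEG3 + LINE1
        assert set(study_cohort["locus"]) == {"14q32", "H19", "MEST", "PEG3", "LINE1"}

    def test_values_clamped_to_percentage_scale(self, study_cohort):
        v = study_cohort["methylation_pct"]
        assert v.between(0, 100).all()
        assert v.notna().all()

    def test_degenerate_noise_free_case_sits_at_baseline(self):
        config = SimulationConfig(
            n_per_group=5, shift_14q_early=0.0, shift_14q_late=0.0, shift_line1=0.0,
            dmr_baseline_sd=1e-9, line1_sd=1e-9, other_locus_sd=1e-9, seed=1)
        df = simulate_cohort(config)
        q14 = df.loc[df["locus"] == "14q32", "methylation_pct"]
        assert np.allclose(q14, 50.0, atol=1e-6)

    def test_group_shifts_recovered_within_three_se(self, calibration_cohort,
                                                    calibration_config):
        cfg = calibration_config
        q14 = calibration_cohort[calibration_cohort["locus"] == "14q32"]
        by = q14.groupby("group")["methylation_pct"]
        se = cfg.dmr_baseline_sd / math.sqrt(3 * 1000)
        assert by.mean()["early_onset"] - by.mean()["normal"] == pytest.approx(
            cfg.shift_14q_early, abs=3 * se * math.sqrt(2))
        assert by.mean()["late_onset"] - by.mean()["normal"] == pytest.approx(
            cfg.shift_14q_late, abs=3 * se * math.sqrt(2))

    def test_h19_coupling_and_bystander_loci(self, calibration_cohort,
                                             calibration_scores):
        index = calibration_scores.set_index("sample_id")["fourteen_q_index"]
        wide = calibration_cohort.pivot_table(index="sample_id", columns="locus",
                                              values="methylation_pct")
        h19_extent = (wide["H19"] - 50).abs()
        r, _ = pearson_correlation(index.loc[wide.index], h19_extent)
        assert r == pytest.approx(0.78, abs=0.05)
        for locus in ("MEST", "PEG3"):
            extent = (wide[locus] - 50).abs()
            r, _ = pearson_correlation(index.loc[wide.index], extent)
            assert abs(r) < 0.05


class TestClones:
    def test_symmetric_alleles_average_half(self):
        sim = simulate_clones(1.0, 0.0, 4000, 10, 1.0, seed=2)
        assert sim.matrix.calls.mean() == pytest.approx(0.5, abs=0.03)

    def test_expected_mean_is_average_of_allele_rates(self):
        sim = simulate_clones(0.9, 0.1, 10000, 20, 1.0, seed=3)
        assert sim.matrix.calls.mean() == pytest.approx(0.5, abs=0.01)

    def test_zero_conversion_leaves_every_cytosine(self):
        sim = simulate_clones(0.3, 0.3, 5, 6, conversion_efficiency=0.0, seed=4)
        assert all(s == sim.reference.sequence for s in sim.sequences)
        assert (sim.matrix.calls == 1).all()

    def test_reference_has_qc_cytosines(self):
        sim = simulate_clones(0.9, 0.1, 2, 3, seed=5)
        assert len(sim.reference.non_cpg_c_positions) >= 5
        assert sim.reference.n_cpg == 3

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            simulate_clones(1.1, 0.1, 10, 5)
        with pytest.raises(ValueError):
            simulate_clones(0.9, 0.1, 10, 0)
        with pytest.raises(ValueError):
            simulate_clones(0.9, 0.1, 1, 5)


class TestTriads:
    def test_independence_when_target_zero(self):
        config = SimulationConfig(triad_r_father_dmr1=0.0, seed=6)
        tr = simulate_triads(5000, config)
        wide = tr[tr["dmr"] == "DMR-1"].pivot_table(
            index="triad_id", columns="member", values="methylation_pct")
        r, _ = pearson_correlation(wide["child"], wide["father"])
        assert abs(r) < 0.05

    def test_exact_copy_at_unit_correlation(self):
        config = SimulationConfig(triad_r_father_dmr1=1.0, seed=7)
        tr = simulate_triads(50, config)
        wide = tr[tr["dmr"] == "DMR-1"].pivot_table(
            index="triad_id", columns="member", values="methylation_pct")
        assert np.allclose(wide["child"], wide["father"])

    def test_too_few_triads_rejected(self):
        with pytest.raises(ValueError):
            simulate_triads(2, SimulationConfig())


class TestOutcomes:
    def test_null_model_breaks_no_association(self):
        config = SimulationConfig(gamma=0.0, beta=0.0, seed=8)
        idx = np.concatenate([np.full(300, 5.0), np.full(300, 20.0)])
        ct, surv = simulate_outcomes(idx, config)
        wide = ct.pivot_table(index="sample_id", columns="gene", values="ct")
        dct = wide["MEG3"] - wide["GAPDH"]
        ids = [f"S-{i + 1:04d}" for i in range(600)]
        r, _ = pearson_correlation(dct.loc[ids], idx)
        assert abs(r) < 0.1
        strat = np.where(idx > 8.5, "hi", "lo")
        assert logrank_test(surv["time"], surv["event"], strat).p_value > 0.001

    def test_expression_strictly_decreasing_without_noise(self):
        config = SimulationConfig(gamma=2.0, expression_noise_sd=1e-12, seed=9)
        idx = np.array([0.0, 10.0, 20.0, 30.0])
        ct, _ = simulate_outcomes(idx, config)
        wide = ct.pivot_table(index="sample_id", columns="gene", values="ct")
        dct = (wide["MEG3"] - wide["GAPDH"]).to_numpy()
        fold = 2.0 ** (-(dct - dct[0]))
        assert np.all(np.diff(fold) < 0)

    def test_high_index_stratum_has_shorter_median_survival(self):
        config = SimulationConfig(beta=1.0, seed=10)
        idx = np.concatenate([np.full(1000, 5.0), np.full(1000, 25.0)])
        _, surv = simulate_outcomes(idx, config)
        lo = km_estimate(surv["time"][:1000], surv["event"][:1000])
        hi = km_estimate(surv["time"][1000:], surv["event"][1000:])
        assert hi.median < lo.median

    def test_invalid_index_values_rejected(self):
        with pytest.raises(ValueError):
            simulate_outcomes([], SimulationConfig())
        with pytest.raises(ValueError):
            simulate_outcomes([np.nan], SimulationConfig())
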