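"""Generator ground-truth and determinism properties."""

import numpy as np
import pandas as pd
import pytest

import lacprofiler as lp
from lacprofiler.synthetic import (
    DEFAULT_TMG_LADDER,
    GENOTYPE_LABELS,
    hill_fraction,
)


class TestHill:
    def test_half_at_k_for_any_steepness(self):
        for h in (0.5, 1, 2, 5.6, 20):
            assert hill_fraction(25.0, 25.0, h) == pytest.approx(0.5, abs=1e-12)

    def test_zero_concentration_gives_zero(self):
        assert hill_fraction(0.0, 25.0, 5.6) == 0.0

    def test_known_point(self):
        # 20^6 / (20^6 + 25^6) evaluated directly
        expected = 20.0**6 / (20.0**6 + 25.0**6)
        assert hill_fraction(20.0, 25.0, 6.0) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.2077, abs=5e-4)


class TestFlowPanel:
    def test_fixed_seed_bit_identical(self):
        p = lp.FlowSimParams(seed=3, n_events=2000)
        a = lp.generate_flow_panel(p, [0.0, 25.0, 100.0])
        b = lp.generate_flow_panel(p, [0.0, 25.0, 100.0])
        for conc in a:
            pd.testing.assert_frame_equal(a[conc], b[conc])

    def test_constitutive_mean_flat(self):
        p = lp.FlowSimParams(response_class="constitutive", seed=5, n_events=5000)
        panel = lp.generate_flow_panel(p, [0.0, 1.0, 10.0, 100.0])
        means = [panel[c]["GFP_true"].mean() for c in panel]
        assert max(means) / min(means) < 2.0

    def test_bimodal_induced_fraction_matches_hill(self):
        p = lp.FlowSimParams(half_max_conc=25.0, hill_coefficient=6.0,
                             seed=11, n_events=20000)
        panel = lp.generate_flow_panel(p, [0.0, 20.0, 100.0])
        gfp = panel[20.0]["GFP_true"]
        # cells split cleanly: low mode median 1.5, high mode 84
        frac_high = float((gfp > 10).mean())
        expected = 20.0**6 / (20.0**6 + 25.0**6)
        assert frac_high == pytest.approx(expected, abs=0.01)

    def test_ladder_must_include_zero(self):
        with pytest.raises(ValueError):
            lp.generate_flow_panel(lp.FlowSimParams(), [1.0, 10.0])
        with pytest.raises(ValueError):
            lp.generate_flow_panel(lp.FlowSimParams(), [])

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            lp.FlowSimParams(response_class="sigmoid")

    def test_spillover_mixing_present_in_observed(self):
        p = lp.FlowSimParams(seed=2, n_events=1000)
        panel = lp.generate_flow_panel(p, [0.0, 100.0])
        ev = panel[100.0]
        np.testing.assert_allclose(
            ev["FL2"], 0.02 * ev["GFP_true"] + ev["RFP_true"], rtol=1e-12
        )


class TestGrowthCurve:
    def test_noise_free_closed_form(self):
        p = lp.GrowthSimParams(lag1=0.0, mu1=0.5, diauxic=False,
                               od_start=0.06, od_max=0.6, noise_sd=0.0)
        curve = lp.generate_growth_curve(p)
        grow = curve.od600 < 0.6
        np.testing.assert_allclose(
            curve.od600[grow], 0.06 * np.exp(0.5 * curve.time[grow]), rtol=1e-12
        )

    def test_diauxic_plateau_duration_exact(self):
        p = lp.GrowthSimParams(lag2=0.5, noise_sd=0.0)
        curve = lp.generate_growth_curve(p)
        on_plateau = np.isclose(curve.od600, p.od_break)
        t_plateau = curve.time[on_plateau]
        # plateau spans exactly lag2 (up to grid quantization at its ends)
        assert t_plateau.max() - t_plateau.min() == pytest.approx(
            0.5, abs=2 * curve.sample_interval
        )

    def test_piecewise_log_linear_residuals_zero(self):
        p = lp.GrowthSimParams(noise_sd=0.0)
        curve = lp.generate_growth_curve(p)
        # within phase 1 the log curve is exactly linear
        in_phase = (curve.time >= p.lag1) & (curve.od600 < p.od_break)
        y = np.log(curve.od600[in_phase])
        t = curve.time[in_phase]
        coef = np.polyfit(t, y, 1)
        assert np.max(np.abs(y - np.polyval(coef, t))) < 1e-10
        assert coef[0] == pytest.approx(p.mu1, rel=1e-10)

    def test_invalid_od_ordering(self):
        with pytest.raises(ValueError):
            lp.GrowthSimParams(od_start=0.3, od_break=0.2)

    def test_duration_too_short(self):
        with pytest.raises(ValueError):
            lp.generate_growth_curve(lp.GrowthSimParams(), duration=1.0)

    def test_seeded_noise_reproducible(self):
        a = lp.generate_growth_curve(lp.GrowthSimParams(seed=9))
        b = lp.generate_growth_curve(lp.GrowthSimParams(seed=9))
        np.testing.assert_array_equal(a.od600, b.od600)


class TestCompetitionSim:
    def test_neutral_fitness_recovers_one(self):
        a = lp.generate_competition(lp.CompetitionSimParams(true_fitness=1.0))
        assert lp.relative_fitness(a) == pytest.approx(1.0, abs=1e-12)

    def test_exact_sampling_inverts_to_truth(self):
        a = lp.generate_competition(lp.CompetitionSimParams(true_fitness=1.08))
        assert lp.relative_fitness(a) == pytest.approx(1.08, abs=1e-7)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            lp.CompetitionSimParams(true_fitness=0.0)
        with pytest.raises(ValueError):
            lp.CompetitionSimParams(cycles=0)
        with pytest.raises(ValueError):
            lp.CompetitionSimParams(dilution_factor=1.0)

    def test_poisson_sampling_deterministic_given_seed(self):
        p = lp.CompetitionSimParams(true_fitness=1.05, count_sampling="poisson", seed=4)
        a, b = lp.generate_competition(p), lp.generate_competition(p)
        assert (a.n_t0, a.n_r0, a.n_t2, a.n_r2) == (b.n_t0, b.n_r0, b.n_t2, b.n_r2)


class TestSequences:
    @pytest.mark.parametrize("label", GENOTYPE_LABELS)
    def test_label_round_trip(self, label):
        recs = lp.generate_lac_sequences(label)
        call = lp.genotype_clone(str(recs[0].seq), str(recs[1].seq))
        assert call.label == label

    def test_wt_identical_to_reference(self):
        from lacprofiler.genotyping import DEFAULT_REFERENCE

        recs = lp.generate_lac_sequences("wt")
        assert str(recs[0].seq) == DEFAULT_REFERENCE.lacI_amplicon
        assert str(recs[1].seq) == DEFAULT_REFERENCE.lacO1_amplicon

    def test_deletion_removes_one_repeat_unit(self):
        from lacprofiler.genotyping import DEFAULT_REFERENCE as R

        recs = lp.generate_lac_sequences("lacI-(ΔTGGC)")
        assert len(recs[0].seq) == len(R.lacI_amplicon) - 4
        assert str(recs[0].seq).count("TGGC") == 2

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            lp.generate_lac_sequences("lacI-(XYZ)")
        with pytest.raises(ValueError):
            lp.generate_lac_sequences("lacO1-G25A")
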