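"""Compensation, gating, bimodality detection, and profile metrics."""

import numpy as np
import pandas as pd
import pytest

import lacprofiler as lp
from lacprofiler.flow import (
    BimodalityCall,
    ConcentrationRecord,
    GateSpec,
    InducerResponseProfile,
    SpilloverMatrix,
    apply_gate,
    bimodal_range,
    classify_regulation,
    compensate,
    crp_reporter_check,
    detect_bimodality,
    estimate_tmg_half_max,
    fit_scatter_gate,
)


def _record(conc, mean, bimodal):
    call = BimodalityCall(is_bimodal=bimodal, mode_locations=[mean],
                          mode_weights=[1.0], separation=0.0, evidence=0.0)
    return ConcentrationRecord(conc=conc, mean_expression=mean,
                               bimodality=call, n_events=1000)


class TestCompensation:
    def test_identity_spill_is_noop(self, small_panel):
        ev = small_panel[0.0]
        out = compensate(ev, SpilloverMatrix.identity())
        np.testing.assert_allclose(out["FL1"], ev["FL1"], rtol=1e-12)
        np.testing.assert_allclose(out["FL2"], ev["FL2"], rtol=1e-12)

    def test_recovers_true_channels(self, small_panel, spill):
        ev = small_panel[100.0]
        out = compensate(ev, spill)
        np.testing.assert_allclose(out["FL1"], ev["GFP_true"], atol=1e-6)
        np.testing.assert_allclose(out["FL2"], ev["RFP_true"], atol=1e-6)

    def test_single_reporter_control_zeroes_other_channel(self, rng, spill):
        gfp = rng.lognormal(3.0, 0.4, size=2000)
        rfp = np.zeros(2000)
        obs = spill.matrix @ np.vstack([gfp, rfp])
        ev = pd.DataFrame({"FSC": np.ones(2000), "SSC": np.ones(2000),
                           "FL1": obs[0], "FL2": obs[1]})
        out = compensate(ev, spill)
        assert np.abs(out["FL2"]).mean() < 1e-9

    def test_negatives_clamped_and_counted(self):
        ev = pd.DataFrame({"FSC": [1.0], "SSC": [1.0], "FL1": [0.0], "FL2": [1.0]})
        out = compensate(ev, SpilloverMatrix(gfp_to_fl2=0.0, rfp_to_fl1=0.5))
        assert out["FL1"].iloc[0] == 0.0
        assert out.attrs["n_clamped"] == 1

    def test_singular_matrix_rejected(self):
        with pytest.raises(ValueError):
            SpilloverMatrix(gfp_to_fl2=1.0, rfp_to_fl1=0.999999)


class TestGate:
    def test_retention_matches_chi_square_closed_form(self, spill):
        panel = lp.generate_flow_panel(lp.FlowSimParams(seed=21), [0.0, 100.0])
        ev = panel[0.0]
        for thr in (0.5, 1.0, 2.0):
            gate = fit_scatter_gate(ev, threshold=thr)
            gated = apply_gate(ev, gate)
            expected = 1.0 - np.exp(-thr**2 / 2.0)
            assert gated.attrs["gate_retained_fraction"] == pytest.approx(
                expected, abs=0.02
            )

    def test_center_near_true_mean(self):
        errs = []
        for s in range(20):
            panel = lp.generate_flow_panel(lp.FlowSimParams(seed=s), [0.0])
            gate = fit_scatter_gate(panel[0.0])
            errs.append((abs(gate.center[0] - 520.0) / 90.0,
                         abs(gate.center[1] - 310.0) / 60.0))
        mean_err = np.mean(errs, axis=0)
        assert np.all(mean_err < 0.1)

    def test_duplicated_events_give_identical_gate(self, small_panel):
        ev = small_panel[0.0]
        doubled = pd.concat([ev, ev], ignore_index=True)
        g1 = fit_scatter_gate(ev)
        g2 = fit_scatter_gate(doubled)
        assert g1.center == g2.center
        np.testing.assert_allclose(g1.covariance, g2.covariance, rtol=1e-9)

    def test_infinite_threshold_retains_all(self, small_panel):
        ev = small_panel[0.0]
        gate = fit_scatter_gate(ev, threshold=np.inf)
        assert len(apply_gate(ev, gate)) == len(ev)

    def test_tiny_threshold_retains_essentially_none(self, small_panel):
        ev = small_panel[0.0]
        gate = fit_scatter_gate(ev, threshold=1e-6)
        assert len(apply_gate(ev, gate)) == 0

    def test_matches_brute_force_membership(self, small_panel):
        ev = small_panel[0.0].head(1000)
        gate = fit_scatter_gate(small_panel[0.0])
        gated = apply_gate(ev, gate)
        inv = np.linalg.inv(gate.covariance)
        keep = []
        for _, row in ev.iterrows():
            d = np.array([row.FSC, row.SSC]) - np.asarray(gate.center)
            keep.append(float(d @ inv @ d) <= gate.mahalanobis_threshold**2)
        assert len(gated) == sum(keep)
        np.testing.assert_array_equal(
            gated[["FSC", "SSC"]].to_numpy(), ev.loc[keep, ["FSC", "SSC"]].to_numpy()
        )

    def test_too_few_events_rejected(self):
        ev = pd.DataFrame({"FSC": np.arange(100.0), "SSC": np.arange(100.0),
                           "FL1": np.ones(100), "FL2": np.ones(100)})
        with pytest.raises(ValueError):
            fit_scatter_gate(ev)


class TestBimodality:
    def test_single_mode_never_flagged(self, rng):
        flagged = 0
        for _ in range(50):
            x = rng.lognormal(np.log(30), 0.4, size=2000)
            flagged += detect_bimodality(x).is_bimodal
        assert flagged == 0

    def test_balanced_well_separated_mixture_flagged(self, rng):
        weights = []
        for _ in range(50):
            lo = rng.lognormal(np.log(2), 0.3, size=1000)
            hi = rng.lognormal(np.log(2) + 1.5 * np.log(10), 0.3, size=1000)
            call = detect_bimodality(np.r_[lo, hi])
            assert call.is_bimodal
            weights.append(call.mode_weights[0])
        assert np.mean(np.abs(np.array(weights) - 0.5)) < 0.05

    def test_minority_below_floor_not_flagged(self, rng):
        lo = rng.lognormal(np.log(2), 0.3, size=3980)
        hi = rng.lognormal(np.log(2) + 2 * np.log(10), 0.3, size=20)  # 0.5%
        assert not detect_bimodality(np.r_[lo, hi]).is_bimodal

    def test_modes_sorted_ascending(self, rng):
        lo = rng.lognormal(np.log(2), 0.3, size=1000)
        hi = rng.lognormal(np.log(200), 0.3, size=1000)
        call = detect_bimodality(np.r_[lo, hi])
        assert call.mode_locations[0] < call.mode_locations[1]

    def test_insufficient_events_rejected(self, rng):
        with pytest.raises(ValueError):
            detect_bimodality(rng.lognormal(0, 1, size=50))


class TestHalfMax:
    def test_exact_grid_hit(self):
        conc = [0, 5, 10, 20, 40]
        means = [1, 1, 51, 101, 101]
        assert estimate_tmg_half_max(conc, means) == 10.0

    def test_log_linear_interpolation(self):
        # half level 50 crossed between 10 and 100:
        # 10^(1 + (50-25)/(100-25)) = 10^(4/3)
        est = estimate_tmg_half_max([0, 10, 100], [0, 25, 100])
        assert est == pytest.approx(10 ** (4.0 / 3.0), rel=1e-9)
        assert est == pytest.approx(21.5, abs=0.05)

    def test_flat_profile_has_no_half_max(self):
        with pytest.warns(UserWarning):
            assert estimate_tmg_half_max([0, 10, 100], [10, 10, 10]) is None

    def test_monotone_in_generator_half_max(self):
        ests = []
        for k in (2.0, 4.0, 8.0, 25.0, 50.0):
            p = lp.FlowSimParams(response_class="graded", half_max_conc=k,
                                 seed=13, n_events=4000)
            panel = lp.generate_flow_panel(p)
            conc = sorted(panel)
            means = [panel[c]["GFP_true"].mean() for c in conc]
            ests.append(estimate_tmg_half_max(conc, means))
        assert all(a < b for a, b in zip(ests, ests[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            estimate_tmg_half_max([0, 10], [0, 10])
        with pytest.raises(ValueError):
            estimate_tmg_half_max([1, 10, 100], [0, 5, 10])


class TestBimodalRangeAndClass:
    def test_no_flags_gives_empty(self):
        recs = [_record(c, 10, False) for c in (0, 10, 20)]
        assert bimodal_range(recs) is None

    def test_contiguous_flags_span(self):
        recs = [_record(c, 10, c in (15, 20, 25, 30)) for c in (0, 10, 15, 20, 25, 30, 50)]
        assert bimodal_range(recs) == (15, 30)

    def test_gap_warns_but_spans(self):
        recs = [_record(c, 10, c in (10, 30)) for c in (0, 10, 20, 30)]
        with pytest.warns(UserWarning):
            assert bimodal_range(recs) == (10, 30)

    def test_constitutive_precedence(self):
        recs = [_record(c, m, False) for c, m in [(0, 60), (10, 70), (100, 100)]]
        prof = InducerResponseProfile(records=recs, tmg_half_max=None,
                                      bimodal_range=None, max_expression=100)
        cls, trigger = classify_regulation(prof)
        assert cls == "constitutive"
        assert "fold" in trigger

    def test_bimodal_class(self):
        recs = [_record(0, 1, False), _record(15, 20, True),
                _record(30, 70, True), _record(100, 80, False)]
        prof = InducerResponseProfile(records=recs, tmg_half_max=20.0,
                                      bimodal_range=(15, 30), max_expression=80)
        assert classify_regulation(prof)[0] == "bimodal"

    def test_lower_threshold_graded_class(self):
        recs = [_record(0, 1, False), _record(4, 40, False), _record(100, 80, False)]
        prof = InducerResponseProfile(records=recs, tmg_half_max=4.0,
                                      bimodal_range=None, max_expression=80)
        assert classify_regulation(prof)[0] == "lower_threshold_graded"


class TestCrpReporter:
    def test_generator_fl2_passes(self, small_panel, spill):
        fl2 = {c: compensate(small_panel[c], spill)["FL2"].to_numpy()
               for c in small_panel}
        report = crp_reporter_check(fl2)
        assert report.passes and report.fold_change < 2

    def test_doubled_top_concentration_fails_fold_change(self, small_panel, spill):
        fl2 = {c: compensate(small_panel[c], spill)["FL2"].to_numpy()
               for c in small_panel}
        fl2[100.0] = fl2[100.0] * 2.0
        report = crp_reporter_check(fl2)
        assert not report.passes and report.fold_change >= 2 and report.all_unimodal

    def test_injected_bimodal_fails_unimodality(self, small_panel, spill, rng):
        fl2 = {c: compensate(small_panel[c], spill)["FL2"].to_numpy()
               for c in small_panel}
        n = len(fl2[20.0])
        bimodal = np.r_[rng.lognormal(np.log(3), 0.3, n // 2),
                        rng.lognormal(np.log(300), 0.3, n - n // 2)]
        fl2[20.0] = bimodal
        report = crp_reporter_check(fl2)
        assert not report.all_unimodal and not report.passes
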