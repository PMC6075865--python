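"""Amperometric detection, kinetics, foot and flicker measurements."""

import numpy as np
import pandas as pd
import pytest

from conftest import isolated_event_params, match_events
from exophys.ampero import (
    CurrentTrace,
    FootParameters,
    cell_summary,
    detect_foot,
    detect_spikes,
    event_frequency,
    foot_flickers,
    spike_kinetics,
)
from exophys.errors import ParameterError
from exophys.filters import gaussian_lowpass
from exophys.synthio import (
    AmperoSimParams,
    gen_amperometric_trace,
    lognormal_shape_from_kinetics,
    spike_template,
)


def make_trace(i_pA, rate=25_000.0):
    n = len(i_pA)
    return CurrentTrace(np.arange(n) / rate, np.asarray(i_pA, float),
                        sample_rate_hz=rate, filter_cutoff_hz=2000.0)


class TestDetection:
    def test_noise_only_trace_empty(self):
        p = AmperoSimParams(event_rate_hz=0.0, duration_s=10.0, seed=0)
        tr, _ = gen_amperometric_trace(p)
        assert detect_spikes(tr) == []

    def test_eligibility_labels_from_truth(self):
        """Events below the charge floor are detected but not frequency-eligible."""
        events = [{"t_s": 0.4 + 0.4 * i} for i in range(8)]
        events += [{"t_s": 0.4 + 0.4 * (8 + i), "amp_pA": 5.0, "half_width_ms": 1.0}
                   for i in range(2)]  # charge ~ 6 fC, below the 10 fC floor
        p = AmperoSimParams(seed=2, duration_s=4.6, events=events,
                            baseline_noise_sd_pA=0.0, foot_prob=0.0)
        tr, truth = gen_amperometric_trace(p)
        detected = detect_spikes(tr)
        assert len(detected) == 10
        assert truth.eligible_frequency.sum() == 8
        assert sum(ev.eligible_frequency for ev in detected) == 8

    def test_threshold_flag_logic(self):
        """amp 5 pA / charge 50 fC: frequency-eligible but not kinetics-eligible."""
        p = isolated_event_params(0, n_events=1, baseline_noise_sd_pA=0.0,
                                  foot_prob=0.0,
                                  event_kwargs={"amp_pA": 5.0, "half_width_ms": 8.0})
        tr, truth = gen_amperometric_trace(p)
        assert 10 < truth.charge_fC.iloc[0] < 5000
        ev = detect_spikes(tr)[0]
        assert ev.eligible_frequency and not ev.eligible_kinetics

    def test_nan_samples_flagged(self):
        p = isolated_event_params(1, n_events=2, baseline_noise_sd_pA=0.0,
                                  foot_prob=0.0)
        tr, _ = gen_amperometric_trace(p)
        pk = int(np.argmax(tr.i_pA))
        tr.i_pA[pk] = np.nan
        evs = detect_spikes(tr)
        flagged = [e for e in evs if e.flagged]
        assert len(flagged) >= 1
        assert all(not e.eligible_frequency and not e.eligible_kinetics
                   for e in flagged)

    def test_sensitivity_and_fdr(self):
        """Detection recovers >=95% of well-sized events with <=5% FDR."""
        tp = fn = fp = 0
        for seed in range(15):
            p = AmperoSimParams(seed=seed, duration_s=10.0, event_rate_hz=0.5)
            tr, truth = gen_amperometric_trace(p)
            evs = [e for e in detect_spikes(tr) if e.eligible_frequency]
            big = truth[(truth.amp_pA >= 3 * p.baseline_noise_sd_pA)
                        & truth.eligible_frequency]
            pairs, unmatched, false_pos = match_events(big, evs)
            tp += len(pairs)
            fn += len(unmatched)
            fp += len(false_pos)
        assert tp / (tp + fn) >= 0.95
        assert fp / max(tp + fp, 1) <= 0.05


class TestKinetics:
    def test_triangular_pulse_closed_form(self):
        """Symmetric triangle, amp 20 pA over 4 ms: half-width 2 ms,
        50-90% rise 0.8 ms."""
        rate = 25_000.0
        n = int(rate * 3)
        i = np.zeros(n)
        t0 = int(1.0 * rate)
        base = int(0.004 * rate)  # 4 ms
        up = np.linspace(0, 20, base // 2 + 1)
        i[t0:t0 + base // 2 + 1] = up
        i[t0 + base // 2:t0 + base] = np.linspace(20, 0, base // 2)
        tr = make_trace(i)
        ev = detect_spikes(tr)[0]
        spike_kinetics(ev, tr)
        assert ev.half_width_ms == pytest.approx(2.0, abs=0.05)
        assert ev.rise_50_90_ms == pytest.approx(0.8, abs=0.05)

    def test_rectangular_pulse(self):
        rate = 25_000.0
        n = int(rate * 3)
        i = np.zeros(n)
        w_ms, amp = 4.0, 12.0
        t0 = int(1.0 * rate)
        i[t0:t0 + int(w_ms * rate / 1e3)] = amp
        tr = make_trace(i)
        ev = detect_spikes(tr)[0]
        spike_kinetics(ev, tr)
        assert ev.half_width_ms == pytest.approx(w_ms, abs=0.1)
        assert ev.charge_fC == pytest.approx(amp * w_ms, rel=0.02)

    def test_template_kinetics_vs_filtered_oracle(self):
        """Measured rise/half-width match a numeric oracle applied to the
        low-pass-filtered spike template."""
        p = isolated_event_params(3, n_events=5, baseline_noise_sd_pA=0.0,
                                  foot_prob=0.0)
        tr, truth = gen_amperometric_trace(p)
        # oracle: evaluate the filtered template on a fine grid
        tm, s = lognormal_shape_from_kinetics(p.rise_50_90_ms, p.half_width_ms)
        dt_ms = 1e3 / p.sample_rate_hz
        tt = np.arange(0.0, 40.0, dt_ms)
        tpl = gaussian_lowpass(spike_template(tt, 1.0, tm, s),
                               p.sample_rate_hz, p.filter_cutoff_hz)
        pk = int(tpl.argmax())
        t50r = np.interp(0.5 * tpl[pk], tpl[:pk + 1], tt[:pk + 1])
        t90r = np.interp(0.9 * tpl[pk], tpl[:pk + 1], tt[:pk + 1])
        t50f = np.interp(0.5 * tpl[pk], tpl[pk:][::-1], tt[pk:][::-1])
        for ev in detect_spikes(tr):
            spike_kinetics(ev, tr)
            assert ev.rise_50_90_ms == pytest.approx(t90r - t50r, abs=2 * dt_ms)
            assert ev.half_width_ms == pytest.approx(t50f - t50r, abs=2 * dt_ms)

    def test_kinetics_requires_eligibility(self):
        p = isolated_event_params(0, n_events=1, baseline_noise_sd_pA=0.0,
                                  foot_prob=0.0,
                                  event_kwargs={"amp_pA": 5.0, "half_width_ms": 8.0})
        tr, _ = gen_amperometric_trace(p)
        ev = detect_spikes(tr)[0]
        with pytest.raises(ParameterError):
            spike_kinetics(ev, tr)

    def test_charge_additivity(self):
        """Charge of disjoint events in one trace equals the sum of the
        per-event charges measured separately."""
        p = isolated_event_params(4, n_events=4, baseline_noise_sd_pA=0.0,
                                  foot_prob=0.0)
        tr, truth = gen_amperometric_trace(p)
        evs = detect_spikes(tr)
        total = sum(ev.charge_fC for ev in evs)
        assert total == pytest.approx(truth.charge_fC.sum(), rel=0.02)


class TestFoot:
    def test_no_foot_event(self):
        p = isolated_event_params(5, n_events=3, baseline_noise_sd_pA=0.0,
                                  foot_prob=0.0)
        tr, _ = gen_amperometric_trace(p)
        for ev in detect_spikes(tr):
            foot = detect_foot(ev, tr)
            assert foot is None or foot.duration_ms < 1.0

    def test_foot_duration_and_charge(self):
        """A 4 ms, 6 pA foot: duration within filter tolerance, charge ~24 fC."""
        p = isolated_event_params(
            6, n_events=6, baseline_noise_sd_pA=0.0,
            event_kwargs={"has_foot": True, "foot_duration_ms": 4.0,
                          "foot_amp_pA": 6.0, "n_flickers": 0},
        )
        tr, truth = gen_amperometric_trace(p)
        for ev in detect_spikes(tr):
            foot = detect_foot(ev, tr)
            assert foot is not None
            assert foot.duration_ms == pytest.approx(4.0, abs=1.0)
            assert foot.charge_fC == pytest.approx(24.0, rel=0.35)
            assert foot.analyzable

    def test_short_foot_not_analyzable(self):
        p = isolated_event_params(
            7, n_events=3, baseline_noise_sd_pA=0.0,
            event_kwargs={"has_foot": True, "foot_duration_ms": 1.2,
                          "foot_amp_pA": 8.0, "n_flickers": 0},
        )
        tr, _ = gen_amperometric_trace(p)
        found = 0
        for ev in detect_spikes(tr):
            foot = detect_foot(ev, tr)
            if foot is not None:
                found += 1
                assert not foot.analyzable
                with pytest.raises(ParameterError):
                    foot_flickers(foot, tr)
        assert found >= 1


class TestFlickers:
    def _trace_with_flickers(self, n_flickers, slope=12.0, seed=0):
        p = isolated_event_params(
            seed, n_events=5, baseline_noise_sd_pA=0.0,
            flicker_amp_pA_per_ms=slope,
            event_kwargs={"has_foot": True, "foot_duration_ms": 8.0,
                          "foot_amp_pA": 6.0, "n_flickers": n_flickers},
        )
        return gen_amperometric_trace(p)

    def test_smooth_ramp_foot_has_no_flickers(self):
        tr, _ = self._trace_with_flickers(0)
        for ev in detect_spikes(tr):
            foot = detect_foot(ev, tr)
            foot_flickers(foot, tr)
            assert foot.flicker_count == 0

    def test_suprathreshold_pulses_counted_exactly(self):
        """Five 12 pA/ms pulses in an 8 ms foot: count 5, freq = 5/duration."""
        tr, truth = self._trace_with_flickers(5, slope=12.0, seed=1)
        for ev in detect_spikes(tr):
            foot = detect_foot(ev, tr)
            foot_flickers(foot, tr)
            assert foot.flicker_count == 5
            assert foot.flicker_freq_per_ms == pytest.approx(
                5 / foot.duration_ms, rel=1e-12)

    def test_subthreshold_pulses_not_counted(self):
        tr, _ = self._trace_with_flickers(5, slope=4.0, seed=2)
        for ev in detect_spikes(tr):
            foot = detect_foot(ev, tr)
            foot_flickers(foot, tr)
            assert foot.flicker_count == 0

    def test_threshold_monotonicity(self):
        """Raising the flicker threshold never increases the count."""
        tr, _ = self._trace_with_flickers(4, slope=12.0, seed=3)
        ev = detect_spikes(tr)[0]
        foot = detect_foot(ev, tr)
        counts = []
        for thr in (3.0, 6.0, 9.0, 15.0):
            foot_flickers(foot, tr, threshold_pA_per_ms=thr)
            counts.append(foot.flicker_count)
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_offset_invariance(self):
        """A trace-wide current offset changes neither count nor frequency."""
        tr, _ = self._trace_with_flickers(3, slope=12.0, seed=4)
        def freqs(trace):
            out = []
            for ev in detect_spikes(trace):
                foot = detect_foot(ev, trace)
                foot_flickers(foot, trace)
                out.append((foot.flicker_count, round(foot.flicker_freq_per_ms, 6)))
            return out
        shifted = CurrentTrace(tr.time_s, tr.i_pA + 20.0,
                               sample_rate_hz=tr.sample_rate_hz,
                               filter_cutoff_hz=tr.filter_cutoff_hz)
        assert freqs(tr) == freqs(shifted)


class TestAggregation:
    def test_event_frequency(self):
        p = isolated_event_params(8, n_events=8, baseline_noise_sd_pA=0.0,
                                  foot_prob=0.0)
        tr, _ = gen_amperometric_trace(p)
        evs = detect_spikes(tr)
        assert event_frequency(tr, evs) == pytest.approx(8 / tr.duration_s)
        assert event_frequency(tr, []) == 0.0

    def test_cell_summary_single_cell(self):
        df = pd.DataFrame({"amp_pA": [1.0, 2.0, 9.0]})
        out = cell_summary({"c1": df}, parameters=("amp_pA",),
                           exclude_small_cells=False)
        assert out.loc["c1", "amp_pA"] == 2.0
        assert out.loc["mean_of_medians", "amp_pA"] == 2.0

    def test_cell_summary_equal_weighting(self):
        """Two cells with medians 2 and 4 average to 3 whatever their sizes."""
        c1 = pd.DataFrame({"amp_pA": [2.0] * 100})
        c2 = pd.DataFrame({"amp_pA": [4.0] * 3})
        out = cell_summary({"c1": c1, "c2": c2}, parameters=("amp_pA",),
                           exclude_small_cells=False)
        assert out.loc["mean_of_medians", "amp_pA"] == 3.0

    def test_cell_summary_small_cell_exclusion(self):
        big = pd.DataFrame({"amp_pA": np.full(25, 10.0)})
        small = pd.DataFrame({"amp_pA": [99.0] * 5})
        out = cell_summary({"big": big, "small": small}, parameters=("amp_pA",))
        assert out.loc["mean_of_medians", "amp_pA"] == 10.0
        assert out.loc["small", "included"] == False  # noqa: E712

    def test_cell_summary_median_recovery(self):
        """Per-cell medians of generated events recover the generating median
        within order-statistic error."""
        rng = np.random.default_rng(0)
        cells = {}
        for c in range(6):
            amps = 35.0 * np.exp(rng.normal(0, 0.45, size=60))
            cells[f"c{c}"] = pd.DataFrame({"amp_pA": amps})
        out = cell_summary(cells, parameters=("amp_pA",))
        assert out.loc["mean_of_medians", "amp_pA"] == pytest.approx(35.0, rel=0.15)

    def test_empty_input_rejected(self):
        with pytest.raises(ParameterError):
            cell_summary({})
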