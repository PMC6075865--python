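"""Seeded generators of synthetic exocytosis data.

Three generators produce data with the statistical structure the analysis
modules assume, together with the ground truth needed for recovery tests:

* :func:`gen_flash_trace` — flash-evoked capacitance responses: a tonic
  pre-flash ramp, then (after a configurable exocytotic delay) a double
  exponential burst plus linear sustained component, with additive Gaussian
  noise.
* :func:`gen_amperometric_trace` — amperometric current traces sampled at
  25 kHz and low-pass filtered at 2 kHz, containing Poisson-placed spike
  events with optional prespike feet and injected fusion-pore flickers,
  plus a ground-truth event table.
* :func:`gen_assembly_timecourse` — second-order SNARE-assembly time
  courses with multiplicative noise.

All randomness flows from the single integer ``seed`` carried by each
parameter set; identical parameters and seed give bitwise-identical output.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from exophys.ampero import (
    AMP_FREQ_MIN_PA,
    AMP_KINETICS_MIN_PA,
    CHARGE_RANGE_FC,
    CurrentTrace,
)
from exophys.capfit import CapacitanceTrace
from exophys.errors import ParameterError
from exophys.filters import gaussian_lowpass, gaussian_sigma_samples
from exophys.snarekin import AssemblyTimeCourse

__all__ = [
    "FlashSimParams",
    "AmperoSimParams",
    "AssemblySimParams",
    "gen_flash_trace",
    "gen_amperometric_trace",
    "gen_assembly_timecourse",
    "spike_template",
    "lognormal_shape_from_kinetics",
]


# ---------------------------------------------------------------------------
# flash-evoked capacitance
# ---------------------------------------------------------------------------

@dataclass
class FlashSimParams:
    """Ground-truth parameters of a flash-evoked capacitance trace.

    Defaults reflect a typical mouse chromaffin cell: ~5 pF resting
    capacitance, an exocytotic burst of a few hundred fF split between a
    fast (RRP, tens of ms) and a slow (SRP, hundreds of ms) component, a
    sustained rate of tens of fF/s, and a few fF/s of tonic secretion
    before the flash.
    """

    A0_fF: float = 5000.0
    A_rrp_fF: float = 150.0
    tau_rrp_ms: float = 20.0
    A_srp_fF: float = 200.0
    tau_srp_ms: float = 250.0
    k_sus_fFps: float = 15.0
    flash_time_s: float = 0.5
    onset_delay_ms: float = 3.0
    pre_rate_fFps: float = 0.0
    noise_sd_fF: float = 5.0
    duration_s: float = 5.5
    sample_rate_hz: float = 2000.0
    seed: int = 0

    def validate(self) -> None:
        if not self.tau_rrp_ms < self.tau_srp_ms:
            raise ParameterError("tau_rrp_ms must be < tau_srp_ms")
        for name in ("A_rrp_fF", "A_srp_fF", "noise_sd_fF", "onset_delay_ms",
                     "duration_s", "sample_rate_hz"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        if self.sample_rate_hz <= 0 or self.duration_s <= 0:
            raise ParameterError("duration_s and sample_rate_hz must be positive")
        onset = self.flash_time_s + self.onset_delay_ms * 1e-3
        if not (0.0 < onset < self.duration_s):
            raise ParameterError("flash_time_s + onset delay must lie within (0, duration_s)")


def flash_waveform(t_s: np.ndarray, p: FlashSimParams) -> np.ndarray:
    """Noiseless flash response: tonic ramp, then burst + sustained release.

    The flash-locked component starts from the back-extrapolated baseline
    value at flash + delay (no step), so the secretory delay is recoverable
    by construction.
    """
    onset = p.flash_time_s + p.onset_delay_ms * 1e-3
    base = p.A0_fF + p.pre_rate_fFps * t_s
    tp_ms = np.clip((t_s - onset) * 1e3, 0.0, None)
    burst = (
        p.A_rrp_fF * -np.expm1(-tp_ms / p.tau_rrp_ms)
        + p.A_srp_fF * -np.expm1(-tp_ms / p.tau_srp_ms)
        + p.k_sus_fFps * tp_ms * 1e-3
    )
    # baseline frozen at its onset value once the burst starts
    base_after = p.A0_fF + p.pre_rate_fFps * onset
    return np.where(t_s < onset, base, base_after + burst)


def gen_flash_trace(params: FlashSimParams) -> CapacitanceTrace:
    """Generate one flash-evoked capacitance trace (additive Gaussian noise)."""
    params.validate()
    n = int(round(params.duration_s * params.sample_rate_hz))
    t = np.arange(n) / params.sample_rate_hz
    cm = flash_waveform(t, params)
    if params.noise_sd_fF > 0:
        rng = np.random.default_rng(params.seed)
        cm = cm + rng.normal(0.0, params.noise_sd_fF, size=n)
    return CapacitanceTrace(
        time_s=t,
        cm_fF=cm,
        flash_time_s=params.flash_time_s,
        meta={"generator": "gen_flash_trace", "params": asdict(params)},
    )


# ---------------------------------------------------------------------------
# amperometry
# ---------------------------------------------------------------------------

_LN_ALPHA = math.sqrt(2.0 * math.log(2.0))          # 50% level
_LN_BETA = math.sqrt(2.0 * math.log(1.0 / 0.9))    # 90% level


def lognormal_shape_from_kinetics(rise_50_90_ms: float, half_width_ms: float
                                  ) -> tuple[float, float]:
    """Solve the log-normal pulse shape (t_mode, sigma) from its kinetics.

    The pulse ``i(t) = A exp(-(ln(t/tm))^2 / (2 s^2))`` has
    ``half_width = 2 tm sinh(s a)`` and
    ``rise_50_90 = tm (exp(-s b) - exp(-s a))`` with ``a = sqrt(2 ln 2)``
    and ``b = sqrt(2 ln(1/0.9))``; the ratio rise/half-width fixes ``s``
    (it is monotone, with supremum ``(a-b)/(2a) ~ 0.305`` as s -> 0) and
    the half-width then fixes ``tm``.
    """
    r = rise_50_90_ms / half_width_ms
    r_max = (_LN_ALPHA - _LN_BETA) / (2.0 * _LN_ALPHA)
    if not 0 < r < r_max:
        raise ParameterError(
            f"rise_50_90/half_width ratio {r:.3f} outside (0, {r_max:.3f}) "
            "achievable by a log-normal pulse"
        )

    def ratio(s: float) -> float:
        return (math.exp(-s * _LN_BETA) - math.exp(-s * _LN_ALPHA)) / (
            2.0 * math.sinh(s * _LN_ALPHA)
        ) - r

    s = brentq(ratio, 1e-6, 20.0)
    tm = half_width_ms / (2.0 * math.sinh(s * _LN_ALPHA))
    return tm, s


def spike_template(t_ms: np.ndarray, amp_pA: float, t_mode_ms: float,
                   sigma: float) -> np.ndarray:
    """Log-normal spike pulse evaluated at ``t_ms`` (zero for t <= 0)."""
    out = np.zeros_like(t_ms, dtype=float)
    pos = t_ms > 0
    out[pos] = amp_pA * np.exp(-(np.log(t_ms[pos] / t_mode_ms)) ** 2 / (2.0 * sigma ** 2))
    return out


def spike_template_charge_fC(amp_pA: float, t_mode_ms: float, sigma: float) -> float:
    """Closed-form integral of the log-normal pulse (pA*ms = fC)."""
    return amp_pA * t_mode_ms * sigma * math.sqrt(2.0 * math.pi) * math.exp(sigma ** 2 / 2.0)


@dataclass
class AmperoSimParams:
    """Parameters of the synthetic amperometric recording.

    Event sizes follow a log-normal amplitude distribution (median
    ``amp_median_pA``, log-SD ``amp_sigma``), the shape typical of
    chromaffin-cell spikes; spike kinetics are set by the 50-90% rise time
    and half-width of a log-normal pulse template.  A fraction
    ``foot_prob`` of events carries a prespike foot realized as a ramp to
    a plateau; flickers are injected into the plateau as derivative pulses
    of slope ``flicker_amp_pA_per_ms`` (rise) followed by a gentle,
    sub-threshold return ramp, so the 6 pA/ms counting threshold can be
    exercised from both sides.  ``baseline_noise_sd_pA`` is the baseline
    noise SD measured on the *filtered* trace (the injected white noise is
    pre-scaled to compensate for the low-pass).
    """

    event_rate_hz: float = 0.5
    amp_median_pA: float = 35.0
    amp_sigma: float = 0.45
    rise_50_90_ms: float = 0.3
    half_width_ms: float = 2.5
    foot_prob: float = 0.5
    foot_duration_median_ms: float = 4.0
    foot_duration_sigma: float = 0.4
    foot_amp_mean_pA: float = 6.0
    foot_amp_sd_pA: float = 1.0
    foot_ramp_slope_pA_per_ms: float = 4.0
    flicker_rate_per_ms: float = 0.5
    flicker_amp_pA_per_ms: float = 12.0
    flicker_duration_ms: float = 0.4
    baseline_noise_sd_pA: float = 1.0
    filter_cutoff_hz: float = 2000.0
    sample_rate_hz: float = 25000.0
    duration_s: float = 10.0
    seed: int = 0
    events: Sequence[dict] | None = None
    """Optional explicit event list overriding Poisson placement; each dict
    may set t_s, amp_pA, half_width_ms, rise_50_90_ms, has_foot,
    foot_duration_ms, foot_amp_pA, n_flickers."""

    def validate(self) -> None:
        if self.duration_s <= 0:
            raise ParameterError("duration_s must be positive")
        if self.sample_rate_hz < 2.0 * self.filter_cutoff_hz:
            raise ParameterError("sample_rate_hz must be >= 2 x filter_cutoff_hz")
        if not 0.0 <= self.foot_prob <= 1.0:
            raise ParameterError("foot_prob must lie in [0, 1]")
        for name in ("event_rate_hz", "flicker_rate_per_ms", "baseline_noise_sd_pA",
                     "foot_duration_median_ms", "flicker_duration_ms"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


def _flicker_waveform(n: int, dt_ms: float, starts_ms: np.ndarray,
                      slope: float, dur_ms: float, t0_ms: float) -> np.ndarray:
    """Sum of flicker bumps: fast rise (counted) then slow 6x-longer return."""
    t = t0_ms + np.arange(n) * dt_ms
    out = np.zeros(n)
    peak = slope * dur_ms
    for st in starts_ms:
        rise_end = st + dur_ms
        fall_end = rise_end + 6.0 * dur_ms
        up = (t >= st) & (t < rise_end)
        down = (t >= rise_end) & (t < fall_end)
        out[up] += slope * (t[up] - st)
        out[down] += peak * (1.0 - (t[down] - rise_end) / (6.0 * dur_ms))
    return out


def gen_amperometric_trace(params: AmperoSimParams
                           ) -> tuple[CurrentTrace, pd.DataFrame]:
    """Generate an amperometric trace plus its ground-truth event table.

    Returns
    -------
    (trace, truth)
        ``truth`` has one row per event: onset/peak times, template
        amplitude and total charge, foot duration/amplitude/charge,
        injected flicker count, and the eligibility labels implied by the
        printed amplitude/charge filters.  Overlapping events superpose.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n = int(round(params.duration_s * params.sample_rate_hz))
    dt_ms = 1e3 / params.sample_rate_hz
    clean = np.zeros(n)

    margin_s = 0.25
    if params.events is not None:
        specs = [dict(ev) for ev in params.events]
    else:
        n_ev = rng.poisson(params.event_rate_hz * params.duration_s)
        t_evs = np.sort(rng.uniform(margin_s, max(params.duration_s - margin_s, margin_s),
                                    size=n_ev))
        specs = [{"t_s": float(te)} for te in t_evs]

    rows = []
    for spec in specs:
        t_ev = float(spec["t_s"])
        amp = float(spec.get("amp_pA",
                             params.amp_median_pA * math.exp(rng.normal(0, params.amp_sigma))))
        hw = float(spec.get("half_width_ms", params.half_width_ms))
        rise = float(spec.get("rise_50_90_ms", params.rise_50_90_ms))
        tm, s = lognormal_shape_from_kinetics(rise, hw)

        has_foot = bool(spec.get("has_foot", rng.random() < params.foot_prob))
        foot_dur = 0.0
        foot_amp = 0.0
        foot_charge = 0.0
        n_flick = 0
        flick_starts = np.empty(0)
        if has_foot:
            foot_dur = float(spec.get(
                "foot_duration_ms",
                params.foot_duration_median_ms * math.exp(rng.normal(0, params.foot_duration_sigma)),
            ))
            foot_amp = float(spec.get(
                "foot_amp_pA",
                max(rng.normal(params.foot_amp_mean_pA, params.foot_amp_sd_pA), 1.0),
            ))
            ramp_ms = foot_amp / params.foot_ramp_slope_pA_per_ms
            ramp_ms = min(ramp_ms, foot_dur)
            plateau_ms = foot_dur - ramp_ms
            # flickers live on the plateau; rise onsets are spaced so each
            # keeps its own suprathreshold derivative run after filtering,
            # and the last rise ends well before the spike upstroke
            min_sep = params.flicker_duration_ms + 0.6
            end_guard = params.flicker_duration_ms + 0.5
            want = spec.get("n_flickers")
            if want is None:
                want = rng.poisson(params.flicker_rate_per_ms * plateau_ms)
            room = max(plateau_ms - end_guard, 0.0)
            capacity = int(1 + room // min_sep) if room > 0 else 0
            n_flick = int(min(want, capacity))
            if n_flick > 0:
                slack = room - (n_flick - 1) * min_sep
                offs = np.sort(rng.uniform(0, slack, size=n_flick)) if slack > 0 else np.zeros(n_flick)
                flick_starts = ramp_ms + offs + min_sep * np.arange(n_flick)

        # --- assemble the event waveform on its local grid --------------
        spike_span_ms = tm * math.exp(s * math.sqrt(2.0 * math.log(1e4))) + 5.0
        ev_len = int(math.ceil((foot_dur + spike_span_ms) / dt_ms)) + 2
        tloc = np.arange(ev_len) * dt_ms
        wave = np.zeros(ev_len)
        if has_foot:
            ramp_ms = foot_amp / params.foot_ramp_slope_pA_per_ms
            ramp_ms = min(ramp_ms, foot_dur)
            wave += np.interp(tloc, [0.0, ramp_ms, foot_dur, foot_dur + 2.0],
                              [0.0, foot_amp, foot_amp, 0.0])
            if n_flick > 0:
                wave += _flicker_waveform(ev_len, dt_ms, flick_starts,
                                          params.flicker_amp_pA_per_ms,
                                          params.flicker_duration_ms, 0.0)
            foot_charge = float(np.trapezoid(
                np.interp(tloc, [0.0, ramp_ms, foot_dur, foot_dur + 2.0],
                          [0.0, foot_amp, foot_amp, 0.0]))) * dt_ms
        wave += spike_template(tloc - foot_dur, amp, tm, s)

        i0 = int(round(t_ev * params.sample_rate_hz))
        i1 = min(i0 + ev_len, n)
        if i0 >= n:
            continue
        clean[i0:i1] += wave[: i1 - i0]

        spike_charge = spike_template_charge_fC(amp, tm, s)
        charge = spike_charge + foot_charge
        rows.append({
            "t_onset_s": t_ev,
            "t_peak_s": t_ev + (foot_dur + tm) * 1e-3,
            "amp_pA": amp,
            "charge_fC": charge,
            "rise_50_90_ms": rise,
            "half_width_ms": hw,
            "has_foot": has_foot,
            "foot_duration_ms": foot_dur if has_foot else np.nan,
            "foot_amp_pA": foot_amp if has_foot else np.nan,
            "foot_charge_fC": foot_charge if has_foot else np.nan,
            "flicker_count": n_flick if has_foot else 0,
            "eligible_frequency": bool(amp > AMP_FREQ_MIN_PA
                                       and CHARGE_RANGE_FC[0] <= charge <= CHARGE_RANGE_FC[1]),
            "eligible_kinetics": bool(amp > AMP_KINETICS_MIN_PA),
        })

    if params.baseline_noise_sd_pA > 0:
        # pre-scale so the stated SD holds after the low-pass
        sigma = gaussian_sigma_samples(params.sample_rate_hz, params.filter_cutoff_hz)
        reduction = math.sqrt(1.0 / (2.0 * math.sqrt(math.pi) * sigma)) if sigma > 0.25 else 1.0
        clean = clean + rng.normal(0.0, params.baseline_noise_sd_pA / reduction, size=n)

    filtered = gaussian_lowpass(clean, params.sample_rate_hz, params.filter_cutoff_hz)

    truth = pd.DataFrame(rows, columns=[
        "t_onset_s", "t_peak_s", "amp_pA", "charge_fC", "rise_50_90_ms",
        "half_width_ms", "has_foot", "foot_duration_ms", "foot_amp_pA",
        "foot_charge_fC", "flicker_count", "eligible_frequency", "eligible_kinetics",
    ])
    trace = CurrentTrace(
        time_s=np.arange(n) / params.sample_rate_hz,
        i_pA=filtered,
        sample_rate_hz=params.sample_rate_hz,
        filter_cutoff_hz=params.filter_cutoff_hz,
        meta={"generator": "gen_amperometric_trace",
              "filter_family": "gaussian",
              "params": {k: v for k, v in asdict(params).items() if k != "events"}},
    )
    return trace, truth


# ---------------------------------------------------------------------------
# SNARE assembly
# ---------------------------------------------------------------------------

@dataclass
class AssemblySimParams:
    """Ground truth for a second-order SNARE-assembly time course.

    Defaults mirror the in vitro assay conditions: limiting reactant at
    3 uM, sampling out to 240 min, and a rate constant giving
    half-saturation within the first hour.  ``cv_noise`` is the
    coefficient of variation of the multiplicative densitometry noise.
    """

    SC0_au: float = 0.05
    SCinf_au: float = 1.0
    A0_M: float = 3e-6
    k_M1s1: float = 140.0
    times_min: Sequence[float] = (0.0, 5.0, 10.0, 20.0, 40.0, 60.0, 120.0, 180.0, 240.0)
    cv_noise: float = 0.1
    seed: int = 0
    group: str = "SNAREs"
    replicate: str = "r0"

    def validate(self) -> None:
        if not (self.SCinf_au > self.SC0_au >= 0):
            raise ParameterError("need SCinf_au > SC0_au >= 0")
        if self.k_M1s1 <= 0 or self.A0_M <= 0:
            raise ParameterError("k_M1s1 and A0_M must be positive")
        t = np.asarray(self.times_min, dtype=float)
        if t.size < 1 or np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ParameterError("times_min must be nonnegative and strictly increasing")
        if self.cv_noise < 0:
            raise ParameterError("cv_noise must be >= 0")


def assembly_law(t_min: np.ndarray, SC0: float, SCinf: float,
                 A0_M: float, k_M1s1: float) -> np.ndarray:
    """Integrated second-order law SC(t) = SC0 + (SCinf-SC0) * A0*k*t / (A0*k*t + 1).

    Follows from A + B -> P with equal initial concentrations A0 = B0;
    time is given in minutes and converted to seconds to match k in
    1/(M*s).
    """
    x = A0_M * k_M1s1 * np.asarray(t_min, dtype=float) * 60.0
    return SC0 + (SCinf - SC0) * x / (x + 1.0)


def gen_assembly_timecourse(params: AssemblySimParams) -> AssemblyTimeCourse:
    """Generate a densitometry time course with multiplicative Gaussian noise."""
    params.validate()
    t = np.asarray(params.times_min, dtype=float)
    v = assembly_law(t, params.SC0_au, params.SCinf_au, params.A0_M, params.k_M1s1)
    if params.cv_noise > 0:
        rng = np.random.default_rng(params.seed)
        v = v * (1.0 + rng.normal(0.0, params.cv_noise, size=t.size))
    return AssemblyTimeCourse(
        times_min=t,
        values_au=np.clip(v, 0.0, None),
        group=params.group,
        replicate=params.replicate,
        meta={"generator": "gen_assembly_timecourse", "params": asdict(params)},
    )
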