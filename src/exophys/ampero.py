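"""Amperometric spike, prespike-foot and flicker analysis.

Carbon-fiber amperometry resolves single-vesicle catecholamine release as
current spikes.  Many spikes are preceded by a small "foot" current that
reports leak of transmitter through the nascent fusion pore; rapid
fluctuations ("flickers") of the foot current derivative report pore
instability.  The analysis chain is:

1. :func:`detect_spikes` — localize events above a running-baseline
   threshold and apply the standard eligibility filters (amplitude > 4 pA
   and charge within 10–5000 fC for frequency analysis; amplitude > 7 pA
   for kinetic analysis).
2. :func:`spike_kinetics` — peak amplitude, charge, 50–90% rise time and
   half-width of the main spike.
3. :func:`detect_foot` — foot segment from the first sustained rise above
   baseline + 3*SD to the main-spike takeoff (second-derivative maximum
   preceding the peak); feet longer than 2 ms are flagged analyzable.
4. :func:`foot_flickers` — the foot-current derivative is low-pass filtered
   at 1.2 kHz and contiguous excursions beyond +-6 pA/ms are counted; the
   flicker frequency is the count divided by the foot duration.  The rms
   noise of the detrended foot current is reported as a
   threshold-independent companion measure.
5. :func:`cell_summary` / :func:`event_frequency` — per-cell medians with
   unweighted (cell-weighted) means across cells, and eligible-event rates.

Charges are in femtocoulombs (1 fC = 1 pA*ms); integrals use the trapezoid
rule on baseline-subtracted current.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

from exophys.errors import ParameterError
from exophys.filters import gaussian_lowpass

__all__ = [
    "CurrentTrace",
    "SpikeEvent",
    "FootParameters",
    "detect_spikes",
    "spike_kinetics",
    "detect_foot",
    "foot_flickers",
    "cell_summary",
    "event_frequency",
    "AMP_FREQ_MIN_PA",
    "CHARGE_RANGE_FC",
    "AMP_KINETICS_MIN_PA",
    "FOOT_MIN_DURATION_MS",
    "FLICKER_THRESHOLD_PA_PER_MS",
    "FLICKER_FILTER_HZ",
]

# Printed eligibility filters for chromaffin-cell amperometry.
AMP_FREQ_MIN_PA = 4.0          # peak amplitude floor for frequency analysis
CHARGE_RANGE_FC = (10.0, 5000.0)
AMP_KINETICS_MIN_PA = 7.0      # peak amplitude floor for kinetic analysis
FOOT_MIN_DURATION_MS = 2.0     # feet shorter than this are not analyzable
FLICKER_THRESHOLD_PA_PER_MS = 6.0
FLICKER_FILTER_HZ = 1200.0     # extra low-pass applied to the derivative


@dataclass
class CurrentTrace:
    """Uniformly sampled amperometric current (oxidation positive, pA)."""

    time_s: np.ndarray
    i_pA: np.ndarray
    sample_rate_hz: float = 25_000.0
    filter_cutoff_hz: float = 2_000.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.i_pA = np.asarray(self.i_pA, dtype=float)
        if self.time_s.shape != self.i_pA.shape or self.time_s.ndim != 1:
            raise ParameterError("time_s and i_pA must be 1-D arrays of equal length")
        if self.time_s.size >= 3:
            dt = np.diff(self.time_s)
            if not np.allclose(dt, dt[0], rtol=1e-6):
                raise ParameterError("sampling must be uniform")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.sample_rate_hz

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0]) + self.dt_s


@dataclass
class FootParameters:
    """Prespike-foot metrics on baseline-subtracted current."""

    duration_ms: float
    charge_fC: float
    amp_pA: float
    rms_noise_pA: float = float("nan")
    flicker_count: int | None = None
    flicker_freq_per_ms: float = float("nan")
    analyzable: bool = False
    start_idx: int = -1
    end_idx: int = -1

    def __post_init__(self) -> None:
        self.analyzable = bool(self.duration_ms > FOOT_MIN_DURATION_MS)


@dataclass
class SpikeEvent:
    """One detected amperometric event."""

    t_peak_s: float
    amp_pA: float
    charge_fC: float
    rise_50_90_ms: float = float("nan")
    half_width_ms: float = float("nan")
    foot: FootParameters | None = None
    eligible_frequency: bool = False
    eligible_kinetics: bool = False
    start_idx: int = -1
    end_idx: int = -1
    peak_idx: int = -1
    flagged: bool = False

    def set_eligibility(self) -> None:
        self.eligible_frequency = bool(
            self.amp_pA > AMP_FREQ_MIN_PA
            and CHARGE_RANGE_FC[0] <= self.charge_fC <= CHARGE_RANGE_FC[1]
        )
        self.eligible_kinetics = bool(self.amp_pA > AMP_KINETICS_MIN_PA)


def _running_baseline(i: np.ndarray, sample_rate_hz: float,
                      window_s: float = 0.2) -> np.ndarray:
    """Running median baseline; robust to sparse events."""
    win = max(3, int(round(window_s * sample_rate_hz)) | 1)
    win = min(win, i.size if i.size % 2 else i.size - 1)
    return median_filter(i, size=win, mode="nearest")


def _baseline_sd(i: np.ndarray, baseline: np.ndarray) -> float:
    """Noise SD from the median absolute deviation of the residual."""
    resid = i - baseline
    mad = np.median(np.abs(resid - np.median(resid)))
    # noiseless traces: MAD is 0 between events; do not fall back to the raw
    # std (dominated by the events themselves)
    return float(1.4826 * mad) if mad > 0 else 1e-9


def detect_spikes(
    trace: CurrentTrace,
    baseline_window_s: float = 0.2,
    detect_sd: float = 4.0,
    hysteresis_sd: float = 2.0,
    min_above_ms: float = 0.2,
) -> list[SpikeEvent]:
    """Detect amperometric events by threshold crossing over a running baseline.

    Detection uses baseline + ``detect_sd``*SD with hysteresis down to
    baseline + ``hysteresis_sd``*SD; the excursion must stay above the
    detection threshold for at least ``min_above_ms`` (rejects isolated
    noise peaks), and event boundaries are taken at the surrounding
    baseline re-crossings.  The printed 4 pA / 10–5000 fC and 7 pA cuts
    are then applied as eligibility flags, not as detection thresholds.
    Events containing NaN samples are flagged and excluded.
    """
    if trace.duration_s < 1.0:
        raise ParameterError("need at least 1 s of data for baseline estimation")
    i = trace.i_pA
    nan_mask = ~np.isfinite(i)
    work = np.where(nan_mask, np.nanmedian(i[~nan_mask]) if (~nan_mask).any() else 0.0, i)
    baseline = _running_baseline(work, trace.sample_rate_hz, baseline_window_s)
    sd = _baseline_sd(work, baseline)
    if sd == 0:
        sd = 1e-12
    excess = work - baseline

    hi = detect_sd * sd
    lo = hysteresis_sd * sd

    min_run = max(1, int(round(min_above_ms * 1e-3 * trace.sample_rate_hz)))

    events: list[SpikeEvent] = []
    n = excess.size
    idx = 0
    while idx < n:
        if excess[idx] > hi:
            run_end = idx
            while run_end < n - 1 and excess[run_end + 1] > hi:
                run_end += 1
            if run_end - idx + 1 < min_run:
                idx = run_end + 1
                continue
            # hysteresis: extend while above the low threshold
            s = idx
            while s > 0 and excess[s - 1] > lo:
                s -= 1
            e = idx
            while e < n - 1 and excess[e + 1] > lo:
                e += 1
            # boundaries at baseline re-crossings
            while s > 0 and excess[s - 1] > 0:
                s -= 1
            while e < n - 1 and excess[e + 1] > 0:
                e += 1
            seg = excess[s:e + 1]
            pk = s + int(np.argmax(seg))
            dt_ms = 1e3 / trace.sample_rate_hz
            # pad one sample each side so edge crossings contribute their
            # half-trapezoid
            qs, qe = max(0, s - 1), min(n - 1, e + 1)
            charge = float(np.trapezoid(np.clip(excess[qs:qe + 1], 0, None))) * dt_ms
            ev = SpikeEvent(
                t_peak_s=float(trace.time_s[pk]),
                amp_pA=float(excess[pk]),
                charge_fC=charge,
                start_idx=s,
                end_idx=e,
                peak_idx=pk,
                flagged=bool(nan_mask[max(0, s - 2):e + 3].any()),
            )
            ev.set_eligibility()
            if ev.flagged:
                ev.eligible_frequency = False
                ev.eligible_kinetics = False
            events.append(ev)
            idx = e + 1
        else:
            idx += 1
    return events


def _crossing_time(t: np.ndarray, y: np.ndarray, level: float,
                   i0: int, i1: int, rising: bool) -> float:
    """Linearly interpolated crossing of ``level`` scanning i0..i1."""
    step = 1 if i1 >= i0 else -1
    prev = i0
    for j in range(i0 + step, i1 + step, step):
        a, b = (prev, j) if step == 1 else (j, prev)
        ya, yb = y[a], y[b]
        crossed = (ya < level <= yb) if rising else (ya >= level > yb)
        if crossed and yb != ya:
            frac = (level - ya) / (yb - ya)
            return float(t[a] + frac * (t[b] - t[a]))
        prev = j
    return float(t[i0])


def spike_kinetics(event: SpikeEvent, trace: CurrentTrace) -> SpikeEvent:
    """Fill main-spike kinetic parameters (in place) and return the event.

    amp = peak minus local baseline; charge = trapezoid integral over the
    event; rise_50_90 = time from 50% to 90% of peak on the rising limb;
    half_width = width at 50% of peak.
    """
    if not event.eligible_kinetics:
        raise ParameterError(
            f"event amplitude {event.amp_pA:.1f} pA below the "
            f"{AMP_KINETICS_MIN_PA:.0f} pA kinetics threshold"
        )
    # pad the segment so the 50% crossings at the event edges are resolvable
    s = max(0, event.start_idx - 2)
    e = min(trace.i_pA.size - 1, event.end_idx + 2)
    pk = event.peak_idx
    t_ms = trace.time_s[s:e + 1] * 1e3
    baseline = _running_baseline(trace.i_pA, trace.sample_rate_hz)
    y = (trace.i_pA - baseline)[s:e + 1]
    pk_rel = pk - s
    peak = y[pk_rel]

    # multi-peak overlap check: another >50%-peak local max separated by a dip
    above = y > 0.5 * peak
    runs = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
    if np.count_nonzero(runs == 1) > 1:
        event.flagged = True
        return event

    t50r = _crossing_time(t_ms, y, 0.5 * peak, pk_rel, 0, rising=True)
    t90r = _crossing_time(t_ms, y, 0.9 * peak, pk_rel, 0, rising=True)
    t50f = _crossing_time(t_ms, y, 0.5 * peak, pk_rel, y.size - 1, rising=False)
    event.rise_50_90_ms = float(t90r - t50r)
    event.half_width_ms = float(t50f - t50r)
    return event


def detect_foot(
    event: SpikeEvent,
    trace: CurrentTrace,
    onset_sd: float = 3.0,
) -> FootParameters | None:
    """Locate and measure the prespike foot of a detected event.

    The foot runs from the first sustained rise above baseline +
    ``onset_sd``*SD to the main-spike takeoff, defined as the maximum of
    the second derivative of the smoothed current preceding the peak.
    Returns ``None`` when no resolvable foot exists (takeoff coincides
    with the event onset).
    """
    s, pk = event.start_idx, event.peak_idx
    baseline = _running_baseline(trace.i_pA, trace.sample_rate_hz)
    sd = _baseline_sd(trace.i_pA, baseline)
    y = trace.i_pA - baseline
    dt_ms = 1e3 / trace.sample_rate_hz

    # onset: first sample of the run above onset_sd*SD that leads into the peak
    onset = s
    thr = onset_sd * sd
    j = pk
    while j > s and y[j - 1] > thr:
        j -= 1
    onset = j

    # takeoff: second-derivative maximum on the main-spike upstroke.  The
    # search is anchored at the last sample below 30% of the peak so that
    # curvature at the foot-onset ramp or at injected flickers cannot be
    # mistaken for the upstroke.
    if pk - onset < 3:
        return None
    below = np.flatnonzero(y[onset:pk] < 0.3 * y[pk])
    j_up = onset + int(below[-1]) if below.size else onset
    margin = int(round(0.8e-3 * trace.sample_rate_hz))
    lo_search = max(onset, j_up - margin)
    if pk - lo_search < 3:
        lo_search = max(onset, pk - 3)
    d2 = np.diff(y[lo_search:pk + 1], n=2)
    if d2.size == 0:
        return None
    takeoff = lo_search + 1 + int(np.argmax(d2))
    dur_ms = (takeoff - onset) * dt_ms
    if dur_ms <= 2 * dt_ms:
        return None
    foot_seg = y[onset:takeoff + 1]
    foot = FootParameters(
        duration_ms=float(dur_ms),
        charge_fC=float(np.trapezoid(foot_seg) * dt_ms),
        amp_pA=float(np.mean(foot_seg)),
        start_idx=onset,
        end_idx=takeoff,
    )
    event.foot = foot
    return foot


def foot_flickers(
    foot: FootParameters,
    trace: CurrentTrace,
    threshold_pA_per_ms: float = FLICKER_THRESHOLD_PA_PER_MS,
    derivative_filter_hz: float = FLICKER_FILTER_HZ,
    detrend_order: int = 3,
) -> FootParameters:
    """Count fusion-pore flickers in an analyzable foot (in place).

    The current derivative within the foot is low-pass filtered at
    ``derivative_filter_hz`` and each contiguous run beyond
    +-``threshold_pA_per_ms`` counts as one flicker (positive and negative
    excursions counted separately, then summed).  The flicker frequency is
    the count divided by the foot duration.  The rms noise is computed on
    the foot current after removing a polynomial trend of order
    ``detrend_order`` (removes the slow foot ramp).
    """
    if not foot.analyzable:
        raise ParameterError(
            f"foot duration {foot.duration_ms:.2f} ms <= "
            f"{FOOT_MIN_DURATION_MS:.0f} ms; flicker analysis restricted to longer feet"
        )
    s, e = foot.start_idx, foot.end_idx
    # derivative on a slightly padded segment to avoid edge transients
    pad = max(3, int(0.5e-3 * trace.sample_rate_hz))
    lo = max(0, s - pad)
    hi = min(trace.i_pA.size - 1, e + pad)
    seg = trace.i_pA[lo:hi + 1]
    dt_ms = 1e3 / trace.sample_rate_hz
    deriv = np.gradient(seg, dt_ms)  # pA/ms
    deriv = gaussian_lowpass(deriv, trace.sample_rate_hz, derivative_filter_hz)
    deriv = deriv[s - lo:s - lo + (e - s + 1)]

    # a suprathreshold run that reaches the end of the foot is the main-spike
    # upstroke itself, not a pore fluctuation; exclude it from the count
    guard = max(1, int(0.1e-3 * trace.sample_rate_hz))
    count = 0
    for sign in (1.0, -1.0):
        above = sign * deriv > threshold_pA_per_ms
        edges = np.diff(np.concatenate(([0], above.view(np.int8), [0])))
        run_ends = np.flatnonzero(edges == -1)  # exclusive end index per run
        count += int(np.count_nonzero(run_ends < deriv.size - guard))

    foot.flicker_count = count
    foot.flicker_freq_per_ms = count / foot.duration_ms

    y = trace.i_pA[s:e + 1]
    x = np.arange(y.size, dtype=float)
    order = min(detrend_order, y.size - 1)
    coef = np.polynomial.polynomial.polyfit(x, y, order)
    resid = y - np.polynomial.polynomial.polyval(x, coef)
    foot.rms_noise_pA = float(np.sqrt(np.mean(resid ** 2)))
    return foot


def event_frequency(trace: CurrentTrace, events: Sequence[SpikeEvent]) -> float:
    """Eligible-event rate in events/s over the recording duration."""
    return sum(ev.eligible_frequency for ev in events) / trace.duration_s


def cell_summary(
    events_by_cell: Mapping[str, Sequence[SpikeEvent] | pd.DataFrame],
    parameters: Sequence[str] = ("amp_pA", "charge_fC", "rise_50_90_ms", "half_width_ms"),
    min_events: int = 20,
    exclude_small_cells: bool = True,
) -> pd.DataFrame:
    """Per-cell medians and the cell-weighted mean of medians.

    Summary statistics follow the standard convention for amperometric
    data: within each cell the median of each parameter over that cell's
    events (robust against the skewed event-size distributions), then the
    unweighted mean +- SEM of those medians across cells, so every cell
    contributes equally regardless of its event count.  Cells with at most
    ``min_events`` events are excluded when ``exclude_small_cells`` is set
    (they are still listed, flagged ``included=False``).

    Returns a DataFrame with one row per cell plus a final ``mean_of_medians``
    and ``sem_of_medians`` row pair indexed by cell id.
    """
    if not events_by_cell:
        raise ParameterError("no cells supplied")
    rows = []
    for cell, evs in events_by_cell.items():
        if isinstance(evs, pd.DataFrame):
            df = evs
        else:
            df = pd.DataFrame(
                [{p: getattr(ev, p, np.nan) for p in parameters} for ev in evs]
            )
        row: dict = {"cell": cell, "n_events": len(df)}
        for p in parameters:
            row[p] = float(df[p].median()) if len(df) and p in df else np.nan
        row["included"] = (len(df) > min_events) or not exclude_small_cells
        rows.append(row)
    per_cell = pd.DataFrame(rows).set_index("cell")
    used = per_cell[per_cell["included"]]
    summary_rows = {}
    for stat, fn in (("mean_of_medians", np.mean),
                     ("sem_of_medians",
                      lambda v: np.std(v, ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan)):
        summary_rows[stat] = {
            p: float(fn(used[p].dropna().to_numpy())) if len(used) else np.nan
            for p in parameters
        }
    summary = pd.DataFrame(summary_rows).T
    summary["n_events"] = np.nan
    summary["included"] = np.nan
    return pd.concat([per_cell, summary])
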