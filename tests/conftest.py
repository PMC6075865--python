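import numpy as np
import pytest

from exophys.synthio import AmperoSimParams, FlashSimParams, gen_amperometric_trace


@pytest.fixture
def noiseless_flash_params():
    """Standard noiseless flash-response ground truth."""
    return FlashSimParams(
        A0_fF=5000.0, A_rrp_fF=150.0, tau_rrp_ms=20.0,
        A_srp_fF=200.0, tau_srp_ms=250.0, k_sus_fFps=15.0,
        flash_time_s=0.5, onset_delay_ms=3.0, pre_rate_fFps=0.0,
        noise_sd_fF=0.0, duration_s=5.5, sample_rate_hz=2000.0, seed=0,
    )


def isolated_event_params(seed: int, n_events: int = 10, spacing_s: float = 0.4,
                          **overrides) -> AmperoSimParams:
    """Amperometric params with deterministically spaced (non-overlapping)
    events so per-event measurements can be matched to ground truth."""
    event_kwargs = overrides.pop("event_kwargs", {})
    events = [{"t_s": 0.4 + spacing_s * i, **event_kwargs}
              for i in range(n_events)]
    return AmperoSimParams(
        seed=seed,
        duration_s=0.4 + spacing_s * n_events + 0.2,
        events=events,
        **overrides,
    )


def match_events(truth, detected, tol_s: float = 0.01):
    """Greedy one-to-one matching of truth rows to detected events by peak time."""
    t_det = np.array([ev.t_peak_s for ev in detected])
    used = np.zeros(len(detected), dtype=bool)
    pairs = []
    unmatched = []
    for idx, row in truth.iterrows():
        if len(t_det) == 0:
            unmatched.append(idx)
            continue
        d = np.abs(t_det - row.t_peak_s)
        d[used] = np.inf
        i = int(np.argmin(d))
        if d[i] < tol_s:
            used[i] = True
            pairs.append((idx, detected[i]))
        else:
            unmatched.append(idx)
    false_pos = [ev for ev, u in zip(detected, used) if not u]
    return pairs, unmatched, false_pos
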