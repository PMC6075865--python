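"""Second-order kinetics of SDS-resistant SNARE complex assembly.

Ternary SNARE complex formation between a preformed t-SNARE acceptor and
synaptobrevin follows, over the assay's time scale, the integrated rate law
of a second-order reaction A + B -> P with equal initial concentrations
(A0 = B0):

    SC(t) = SC0 + (SCinf - SC0) * A0*k*t / (A0*k*t + 1)

where SC(t) is the densitometry value of assembled complex at time t, SC0
and SCinf its values at t = 0 and t = infinity, A0 the initial reactant
concentration (mol/L, fixed by the experiment design; 3 uM by default) and
k the rate constant in 1/(M*s).  A0 and k are not separately identifiable
from a single curve, so A0 is held fixed and only SC0, SCinf and k are
fitted.

Group comparison follows the rank-based route customary for small-n
densitometry: Kruskal-Wallis across groups with Dunn's post test against
the control, and rates reported as percent of the control mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares

from exophys.errors import FitError, ParameterError
from exophys.groupstats import dunn_test

__all__ = [
    "AssemblyTimeCourse",
    "AssemblyFit",
    "fit_assembly",
    "normalize_timecourse",
    "compare_rates",
    "DEFAULT_A0_M",
]

DEFAULT_A0_M = 3e-6  # limiting reactant (GST-SybII) concentration, mol/L


@dataclass
class AssemblyTimeCourse:
    """One densitometry time course (minutes vs arbitrary units)."""

    times_min: np.ndarray
    values_au: np.ndarray
    group: str = ""
    replicate: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values_au = np.asarray(self.values_au, dtype=float)
        if self.times_min.shape != self.values_au.shape or self.times_min.ndim != 1:
            raise ParameterError("times_min and values_au must be 1-D arrays of equal length")
        if self.times_min.size >= 2 and not np.all(np.diff(self.times_min) > 0):
            raise ParameterError("times_min must be strictly increasing")
        if not np.all(np.isfinite(self.values_au)) or np.any(self.values_au < 0):
            raise ParameterError("values_au must be finite and >= 0")


@dataclass
class AssemblyFit:
    """Fitted parameters of the integrated second-order law."""

    SC0_au: float
    SCinf_au: float
    A0_M: float
    k_M1s1: float
    residual_rms: float
    converged: bool
    k_at_boundary: bool = False


def _law(t_min: np.ndarray, SC0: float, SCinf: float, A0: float, k: float) -> np.ndarray:
    x = A0 * k * t_min * 60.0
    return SC0 + (SCinf - SC0) * x / (x + 1.0)


def fit_assembly(tc: AssemblyTimeCourse, A0_M: float = DEFAULT_A0_M) -> AssemblyFit:
    """Least-squares fit of SC0, SCinf and k with A0 held fixed.

    Raises
    ------
    ParameterError
        For fewer than 4 time points (3 parameters) or nonpositive A0.
    """
    if tc.times_min.size < 4:
        raise ParameterError("need at least 4 time points to fit 3 parameters")
    if A0_M <= 0:
        raise ParameterError("A0_M must be positive")
    t = tc.times_min
    y = tc.values_au

    sc0_0 = float(y[0])
    scinf_0 = float(max(y.max(), sc0_0 + 1e-9))
    # crude k guess from the time of half rise
    half = sc0_0 + 0.5 * (scinf_0 - sc0_0)
    idx = np.searchsorted(y, half)
    t_half = float(t[min(idx, t.size - 1)]) or float(t[-1]) / 4 or 1.0
    k0 = 1.0 / (A0_M * t_half * 60.0)

    scale = max(scinf_0 - sc0_0, 1e-9)

    def resid(p: np.ndarray) -> np.ndarray:
        sc0, scinf, logk = p
        return (_law(t, sc0, scinf, A0_M, np.exp(logk)) - y) / scale

    sol = least_squares(
        resid,
        np.array([sc0_0, scinf_0, np.log(k0)]),
        bounds=(np.array([0.0, 0.0, np.log(1e-6)]), np.array([np.inf, np.inf, np.log(1e9)])),
        xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=10000,
    )
    sc0, scinf, logk = sol.x
    k = float(np.exp(logk))
    rms = float(np.sqrt(np.mean((sol.fun * scale) ** 2)))
    # degenerate outcomes: k pinned at its lower bound, or a collapsed
    # amplitude (flat data) that leaves k unidentified
    at_boundary = bool(logk < np.log(1e-6) + 1e-6
                       or (scinf - sc0) < 1e-6 * max(abs(float(np.max(y))), 1e-12))
    return AssemblyFit(
        SC0_au=float(sc0),
        SCinf_au=float(scinf),
        A0_M=float(A0_M),
        k_M1s1=k,
        residual_rms=rms,
        converged=bool(sol.success) and not at_boundary,
        k_at_boundary=at_boundary,
    )


def normalize_timecourse(
    tc: AssemblyTimeCourse,
    t_ref_min: float = 240.0,
    tol_min: float = 10.0,
) -> AssemblyTimeCourse:
    """Normalize values to the complex formation at a reference time.

    The sample nearest to ``t_ref_min`` (within ``tol_min``) defines the
    reference value; all values are divided by it so the normalized curve
    is 1 at the reference time.
    """
    i = int(np.argmin(np.abs(tc.times_min - t_ref_min)))
    if abs(tc.times_min[i] - t_ref_min) > tol_min:
        raise ParameterError(
            f"no sample within {tol_min} min of the reference time {t_ref_min} min"
        )
    ref = tc.values_au[i]
    if ref <= 0:
        raise ParameterError("reference value must be positive for normalization")
    return AssemblyTimeCourse(
        times_min=tc.times_min.copy(),
        values_au=tc.values_au / ref,
        group=tc.group,
        replicate=tc.replicate,
        meta={**tc.meta, "normalized_to_min": t_ref_min},
    )


def compare_rates(
    fits_by_group: Mapping[str, Sequence[AssemblyFit]] | Mapping[str, Sequence[float]],
    control: str = "SNAREs",
    alpha: float = 0.05,
    adjust: str = "bonferroni",
) -> dict:
    """Compare group rate constants against a control group.

    Parameters
    ----------
    fits_by_group
        Mapping of group label to per-replicate :class:`AssemblyFit` (or
        raw k values).
    control
        Label of the control group; other groups are expressed as percent
        of the control mean (SEM propagated from both group SEMs).
    adjust
        P-value adjustment for Dunn's pairwise z tests ("bonferroni" or
        "none").

    Returns
    -------
    dict
        ``kruskal_p``, ``kruskal_H`` and a DataFrame ``table`` with one row
        per group: mean k +- SEM, percent of control +- SEM, and Dunn's
        p-value vs control.
    """
    if control not in fits_by_group:
        raise ParameterError(f"control group {control!r} missing from input")
    if len(fits_by_group) < 2:
        raise ParameterError("need at least 2 groups")
    ks = {
        g: np.asarray([f.k_M1s1 if isinstance(f, AssemblyFit) else float(f) for f in v],
                      dtype=float)
        for g, v in fits_by_group.items()
    }
    for g, v in ks.items():
        if v.size < 3:
            raise ParameterError(f"group {g!r} has fewer than 3 replicates")

    groups = list(ks)
    H, kw_p = stats.kruskal(*ks.values())
    dunn = dunn_test(ks, control=control, adjust=adjust)

    kc = ks[control]
    mc = kc.mean()
    sem_c = kc.std(ddof=1) / np.sqrt(kc.size)
    rows = []
    for g in groups:
        v = ks[g]
        m = v.mean()
        sem = v.std(ddof=1) / np.sqrt(v.size)
        pct = 100.0 * m / mc
        # SEM of the ratio by first-order error propagation
        pct_sem = pct * np.sqrt((sem / m) ** 2 + (sem_c / mc) ** 2) if m > 0 else np.nan
        rows.append({
            "group": g,
            "n": v.size,
            "k_mean_M1s1": m,
            "k_sem_M1s1": sem,
            "pct_of_control": pct,
            "pct_sem": pct_sem,
            "dunn_p_vs_control": dunn.get(g, np.nan),
            "significant": bool(dunn.get(g, np.nan) < alpha) if g != control else False,
        })
    return {
        "kruskal_H": float(H),
        "kruskal_p": float(kw_p),
        "control": control,
        "table": pd.DataFrame(rows).set_index("group"),
    }
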