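"""Reading and writing the package's plain-text formats.

Traces travel as two-column CSV with a header line (``time_s,cm_fF`` or
``time_s,i_pA``); trace-level metadata such as the flash time rides in
``# key=value`` comment lines before the header, with an optional JSON
sidecar for generator parameters and ground truth.  Tabular results
(per-event, per-cell, fits, comparisons) are written as TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from exophys.ampero import CurrentTrace
from exophys.capfit import CapacitanceTrace
from exophys.errors import ParameterError
from exophys.snarekin import AssemblyTimeCourse

__all__ = [
    "read_capacitance_csv",
    "write_capacitance_csv",
    "read_current_csv",
    "write_current_csv",
    "read_assembly_tsv",
    "write_sidecar",
]


def _read_header_meta(path: Path) -> dict:
    meta: dict = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if "=" in body:
                k, v = body.split("=", 1)
                try:
                    meta[k.strip()] = float(v)
                except ValueError:
                    meta[k.strip()] = v.strip()
    return meta


def read_capacitance_csv(path: str | Path) -> CapacitanceTrace:
    """Read a (time_s, cm_fF) CSV with optional ``# flash_time_s=`` header."""
    path = Path(path)
    meta = _read_header_meta(path)
    df = pd.read_csv(path, comment="#")
    if not {"time_s", "cm_fF"}.issubset(df.columns):
        raise ParameterError(f"{path}: expected columns time_s, cm_fF")
    return CapacitanceTrace(
        time_s=df["time_s"].to_numpy(),
        cm_fF=df["cm_fF"].to_numpy(),
        flash_time_s=meta.get("flash_time_s"),
        meta=meta,
    )


def write_capacitance_csv(trace: CapacitanceTrace, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        if trace.flash_time_s is not None:
            fh.write(f"# flash_time_s={trace.flash_time_s}\n")
        pd.DataFrame({"time_s": trace.time_s, "cm_fF": trace.cm_fF}).to_csv(fh, index=False)


def read_current_csv(path: str | Path) -> CurrentTrace:
    """Read a (time_s, i_pA) CSV; sample rate and cutoff from header or inferred."""
    path = Path(path)
    meta = _read_header_meta(path)
    df = pd.read_csv(path, comment="#")
    if not {"time_s", "i_pA"}.issubset(df.columns):
        raise ParameterError(f"{path}: expected columns time_s, i_pA")
    t = df["time_s"].to_numpy()
    rate = meta.get("sample_rate_hz")
    if rate is None:
        rate = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 25_000.0
    return CurrentTrace(
        time_s=t,
        i_pA=df["i_pA"].to_numpy(),
        sample_rate_hz=float(rate),
        filter_cutoff_hz=float(meta.get("filter_cutoff_hz", 2000.0)),
        meta=meta,
    )


def write_current_csv(trace: CurrentTrace, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# sample_rate_hz={trace.sample_rate_hz}\n")
        fh.write(f"# filter_cutoff_hz={trace.filter_cutoff_hz}\n")
        pd.DataFrame({"time_s": trace.time_s, "i_pA": trace.i_pA}).to_csv(fh, index=False)


def read_assembly_tsv(path: str | Path) -> list[AssemblyTimeCourse]:
    """Read long-format TSV (group, replicate, time_min, value_au)."""
    df = pd.read_csv(path, sep="\t")
    need = {"group", "replicate", "time_min", "value_au"}
    if not need.issubset(df.columns):
        raise ParameterError(f"{path}: expected columns {sorted(need)}")
    out = []
    for (grp, rep), sub in df.groupby(["group", "replicate"], sort=False):
        sub = sub.sort_values("time_min")
        out.append(AssemblyTimeCourse(
            times_min=sub["time_min"].to_numpy(),
            values_au=sub["value_au"].to_numpy(),
            group=str(grp),
            replicate=str(rep),
        ))
    return out


def write_sidecar(meta: dict, path: str | Path) -> None:
    """Write generator parameters / ground truth as a JSON sidecar."""

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, pd.DataFrame):
            return o.to_dict(orient="list")
        return str(o)

    Path(path).write_text(json.dumps(meta, indent=1, default=default))
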