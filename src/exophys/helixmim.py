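"""SNAP25-SN1 mimicry scoring: similarity, hydrophobic moment, helical wheel.

Two sequence properties quantify how well a peptide segment mimics a SNARE
motif:

* **Percent similarity** — the fraction of aligned positions whose BLOSUM62
  substitution score is positive (identities included), following the
  similarity convention of classical global-alignment tools.  Equal-length
  segments are compared gaplessly; unequal lengths fall back to a global
  alignment with affine gaps (open 10, extend 0.5).
* **Hydrophobic moment (muH)** — the Eisenberg mean helical hydrophobic
  moment per residue,

      muH = (1/N) * sqrt[ (sum_n H_n sin(n*delta))^2
                        + (sum_n H_n cos(n*delta))^2 ]

  with H_n the normalized-consensus hydrophobicity of residue n and
  delta = 100 degrees per residue for an ideal alpha helix.  A large muH
  marks an amphipathic helix whose hydrophobic residues cluster on one
  face — the hallmark of SNARE-motif (heptad-repeat) segments.

:func:`scan_sn_mimicry` slides a window along a query protein and scores
each window against a set of target segments, supporting cross-species
comparisons of complexin C-termini with their cognate SNAREs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from exophys.errors import ParameterError

__all__ = [
    "PeptideSegment",
    "SimilarityResult",
    "HelixWindow",
    "percent_similarity",
    "hydrophobic_moment",
    "helical_wheel",
    "scan_sn_mimicry",
    "EISENBERG_CONSENSUS",
    "HYDROPHOBICITY_SCALES",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")

# Eisenberg normalized consensus hydrophobicity scale.
EISENBERG_CONSENSUS: dict[str, float] = {
    "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
    "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
    "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
    "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
}

# Named, swappable hydrophobicity tables.
HYDROPHOBICITY_SCALES: dict[str, dict[str, float]] = {
    "eisenberg_consensus": EISENBERG_CONSENSUS,
}

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _check_sequence(seq: str, name: str) -> str:
    seq = seq.upper()
    for i, aa in enumerate(seq, start=1):
        if aa not in STANDARD_AA:
            raise ParameterError(
                f"non-standard residue {aa!r} at position {i} of {name or 'sequence'}"
            )
    return seq


@dataclass(frozen=True)
class PeptideSegment:
    """A peptide segment with 1-based inclusive residue coordinates."""

    name: str
    sequence: str
    start_res: int = 1
    end_res: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _check_sequence(self.sequence, self.name))
        if self.end_res == 0:
            object.__setattr__(self, "end_res", self.start_res + len(self.sequence) - 1)
        if self.end_res - self.start_res + 1 != len(self.sequence):
            raise ParameterError(
                f"{self.name}: residue range {self.start_res}-{self.end_res} does not "
                f"match sequence length {len(self.sequence)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimilarityResult:
    """Outcome of a pairwise percent-similarity comparison."""

    a: str
    b: str
    matrix_name: str
    aligned_length: int
    n_similar: int
    percent_similarity: float
    mode: str  # "gapless" | "global-affine"


@dataclass
class HelixWindow:
    """A segment projected onto an ideal helix, with its hydrophobic moment."""

    segment: PeptideSegment
    delta_deg: float
    angle_deg: np.ndarray
    H_n: np.ndarray
    muH: float
    scale: str = "eisenberg_consensus"


def percent_similarity(
    a: PeptideSegment | str,
    b: PeptideSegment | str,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    mode: str = "auto",
) -> SimilarityResult:
    """BLOSUM62 percent similarity between two peptide segments.

    A position counts as *similar* when its BLOSUM62 substitution score is
    strictly positive (identities included).  Equal-length inputs are
    compared position-wise without gaps; unequal lengths are globally
    aligned with affine gap penalties first, and the percentage is taken
    over aligned (non-gap) columns.  ``mode`` may force ``"gapless"`` or
    ``"global"`` instead of the length-based ``"auto"`` choice.
    """
    sa = a if isinstance(a, PeptideSegment) else PeptideSegment("a", a)
    sb = b if isinstance(b, PeptideSegment) else PeptideSegment("b", b)
    if len(sa) == 0 or len(sb) == 0:
        raise ParameterError("sequences must be non-empty")
    if mode not in ("auto", "gapless", "global"):
        raise ParameterError(f"unknown alignment mode {mode!r}")
    if mode == "gapless" and len(sa) != len(sb):
        raise ParameterError("gapless mode requires equal-length sequences")

    if mode == "gapless" or (mode == "auto" and len(sa) == len(sb)):
        cols = list(zip(sa.sequence, sb.sequence))
        mode = "gapless"
    else:
        aligner = PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = _BLOSUM62
        aligner.open_gap_score = -gap_open
        aligner.extend_gap_score = -gap_extend
        aln = aligner.align(sa.sequence, sb.sequence)[0]
        ta, tb = str(aln[0]), str(aln[1])
        cols = [(x, y) for x, y in zip(ta, tb) if x != "-" and y != "-"]
        mode = "global-affine"

    n_similar = sum(1 for x, y in cols if _BLOSUM62[x][y] > 0)
    aligned = len(cols)
    return SimilarityResult(
        a=sa.name, b=sb.name,
        matrix_name="BLOSUM62",
        aligned_length=aligned,
        n_similar=n_similar,
        percent_similarity=100.0 * n_similar / aligned,
        mode=mode,
    )


def hydrophobic_moment(
    seg: PeptideSegment | str,
    delta_deg: float = 100.0,
    scale: str = "eisenberg_consensus",
    phase_deg: float = 0.0,
) -> HelixWindow:
    """Mean helical hydrophobic moment per residue of a segment.

    ``delta_deg`` is the angular step per residue (100 degrees for an
    ideal alpha helix).  The moment is rotation invariant: any constant
    phase offset ``phase_deg`` leaves muH unchanged.
    """
    s = seg if isinstance(seg, PeptideSegment) else PeptideSegment("query", seg)
    table = HYDROPHOBICITY_SCALES[scale]
    H = np.array([table[aa] for aa in s.sequence])
    n = np.arange(len(s))
    ang = np.deg2rad(n * delta_deg + phase_deg)
    muH = float(np.hypot(np.sum(H * np.sin(ang)), np.sum(H * np.cos(ang))) / len(s))
    return HelixWindow(
        segment=s,
        delta_deg=delta_deg,
        angle_deg=(n * delta_deg) % 360.0,
        H_n=H,
        muH=muH,
        scale=scale,
    )


def helical_wheel(
    seg: PeptideSegment | str,
    delta_deg: float = 100.0,
    radius0: float = 1.0,
    spiral: float = 0.02,
) -> list[tuple[str, float, float]]:
    """Deterministic helical-wheel plotting table.

    Residue ``n`` (1-based) sits at angle ``(n-1)*delta mod 360`` degrees;
    the radius grows by ``spiral`` per residue so that residues landing on
    the same spoke after a full turn remain distinguishable.
    """
    s = seg if isinstance(seg, PeptideSegment) else PeptideSegment("query", seg)
    if len(s) < 1:
        raise ParameterError("segment must contain at least one residue")
    return [
        (aa, (i * delta_deg) % 360.0, radius0 + spiral * i)
        for i, aa in enumerate(s.sequence)
    ]


def scan_sn_mimicry(
    query: str | PeptideSegment,
    targets: Sequence[PeptideSegment],
    window: int | None = None,
    delta_deg: float = 100.0,
) -> pd.DataFrame:
    """Slide a window along ``query`` and score each window vs each target.

    For every window position and every target the BLOSUM62 percent
    similarity and the window's hydrophobic moment are reported; a final
    per-target summary block gives the best-scoring window and the mean
    +- SEM of the per-target best scores across all supplied targets with
    the same ``name`` prefix (supporting multi-species inputs).

    Returns a tidy DataFrame with columns (target, win_start, win_seq,
    percent_similarity, muH).
    """
    if not targets:
        raise ParameterError("no target segments supplied")
    qseq = query.sequence if isinstance(query, PeptideSegment) else _check_sequence(query, "query")
    if window is None:
        window = len(targets[0])
    if window > len(qseq):
        raise ParameterError("window exceeds query length")
    rows = []
    for start in range(len(qseq) - window + 1):
        wseq = qseq[start:start + window]
        mu = hydrophobic_moment(wseq, delta_deg=delta_deg).muH
        for tgt in targets:
            sim = percent_similarity(PeptideSegment("win", wseq), tgt)
            rows.append({
                "target": tgt.name,
                "win_start": start + 1,
                "win_seq": wseq,
                "percent_similarity": sim.percent_similarity,
                "muH": mu,
            })
    return pd.DataFrame(rows)


def mimicry_summary(scan: pd.DataFrame) -> pd.DataFrame:
    """Best window per target plus mean +- SEM across targets.

    The mean over k species-specific targets equals the arithmetic mean of
    their individually computed best scores.
    """
    best = scan.loc[scan.groupby("target")["percent_similarity"].idxmax()]
    best = best.set_index("target")
    vals = best["percent_similarity"].to_numpy()
    best.loc["mean"] = {
        "percent_similarity": float(np.mean(vals)),
        "muH": float(np.mean(best["muH"].to_numpy())),
    }
    if vals.size > 1:
        best.loc["sem"] = {
            "percent_similarity": float(np.std(vals, ddof=1) / np.sqrt(vals.size)),
            "muH": float(np.std(best["muH"].to_numpy()[:-1], ddof=1) / np.sqrt(vals.size)),
        }
    return best
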