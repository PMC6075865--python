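"""Reference peptide segments for SNAP25-SN1 mimicry analysis.

The complexin II (CpxII) C-terminal domain carries an amphipathic helix
whose membrane-proximal half closely resembles the C-terminal half of the
SNAP25 SN1 SNARE motif.  This module holds the mouse segments used in that
comparison:

* ``CPX2_CTD_PEPTIDE`` — the CpxII C-terminal peptide (residues 101–134)
  used for acute infusion experiments, and its scrambled control.
* ``SEGMENTS`` — the 18-residue comparison windows covering the
  hydrophobic-layer range +2…+7 of each SNARE motif: CpxII CTD residues
  117–134 aligned against SNAP25a SN1 (60–77), SNAP25a SN2 (181–198),
  SybII/VAMP2 (63–80) and Syntaxin-1a (233–250).

Residue numbering is 1-based inclusive in the parent protein.
"""

from __future__ import annotations

from exophys.helixmim import PeptideSegment

__all__ = [
    "CPX2_CTD_PEPTIDE",
    "CPX2_CTD_SCRAMBLED",
    "CPX2_CTD_START_RES",
    "SEGMENTS",
    "ctd_boxed_segment",
]

# CpxII C-terminal peptide, residues 101-134 of mouse complexin II.
CPX2_CTD_PEPTIDE = "IPAGCGDEEEEEEESILDTVLKYLPGPLQDMFKK"
CPX2_CTD_START_RES = 101
# Scrambled control peptide (same composition, shuffled order).
CPX2_CTD_SCRAMBLED = "KVPYELGGQLPELKTSDPIEGEDEDELFMKEIAC"


def ctd_boxed_segment() -> PeptideSegment:
    """CpxII residues 117-134: the amphipathic, SN1-mimetic half of the CTD."""
    seq = CPX2_CTD_PEPTIDE[117 - CPX2_CTD_START_RES:]
    return PeptideSegment(name="CpxII-CTD", sequence=seq, start_res=117, end_res=134)


# 18-residue comparison windows (hydrophobic layers +2..+7 of each SNARE
# motif) from the canonical mouse sequences.  SN1/SN2 are from the SNAP25a
# splice variant.
SEGMENTS: dict[str, PeptideSegment] = {
    "CpxII-CTD": ctd_boxed_segment(),
    "SNAP25-SN1": PeptideSegment(
        name="SNAP25-SN1", sequence="VEEGMNHINQDMKEAEKN", start_res=60, end_res=77
    ),
    "SNAP25-SN2": PeptideSegment(
        name="SNAP25-SN2", sequence="IMEKADSNKTRIDEANQR", start_res=181, end_res=198
    ),
    "SybII": PeptideSegment(
        name="SybII", sequence="LDDRADALQAGASQFETS", start_res=63, end_res=80
    ),
    "Syx1a": PeptideSegment(
        name="Syx1a", sequence="IEYNVEHAVDYVERAVSD", start_res=233, end_res=250
    ),
}
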