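"""scc / mcc / NC typing of called TLRs from their domain architecture."""

from __future__ import annotations

from dataclasses import dataclass

from tollscan.domain_scan import Architecture

MEMBRANE_PROXIMAL_WINDOW = 60

TLR_TYPES = ("scc", "mcc", "NC")


@dataclass(frozen=True)
class TlrType:
    seq_id: str
    tlr_type: str  # scc | mcc | NC


def classify_type(
    arch: Architecture,
    membrane_proximal_window: int = MEMBRANE_PROXIMAL_WINDOW,
) -> TlrType:
    """Type a TLR by its cysteine-cap layout.

    * ``mcc`` — two or more LRRCT caps (an LRRNT may be present but is never
      decisive).
    * ``scc`` — exactly one LRRCT whose end lies within
      ``membrane_proximal_window`` residues of the TM start.
    * ``NC`` — fragment, no detected LRRCT, or a single LRRCT that is not
      membrane-proximal: the type cannot be determined.
    """
    if not (arch.has_tir and arch.has_tm and arch.n_lrr >= 1):
        raise ValueError(f"{arch.seq_id}: not a TLR architecture")
    if arch.n_lrrct >= 2:
        return TlrType(arch.seq_id, "mcc")
    if not arch.complete:
        return TlrType(arch.seq_id, "NC")
    if arch.n_lrrct == 1:
        lrrct = arch.hits_of("LRRCT")[0]
        tm = arch.tm
        assert tm is not None
        if lrrct.end < tm.start and tm.start - lrrct.end <= membrane_proximal_window:
            return TlrType(arch.seq_id, "scc")
    return TlrType(arch.seq_id, "NC")
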