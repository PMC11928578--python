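"""Retroviral feature vocabulary: genes, infectivity motifs, ORF status.

The gammaretroviral Gag carries two "late domain" motifs required for viral
budding: a PRPPIY-type motif (variant form PQPPVL) and the PPxY motif proper
(PPPY, variant TPPY).  Env carries the CETTG motif associated with
infectivity/cytopathology, frequently altered or lost in endogenized copies.
Both the synthetic-genome generator (when recording ground truth) and the
annotator (when reporting what it sees) classify motif states through the
functions here, so a truth/report disagreement always reflects a real
annotation error, never two divergent notions of "intact".
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import internal_stops, translate

GENES = ("gag", "pro", "pol", "env")

# canonical / variant motif forms
LATE1_STATES = ("PRPPIY", "PQPPVL")
LATE2_STATES = ("PPPY", "TPPY")
CETTG = "CETTG"

# amino-acid offset of each motif within its gene (codon index, frame 0)
MOTIF_AA_OFFSET = {"late1": 120, "late2": 160, "cettg": 300}
MOTIF_GENE = {"late1": "gag", "late2": "gag", "cettg": "env"}
MOTIF_WINDOW_AA = 15  # search this many residues either side of the offset


@dataclass
class MotifReport:
    gag_late_domain_1: str = "absent"   # PRPPIY | PQPPVL | other | absent
    gag_late_domain_2: str = "absent"   # PPPY | TPPY | other | absent
    env_cettg: str = "absent"           # CETTG | altered | absent


@dataclass
class OrfReport:
    status: dict = field(default_factory=dict)          # gene -> status
    stop_positions: dict = field(default_factory=dict)  # gene -> [codon idx]
    longest_orf: dict = field(default_factory=dict)     # gene -> codons


def _window(aa_seq: str, offset: int, motif_len: int) -> str:
    lo = max(0, offset - MOTIF_WINDOW_AA)
    hi = offset + motif_len + MOTIF_WINDOW_AA
    return aa_seq[lo:hi]


def _classify(aa_seq: str | None, offset: int, states: tuple[str, ...]) -> str:
    if not aa_seq:
        return "absent"
    win = _window(aa_seq, offset, len(states[0]))
    for state in states:
        if state in win:
            return state
    return "other"


def classify_motifs(gag_seq: str | None, env_seq: str | None,
                    env_ref_len: int | None = None) -> MotifReport:
    """Classify motif states from gene nucleotide sequences (frame 0).

    ``env_ref_len`` is the reference (intact) env length in nt; when the
    observed env has lost more than half of it — the hallmark of the large
    env deletion — the CETTG region is gone and the motif is "absent" rather
    than "altered".
    """
    rep = MotifReport()
    if gag_seq:
        gag_aa = translate(gag_seq)
        rep.gag_late_domain_1 = _classify(
            gag_aa, MOTIF_AA_OFFSET["late1"], LATE1_STATES)
        rep.gag_late_domain_2 = _classify(
            gag_aa, MOTIF_AA_OFFSET["late2"], LATE2_STATES)
    if env_seq:
        if env_ref_len is not None and len(env_seq) < 0.5 * env_ref_len:
            rep.env_cettg = "absent"
        else:
            env_aa = translate(env_seq)
            win = _window(env_aa, MOTIF_AA_OFFSET["cettg"], len(CETTG))
            rep.env_cettg = CETTG if CETTG in win else "altered"
    return rep


def orf_status(gene_seq: str | None, ref_len: int,
               full_length_fraction: float = 0.9) -> tuple[str, list[int], int]:
    """(status, internal stop codon indices, longest ORF in codons).

    full_length requires zero internal stops and observed length at or above
    ``full_length_fraction`` of the reference gene length.
    """
    if not gene_seq:
        return "absent", [], 0
    stops = internal_stops(gene_seq)
    n_codons = len(gene_seq) // 3
    if stops:
        longest = max(
            b - a - 1 for a, b in zip([-1] + stops, stops + [n_codons]))
    else:
        longest = n_codons
    if len(gene_seq) < full_length_fraction * ref_len:
        return ("premature_stop" if stops else "partial"), stops, longest
    return ("premature_stop" if stops else "full_length"), stops, longest
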