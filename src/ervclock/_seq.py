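"""Small shared sequence utilities (DNA over A/C/G/T/N, 0-based half-open)."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_TO_INT = {b: i for i, b in enumerate(BASES)}
_A, _C, _G, _T = 0, 1, 2, 3

# transition partner per base index: A<->G, C<->T
TRANSITION = np.array([_G, _T, _A, _C], dtype=np.int8)
# the two transversion targets per base index
TRANSVERSIONS = np.array([[_C, _T], [_A, _G], [_C, _T], [_A, _G]], dtype=np.int8)

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# standard genetic code, DNA codons
_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

# reverse table: amino acid -> list of codons (deterministic order)
AA_TO_CODONS: dict[str, list[str]] = {}
for codon in sorted(_CODON_TABLE):
    AA_TO_CODONS.setdefault(_CODON_TABLE[codon], []).append(codon)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def translate(seq: str) -> str:
    """Translate a DNA string in frame 0; trailing partial codon ignored.

    Codons containing N or gaps translate to 'X'.
    """
    n = len(seq) // 3
    out = []
    for i in range(n):
        out.append(_CODON_TABLE.get(seq[3 * i:3 * i + 3].upper(), "X"))
    return "".join(out)


def internal_stops(seq: str) -> list[int]:
    """Codon indices of in-frame stop codons, excluding the final codon."""
    n = len(seq) // 3
    return [i for i in range(n - 1)
            if seq[3 * i:3 * i + 3].upper() in STOP_CODONS]


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list(BASES))[rng.integers(0, 4, size=length)])


def to_int_array(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, i in BASE_TO_INT.items():
        out[arr == ord(base)] = i
        out[arr == ord(base.lower())] = i
    return out


def from_int_array(arr: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[arr].tobytes().decode("ascii")


def encode_aa(aa_seq: str, rng: np.random.Generator | None = None) -> str:
    """Back-translate a protein string into DNA, picking codons uniformly."""
    out = []
    for aa in aa_seq:
        codons = AA_TO_CODONS[aa]
        if rng is None:
            out.append(codons[0])
        else:
            out.append(codons[int(rng.integers(0, len(codons)))])
    return "".join(out)
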