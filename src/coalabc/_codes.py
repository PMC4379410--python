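"""Genetic-code lookup tables shared across the simulator and the summary statistics.

The state space is the 61 sense codons of the universal genetic code, ordered
lexicographically over A<C<G<T.  Nucleotides are coded 0..3 (A,C,G,T); any other
symbol (gap, ambiguity) is coded -1.  Codons and amino acids use -1 for
"invalid/unknown" in observed data.
"""
from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
NT_INDEX = {b: i for i, b in enumerate(BASES)}

_table = CodonTable.unambiguous_dna_by_id[1]  # universal code
STOP_CODONS = frozenset(_table.stop_codons)

SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(
        b1 + b2 + b3
        for b1 in BASES
        for b2 in BASES
        for b3 in BASES
        if b1 + b2 + b3 not in STOP_CODONS
    )
)
N_CODONS = len(SENSE_CODONS)  # 61
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}

AA_LETTERS = tuple(sorted({_table.forward_table[c] for c in SENSE_CODONS}))  # 20
AA_INDEX = {a: i for i, a in enumerate(AA_LETTERS)}

# codon index -> its three nucleotide codes
CODON_NT = np.array(
    [[NT_INDEX[b] for b in codon] for codon in SENSE_CODONS], dtype=np.int8
)
# codon index -> amino-acid index
CODON_AA = np.array(
    [AA_INDEX[_table.forward_table[c]] for c in SENSE_CODONS], dtype=np.int8
)

# base-4 packed triplet -> codon index (-1 for the three stops)
NT3_TO_CODON = np.full(64, -1, dtype=np.int16)
for _i, _c in enumerate(SENSE_CODONS):
    _n = CODON_NT[_i]
    NT3_TO_CODON[_n[0] * 16 + _n[1] * 4 + _n[2]] = _i

# purine<->purine or pyrimidine<->pyrimidine
TRANSITION = np.zeros((4, 4), dtype=bool)
TRANSITION[NT_INDEX["A"], NT_INDEX["G"]] = TRANSITION[NT_INDEX["G"], NT_INDEX["A"]] = True
TRANSITION[NT_INDEX["C"], NT_INDEX["T"]] = TRANSITION[NT_INDEX["T"], NT_INDEX["C"]] = True

# --- structural masks over codon pairs, used to build GY94 rate matrices ---
_diff = CODON_NT[:, None, :] != CODON_NT[None, :, :]  # (61,61,3)
N_DIFF = _diff.sum(axis=2)
DIFF_ONE = N_DIFF == 1  # single-nucleotide neighbours
DIFF_POS = np.where(DIFF_ONE, _diff.argmax(axis=2), -1)  # which codon position changed

_i_idx, _j_idx = np.indices((N_CODONS, N_CODONS))
_pos = np.clip(DIFF_POS, 0, 2)
_from_nt = CODON_NT[_i_idx, _pos]
_to_nt = CODON_NT[_j_idx, _pos]
IS_TRANSITION = DIFF_ONE & TRANSITION[_from_nt, _to_nt]
IS_NONSYN = DIFF_ONE & (CODON_AA[:, None] != CODON_AA[None, :])

del _diff, _i_idx, _j_idx, _pos, _from_nt, _to_nt, _i, _c, _n


def encode_nt(seq: str) -> np.ndarray:
    """Encode a nucleotide string to int8 codes; non-ACGT (gaps, ambiguities) -> -1."""
    out = np.full(len(seq), -1, dtype=np.int8)
    for i, ch in enumerate(seq.upper().replace("U", "T")):
        out[i] = NT_INDEX.get(ch, -1)
    return out


def decode_nt(codes: np.ndarray) -> str:
    return "".join(BASES[c] if c >= 0 else "-" for c in codes)
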