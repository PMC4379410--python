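"""In-frame coding alignments with nucleotide, codon and amino-acid views.

Sequences are stored as integer code matrices (A,C,G,T = 0..3; anything else,
including gaps and IUPAC ambiguities, = -1).  The codon view maps each
nucleotide triplet to one of the 61 sense codons of the universal code; a
codon containing any non-ACGT symbol is coded -1 for that sequence and is
excluded from codon/amino-acid statistics (pairwise deletion).  In-frame stop
codons are a validation error: simulated data cannot contain them and observed
data carrying them is not a valid coding alignment.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from ._codes import BASES, CODON_AA, CODON_NT, NT3_TO_CODON, decode_nt, encode_nt

__all__ = ["CodingAlignment", "read_alignment", "write_fasta", "write_phylip"]


@dataclass
class CodingAlignment:
    """n sequences x L codons, with cached integer views at all three levels."""

    nts: np.ndarray  # (n, 3L) int8, -1 for non-ACGT
    labels: list[str]
    _codons: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        n, l_nt = self.nts.shape
        if l_nt < 3 or l_nt % 3:
            raise ValueError("alignment length must be a positive multiple of 3")
        if len(self.labels) != n:
            raise ValueError("one label per sequence required")

    @classmethod
    def from_codon_matrix(cls, codons: np.ndarray,
                          labels: list[str] | None = None) -> "CodingAlignment":
        """Build from a matrix of sense-codon indices (simulated data)."""
        n, L = codons.shape
        nts = CODON_NT[codons].reshape(n, 3 * L).astype(np.int8)
        aln = cls(nts, labels or [f"seq{i}" for i in range(n)])
        aln._codons = codons.astype(np.int16)
        return aln

    @classmethod
    def from_strings(cls, seqs: list[str],
                     labels: list[str] | None = None) -> "CodingAlignment":
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("sequences have unequal lengths")
        nts = np.stack([encode_nt(s) for s in seqs])
        aln = cls(nts, labels or [f"seq{i}" for i in range(len(seqs))])
        aln._check_stops()
        return aln

    def _check_stops(self):
        n, L = self.nts.shape[0], self.n_codons
        triplets = self.nts.reshape(n, L, 3)
        clean = (triplets >= 0).all(axis=2)
        packed = (triplets[..., 0].astype(np.int32) * 16
                  + triplets[..., 1] * 4 + triplets[..., 2])
        codons = np.where(clean, NT3_TO_CODON[np.where(clean, packed, 0)], -1)
        stops = clean & (codons == -1)
        if stops.any():
            i, j = np.argwhere(stops)[0]
            raise ValueError(
                f"in-frame stop codon in sequence {self.labels[i]!r} at codon {j}"
            )
        self._codons = codons.astype(np.int16)

    @property
    def n_sequences(self) -> int:
        return self.nts.shape[0]

    @property
    def n_codons(self) -> int:
        return self.nts.shape[1] // 3

    @property
    def l_nt(self) -> int:
        return self.nts.shape[1]

    @property
    def codons(self) -> np.ndarray:
        """(n, L) sense-codon indices, -1 where any base is missing."""
        if self._codons is None:
            self._check_stops()
        return self._codons

    @property
    def amino_acids(self) -> np.ndarray:
        """(n, L) amino-acid indices, -1 where the codon is invalid."""
        cod = self.codons
        return np.where(cod >= 0, CODON_AA[np.clip(cod, 0, None)], -1).astype(np.int8)

    def sequence_str(self, i: int) -> str:
        return decode_nt(self.nts[i])


def read_alignment(path: str | Path, fmt: str | None = None) -> CodingAlignment:
    """Read a FASTA or sequential PHYLIP coding alignment."""
    path = Path(path)
    if fmt is None:
        with open(path) as fh:
            first = fh.readline()
        fmt = "fasta" if first.startswith(">") else "phylip-sequential"
    records = list(SeqIO.parse(str(path), fmt))
    if not records:
        raise ValueError(f"no sequences found in {path}")
    return CodingAlignment.from_strings(
        [str(r.seq) for r in records], [r.id for r in records]
    )


def write_fasta(aln: CodingAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, label in enumerate(aln.labels):
            fh.write(f">{label}\n{aln.sequence_str(i)}\n")


def write_phylip(aln: CodingAlignment, path: str | Path) -> None:
    """Sequential (relaxed) PHYLIP."""
    with open(path, "w") as fh:
        fh.write(f" {aln.n_sequences} {aln.l_nt}\n")
        for i, label in enumerate(aln.labels):
            fh.write(f"{label[:10]:<10}{aln.sequence_str(i)}\n")
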