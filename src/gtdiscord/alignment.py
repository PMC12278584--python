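"""Codon alignment container and FASTA I/O.

Alignments are stored as integer matrices over the 61 sense codons of the
standard genetic code; any codon containing a gap or ambiguity character is
treated as fully missing (-1).  Stop codons are rejected on input with the
offending taxon and codon position reported.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable

NUCLEOTIDES = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

_standard = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = tuple(sorted(_standard.stop_codons))
SENSE_CODONS = tuple(sorted(_standard.forward_table))
CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
CODON_AA = {c: _standard.forward_table[c] for c in SENSE_CODONS}
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
# amino-acid index of each sense codon, aligned with SENSE_CODONS
CODON_AA_INDEX = np.array([AA_INDEX[CODON_AA[c]] for c in SENSE_CODONS])

MISSING = -1


class StopCodonError(ValueError):
    """A stop codon was found in protein-coding input."""


def encode_codon(codon: str, taxon: str = "?", position: int = 0) -> int:
    codon = codon.upper().replace("U", "T")
    if codon in CODON_INDEX:
        return CODON_INDEX[codon]
    if codon in STOP_CODONS:
        raise StopCodonError(
            f"stop codon {codon} at codon position {position + 1} in {taxon!r}")
    return MISSING  # gaps / ambiguity codes


@dataclass
class CodonAlignment:
    """One locus: a taxa x codon-sites integer matrix over sense codons."""

    locus_id: str
    taxa: list[str]
    codons: np.ndarray  # (n_taxa, n_codons), int, MISSING for gaps

    def __post_init__(self) -> None:
        self.codons = np.asarray(self.codons, dtype=np.int64)
        if self.codons.ndim != 2 or self.codons.shape[0] != len(self.taxa):
            raise ValueError("codon matrix shape does not match taxa")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.codons.size and (self.codons.max() >= len(SENSE_CODONS)
                                 or self.codons.min() < MISSING):
            raise ValueError("codon state out of range")

    # ------------------------------------------------------------ properties
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_codons(self) -> int:
        return self.codons.shape[1]

    # ---------------------------------------------------------- constructors
    @classmethod
    def from_sequences(cls, sequences: Mapping[str, str],
                       locus_id: str = "") -> "CodonAlignment":
        taxa = list(sequences)
        lengths = {len(s) for s in sequences.values()}
        if len(lengths) != 1:
            raise ValueError("sequences are not aligned (unequal lengths)")
        (length,) = lengths
        if length % 3 != 0:
            raise ValueError(f"alignment length {length} is not a multiple of 3")
        n_codons = length // 3
        mat = np.full((len(taxa), n_codons), MISSING, dtype=np.int64)
        for r, taxon in enumerate(taxa):
            seq = sequences[taxon]
            for s in range(n_codons):
                mat[r, s] = encode_codon(seq[3 * s:3 * s + 3], taxon, s)
        return cls(locus_id, taxa, mat)

    @classmethod
    def from_fasta(cls, path: str | Path, locus_id: str | None = None) -> "CodonAlignment":
        path = Path(path)
        records = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls.from_sequences(records, locus_id or path.stem)

    # ------------------------------------------------------------------ I/O
    def codon_string(self, row: int) -> str:
        out = []
        for s in self.codons[row]:
            out.append("---" if s == MISSING else SENSE_CODONS[s])
        return "".join(out)

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r, taxon in enumerate(self.taxa):
                fh.write(f">{taxon}\n{self.codon_string(r)}\n")

    # ------------------------------------------------------------ transforms
    def nucleotide_matrix(self) -> np.ndarray:
        """Nucleotide view: (n_taxa, 3*n_codons) ints, MISSING for gaps."""
        out = np.full((self.n_taxa, 3 * self.n_codons), MISSING, dtype=np.int64)
        codon_nucs = np.array(
            [[NUC_INDEX[c] for c in codon] for codon in SENSE_CODONS])
        present = self.codons != MISSING
        for pos in range(3):
            col = out[:, pos::3]
            col[present] = codon_nucs[self.codons[present], pos]
        return out

    def amino_acid_matrix(self) -> np.ndarray:
        out = np.full_like(self.codons, MISSING)
        present = self.codons != MISSING
        out[present] = CODON_AA_INDEX[self.codons[present]]
        return out

    def subset(self, taxa: Iterable[str]) -> "CodonAlignment":
        taxa = list(taxa)
        missing = set(taxa) - set(self.taxa)
        if missing:
            raise ValueError(f"taxa not in alignment: {sorted(missing)}")
        rows = [self.taxa.index(t) for t in taxa]
        return CodonAlignment(self.locus_id, taxa, self.codons[rows].copy())
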