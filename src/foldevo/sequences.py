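"""Codon-level genotypes, genetic codes, translation and GC accounting.

The evolving genotype is a protein-coding DNA sequence read in a fixed
frame.  Mutation acts at the nucleotide level (see :mod:`foldevo.evolution`)
while selection acts on the translated protein, so this module provides the
genotype side of the genotype-to-phenotype map: genetic codes (the standard
bacterial code and the UGA->Trp reassignment found in *Hodgkinia
cicadicola*), translation, GC-content accounting by codon position, and the
stationary codon measure of the HKY mutation process, from which the
mutational pull of GC bias on amino-acid composition (hydrophobicity in
particular) can be computed exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = "ACGT"
NT_INDEX = {nt: i for i, nt in enumerate(NUCLEOTIDES)}

#: Fixed alphabetical one-letter amino-acid order used throughout the package
#: (energy matrices, hydrophobicity scales, lookup tables).
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: All 64 codons in lexicographic ACGT order; codon index = 16*n1 + 4*n2 + n3.
CODONS = ["".join(c) for c in itertools.product(NUCLEOTIDES, repeat=3)]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

STOP = "*"

#: Kyte-Doolittle hydropathy scale (Kyte & Doolittle 1982), the default
#: diagnostic hydrophobicity scale.  Positive = hydrophobic.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}


class NonviableSequenceError(ValueError):
    """Raised when a coding sequence contains a stop codon.

    Callers in the evolutionary dynamics map this condition to fitness 0
    (a truncated protein is treated as lethal), they never propagate it.
    """


@dataclass(frozen=True)
class GeneticCode:
    """A total map from the 64 codons to amino acids or stop.

    ``table[codon]`` is a one-letter amino acid or ``"*"`` for stop.
    """

    name: str
    table: Mapping[str, str]

    def __post_init__(self) -> None:
        if set(self.table) != set(CODONS):
            raise ValueError("genetic code must map all 64 codons exactly once")
        bad = set(self.table.values()) - set(AMINO_ACIDS) - {STOP}
        if bad:
            raise ValueError(f"unknown amino-acid symbols in code: {bad}")

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.table[c] == STOP)

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(c for c in CODONS if self.table[c] != STOP)

    def aa_lookup(self) -> np.ndarray:
        """Codon-index -> amino-acid-index array, -1 for stop codons."""
        out = np.full(64, -1, dtype=np.int64)
        for codon, aa in self.table.items():
            if aa != STOP:
                out[CODON_INDEX[codon]] = AA_INDEX[aa]
        return out


def _code_from_ncbi(name: str, ncbi_id: int) -> GeneticCode:
    tbl = CodonTable.unambiguous_dna_by_id[ncbi_id]
    table = dict(tbl.forward_table)
    for stop in tbl.stop_codons:
        table[stop] = STOP
    return GeneticCode(name=name, table=table)


#: Standard (bacterial) genetic code: 61 sense codons, 3 stops.
STANDARD_CODE = _code_from_ncbi("standard", 1)

#: UGA->Trp reassignment (as in *Hodgkinia*; NCBI translation table 4):
#: TGA codes for tryptophan, leaving exactly 2 stop codons.
UGA_TRP_CODE = _code_from_ncbi("uga_trp", 4)

GENETIC_CODES: dict[str, GeneticCode] = {
    "standard": STANDARD_CODE,
    "uga_trp": UGA_TRP_CODE,
}


@dataclass
class CodingSequence:
    """An in-frame protein-coding DNA sequence plus its genetic code."""

    nucleotides: str
    code: GeneticCode = STANDARD_CODE

    def __post_init__(self) -> None:
        self.nucleotides = self.nucleotides.upper().replace("U", "T")
        if len(self.nucleotides) % 3 != 0:
            raise ValueError("coding sequence length must be a multiple of 3")
        bad = set(self.nucleotides) - set(NUCLEOTIDES)
        if bad:
            raise ValueError(f"non-ACGT characters in sequence: {bad}")

    @classmethod
    def from_codons(cls, codons: Iterable[str], code: GeneticCode = STANDARD_CODE) -> "CodingSequence":
        return cls("".join(codons), code)

    @property
    def codons(self) -> list[str]:
        s = self.nucleotides
        return [s[i:i + 3] for i in range(0, len(s), 3)]

    @property
    def n_codons(self) -> int:
        return len(self.nucleotides) // 3

    def nt_indices(self) -> np.ndarray:
        return np.array([NT_INDEX[n] for n in self.nucleotides], dtype=np.int64)

    def __len__(self) -> int:
        return len(self.nucleotides)


def translate(seq: CodingSequence) -> str:
    """Translate a coding sequence, raising on any stop codon.

    The evolutionary dynamics treats premature stops as lethal, so callers
    catch :class:`NonviableSequenceError` and assign fitness 0.
    """
    if len(seq) == 0:
        raise ValueError("empty coding sequence")
    aas = []
    for i, codon in enumerate(seq.codons):
        aa = seq.code.table[codon]
        if aa == STOP:
            raise NonviableSequenceError(f"stop codon {codon} at codon position {i}")
        aas.append(aa)
    return "".join(aas)


def reverse_translate(protein: str, code: GeneticCode = STANDARD_CODE,
                      chooser: Mapping[str, str] | None = None,
                      gc: float | None = None, kappa: float = 4.0) -> CodingSequence:
    """Back-translate a protein through a fixed codon-choice map.

    If ``chooser`` is None, the codon with the highest HKY-stationary
    probability at GC usage ``gc`` (default 0.5) is chosen for each amino
    acid, giving a deterministic genotype whose translation round-trips.
    """
    if chooser is None:
        g = 0.5 if gc is None else gc
        p = hky_stationary_codon_distribution(g, kappa, code, exclude_stops=True)
        chooser = {}
        for aa in set(protein):
            cands = [c for c in code.sense_codons if code.table[c] == aa]
            if not cands:
                raise ValueError(f"amino acid {aa} has no codon under code {code.name}")
            chooser[aa] = max(cands, key=lambda c: p[CODON_INDEX[c]])
    return CodingSequence.from_codons((chooser[aa] for aa in protein), code)


def gc_content(seq: CodingSequence, positions: Sequence[int] = (1, 2, 3)) -> float:
    """Fraction of G or C among nucleotides at the selected codon positions.

    ``positions`` uses 1-based codon positions; GC3 is ``positions=(3,)``.
    """
    pos = sorted(set(positions))
    if not pos or any(p not in (1, 2, 3) for p in pos):
        raise ValueError("positions must be a non-empty subset of {1, 2, 3}")
    nts = []
    s = seq.nucleotides
    for p in pos:
        nts.append(s[p - 1::3])
    joined = "".join(nts)
    return (joined.count("G") + joined.count("C")) / len(joined)


def hky_nucleotide_frequencies(gc: float) -> np.ndarray:
    """HKY stationary nucleotide frequencies in ACGT order.

    Chargaff's second parity rule is imposed: f_A = f_T = (1-gc)/2 and
    f_C = f_G = gc/2, so the mutation model depends on GC usage alone.
    """
    if not 0.0 < gc < 1.0:
        raise ValueError("gc usage must be strictly between 0 and 1")
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def hky_stationary_codon_distribution(gc: float, kappa: float = 4.0,
                                      code: GeneticCode = STANDARD_CODE,
                                      exclude_stops: bool = False) -> np.ndarray:
    """Stationary codon probabilities of the HKY mutation process.

    The stationary law of HKY is the product measure of the nucleotide
    frequencies over the three codon positions; the transition/transversion
    ratio ``kappa`` affects the dynamics but not the stationary measure (it
    is accepted here so callers can pass a full mutation parameterization).
    With ``exclude_stops`` the measure is renormalized over sense codons,
    giving the codon usage expected under mutation alone in coding frame.
    """
    pi = hky_nucleotide_frequencies(gc)
    del kappa  # stationary law is kappa-independent
    p = np.ones(64)
    for i, codon in enumerate(CODONS):
        for nt in codon:
            p[i] *= pi[NT_INDEX[nt]]
    if exclude_stops:
        for stop in code.stop_codons:
            p[CODON_INDEX[stop]] = 0.0
        p /= p.sum()
    return p


def kd_scale_vector(normalized: bool = False) -> np.ndarray:
    """Kyte-Doolittle scale as a 20-vector in ``AMINO_ACIDS`` order.

    With ``normalized=True`` the scale is affinely mapped to [0, 1]
    (Arg -> 0, Ile -> 1), the form used by the synthetic hydrophobic
    contact potential.
    """
    h = np.array([KYTE_DOOLITTLE[a] for a in AMINO_ACIDS])
    if normalized:
        h = (h - h.min()) / (h.max() - h.min())
    return h


def expected_hydrophobicity(gc: float, kappa: float = 4.0,
                            scale: np.ndarray | None = None,
                            code: GeneticCode = STANDARD_CODE) -> float:
    """Mean hydrophobicity of a residue drawn from the mutation-only codon measure.

    Because AT-rich codons encode the strongly hydrophobic residues
    (F, I, L, M, Y) while GC-rich codons encode A, G, P, R, W, this
    expectation decreases with GC usage for any standard hydrophobicity
    scale: AT mutation bias pushes proteomes hydrophobic.
    """
    if scale is None:
        scale = kd_scale_vector()
    scale = np.asarray(scale, dtype=float)
    if scale.shape != (20,):
        raise ValueError("scale must be a 20-vector in AMINO_ACIDS order")
    p = hky_stationary_codon_distribution(gc, kappa, code, exclude_stops=True)
    aa_of = code.aa_lookup()
    sense = aa_of >= 0
    return float(np.dot(p[sense], scale[aa_of[sense]]))


def random_coding_sequence(n_codons: int, gc: float, rng: np.random.Generator,
                           kappa: float = 4.0,
                           code: GeneticCode = STANDARD_CODE) -> CodingSequence:
    """Draw a stop-free coding sequence from the HKY-stationary codon measure."""
    p = hky_stationary_codon_distribution(gc, kappa, code, exclude_stops=True)
    idx = rng.choice(64, size=n_codons, p=p)
    return CodingSequence.from_codons((CODONS[i] for i in idx), code)


# --------------------------------------------------------------------------
# FASTA I/O

def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into (id, sequence) tuples."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def write_fasta(path, records: Iterable[tuple[str, str]]) -> None:
    """Write (id, sequence) tuples to a FASTA file."""
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")
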