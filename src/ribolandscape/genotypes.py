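"""Combinatorial genotype library over the variable positions of a ribozyme.

The experimental system is a combinatorial library of the *Azoarcus* group I
self-splicing intron in which a small number of nucleotide positions (seven in
the shipped default) are fully randomized, giving ``4**L`` sequence variants.
A *genotype* is represented throughout the package as the length-``L`` string
of RNA alleles at the variable positions, ordered by position; the fixed
remainder of the reference sequence is implied.  Genotypes sort
lexicographically with ``A < C < G < U`` (which is plain ASCII order), and the
integer encoding used for vectorized work is the base-4 number obtained by
reading the allele string with ``A,C,G,U -> 0,1,2,3``, so integer order equals
lexicographic order.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np

RNA_ALPHABET = "ACGU"
ALLELE_INDEX = {c: i for i, c in enumerate(RNA_ALPHABET)}

# DNA template of the Azoarcus group I intron library ("N" marks the
# randomized sites).  The template starts at intron nucleotide 9, so intron
# numbering = 0-based offset + 9; the N offsets map to intron positions
# 90, 119, 128, 153, 158, 177 and 184.
_TEMPLATE_DNA = (
    "GTGCCTTGCGCCGGGAAACCACGCA"
    "AGGGATGGTGTCAAATTCGGCGAAACC"
    "TAAGCGCCCGCCCGGGCGTATGGCA"
    "ACGCNGAGCCAAGCT"
    "TCGGCGCCTGCGCCGATGNAGGT"
    "GTAGNGACTAGACGGCACCCACC"
    "TAAGGCNAACGNTATGGTGAAG"
    "GCATAGTCNAGGG"
    "AGNGGCGAAAG"
    "TCACACAAACCGG"
)

#: Wild-type alleles at the randomized sites, in position order.
WILD_TYPE_ALLELES = "CAAACCU"

DEFAULT_VARIABLE_POSITIONS: tuple[int, ...] = tuple(
    i for i, c in enumerate(_TEMPLATE_DNA) if c == "N"
)

#: Intron-numbering labels for the default variable positions (metadata only).
DEFAULT_POSITION_LABELS: tuple[int, ...] = tuple(
    i + 9 for i in DEFAULT_VARIABLE_POSITIONS
)

#: Magnesium concentrations (mM) of the default titration series.
DEFAULT_MG_LEVELS: tuple[float, ...] = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 16.0, 48.0)


def dna_to_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def rna_to_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _build_default_reference() -> str:
    seq = list(dna_to_rna(_TEMPLATE_DNA))
    for pos, allele in zip(DEFAULT_VARIABLE_POSITIONS, WILD_TYPE_ALLELES):
        seq[pos] = allele
    return "".join(seq)


DEFAULT_REFERENCE: str = _build_default_reference()


class LibraryValidationError(ValueError):
    """A LibrarySpec field violates its invariant; names the offending field."""

    def __init__(self, fld: str, message: str):
        self.field = fld
        super().__init__(f"{fld}: {message}")


@dataclass(frozen=True)
class LibrarySpec:
    """Immutable description of a combinatorial variant library.

    Parameters
    ----------
    reference_sequence
        The full-length wild-type sequence (RNA alphabet; DNA input is
        converted).  Alleles at ``variable_positions`` define the wild-type
        genotype.
    variable_positions
        Strictly increasing 0-based offsets of the randomized sites.
    mg_levels
        Strictly increasing magnesium concentrations (mM) of the titration.
    replicates
        Number of experimental replicates per condition.
    position_labels
        Optional display labels (e.g. intron numbering); metadata only.
    """

    reference_sequence: str = DEFAULT_REFERENCE
    variable_positions: tuple[int, ...] = DEFAULT_VARIABLE_POSITIONS
    mg_levels: tuple[float, ...] = DEFAULT_MG_LEVELS
    replicates: int = 3
    position_labels: tuple[int, ...] | None = field(default=None)

    def __post_init__(self):
        ref = dna_to_rna(str(self.reference_sequence))
        if not ref or any(c not in RNA_ALPHABET for c in ref):
            raise LibraryValidationError(
                "reference_sequence", "must be a non-empty A/C/G/U(T) string"
            )
        object.__setattr__(self, "reference_sequence", ref)
        pos = tuple(int(p) for p in self.variable_positions)
        object.__setattr__(self, "variable_positions", pos)
        if len(pos) == 0:
            raise LibraryValidationError("variable_positions", "must be non-empty")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise LibraryValidationError(
                "variable_positions", "must be strictly increasing"
            )
        if pos[0] < 0 or pos[-1] >= len(ref):
            raise LibraryValidationError(
                "variable_positions",
                f"offsets must lie within the reference (length {len(ref)})",
            )
        mg = tuple(float(m) for m in self.mg_levels)
        object.__setattr__(self, "mg_levels", mg)
        if len(mg) == 0 or any(m <= 0 for m in mg):
            raise LibraryValidationError("mg_levels", "must be positive")
        if any(b <= a for a, b in zip(mg, mg[1:])):
            raise LibraryValidationError("mg_levels", "must be strictly increasing")
        if int(self.replicates) < 1:
            raise LibraryValidationError("replicates", "must be a positive integer")
        object.__setattr__(self, "replicates", int(self.replicates))
        if self.position_labels is not None:
            labels = tuple(self.position_labels)
            if len(labels) != len(pos):
                raise LibraryValidationError(
                    "position_labels", "must have one label per variable position"
                )
            object.__setattr__(self, "position_labels", labels)

    @property
    def n_positions(self) -> int:
        return len(self.variable_positions)

    @property
    def library_size(self) -> int:
        return 4 ** self.n_positions

    @property
    def wild_type_alleles(self) -> str:
        return "".join(self.reference_sequence[p] for p in self.variable_positions)

    def full_sequence(self, genotype: str) -> str:
        """Reference sequence with the genotype's alleles substituted in."""
        if len(genotype) != self.n_positions:
            raise ValueError(
                f"genotype length {len(genotype)} != {self.n_positions} positions"
            )
        seq = list(self.reference_sequence)
        for pos, allele in zip(self.variable_positions, genotype):
            seq[pos] = allele
        return "".join(seq)


def build_library(spec: LibrarySpec) -> list[str]:
    """All ``4**L`` genotypes in lexicographic (A<C<G<U) order.

    The wild-type genotype is always a member; every allele combination
    appears exactly once.
    """
    return [
        "".join(alleles)
        for alleles in itertools.product(RNA_ALPHABET, repeat=spec.n_positions)
    ]


def genotype_to_index(genotype: str) -> int:
    """Base-4 integer encoding (A,C,G,U -> 0..3); equals lexicographic rank."""
    idx = 0
    for c in genotype:
        idx = idx * 4 + ALLELE_INDEX[c]
    return idx


def index_to_genotype(index: int, n_positions: int) -> str:
    alleles = []
    for _ in range(n_positions):
        alleles.append(RNA_ALPHABET[index % 4])
        index //= 4
    return "".join(reversed(alleles))


@lru_cache(maxsize=8)
def genotype_digit_matrix(n_positions: int) -> np.ndarray:
    """(4**L, L) array of allele codes for every genotype in lexicographic order."""
    idx = np.arange(4**n_positions)
    digits = np.empty((idx.size, n_positions), dtype=np.uint8)
    for p in range(n_positions):
        shift = n_positions - 1 - p
        digits[:, p] = (idx >> (2 * shift)) & 3
    return digits


def hamming_distance(g1: str, g2: str) -> int:
    if len(g1) != len(g2):
        raise ValueError(f"length mismatch: {len(g1)} vs {len(g2)}")
    return sum(a != b for a, b in zip(g1, g2))


def neighbors(genotype: str) -> list[str]:
    """The ``3L`` genotypes at Hamming distance 1, in deterministic order."""
    out = []
    for p, allele in enumerate(genotype):
        for alt in RNA_ALPHABET:
            if alt != allele:
                out.append(genotype[:p] + alt + genotype[p + 1 :])
    return out


@lru_cache(maxsize=8)
def neighbor_index_table(n_positions: int) -> np.ndarray:
    """(4**L, 3L) array: row g lists the indices of g's single-step neighbors."""
    digits = genotype_digit_matrix(n_positions).astype(np.int64)
    idx = np.arange(4**n_positions, dtype=np.int64)
    cols = []
    for p in range(n_positions):
        place = 4 ** (n_positions - 1 - p)
        current = digits[:, p]
        for delta in (1, 2, 3):
            new = (current + delta) % 4
            cols.append(idx + (new - current) * place)
    return np.stack(cols, axis=1)


def distances_to(genotype: str, n_positions: int) -> np.ndarray:
    """Hamming distance from ``genotype`` to every library member (lex order)."""
    digits = genotype_digit_matrix(n_positions)
    target = np.array([ALLELE_INDEX[c] for c in genotype], dtype=np.uint8)
    return (digits != target[None, :]).sum(axis=1)


def iter_library(spec: LibrarySpec) -> Iterator[str]:
    return iter(build_library(spec))
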