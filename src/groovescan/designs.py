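"""Library designs: fixed flanking residues around NNK-randomized peptide positions.

A design describes one yeast-display peptide library: the fixed flank residues
that constrain the binding register, the number of NNK-randomized positions,
the constant DNA context of the peptide-encoding region (3C-protease-site
coding sequence and an allele-identifying polymorphic segment), and the inline
barcode assigned to each round of selection.

The built-in designs mirror the two library architectures used for HLA-DR
selections: a randomized 9mer flanked by AA...WEEG (single designed register)
and a randomized 13mer flanked by A...G whose central 9mer window is the
designed core, leaving positions P(-2)..P11 diversified.

The constant-region nucleotide sequences and barcodes here are synthetic
stand-ins (real amplicon constants are instrument/primer specific); they carry
the structural features the read filters rely on and can be replaced via JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

from Bio.Data.CodonTable import standard_dna_table

# Fixed residue order used for every matrix in the package (alphabetical).
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}
STOP = "*"

#: all 32 NNK codons (N = any nucleotide, K = G or T)
NNK_CODONS = tuple(a + b + c for a in "ACGT" for b in "ACGT" for c in "GT")

#: standard genetic code as codon -> residue ('*' for stops), from Biopython
GENETIC_CODE = dict(standard_dna_table.forward_table)
for _stop in standard_dna_table.stop_codons:
    GENETIC_CODE[_stop] = STOP

#: number of NNK codons per residue (Leu/Arg/Ser have 3; amber TAG is the one stop)
NNK_CODON_COUNT = {}
for _c in NNK_CODONS:
    _aa = GENETIC_CODE[_c]
    NNK_CODON_COUNT[_aa] = NNK_CODON_COUNT.get(_aa, 0) + 1

#: single canonical codon used to encode each fixed flank residue
CANONICAL_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGC",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

# 3C protease site LEVLFQ/GP, encoded with the canonical codons above.
_3C_DNA = "".join(CANONICAL_CODON[a] for a in "LEVLFQGP")

# Synthetic allele-identifying polymorphic segments (stand-ins; see module docstring).
_POLY_TAG = {"dr401": "AAGGACATCCTG", "dr402": "AAGGACGAGGTG"}

# Synthetic inline round barcodes, one per selection round (0 = unselected).
_BARCODES = ("ACTGAC", "GTCAGT", "TTGCCA", "CAAGGT", "GGATTC", "TCCAAG")


@dataclass(frozen=True)
class LibraryDesign:
    """One peptide library: flanks, randomized positions, constant DNA context."""

    name: str
    flank5_aa: str
    n_random: int
    flank3_aa: str
    expected_core_offset: int
    constant5_dna: str
    constant3_dna: str
    barcode_by_round: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_random not in (9, 13):
            raise ValueError(f"n_random must be 9 or 13, got {self.n_random}")
        if self.expected_core_offset + 9 > self.peptide_length:
            raise ValueError("expected core does not fit inside the peptide")
        barcodes = list(self.barcode_by_round.values())
        if len(set(barcodes)) != len(barcodes):
            raise ValueError("round barcodes must be unique")
        if barcodes and len({len(b) for b in barcodes}) != 1:
            raise ValueError("round barcodes must share a length")

    @property
    def peptide_length(self) -> int:
        return len(self.flank5_aa) + self.n_random + len(self.flank3_aa)

    @property
    def barcode_length(self) -> int:
        return len(next(iter(self.barcode_by_round.values()))) if self.barcode_by_round else 0

    @property
    def read_length(self) -> int:
        """Expected amplicon length: barcode + 5' constant + peptide CDS + 3' constant."""
        return (self.barcode_length + len(self.constant5_dna)
                + 3 * self.peptide_length + len(self.constant3_dna))

    @property
    def template(self) -> str:
        """Peptide template with X at randomized positions, e.g. AAXXXXXXXXXWEEG."""
        return self.flank5_aa + "X" * self.n_random + self.flank3_aa

    @property
    def randomized_slice(self) -> slice:
        """Slice of the peptide covering the NNK-randomized positions."""
        return slice(len(self.flank5_aa), len(self.flank5_aa) + self.n_random)

    def round_of_barcode(self, barcode: str) -> int | None:
        for rnd, bc in self.barcode_by_round.items():
            if bc == barcode:
                return rnd
        return None

    def flank_dna(self) -> tuple[str, str]:
        """Canonical-codon DNA encoding the fixed flank residues."""
        f5 = "".join(CANONICAL_CODON[a] for a in self.flank5_aa)
        f3 = "".join(CANONICAL_CODON[a] for a in self.flank3_aa)
        return f5, f3

    def to_json(self, path) -> None:
        d = asdict(self)
        d["barcode_by_round"] = {str(k): v for k, v in self.barcode_by_round.items()}
        with open(path, "w") as fh:
            json.dump(d, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LibraryDesign":
        with open(path) as fh:
            d = json.load(fh)
        d["barcode_by_round"] = {int(k): v for k, v in d["barcode_by_round"].items()}
        return cls(**d)


def _make_design(name: str, allele: str, flank5: str, n_random: int, flank3: str,
                 core_offset: int, n_rounds: int = 5) -> LibraryDesign:
    constant5 = "GCTAGCGGTTCC"  # synthetic 5' amplicon constant
    constant3 = "GGAGGCTCC" + _3C_DNA + _POLY_TAG[allele]
    return LibraryDesign(
        name=name,
        flank5_aa=flank5,
        n_random=n_random,
        flank3_aa=flank3,
        expected_core_offset=core_offset,
        constant5_dna=constant5,
        constant3_dna=constant3,
        barcode_by_round={r: _BARCODES[r] for r in range(n_rounds + 1)},
    )


_BUILTINS = {
    # 9mer libraries: AA + X9 + WEEG, designed core = the 9 randomized positions.
    "dr401_9mer": lambda: _make_design("dr401_9mer", "dr401", "AA", 9, "WEEG", 2),
    "dr402_9mer": lambda: _make_design("dr402_9mer", "dr402", "AA", 9, "WEEG", 2),
    # 13mer library: A + X13 + G, designed core = the central 9mer window so that
    # P(-2)..P11 are diversified.
    "dr401_13mer": lambda: _make_design("dr401_13mer", "dr401", "A", 13, "G", 3),
}


def builtin_design(name: str) -> LibraryDesign:
    """Return one of the built-in library designs.

    Parameters
    ----------
    name : one of ``dr401_9mer``, ``dr401_13mer``, ``dr402_9mer``.
    """
    try:
        factory = _BUILTINS[name]
    except KeyError:
        raise ValueError(f"unknown builtin design: {name!r}") from None
    return factory()
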