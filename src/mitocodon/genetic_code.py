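"""Genetic-code abstraction built on NCBI translation tables.

The toolkit defaults to the vertebrate mitochondrial code (NCBI table 2),
under which TGA encodes Trp, ATA encodes Met, and AGA/AGG are stop codons,
so the synonymous-family structure differs from the standard code (e.g. Arg
is a 4-fold family CGN, and Met/Trp are 2-fold families). All downstream
indices (RSCU, ENC, GC3s, CAI, ...) derive their family partition from the
active code rather than hard-coding standard-code degeneracies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from itertools import product

from Bio.Data import CodonTable

BASES = "TCAG"
ALL_CODONS = tuple("".join(p) for p in product(BASES, repeat=3))

#: Default start-codon policy: permissive {ATG, GTG}. Vertebrate mitogenome
#: annotations use GTG for COX1 in many clupeiform fishes; NCBI table 2
#: formally allows ATT/ATC/ATA as well, which `strict=False` on
#: :func:`mitocodon.io.extract_cds` admits via the table itself.
DEFAULT_START_CODONS = frozenset({"ATG", "GTG"})


@dataclass(frozen=True)
class GeneticCode:
    """A translation table with its synonymous-family partition.

    Parameters
    ----------
    table_id : int
        NCBI translation table number (2 = vertebrate mitochondrial).
    """

    table_id: int
    codon_to_aa: dict = field(repr=False)
    stop_codons: frozenset
    start_codons: frozenset
    families: dict = field(repr=False)  # aa -> tuple of sense codons

    @classmethod
    def from_ncbi(cls, table_id: int = 2) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = dict(table.forward_table)
        stops = frozenset(table.stop_codons)
        families: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            if codon in stops:
                continue
            families.setdefault(codon_to_aa[codon], []).append(codon)
        return cls(
            table_id=table_id,
            codon_to_aa=codon_to_aa,
            stop_codons=stops,
            start_codons=frozenset(table.start_codons),
            families={aa: tuple(cods) for aa, cods in families.items()},
        )

    # -- family structure ---------------------------------------------------

    @property
    def sense_codons(self) -> tuple:
        return tuple(c for c in ALL_CODONS if c not in self.stop_codons)

    def degeneracy(self, codon: str) -> int:
        """Number of synonyms (family size) of the codon's amino acid."""
        return len(self.families[self.codon_to_aa[codon]])

    def family_of(self, codon: str) -> tuple:
        return self.families[self.codon_to_aa[codon]]

    def degeneracy_classes(self) -> dict:
        """Map family size k -> list of amino acids with k synonyms."""
        classes: dict[int, list[str]] = {}
        for aa, cods in self.families.items():
            classes.setdefault(len(cods), []).append(aa)
        return classes

    def multi_synonym_codons(self) -> tuple:
        """Sense codons of amino acids with at least two synonyms."""
        return tuple(c for c in self.sense_codons if self.degeneracy(c) > 1)

    def synonymous_third_bases(self, codon: str) -> frozenset:
        """Bases that keep the amino acid unchanged at position 3."""
        aa = self.codon_to_aa[codon]
        return frozenset(
            b
            for b in BASES
            if codon[:2] + b not in self.stop_codons
            and self.codon_to_aa[codon[:2] + b] == aa
        )

    def is_stop(self, codon: str) -> bool:
        return codon in self.stop_codons

    def translate(self, cds: str) -> str:
        """Translate a frame-valid CDS; trailing stop rendered as '*'."""
        if len(cds) % 3:
            raise ValueError(f"CDS length {len(cds)} not a multiple of 3")
        out = []
        for i in range(0, len(cds), 3):
            codon = cds[i : i + 3].upper()
            out.append("*" if codon in self.stop_codons else self.codon_to_aa.get(codon, "X"))
        return "".join(out)


@lru_cache(maxsize=8)
def get_code(table_id: int = 2) -> GeneticCode:
    """Cached accessor for :class:`GeneticCode` instances."""
    return GeneticCode.from_ncbi(table_id)
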