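"""Base composition and strand-skew statistics.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C), computed over
unambiguous bases only. Codon-position composition pools positions 1/2/3
across all codons of a CDS set and reports GC1, GC2, GC3 and their mean
GC12 = (GC1 + GC2)/2, the quantities behind neutrality-plot analysis.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .genetic_code import GeneticCode, get_code


@dataclass(frozen=True)
class CompositionRecord:
    context: str
    counts: dict  # base -> count over A/T/G/C
    n_ambiguous: int

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def fraction(self, base: str) -> float:
        return self.counts[base] / self.total

    @property
    def at_content(self) -> float:
        return (self.counts["A"] + self.counts["T"]) / self.total

    @property
    def gc_content(self) -> float:
        return (self.counts["G"] + self.counts["C"]) / self.total

    @property
    def at_skew(self) -> float:
        a, t = self.counts["A"], self.counts["T"]
        if a + t == 0:
            raise ZeroDivisionError(f"{self.context}: no A/T bases")
        return (a - t) / (a + t)

    @property
    def gc_skew(self) -> float:
        g, c = self.counts["G"], self.counts["C"]
        if g + c == 0:
            raise ZeroDivisionError(f"{self.context}: no G/C bases")
        return (g - c) / (g + c)


def composition(seq: str, context: str = "sequence") -> CompositionRecord:
    """Count bases and derive fractions/skews; ambiguity codes are tallied
    separately and excluded from all fractions."""
    if not seq:
        raise ValueError("empty sequence")
    tally = Counter(seq.upper())
    counts = {b: tally.get(b, 0) for b in "ATGC"}
    n_ambiguous = len(seq) - sum(counts.values())
    if sum(counts.values()) == 0:
        raise ValueError("sequence contains no unambiguous bases")
    return CompositionRecord(context=context, counts=counts, n_ambiguous=n_ambiguous)


def codon_position_composition(
    cds_set,
    code: GeneticCode | None = None,
    exclude_stops: bool = True,
) -> dict:
    """Pool codon-position base counts across a CDS set.

    Returns {"p1": CompositionRecord, "p2": ..., "p3": ..., "GC1": ...,
    "GC2": ..., "GC3": ..., "GC12": ...}. Terminal/internal stop codons are
    dropped from the pool by default, consistent with the codon-usage
    indices.
    """
    code = code or get_code(2)
    pos_seqs = {1: [], 2: [], 3: []}
    for cds in cds_set:
        seq = cds.sequence if hasattr(cds, "sequence") else cds
        if len(seq) % 3:
            raise ValueError(f"CDS length {len(seq)} violates reading frame")
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3].upper()
            if exclude_stops and code.is_stop(codon):
                continue
            for p in (1, 2, 3):
                pos_seqs[p].append(codon[p - 1])
    out = {
        f"p{p}": composition("".join(pos_seqs[p]), context=f"position {p}")
        for p in (1, 2, 3)
    }
    out["GC1"] = out["p1"].gc_content
    out["GC2"] = out["p2"].gc_content
    out["GC3"] = out["p3"].gc_content
    out["GC12"] = (out["GC1"] + out["GC2"]) / 2
    return out


def gene_length_table(records) -> "pandas.DataFrame":
    """Gene x taxon matrix of feature lengths in bp, plus per-taxon totals.

    Missing genes are left as NA (pandas missing value), never zero.
    """
    import pandas as pd

    cells = {}
    for rec in records:
        for f in rec.features:
            cells.setdefault(f.name, {})[rec.taxon] = f.length
    df = pd.DataFrame(cells).T
    df.index.name = "gene"
    from .io import PCG_NAMES

    order = [g for g in PCG_NAMES if g in df.index] + [
        g for g in df.index if g not in PCG_NAMES
    ]
    df = df.loc[order]
    pcg = df.loc[[g for g in PCG_NAMES if g in df.index]]
    df.loc["PCG_total"] = pcg.sum(axis=0, min_count=1)
    return df
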