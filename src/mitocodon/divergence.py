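"""Per-gene divergence statistics across taxa.

Nucleotide diversity (Nei's pi), Kimura 2-parameter distances, and
Nei-Gojobori (proportional method) synonymous/nonsynonymous rates with
Jukes-Cantor correction. The Nei-Gojobori pathway and site accounting is
generalized to any genetic code; under the vertebrate mitochondrial code
the stop set {TAA, TAG, AGA, AGG} shapes both the potential-site counts
and the admissible mutation pathways.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations, permutations

from .genetic_code import GeneticCode, get_code

GAP_CHARS = frozenset("-.~?")
VALID = frozenset("ACGT")

_PURINES = frozenset("AG")


def _is_transition(a: str, b: str) -> bool:
    return (a in _PURINES) == (b in _PURINES)


@dataclass
class AlignmentBlock:
    """Equal-length homologous sequences for one gene across taxa.

    ``codon_positions`` optionally records the original codon position
    (1/2/3) of each column; position-stripping operations set and consult
    it so that successive strips compose correctly.
    """

    gene: str
    taxa: list
    sequences: list
    codon_positions: list | None = None

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in number")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"{self.gene}: unequal sequence lengths {sorted(lengths)}")
        self.sequences = [s.upper() for s in self.sequences]

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def pairs(self):
        return combinations(range(self.n_taxa), 2)

    @classmethod
    def from_fasta(cls, path, gene: str | None = None) -> "AlignmentBlock":
        from Bio import SeqIO
        from pathlib import Path

        taxa, seqs = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            taxa.append(rec.id)
            seqs.append(str(rec.seq).upper())
        if len(seqs) < 2:
            raise ValueError(f"{path}: alignment needs at least 2 sequences")
        return cls(gene=gene or Path(path).stem, taxa=taxa, sequences=seqs)

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for taxon, seq in zip(self.taxa, self.sequences):
                fh.write(f">{taxon}\n{seq}\n")


@dataclass(frozen=True)
class PairwiseDivergence:
    pair: tuple
    sites_compared: int
    P: float = float("nan")  # transition proportion
    Q: float = float("nan")  # transversion proportion
    d_k2p: float = float("nan")
    Ka: float = float("nan")
    Ks: float = float("nan")

    @property
    def ka_ks(self) -> float:
        if self.Ks == 0 or math.isnan(self.Ks) or math.isnan(self.Ka):
            return float("nan")
        return self.Ka / self.Ks


# -- nucleotide diversity ----------------------------------------------------


def nucleotide_diversity(block: AlignmentBlock, site_handling: str = "complete") -> float:
    """Nei's pi: mean over unordered pairs of (differences / compared sites).

    ``complete`` deletion (the DnaSP convention) drops every column with a
    gap or ambiguity in any sequence before comparing; ``pairwise`` drops
    columns per pair.
    """
    if block.n_taxa < 2:
        raise ValueError("pi needs at least 2 sequences")
    seqs = block.sequences
    if site_handling == "complete":
        keep = [
            i for i in range(block.length)
            if all(s[i] in VALID for s in seqs)
        ]
        if not keep:
            raise ValueError(f"{block.gene}: no comparable sites after complete deletion")
        seqs = ["".join(s[i] for i in keep) for s in seqs]
    elif site_handling != "pairwise":
        raise ValueError(f"unknown site handling {site_handling!r}")
    total = 0.0
    n_pairs = 0
    for i, j in block.pairs():
        si, sj = seqs[i], seqs[j]
        compared = diffs = 0
        for a, b in zip(si, sj):
            if a in VALID and b in VALID:
                compared += 1
                if a != b:
                    diffs += 1
        if compared == 0:
            raise ValueError(f"{block.gene}: pair {i},{j} has no comparable sites")
        total += diffs / compared
        n_pairs += 1
    return total / n_pairs


# -- K2P ---------------------------------------------------------------------


def k2p(seq_i: str, seq_j: str, pair=("i", "j")) -> PairwiseDivergence:
    """Kimura 2-parameter distance from transition (P) and transversion (Q)
    proportions: d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).

    Columns with gaps or ambiguity codes in either sequence are excluded
    pairwise. Saturated pairs (a log argument <= 0) yield NaN.
    """
    if len(seq_i) != len(seq_j):
        raise ValueError("sequences differ in length")
    n = ts = tv = 0
    for a, b in zip(seq_i.upper(), seq_j.upper()):
        if a not in VALID or b not in VALID:
            continue
        n += 1
        if a != b:
            if _is_transition(a, b):
                ts += 1
            else:
                tv += 1
    if n == 0:
        raise ValueError("no comparable sites")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        d = float("nan")  # saturated
    else:
        d = -0.5 * math.log(w1) - 0.25 * math.log(w2)
    return PairwiseDivergence(pair=tuple(pair), sites_compared=n, P=P, Q=Q, d_k2p=d)


# -- Nei-Gojobori ------------------------------------------------------------


@lru_cache(maxsize=16)
def _site_table(table_id: int) -> dict:
    """Per-codon potential synonymous-site counts.

    For each sense codon, s = sum over the three positions of (number of
    synonymous single-nucleotide changes at that position) / 3. Changes
    creating stop codons count as nonsynonymous so that s + n = 3 exactly.
    """
    code = get_code(table_id)
    table = {}
    for codon in code.sense_codons:
        s = 0.0
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1 :]
                if not code.is_stop(mutant) and code.codon_to_aa[mutant] == code.codon_to_aa[codon]:
                    s += 1.0 / 3.0
        table[codon] = s
    return table


@lru_cache(maxsize=200_000)
def _pathway_diffs(codon_i: str, codon_j: str, table_id: int) -> tuple:
    """Observed (synonymous, nonsynonymous) differences between two codons,
    averaged over all shortest substitution pathways.

    Pathways passing through a stop codon are excluded; if every pathway is
    blocked, all pathways are used with stop-traversing steps counted as
    nonsynonymous (the conservative fallback).
    """
    code = get_code(table_id)
    positions = [p for p in range(3) if codon_i[p] != codon_j[p]]
    if not positions:
        return (0.0, 0.0)

    def walk(order):
        sd = nd = 0.0
        current = codon_i
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_j[pos] + current[pos + 1 :]
            if code.is_stop(nxt):
                blocked = True
                nd += 1.0
            elif code.is_stop(current):
                nd += 1.0
            elif code.codon_to_aa[current] == code.codon_to_aa[nxt]:
                sd += 1.0
            else:
                nd += 1.0
            current = nxt
        return sd, nd, blocked

    results = [walk(order) for order in permutations(positions)]
    open_paths = [(s, n) for s, n, blocked in results if not blocked]
    pool = open_paths or [(s, n) for s, n, _ in results]
    sd = sum(s for s, _ in pool) / len(pool)
    nd = sum(n for _, n in pool) / len(pool)
    return (sd, nd)


def nei_gojobori(
    codon_seq_i: str,
    codon_seq_j: str,
    code: GeneticCode | None = None,
    pair=("i", "j"),
) -> PairwiseDivergence:
    """Nei-Gojobori proportional method with Jukes-Cantor correction.

    Potential synonymous (S) and nonsynonymous (N) site counts are averaged
    over the two sequences; observed differences are partitioned by
    averaging over all shortest substitution pathways between differing
    codons. Ks = -3/4 ln(1 - 4 pS / 3) and likewise Ka; a proportion >= 3/4
    leaves the corrected rate undefined (NaN).

    Codons with gaps/ambiguity in either sequence, and stop codons, are
    excluded pairwise.
    """
    code = code or get_code(2)
    if len(codon_seq_i) != len(codon_seq_j):
        raise ValueError("sequences differ in length")
    if len(codon_seq_i) % 3:
        raise ValueError("sequence length violates reading frame")
    sites = _site_table(code.table_id)
    s_i = s_j = 0.0
    sd = nd = 0.0
    n_codons = 0
    for k in range(0, len(codon_seq_i), 3):
        ci = codon_seq_i[k : k + 3].upper()
        cj = codon_seq_j[k : k + 3].upper()
        if ci not in sites or cj not in sites:  # gap/ambiguous/stop codon
            continue
        n_codons += 1
        s_i += sites[ci]
        s_j += sites[cj]
        dsd, dnd = _pathway_diffs(ci, cj, code.table_id)
        sd += dsd
        nd += dnd
    if n_codons == 0:
        raise ValueError("no comparable codons")
    S = (s_i + s_j) / 2.0
    N = 3.0 * n_codons - S
    pS = sd / S if S > 0 else float("nan")
    pN = nd / N if N > 0 else float("nan")

    def jc(p):
        if math.isnan(p) or p >= 0.75:
            return float("nan")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    return PairwiseDivergence(
        pair=tuple(pair), sites_compared=3 * n_codons,
        Ka=jc(pN), Ks=jc(pS),
    )


def potential_sites(codon_seq_i: str, codon_seq_j: str, code: GeneticCode | None = None):
    """(S, N, codons_compared) for a sequence pair; S + N = 3 * codons."""
    code = code or get_code(2)
    sites = _site_table(code.table_id)
    s_i = s_j = 0.0
    n_codons = 0
    for k in range(0, len(codon_seq_i), 3):
        ci, cj = codon_seq_i[k : k + 3].upper(), codon_seq_j[k : k + 3].upper()
        if ci not in sites or cj not in sites:
            continue
        n_codons += 1
        s_i += sites[ci]
        s_j += sites[cj]
    S = (s_i + s_j) / 2.0
    return S, 3.0 * n_codons - S, n_codons


# -- per-gene summaries ------------------------------------------------------


def pairwise_k2p(block: AlignmentBlock) -> list:
    return [
        k2p(block.sequences[i], block.sequences[j], pair=(block.taxa[i], block.taxa[j]))
        for i, j in block.pairs()
    ]


def pairwise_kaks(block: AlignmentBlock, code: GeneticCode | None = None) -> list:
    return [
        nei_gojobori(
            block.sequences[i], block.sequences[j], code=code,
            pair=(block.taxa[i], block.taxa[j]),
        )
        for i, j in block.pairs()
    ]


def gene_summary(
    blocks: dict,
    code: GeneticCode | None = None,
    ratio_averaging: str = "mean_of_ratios",
    pi_site_handling: str = "complete",
) -> "pandas.DataFrame":
    """Per-gene table of Pi, mean pairwise K2P and mean Ka/Ks.

    ``ratio_averaging``: "mean_of_ratios" (arithmetic mean of defined
    per-pair Ka/Ks, the default) or "ratio_of_means" (mean Ka / mean Ks).
    """
    import numpy as np
    import pandas as pd

    from .io import PCG_NAMES

    rows = []
    for gene in sorted(blocks, key=lambda g: PCG_NAMES.index(g) if g in PCG_NAMES else 99):
        block = blocks[gene]
        pi = nucleotide_diversity(block, site_handling=pi_site_handling)
        k2ps = [d.d_k2p for d in pairwise_k2p(block)]
        kaks_pairs = pairwise_kaks(block, code=code)
        if ratio_averaging == "mean_of_ratios":
            ratios = [d.ka_ks for d in kaks_pairs if not math.isnan(d.ka_ks)]
            kaks = float(np.mean(ratios)) if ratios else float("nan")
        elif ratio_averaging == "ratio_of_means":
            kas = [d.Ka for d in kaks_pairs if not math.isnan(d.Ka)]
            kss = [d.Ks for d in kaks_pairs if not math.isnan(d.Ks)]
            kaks = float(np.mean(kas) / np.mean(kss)) if kas and kss and np.mean(kss) else float("nan")
        else:
            raise ValueError(f"unknown ratio averaging {ratio_averaging!r}")
        rows.append(
            {
                "gene": gene,
                "Pi": pi,
                "K2P_mean": float(np.nanmean(k2ps)),
                "KaKs_mean": kaks,
            }
        )
    return pd.DataFrame(rows)
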