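"""Synthetic mitogenome and CDS-family generator.

Produces codon-aligned gene families evolved on a star tree under a simple
codon-level Markov process (transition/transversion ratio ``kappa``,
nonsynonymous/synonymous ratio ``omega``), with third-position composition
controlled at the root (GC3 and AT/GC skews), and can emit the result as
minimal annotated GenBank records exercising every parsing path: a
GTG-initiated gene, a truncated-stop gene, a light-strand gene, 22 tRNAs,
two rRNAs, a control region of per-taxon variable length and the
light-strand replication origin.

Every operation is driven by a mandatory integer seed; identical configs
produce byte-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from pathlib import Path

import numpy as np

from .divergence import AlignmentBlock
from .genetic_code import GeneticCode, get_code
from .io import PCG_NAMES, MitogenomeRecord, GeneFeature, write_genbank

#: Approximate codon counts of the 13 vertebrate mitochondrial PCGs.
DEFAULT_GENES = (
    ("ATP6", 227), ("ATP8", 56), ("COX1", 518), ("COX2", 230), ("COX3", 261),
    ("CYTB", 380), ("NAD1", 324), ("NAD2", 348), ("NAD3", 116), ("NAD4", 460),
    ("NAD4L", 98), ("NAD5", 612), ("NAD6", 172),
)

TRNA_LABELS = (
    "tRNA-Phe", "tRNA-Val", "tRNA-Leu", "tRNA-Ile", "tRNA-Gln", "tRNA-Met",
    "tRNA-Trp", "tRNA-Ala", "tRNA-Asn", "tRNA-Cys", "tRNA-Tyr", "tRNA-Ser",
    "tRNA-Asp", "tRNA-Lys", "tRNA-Gly", "tRNA-Arg", "tRNA-His", "tRNA-Ser",
    "tRNA-Leu", "tRNA-Glu", "tRNA-Thr", "tRNA-Pro",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator.

    ``divergence`` is the expected pairwise divergence d between any two
    tips of the star tree, in substitutions per nucleotide site (each tip
    sits d/2 from the root). Composition targets apply to the third codon
    position of the root sequence; skews use the (X - Y)/(X + Y)
    convention.
    """

    seed: int
    n_taxa: int = 7
    genes: tuple = DEFAULT_GENES
    target_gc3: float = 0.405
    at3_skew: float = 0.31
    gc3_skew: float = -0.47
    kappa: float = 2.0
    omega: float = 0.03
    divergence: float = 0.2
    table_id: int = 2

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.omega < 0 or self.divergence < 0:
            raise ValueError("omega and divergence must be non-negative")

    def third_position_probs(self) -> dict:
        """Solve base probabilities at position 3 from GC3 and the skews."""
        gc = self.target_gc3
        at = 1.0 - gc
        a = at * (1.0 + self.at3_skew) / 2.0
        t = at - a
        g = gc * (1.0 + self.gc3_skew) / 2.0
        c = gc - g
        probs = {"A": a, "T": t, "G": g, "C": c}
        if any(p < 0 for p in probs.values()):
            raise ValueError(f"unattainable composition target: {probs}")
        return probs


@dataclass
class TruthRecord:
    """Realized event counts per branch, for estimator-recovery oracles."""

    config: SimulationConfig
    substitutions: dict = field(default_factory=dict)  # (gene, taxon) -> counts

    def totals(self) -> dict:
        keys = ("synonymous", "nonsynonymous", "transitions", "transversions")
        out = {k: 0 for k in keys}
        for counts in self.substitutions.values():
            for k in keys:
                out[k] += counts[k]
        return out


_PURINES = frozenset("AG")


@lru_cache(maxsize=32)
def _rate_tables(table_id: int, kappa: float, omega: float):
    """Per-codon total rates and neighbor transition kernels.

    Rate of a single-nucleotide change is kappa^[transition] *
    omega^[nonsynonymous]; changes into stop codons are forbidden.
    """
    code = get_code(table_id)
    totals = {}
    neighbors = {}
    for codon in code.sense_codons:
        nbrs = []
        rates = []
        for pos in range(3):
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mutant = codon[:pos] + b + codon[pos + 1 :]
                if code.is_stop(mutant):
                    continue
                is_ts = (codon[pos] in _PURINES) == (b in _PURINES)
                is_nonsyn = code.codon_to_aa[mutant] != code.codon_to_aa[codon]
                rate = (kappa if is_ts else 1.0) * (omega if is_nonsyn else 1.0)
                if rate > 0:
                    nbrs.append((mutant, is_ts, is_nonsyn))
                    rates.append(rate)
        total = float(sum(rates))
        totals[codon] = total
        cum = np.cumsum(rates) / total if total > 0 else np.array([])
        neighbors[codon] = (nbrs, cum)
    return totals, neighbors


def _sample_root(rng, n_codons: int, config: SimulationConfig, code: GeneticCode) -> list:
    """Root codons with exact third-position sampling distribution.

    Positions 1-2 are uniform; when a draw forms a stop codon only the
    first two positions are resampled, so the third-position marginal
    matches the target exactly.
    """
    p3 = config.third_position_probs()
    bases = np.array(list("ACGT"))
    thirds = rng.choice(bases, size=n_codons, p=[p3[b] for b in "ACGT"])
    codons = []
    for third in thirds:
        while True:
            prefix = "".join(rng.choice(bases, size=2))
            codon = prefix + third
            if not code.is_stop(codon):
                codons.append(codon)
                break
    return codons


def _evolve_branch(rng, codons: list, branch_nt: float, scale: float, totals, neighbors):
    """Evolve each codon site independently for duration T = 3*branch_nt/scale.

    ``scale`` is the mean per-codon rate of the root sequence, so the
    expected number of substitutions per nucleotide site equals branch_nt
    (up to composition drift along the branch).
    """
    counts = {"synonymous": 0, "nonsynonymous": 0, "transitions": 0, "transversions": 0}
    if branch_nt == 0 or scale == 0:
        return list(codons), counts
    duration = 3.0 * branch_nt / scale
    out = []
    for codon in codons:
        t = 0.0
        current = codon
        while True:
            rate = totals[current]
            if rate == 0:
                break
            t += rng.exponential(1.0 / rate)
            if t >= duration:
                break
            nbrs, cum = neighbors[current]
            idx = int(np.searchsorted(cum, rng.random(), side="right"))
            nxt, is_ts, is_nonsyn = nbrs[idx]
            counts["nonsynonymous" if is_nonsyn else "synonymous"] += 1
            counts["transitions" if is_ts else "transversions"] += 1
            current = nxt
        out.append(current)
    return out, counts


def simulate_cds_family(config: SimulationConfig):
    """Simulate all genes across the star tree.

    Returns (blocks, truth): ``blocks`` maps gene name to a gap-free
    codon-aligned :class:`AlignmentBlock` (no stop codons appear at any
    point), ``truth`` records realized substitution counts per branch.
    """
    rng = np.random.default_rng(config.seed)
    code = get_code(config.table_id)
    totals, neighbors = _rate_tables(config.table_id, config.kappa, config.omega)
    taxa = [f"taxon_{i + 1:02d}" for i in range(config.n_taxa)]
    branch = config.divergence / 2.0
    blocks = {}
    truth = TruthRecord(config=config)
    for gene, n_codons in config.genes:
        root = _sample_root(rng, n_codons, config, code)
        scale = float(np.mean([totals[c] for c in root]))
        seqs = []
        for taxon in taxa:
            tip, counts = _evolve_branch(rng, root, branch, scale, totals, neighbors)
            truth.substitutions[(gene, taxon)] = counts
            seqs.append("".join(tip))
        blocks[gene] = AlignmentBlock(gene=gene, taxa=list(taxa), sequences=seqs)
    return blocks, truth


# -- GenBank emission --------------------------------------------------------


def _random_seq(rng, length: int, at_rich: float = 0.6) -> str:
    p_at = at_rich / 2.0
    p_gc = (1.0 - at_rich) / 2.0
    return "".join(rng.choice(list("ATGC"), size=length, p=[p_at, p_at, p_gc, p_gc]))


def build_genome(
    rng,
    taxon: str,
    accession: str,
    gene_seqs: dict,
    cr_length: int = 900,
    trna_length: int = 70,
) -> MitogenomeRecord:
    """Assemble one annotated circular genome from per-gene CDS strings.

    COX1 is written GTG-initiated, NAD4 with a truncated (T) stop, and
    NAD6 on the light strand; the control region sits between tRNA-Pro and
    tRNA-Phe, the OL between tRNA-Asn and tRNA-Cys.
    """
    entries = []  # (name, kind, genome_seq, strand)

    def cds_entry(gene):
        seq = gene_seqs[gene]
        start = "GTG" if gene == "COX1" else "ATG"
        seq = start + seq[3:]
        if gene == "NAD4":
            body = seq + "T"  # truncated stop, completed to TAA downstream
        else:
            body = seq + "TAA"
        strand = "L" if gene == "NAD6" else "H"
        return (gene, "CDS", body, strand)

    trnas = iter(TRNA_LABELS)

    def trna_entry():
        return (next(trnas), "tRNA", _random_seq(rng, trna_length), "H")

    entries.append(trna_entry())  # tRNA-Phe
    entries.append(("srRNA", "rRNA", _random_seq(rng, 950), "H"))
    entries.append(trna_entry())  # tRNA-Val
    entries.append(("lrRNA", "rRNA", _random_seq(rng, 1600), "H"))
    entries.append(trna_entry())  # tRNA-Leu
    order = [g for g, _ in DEFAULT_GENES if g in gene_seqs]
    for i, gene in enumerate(order):
        entries.append(cds_entry(gene))
        # spread the remaining tRNAs between genes; place OL after tRNA-Asn
        for _ in range(2 if i < 6 else 1):
            try:
                entry = trna_entry()
            except StopIteration:
                break
            entries.append(entry)
            if entry[0] == "tRNA-Asn":
                entries.append(("OL", "origin_light", _random_seq(rng, 35), "H"))
    for label in trnas:  # any leftovers before the control region
        entries.append((label, "tRNA", _random_seq(rng, trna_length), "H"))
    entries.append(("CR", "control_region", _random_seq(rng, cr_length, at_rich=0.68), "H"))

    genome_parts = []
    features = []
    cursor = 1
    from Bio.Seq import Seq

    for name, kind, seq, strand in entries:
        genome_seq = str(Seq(seq).reverse_complement()) if strand == "L" else seq
        genome_parts.append(genome_seq)
        features.append(
            GeneFeature(
                name=name, kind=kind, start=cursor, end=cursor + len(seq) - 1,
                strand=strand, sequence=seq,
            )
        )
        cursor += len(seq)
    return MitogenomeRecord(
        accession=accession, taxon=taxon, sequence="".join(genome_parts),
        features=features,
    )


def emit_genbank(config: SimulationConfig, blocks: dict, out_dir) -> list:
    """Write one minimal annotated GenBank record per taxon.

    Control-region length varies across taxa (so genome lengths differ
    while PCG totals match). Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed + 1)
    any_block = next(iter(blocks.values()))
    paths = []
    for i, taxon in enumerate(any_block.taxa):
        gene_seqs = {}
        for gene, block in blocks.items():
            gene_seqs[gene] = block.sequences[block.taxa.index(taxon)]
        record = build_genome(
            rng,
            taxon=taxon,
            accession=f"SYN{i + 1:04d}",
            gene_seqs=gene_seqs,
            cr_length=850 + 40 * i,
        )
        path = out_dir / f"{taxon}.gb"
        write_genbank(record, path)
        paths.append(path)
    return paths
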