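"""Concatenated phylogenetic datasets with partition bookkeeping.

Builds the five standard mitogenomic supermatrices — PCGs, PCGs12 (third
codon positions excluded), PCGsRNA, PCGs12RNA, and Mt — from per-gene
alignment blocks, with codon-position stripping, a simple gap-fraction
trimmer, and partition tables suitable for external model selection and
tree inference (NEXUS sets block, relaxed PHYLIP, FASTA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .divergence import AlignmentBlock
from .io import CANONICAL_GENE_ORDER, PCG_NAMES

DATASET_IDS = ("PCGs", "PCGs12", "PCGsRNA", "PCGs12RNA", "Mt")


@dataclass
class SupermatrixSpec:
    """Which partitions a concatenated dataset includes.

    ``dataset_id`` selects one of the five canonical designs; PCGs12*
    variants keep only codon positions 1-2 of every CDS partition.
    """

    dataset_id: str
    include_rna: bool
    include_noncoding: bool
    keep_positions: tuple  # codon positions retained in CDS partitions

    @classmethod
    def for_dataset(cls, dataset_id: str) -> "SupermatrixSpec":
        if dataset_id not in DATASET_IDS:
            raise ValueError(f"unknown dataset {dataset_id!r}; choose from {DATASET_IDS}")
        return cls(
            dataset_id=dataset_id,
            include_rna=dataset_id in ("PCGsRNA", "PCGs12RNA", "Mt"),
            include_noncoding=dataset_id == "Mt",
            keep_positions=(1, 2) if "12" in dataset_id else (1, 2, 3),
        )


@dataclass
class Partition:
    gene: str
    start: int  # 1-based inclusive within the concatenation
    end: int
    kind: str
    positions: tuple


@dataclass
class Supermatrix:
    block: AlignmentBlock
    partitions: list
    spec: SupermatrixSpec
    provenance: list = field(default_factory=list)  # (gene, original column) per output column

    @property
    def n_sites(self) -> int:
        return self.block.length


def strip_positions(block: AlignmentBlock, keep=(1, 2)) -> AlignmentBlock:
    """Retain alignment columns by codon-position membership.

    The block must be codon-framed (length divisible by 3). keep=(1,2,3)
    is the identity.
    """
    keep = tuple(sorted(set(keep)))
    if not keep or any(p not in (1, 2, 3) for p in keep):
        raise ValueError(f"invalid position set {keep}")
    if block.codon_positions is not None:
        positions = block.codon_positions
    else:
        if block.length % 3:
            raise ValueError(f"{block.gene}: length {block.length} is not codon-framed")
        positions = [(i % 3) + 1 for i in range(block.length)]
    cols = [i for i, p in enumerate(positions) if p in keep]
    return AlignmentBlock(
        gene=block.gene,
        taxa=list(block.taxa),
        sequences=["".join(s[i] for i in cols) for s in block.sequences],
        codon_positions=[positions[i] for i in cols],
    )


def gap_trim(
    block: AlignmentBlock,
    max_gap_fraction: float = 0.5,
    codon_framed: bool = False,
) -> AlignmentBlock:
    """Drop columns whose gap fraction exceeds the threshold.

    A light-weight surrogate for alignment-trimming tools: codon-framed
    blocks drop whole codons whenever any member column fails. Idempotent.
    """
    n = block.n_taxa
    gap_frac = [
        sum(1 for s in block.sequences if s[i] in "-.~?") / n
        for i in range(block.length)
    ]
    if codon_framed:
        if block.length % 3:
            raise ValueError(f"{block.gene}: not codon-framed")
        drop = set()
        for c in range(block.length // 3):
            if any(gap_frac[3 * c + p] > max_gap_fraction for p in range(3)):
                drop.update((3 * c, 3 * c + 1, 3 * c + 2))
    else:
        drop = {i for i, g in enumerate(gap_frac) if g > max_gap_fraction}
    keep = [i for i in range(block.length) if i not in drop]
    if not keep:
        raise ValueError(f"{block.gene}: every column exceeds the gap threshold")
    return AlignmentBlock(
        gene=block.gene,
        taxa=list(block.taxa),
        sequences=["".join(s[i] for i in keep) for s in block.sequences],
    )


def _ordered(blocks: dict) -> list:
    known = [g for g in CANONICAL_GENE_ORDER if g in blocks]
    extra = sorted(g for g in blocks if g not in CANONICAL_GENE_ORDER)
    return known + extra


def concatenate(
    blocks: dict,
    spec: SupermatrixSpec | None = None,
    kinds: dict | None = None,
    permissive: bool = False,
) -> Supermatrix:
    """Concatenate per-gene blocks into a supermatrix with partition table.

    ``blocks`` maps gene name -> AlignmentBlock; ``kinds`` maps gene ->
    {CDS, rRNA, tRNA, noncoding} (PCG names default to CDS, srRNA/lrRNA
    and tRNA-* names are inferred). Taxon sets must agree across blocks
    unless ``permissive`` pads missing taxa with gaps.
    """
    spec = spec or SupermatrixSpec.for_dataset("PCGs")
    kinds = dict(kinds or {})

    def kind_of(gene):
        if gene in kinds:
            return kinds[gene]
        if gene in PCG_NAMES:
            return "CDS"
        if gene in ("srRNA", "lrRNA"):
            return "rRNA"
        if gene.startswith("tRNA"):
            return "tRNA"
        return "noncoding"

    selected = {}
    for gene in _ordered(blocks):
        k = kind_of(gene)
        if k == "CDS":
            selected[gene] = (blocks[gene], k)
        elif k in ("rRNA", "tRNA") and spec.include_rna:
            selected[gene] = (blocks[gene], k)
        elif k == "noncoding" and spec.include_noncoding:
            selected[gene] = (blocks[gene], k)
    if not selected:
        raise ValueError("no partitions selected")

    all_taxa = sorted({t for b, _ in selected.values() for t in b.taxa})
    for gene, (b, _) in selected.items():
        missing = set(all_taxa) - set(b.taxa)
        if missing and not permissive:
            raise ValueError(f"{gene}: missing taxa {sorted(missing)} (strict mode)")

    pieces = {t: [] for t in all_taxa}
    partitions = []
    provenance = []
    cursor = 1
    for gene in _ordered(selected):
        b, kind = selected[gene]
        if kind == "CDS" and spec.keep_positions != (1, 2, 3):
            kept_cols = [i for i in range(b.length) if (i % 3) + 1 in spec.keep_positions]
            b = strip_positions(b, keep=spec.keep_positions)
        else:
            kept_cols = list(range(b.length))
        idx = {t: i for i, t in enumerate(b.taxa)}
        for t in all_taxa:
            if t in idx:
                pieces[t].append(b.sequences[idx[t]])
            else:
                pieces[t].append("-" * b.length)
        partitions.append(
            Partition(
                gene=gene, start=cursor, end=cursor + b.length - 1, kind=kind,
                positions=spec.keep_positions if kind == "CDS" else (1, 2, 3),
            )
        )
        provenance.extend((gene, c) for c in kept_cols)
        cursor += b.length

    block = AlignmentBlock(
        gene=spec.dataset_id,
        taxa=all_taxa,
        sequences=["".join(pieces[t]) for t in all_taxa],
    )
    return Supermatrix(block=block, partitions=partitions, spec=spec, provenance=provenance)


# -- writers -----------------------------------------------------------------


def write_phylip(sm: Supermatrix, path) -> None:
    """Relaxed PHYLIP: names of any length, single space separator."""
    with open(path, "w") as fh:
        fh.write(f" {sm.block.n_taxa} {sm.n_sites}\n")
        width = max(len(t) for t in sm.block.taxa) + 2
        for taxon, seq in zip(sm.block.taxa, sm.block.sequences):
            fh.write(f"{taxon:<{width}}{seq}\n")


def write_fasta(sm: Supermatrix, path) -> None:
    sm.block.write_fasta(path)


def write_nexus(sm: Supermatrix, path) -> None:
    """NEXUS with a sets block: one charset per partition; CDS partitions
    retaining all three positions also get per-position charsets."""
    with open(path, "w") as fh:
        fh.write("#NEXUS\n\nBEGIN DATA;\n")
        fh.write(f"  DIMENSIONS NTAX={sm.block.n_taxa} NCHAR={sm.n_sites};\n")
        fh.write("  FORMAT DATATYPE=DNA MISSING=? GAP=-;\n  MATRIX\n")
        width = max(len(t) for t in sm.block.taxa) + 2
        for taxon, seq in zip(sm.block.taxa, sm.block.sequences):
            safe = taxon.replace(" ", "_")
            fh.write(f"    {safe:<{width}}{seq}\n")
        fh.write("  ;\nEND;\n\nBEGIN SETS;\n")
        for p in sm.partitions:
            fh.write(f"  CHARSET {p.gene.replace('-', '_')} = {p.start}-{p.end};\n")
            if p.kind == "CDS" and p.positions == (1, 2, 3):
                for pos in (1, 2, 3):
                    fh.write(
                        f"  CHARSET {p.gene.replace('-', '_')}_pos{pos} = "
                        f"{p.start + pos - 1}-{p.end}\\3;\n"
                    )
        fh.write("END;\n")


def partition_table(sm: Supermatrix) -> list:
    return [
        {
            "gene": p.gene, "start": p.start, "end": p.end, "kind": p.kind,
            "positions": "".join(str(x) for x in p.positions),
        }
        for p in sm.partitions
    ]
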