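"""Reading and writing annotated mitogenomes.

Parses GenBank flat files into :class:`MitogenomeRecord` objects, normalizes
gene names to a controlled vocabulary (13 protein-coding genes, 22 tRNAs,
two rRNAs, the control region and the light-strand replication origin),
extracts coding sequences in coding orientation, and validates them under
the active genetic code (truncated-stop completion, start-codon policy, no
internal stops).

Coordinates are 1-based inclusive internally, following the GenBank
convention; features may wrap the origin of the circular molecule.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genetic_code import DEFAULT_START_CODONS, GeneticCode, get_code

logger = logging.getLogger(__name__)

PCG_NAMES = (
    "ATP6", "ATP8", "COX1", "COX2", "COX3", "CYTB",
    "NAD1", "NAD2", "NAD3", "NAD4", "NAD4L", "NAD5", "NAD6",
)

#: Canonical partition order for concatenated outputs: PCGs first, then
#: rRNAs, then tRNAs alphabetically.
CANONICAL_GENE_ORDER = PCG_NAMES + ("srRNA", "lrRNA")

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


def _load_synonyms() -> dict:
    table = {}
    with resources.files("mitocodon.data").joinpath("gene_synonyms.tsv").open() as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            table[row["synonym"].upper()] = row["canonical"]
    return table


_SYNONYMS = _load_synonyms()
_TRNA_RE = re.compile(r"^(TRN[A-Z]\d?|TRNA[-_ ]?([A-Z]{3})\d?.*)$", re.IGNORECASE)


def normalize_gene_name(raw: str, kind: str | None = None) -> str | None:
    """Map an annotation label to the controlled vocabulary.

    Returns None when the label cannot be mapped (callers warn and keep the
    verbatim name rather than dropping the feature).
    """
    name = raw.strip().upper().replace("_", " ")
    if name in _SYNONYMS:
        return _SYNONYMS[name]
    if kind == "tRNA" or name.startswith("TRN"):
        m = re.match(r"^TRNA[- ]?([A-Z]{3})", name)
        if m and m.group(1) in AA3_TO_1:
            return f"tRNA-{m.group(1).title()}"
        m = re.match(r"^TRN([A-Z])\d?$", name)
        if m:
            for aa3, aa1 in AA3_TO_1.items():
                if aa1 == m.group(1):
                    return f"tRNA-{aa3.title()}"
    return None


@dataclass(frozen=True)
class GeneFeature:
    """One annotated gene on a circular mitogenome.

    start/end are 1-based inclusive on the forward (heavy) strand as stored
    in the file; ``sequence`` is always in coding orientation (L-strand
    features arrive reverse-complemented).
    """

    name: str
    kind: str  # CDS | tRNA | rRNA | control_region | origin_light
    start: int
    end: int
    strand: str  # H | L
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MitogenomeRecord:
    accession: str
    taxon: str
    sequence: str
    features: list = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)

    def cds_features(self) -> list:
        return [f for f in self.features if f.kind == "CDS"]

    def features_of_kind(self, kind: str) -> list:
        return [f for f in self.features if f.kind == kind]

    def get_gene(self, name: str) -> GeneFeature | None:
        for f in self.features:
            if f.name == name:
                return f
        return None


def extract_subsequence(genome: str, start: int, end: int, strand: str = "H") -> str:
    """Slice [start, end] (1-based inclusive) off a circular genome.

    start > end denotes a feature wrapping the origin: the suffix from
    ``start`` is stitched to the prefix ending at ``end``.
    """
    if start > end:
        seg = genome[start - 1 :] + genome[:end]
    else:
        seg = genome[start - 1 : end]
    if strand == "L":
        seg = str(Seq(seg).reverse_complement())
    return seg


def _feature_name(feat) -> str:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return feat.qualifiers[key][0]
    return feat.type


_KIND_BY_TYPE = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}


def _classify(feat, name_norm) -> str | None:
    if feat.type in _KIND_BY_TYPE:
        return _KIND_BY_TYPE[feat.type]
    if name_norm == "CR" or feat.type in ("D-loop",):
        return "control_region"
    if name_norm == "OL" or feat.type == "rep_origin":
        return "origin_light"
    if feat.type == "misc_feature":
        raw = _feature_name(feat).upper()
        if "D-LOOP" in raw or "CONTROL" in raw:
            return "control_region"
        if "ORIGIN" in raw or raw == "OL":
            return "origin_light"
    return None


def parse_genbank(path) -> MitogenomeRecord:
    """Read one annotated mitogenome from a GenBank flat file.

    Gene names are normalized to the controlled vocabulary; unmappable
    names trigger a warning and are retained verbatim. L-strand features
    are reverse-complemented into coding orientation; origin-spanning
    features are stitched.
    """
    seqrec = SeqIO.read(str(path), "genbank")
    genome = str(seqrec.seq).upper()
    if not genome:
        raise ValueError(f"{path}: record has no sequence")
    features = []
    for feat in seqrec.features:
        if feat.type in ("source", "gene"):
            continue
        raw_name = _feature_name(feat)
        kind_hint = _KIND_BY_TYPE.get(feat.type)
        name = normalize_gene_name(raw_name, kind=kind_hint)
        kind = _classify(feat, name)
        if kind is None:
            continue
        if name is None and kind == "control_region":
            name = "CR"
        elif name is None and kind == "origin_light":
            name = "OL"
        if name is None:
            logger.warning(
                "%s: unmappable gene name %r (kind %s) retained verbatim",
                seqrec.id, raw_name, kind,
            )
            name = raw_name
        loc = feat.location
        strand = "L" if loc.strand == -1 else "H"
        parts = sorted(loc.parts, key=lambda p: int(p.start))
        if len(parts) > 1 and int(parts[-1].end) == len(genome) and int(parts[0].start) == 0:
            # compound location wrapping the origin
            start, end = int(parts[-1].start) + 1, int(parts[0].end)
        else:
            start, end = int(loc.start) + 1, int(loc.end)
        seq = extract_subsequence(genome, start, end, strand)
        features.append(
            GeneFeature(name=name, kind=kind, start=start, end=end, strand=strand, sequence=seq)
        )
    return MitogenomeRecord(
        accession=seqrec.id,
        taxon=seqrec.annotations.get("organism", seqrec.description) or seqrec.id,
        sequence=genome,
        features=features,
    )


def parse_genbank_dir(directory) -> list:
    """Parse every .gb/.gbk/.genbank file in a directory, sorted by name."""
    paths = sorted(
        p for p in Path(directory).iterdir()
        if p.suffix.lower() in (".gb", ".gbk", ".genbank")
    )
    if not paths:
        raise FileNotFoundError(f"no GenBank files found in {directory}")
    return [parse_genbank(p) for p in paths]


def complete_stop(cds: str) -> str:
    """Complete a truncated mitochondrial stop codon by polyadenylation.

    Mitochondrial CDSs often end in a bare T or TA at the transcript edge;
    post-transcriptional polyadenylation yields the complete TAA stop. If
    the sequence length mod 3 is 1 and it ends in T (or mod 3 is 2 ending
    in TA), append A's to form TAA; a frame remainder that is not a
    truncated stop is an error.
    """
    cds = cds.upper()
    rem = len(cds) % 3
    if rem == 0:
        return cds
    tail = cds[-rem:]
    if rem == 1 and tail == "T":
        return cds + "AA"
    if rem == 2 and tail == "TA":
        return cds + "A"
    raise ValueError(
        f"CDS length mod 3 == {rem} but trailing {tail!r} is not a truncated stop"
    )


@dataclass(frozen=True)
class ValidatedCDS:
    """A frame-valid coding sequence ready for codon analyses."""

    gene: str
    taxon: str
    sequence: str  # stop-completed, length % 3 == 0

    @property
    def n_codons(self) -> int:
        return len(self.sequence) // 3

    def codons(self) -> list:
        return [self.sequence[i : i + 3] for i in range(0, len(self.sequence), 3)]


def validate_cds(
    seq: str,
    gene: str,
    taxon: str,
    code: GeneticCode,
    start_codons=DEFAULT_START_CODONS,
    strict: bool = False,
) -> ValidatedCDS:
    """Stop-complete and validate one CDS under the active code."""
    seq = complete_stop(seq.upper())
    start = seq[:3]
    allowed = frozenset(start_codons) if strict else frozenset(start_codons) | code.start_codons
    if start not in allowed:
        raise ValueError(f"{taxon}/{gene}: start codon {start} not in {sorted(allowed)}")
    for i in range(0, len(seq) - 3, 3):
        codon = seq[i : i + 3]
        if code.is_stop(codon):
            raise ValueError(
                f"{taxon}/{gene}: internal stop codon {codon} at nt {i + 1}"
            )
    return ValidatedCDS(gene=gene, taxon=taxon, sequence=seq)


def extract_cds(
    record: MitogenomeRecord,
    code: GeneticCode | None = None,
    start_codons=DEFAULT_START_CODONS,
    strict: bool = False,
) -> list:
    """Extract and validate all protein-coding genes of a parsed record."""
    code = code or get_code(2)
    out = []
    for feat in record.cds_features():
        out.append(
            validate_cds(
                feat.sequence, feat.name, record.taxon, code,
                start_codons=start_codons, strict=strict,
            )
        )
    return out


# -- writers ----------------------------------------------------------------


def write_gene_fastas(records: list, out_dir, code: GeneticCode | None = None) -> dict:
    """Write one unaligned multi-FASTA per PCG across all records.

    Returns {gene: path}. Genes missing from some taxa are written with the
    taxa that carry them.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_gene: dict[str, list] = {}
    for rec in records:
        for cds in extract_cds(rec, code=code):
            by_gene.setdefault(cds.gene, []).append((rec.taxon, cds.sequence))
    paths = {}
    for gene in sorted(by_gene, key=lambda g: PCG_NAMES.index(g) if g in PCG_NAMES else 99):
        path = out_dir / f"{gene}.fasta"
        with open(path, "w") as fh:
            for taxon, seq in by_gene[gene]:
                fh.write(f">{taxon}\n{seq}\n")
        paths[gene] = path
    return paths


def feature_table(records: list) -> list:
    """Flat per-feature rows (accession, gene, kind, start, end, strand, length)."""
    rows = []
    for rec in records:
        for f in rec.features:
            rows.append(
                {
                    "accession": rec.accession,
                    "gene": f.name,
                    "kind": f.kind,
                    "start": f.start,
                    "end": f.end,
                    "strand": f.strand,
                    "length": f.length,
                }
            )
    return rows


_KIND_TO_GB = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "control_region": "D-loop",
    "origin_light": "rep_origin",
}


def write_genbank(record: MitogenomeRecord, path) -> None:
    """Write a MitogenomeRecord back to a GenBank flat file (round-trip safe)."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.accession,
        name=record.accession.split(".")[0][:16],
        description=f"{record.taxon} mitochondrion, complete genome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular",
            "organism": record.taxon,
        },
    )
    L = record.length
    for f in record.features:
        strand = -1 if f.strand == "L" else 1
        if f.start > f.end:  # wraps the origin
            loc = CompoundLocation(
                [
                    SimpleLocation(f.start - 1, L, strand),
                    SimpleLocation(0, f.end, strand),
                ]
            )
        else:
            loc = SimpleLocation(f.start - 1, f.end, strand)
        qualifiers = {"gene": [f.name]}
        gb_type = _KIND_TO_GB[f.kind]
        if gb_type == "D-loop":
            gb_type = "misc_feature"
            qualifiers["note"] = ["control region"]
        seqrec.features.append(SeqFeature(loc, type=gb_type, qualifiers=qualifiers))
    SeqIO.write(seqrec, str(path), "genbank")
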