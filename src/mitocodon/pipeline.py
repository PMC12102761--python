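"""End-to-end orchestration: extract -> composition -> indices -> bias ->
divergence -> supermatrix, with a serializable run configuration and a
manifest recording every analytic choice.

All tables are UTF-8 TSV with one header row, floats formatted at 4
decimals, genes in canonical order, so reruns diff cleanly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .bias import (
    classify_codons, enc_deviation, enc_expected, index_correlation,
    neutrality_fit, pr2, rank_gene_groups,
)
from .codon_metrics import (
    cai_weights, count_codons, optimal_codons_from_reference, rscu,
    usage_indices,
)
from .composition import codon_position_composition, composition, gene_length_table
from .divergence import AlignmentBlock, gene_summary
from .genetic_code import get_code
from .io import PCG_NAMES, extract_cds, feature_table, parse_genbank_dir
from .supermatrix import (
    SupermatrixSpec, concatenate, partition_table, write_fasta, write_nexus,
    write_phylip,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.4f"


@dataclass
class RunConfig:
    """Every analytic choice of a pipeline run, serializable to flat YAML."""

    genbank_dir: str | None = None
    alignments_dir: str | None = None
    out_dir: str = "mitocodon_out"
    code_table: int = 2
    cai_reference: str = "pooled"  # pooled | path to a weight TSV
    cai_w_floor: float = 0.01
    group_key: str = "ENC"
    group_size: int = 3
    delta_rscu_threshold: float = 0.08
    hfc_rscu_threshold: float = 1.0
    pr2_mode: str = "fourfold_only"
    ratio_averaging: str = "mean_of_ratios"
    pi_site_handling: str = "complete"
    datasets: tuple = ("PCGs", "PCGs12", "PCGsRNA", "PCGs12RNA")
    gap_trim_threshold: float = 0.5
    seed: int = 0
    quiet: bool = False

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["datasets"] = list(d["datasets"])
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "datasets" in raw:
            raw["datasets"] = tuple(raw["datasets"])
        return cls(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)


def _stage(name, quiet):
    class _Timer:
        def __enter__(self):
            self.t0 = time.perf_counter()
            if not quiet:
                logger.info("stage %s started", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            dt = time.perf_counter() - self.t0
            if exc_type is not None:
                logger.error("stage %s failed after %.1fs: %s", name, dt, exc)
            elif not quiet:
                logger.info("stage %s finished in %.1fs", name, dt)
            return False

    return _Timer()


def blocks_from_records(records, code) -> dict:
    """Per-gene AlignmentBlocks from extracted CDS (terminal stop removed).

    Only genes whose CDS lengths agree across all taxa form blocks; others
    are reported for external alignment.
    """
    by_gene: dict[str, list] = {}
    for rec in records:
        for cds in extract_cds(rec, code=code):
            seq = cds.sequence
            if code.is_stop(seq[-3:]):
                seq = seq[:-3]
            by_gene.setdefault(cds.gene, []).append((cds.taxon, seq))
    blocks = {}
    for gene, pairs in by_gene.items():
        lengths = {len(s) for _, s in pairs}
        if len(lengths) > 1:
            logger.warning(
                "%s: unequal CDS lengths %s across taxa; supply an alignment "
                "for this gene", gene, sorted(lengths),
            )
            continue
        blocks[gene] = AlignmentBlock(
            gene=gene, taxa=[t for t, _ in pairs], sequences=[s for _, s in pairs]
        )
    return blocks


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and return {output name: path}.

    Either ``genbank_dir`` (annotated mitogenomes) or ``alignments_dir``
    (per-gene aligned FASTA) must be provided; with both, composition and
    codon indices come from the GenBank records and divergence from the
    alignments.
    """
    code = get_code(config.code_table)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bias_dir = out / "bias"
    bias_dir.mkdir(exist_ok=True)
    outputs = {}

    records = []
    if config.genbank_dir:
        with _stage("parse", config.quiet):
            records = parse_genbank_dir(config.genbank_dir)

    if config.alignments_dir:
        with _stage("load_alignments", config.quiet):
            blocks = {
                p.stem: AlignmentBlock.from_fasta(p)
                for p in sorted(Path(config.alignments_dir).glob("*.fasta"))
            }
            if not blocks:
                raise FileNotFoundError(
                    f"no .fasta alignments in {config.alignments_dir}"
                )
    elif records:
        blocks = blocks_from_records(records, code)
    else:
        raise ValueError("provide genbank_dir and/or alignments_dir")

    per_taxon_cds = {}
    if records:
        for rec in records:
            per_taxon_cds[rec.taxon] = extract_cds(rec, code=code)
    else:
        for block in blocks.values():
            for taxon, seq in zip(block.taxa, block.sequences):
                from .io import ValidatedCDS

                per_taxon_cds.setdefault(taxon, []).append(
                    ValidatedCDS(gene=block.gene, taxon=taxon,
                                 sequence=seq.replace("-", ""))
                )

    # -- composition --------------------------------------------------------
    with _stage("composition", config.quiet):
        rows = []
        for rec in records:
            comp = composition(rec.sequence, context="genome")
            rows.append(_comp_row(rec.taxon, "genome", comp))
        for taxon, cds_list in per_taxon_cds.items():
            pooled = composition(
                "".join(c.sequence for c in cds_list), context="PCGs"
            )
            rows.append(_comp_row(taxon, "PCGs", pooled))
            pos = codon_position_composition(cds_list, code=code)
            for p in (1, 2, 3):
                rows.append(_comp_row(taxon, f"codon_position_{p}", pos[f"p{p}"]))
        comp_df = pd.DataFrame(rows)
        _write_tsv(comp_df, out / "composition.tsv")
        outputs["composition"] = out / "composition.tsv"
        if records:
            _write_tsv(pd.DataFrame(feature_table(records)), out / "features.tsv")
            _write_tsv(gene_length_table(records), out / "gene_lengths.tsv", index=True)
            outputs["features"] = out / "features.tsv"
            outputs["gene_lengths"] = out / "gene_lengths.tsv"

    # -- indices and RSCU ----------------------------------------------------
    with _stage("indices", config.quiet):
        index_frames = []
        rscu_rows = []
        rscu_by_taxon = {}
        for taxon, cds_list in per_taxon_cds.items():
            df = usage_indices(cds_list, code=code, w_floor=config.cai_w_floor)
            index_frames.append(df)
            pooled_counts = count_codons(cds_list[0], code=code)
            for c in cds_list[1:]:
                pooled_counts = pooled_counts + count_codons(c, code=code)
            table = rscu(pooled_counts)
            rscu_by_taxon[taxon] = (table, pooled_counts, cds_list)
            for codon, value in sorted(table.rscu.items()):
                rscu_rows.append(
                    {
                        "taxon": taxon, "codon": codon,
                        "amino_acid": code.codon_to_aa[codon], "rscu": value,
                    }
                )
        indices_df = pd.concat(index_frames, ignore_index=True)
        _write_tsv(indices_df, out / "indices.tsv")
        _write_tsv(pd.DataFrame(rscu_rows), out / "rscu.tsv")
        outputs["indices"] = out / "indices.tsv"
        outputs["rscu"] = out / "rscu.tsv"

    # -- bias diagnostics ----------------------------------------------------
    with _stage("bias", config.quiet):
        neut_rows, encg_rows, pr2_rows, class_rows, corr_rows = [], [], [], [], []
        for taxon, (table, pooled_counts, cds_list) in rscu_by_taxon.items():
            df = indices_df[indices_df["taxon"] == taxon]
            fit = neutrality_fit(df[["GC3", "GC12"]].values, taxon=taxon)
            neut_rows.append(
                {
                    "taxon": taxon, "slope": fit.slope, "intercept": fit.intercept,
                    "R2": fit.r2, "p_value": fit.p_value, "n_genes": len(fit.points),
                }
            )
            for _, row in df.iterrows():
                encg_rows.append(
                    {
                        "taxon": taxon, "gene": row["gene"], "GC3s": row["GC3s"],
                        "ENC_obs": row["ENC"], "ENC_exp": enc_expected(row["GC3s"]),
                        "deviation": enc_deviation(row["ENC"], row["GC3s"]),
                    }
                )
            for cds in cds_list:
                counts = count_codons(cds, code=code)
                try:
                    point = pr2(counts, mode=config.pr2_mode, gene=cds.gene, taxon=taxon)
                except ValueError:
                    continue
                pr2_rows.append(
                    {
                        "taxon": taxon, "gene": point.gene, "x_G3": point.x,
                        "y_A3": point.y, "quadrant": point.quadrant,
                    }
                )
            groups = rank_gene_groups(df, key=config.group_key, group_size=config.group_size)
            by_gene = {c.gene: c for c in cds_list}
            high_counts = _pool_counts([by_gene[g] for g in groups["high"]], code)
            low_counts = _pool_counts([by_gene[g] for g in groups["low"]], code)
            cls = classify_codons(
                table, rscu(high_counts), rscu(low_counts),
                rscu_threshold=config.hfc_rscu_threshold,
                delta_threshold=config.delta_rscu_threshold,
                taxon=taxon, group_meta=groups,
            )
            for codon in sorted(table.rscu):
                class_rows.append(
                    {
                        "taxon": taxon, "codon": codon,
                        "amino_acid": code.codon_to_aa[codon],
                        "rscu": table.rscu[codon],
                        "delta_rscu": cls.delta_rscu.get(codon, float("nan")),
                        "hfc": codon in cls.hfc,
                        "high_expression": codon in cls.high_expression,
                        "optimal": codon in cls.optimal,
                    }
                )
            corr = index_correlation(df)
            for i, a in enumerate(corr["r"].index):
                for b in corr["r"].columns[i + 1 :]:
                    corr_rows.append(
                        {
                            "taxon": taxon, "index_a": a, "index_b": b,
                            "r": corr["r"].loc[a, b], "p": corr["p"].loc[a, b],
                            "stars": corr["stars"].loc[a, b],
                        }
                    )
        _write_tsv(pd.DataFrame(neut_rows), bias_dir / "neutrality.tsv")
        _write_tsv(pd.DataFrame(encg_rows), bias_dir / "enc_gc3.tsv")
        _write_tsv(pd.DataFrame(pr2_rows), bias_dir / "pr2.tsv")
        _write_tsv(pd.DataFrame(class_rows), bias_dir / "codon_classes.tsv")
        _write_tsv(pd.DataFrame(corr_rows), bias_dir / "correlation.tsv")
        for name in ("neutrality", "enc_gc3", "pr2", "codon_classes", "correlation"):
            outputs[f"bias/{name}"] = bias_dir / f"{name}.tsv"

    # -- divergence ----------------------------------------------------------
    with _stage("divergence", config.quiet):
        div_df = gene_summary(
            blocks, code=code, ratio_averaging=config.ratio_averaging,
            pi_site_handling=config.pi_site_handling,
        )
        missing = [g for g in PCG_NAMES if g not in set(div_df["gene"])]
        if missing:
            logger.warning("divergence: missing genes %s", missing)
        _write_tsv(div_df, out / "divergence.tsv")
        outputs["divergence"] = out / "divergence.tsv"

    # -- supermatrices -------------------------------------------------------
    with _stage("supermatrix", config.quiet):
        sm_dir = out / "supermatrix"
        sm_dir.mkdir(exist_ok=True)
        for dataset in config.datasets:
            spec = SupermatrixSpec.for_dataset(dataset)
            sm = concatenate(blocks, spec=spec)
            write_nexus(sm, sm_dir / f"{dataset}.nex")
            write_phylip(sm, sm_dir / f"{dataset}.phy")
            write_fasta(sm, sm_dir / f"{dataset}.fasta")
            _write_tsv(pd.DataFrame(partition_table(sm)), sm_dir / f"{dataset}.partitions.tsv")
            outputs[f"supermatrix/{dataset}"] = sm_dir / f"{dataset}.nex"

    # -- manifest ------------------------------------------------------------
    manifest = {
        "package": "mitocodon",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "outputs": {k: str(v) for k, v in sorted(outputs.items())},
        "n_taxa": len(per_taxon_cds),
        "n_genes": len(blocks),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    outputs["manifest"] = out / "manifest.json"
    return outputs


def _comp_row(taxon, context, comp) -> dict:
    return {
        "taxon": taxon, "context": context,
        "A": comp.counts["A"], "T": comp.counts["T"],
        "G": comp.counts["G"], "C": comp.counts["C"],
        "AT_content": comp.at_content, "GC_content": comp.gc_content,
        "AT_skew": comp.at_skew, "GC_skew": comp.gc_skew,
        "n_ambiguous": comp.n_ambiguous,
    }


def _pool_counts(cds_list, code):
    pooled = count_codons(cds_list[0], code=code)
    for c in cds_list[1:]:
        pooled = pooled + count_codons(c, code=code)
    return pooled
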