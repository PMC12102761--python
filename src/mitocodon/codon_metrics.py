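"""Codon counting and the per-gene codon-usage index battery.

Implements RSCU, Wright's effective number of codons (ENC), the synonymous
third-position base frequencies (GC3s, A3s, T3s, G3s, C3s), the codon
adaptation index (CAI), codon bias index (CBI), frequency of optimal
codons (FOP), and the protein-level GRAVY and aromaticity summaries.

All indices derive their synonymous-family structure from the active
genetic code. Under the vertebrate mitochondrial code every amino acid has
at least two synonyms (Met and Trp are 2-fold, Arg is the 4-fold CGN box),
so the standard-code exclusion of Met/Trp from "synonymous" statistics does
not apply; a legacy option reproduces the standard-code exclusion rule for
comparability with CodonW-lineage outputs.

X3s definitions follow the CodonW convention: each base's denominator is
restricted to codons whose family permits that base at a synonymous third
position, so the four values need not sum to 1. GC3s uses the common
denominator of all synonymous-family codons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .genetic_code import GeneticCode, get_code

#: Kyte-Doolittle hydropathy values, the standard scale behind GRAVY.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

AROMATIC = frozenset("FYW")


@dataclass
class CodonCountTable:
    """Codon counts for one gene (or a concatenated gene set) of one taxon."""

    context: str
    counts: dict  # codon -> int, sense codons only when stops excluded
    code: GeneticCode
    n_ambiguous: int = 0

    @property
    def n_codons(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        if other.code.table_id != self.code.table_id:
            raise ValueError("cannot add counts under different genetic codes")
        merged = dict(self.counts)
        for codon, n in other.counts.items():
            merged[codon] = merged.get(codon, 0) + n
        return CodonCountTable(
            context=f"{self.context}+{other.context}",
            counts=merged,
            code=self.code,
            n_ambiguous=self.n_ambiguous + other.n_ambiguous,
        )


def count_codons(
    cds, code: GeneticCode | None = None, exclude_stops: bool = True
) -> CodonCountTable:
    """Tally codons of a frame-valid CDS.

    Stop codons are dropped when ``exclude_stops`` (the default, matching
    usage-index conventions). Codons containing non-ACGT characters are
    skipped and tallied as ambiguous. The initiation codon is counted as
    written (no forced-Met recoding).
    """
    code = code or get_code(2)
    seq = (cds.sequence if hasattr(cds, "sequence") else cds).upper()
    context = getattr(cds, "gene", "cds")
    if len(seq) % 3:
        raise ValueError(f"{context}: CDS length {len(seq)} violates frame")
    counts: dict[str, int] = {}
    n_amb = 0
    for i in range(0, len(seq), 3):
        codon = seq[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            n_amb += 1
            continue
        if exclude_stops and code.is_stop(codon):
            continue
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(context=context, counts=counts, code=code, n_ambiguous=n_amb)


@dataclass
class RSCUTable:
    """Relative synonymous codon usage for one context.

    rscu maps each sense codon of a multi-synonym family to its RSCU value;
    families with zero observed codons are listed in ``undefined_families``.
    """

    context: str
    rscu: dict
    code: GeneticCode
    undefined_families: tuple = field(default_factory=tuple)

    def family_sum(self, aa: str) -> float:
        return sum(self.rscu[c] for c in self.code.families[aa] if c in self.rscu)


def rscu(counts: CodonCountTable, include_single: bool = False) -> RSCUTable:
    """RSCU(c) = observed(c) * k / total(family), k = family degeneracy.

    Values > 1 mark preferentially used codons; family values sum to the
    family's degeneracy. Single-synonym families are excluded by default.
    """
    code = counts.code
    values: dict[str, float] = {}
    undefined = []
    for aa, family in code.families.items():
        if len(family) < 2 and not include_single:
            continue
        total = sum(counts.counts.get(c, 0) for c in family)
        if total == 0:
            undefined.append(aa)
            continue
        k = len(family)
        for c in family:
            values[c] = counts.counts.get(c, 0) * k / total
    return RSCUTable(
        context=counts.context, rscu=values, code=code,
        undefined_families=tuple(undefined),
    )


def enc(counts: CodonCountTable) -> float:
    """Wright's effective number of codons, generalized to the active code.

    Per-family codon homozygosity is estimated as
    F = (n * sum(p_i^2) - 1) / (n - 1) for family sample size n > 1; ENC is
    the sum over degeneracy classes k of m_k / mean(F) where m_k counts the
    k-fold families. Families with n <= 1 (or F = 0) are omitted from their
    class average; an entirely missing class is imputed at F = 1/k. Single-
    synonym families contribute one codon each. The estimate is clamped to
    [20, 61].
    """
    code = counts.code
    classes = code.degeneracy_classes()
    total = 0.0
    any_defined = False
    for k, aas in sorted(classes.items()):
        if k == 1:
            total += len(aas)
            continue
        f_values = []
        for aa in aas:
            family = code.families[aa]
            n = sum(counts.counts.get(c, 0) for c in family)
            if n <= 1:
                continue
            s = sum((counts.counts.get(c, 0) / n) ** 2 for c in family)
            f_hat = (n * s - 1) / (n - 1)
            if f_hat > 0:
                f_values.append(f_hat)
        if f_values:
            f_bar = sum(f_values) / len(f_values)
            any_defined = True
        else:
            f_bar = 1.0 / k  # Wright's imputation for an unobserved class
        total += len(aas) / f_bar
    if not any_defined:
        raise ValueError(f"{counts.context}: too few codons to estimate ENC")
    return min(max(total, 20.0), 61.0)


def x3s(counts: CodonCountTable, legacy_exclude: tuple = ()) -> dict:
    """Synonymous third-position base frequencies (CodonW conventions).

    GC3s: G+C-ending fraction over all codons of multi-synonym families
    (stops excluded). A3s/T3s/G3s/C3s: for each base X, the fraction of
    codons carrying X at position 3 among codons whose family permits X at
    a synonymous third position, so the four values can exceed 1 in sum.

    ``legacy_exclude`` names amino acids (one-letter) to drop regardless of
    degeneracy, reproducing the standard-code "exclude Met and Trp" rule of
    CodonW when applied under other codes (pass ("M", "W")).
    """
    code = counts.code
    excluded = {aa.upper() for aa in legacy_exclude}
    n_syn = 0
    gc_num = 0
    per_base_num = {b: 0 for b in "ATGC"}
    per_base_den = {b: 0 for b in "ATGC"}
    for codon, n in counts.counts.items():
        aa = code.codon_to_aa.get(codon)
        if aa is None or aa in excluded or code.degeneracy(codon) < 2:
            continue
        n_syn += n
        third = codon[2]
        if third in "GC":
            gc_num += n
        allowed = code.synonymous_third_bases(codon)
        for b in "ATGC":
            if b in allowed:
                per_base_den[b] += n
                if third == b:
                    per_base_num[b] += n
    if n_syn == 0:
        raise ValueError(f"{counts.context}: no synonymous-family codons")
    out = {"GC3s": gc_num / n_syn}
    for b in "ATGC":
        out[f"{b}3s"] = per_base_num[b] / per_base_den[b] if per_base_den[b] else float("nan")
    return out


# -- CAI --------------------------------------------------------------------


def cai_weights(reference: RSCUTable, w_floor: float = 0.01) -> dict:
    """Relative adaptiveness w(c) = RSCU(c) / max RSCU in c's family.

    Codons unused in the reference receive the configurable floor (CodonW-
    lineage convention) rather than a hard zero.
    """
    code = reference.code
    weights: dict[str, float] = {}
    for aa, family in code.families.items():
        if len(family) < 2:
            continue
        vals = [reference.rscu.get(c) for c in family]
        if any(v is None for v in vals):
            continue  # family unobserved in the reference
        vmax = max(vals)
        if vmax == 0:
            continue
        for c, v in zip(family, vals):
            weights[c] = (v / vmax) if v > 0 else w_floor
    return weights


def cai(counts: CodonCountTable, weights: dict) -> float:
    """Codon adaptation index: geometric mean of reference weights over the
    gene's codons, restricted to codons with a defined weight."""
    log_sum = 0.0
    n = 0
    for codon, k in counts.counts.items():
        w = weights.get(codon)
        if w is None:
            continue
        log_sum += k * math.log(w)
        n += k
    if n == 0:
        raise ValueError(f"{counts.context}: no codons with defined CAI weights")
    return math.exp(log_sum / n)


# -- CBI / FOP --------------------------------------------------------------


def optimal_codons_from_reference(reference: RSCUTable) -> frozenset:
    """One optimal codon per multi-synonym family: the highest-RSCU member
    of the pooled reference (ties broken alphabetically for determinism)."""
    code = reference.code
    chosen = []
    for aa, family in code.families.items():
        if len(family) < 2:
            continue
        scored = [(reference.rscu.get(c, 0.0), c) for c in family]
        best = max(scored, key=lambda t: (t[0], [-ord(ch) for ch in t[1]]))
        if best[0] > 0:
            chosen.append(best[1])
    return frozenset(chosen)


def cbi_fop(counts: CodonCountTable, optimal_set) -> dict:
    """Codon bias index and frequency of optimal codons.

    FOP = N_opt / N_tot over codons belonging to families with at least one
    optimal member. CBI = (N_opt - N_rand) / (N_tot - N_rand) where N_rand
    is the expected optimal count under uniform synonym usage.
    """
    optimal_set = frozenset(optimal_set)
    if not optimal_set:
        raise ValueError("empty optimal-codon set")
    code = counts.code
    families_with_opt = {
        aa for aa, fam in code.families.items() if any(c in optimal_set for c in fam)
    }
    n_opt = n_tot = 0
    n_rand = 0.0
    for aa in families_with_opt:
        family = code.families[aa]
        n_fam = sum(counts.counts.get(c, 0) for c in family)
        if n_fam == 0:
            continue
        opt_in_fam = sum(1 for c in family if c in optimal_set)
        n_tot += n_fam
        n_opt += sum(counts.counts.get(c, 0) for c in family if c in optimal_set)
        n_rand += n_fam * opt_in_fam / len(family)
    if n_tot == 0:
        raise ValueError(f"{counts.context}: no codons in optimal-bearing families")
    fop = n_opt / n_tot
    cbi_val = (n_opt - n_rand) / (n_tot - n_rand) if n_tot != n_rand else 0.0
    return {"CBI": cbi_val, "FOP": fop}


# -- protein-level indices ---------------------------------------------------


def gravy_aromo(cds, code: GeneticCode | None = None) -> dict:
    """Grand average of hydropathy and aromatic fraction of the translated
    protein (terminal stop excluded)."""
    code = code or get_code(2)
    seq = cds.sequence if hasattr(cds, "sequence") else cds
    protein = code.translate(seq).rstrip("*")
    if "*" in protein:
        raise ValueError("internal stop codon in CDS")
    protein = protein.replace("X", "")
    if not protein:
        raise ValueError("zero-length protein")
    gravy = sum(KYTE_DOOLITTLE[aa] for aa in protein) / len(protein)
    aromo = sum(1 for aa in protein if aa in AROMATIC) / len(protein)
    return {"GRAVY": gravy, "AROMO": aromo, "L_aa": len(protein)}


# -- assembled per-gene record ----------------------------------------------

INDEX_COLUMNS = (
    "T3s", "C3s", "A3s", "G3s", "CAI", "CBI", "FOP", "ENC", "GC3s",
    "GC1", "GC2", "GC3", "GC12", "GC", "GRAVY", "AROMO", "L_aa",
)


def usage_indices(
    cds_list,
    code: GeneticCode | None = None,
    reference: RSCUTable | None = None,
    optimal_set=None,
    w_floor: float = 0.01,
) -> "pandas.DataFrame":
    """Compute the full index battery for a list of validated CDS.

    When no reference is given, CAI weights and the optimal-codon set are
    derived from the pooled codon usage of the input itself (self-
    referential mitochondrial reference).
    """
    import pandas as pd

    from .composition import codon_position_composition

    code = code or get_code(2)
    tables = [count_codons(c, code=code) for c in cds_list]
    if reference is None:
        pooled = tables[0]
        for t in tables[1:]:
            pooled = pooled + t
        reference = rscu(pooled)
    weights = cai_weights(reference, w_floor=w_floor)
    if optimal_set is None:
        optimal_set = optimal_codons_from_reference(reference)
    rows = []
    for cds, table in zip(cds_list, tables):
        pos = codon_position_composition([cds], code=code)
        row = {
            "taxon": getattr(cds, "taxon", ""),
            "gene": getattr(cds, "gene", table.context),
            "n_codons": table.n_codons,
            "ENC": enc(table),
            "CAI": cai(table, weights),
            "GC1": pos["GC1"], "GC2": pos["GC2"], "GC3": pos["GC3"],
            "GC12": pos["GC12"],
        }
        row["GC"] = (pos["GC1"] + pos["GC2"] + pos["GC3"]) / 3
        row.update(x3s(table))
        row.update(cbi_fop(table, optimal_set))
        row.update(gravy_aromo(cds, code=code))
        rows.append(row)
    return pd.DataFrame(rows)
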