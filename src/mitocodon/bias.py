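"""Diagnostics separating mutational pressure from selection.

Neutrality plot (GC12 regressed on GC3 across genes), Wright's ENC-GC3s
expectation under pure mutational pressure, PR2-bias coordinates, codon
classification (high-frequency / high-expression / optimal), and the index
correlation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .codon_metrics import CodonCountTable, RSCUTable
from .genetic_code import GeneticCode


@dataclass(frozen=True)
class NeutralityFit:
    taxon: str
    points: tuple  # ((gc3, gc12), ...)
    slope: float
    intercept: float
    r2: float
    p_value: float


def neutrality_fit(per_gene_composition, taxon: str = "") -> NeutralityFit:
    """OLS of GC12 on GC3 across genes.

    A slope near 1 indicates mutation pressure acting equally on all codon
    positions; a slope near 0 indicates selection constraining positions 1-2
    independently of third-position drift.
    """
    points = tuple((float(x), float(y)) for x, y in per_gene_composition)
    if len(points) < 3:
        raise ValueError("neutrality fit needs at least 3 genes")
    gc3 = np.array([p[0] for p in points])
    gc12 = np.array([p[1] for p in points])
    if np.ptp(gc3) == 0:
        return NeutralityFit(taxon, points, float("nan"), float("nan"),
                             float("nan"), float("nan"))
    res = stats.linregress(gc3, gc12)
    return NeutralityFit(
        taxon=taxon, points=points, slope=res.slope, intercept=res.intercept,
        r2=res.rvalue ** 2, p_value=res.pvalue,
    )


def enc_expected(gc3s: float) -> float:
    """Expected ENC under mutational pressure alone (Wright's curve):
    ENC = 2 + s + 29 / (s^2 + (1 - s)^2), s = GC3s.

    Symmetric about s = 0.5 where it peaks at 60.5; tends to 31 as s
    approaches 0 or 1.
    """
    s = float(gc3s)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s {s} outside [0, 1]")
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) ** 2)


def enc_deviation(enc_obs: float, gc3s: float) -> float:
    """Relative shortfall of observed ENC from the mutational expectation:
    (ENC_exp - ENC_obs) / ENC_exp. Positive values indicate bias beyond
    what composition alone explains."""
    exp = enc_expected(gc3s)
    return (exp - enc_obs) / exp


@dataclass(frozen=True)
class PR2Point:
    gene: str
    taxon: str
    x: float  # G3 / (G3 + C3)
    y: float  # A3 / (A3 + T3)
    quadrant: str  # I..IV or "boundary"


def _quadrant(x: float, y: float) -> str:
    if x == 0.5 or y == 0.5:
        return "boundary"
    if x > 0.5:
        return "I" if y > 0.5 else "IV"
    return "II" if y > 0.5 else "III"


def pr2(
    counts: CodonCountTable,
    mode: str = "fourfold_only",
    gene: str = "",
    taxon: str = "",
) -> PR2Point:
    """Parity-rule-2 coordinates from third-position counts.

    Under strand-symmetric mutation with no selection A3 = T3 and G3 = C3,
    placing genes at (0.5, 0.5). ``fourfold_only`` (classical PR2) uses
    third positions of fourfold-degenerate families where any base is
    synonymous; ``all_synonymous`` uses every multi-synonym family.
    """
    if mode not in ("fourfold_only", "all_synonymous"):
        raise ValueError(f"unknown PR2 mode {mode!r}")
    code = counts.code
    tallies = {b: 0 for b in "ATGC"}
    for codon, n in counts.counts.items():
        if codon in code.stop_codons:
            continue
        deg = code.degeneracy(codon)
        if mode == "fourfold_only":
            if len(code.synonymous_third_bases(codon)) != 4:
                continue
        elif deg < 2:
            continue
        tallies[codon[2]] += n
    at = tallies["A"] + tallies["T"]
    gc = tallies["G"] + tallies["C"]
    if at == 0 or gc == 0:
        raise ValueError(f"{counts.context}: empty PR2 stratum under mode {mode}")
    x = tallies["G"] / gc
    y = tallies["A"] / at
    return PR2Point(gene=gene or counts.context, taxon=taxon, x=x, y=y,
                    quadrant=_quadrant(x, y))


@dataclass
class CodonClassification:
    """Per-codon bias flags for one taxon.

    HFC: RSCU > 1 in the full gene set. High-expression: RSCU difference
    between the high-bias and low-bias gene groups (dRSCU) > 0.08.
    Optimal: both. Flags are only assigned to sense codons of multi-synonym
    families; codons whose dRSCU is undefined (a group missing the family)
    are listed separately.
    """

    taxon: str
    hfc: frozenset
    high_expression: frozenset
    optimal: frozenset
    delta_rscu: dict
    undefined: frozenset
    group_meta: dict

    def ending_base_counts(self, which: str = "hfc") -> dict:
        codons = getattr(self, which)
        out = {b: 0 for b in "ATGC"}
        for c in codons:
            out[c[2]] += 1
        return out


def classify_codons(
    rscu_all: RSCUTable,
    rscu_high: RSCUTable,
    rscu_low: RSCUTable,
    rscu_threshold: float = 1.0,
    delta_threshold: float = 0.08,
    taxon: str = "",
    group_meta: dict | None = None,
) -> CodonClassification:
    """Flag high-frequency, high-expression and optimal codons.

    dRSCU = RSCU(high-bias group) - RSCU(low-bias group); the optimal set
    is by construction the intersection of the HFC and high-expression
    sets.
    """
    hfc = frozenset(c for c, v in rscu_all.rscu.items() if v > rscu_threshold)
    delta = {}
    undefined = []
    for codon in rscu_all.rscu:
        hi = rscu_high.rscu.get(codon)
        lo = rscu_low.rscu.get(codon)
        if hi is None or lo is None:
            undefined.append(codon)
            continue
        delta[codon] = hi - lo
    high_expr = frozenset(c for c, d in delta.items() if d > delta_threshold)
    return CodonClassification(
        taxon=taxon,
        hfc=hfc,
        high_expression=high_expr,
        optimal=hfc & high_expr,
        delta_rscu=delta,
        undefined=frozenset(undefined),
        group_meta=group_meta or {},
    )


def rank_gene_groups(index_df, key: str = "ENC", group_size: int = 3) -> dict:
    """Split genes into high-bias and low-bias groups by an index ranking.

    With ENC as the key, low values mean strong bias, so the high-bias
    group is the ``group_size`` lowest-ENC genes and the low-bias group the
    highest. With CAI the ordering is reversed (high CAI = high bias).
    """
    df = index_df.sort_values(key)
    genes = list(df["gene"])
    ascending_is_biased = key.upper() in ("ENC",)
    if ascending_is_biased:
        high = genes[:group_size]
        low = genes[-group_size:]
    else:
        high = genes[-group_size:]
        low = genes[:group_size]
    return {"high": high, "low": low, "key": key, "group_size": group_size}


def index_correlation(index_df, columns=None) -> dict:
    """Pearson correlations (with two-sided p-values) between usage indices
    across the genes of one taxon.

    Returns {"r": DataFrame, "p": DataFrame, "stars": DataFrame}; constant
    columns yield NaN entries rather than errors.
    """
    import pandas as pd

    from .codon_metrics import INDEX_COLUMNS

    cols = [c for c in (columns or INDEX_COLUMNS) if c in index_df.columns]
    data = index_df[cols].astype(float)
    if len(data) < 3:
        raise ValueError("correlation needs at least 3 genes")
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            xi, xj = data.iloc[:, i], data.iloc[:, j]
            if xi.std() == 0 or xj.std() == 0:
                continue
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
            else:
                rr, pp = stats.pearsonr(xi, xj)
                r[i, j] = r[j, i] = rr
                p[i, j] = p[j, i] = pp
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)

    def star(pv):
        if np.isnan(pv):
            return ""
        if pv < 0.001:
            return "***"
        if pv < 0.01:
            return "**"
        if pv < 0.05:
            return "*"
        return ""

    stars = p_df.map(star)
    np.fill_diagonal(stars.values, "")
    return {"r": r_df, "p": p_df, "stars": stars}
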