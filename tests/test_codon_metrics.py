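"""Codon-usage index battery against naive reference implementations.

The oracle functions below re-derive each index directly from its formula
with no shared code, then the package implementation is checked against
them on random count tables.
"""

import math
import random

import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocodon import (
    cai, cai_weights, cbi_fop, count_codons, enc, gravy_aromo, rscu, x3s,
)
from mitocodon.codon_metrics import (
    CodonCountTable, optimal_codons_from_reference, usage_indices,
)
from mitocodon.genetic_code import get_code

# -- naive oracles -----------------------------------------------------------


def oracle_rscu(counts, code):
    out = {}
    for aa, family in code.families.items():
        if len(family) < 2:
            continue
        total = sum(counts.get(c, 0) for c in family)
        if total == 0:
            continue
        for c in family:
            out[c] = counts.get(c, 0) * len(family) / total
    return out


def oracle_enc(counts, code):
    by_k = {}
    for aa, family in code.families.items():
        k = len(family)
        n = sum(counts.get(c, 0) for c in family)
        if k == 1:
            continue
        if n > 1:
            s = sum((counts.get(c, 0) / n) ** 2 for c in family)
            f = (n * s - 1) / (n - 1)
            if f > 0:
                by_k.setdefault(k, []).append(f)
    total = sum(len(fam) == 1 for fam in code.families.values())
    for k in sorted({len(f) for f in code.families.values()} - {1}):
        m_k = sum(1 for f in code.families.values() if len(f) == k)
        fs = by_k.get(k)
        f_bar = sum(fs) / len(fs) if fs else 1.0 / k
        total += m_k / f_bar
    return min(max(total, 20.0), 61.0)


def oracle_cai(counts, weights):
    logs, n = 0.0, 0
    for codon, k in counts.items():
        if codon in weights:
            logs += k * math.log(weights[codon])
            n += k
    return math.exp(logs / n)


def oracle_cbi_fop(counts, optimal, code):
    n_opt = n_tot = 0
    n_rand = 0.0
    for aa, family in code.families.items():
        opt_members = [c for c in family if c in optimal]
        if not opt_members:
            continue
        n_fam = sum(counts.get(c, 0) for c in family)
        n_tot += n_fam
        n_opt += sum(counts.get(c, 0) for c in opt_members)
        n_rand += n_fam * len(opt_members) / len(family)
    fop = n_opt / n_tot
    cbi = (n_opt - n_rand) / (n_tot - n_rand)
    return cbi, fop


def random_table(rng, code, lam=8):
    counts = {c: rng.poisson(lam) for c in code.sense_codons}
    return CodonCountTable(context="rand", counts={k: int(v) for k, v in counts.items()},
                           code=code)


# -- counting ----------------------------------------------------------------


class TestCountCodons:
    def test_stop_exclusion(self, code2):
        table = count_codons("ATGATGTAA", code=code2)
        assert table.counts == {"ATG": 2}
        assert table.n_codons == 2

    def test_aga_is_stop_under_table2(self, code2):
        table = count_codons("ATGAGAATG", code=code2)
        assert "AGA" not in table.counts

    def test_ambiguous_codons_tallied(self, code2):
        table = count_codons("ATGNNNCTT", code=code2)
        assert table.n_ambiguous == 1
        assert table.n_codons == 2

    def test_additivity_under_concatenation(self, code2):
        a, b = "ATGCTTCCA", "GGGCTTTGA"
        merged = count_codons(a + b, code=code2)
        summed = count_codons(a, code=code2) + count_codons(b, code=code2)
        assert merged.counts == summed.counts


# -- RSCU --------------------------------------------------------------------


class TestRSCU:
    def test_uniform_twofold_family(self, code2):
        table = CodonCountTable("t", {"TTT": 5, "TTC": 5}, code2)
        vals = rscu(table).rscu
        assert vals["TTT"] == vals["TTC"] == 1.0

    def test_extreme_bias(self, code2):
        table = CodonCountTable("t", {"TTT": 10, "TTC": 0}, code2)
        vals = rscu(table).rscu
        assert vals["TTT"] == 2.0 and vals["TTC"] == 0.0

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_family_sums_equal_degeneracy(self, code2, seed):
        import numpy as np

        rng = np.random.default_rng(seed)
        table = random_table(rng, code2)
        result = rscu(table)
        for aa, family in code2.families.items():
            if aa in result.undefined_families or len(family) < 2:
                continue
            assert result.family_sum(aa) == pytest.approx(len(family))

    def test_matches_oracle(self, code2):
        import numpy as np

        rng = np.random.default_rng(3)
        table = random_table(rng, code2)
        assert rscu(table).rscu == pytest.approx(oracle_rscu(table.counts, code2))


# -- ENC ---------------------------------------------------------------------


class TestENC:
    def test_uniform_usage_reaches_61_under_standard_code(self, code1):
        table = CodonCountTable("t", {c: 100 for c in code1.sense_codons}, code1)
        assert enc(table) == pytest.approx(61.0, abs=0.15)

    def test_one_codon_per_family_reaches_20(self, code1):
        counts = {fam[0]: 100 for fam in code1.families.values()}
        table = CodonCountTable("t", counts, code1)
        assert enc(table) == pytest.approx(20.0, abs=1e-9)

    def test_table2_uniform_limit_is_60(self, code2):
        # table 2 has 60 sense codons, so the no-bias limit is 60, not 61;
        # Wright's estimator approaches the limit from above as n grows
        table = CodonCountTable("t", {c: 10000 for c in code2.sense_codons}, code2)
        assert enc(table) == pytest.approx(60.0, abs=0.01)

    def test_concentration_decreases_enc(self, code2):
        spread = CodonCountTable(
            "t", {c: 50 for fam in code2.families.values() for c in fam}, code2
        )
        concentrated = CodonCountTable(
            "t",
            {c: (200 if i == 0 else 2) for fam in code2.families.values()
             for i, c in enumerate(fam)},
            code2,
        )
        assert enc(concentrated) < enc(spread)

    def test_relabeling_within_families_is_invariant(self, code2):
        import numpy as np

        rng = np.random.default_rng(11)
        table = random_table(rng, code2)
        rotated = {}
        for fam in code2.families.values():
            for i, c in enumerate(fam):
                rotated[fam[(i + 1) % len(fam)]] = table.counts.get(c, 0)
        assert enc(CodonCountTable("t", rotated, code2)) == pytest.approx(enc(table))

    def test_matches_oracle_on_random_tables(self, code2):
        import numpy as np

        for seed in range(100):
            rng = np.random.default_rng(seed)
            table = random_table(rng, code2, lam=4)
            assert enc(table) == pytest.approx(
                oracle_enc(table.counts, code2), abs=1e-9
            )


# -- X3s ---------------------------------------------------------------------


class TestX3s:
    def test_gc3s_saturation(self, code2):
        table = CodonCountTable("t", {"TTC": 4, "CTG": 6}, code2)
        assert x3s(table)["GC3s"] == 1.0

    def test_per_base_denominators_differ(self, code2):
        # TTT (Phe): third position synonymously T/C only; A3s denominator
        # must exclude it while T3s includes it.
        table = CodonCountTable("t", {"TTT": 10, "CTA": 10}, code2)
        vals = x3s(table)
        assert vals["A3s"] == pytest.approx(1.0)  # CTA only, 10/10
        assert vals["T3s"] == pytest.approx(0.5)  # TTT among both codons

    def test_zero_denominator_errors(self, code2):
        with pytest.raises(ValueError):
            x3s(CodonCountTable("t", {}, code2))

    def test_third_position_preserving_swap_keeps_gc3s(self, code2):
        table = CodonCountTable("t", {"CTA": 7, "CTG": 3, "GTA": 2}, code2)
        swapped = CodonCountTable("t", {"TTA": 7, "TTG": 3, "GTA": 2}, code2)
        assert x3s(table)["GC3s"] == pytest.approx(x3s(swapped)["GC3s"])


# -- CAI ---------------------------------------------------------------------


class TestCAI:
    def test_preferred_codons_give_unit_weights_and_cai_one(self, code2):
        ref_counts = {}
        for fam in code2.families.values():
            ref_counts[fam[0]] = 50
            for c in fam[1:]:
                ref_counts[c] = 10
        reference = rscu(CodonCountTable("ref", ref_counts, code2))
        weights = cai_weights(reference)
        for fam in code2.families.values():
            if len(fam) < 2:
                continue
            assert weights[fam[0]] == 1.0
        gene = CodonCountTable(
            "g", {fam[0]: 5 for fam in code2.families.values()}, code2
        )
        assert cai(gene, weights) == pytest.approx(1.0)

    def test_unused_reference_codon_gets_floor(self, code2):
        reference = rscu(CodonCountTable("ref", {"TTT": 10, "TTC": 0}, code2))
        weights = cai_weights(reference, w_floor=0.01)
        assert weights["TTC"] == 0.01

    def test_matches_oracle(self, code2):
        import numpy as np

        rng = np.random.default_rng(5)
        ref = rscu(random_table(rng, code2))
        weights = cai_weights(ref)
        gene = random_table(rng, code2, lam=3)
        assert cai(gene, weights) == pytest.approx(
            oracle_cai(gene.counts, weights), abs=1e-12
        )


# -- CBI / FOP ---------------------------------------------------------------


class TestCBIFOP:
    def test_all_optimal_gives_unity(self, code2):
        optimal = frozenset(fam[0] for fam in code2.families.values())
        gene = CodonCountTable("g", {fam[0]: 5 for fam in code2.families.values()}, code2)
        result = cbi_fop(gene, optimal)
        assert result["FOP"] == 1.0
        assert result["CBI"] == pytest.approx(1.0)

    def test_uniform_usage_gives_zero_cbi(self, code2):
        optimal = frozenset(fam[0] for fam in code2.families.values())
        gene = CodonCountTable(
            "g", {c: 6 for fam in code2.families.values() for c in fam}, code2
        )
        result = cbi_fop(gene, optimal)
        assert result["CBI"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_optimal_set_errors(self, code2):
        with pytest.raises(ValueError):
            cbi_fop(CodonCountTable("g", {"TTT": 1}, code2), frozenset())

    def test_matches_oracle_on_random_tables(self, code2):
        import numpy as np

        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            ref = rscu(random_table(rng, code2))
            optimal = optimal_codons_from_reference(ref)
            gene = random_table(rng, code2, lam=3)
            expected_cbi, expected_fop = oracle_cbi_fop(gene.counts, optimal, code2)
            got = cbi_fop(gene, optimal)
            assert got["CBI"] == pytest.approx(expected_cbi, abs=1e-9)
            assert got["FOP"] == pytest.approx(expected_fop, abs=1e-9)


# -- GRAVY / AROMO -----------------------------------------------------------


class TestGravyAromo:
    def test_poly_ile_gravy(self, code2):
        result = gravy_aromo("ATCATCATCATC", code=code2)
        assert result["GRAVY"] == pytest.approx(4.5)

    def test_aromatic_saturation(self, code2):
        # Phe-Tyr-Trp only
        result = gravy_aromo("TTTTATTGA", code=code2)
        assert result["AROMO"] == 1.0

    def test_agrees_with_protparam(self, code2, sim_blocks):
        blocks, _ = sim_blocks
        seq = blocks["COX1"].sequences[0]
        protein = code2.translate(seq).rstrip("*")
        pa = ProteinAnalysis(protein)
        result = gravy_aromo(seq, code=code2)
        assert result["GRAVY"] == pytest.approx(pa.gravy(), abs=1e-9)
        assert result["AROMO"] == pytest.approx(pa.aromaticity(), abs=1e-9)


# -- assembled table ---------------------------------------------------------


def test_usage_indices_shape_and_ranges(sim_blocks, code2):
    from mitocodon.io import ValidatedCDS

    blocks, _ = sim_blocks
    cds_list = [
        ValidatedCDS(gene=g, taxon=b.taxa[0], sequence=b.sequences[0])
        for g, b in blocks.items()
    ]
    df = usage_indices(cds_list, code=code2)
    assert len(df) == 13
    assert ((df["ENC"] >= 20) & (df["ENC"] <= 61)).all()
    assert ((df["CAI"] > 0) & (df["CAI"] <= 1)).all()
    assert ((df["FOP"] >= 0) & (df["FOP"] <= 1)).all()
    assert ((df["CBI"] >= -1) & (df["CBI"] <= 1)).all()
    assert ((df["AROMO"] >= 0) & (df["AROMO"] <= 1)).all()
    assert df["GC12"].equals((df["GC1"] + df["GC2"]) / 2)
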