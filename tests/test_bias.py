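"""Neutrality, ENC-GC3s, PR2 and codon-classification diagnostics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mitocodon import (
    classify_codons, enc_expected, index_correlation, neutrality_fit, pr2, rscu,
)
from mitocodon.bias import enc_deviation, rank_gene_groups
from mitocodon.codon_metrics import CodonCountTable


class TestNeutrality:
    def test_identity_line(self):
        pts = [(x, x) for x in (0.2, 0.3, 0.4, 0.5)]
        fit = neutrality_fit(pts)
        assert fit.slope == pytest.approx(1.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_flat_response(self):
        fit = neutrality_fit([(0.2, 0.4), (0.3, 0.4), (0.5, 0.4)])
        assert fit.slope == pytest.approx(0.0)

    def test_zero_gc3_variance_flagged(self):
        fit = neutrality_fit([(0.3, 0.1), (0.3, 0.2), (0.3, 0.5)])
        assert np.isnan(fit.slope)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            neutrality_fit([(0.1, 0.2), (0.3, 0.4)])


class TestEncExpected:
    def test_midpoint_value(self):
        assert enc_expected(0.5) == pytest.approx(60.5)

    def test_limits(self):
        assert enc_expected(0.0) == pytest.approx(31.0)
        assert enc_expected(1.0) == pytest.approx(32.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(0.0, 1.0))
    def test_near_symmetry_and_peak(self, s):
        # the curve is symmetric up to the linear term: f(s) - f(1-s) = 2s - 1
        assert enc_expected(s) - enc_expected(1.0 - s) == pytest.approx(2 * s - 1)
        assert enc_expected(s) <= 60.51

    def test_deviation_sign(self):
        assert enc_deviation(40.0, 0.5) > 0  # observed below expectation
        assert enc_deviation(60.5, 0.5) == pytest.approx(0.0)


class TestPR2:
    def test_parity_lands_on_boundary(self, code2):
        # fourfold Leu box CTN with A3=T3 and G3=C3
        table = CodonCountTable("t", {"CTA": 5, "CTT": 5, "CTG": 2, "CTC": 2}, code2)
        point = pr2(table, gene="g")
        assert (point.x, point.y) == (0.5, 0.5)
        assert point.quadrant == "boundary"

    def test_scaling_invariance(self, code2):
        counts = {"CTA": 8, "CTT": 3, "CTG": 2, "CTC": 5, "GTA": 1, "GTG": 4}
        a = pr2(CodonCountTable("t", counts, code2))
        b = pr2(CodonCountTable("t", {k: 3 * v for k, v in counts.items()}, code2))
        assert (a.x, a.y) == (pytest.approx(b.x), pytest.approx(b.y))

    def test_fourfold_mode_excludes_twofold_families(self, code2):
        # TTT/TTC (Phe) are not fourfold-synonymous at position 3
        table = CodonCountTable("t", {"TTT": 50, "TTC": 50, "CTA": 1, "CTG": 1}, code2)
        point = pr2(table, mode="fourfold_only")
        assert point.y == pytest.approx(1.0)  # only CTA contributes to A/T
        all_syn = pr2(table, mode="all_synonymous")
        assert all_syn.y < point.y

    def test_empty_stratum_errors(self, code2):
        with pytest.raises(ValueError):
            pr2(CodonCountTable("t", {"TTT": 5}, code2), mode="fourfold_only")

    def test_quadrant_ii_for_a_and_c_preference(self, code2):
        table = CodonCountTable("t", {"CTA": 10, "CTT": 2, "CTC": 6, "CTG": 1}, code2)
        point = pr2(table)
        assert point.quadrant == "II"
        assert point.y > 0.5 and point.x < 0.5


count_tables = st.dictionaries(
    st.sampled_from(["TTT", "TTC", "CTA", "CTG", "CTT", "CTC", "ATA", "ATG",
                     "GCA", "GCC", "GCG", "GCT", "TCA", "TCC", "AGC", "AGT"]),
    st.integers(0, 50),
    min_size=4,
)


class TestClassification:
    def test_threshold_logic(self, code2):
        all_t = CodonCountTable("a", {"TTT": 15, "TTC": 5}, code2)
        high = CodonCountTable("h", {"TTT": 12, "TTC": 8}, code2)
        low = CodonCountTable("l", {"TTT": 10, "TTC": 10}, code2)
        cls = classify_codons(rscu(all_t), rscu(high), rscu(low))
        # TTT: RSCU 1.5 > 1, dRSCU = 1.2 - 1.0 = 0.2 > 0.08 -> optimal
        assert "TTT" in cls.optimal
        # TTC: RSCU 0.5, not an HFC; dRSCU = 0.8 - 1.0 < 0
        assert "TTC" not in cls.hfc and "TTC" not in cls.high_expression

    def test_zero_delta_keeps_hfc_only(self, code2):
        all_t = CodonCountTable("a", {"TTT": 15, "TTC": 5}, code2)
        same = CodonCountTable("h", {"TTT": 15, "TTC": 5}, code2)
        cls = classify_codons(rscu(all_t), rscu(same), rscu(same))
        assert "TTT" in cls.hfc and "TTT" not in cls.high_expression

    def test_missing_family_in_group_flagged(self, code2):
        all_t = CodonCountTable("a", {"CTA": 5, "TTT": 5}, code2)
        high = CodonCountTable("h", {"CTA": 5}, code2)
        low = CodonCountTable("l", {"CTA": 5, "TTT": 5}, code2)
        cls = classify_codons(rscu(all_t), rscu(high), rscu(low))
        assert "TTT" in cls.undefined

    @settings(max_examples=60, deadline=None)
    @given(count_tables, count_tables, count_tables)
    def test_flag_hierarchy_on_random_inputs(self, code2, c_all, c_high, c_low):
        cls = classify_codons(
            rscu(CodonCountTable("a", c_all, code2)),
            rscu(CodonCountTable("h", c_high, code2)),
            rscu(CodonCountTable("l", c_low, code2)),
        )
        assert cls.optimal <= cls.hfc
        assert cls.optimal <= cls.high_expression
        assert cls.optimal == cls.hfc & cls.high_expression


class TestGeneGroups:
    def test_enc_ranking_puts_low_enc_in_high_bias_group(self):
        import pandas as pd

        df = pd.DataFrame({"gene": list("abcdef"), "ENC": [30, 55, 40, 35, 60, 50]})
        groups = rank_gene_groups(df, key="ENC", group_size=2)
        assert groups["high"] == ["a", "d"]
        assert set(groups["low"]) == {"e", "b"}


class TestCorrelation:
    def test_symmetric_with_unit_diagonal(self, pipeline_outputs):
        import pandas as pd

        _, outputs = pipeline_outputs
        df = pd.read_csv(outputs["indices"], sep="\t")
        one = df[df["taxon"] == df["taxon"].iloc[0]]
        corr = index_correlation(one)
        r = corr["r"].values
        assert np.allclose(r, r.T, equal_nan=True)
        assert np.allclose(np.diag(r), 1.0)

    def test_cbi_fop_strongly_correlated(self, pipeline_outputs):
        import pandas as pd

        _, outputs = pipeline_outputs
        df = pd.read_csv(outputs["indices"], sep="\t")
        for taxon, sub in df.groupby("taxon"):
            corr = index_correlation(sub)
            assert corr["r"].loc["CBI", "FOP"] > 0
            assert corr["p"].loc["CBI", "FOP"] < 0.001

    def test_null_calibration_of_pearson_p(self):
        # independent columns, n = 13 genes: the 0.05 test should reject
        # in about 5% of replicates
        rng = np.random.default_rng(0)
        hits = 0
        reps = 1000
        for _ in range(reps):
            x, y = rng.normal(size=13), rng.normal(size=13)
            if stats.pearsonr(x, y)[1] < 0.05:
                hits += 1
        assert 0.03 < hits / reps < 0.07
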