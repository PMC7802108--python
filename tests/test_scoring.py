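"""Staining score, confidence score, and the ranked query table."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import stainscore as ss
from stainscore.errors import NoGenesMatchedError, UndefinedScoreError

WEIGHT = {"High": 100.0, "Medium": 50.0, "Low": 25.0, "Not detected": 0.0}
RANK = {"Not detected": 0, "Low": 1, "Medium": 2, "High": 3}


def brute_force_scores(records: pd.DataFrame, tokens) -> dict:
    """Independent oracle: enumerate (key, gene, level) triples directly."""
    tokens = {t.upper() for t in tokens}
    best = {}
    for row in records.itertuples():
        gene = row.gene_name.upper()
        if gene not in tokens:
            continue
        key = (row.tissue.casefold(), row.cell_type.casefold())
        cur = best.get((key, gene))
        if cur is None or RANK[row.level] > RANK[cur]:
            best[(key, gene)] = row.level
    per_key = {}
    for (key, gene), level in best.items():
        per_key.setdefault(key, []).append(level)
    return {
        key: sum(WEIGHT[lv] for lv in levels) / len(levels)
        for key, levels in per_key.items()
    }


class TestStainingScore:
    @pytest.mark.parametrize(
        "t,h,m,l,expected",
        [
            (4, 3, 0, 0, 75.0),
            (4, 0, 1, 0, 12.5),
            (3, 1, 1, 1, 175.0 / 3),
            (5, 0, 0, 0, 0.0),
            (2, 2, 0, 0, 100.0),
        ],
    )
    def test_equation(self, t, h, m, l, expected):
        comp = ss.ScoreComponents(t=t, h=h, m=m, l=l, nd=t - h - m - l)
        assert ss.staining_score(comp) == pytest.approx(expected)

    def test_t_zero_is_undefined(self):
        with pytest.raises(UndefinedScoreError):
            ss.staining_score(ss.ScoreComponents(t=0, h=0, m=0, l=0, nd=0))

    def test_inconsistent_components_rejected(self):
        with pytest.raises(ValueError):
            ss.ScoreComponents(t=4, h=3, m=3, l=0, nd=0)

    @given(
        h=st.integers(0, 20), m=st.integers(0, 20),
        l=st.integers(0, 20), nd=st.integers(0, 20),
    )
    def test_bounds_and_attainment(self, h, m, l, nd):
        t = h + m + l + nd
        if t == 0:
            return
        s = ss.staining_score(ss.ScoreComponents(t=t, h=h, m=m, l=l, nd=nd))
        assert 0.0 <= s <= 100.0
        assert (s == 100.0) == (h == t)
        assert (s == 0.0) == (nd == t)

    @given(h=st.integers(0, 10), m=st.integers(0, 10), l=st.integers(0, 10), nd=st.integers(1, 10))
    def test_level_upgrade_never_decreases_score(self, h, m, l, nd):
        t = h + m + l + nd
        base = ss.staining_score(ss.ScoreComponents(t=t, h=h, m=m, l=l, nd=nd))
        upgrades = [
            ss.ScoreComponents(t=t, h=h, m=m, l=l + 1, nd=nd - 1),  # nd -> Low
            ss.ScoreComponents(t=t, h=h, m=m + 1, l=l, nd=nd - 1),  # nd -> Medium
            ss.ScoreComponents(t=t, h=h + 1, m=m, l=l, nd=nd - 1),  # nd -> High
        ]
        for comp in upgrades:
            assert ss.staining_score(comp) >= base


class TestConfidenceScore:
    @pytest.mark.parametrize(
        "p,s,expected",
        [(5, 57.75, 5.775), (16, 42.5, 13.6), (50, 66.75, 66.75), (3, 50, 3.0), (120, 40, 40.0)],
    )
    def test_equation_with_cap(self, p, s, expected):
        assert ss.confidence_score(p, s) == pytest.approx(expected)

    def test_zero_proteins_gives_zero(self):
        assert ss.confidence_score(0, 80.0) == 0.0

    @given(p=st.integers(0, 200), s=st.floats(0, 100, allow_nan=False))
    def test_never_exceeds_staining_score(self, p, s):
        c = ss.confidence_score(p, s)
        assert 0.0 <= c <= s + 1e-12
        if p >= 50 or s == 0:
            assert c == pytest.approx(s)


class TestScoreQuery:
    def test_worked_example_ranks_and_scores(self, worked_records, worked_query):
        res = ss.score_query(worked_records, worked_query)
        top3 = res.head(3)
        assert list(top3["display"]) == [
            "PANCREAS - exocrine glandular cells",
            "PITUITARY GLAND - cells in anterior",
            "SMALL INTESTINE - glandular cells",
        ]
        assert list(top3["staining_score"]) == [75.0, 25.0, 12.5]
        assert (res["staining_score"].iloc[3:] == 0.0).all()

    def test_single_gene_high_in_one_key(self):
        rec = ss.worked_example_fixture()
        res = ss.score_query(rec, "PRL")
        assert res.iloc[0]["display"] == "PITUITARY GLAND - cells in anterior"
        assert res.iloc[0]["staining_score"] == 100.0
        assert (res["staining_score"].iloc[1:] == 0.0).all()

    def test_query_order_invariance(self, small_atlas):
        genes = sorted(small_atlas["gene_name"].unique())[:12]
        fwd = ss.score_query(small_atlas, genes)
        rev = ss.score_query(small_atlas, genes[::-1])
        pd.testing.assert_frame_equal(fwd, rev)

    def test_matches_brute_force_oracle(self, small_atlas):
        genes = sorted(small_atlas["gene_name"].unique())[:15]
        res = ss.score_query(small_atlas, genes, ss.ScoreOptions(compute_pvalues=False))
        oracle = brute_force_scores(small_atlas, genes)
        assert len(res) == len(oracle)
        for row in res.itertuples():
            key = (row.tissue.casefold(), row.cell_type.casefold())
            assert row.staining_score == pytest.approx(oracle[key])

    def test_duplicating_records_leaves_scores_unchanged(self, small_atlas):
        genes = sorted(small_atlas["gene_name"].unique())[:10]
        doubled = pd.concat([small_atlas, small_atlas], ignore_index=True)
        a = ss.score_query(small_atlas, genes)
        b = ss.score_query(doubled, genes)
        pd.testing.assert_frame_equal(a, b)

    def test_no_genes_matched_lists_unmatched_tokens(self, worked_records):
        with pytest.raises(NoGenesMatchedError) as err:
            ss.score_query(worked_records, "NOPE1 NOPE2")
        assert set(err.value.unmatched) == {"NOPE1", "NOPE2"}

    def test_detected_proteins_toggle(self, worked_records, worked_query):
        shown = ss.score_query(worked_records, worked_query, ss.ScoreOptions(show_proteins=True))
        assert shown.iloc[0]["detected_proteins"] == [
            ("CELA3A", "High"), ("PNLIP", "High"), ("PRSS1", "High"),
        ]
        hidden = ss.score_query(worked_records, worked_query, ss.ScoreOptions(show_proteins=False))
        assert "detected_proteins" not in hidden.columns

    def test_tie_break_is_deterministic(self):
        rec = pd.DataFrame(
            {
                "gene_id": ["E1"] * 3,
                "gene_name": ["A"] * 3,
                "tissue": ["zeta", "alpha", "beta"],
                "cell_type": ["c", "c", "c"],
                "level": ["High", "High", "High"],
                "reliability": ["Supported"] * 3,
            }
        )
        res = ss.score_query(rec, "A", ss.ScoreOptions(compute_pvalues=False))
        assert list(res["tissue"]) == ["alpha", "beta", "zeta"]

    def test_dilute_by_unmatched_option(self):
        # gene B never evaluated in the key: default t=1, diluted t=2
        rec = pd.DataFrame(
            {
                "gene_id": ["E1", "E2"],
                "gene_name": ["A", "B"],
                "tissue": ["liver", "lung"],
                "cell_type": ["hepatocytes", "pneumocytes"],
                "level": ["High", "High"],
                "reliability": ["Supported"] * 2,
            }
        )
        strict = ss.score_query(rec, "A B", ss.ScoreOptions(compute_pvalues=False))
        assert set(strict["staining_score"]) == {100.0}
        diluted = ss.score_query(
            rec, "A B", ss.ScoreOptions(compute_pvalues=False, dilute_by_unmatched=True)
        )
        assert set(diluted["staining_score"]) == {50.0}

    def test_confidence_column_uses_matched_gene_count(self, worked_records, worked_query):
        res = ss.score_query(worked_records, worked_query, ss.ScoreOptions(confidence=True))
        top = res.iloc[0]
        assert top["confidence_score"] == pytest.approx(
            ss.confidence_score(4, top["staining_score"])
        )
        assert (res["confidence_score"] <= res["staining_score"] + 1e-12).all()


class TestScoreQueryCancer:
    def _cancer(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene_id", "gene_name", "cancer", "n_high", "n_medium", "n_low", "n_not_detected"],
        )

    def test_all_high_scores_100(self):
        rec = self._cancer([("E1", "A", "cancer x", 4, 0, 0, 0)])
        res = ss.score_query_cancer(rec, "A", ss.ScoreOptions(compute_pvalues=False))
        assert res.iloc[0]["staining_score"] == 100.0

    def test_fractional_level_weights(self):
        # 2 high + 2 medium patients -> h=0.5, m=0.5, t=1 -> 75
        rec = self._cancer([("E1", "A", "cancer x", 2, 2, 0, 0)])
        res = ss.score_query_cancer(rec, "A", ss.ScoreOptions(compute_pvalues=False))
        assert res.iloc[0]["staining_score"] == pytest.approx(75.0)

    def test_two_genes_average(self):
        rec = self._cancer(
            [("E1", "A", "cancer x", 4, 0, 0, 0), ("E2", "B", "cancer x", 0, 0, 0, 4)]
        )
        res = ss.score_query_cancer(rec, "A B", ss.ScoreOptions(compute_pvalues=False))
        assert res.iloc[0]["staining_score"] == pytest.approx(50.0)

    def test_duplicate_pairs_pool_patient_counts(self):
        rec = self._cancer(
            [("E1", "A", "cancer x", 1, 0, 0, 0), ("E1", "A", "cancer x", 1, 0, 0, 2)]
        )
        res = ss.score_query_cancer(rec, "A", ss.ScoreOptions(compute_pvalues=False))
        assert res.iloc[0]["staining_score"] == pytest.approx(50.0)


def test_score_query_on_generated_atlas_matches_oracle(hetero_atlas):
    rng = np.random.default_rng(0)
    genes = rng.choice(np.sort(hetero_atlas["gene_name"].unique()), size=30, replace=False)
    res = ss.score_query(hetero_atlas, list(genes), ss.ScoreOptions(compute_pvalues=False))
    oracle = brute_force_scores(hetero_atlas, genes)
    assert len(res) == len(oracle)
    for row in res.itertuples():
        assert row.staining_score == pytest.approx(
            oracle[(row.tissue.casefold(), row.cell_type.casefold())]
        )
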