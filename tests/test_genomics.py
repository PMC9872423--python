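"""Genomic feature derivation: ssGSEA, signatures, quartile binarization."""

import numpy as np
import pandas as pd
import pytest

from deepradiomics.genomics import (GeneSet, GenomicFeatureTable,
                                    assemble_gf_table, binarize_top_quartile,
                                    read_gmt, signature_score, ssgsea_score,
                                    write_gmt)


def _brute_force_ssgsea(sample: pd.Series, genes: set, alpha: float) -> float:
    """Independent step-by-step running-sum enumeration."""
    ordered = sorted(sample.index, key=lambda g: (-sample[g], g))
    n = len(ordered)
    n_in = sum(g in genes for g in ordered)
    wsum = sum((n - i) ** alpha for i, g in enumerate(ordered) if g in genes)
    p_in = p_out = 0.0
    score = 0.0
    for i, g in enumerate(ordered):
        if g in genes:
            p_in += (n - i) ** alpha / wsum
        else:
            p_out += 1.0 / (n - n_in)
        score += p_in - p_out
    return score


class TestSsgsea:
    def test_four_gene_hand_enumeration(self):
        s = pd.Series({"g1": 4.0, "g2": 3.0, "g3": 2.0, "g4": 1.0})
        # set = top gene, alpha 0: steps 1, 2/3, 1/3, 0 -> 2.0
        assert ssgsea_score(s, ["g1"], alpha=0.0) == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_stepwise_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        s = pd.Series(rng.normal(size=12),
                      index=[f"g{i}" for i in range(12)])
        genes = set(rng.choice(s.index, size=4, replace=False))
        got = ssgsea_score(s, sorted(genes), alpha=0.25)
        assert got == pytest.approx(_brute_force_ssgsea(s, genes, 0.25))

    def test_invariant_to_monotone_transforms(self, rng):
        s = pd.Series(rng.normal(size=20), index=[f"g{i}" for i in range(20)])
        gs = GeneSet("s", [f"g{i}" for i in range(0, 20, 3)])
        base = ssgsea_score(s, gs)
        assert ssgsea_score(np.exp(s), gs) == pytest.approx(base, abs=1e-9)
        assert ssgsea_score(3.0 * s + 11.0, gs) == pytest.approx(base, abs=1e-9)

    def test_set_complement_swap_negates_at_alpha_zero(self, rng):
        s = pd.Series(rng.normal(size=10), index=[f"g{i}" for i in range(10)])
        inset = [f"g{i}" for i in range(4)]
        outset = [f"g{i}" for i in range(4, 10)]
        a = ssgsea_score(s, inset, alpha=0.0)
        b = ssgsea_score(s, outset, alpha=0.0)
        assert a == pytest.approx(-b)

    def test_empty_overlap_or_complement_rejected(self):
        s = pd.Series({"g1": 1.0, "g2": 2.0})
        with pytest.raises(ValueError, match="overlap"):
            ssgsea_score(s, ["zz"])
        with pytest.raises(ValueError, match="complement"):
            ssgsea_score(s, ["g1", "g2"])


class TestSignatureScore:
    @pytest.fixture()
    def expr(self):
        return pd.DataFrame({"pA": [3.0, 4.0], "pB": [1.0, 0.0]},
                            index=["g1", "g2"])

    def test_weighted_sum(self, expr):
        out = signature_score(expr, {"g1": 2.0, "g2": -1.0})
        assert out["pA"] == pytest.approx(2.0)  # 2*3 - 4
        assert out["pB"] == pytest.approx(2.0)

    def test_zero_weights_give_zero(self, expr):
        assert (signature_score(expr, {"g1": 0.0, "g2": 0.0}) == 0).all()

    def test_single_gene_recovers_its_row(self, expr):
        out = signature_score(expr, {"g2": 1.0})
        pd.testing.assert_series_equal(out, expr.loc["g2"], check_names=False)

    def test_missing_genes_skipped_with_log(self, expr, caplog):
        with caplog.at_level("WARNING"):
            out = signature_score(expr, {"g1": 1.0, "nope": 5.0})
        assert "skipped" in caplog.text
        pd.testing.assert_series_equal(out, expr.loc["g1"], check_names=False)

    def test_no_present_gene_rejected(self, expr):
        with pytest.raises(ValueError, match="no weighted gene"):
            signature_score(expr, {"zz": 1.0})


class TestBinarizeTopQuartile:
    def test_eight_distinct_scores_give_two_positives(self):
        out = binarize_top_quartile(pd.Series(range(8), dtype=float))
        assert out.sum() == 2
        assert out.iloc[-2:].tolist() == [1, 1]

    def test_110_distinct_scores_give_28_positives(self):
        out = binarize_top_quartile(pd.Series(np.arange(110), dtype=float))
        assert out.sum() == 28

    def test_ties_spanning_cut_are_all_positive(self):
        out = binarize_top_quartile(pd.Series([0, 1, 2, 3, 3, 3, 3, 3],
                                              dtype=float))
        assert out.sum() == 5

    def test_positive_set_dominates_negative_set(self, rng):
        scores = pd.Series(rng.normal(size=37))
        out = binarize_top_quartile(scores)
        assert out.sum() >= int(np.ceil(37 / 4))
        assert scores[out == 0].max() <= scores[out == 1].min()

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            binarize_top_quartile(pd.Series([2.0] * 8))

    def test_too_few_patients_rejected(self):
        with pytest.raises(ValueError, match="4 patients"):
            binarize_top_quartile(pd.Series([1.0, 2.0, 3.0]))


class TestAssembleGfTable:
    @pytest.fixture()
    def expr(self, rng):
        genes = [f"g{i:03d}" for i in range(40)]
        pats = [f"p{i}" for i in range(8)]
        return pd.DataFrame(rng.normal(size=(40, 8)), index=genes,
                            columns=pats)

    def test_column_count_is_sum_of_categories(self, expr):
        sigs = {"sigA": {"g000": 1.0}, "sigB": {"g001": 2.0, "g002": -1.0}}
        paths = [GeneSet("pw1", ["g003", "g004"]), GeneSet("pw2", ["g005"])]
        table = assemble_gf_table(expr, list(expr.index[:5]), sigs, paths)
        assert table.values.shape == (8, 5 + 2 + 2)
        assert table.categories.value_counts().to_dict() == {
            "risk_gene": 5, "signature": 2, "pathway": 2}

    def test_patient_order_follows_expression(self, expr):
        table = assemble_gf_table(expr, list(expr.index[:3]))
        assert table.patient_ids == list(expr.columns)

    def test_no_pathways_yields_two_categories(self, expr):
        table = assemble_gf_table(expr, list(expr.index[:4]),
                                  {"s": {"g000": 1.0}}, [])
        assert set(table.categories) == {"risk_gene", "signature"}

    def test_duplicate_ids_rejected(self, expr):
        with pytest.raises(ValueError, match="duplicate"):
            assemble_gf_table(expr, ["g000"], {"g000": {"g001": 1.0}})

    def test_tsv_round_trip(self, expr, tmp_path):
        table = assemble_gf_table(expr, list(expr.index[:3]),
                                  {"s": {"g000": 1.0}},
                                  [GeneSet("pw", ["g001", "g002"])])
        table.to_tsv(tmp_path / "gf.tsv")
        back = GenomicFeatureTable.from_tsv(tmp_path / "gf.tsv")
        pd.testing.assert_frame_equal(back.values, table.values)
        assert back.categories.tolist() == table.categories.tolist()


def test_gmt_round_trip(tmp_path):
    sets = [GeneSet("a", ["g1", "g2"]), GeneSet("b", ["g3"])]
    write_gmt(sets, tmp_path / "sets.gmt")
    back = read_gmt(tmp_path / "sets.gmt")
    assert [(s.set_id, s.genes) for s in back] == [("a", ["g1", "g2"]),
                                                  ("b", ["g3"])]
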