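"""Gene-set scoring (ssGSEA/GSVA), GMT parsing, group reports."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from m6apat.enrichment import (
    GeneSetCollection,
    group_difference_report,
    gsva_scores,
    read_gmt,
    ssgsea_scores,
    write_gmt,
)


class TestGmt:
    def test_round_trip(self, tmp_path):
        coll = GeneSetCollection(
            sets={"S1": ["a", "b", "c"], "S2": ["d", "e"]},
            descriptions={"S1": "first", "S2": "second"},
        )
        path = tmp_path / "x.gmt"
        write_gmt(coll, path)
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions["S1"] == "first"

    def test_short_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("S1\tdesc\ta\nS2\tdesc\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(path)

    def test_duplicate_set_name_rejected(self, tmp_path):
        path = tmp_path / "dup.gmt"
        path.write_text("S1\td\ta\nS1\td\tb\n")
        with pytest.raises(ValueError, match="duplicated set name"):
            read_gmt(path)

    def test_repeated_member_stored_once(self, tmp_path):
        path = tmp_path / "rep.gmt"
        path.write_text("S1\td\ta\tb\ta\n")
        assert read_gmt(path).sets["S1"] == ["a", "b"]


class TestSsgsea:
    def test_hand_computed_running_sum(self):
        # 3 genes, the set holds the top gene, alpha=0:
        # walk = (+1, -1/2, -1/2) running values (1, 1/2, 0) -> integral 1.5
        m = pd.DataFrame({"s": [3.0, 2.0, 1.0]}, index=["g1", "g2", "g3"])
        coll = GeneSetCollection(sets={"top": ["g1"]})
        scores = ssgsea_scores(m, coll, alpha=0.0, normalize=False)
        assert scores.loc["top", "s"] == pytest.approx(1.5)

    def test_identical_rank_columns_get_identical_scores(self):
        rng = np.random.default_rng(0)
        col = rng.normal(size=30)
        m = pd.DataFrame(
            {"s1": col, "s2": 2 * col + 5},  # same ranks
            index=[f"g{i}" for i in range(30)],
        )
        coll = GeneSetCollection(sets={"S": [f"g{i}" for i in range(5)]})
        scores = ssgsea_scores(m, coll, normalize=False)
        assert scores["s1"].iloc[0] == pytest.approx(scores["s2"].iloc[0])

    def test_monotone_per_sample_transform_invariance(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(rng.normal(7, 1, (40, 6)),
                         index=[f"g{i}" for i in range(40)],
                         columns=[f"s{j}" for j in range(6)])
        coll = GeneSetCollection(sets={"S": [f"g{i}" for i in range(8)]})
        a = ssgsea_scores(m, coll, normalize=False)
        b = ssgsea_scores(2.0**m, coll, normalize=False)
        np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-10)

    def test_normalized_global_range_is_exactly_one(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(50, 8)),
                         index=[f"g{i}" for i in range(50)],
                         columns=[f"s{j}" for j in range(8)])
        coll = GeneSetCollection(
            sets={"A": [f"g{i}" for i in range(6)], "B": [f"g{i}" for i in range(20, 30)]}
        )
        scores = ssgsea_scores(m, coll, normalize=True)
        rng_val = scores.to_numpy().max() - scores.to_numpy().min()
        assert rng_val == pytest.approx(1.0, abs=1e-12)

    def test_all_gene_set_rejected_and_no_overlap_dropped(self):
        m = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("wxyz"))
        with pytest.raises(ValueError, match="every gene"):
            ssgsea_scores(m, GeneSetCollection(sets={"all": list("abcd")}))
        with pytest.warns(UserWarning, match="dropped"):
            scores = ssgsea_scores(
                m, GeneSetCollection(sets={"none": ["zz"], "ok": ["a", "b"]})
            )
        assert list(scores.index) == ["ok"]


class TestGsva:
    def test_opposite_rank_samples_get_opposite_signs(self):
        n = 20
        up = np.arange(n, dtype=float)
        m = pd.DataFrame(
            {"s1": up, "s2": up[::-1], "s3": np.r_[up[:10], up[10:]] * 0.9},
            index=[f"g{i}" for i in range(n)],
        )
        coll = GeneSetCollection(sets={"high": [f"g{i}" for i in range(15, 20)]})
        scores = gsva_scores(m, coll)
        assert scores.loc["high", "s1"] > 0 > scores.loc["high", "s2"]

    def test_constant_genes_score_zero(self):
        m = pd.DataFrame(np.ones((10, 4)),
                         index=[f"g{i}" for i in range(10)],
                         columns=list("wxyz"))
        coll = GeneSetCollection(sets={"S": ["g0", "g1", "g2"]})
        scores = gsva_scores(m, coll)
        assert np.max(np.abs(scores.to_numpy())) < 0.15

    def test_needs_three_samples(self):
        m = pd.DataFrame(np.ones((5, 2)), index=list("abcde"), columns=["s1", "s2"])
        with pytest.raises(ValueError, match="3 samples"):
            gsva_scores(m, GeneSetCollection(sets={"S": ["a"]}))

    def test_ordering_concordant_with_ssgsea_on_planted_signal(self, corrected_cohort):
        cfg, corrected, annotation, truth = corrected_cohort
        from m6apat.synthetic import make_fixture_genesets

        coll = make_fixture_genesets(cfg, truth)
        sub = corrected.iloc[:400]
        coll_sub = coll.restrict(sub.index)
        ss = ssgsea_scores(sub, coll_sub)
        gv = gsva_scores(sub, coll_sub)
        planted = [s for names in truth.immune_up_sets.values() for s in names
                   if s in gv.index]
        rhos = [spearmanr(ss.loc[s], gv.loc[s]).statistic for s in planted]
        assert np.mean(rhos) > 0.8


class TestGroupReport:
    def test_identical_groups_all_p_one(self):
        m = pd.DataFrame([[1.0, 2.0, 1.0, 2.0], [5.0, 6.0, 5.0, 6.0]],
                         columns=list("wxyz"))
        rep = group_difference_report(m, ["a", "a", "b", "b"])
        assert (rep["p_value"] == 1.0).all()

    def test_shifted_row_has_smallest_kruskal_p(self):
        rng = np.random.default_rng(3)
        m = pd.DataFrame(rng.normal(size=(10, 30)),
                         columns=[f"s{i}" for i in range(30)])
        labels = np.repeat(["a", "b", "c"], 10)
        m.iloc[4, labels == "c"] += 3.0
        rep = group_difference_report(m, labels)
        assert rep.attrs["test"] == "kruskal-wallis"
        assert rep["p_value"].idxmin() == 4

    def test_empty_group_rejected(self):
        m = pd.DataFrame([[1.0, 2.0]], columns=["x", "y"])
        with pytest.raises(ValueError):
            group_difference_report(m, ["a", "a"])

    def test_agreement_with_reference_ssgsea_implementation(self):
        import gseapy

        rng = np.random.default_rng(5)
        m = pd.DataFrame(
            rng.normal(7, 1, (80, 10)) + np.linspace(0, 2, 80)[:, None],
            index=[f"g{i}" for i in range(80)],
            columns=[f"s{j}" for j in range(10)],
        )
        sets = {"HI": [f"g{i}" for i in range(65, 80)],
                "LO": [f"g{i}" for i in range(15)]}
        ours = ssgsea_scores(m, GeneSetCollection(sets={k: list(v) for k, v in sets.items()}),
                             normalize=False)
        res = gseapy.ssgsea(data=m, gene_sets={k: list(v) for k, v in sets.items()},
                            outdir=None, sample_norm_method="rank", min_size=2,
                            no_plot=True, threads=1, seed=0)
        theirs = res.res2d.pivot(index="Term", columns="Name", values="ES").astype(float)
        for s in ("HI", "LO"):
            rho = spearmanr(ours.loc[s, theirs.columns], theirs.loc[s]).statistic
            assert rho > 0.8
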