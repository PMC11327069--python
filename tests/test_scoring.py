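"""ssGSEA scores vs an independent running-sum oracle; score statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from epilnc.scoring import (
    GeneSet, build_epi_sets, compare_groups, correlate_scores, read_gmt,
    ssgsea_score,
)


def ssgsea_oracle(expr_col: pd.Series, members: set, alpha: float) -> float:
    """Straightforward re-derivation of the single-sample running sum."""
    ranks = stats.rankdata(expr_col.to_numpy(), method="average")
    order = np.argsort(-ranks, kind="stable")
    genes = expr_col.index.to_numpy()[order]
    r_sorted = ranks[order]
    in_set = np.array([g in members for g in genes])
    n_out = len(genes) - in_set.sum()
    if n_out == 0:
        return 0.0
    w = np.where(in_set, r_sorted ** alpha, 0.0)
    es = 0.0
    p_in = p_out = 0.0
    w_total = w.sum()
    for i in range(len(genes)):
        if in_set[i]:
            p_in += w[i] / w_total
        else:
            p_out += 1.0 / n_out
        es += p_in - p_out
    return es


def expr_frame(rng, n_genes=50, n_samples=6):
    return pd.DataFrame(rng.lognormal(2, 1, size=(n_genes, n_samples)),
                        index=[f"g{i}" for i in range(n_genes)],
                        columns=[f"s{j}" for j in range(n_samples)])


class TestSsgsea:
    def test_matches_oracle_on_random_matrices(self, rng):
        for _ in range(10):
            expr = expr_frame(rng)
            members = tuple(rng.choice(expr.index, size=5, replace=False))
            gs = GeneSet("S", members)
            scores = ssgsea_score(expr, [gs])
            for col in expr.columns:
                assert scores.loc["S", col] == pytest.approx(
                    ssgsea_oracle(expr[col], set(members), 0.25), abs=1e-10)

    def test_all_gene_set_scores_zero(self, rng):
        expr = expr_frame(rng, n_genes=10)
        gs = GeneSet("ALL", tuple(expr.index))
        assert (ssgsea_score(expr, [gs]) == 0.0).all().all()

    def test_top_gene_set_beats_bottom_gene_set(self, rng):
        expr = expr_frame(rng, n_genes=20, n_samples=1)
        col = expr.iloc[:, 0]
        top = GeneSet("top", (col.idxmax(),))
        bottom = GeneSet("bottom", (col.idxmin(),))
        s = ssgsea_score(expr, [top, bottom])
        assert s.loc["top"].iloc[0] > s.loc["bottom"].iloc[0]

    @pytest.mark.parametrize("transform", [np.exp, lambda x: x ** 3, np.log1p])
    def test_rank_invariance_under_monotone_transforms(self, rng, transform):
        expr = expr_frame(rng)
        gs = GeneSet("S", tuple(expr.index[:7]))
        a = ssgsea_score(expr, [gs])
        b = ssgsea_score(expr.apply(transform), [gs])
        pd.testing.assert_frame_equal(a, b)

    def test_unmatched_set_rejected(self, rng):
        expr = expr_frame(rng)
        with pytest.raises(ValueError, match="ABSENT"):
            ssgsea_score(expr, [GeneSet("ABSENT", ("nope1", "nope2"))])

    def test_normalize_bounds_scores(self, rng):
        expr = expr_frame(rng)
        sets = [GeneSet("S", tuple(expr.index[:5])), GeneSet("R", tuple(expr.index[5:9]))]
        s = ssgsea_score(expr, sets, normalize=True)
        assert float(s.min().min()) >= 0.0 and float(s.max().max()) <= 1.0


class TestCompareGroups:
    def cond(self, n=5):
        cols = [f"t{i}" for i in range(n)] + [f"n{i}" for i in range(n)]
        return pd.Series(["tumor"] * n + ["normal"] * n, index=cols), cols

    def test_identical_groups_near_one(self):
        cond, cols = self.cond()
        scores = pd.DataFrame([[1.0] * 10], index=["S"], columns=cols)
        out = compare_groups(scores, cond)
        assert out.loc["S", "p_value"] == 1.0

    def test_planted_shift_detected(self, rng):
        cond, cols = self.cond(10)
        base = rng.normal(0, 1, size=20)
        base[:10] += 5.0
        scores = pd.DataFrame([base], index=["S"], columns=cols)
        out = compare_groups(scores, cond)
        assert out.loc["S", "direction"] == "up"
        assert out.loc["S", "fdr"] < 0.05

    def test_single_sample_group_rejected(self):
        cond = pd.Series(["tumor", "normal", "normal"], index=["a", "b", "c"])
        scores = pd.DataFrame([[1, 2, 3]], index=["S"], columns=["a", "b", "c"])
        with pytest.raises(ValueError):
            compare_groups(scores, cond)


class TestCorrelate:
    def test_self_correlation_is_one(self, rng):
        cols = [f"s{i}" for i in range(20)]
        scores = pd.DataFrame(rng.normal(size=(2, 20)), index=["A", "B"], columns=cols)
        out = correlate_scores(scores, scores)
        self_rows = out[out["score_set"] == out["other"]]
        assert np.allclose(self_rows["rho"], 1.0)

    def test_independent_vectors_have_small_rho(self, rng):
        cols = [f"s{i}" for i in range(100)]
        n_small = 0
        for _ in range(40):
            a = pd.DataFrame(rng.normal(size=(1, 100)), index=["A"], columns=cols)
            b = pd.DataFrame(rng.normal(size=(1, 100)), index=["B"], columns=cols)
            rho = correlate_scores(a, b)["rho"].iloc[0]
            n_small += abs(rho) < 0.3
        assert n_small >= 38  # >= 95% of replicates

    def test_planted_dependence_detected(self, rng):
        cols = [f"s{i}" for i in range(50)]
        x = rng.normal(size=50)
        a = pd.DataFrame([x], index=["A"], columns=cols)
        b = pd.DataFrame([x + rng.normal(0, 0.3, 50)], index=["B"], columns=cols)
        out = correlate_scores(a, b)
        assert out["rho"].iloc[0] > 0.5
        assert out["fdr"].iloc[0] < 0.05

    def test_spearman_matches_rank_pearson_oracle(self, rng):
        cols = [f"s{i}" for i in range(30)]
        a = pd.DataFrame(rng.normal(size=(1, 30)), index=["A"], columns=cols)
        b = pd.DataFrame(rng.normal(size=(1, 30)), index=["B"], columns=cols)
        rho = correlate_scores(a, b)["rho"].iloc[0]
        ra = stats.rankdata(a.iloc[0])
        rb = stats.rankdata(b.iloc[0])
        oracle = np.corrcoef(ra, rb)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)


class TestSetsIO:
    def test_gmt_round_trip(self, tmp_path):
        p = tmp_path / "sets.gmt"
        p.write_text("S1\tdesc\tg1\tg2\tg3\nS2\tdesc\tg4\tg5\n")
        sets = read_gmt(p)
        assert [s.name for s in sets] == ["S1", "S2"]
        assert sets[0].genes == ("g1", "g2", "g3")

    def test_build_epi_sets_from_cohort_truth(self, cohort):
        import pandas as pd
        from epilnc.epi_classify import classify
        biotypes = pd.Series({g.gene_id: g.biotype for g in cohort.annotation.genes})
        de = pd.DataFrame({"significant": pd.Series(
            {gid: gid in cohort.truth.true_de_genes for gid in biotypes.index})})
        ev = pd.DataFrame([(gid, el, src, "x")
                           for gid, evs in cohort.truth.true_epi_genes.items()
                           for src, el in evs],
                          columns=["gene_id", "element", "source", "direction"])
        ann = classify(de, ev, biotypes)
        sets = build_epi_sets(ann, biotype="lncRNA")
        assert sets, "expected at least one epi-lncRNA set"
        epi_lnc = set(ann.index[(ann["biotype"] == "lncRNA") & ann["is_epi"]])
        for s in sets:
            assert set(s.genes) <= epi_lnc
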