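import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tamnet import gsea, preprocess
from tamnet.io import GeneSetCollection
from tamnet.simulate import SimulationConfig, default_config, generate_dataset, generate_gene_sets

from conftest import make_design, make_log_matrix


def ranked_from(metric, genes=None):
    metric = np.asarray(metric, dtype=float)
    genes = genes or [f"g{i}" for i in range(len(metric))]
    order = sorted(range(len(genes)), key=lambda i: (-metric[i], genes[i]))
    return gsea.RankedList([genes[i] for i in order], metric[order], ("a", "b"))


class TestRankGenes:
    def test_equal_groups_zero_metric(self, small_design):
        le = make_log_matrix(np.tile(np.arange(16.0) % 4, (3, 1)), design=small_design)
        rl = gsea.rank_genes(le, small_design, "TPC1_4h", "RPMI_4h")
        assert np.allclose(rl.metric, 0.0)

    def test_variance_floor_worked_example(self, small_design):
        # group a constant 2 (sd floored to 0.4), group b constant 1 (floor 0.2)
        vals = np.ones((1, 16))
        for s in small_design.groups["TPC1_4h"]:
            vals[0, small_design.samples.index(s)] = 2.0
        le = make_log_matrix(vals, design=small_design)
        rl = gsea.rank_genes(le, small_design, "TPC1_4h", "RPMI_4h")
        assert rl.metric[0] == pytest.approx(1.0 / 0.6)

    def test_antisymmetry(self, default_log_expr):
        le, design = default_log_expr
        fwd = gsea.rank_genes(le, design, "TPC1_4h", "RPMI_4h")
        rev = gsea.rank_genes(le, design, "RPMI_4h", "TPC1_4h")
        fwd_m = pd.Series(fwd.metric, index=fwd.genes)
        rev_m = pd.Series(rev.metric, index=rev.genes)
        np.testing.assert_allclose(fwd_m, -rev_m[fwd_m.index], atol=1e-12)
        assert fwd.genes == rev.genes[::-1] or np.allclose(fwd.metric, 0)


class TestEnrichmentScore:
    def test_singleton_extremes(self):
        rl = ranked_from(np.linspace(3, -3, 11))
        es_top, _ = gsea.enrichment_score(rl, [rl.genes[0]])
        es_bot, _ = gsea.enrichment_score(rl, [rl.genes[-1]])
        assert es_top == pytest.approx(1.0)
        assert es_bot == pytest.approx(-1.0)

    def test_unweighted_hand_example(self):
        rl = ranked_from([4.0, 3.0, 2.0, 1.0])
        es, running = gsea.enrichment_score(rl, [rl.genes[0], rl.genes[2]], weight=0)
        np.testing.assert_allclose(running, [0.5, 0.0, 0.5, 0.0])
        assert es == pytest.approx(0.5)

    def test_unweighted_equals_ks_statistic(self):
        """|ES| at weight 0 equals the two-sample KS statistic between hit and
        miss rank positions (independent scipy oracle), exactly, N <= 20."""
        rng = np.random.default_rng(0)
        for trial in range(200):
            N = int(rng.integers(3, 21))
            k = int(rng.integers(1, N))
            rl = ranked_from(rng.normal(size=N))
            hits = list(rng.choice(rl.genes, size=k, replace=False))
            es, _ = gsea.enrichment_score(rl, hits, weight=0)
            pos = rl.positions(hits)
            miss = np.setdiff1d(np.arange(N), pos)
            ks = stats.ks_2samp(pos, miss).statistic
            assert abs(es) == pytest.approx(ks, abs=1e-12)

    def test_es_bounded_and_complement_sign(self):
        rng = np.random.default_rng(1)
        for trial in range(50):
            N = int(rng.integers(4, 30))
            rl = ranked_from(rng.normal(size=N))
            k = int(rng.integers(1, N))
            hits = list(rng.choice(rl.genes, size=k, replace=False))
            comp = [g for g in rl.genes if g not in hits]
            es, running = gsea.enrichment_score(rl, hits, weight=0)
            es_c, _ = gsea.enrichment_score(rl, comp, weight=0)
            assert -1.0 - 1e-9 <= es <= 1.0 + 1e-9
            tie = abs(running.max() + running.min()) < 1e-12
            if abs(es) > 1e-9 and not tie:
                # complement walk is the mirror image, so the signs flip
                # (on an exact max/min tie both resolve to the positive peak)
                assert np.sign(es) == -np.sign(es_c)

    def test_degenerate_sets_rejected(self):
        rl = ranked_from([3.0, 2.0, 1.0])
        with pytest.raises(ValueError, match="intersect"):
            gsea.enrichment_score(rl, ["nope"])
        with pytest.raises(ValueError, match="whole"):
            gsea.enrichment_score(rl, rl.genes)

    def test_fast_position_formula_matches_running_sum(self):
        rng = np.random.default_rng(2)
        for trial in range(100):
            N = int(rng.integers(5, 50))
            rl = ranked_from(rng.normal(size=N))
            k = int(rng.integers(1, N))
            hits = list(rng.choice(rl.genes, size=k, replace=False))
            for weight in (0.0, 1.0, 2.0):
                es, running = gsea.enrichment_score(rl, hits, weight=weight)
                w = np.abs(rl.metric) ** weight
                fast = gsea._es_from_positions(rl.positions(hits)[None, :], w, N)[0]
                assert abs(fast) == pytest.approx(abs(es), abs=1e-12)
                if abs(running.max() + running.min()) > 1e-9:
                    # sign can flip between routes only on an exact peak tie
                    assert fast == pytest.approx(es, abs=1e-12)


class TestPermutationTest:
    def test_determinism(self, default_log_expr):
        le, design = default_log_expr
        rl = gsea.rank_genes(le, design, "TPC1_4h", "RPMI_4h")
        coll = GeneSetCollection(
            {f"S{i}": ("d", [f"G{j:05d}" for j in range(10 * i + 1, 10 * i + 21)])
             for i in range(5)}
        )
        r1 = gsea.permutation_test(rl, coll, n_perm=200, seed=4)
        r2 = gsea.permutation_test(rl, coll, n_perm=200, seed=4)
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_small_sets_skipped(self, default_log_expr):
        le, design = default_log_expr
        rl = gsea.rank_genes(le, design, "TPC1_4h", "RPMI_4h")
        coll = GeneSetCollection({"tiny": ("d", ["G00001", "G00002"])})
        res = gsea.permutation_test(rl, coll, n_perm=100, seed=0)
        assert "tiny" in res.skipped and res.table.empty

    def test_null_nes_magnitude_near_one(self, default_log_expr):
        """NES normalizes by the mean same-sign |null ES|, so null-set NES
        magnitudes average about 1."""
        le, design = default_log_expr
        rl = gsea.rank_genes(le, design, "TPC1_4h", "RPMI_4h")
        rng = np.random.default_rng(8)
        coll = GeneSetCollection(
            {f"R{i}": ("d", list(rng.choice(le.genes, 25, replace=False)))
             for i in range(40)}
        )
        res = gsea.permutation_test(rl, coll, n_perm=1000, seed=8)
        assert abs(res.table["nes"].abs().mean() - 1.0) < 0.25

    def test_planted_set_detected(self, default_log_expr):
        matrix, design, truth = generate_dataset(default_config(seed=11))
        le = preprocess.normalize_log_cpm(preprocess.filter_present(matrix, design))
        rl = gsea.rank_genes(le, design, "TPC1_4h", "RPMI_4h")
        sets = generate_gene_sets(truth, n_random_sets=5, seed=11)
        res = gsea.permutation_test(rl, sets, n_perm=1000, seed=11)
        early = res.table.loc["TRUE_M_early"]
        assert early["nes"] > 1.0 and early["p"] < 0.05
        down = res.table.loc["TRUE_M_down"]
        assert down["nes"] < -1.0 and down["p"] < 0.05

    def test_leading_edge_members_of_set(self, default_log_expr):
        le, design = default_log_expr
        rl = gsea.rank_genes(le, design, "TPC1_4h", "RPMI_4h")
        coll = GeneSetCollection({"S": ("d", [f"G{j:05d}" for j in range(1, 40)])})
        res = gsea.permutation_test(rl, coll, n_perm=100, seed=1)
        lead = res.table.loc["S", "leading_edge"].split(",")
        assert set(lead) <= set(coll.genes_of("S"))
        assert len(lead) >= 1


class TestVolcano:
    @pytest.mark.parametrize(
        "nes,p,expected",
        [
            (1.5, 0.03, "dark_red"),
            (1.5, 0.07, "light_red"),
            (-1.2, 0.03, "dark_blue"),
            (-1.2, 0.07, "light_blue"),
            (0.5, 0.001, "unclassed"),
            (1.0, 0.05, "dark_red"),      # inclusive boundaries
            (1.0, 0.1, "light_red"),
            (1.0, 0.1000001, "unclassed"),
            (-1.0, 0.05, "dark_blue"),
            (0.999, 0.01, "unclassed"),
        ],
    )
    def test_classing_thresholds(self, nes, p, expected):
        table = pd.DataFrame({"nes": [nes], "p": [p]}, index=["S"])
        out = gsea.volcano_table(table)
        assert out["class"].iloc[0] == expected
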