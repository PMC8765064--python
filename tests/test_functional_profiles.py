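"""KO rarefaction, single-copy normalization, fold-change classification,
and the pathway-of-interest rule."""

import numpy as np
import pandas as pd
import pytest

from cryograd import (
    AsvTable,
    PathwayMap,
    classify_enriched,
    ko_richness,
    log2_fold_change,
    mann_whitney_u,
    pathways_of_interest,
    rarefy_ko_table,
    read_pathway_map,
    simulate_ko_table,
    single_copy_normalize,
)


def ko(values, samples=None, kos=None) -> AsvTable:
    values = np.asarray(values)
    samples = samples or [f"S{i + 1}" for i in range(values.shape[0])]
    kos = kos or [f"K{j + 1:05d}" for j in range(values.shape[1])]
    return AsvTable(pd.DataFrame(values, index=samples, columns=kos))


def group_labels(samples, n_high):
    return pd.Series(["high"] * n_high + ["low"] * (len(samples) - n_high),
                     index=samples, name="group")


class TestRarefyKo:
    def test_row_sums_equal_depth(self):
        rng = np.random.default_rng(0)
        table = ko(rng.integers(0, 200, (4, 30)))
        out = rarefy_ko_table(table, depth=500, seed=1)
        totals = table.data.sum(axis=1)
        assert (totals >= 500).all()
        np.testing.assert_array_equal(out.data.sum(axis=1), 500)

    def test_exact_depth_row_unchanged(self):
        table = ko([[100, 200, 700]])
        out = rarefy_ko_table(table, depth=1000, seed=0)
        pd.testing.assert_frame_equal(out.data, table.data)

    def test_sample_below_depth_named(self):
        table = ko([[10, 10], [500, 500]])
        with pytest.raises(ValueError, match="S1"):
            rarefy_ko_table(table, depth=100, seed=0)

    def test_hypergeometric_expectation(self):
        counts = np.array([[300, 100, 600]])
        depth = 200
        draws = np.array([
            rarefy_ko_table(ko(counts), depth, seed=s).data.to_numpy()[0]
            for s in range(200)
        ])
        expected = depth * counts[0] / counts.sum()
        n_tot = counts.sum()
        var = (depth * (counts[0] / n_tot) * (1 - counts[0] / n_tot)
               * (n_tot - depth) / (n_tot - 1))
        se = np.sqrt(var / 200)
        assert (np.abs(draws.mean(axis=0) - expected) < 3 * se).all()


class TestSingleCopyNormalize:
    def test_uniform_single_copy_halves_everything(self):
        table = ko([[4.0, 6.0, 2.0, 2.0, 2.0, 2.0, 2.0]],
                   kos=["Ka", "Kb", "U1", "U2", "U3", "U4", "U5"])
        out = single_copy_normalize(table, ["U1", "U2", "U3", "U4", "U5"])
        np.testing.assert_allclose(out.data.loc["S1", ["Ka", "Kb"]], [2.0, 3.0])

    def test_median_single_copy_becomes_one(self):
        rng = np.random.default_rng(1)
        uscg = [f"U{i}" for i in range(7)]
        table = ko(rng.uniform(0.5, 5.0, (4, 12)),
                   kos=[f"Ka{i}" for i in range(5)] + uscg)
        out = single_copy_normalize(table, uscg)
        np.testing.assert_allclose(out.data[uscg].median(axis=1), 1.0)

    def test_scale_invariance_per_sample(self):
        rng = np.random.default_rng(2)
        uscg = [f"U{i}" for i in range(5)]
        data = rng.uniform(0.5, 5.0, (3, 8))
        out1 = single_copy_normalize(ko(data, kos=list("abc") + uscg), uscg)
        data2 = data.copy()
        data2[1] *= 7.0
        out2 = single_copy_normalize(ko(data2, kos=list("abc") + uscg), uscg)
        pd.testing.assert_frame_equal(out1.data, out2.data)

    def test_too_few_uscg_and_zero_median_error(self):
        table = ko([[1.0, 2.0]], kos=["U1", "U2"])
        with pytest.raises(ValueError, match=">= 5"):
            single_copy_normalize(table, ["U1", "U2"])
        uscg = [f"U{i}" for i in range(5)]
        zero = ko([[0.0] * 5 + [3.0]], kos=uscg + ["Ka"])
        with pytest.raises(ValueError, match="median"):
            single_copy_normalize(zero, uscg)


class TestKoRichness:
    def test_zero_sample_and_brute_force(self):
        rng = np.random.default_rng(3)
        data = rng.integers(0, 3, (4, 20))
        data[0] = 0
        table = ko(data)
        rich = ko_richness(table)
        assert rich.iloc[0] == 0
        for i in range(4):
            assert rich.iloc[i] == int((data[i] > 0).sum())

    def test_invariant_under_normalization(self):
        rng = np.random.default_rng(4)
        uscg = [f"U{i}" for i in range(5)]
        table = ko(rng.integers(0, 4, (3, 10)) + 0.0,
                   kos=[f"Ka{i}" for i in range(5)] + uscg)
        table.data[uscg] += 1.0  # keep medians positive
        assert (ko_richness(single_copy_normalize(table, uscg))
                == ko_richness(table)).all()


class TestFoldChange:
    def test_hand_value_without_pseudocount(self):
        table = ko([[4.0], [4.0], [1.0], [1.0]])
        groups = group_labels(table.sample_ids, 2)
        fc = log2_fold_change(table, groups, eps_mode="none")
        assert fc.iloc[0] == pytest.approx(-2.0)  # log2(1/4)

    def test_equal_means_give_zero(self):
        table = ko([[3.0], [3.0]])
        groups = group_labels(table.sample_ids, 1)
        assert log2_fold_change(table, groups,
                                eps_mode="none").iloc[0] == 0.0

    def test_swapping_groups_negates(self):
        rng = np.random.default_rng(5)
        table = ko(rng.uniform(0.1, 5.0, (6, 8)))
        g = group_labels(table.sample_ids, 3)
        swapped = g.map({"high": "low", "low": "high"})
        fc = log2_fold_change(table, g)
        np.testing.assert_allclose(log2_fold_change(table, swapped), -fc)

    def test_zero_mean_requires_pseudocount(self):
        table = ko([[0.0], [2.0]])
        groups = group_labels(table.sample_ids, 1)
        with pytest.raises(ValueError, match="zero group mean"):
            log2_fold_change(table, groups, eps_mode="none")
        fc = log2_fold_change(table, groups, eps_mode="half_min")
        assert np.isfinite(fc.iloc[0])


class TestClassification:
    @pytest.mark.parametrize(
        "fc, expected",
        [(-1.1, "high_enriched"), (-1.0, "neither"), (0.0, "neither"),
         (1.0, "neither"), (1.2, "low_enriched")],
    )
    def test_strict_boundaries(self, fc, expected):
        cls = classify_enriched(pd.Series({"K00001": fc}))
        assert cls.loc["K00001", "class"] == expected


class TestPathways:
    def pmap(self):
        return PathwayMap(
            names={"ko00680": "Methane metabolism", "ko00190": "Oxphos",
                   "ko00910": "Nitrogen metabolism"},
            members={
                "ko00680": frozenset(f"K{i:05d}" for i in range(1, 7)),
                "ko00190": frozenset(f"K{i:05d}" for i in range(3, 8)),
                "ko00910": frozenset(f"K{i:05d}" for i in range(100, 104)),
            },
        )

    def classification(self, high_ids):
        all_ids = [f"K{i:05d}" for i in range(1, 110)]
        fc = pd.Series(0.0, index=all_ids)
        fc[list(high_ids)] = -2.0
        return classify_enriched(fc)

    def test_at_least_five_genes_flags(self):
        cls = self.classification([f"K{i:05d}" for i in range(1, 6)])
        out = pathways_of_interest(cls, self.pmap(), min_genes=5)
        assert list(out["pathway_id"]) == ["ko00680"]
        assert out.loc[0, "n_high_enriched"] == 5

    def test_four_genes_do_not_flag(self):
        cls = self.classification([f"K{i:05d}" for i in range(1, 5)])
        out = pathways_of_interest(cls, self.pmap(), min_genes=5)
        assert out.empty

    def test_shared_ko_counts_in_both_pathways(self):
        cls = self.classification([f"K{i:05d}" for i in range(3, 8)])
        out = pathways_of_interest(cls, self.pmap(), min_genes=4)
        counts = dict(zip(out["pathway_id"], out["n_high_enriched"]))
        assert counts["ko00190"] == 5  # K3..K7 all members
        assert counts["ko00680"] == 4  # K3..K6 shared with methane pathway

    def test_blocklist_skips_pathway(self):
        cls = self.classification([f"K{i:05d}" for i in range(1, 8)])
        out = pathways_of_interest(cls, self.pmap(), min_genes=4,
                                   blocklist=("ko00190",))
        assert "ko00190" not in set(out["pathway_id"])

    def test_empty_map_errors(self):
        with pytest.raises(ValueError, match="empty"):
            PathwayMap(names={}, members={})

    def test_reader_round_trip(self, tmp_path):
        path = tmp_path / "pmap.tsv"
        path.write_text(
            "pathway_id\tpathway_name\tko_id\n"
            "ko00680\tMethane metabolism\tK00001\n"
            "ko00680\tMethane metabolism\tK00002\n"
            "ko00190\tOxphos\tK00002\n"
        )
        pmap = read_pathway_map(path)
        assert pmap.members["ko00680"] == frozenset({"K00001", "K00002"})
        assert pmap.members["ko00190"] == frozenset({"K00002"})
        assert pmap.names["ko00680"] == "Methane metabolism"


class TestChainProperties:
    def test_full_chain_invariant_to_column_order(self):
        groups = group_labels([f"S{i + 1}" for i in range(10)], 5)
        table, truth = simulate_ko_table(groups, seed=7, n_kos=120,
                                         n_enriched=10, n_low_only=10)
        depth = int(table.data.sum(axis=1).min())

        def chain(t):
            r = rarefy_ko_table(t, depth, seed=3)
            norm = single_copy_normalize(r, truth.uscg_ids)
            return classify_enriched(log2_fold_change(norm, groups))

        out1 = chain(table)
        shuffled = AsvTable(table.data[list(reversed(table.data.columns))])
        out2 = chain(shuffled)
        pd.testing.assert_frame_equal(out1.sort_index(), out2.sort_index())

    def test_low_elevation_samples_are_gene_richer(self):
        """Planted low-only genes make low-elevation samples KO-richer, and
        the Mann-Whitney contrast flags it."""
        samples = [f"S{i + 1}" for i in range(14)]
        groups = group_labels(samples, 7)
        table, _ = simulate_ko_table(groups, seed=11)
        rich = ko_richness(table)
        high = rich[groups == "high"]
        low = rich[groups == "low"]
        assert high.median() < low.median()
        _, p = mann_whitney_u(high, low)
        assert p < 0.05
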