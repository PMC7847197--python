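import numpy as np
import pandas as pd
import pytest

from streamtox.community_metrics import (
    dominant_families,
    family_abundances,
    stone_metrics,
    summarize_by_site,
)


def _one_stone(taxonomy, **counts):
    row = {t: counts.get(t, 0) for t in taxonomy["taxon"]}
    return pd.DataFrame([row], index=pd.Index(["s1"], name="stone"))


class TestStoneMetrics:
    def test_direct_tally(self, taxonomy):
        counts = _one_stone(taxonomy, Baetis=10, Hydropsyche=5)
        m = stone_metrics(counts, taxonomy).iloc[0]
        assert m["total_abundance"] == 15
        assert m["total_richness"] == 2
        assert m["ephemeroptera_abundance"] == 10
        assert m["ephemeroptera_richness"] == 1
        assert m["trichoptera_richness"] == 1
        assert m["diptera_richness"] == 0
        assert m["diptera_abundance"] == 0

    def test_empty_stone_all_zero(self, taxonomy):
        m = stone_metrics(_one_stone(taxonomy), taxonomy).iloc[0]
        assert (m == 0).all()

    def test_brute_force_oracle_on_45_stones(self, counts_45, taxonomy):
        """Vectorized metrics equal an independent cell-by-cell tally."""
        metrics = stone_metrics(counts_45, taxonomy)
        orders = dict(zip(taxonomy["taxon"], taxonomy["order"]))
        for idx, row in counts_45.iterrows():
            expect = {
                "total_abundance": sum(row),
                "total_richness": sum(v > 0 for v in row),
            }
            for order in ("Ephemeroptera", "Trichoptera", "Diptera"):
                sub = [v for t, v in row.items() if orders[t] == order]
                expect[f"{order.lower()}_abundance"] = sum(sub)
                expect[f"{order.lower()}_richness"] = sum(v > 0 for v in sub)
            for name, val in expect.items():
                assert metrics.loc[idx, name] == val

    def test_non_insect_taxa_counted_in_totals_only(self, taxonomy):
        counts = _one_stone(taxonomy, **{"Oligochaeta gen.": 7})
        m = stone_metrics(counts, taxonomy).iloc[0]
        assert m["total_abundance"] == 7 and m["total_richness"] == 1
        assert m["ephemeroptera_abundance"] == 0
        assert m["diptera_abundance"] == 0

    def test_unknown_taxon_listed_in_error(self, taxonomy):
        counts = _one_stone(taxonomy)
        counts["Mystery"] = 3
        with pytest.raises(ValueError, match="Mystery"):
            stone_metrics(counts, taxonomy)

    def test_order_sums_bounded_by_totals(self, counts_45, taxonomy):
        m = stone_metrics(counts_45, taxonomy)
        insect_ab = m[[c for c in m if c.endswith("_abundance") and c != "total_abundance"]]
        insect_ri = m[[c for c in m if c.endswith("_richness") and c != "total_richness"]]
        assert (insect_ab.sum(axis=1) <= m["total_abundance"]).all()
        assert (insect_ri.sum(axis=1) <= m["total_richness"]).all()


class TestDominantFamilies:
    def _table(self, taxonomy, n_stones, n_occupied, count=100):
        """Baetis everywhere; Hydropsyche on the first n_occupied stones at
        50% share."""
        rows = []
        for i in range(n_stones):
            rows.append(
                {t: 0 for t in taxonomy["taxon"]}
                | {"Baetis": count, "Hydropsyche": count if i < n_occupied else 0}
            )
        return pd.DataFrame(rows, index=pd.RangeIndex(n_stones, name="stone"))

    def test_boundary_14_of_45_excluded(self, taxonomy):
        """Occupancy must exceed the rounded-up 30% of 45 stones (14), so a
        family on exactly 14 stones does not qualify."""
        counts = self._table(taxonomy, 45, 14)
        assert "Hydropsychidae" not in dominant_families(counts, taxonomy)

    def test_15_of_45_included(self, taxonomy):
        counts = self._table(taxonomy, 45, 15)
        assert "Hydropsychidae" in dominant_families(counts, taxonomy)

    def test_sole_family_on_all_stones_qualifies(self, taxonomy):
        counts = self._table(taxonomy, 45, 0)
        assert dominant_families(counts, taxonomy) == {"Baetidae"}

    def test_monotone_in_thresholds(self, counts_45, taxonomy):
        base = dominant_families(counts_45, taxonomy)
        assert dominant_families(counts_45, taxonomy, share_threshold=0.20) <= base
        assert dominant_families(counts_45, taxonomy, occupancy_threshold=0.60) <= base

    def test_all_stones_scope_is_stricter(self, counts_45, taxonomy):
        any_stone = dominant_families(counts_45, taxonomy, share_scope="any_stone")
        all_stones = dominant_families(counts_45, taxonomy, share_scope="all_stones")
        assert all_stones <= any_stone

    def test_invalid_threshold_rejected(self, counts_45, taxonomy):
        with pytest.raises(ValueError):
            dominant_families(counts_45, taxonomy, share_threshold=0.0)

    def test_family_abundance_sums(self, counts_45, taxonomy):
        fam = family_abundances(counts_45, taxonomy, ["Ephemerellidae", "Baetidae"])
        assert (fam["Baetidae"] == counts_45["Baetis"]).all()
        assert (fam["Ephemerellidae"] == 0).all()


class TestSummarizeBySite:
    def test_log_transform_hand_example(self):
        values = pd.DataFrame(
            {"abundance": [9, 99]},
            index=pd.MultiIndex.from_tuples(
                [("A", 1), ("A", 2)], names=["site", "stone"]
            ),
        )
        tidy = summarize_by_site(values, transform="log10p1")
        assert tidy.loc[0, "mean"] == pytest.approx(1.5)
        assert tidy.loc[0, "se"] == pytest.approx(0.5)
        assert tidy.loc[0, "n"] == 2

    def test_identical_stones_zero_se(self):
        values = pd.DataFrame(
            {"m": [4, 4, 4]},
            index=pd.MultiIndex.from_tuples(
                [("A", i) for i in range(3)], names=["site", "stone"]
            ),
        )
        assert summarize_by_site(values).loc[0, "se"] == 0.0

    def test_single_stone_flagged_undefined_se(self):
        values = pd.DataFrame(
            {"m": [4]},
            index=pd.MultiIndex.from_tuples([("A", 1)], names=["site", "stone"]),
        )
        row = summarize_by_site(values).loc[0]
        assert row["mean"] == 4 and np.isnan(row["se"])

    def test_no_transform_leaves_richness_integers(self, counts_45, taxonomy):
        from streamtox.community_metrics import stone_metrics

        rich = stone_metrics(counts_45, taxonomy)[["total_richness"]]
        tidy = summarize_by_site(rich, transform="none")
        per_site = rich.groupby(level="site").mean()["total_richness"]
        for _, row in tidy.iterrows():
            assert row["mean"] == pytest.approx(per_site[row["site"]])

    def test_matches_elementwise_log_oracle(self, counts_45, taxonomy):
        """Site means under log10p1 equal the mean of log10(x+1) computed
        element-by-element, to full precision."""
        from streamtox.community_metrics import stone_metrics

        ab = stone_metrics(counts_45, taxonomy)[["total_abundance"]]
        tidy = summarize_by_site(ab, transform="log10p1").set_index("site")
        for site, group in ab.groupby(level="site"):
            oracle = np.mean([np.log10(v + 1) for v in group["total_abundance"]])
            assert tidy.loc[site, "mean"] == pytest.approx(oracle, abs=1e-12)
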