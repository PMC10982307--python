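import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

import eurosoy as es
from eurosoy.regionalize import (CLUSTER_LABELS, ClusteringConfig,
                                 clustering_feature_columns)


class TestSummarizeSite:
    def test_all_failed_site(self, subarctic_run):
        s = es.summarize_site(subarctic_run)
        for mg in es.MATURITY_GROUPS:
            assert s[f"yield_{mg}"] == 0.0
            assert s[f"success_{mg}"] == 0.0
        assert np.isnan(s["planting_doy"])  # never planted: absent-coded

    def test_success_is_proportion_of_years(self, continental_run):
        s = es.summarize_site(continental_run)
        rf = continental_run[continental_run["config"] == "rainfed_mid"]
        for mg in es.MATURITY_GROUPS:
            sub = rf[rf["maturity_group"] == mg]
            assert s[f"success_{mg}"] == pytest.approx(1 - sub["failed"].mean())
            assert 0.0 <= s[f"success_{mg}"] <= 1.0

    def test_rainfed_mean_pools_years_and_members(self, continental_run):
        s = es.summarize_site(continental_run)
        rf = continental_run[continental_run["config"].str.startswith("rainfed")]
        mg = "000"
        manual = rf.loc[rf["maturity_group"] == mg, "yield_t_ha"].mean()
        assert s[f"yield_{mg}"] == pytest.approx(manual)

    def test_missing_maturity_group_rejected(self, continental_run):
        partial = continental_run[continental_run["maturity_group"] != "II"]
        with pytest.raises(ValueError, match="II"):
            es.summarize_site(partial)

    def test_fifteen_clustering_statistics(self):
        assert len(clustering_feature_columns()) == 15


class TestSpatialWeights:
    def _sites(self, coords):
        return pd.DataFrame({"site_id": range(len(coords)),
                             "lat": [c[0] for c in coords],
                             "lon": [c[1] for c in coords]})

    def test_band_membership(self):
        # 0.45 deg latitude ~ 50 km: inside; 0.72 deg ~ 80 km: outside
        w = es.build_spatial_weights(self._sites([(45.0, 10.0), (45.45, 10.0)]))
        assert w[0, 1] == 1
        w = es.build_spatial_weights(self._sites([(45.0, 10.0), (45.72, 10.0)]))
        assert w[0, 1] == 0

    def test_half_degree_latitude_neighbours_connected(self):
        w = es.build_spatial_weights(
            self._sites([(45.0, 10.0), (45.5, 10.0), (46.0, 10.0)]))
        assert w[0, 1] == 1 and w[1, 2] == 1
        assert w[0, 2] == 0  # 1 degree ~ 111 km, outside the 75-km band

    def test_symmetric_no_self_edges(self):
        grid = es.gen_site_grid(4, 4, 0.5)
        w = es.build_spatial_weights(grid)
        assert (w != w.T).nnz == 0
        assert w.diagonal().sum() == 0

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            es.build_spatial_weights(self._sites([(45.0, 10.0)]))


def _planted_summaries(grid, block_of, block_means, noise_sd, rng):
    cols = clustering_feature_columns()
    rows = []
    for sid in grid["site_id"]:
        b = block_of(sid)
        rows.append(block_means[b] + rng.normal(0, noise_sd, len(cols)))
    return pd.DataFrame(rows, columns=cols,
                        index=pd.Index(grid["site_id"], name="site_id"))


class TestClusterSites:
    def test_identical_blocks_recovered_exactly(self):
        """Two spatially separated blocks of identical summaries: with a
        disconnected 75-km graph each component becomes one cluster."""
        g1 = es.gen_site_grid(2, 3, 0.5)
        g2 = es.gen_site_grid(2, 3, 0.5)
        g2["lat"] += 10.0
        g2["site_id"] += 100
        grid = pd.concat([g1, g2], ignore_index=True)
        rng = np.random.default_rng(0)
        summ = _planted_summaries(
            grid, lambda s: int(s >= 100),
            {0: np.zeros(15), 1: np.ones(15)}, 0.0, rng)
        w = es.build_spatial_weights(grid)
        labels = es.cluster_sites(summ, w, ClusteringConfig(n_clusters=2))
        truth = (grid["site_id"] >= 100).astype(int)
        assert adjusted_rand_score(truth, labels) == 1.0

    def test_deterministic(self):
        grid = es.gen_site_grid(4, 5, 0.5)
        rng = np.random.default_rng(3)
        summ = _planted_summaries(grid, lambda s: s % 2,
                                  {0: np.zeros(15), 1: np.ones(15)}, 0.3, rng)
        w = es.build_spatial_weights(grid)
        l1 = es.cluster_sites(summ, w, ClusteringConfig(n_clusters=4))
        l2 = es.cluster_sites(summ, w, ClusteringConfig(n_clusters=4))
        assert (l1 == l2).all()

    def test_constant_variable_dropped_with_warning(self):
        grid = es.gen_site_grid(3, 3, 0.5)
        rng = np.random.default_rng(5)
        summ = _planted_summaries(grid, lambda s: s % 2,
                                  {0: np.zeros(15), 1: np.ones(15)}, 0.2, rng)
        summ["planting_doy"] = 120.0  # constant across sites
        w = es.build_spatial_weights(grid)
        with pytest.warns(UserWarning, match="constant"):
            es.cluster_sites(summ, w, ClusteringConfig(n_clusters=2))

    def test_clusters_are_spatially_connected(self):
        from scipy.sparse.csgraph import connected_components
        grid = es.gen_site_grid(6, 6, 0.5)
        rng = np.random.default_rng(7)
        summ = _planted_summaries(grid, lambda s: s % 3,
                                  {i: rng.normal(size=15) for i in range(3)},
                                  0.3, rng)
        w = es.build_spatial_weights(grid)
        labels = es.cluster_sites(summ, w, ClusteringConfig(n_clusters=5))
        for lab in np.unique(labels):
            idx = np.flatnonzero(labels == lab)
            ncomp, _ = connected_components(w[idx][:, idx], directed=False)
            assert ncomp == 1

    def test_scale_invariance_through_minmax(self):
        """Min-max normalization makes the partition invariant under any
        positive affine rescaling of a raw input variable."""
        grid = es.gen_site_grid(4, 5, 0.5)
        rng = np.random.default_rng(11)
        summ = _planted_summaries(grid, lambda s: s % 2,
                                  {0: np.zeros(15), 1: np.ones(15)}, 0.25, rng)
        w = es.build_spatial_weights(grid)
        l1 = es.cluster_sites(summ, w, ClusteringConfig(n_clusters=3))
        scaled = summ.copy()
        scaled["yield_0000"] = scaled["yield_0000"] * 37.0 + 5.0
        l2 = es.cluster_sites(scaled, w, ClusteringConfig(n_clusters=3))
        assert adjusted_rand_score(l1, l2) == 1.0


class TestClusterSummaryTable:
    def _summaries(self, values):
        cols = ([f"yield_{mg}" for mg in es.MATURITY_GROUPS]
                + [f"success_{mg}" for mg in es.MATURITY_GROUPS]
                + [f"potential_{mg}" for mg in es.MATURITY_GROUPS]
                + ["planting_doy"])
        df = pd.DataFrame(values, columns=cols)
        df.index.name = "site_id"
        return df

    def test_two_cluster_toy_means(self):
        """Hand-set yields {3,3,3} and {5,5,5} give rows 3.0 +/- 0 and
        5.0 +/- 0 for the best maturity group."""
        vals = []
        for y in (3.0, 3.0, 3.0, 5.0, 5.0, 5.0):
            vals.append([y] * 7 + [1.0] * 7 + [y + 1] * 7 + [120.0])
        summ = self._summaries(vals)
        labels = np.array([0, 0, 0, 1, 1, 1])
        tab = es.cluster_summary_table(labels, summ)
        assert list(tab["cluster"]) == ["A", "B"]
        assert tab["yield_rainfed_mean"].tolist() == [3.0, 5.0]
        assert tab["yield_rainfed_sd"].tolist() == [0.0, 0.0]
        assert (tab["success_pct"] == 100.0).all()

    def test_all_failed_cluster_coded_na(self):
        vals = [[0.0] * 7 + [0.0] * 7 + [0.0] * 7 + [np.nan]] * 3
        summ = self._summaries(vals)
        tab = es.cluster_summary_table(np.zeros(3, dtype=int), summ)
        assert tab.loc[0, "mg_rainfed"] == "na"
        assert tab.loc[0, "mg_potential"] == "na"
        assert tab.loc[0, "yield_rainfed_mean"] == 0.0
        assert tab.loc[0, "success_pct"] == 0.0

    def test_single_cluster_equals_global_summary(self, continental_run):
        summ = es.summarize_sites(continental_run)
        tab = es.cluster_summary_table(np.zeros(len(summ), dtype=int), summ)
        assert len(tab) == 1
        mg = tab.loc[0, "mg_rainfed"]
        assert tab.loc[0, "yield_rainfed_mean"] == pytest.approx(
            summ[f"yield_{mg}"].mean())

    def test_best_mg_tie_broken_toward_earlier_group(self):
        vals = [[2.0] * 7 + [1.0] * 7 + [3.0] * 7 + [120.0]] * 4
        summ = self._summaries(vals)
        tab = es.cluster_summary_table(np.zeros(4, dtype=int), summ)
        assert tab.loc[0, "mg_rainfed"] == "0000"


class TestFixture:
    def test_fixture_shape_and_invariants(self, table1):
        assert len(table1) == 16
        assert list(table1["cluster"]) == list(CLUSTER_LABELS[:16])
        assert (table1["arable_ha"] > 0).all()
        assert table1["success_pct"].between(0, 100).all()
        assert (table1["yield_rainfed_mean"]
                <= table1["yield_potential_mean"]).all()
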