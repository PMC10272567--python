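import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from osmonet import switch_genes
from osmonet.io import ExpressionMatrix, OsmonetError
from osmonet.switch_genes import SwimConfig


def _expr(values, index, samples=None):
    df = pd.DataFrame(values, index=index)
    df.columns = samples or [f"s{i}" for i in range(df.shape[1])]
    return ExpressionMatrix(df, scale_tag="raw")


class TestSwimFilter:
    def test_zero_fraction_rule(self, tiny_design):
        rng = np.random.default_rng(0)
        vals = rng.uniform(50, 500, (3, 24))
        vals[0, :19] = 0.0  # 19/24 = 79% zeros -> removed
        vals[1, :12] = 0.0  # 50% zeros -> kept by the zero rule
        m = _expr(vals, ["mostly_zero", "half_zero", "ok"], tiny_design.sample_ids)
        kept = switch_genes.swim_filter(m, tiny_design, SwimConfig(fc_min=0, fdr_max=1.0,
                                                                  min_iqr_percentile=0))
        assert "mostly_zero" not in kept

    def test_constant_gene_removed(self, tiny_design):
        rng = np.random.default_rng(0)
        vals = rng.uniform(50, 500, (20, 24))
        vals[0] = 100.0
        names = ["flat"] + [f"g{i}" for i in range(19)]
        m = _expr(vals, names, tiny_design.sample_ids)
        kept = switch_genes.swim_filter(m, tiny_design, SwimConfig(fc_min=0, fdr_max=1.0))
        assert "flat" not in kept

    def test_fc_and_fdr_inclusive(self, tiny_design):
        # g0 has an exact linear PEG/control mean ratio of 2 (inclusive >=)
        rng = np.random.default_rng(1)
        vals = rng.uniform(90, 110, (30, 24))
        m_df = pd.DataFrame(vals, index=[f"g{i}" for i in range(30)],
                            columns=tiny_design.sample_ids)
        for organ in ("leaf", "root"):
            ctl = tiny_design.samples_where(organ=organ, treatment="control")
            peg = tiny_design.samples_where(organ=organ, treatment="peg")
            m_df.loc["g0", ctl] = [99.0, 100.0, 101.0] * 2
            m_df.loc["g0", peg] = [199.0, 200.0, 201.0] * 2
        m = ExpressionMatrix(m_df, scale_tag="raw")
        kept = switch_genes.swim_filter(m, tiny_design, SwimConfig(min_iqr_percentile=0))
        assert "g0" in kept


class TestSwimNetwork:
    def _matrix(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        vals = np.power(2.0, rng.normal(8, 1, (n, 24)))
        return _expr(vals, [f"g{i:03d}" for i in range(n)])

    def test_percentile_zero_complete_graph(self):
        m = self._matrix(10)
        net, _ = switch_genes.swim_network(m, set(m.row_ids), SwimConfig(corr_percentile=0))
        assert net.number_of_edges() == 45

    def test_percentile_100_only_max_pairs(self):
        m = self._matrix(10)
        net, cutoff = switch_genes.swim_network(m, set(m.row_ids), SwimConfig(corr_percentile=100))
        assert net.number_of_edges() >= 1
        for _, _, d in net.edges(data=True):
            assert abs(d["r"]) == pytest.approx(cutoff)

    def test_edge_count_matches_brute_force(self):
        # oracle: numpy percentile of the |r| list computed pair by pair
        m = self._matrix(50, seed=3)
        cfg = SwimConfig(corr_percentile=85)
        net, cutoff = switch_genes.swim_network(m, set(m.row_ids), cfg)
        logv = np.log2(m.values.to_numpy() + 1.0)
        rs = [abs(np.corrcoef(logv[i], logv[j])[0, 1])
              for i, j in itertools.combinations(range(50), 2)]
        expected_cut = np.percentile(rs, 85)
        assert cutoff == pytest.approx(expected_cut, rel=1e-9)
        assert net.number_of_edges() == sum(r >= expected_cut for r in rs)

    def test_too_few_genes_errors(self):
        m = self._matrix(5)
        with pytest.raises(OsmonetError):
            switch_genes.swim_network(m, {"g000"}, SwimConfig())


class TestSwimModules:
    def test_planted_modules_recovered(self, tiny_design):
        rng = np.random.default_rng(0)
        patterns = [rng.normal(0, 2, 24) for _ in range(3)]
        rows, labels = [], []
        for mod, pat in enumerate(patterns):
            for i in range(15):
                rows.append(pat + rng.normal(0, 0.1, 24))
                labels.append(mod)
        m = _expr(np.power(2.0, np.array(rows) + 8), [f"g{i}" for i in range(45)],
                  tiny_design.sample_ids)
        modules, scree = switch_genes.swim_modules(m, set(m.row_ids), SwimConfig(), seed=0)
        from sklearn.metrics import adjusted_rand_score
        assert adjusted_rand_score(labels, modules[[f"g{i}" for i in range(45)]]) == 1.0
        assert list(scree.columns) == ["k", "sse"]

    def test_deterministic(self, tiny_design):
        rng = np.random.default_rng(0)
        m = _expr(np.power(2.0, rng.normal(8, 1, (30, 24))),
                  [f"g{i}" for i in range(30)], tiny_design.sample_ids)
        a, _ = switch_genes.swim_modules(m, set(m.row_ids), seed=4)
        b, _ = switch_genes.swim_modules(m, set(m.row_ids), seed=4)
        pd.testing.assert_series_equal(a, b)

    def test_k1_rejected(self, tiny_design):
        rng = np.random.default_rng(0)
        m = _expr(np.power(2.0, rng.normal(8, 1, (10, 24))),
                  [f"g{i}" for i in range(10)], tiny_design.sample_ids)
        with pytest.raises(OsmonetError, match="k"):
            switch_genes.swim_modules(m, set(m.row_ids), SwimConfig(k_modules=1))


class TestCartography:
    def _net_and_modules(self):
        g = nx.Graph()
        # module 1: triangle a,b,c; module 2: d,e; node x bridges
        g.add_edges_from([("a", "b"), ("b", "c"), ("a", "c"), ("d", "e")])
        g.add_edges_from([("x", "d"), ("x", "e"), ("x", "a")])
        modules = pd.Series({"a": 1, "b": 1, "c": 1, "d": 2, "e": 2, "x": 1})
        return g, modules

    def test_all_internal_kpi_zero(self):
        g, modules = self._net_and_modules()
        carto = switch_genes.cartography(g, modules)
        assert carto.loc["b", "K_pi"] == pytest.approx(0.0)

    def test_all_external_kpi_one(self):
        g = nx.Graph([("x", "a"), ("x", "b")])
        modules = pd.Series({"x": 1, "a": 2, "b": 2})
        carto = switch_genes.cartography(g, modules)
        assert carto.loc["x", "K_pi"] == pytest.approx(1.0)

    def test_kpi_identity(self, rng):
        g = nx.gnp_random_graph(40, 0.2, seed=1)
        modules = pd.Series(rng.integers(1, 4, 40), index=range(40))
        carto = switch_genes.cartography(g, modules)
        lhs = carto["K_pi"] + (carto["k_within"] / carto["k_total"]) ** 2
        np.testing.assert_allclose(lhs, 1.0, atol=1e-12)
        assert ((carto["K_pi"] >= 0) & (carto["K_pi"] <= 1)).all()

    def test_equal_kwithin_gives_zero_z(self):
        g = nx.cycle_graph(["a", "b", "c", "d"])
        modules = pd.Series(1, index=["a", "b", "c", "d"])
        carto = switch_genes.cartography(g, modules)
        np.testing.assert_allclose(carto["z_g"], 0.0)

    def test_isolated_node_excluded(self):
        g = nx.Graph([("a", "b")])
        g.add_node("lonely")
        modules = pd.Series({"a": 1, "b": 1, "lonely": 1})
        carto = switch_genes.cartography(g, modules)
        assert "lonely" not in carto.index

    def test_missing_module_errors(self):
        g = nx.Graph([("a", "b")])
        with pytest.raises(OsmonetError, match="module"):
            switch_genes.cartography(g, pd.Series({"a": 1}))


class TestApcc:
    def test_uniform_negative_edges(self):
        g = nx.star_graph(["x", "a", "b", "c"])
        nx.set_edge_attributes(g, -0.95, "r")
        ap = switch_genes.apcc(g)
        assert ap["x"] == pytest.approx(-0.95)

    def test_positive_neighbors(self):
        g = nx.Graph([("x", "a", {"r": 0.99})])
        assert switch_genes.apcc(g)["x"] == pytest.approx(0.99)

    def test_symmetric_neighbors_cancel(self):
        g = nx.Graph([("x", "a", {"r": 0.9}), ("x", "b", {"r": -0.9})])
        assert switch_genes.apcc(g)["x"] == pytest.approx(0.0)

    def test_within_incident_edge_range(self, rng):
        g = nx.gnp_random_graph(30, 0.3, seed=2)
        for _, _, d in g.edges(data=True):
            d["r"] = float(rng.uniform(-1, 1))
        ap = switch_genes.apcc(g)
        for node in ap.index:
            rs = [g.edges[node, nb]["r"] for nb in g.neighbors(node)]
            assert min(rs) - 1e-12 <= ap[node] <= max(rs) + 1e-12


class TestClassifySwitch:
    def _carto(self, rows):
        df = pd.DataFrame(
            rows, columns=["gene_id", "module", "k_total", "k_within", "z_g", "K_pi"]
        ).set_index("gene_id")
        return df

    def test_switch_conditions(self):
        carto = self._carto([
            ("hub_neg", 1, 50, 2, 0.5, 0.9),
            ("hub_pos", 1, 45, 40, 0.5, 0.2),
            ("local", 1, 40, 38, 3.0, 0.9),
            ("small", 1, 2, 2, 0.1, 0.0),
        ])
        ap = pd.Series({"hub_neg": -0.4, "hub_pos": 0.6, "local": -0.4, "small": 0.1})
        out = switch_genes.classify_switch(carto, ap, SwimConfig(hub_top_frac=0.5))
        assert bool(out.loc["hub_neg", "is_switch"])
        assert out.loc["hub_neg", "role"] == "fight_club_hub"
        assert not bool(out.loc["hub_pos", "is_switch"])
        assert out.loc["hub_pos", "role"] == "party_hub"
        assert not bool(out.loc["local", "is_switch"])  # z_g too high
        assert not bool(out.loc["small", "is_switch"])

    def test_switch_implies_fight_club(self, pipeline_bundle):
        res = pipeline_bundle["swim"]["result"]
        assert (res.loc[res["is_switch"], "role"] == "fight_club_hub").all()

    def test_planted_anti_hub_is_fight_club(self, default_sim, pipeline_bundle):
        truth = default_sim["truth"].genes
        res = pipeline_bundle["swim"]["result"]
        anti = [g for g in truth.index[truth["is_anti_hub"]] if g in res.index]
        assert anti, "anti-hubs should survive the swim filter"
        assert (res.loc[anti, "apcc"] < 0).all()
        assert (res.loc[anti, "role"] == "fight_club_hub").all()
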