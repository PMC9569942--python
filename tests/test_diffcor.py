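"""Differential correlation statistics and interactome network assembly."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from recurnet.diffcor import (
    PairCorrelation,
    build_network,
    degree_table,
    differential_correlation_scan,
    export_network,
    fisher_z_diff,
    import_network,
    pair_correlations,
)

from _oracles import spearman_oracle


def _meta(n_case, n_ctrl, prefix="s"):
    ids = [f"{prefix}{j}" for j in range(n_case + n_ctrl)]
    return pd.DataFrame(
        {"group": ["BCR"] * n_case + ["BRF"] * n_ctrl},
        index=pd.Index(ids, name="sample"),
    )


def _frames(x_by_feature, y_by_feature, n_samples):
    cols = [f"s{j}" for j in range(n_samples)]
    return (
        pd.DataFrame(x_by_feature, index=cols).T,
        pd.DataFrame(y_by_feature, index=cols).T,
    )


def _pairs(*pairs):
    return pd.DataFrame(
        [{"source": s, "target": t, "edge_type": "miRNA-target",
          "evidence": "validated", "source_db": "test"} for s, t in pairs]
    )


class TestPairCorrelations:
    def test_spearman_worked_example(self):
        # d^2 sum = 4 -> r_s = 1 - 6*4/(5*24) = 0.8, same series in each group
        x = np.array([1, 2, 3, 4, 5], dtype=float)
        y = np.array([2, 1, 4, 3, 5], dtype=float)
        src, tgt = _frames({"m": np.r_[x, x]}, {"g": np.r_[y, y]}, 10)
        out, skipped = pair_correlations(src, tgt, _meta(5, 5), _pairs(("m", "g")))
        assert not skipped
        assert all(pc.r_s == pytest.approx(0.8) for pc in out)

    def test_exact_linear_relation(self):
        x = np.arange(1.0, 9.0)
        src, tgt = _frames({"m": x}, {"g": 2 * x}, 8)
        out, _ = pair_correlations(src, tgt, _meta(4, 4), _pairs(("m", "g")))
        for pc in out:
            assert pc.r_s == pytest.approx(1.0)
            assert pc.r_p == pytest.approx(1.0)
            assert pc.adj_r2 == pytest.approx(1.0)

    def test_monotone_decreasing_gives_minus_one(self):
        x = np.arange(1.0, 9.0)
        src, tgt = _frames({"m": x}, {"g": np.exp(-x)}, 8)
        out, _ = pair_correlations(src, tgt, _meta(4, 4), _pairs(("m", "g")))
        assert all(pc.r_s == pytest.approx(-1.0) for pc in out)

    def test_absent_feature_and_zero_variance_skipped_not_fatal(self):
        x = np.arange(1.0, 9.0)
        src, tgt = _frames({"m": x, "flat": np.ones(8)}, {"g": x}, 8)
        out, skipped = pair_correlations(
            src, tgt, _meta(4, 4), _pairs(("m", "g"), ("ghost", "g"), ("flat", "g"))
        )
        assert {s["reason"] for s in skipped} >= {"feature absent"}
        assert any("zero variance" in s["reason"] for s in skipped)
        assert len(out) == 2  # only the (m, g) pair, both groups

    @settings(max_examples=60)
    @given(st.lists(st.integers(0, 6), min_size=4, max_size=12),
           st.lists(st.integers(0, 6), min_size=4, max_size=12))
    def test_spearman_equals_midrank_oracle_with_ties(self, xs, ys):
        n = min(len(xs), len(ys))
        x, y = np.array(xs[:n], float), np.array(ys[:n], float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            return
        assert stats.spearmanr(x, y).statistic == pytest.approx(
            spearman_oracle(x, y), abs=1e-12
        )


class TestFisherZ:
    def test_equal_correlations_give_zero(self):
        z, p = fisher_z_diff(0.5, 30, 0.5, 30)
        assert z == 0.0
        assert p == 1.0

    def test_worked_example_28_per_group(self):
        z, p = fisher_z_diff(0.8, 28, 0.2, 28)
        assert z == pytest.approx(3.168, abs=2e-3)
        assert p == pytest.approx(1.53e-3, rel=0.02)

    def test_sign_flips_under_joint_negation(self):
        z1, p1 = fisher_z_diff(0.7, 20, -0.1, 25)
        z2, p2 = fisher_z_diff(-0.7, 20, 0.1, 25)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_small_group_names_variance_constraint(self):
        with pytest.raises(ValueError, match="n - 3|n-3|variance"):
            fisher_z_diff(0.5, 3, 0.2, 30)

    def test_spearman_variance_correction_widens_se(self):
        z1, _ = fisher_z_diff(0.8, 30, 0.2, 30, variance=1.0)
        z2, _ = fisher_z_diff(0.8, 30, 0.2, 30, variance=1.06)
        assert abs(z2) < abs(z1)


class TestScan:
    @staticmethod
    def _corrs(rs_pairs, n=30):
        out = []
        for i, (r_bcr, r_brf) in enumerate(rs_pairs):
            for grp, r in (("BCR", r_bcr), ("BRF", r_brf)):
                out.append(PairCorrelation(f"m{i}", f"g{i}", grp, n, r, r, r**2))
        return out

    def test_group_swap_antisymmetry(self):
        corrs = self._corrs([(0.8, -0.2), (0.1, 0.5), (0.0, 0.0)])
        swapped = [
            PairCorrelation(pc.source, pc.target,
                            "BRF" if pc.group == "BCR" else "BCR",
                            pc.n, pc.r_s, pc.r_p, pc.adj_r2)
            for pc in corrs
        ]
        a = differential_correlation_scan(corrs)
        b = differential_correlation_scan(swapped)
        assert np.allclose(a["delta"], -b["delta"])
        assert np.allclose(a["z"], -b["z"])
        assert np.allclose(a["p"], b["p"])
        assert (a["selected"] == b["selected"]).all()

    def test_missing_group_skipped(self):
        corrs = self._corrs([(0.8, -0.2)])
        corrs.append(PairCorrelation("lonely", "g9", "BCR", 30, 0.5, 0.5, 0.25))
        res = differential_correlation_scan(corrs)
        assert "lonely" not in set(res["source"])

    def test_min_abs_delta_gate(self):
        corrs = self._corrs([(0.9, -0.5), (0.35, 0.05)], n=200)
        res = differential_correlation_scan(corrs, min_abs_delta=0.5)
        sel = res.set_index("source")["selected"]
        assert bool(sel["m0"]) and not bool(sel["m1"])

    def test_invalid_selection_rule_rejected(self):
        with pytest.raises(ValueError):
            differential_correlation_scan([], select_on="bonferroni")


def _toy_scan(selected_rho=(0.9, -0.5), unselected_rho=(0.1, 0.15)):
    rng = np.random.default_rng(42)
    n = 40
    rows = {}
    for name, (r1, r2) in (("sel", selected_rho), ("null", unselected_rho)):
        for grp, r in (("BCR", r1), ("BRF", r2)):
            z = rng.standard_normal(n)
            e = rng.standard_normal(n)
            rows[(name, grp)] = (z, r * z + np.sqrt(1 - r**2) * e)
    src = {}
    tgt = {}
    for i, name in enumerate(("sel", "null")):
        src[f"miR-{name}"] = np.r_[rows[(name, "BCR")][0], rows[(name, "BRF")][0]]
        tgt[f"G-{name}"] = np.r_[rows[(name, "BCR")][1], rows[(name, "BRF")][1]]
    frames = _frames(src, tgt, 2 * n)
    pairs = _pairs(("miR-sel", "G-sel"), ("miR-null", "G-null"))
    corrs, _ = pair_correlations(*frames, _meta(n, n), pairs)
    return differential_correlation_scan(corrs), pairs


class TestNetwork:
    def test_single_selected_pair_yields_one_edge_two_nodes(self):
        res, pairs = _toy_scan()
        assert res.set_index("source")["selected"]["miR-sel"]
        g = build_network(res, pairs)
        assert g.number_of_edges() == 1
        assert set(g.nodes) == {"miR-sel", "G-sel"}
        assert g.nodes["miR-sel"]["node_type"] == "miRNA"
        assert g.nodes["G-sel"]["node_type"] == "gene"

    def test_de_flags_pass_through(self):
        res, pairs = _toy_scan()
        ann = {"G-sel": {"de_cohortB": True, "direction": "↑"}}
        g = build_network(res, pairs, ann)
        assert g.nodes["G-sel"]["de_cohortB"] and not g.nodes["G-sel"]["de_cohortA"]
        assert not g.nodes["miR-sel"]["de_cohortA"]

    def test_shared_target_merges_into_single_node(self):
        corrs = TestScan._corrs([(0.95, -0.6), (0.95, -0.6)], n=100)
        # second pair targets the same gene
        for pc in corrs:
            if pc.source == "m1":
                pc.target = "g0"
        pairs = _pairs(("m0", "g0"), ("m1", "g0"))
        res = differential_correlation_scan(corrs)
        g = build_network(res, pairs)
        assert g.degree("g0") == 2
        assert g.number_of_nodes() == 3

    def test_edge_and_node_count_bookkeeping(self):
        res, pairs = _toy_scan()
        g = build_network(res, pairs)
        assert g.number_of_edges() <= len(res)
        assert g.number_of_nodes() <= 2 * g.number_of_edges() or g.number_of_edges() == 0

    def test_supplementary_ppi_edge_included_among_nodes(self):
        corrs = TestScan._corrs([(0.95, -0.6), (0.95, -0.6)], n=100)
        pairs = _pairs(("m0", "g0"), ("m1", "g1"))
        ppi = pd.DataFrame([{"source": "g0", "target": "g1", "edge_type": "PPI",
                             "evidence": "n/a", "source_db": "test"}])
        catalog = pd.concat([pairs, ppi], ignore_index=True)
        res = differential_correlation_scan(corrs)
        g = build_network(res, catalog)
        assert g.has_edge("g0", "g1")
        assert g.edges["g0", "g1"]["edge_type"] == "PPI"

    def test_degree_table_sorted(self):
        res, pairs = _toy_scan()
        tab = degree_table(build_network(res, pairs))
        assert list(tab["degree"]) == sorted(tab["degree"], reverse=True)


class TestExport:
    @staticmethod
    def _network():
        res, pairs = _toy_scan()
        return build_network(res, pairs, {"G-sel": {"de_cohortA": True}})

    @pytest.mark.parametrize("fmt", ["graphml", "json"])
    def test_round_trip_preserves_structure_and_annotations(self, tmp_path, fmt):
        g = self._network()
        path = tmp_path / f"net.{fmt}"
        export_network(g, path, fmt)
        back = import_network(path, fmt)
        assert set(back.nodes) == set(g.nodes)
        assert {frozenset(e) for e in back.edges} == {frozenset(e) for e in g.edges}
        for n in g.nodes:
            assert bool(back.nodes[n]["de_cohortA"]) == g.nodes[n]["de_cohortA"]
            assert back.nodes[n]["node_type"] == g.nodes[n]["node_type"]
        for u, v, d in g.edges(data=True):
            d2 = back.edges[u, v]
            assert float(d2["delta"]) == pytest.approx(d["delta"])
            assert d2["edge_type"] == d["edge_type"]

    def test_tsv_export_parses(self, tmp_path):
        g = self._network()
        path = tmp_path / "net.tsv"
        export_network(g, path, "tsv")
        df = pd.read_csv(path, sep="\t")
        assert {"source", "target", "edge_type", "delta"} <= set(df.columns)
        assert len(df) == g.number_of_edges()

    def test_empty_network_exports_valid_documents(self, tmp_path):
        import networkx as nx

        g = nx.Graph()
        for fmt in ("graphml", "json"):
            path = tmp_path / f"empty.{fmt}"
            export_network(g, path, fmt)
            assert import_network(path, fmt).number_of_nodes() == 0

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="unknown format"):
            export_network(self._network(), tmp_path / "x.bin", "gexf2")

    def test_graphml_document_structure(self, tmp_path):
        from lxml import etree

        path = tmp_path / "net.graphml"
        export_network(self._network(), path, "graphml")
        tree = etree.parse(str(path))
        root = tree.getroot()
        ns = "http://graphml.graphdrawing.org/xmlns"
        assert root.tag == f"{{{ns}}}graphml"
        declared = {k.get("id") for k in root.findall(f"{{{ns}}}key")}
        node_ids = {n.get("id") for n in root.iter(f"{{{ns}}}node")}
        for edge in root.iter(f"{{{ns}}}edge"):
            assert edge.get("source") in node_ids
            assert edge.get("target") in node_ids
        for data in root.iter(f"{{{ns}}}data"):
            assert data.get("key") in declared
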