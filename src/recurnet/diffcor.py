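"""Differential miRNA-target correlation analysis and the interactome network.

For every catalog-defined interaction pair, Spearman and Pearson correlations
(and the adjusted R-squared of a simple linear regression) are computed per
prognosis group on log2CPM expression. The differential-correlation statistic
is delta = r_s(BCR) - r_s(BRF); its significance comes from the two-sample
Fisher r-to-z test. Selected pairs are assembled into a typed network with DE
annotations, exportable as GraphML / JSON / edge-list TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .de import GROUP_CASE, GROUP_CONTROL, bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "PairCorrelation",
    "pair_correlations",
    "fisher_z_diff",
    "differential_correlation_scan",
    "build_network",
    "export_network",
    "import_network",
    "degree_table",
]

# Fieller-Hartley-Pearson variance inflation for Spearman's coefficient in the
# r-to-z test; enabled by passing variance=SPEARMAN_VARIANCE.
SPEARMAN_VARIANCE = 1.06


@dataclass
class PairCorrelation:
    """Per-group correlation statistics for one interaction pair."""

    source: str
    target: str
    group: str
    n: int
    r_s: float
    r_p: float
    adj_r2: float


def _adjusted_r2(r_p: float, n: int) -> float:
    # simple regression of target on source: R^2 = r_p^2, one predictor
    return 1.0 - (1.0 - r_p**2) * (n - 1) / (n - 2)


def pair_correlations(
    expr_source: pd.DataFrame,
    expr_target: pd.DataFrame,
    meta: pd.DataFrame,
    pairs: pd.DataFrame,
) -> tuple[list[PairCorrelation], list[dict]]:
    """Spearman/Pearson/adjusted-R2 per catalog pair and prognosis group.

    Expression frames are feature-by-sample on the log2CPM scale and must share
    the sample set described by ``meta``. Pairs referencing absent features or
    zero-variance vectors are skipped with a recorded reason, not fatally.
    Returns (correlations, skipped).
    """
    samples = list(expr_source.columns)
    if list(expr_target.columns) != samples:
        raise ValueError("source and target matrices must be sample-aligned")
    groups = meta.loc[samples, "group"].to_numpy()
    out: list[PairCorrelation] = []
    skipped: list[dict] = []
    for row in pairs.itertuples(index=False):
        src, tgt = str(row.source), str(row.target)
        if src not in expr_source.index or tgt not in expr_target.index:
            skipped.append({"source": src, "target": tgt, "reason": "feature absent"})
            continue
        x_all = expr_source.loc[src].to_numpy(dtype=float)
        y_all = expr_target.loc[tgt].to_numpy(dtype=float)
        for grp in (GROUP_CASE, GROUP_CONTROL):
            mask = groups == grp
            n = int(mask.sum())
            if n < 4:
                skipped.append({"source": src, "target": tgt,
                                "reason": f"group {grp} has n < 4"})
                continue
            x, y = x_all[mask], y_all[mask]
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                skipped.append({"source": src, "target": tgt,
                                "reason": f"zero variance in group {grp}"})
                continue
            r_s = float(stats.spearmanr(x, y).statistic)
            r_p = float(stats.pearsonr(x, y).statistic)
            out.append(PairCorrelation(src, tgt, grp, n, r_s, r_p,
                                       _adjusted_r2(r_p, n)))
    return out, skipped


def fisher_z_diff(
    r1: float, n1: int, r2: float, n2: int, variance: float = 1.0
) -> tuple[float, float]:
    """Two-sample Fisher r-to-z test for the difference of two correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(v/(n1-3) + v/(n2-3)); the two-sided p
    comes from the standard normal tail. ``variance`` defaults to 1 (Pearson
    theory); pass SPEARMAN_VARIANCE (1.06) for the Fieller-Hartley-Pearson
    correction appropriate to Spearman coefficients.
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("Fisher z variance 1/(n-3) requires n >= 4 per group")
    clip = 1.0 - 1e-7
    z1 = math.atanh(max(-clip, min(clip, r1)))
    z2 = math.atanh(max(-clip, min(clip, r2)))
    se = math.sqrt(variance / (n1 - 3) + variance / (n2 - 3))
    z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(min(p, 1.0))


def differential_correlation_scan(
    paircorrs: list[PairCorrelation],
    alpha: float = 0.05,
    min_abs_delta: float = 0.0,
    variance: float = 1.0,
    select_on: str = "p",
) -> pd.DataFrame:
    """Differential correlation (BCR r_s minus BRF r_s) with Fisher-z p-values.

    Pairs missing either group are skipped. FDR is Benjamini-Hochberg across
    all scanned pairs. A pair is ``selected`` when its p-value (raw by default;
    FDR when ``select_on='fdr'``) is <= alpha and |delta| >= ``min_abs_delta``.
    """
    if select_on not in {"p", "fdr"}:
        raise ValueError("select_on must be 'p' or 'fdr'")
    by_pair: dict[tuple[str, str], dict[str, PairCorrelation]] = {}
    for pc in paircorrs:
        by_pair.setdefault((pc.source, pc.target), {})[pc.group] = pc
    rows = []
    for (src, tgt), groups in by_pair.items():
        if GROUP_CASE not in groups or GROUP_CONTROL not in groups:
            log.debug("pair (%s, %s) missing a group; skipped", src, tgt)
            continue
        a, b = groups[GROUP_CASE], groups[GROUP_CONTROL]
        z, p = fisher_z_diff(a.r_s, a.n, b.r_s, b.n, variance=variance)
        rows.append(
            {
                "source": src,
                "target": tgt,
                "n_bcr": a.n,
                "n_brf": b.n,
                "r_s_bcr": a.r_s,
                "r_s_brf": b.r_s,
                "r_p_bcr": a.r_p,
                "r_p_brf": b.r_p,
                "adj_r2_bcr": a.adj_r2,
                "adj_r2_brf": b.adj_r2,
                "delta": a.r_s - b.r_s,
                "z": z,
                "p": p,
            }
        )
    res = pd.DataFrame(rows)
    if len(res):
        res["fdr"] = bh_adjust(res["p"].to_numpy())
        crit = res["fdr"] if select_on == "fdr" else res["p"]
        res["selected"] = (crit <= alpha) & (res["delta"].abs() >= min_abs_delta)
    else:
        res = pd.DataFrame(
            columns=["source", "target", "n_bcr", "n_brf", "r_s_bcr", "r_s_brf",
                     "r_p_bcr", "r_p_brf", "adj_r2_bcr", "adj_r2_brf", "delta",
                     "z", "p", "fdr", "selected"]
        )
    return res


def _node_type(node: str, catalog: pd.DataFrame) -> str:
    """Infer node type from the typed edges it participates in."""
    src_types = set(catalog.loc[catalog["source"] == node, "edge_type"])
    tgt_types = set(catalog.loc[catalog["target"] == node, "edge_type"])
    if "miRNA-target" in src_types:
        return "miRNA"
    if "lncRNA-target" in src_types:
        return "lncRNA"
    if "TF-target" in src_types:
        return "TF"
    return "gene"


def build_network(
    diffcor: pd.DataFrame,
    catalog: pd.DataFrame,
    de_annotations: dict[str, dict] | None = None,
) -> nx.Graph:
    """Assemble the typed interactome network of selected pairs.

    Nodes are the endpoints of selected miRNA-target edges, annotated with
    per-cohort DE flags and direction (``de_annotations`` maps node id ->
    {"de_cohortA": bool, "de_cohortB": bool, "direction": str}). PPI /
    TF-target / lncRNA-target catalog edges among included nodes are appended
    with their own correlation annotations when scanned.
    """
    de_annotations = de_annotations or {}
    g = nx.Graph()
    stats_by_pair = {
        (r.source, r.target): r for r in diffcor.itertuples(index=False)
    }
    selected = diffcor[diffcor["selected"]] if len(diffcor) else diffcor
    cat_type = {
        (str(r.source), str(r.target)): (str(r.edge_type), str(r.evidence))
        for r in catalog.itertuples(index=False)
    }

    def add_node(node: str) -> None:
        ann = de_annotations.get(node, {})
        g.add_node(
            node,
            node_type=_node_type(node, catalog),
            de_cohortA=bool(ann.get("de_cohortA", False)),
            de_cohortB=bool(ann.get("de_cohortB", False)),
            direction=str(ann.get("direction", "")),
        )

    def edge_attrs(r) -> dict:
        return {
            "r_s_bcr": float(r.r_s_bcr),
            "r_s_brf": float(r.r_s_brf),
            "r_p_bcr": float(r.r_p_bcr),
            "r_p_brf": float(r.r_p_brf),
            "adj_r2_bcr": float(r.adj_r2_bcr),
            "adj_r2_brf": float(r.adj_r2_brf),
            "delta": float(r.delta),
            "p": float(r.p),
            "fdr": float(r.fdr),
        }

    for r in selected.itertuples(index=False):
        etype, evid = cat_type.get((r.source, r.target), ("miRNA-target", "n/a"))
        if etype != "miRNA-target":
            continue
        add_node(r.source)
        add_node(r.target)
        g.add_edge(r.source, r.target, edge_type=etype, evidence=evid, **edge_attrs(r))
    # supplement with non-miRNA catalog edges among included nodes
    for (src, tgt), (etype, evid) in cat_type.items():
        if etype == "miRNA-target":
            continue
        if src in g.nodes and tgt in g.nodes and not g.has_edge(src, tgt):
            attrs = {"edge_type": etype, "evidence": evid}
            r = stats_by_pair.get((src, tgt))
            if r is not None:
                attrs.update(edge_attrs(r))
            g.add_edge(src, tgt, **attrs)
    return g


_FORMATS = {"graphml", "tsv", "json"}


def export_network(network: nx.Graph, path: str | Path, fmt: str = "graphml") -> None:
    """Write the network losslessly as GraphML, node-link JSON, or edge-list TSV."""
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {sorted(_FORMATS)}")
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(network, path)
    elif fmt == "json":
        import json

        data = nx.node_link_data(network, edges="edges")
        with open(path, "w") as fh:
            json.dump(data, fh, indent=2, sort_keys=True)
    else:
        rows = []
        for u, v, attrs in network.edges(data=True):
            rows.append({"source": u, "target": v, **attrs})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def import_network(path: str | Path, fmt: str = "graphml") -> nx.Graph:
    fmt = fmt.lower()
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "json":
        import json

        with open(path) as fh:
            return nx.node_link_graph(json.load(fh), edges="edges")
    raise ValueError(f"import supported for graphml/json, not {fmt!r}")


def degree_table(network: nx.Graph) -> pd.DataFrame:
    """Static per-node summary: type, DE flags, degree."""
    columns = ["node", "node_type", "de_cohortA", "de_cohortB", "degree"]
    rows = [
        {
            "node": n,
            "node_type": d.get("node_type", ""),
            "de_cohortA": d.get("de_cohortA", False),
            "de_cohortB": d.get("de_cohortB", False),
            "degree": network.degree(n),
        }
        for n, d in network.nodes(data=True)
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows).sort_values("degree", ascending=False).reset_index(drop=True)
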