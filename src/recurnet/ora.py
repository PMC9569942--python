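"""Hypergeometric over-representation analysis of network members.

Gene membership comes from GMT collections (GO/KEGG/Reactome-style); miRNA
membership is supplied by an explicit miRNA-to-pathway annotation table, since
miRNAs are not members of ordinary gene sets. The universe defaults to the
union of all collection members (annotation miRNAs included) and can be
overridden explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from scipy import stats

__all__ = ["GeneSetCollection", "ora_test", "run_ora"]


@dataclass
class GeneSetCollection:
    """Named gene sets plus an optional explicit universe.

    ``sets`` maps set id -> {"name": str, "members": [ids]}; ``mirna_members``
    maps set id -> [miRNA ids] from the annotation table.
    """

    sets: dict[str, dict]
    universe: list[str] | None = None
    mirna_members: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for set_id, rec in self.sets.items():
            if not rec.get("members"):
                raise ValueError(f"gene set {set_id!r} has no members")

    def all_members(self, set_id: str) -> set[str]:
        return set(self.sets[set_id]["members"]) | set(self.mirna_members.get(set_id, []))

    def effective_universe(self) -> set[str]:
        if self.universe is not None:
            u = set(self.universe)
            if not u:
                raise ValueError("explicit universe is empty")
            return u
        u: set[str] = set()
        for set_id in self.sets:
            u |= self.all_members(set_id)
        if not u:
            raise ValueError("collection defines an empty universe")
        return u


def ora_test(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p-value P(X >= k), X ~ Hypergeom(N, K, n).

    N = universe size, K = set size in the universe, n = query size in the
    universe, k = overlap.
    """
    if not (0 <= k <= min(K, n)) or K > N or n > N or min(K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def run_ora(
    query: list[str] | set[str],
    collection: GeneSetCollection,
    alpha: float = 0.05,
    adjust: bool = False,
) -> pd.DataFrame:
    """One hypergeometric test per set for a query of gene and miRNA ids.

    Query ids outside the universe are ignored (they carry no information
    under the urn model). ``significant`` means p < alpha on the raw p-value;
    pass ``adjust=True`` to threshold on Benjamini-Hochberg FDR instead.
    Results are sorted by p; overlap genes and miRNAs are reported separately.
    """
    query = {str(q) for q in query}
    if not query:
        raise ValueError("query is empty")
    universe = collection.effective_universe()
    mirnas_in_universe = {
        m for members in collection.mirna_members.values() for m in members
    }
    q_in = query & universe
    n = len(q_in)
    N = len(universe)
    rows = []
    for set_id, rec in collection.sets.items():
        members = collection.all_members(set_id) & universe
        K = len(members)
        overlap = q_in & members
        k = len(overlap)
        genes = sorted(overlap - mirnas_in_universe)
        mirnas = sorted(overlap & mirnas_in_universe)
        rows.append(
            {
                "set_id": set_id,
                "name": rec.get("name", set_id),
                "overlap_genes": ";".join(genes),
                "overlap_mirnas": ";".join(mirnas),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": ora_test(k, K, n, N),
            }
        )
    res = pd.DataFrame(rows).sort_values("p", kind="stable").reset_index(drop=True)
    if adjust:
        from .de import bh_adjust

        res["fdr"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["fdr"] < alpha
    else:
        res["significant"] = res["p"] < alpha
    return res
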