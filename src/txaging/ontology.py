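"""Conditional overrepresentation testing on an ontology DAG.

Terms are tested children-before-parents with Fisher's exact test; once a
more specific child term is significantly overrepresented, its genes are
excluded from the parent's table, decorrelating the reported terms. Term
significance is assessed at uncorrected p < 0.05 (multiplicity correction
for this conditional procedure is left to the caller). A directional test
per term combines a one-sample t test, an exact binomial sign test and a
Wilcoxon signed-rank test of member fold changes against a no-change null;
a direction is reported only when all three agree at p < 0.05. Terms are
clustered by the Jaccard similarity of their ancestor sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

__all__ = [
    "OntologyDAG",
    "conditional_overrepresentation",
    "directional_term_test",
    "term_similarity_cluster",
]


@dataclass
class OntologyDAG:
    """Acyclic term hierarchy with gene annotations propagated to ancestors."""

    parents: dict[str, list[str]]  # term -> parent terms
    direct_annotations: dict[str, set[str]]  # term -> directly annotated genes
    graph: nx.DiGraph = field(init=False)  # edges child -> parent
    propagated: dict[str, set[str]] = field(init=False)

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        for term in set(self.parents) | set(self.direct_annotations):
            g.add_node(term)
        for child, ps in self.parents.items():
            for p in ps:
                g.add_edge(child, p)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("ontology contains a cycle")
        self.graph = g
        self.propagated = {}
        # children before parents, so each term unions its children's genes
        for term in nx.topological_sort(g):
            genes = set(self.direct_annotations.get(term, set()))
            for child in g.predecessors(term):
                genes |= self.propagated[child]
            self.propagated[term] = genes

    @classmethod
    def from_tables(cls, term_parent: pd.DataFrame, term_gene: pd.DataFrame) -> "OntologyDAG":
        """Build from (term, parent) and (term, gene) two-column tables."""
        parents: dict[str, list[str]] = {}
        for _, row in term_parent.iterrows():
            parents.setdefault(str(row.iloc[0]), []).append(str(row.iloc[1]))
        annotations: dict[str, set[str]] = {}
        for _, row in term_gene.iterrows():
            annotations.setdefault(str(row.iloc[0]), set()).add(str(row.iloc[1]))
        return cls(parents=parents, direct_annotations=annotations)

    def ancestors(self, term: str, include_self: bool = True) -> set[str]:
        anc = set(nx.descendants(self.graph, term))  # edges point child -> parent
        if include_self:
            anc.add(term)
        return anc

    def descendants(self, term: str) -> set[str]:
        return set(nx.ancestors(self.graph, term))

    @property
    def terms(self) -> list[str]:
        return list(self.graph.nodes)


def conditional_overrepresentation(
    query: set[str],
    background: set[str],
    dag: OntologyDAG,
    alpha: float = 0.05,
    conditional: bool = True,
) -> pd.DataFrame:
    """Fisher overrepresentation per term with child-term conditioning.

    Terms are processed in topological (children-first) order; with
    ``conditional=True`` a term's annotation set excludes any gene annotated
    to one of its already-significant descendants before the 2x2 table is
    formed. Terms with zero conditioned background annotations are skipped
    with a flag. Query genes must be drawn from the background universe.
    """
    query = set(query)
    background = set(background)
    if not query <= background:
        missing = next(iter(query - background))
        raise ValueError(f"query gene {missing!r} absent from background")
    n_bg = len(background)
    n_query = len(query)
    significant: set[str] = set()
    records = []
    for term in nx.topological_sort(dag.graph):
        genes = dag.propagated.get(term, set()) & background
        if conditional:
            for child in dag.descendants(term) & significant:
                genes = genes - dag.propagated[child]
        k = len(genes)
        if k == 0:
            records.append(
                {"term": term, "conditioned_count": 0, "overlap": 0, "odds_ratio": np.nan, "p": np.nan, "significant": False, "skipped": True}
            )
            continue
        overlap = len(genes & query)
        table = [[overlap, n_query - overlap], [k - overlap, n_bg - n_query - (k - overlap)]]
        res = stats.fisher_exact(table, alternative="greater")
        sig = res.pvalue < alpha
        if sig:
            significant.add(term)
        records.append(
            {
                "term": term,
                "conditioned_count": k,
                "overlap": overlap,
                "odds_ratio": float(res.statistic) if np.isfinite(res.statistic) else np.inf,
                "p": float(res.pvalue),
                "significant": bool(sig),
                "skipped": False,
            }
        )
    return pd.DataFrame(records).set_index("term")


def directional_term_test(member_fc: np.ndarray, null_center: float = 1.0, alpha: float = 0.05) -> dict:
    """Triple directional test of a term's member fold changes.

    One-sample t test, exact binomial sign test and Wilcoxon signed-rank
    test, each one-sided in both directions against ``null_center``; the
    reported direction (up/down) requires all three tests significant at
    ``alpha`` on the same side, otherwise 'none'. Degenerate inputs (all
    members tied at the null center) yield p = 1 throughout.
    """
    fc = np.asarray(member_fc, dtype=float)
    fc = fc[np.isfinite(fc)]
    if len(fc) < 3:
        raise ValueError("need at least 3 finite member fold changes")
    diffs = fc - null_center
    nonzero = diffs[diffs != 0]

    out: dict[str, float | str] = {"mean_fc": float(np.mean(fc)), "n": int(len(fc))}
    if np.ptp(fc) == 0 and fc[0] == null_center:
        for key in ("p_t_up", "p_t_down", "p_binom_up", "p_binom_down", "p_wilcoxon_up", "p_wilcoxon_down"):
            out[key] = 1.0
        out["triangle"] = "none"
        return out

    t_up = stats.ttest_1samp(fc, null_center, alternative="greater").pvalue if np.ptp(fc) > 0 else (0.0 if fc[0] > null_center else 1.0)
    t_down = stats.ttest_1samp(fc, null_center, alternative="less").pvalue if np.ptp(fc) > 0 else (0.0 if fc[0] < null_center else 1.0)
    if len(nonzero) == 0:
        b_up = b_down = w_up = w_down = 1.0
    else:
        k_up = int(np.sum(nonzero > 0))
        b_up = stats.binomtest(k_up, len(nonzero), 0.5, alternative="greater").pvalue
        b_down = stats.binomtest(k_up, len(nonzero), 0.5, alternative="less").pvalue
        w_up = stats.wilcoxon(nonzero, alternative="greater", mode="auto").pvalue
        w_down = stats.wilcoxon(nonzero, alternative="less", mode="auto").pvalue
    out.update(
        p_t_up=float(t_up), p_t_down=float(t_down),
        p_binom_up=float(b_up), p_binom_down=float(b_down),
        p_wilcoxon_up=float(w_up), p_wilcoxon_down=float(w_down),
    )
    if max(t_up, b_up, w_up) < alpha:
        out["triangle"] = "up"
    elif max(t_down, b_down, w_down) < alpha:
        out["triangle"] = "down"
    else:
        out["triangle"] = "none"
    return out


def term_similarity_cluster(terms: list[str], dag: OntologyDAG) -> tuple[pd.DataFrame, np.ndarray]:
    """Cluster terms by shared ancestry: distance = 1 - Jaccard(ancestors).

    Each term's ancestor set includes the term itself. Returns the distance
    matrix and the average-linkage dendrogram.
    """
    if len(terms) < 2:
        raise ValueError("need at least 2 terms")
    anc = {t: dag.ancestors(t) for t in terms}
    n = len(terms)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = anc[terms[i]], anc[terms[j]]
            jac = len(a & b) / len(a | b) if (a | b) else 0.0
            dist[i, j] = dist[j, i] = 1.0 - jac
    Z = linkage(squareform(dist, checks=False), method="average")
    return pd.DataFrame(dist, index=terms, columns=terms), Z
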