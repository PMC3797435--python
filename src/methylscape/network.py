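"""Co-expression network construction and characterization.

Builds the induced co-expression graph over a candidate gene set, extracts
its largest connected component, fits a power-law degree distribution by
log-log least squares (the exponent is the fitted slope, so a decaying
distribution reports a negative gamma), expands seed protein modules with
first-degree interaction neighbors, and scores term over-representation by
one-sided Fisher (hypergeometric) tests with Benjamini-Hochberg correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def build_network(gene_set: Sequence[str], edge_table: pd.DataFrame
                  ) -> Tuple[nx.Graph, List[str]]:
    """Induced subgraph of the edge table on ``gene_set``.

    Returns ``(graph, unconnected)`` where ``unconnected`` lists query genes
    with no edge inside the set (the isolated remainder).  Self-loops and
    duplicate edges are discarded.
    """
    cols = list(edge_table.columns)
    if len(cols) < 2:
        raise ValueError("edge table needs at least two id columns")
    genes = set(gene_set)
    g = nx.Graph()
    g.add_nodes_from(sorted(genes))
    weight_col = cols[2] if len(cols) > 2 else None
    for row in edge_table.itertuples(index=False):
        a, b = row[0], row[1]
        if a == b or a not in genes or b not in genes:
            continue
        attrs = {"weight": float(row[2])} if weight_col else {}
        g.add_edge(a, b, **attrs)
    unconnected = sorted(n for n in g.nodes if g.degree(n) == 0)
    g.remove_nodes_from(unconnected)
    return g, unconnected


def largest_component(graph: nx.Graph) -> nx.Graph:
    """Maximum-order connected component; ties broken by smallest member id."""
    if graph.number_of_nodes() == 0:
        return nx.Graph()
    comps = sorted(
        (sorted(c) for c in nx.connected_components(graph)),
        key=lambda members: (-len(members), members[0]),
    )
    return graph.subgraph(comps[0]).copy()


@dataclass
class PowerLawFit:
    gamma: float        # slope of the log10 p(k) vs log10 k regression
    r_squared: float
    k_values: np.ndarray
    frequencies: np.ndarray


def fit_power_law(degree_sequence: Sequence[int]) -> PowerLawFit:
    """Least-squares line on (log10 k, log10 p(k)) over observed degrees.

    Degree-zero nodes are excluded (log undefined); needs at least three
    distinct positive degrees unless the input is the degenerate two-point
    case, where the two-point slope is returned with r^2 = 1.
    """
    degrees = np.asarray(degree_sequence, dtype=int)
    degrees = degrees[degrees > 0]
    if degrees.size == 0:
        raise ValueError("no positive degrees to fit")
    k, counts = np.unique(degrees, return_counts=True)
    if k.size < 2:
        raise ValueError("need at least two distinct positive degrees")
    p = counts / counts.sum()
    x, y = np.log10(k), np.log10(p)
    slope, intercept = np.polyfit(x, y, 1)
    if k.size == 2:
        r2 = 1.0
    else:
        r = np.corrcoef(x, y)[0, 1]
        r2 = float(r * r)
    return PowerLawFit(gamma=float(slope), r_squared=r2, k_values=k,
                       frequencies=p)


def expand_modules(seed_modules: Sequence[Sequence[str]],
                   ppi_edges: pd.DataFrame
                   ) -> List[Dict[str, List[str]]]:
    """Expand each seed module with all first-degree interaction neighbors.

    Returns one record per module with ``seed`` and ``added`` member lists
    (provenance retained).
    """
    cols = list(ppi_edges.columns)
    neighbors: Dict[str, Set[str]] = {}
    for row in ppi_edges.itertuples(index=False):
        a, b = row[0], row[1]
        if a == b:
            continue
        neighbors.setdefault(a, set()).add(b)
        neighbors.setdefault(b, set()).add(a)
    out = []
    for module in seed_modules:
        seed = sorted(set(module))
        added: Set[str] = set()
        for member in seed:
            added |= neighbors.get(member, set())
        added -= set(seed)
        out.append({"seed": seed, "added": sorted(added)})
    return out


@dataclass
class EnrichmentResult:
    term_id: str
    overlap: int
    term_size: int
    query_size: int
    universe_size: int
    p_value: float
    adjusted_p: float


def fisher_enrichment(query: Sequence[str],
                      term_sets: Dict[str, Sequence[str]],
                      universe: Sequence[str]) -> List[EnrichmentResult]:
    """One-sided over-representation test per term, BH-adjusted across terms.

    ``P(X >= overlap)`` under the hypergeometric null of drawing
    ``|query|`` genes from the universe.
    """
    uni = set(universe)
    q = set(query)
    if not q <= uni:
        raise ValueError("query must be a subset of the universe")
    terms = sorted(term_sets)
    pvals = []
    rows = []
    for term in terms:
        t = set(term_sets[term])
        if not t <= uni:
            raise ValueError(f"term {term!r} is not a subset of the universe")
        overlap = len(q & t)
        # P(X >= overlap), X ~ Hypergeom(M=|U|, K=|t|, n=|q|)
        p = float(stats.hypergeom.sf(overlap - 1, len(uni), len(t), len(q)))
        p = min(1.0, p)
        pvals.append(p)
        rows.append((term, overlap, len(t)))
    if pvals:
        _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
    else:
        adjusted = []
    return [
        EnrichmentResult(term_id=term, overlap=ov, term_size=ts,
                         query_size=len(q), universe_size=len(uni),
                         p_value=p, adjusted_p=float(ap))
        for (term, ov, ts), p, ap in zip(rows, pvals, adjusted)
    ]


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, original order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, adjusted, _, _ = multipletests(p, method="fdr_bh")
    return adjusted


def enrichment_table(results: List[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def write_graphml(graph: nx.Graph, path: str) -> None:
    nx.write_graphml(graph, path)
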