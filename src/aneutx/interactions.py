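"""Co-expression and co-location interaction networks.

Candidate regulatory interactions between differentially expressed noncoding
features (lncRNAs or TE families) and mRNAs are screened two ways:

* co-expression — Pearson correlation of expression profiles across samples,
  kept at |r| > 0.95 and p < 0.05 (two-sided t-transform, n-2 df), retaining
  only pairs whose endpoints are differentially expressed in at least two
  aneuploid comparisons;
* co-location — genomic proximity, same chromosome within a 10 kb window
  between feature spans (bedtools-window semantics; overlap counts as 0 bp).

Edges assemble into a typed undirected network (networkx) with per-node
degrees and connected components as the summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .annotation import TranscriptRecord
from .quantify import CountMatrix

logger = logging.getLogger(__name__)

R_THRESHOLD = 0.95
P_THRESHOLD = 0.05
WINDOW = 10_000


def _pearson_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r between every row of x and every row of y (shared columns)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    xn = np.sqrt((xc ** 2).sum(axis=1, keepdims=True))
    yn = np.sqrt((yc ** 2).sum(axis=1, keepdims=True))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc @ yc.T) / (xn @ yn.T)
    return np.clip(r, -1.0, 1.0)


def coexpression_pairs(
    expr: CountMatrix,
    sources: list[str],
    targets: list[str],
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    samples: list[str] | None = None,
) -> pd.DataFrame:
    """Source-target pairs passing |r| > r_threshold and p < p_threshold.

    Correlation runs across ``samples`` (default: all columns).  Zero-variance
    profiles are skipped with a log message.  Returns a DataFrame
    (source_id, target_id, r, p_value).
    """
    cols = samples or list(expr.values.columns)
    n = len(cols)
    if n < 3:
        raise ValueError("coexpression_pairs: need >= 3 samples")
    sub = expr.values[cols]
    x = sub.loc[sources].to_numpy(dtype=float)
    y = sub.loc[targets].to_numpy(dtype=float)
    r = _pearson_matrix(x, y)
    var0_src = np.isclose(x.std(axis=1), 0.0)
    var0_tgt = np.isclose(y.std(axis=1), 0.0)
    if var0_src.any() or var0_tgt.any():
        logger.info(
            "coexpression_pairs: skipping %d zero-variance profiles",
            int(var0_src.sum() + var0_tgt.sum()),
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isclose(np.abs(r), 1.0), 0.0, p)
    keep = (np.abs(r) > r_threshold) & (p < p_threshold)
    keep &= ~var0_src[:, None] & ~var0_tgt[None, :]
    si, ti = np.nonzero(keep)
    out = pd.DataFrame(
        {
            "source_id": [sources[i] for i in si],
            "target_id": [targets[j] for j in ti],
            "r": r[si, ti],
            "p_value": p[si, ti],
        }
    )
    return out[out["source_id"] != out["target_id"]].reset_index(drop=True)


def shared_pair_filter(
    edges_per_comparison: dict[str, pd.DataFrame], min_comparisons: int = 2
) -> pd.DataFrame:
    """Keep pairs supported in at least ``min_comparisons`` aneuploid comparisons.

    Support means the pair appears in that comparison's edge table (both
    endpoints differentially expressed there).  r and p of the retained edge
    are taken from the first supporting comparison (sorted label order).
    """
    support: dict[tuple[str, str], list[str]] = {}
    stats_: dict[tuple[str, str], tuple[float, float]] = {}
    for name in sorted(edges_per_comparison):
        for row in edges_per_comparison[name].itertuples():
            key = (row.source_id, row.target_id)
            support.setdefault(key, []).append(name)
            stats_.setdefault(key, (row.r, row.p_value))
    rows = [
        (s, t, stats_[(s, t)][0], stats_[(s, t)][1], ",".join(names), len(names))
        for (s, t), names in sorted(support.items())
        if len(names) >= min_comparisons
    ]
    return pd.DataFrame(
        rows,
        columns=["source_id", "target_id", "r", "p_value", "supports", "n_supports"],
    )


def colocated_pairs(
    lncrnas: list[TranscriptRecord],
    mrnas: list[TranscriptRecord],
    window: int = WINDOW,
) -> pd.DataFrame:
    """Same-chromosome lncRNA-mRNA pairs within ``window`` bp of each other.

    Distance is the number of bases strictly between the two spans (0 when
    they overlap); ``side`` is the mRNA's position relative to the lncRNA's
    strand orientation.  Strand plays no role in the distance itself.
    """
    rows = []
    for lnc in lncrnas:
        for m in mrnas:
            if m.chrom != lnc.chrom or m.feature_id == lnc.feature_id:
                continue
            if m.start <= lnc.end and lnc.start <= m.end:
                rows.append((lnc.feature_id, m.feature_id, 0, "overlapping"))
                continue
            if m.end < lnc.start:
                gap = lnc.start - m.end - 1
                side = "upstream" if lnc.strand == "+" else "downstream"
            else:
                gap = m.start - lnc.end - 1
                side = "downstream" if lnc.strand == "+" else "upstream"
            if gap <= window:
                rows.append((lnc.feature_id, m.feature_id, gap, side))
    return pd.DataFrame(rows, columns=["lncRNA_id", "mRNA_id", "distance", "side"])


def build_network(
    edges: pd.DataFrame,
    node_types: dict[str, str],
    node_attrs: pd.DataFrame | None = None,
) -> nx.Graph:
    """Assemble a typed interaction network from an edge table.

    ``edges`` needs source/target columns (source_id/target_id or
    lncRNA_id/mRNA_id); remaining columns become edge attributes.
    ``node_types`` maps node id -> {lncRNA, mRNA, TE_family}; every endpoint
    must be present (dangling endpoints are an error).  ``node_attrs`` can
    carry optional external attributes (e.g. a precomputed PPI degree),
    indexed by node id.
    """
    cols = list(edges.columns)
    if {"source_id", "target_id"}.issubset(cols):
        src_col, tgt_col = "source_id", "target_id"
    elif {"lncRNA_id", "mRNA_id"}.issubset(cols):
        src_col, tgt_col = "lncRNA_id", "mRNA_id"
    else:
        raise ValueError("build_network: no recognizable endpoint columns")
    g = nx.Graph()
    for row in edges.to_dict("records"):
        s, t = row.pop(src_col), row.pop(tgt_col)
        if s == t:
            raise ValueError(f"build_network: self-loop at {s}")
        for node in (s, t):
            if node not in node_types:
                raise ValueError(f"build_network: dangling endpoint {node}")
        g.add_node(s, type=node_types[s])
        g.add_node(t, type=node_types[t])
        g.add_edge(s, t, **row)
    if node_attrs is not None:
        for node, attrs in node_attrs.iterrows():
            if node in g:
                g.nodes[node].update(attrs.to_dict())
    return g


def network_summary(g: nx.Graph, top_k: int = 10) -> dict:
    """Node/edge counts by type, degree ranking and connected components."""
    by_type: dict[str, int] = {}
    for _, t in g.nodes(data="type"):
        by_type[t] = by_type.get(t, 0) + 1
    degrees = sorted(g.degree, key=lambda kv: (-kv[1], kv[0]))
    components = sorted((sorted(c) for c in nx.connected_components(g)), key=len, reverse=True)
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "nodes_by_type": by_type,
        "top_degree": degrees[:top_k],
        "n_components": len(components),
        "component_sizes": [len(c) for c in components],
    }


def write_network(g: nx.Graph, prefix: str | Path) -> None:
    """Export the network as GraphML plus node and edge TSVs."""
    prefix = Path(prefix)
    nx.write_graphml(g, prefix.with_suffix(".graphml"))
    nodes = pd.DataFrame(
        [{"node_id": n, **attrs} for n, attrs in g.nodes(data=True)]
    )
    edges = pd.DataFrame(
        [{"source_id": u, "target_id": v, **attrs} for u, v, attrs in g.edges(data=True)]
    )
    nodes.to_csv(prefix.parent / (prefix.name + ".nodes.tsv"), sep="\t", index=False)
    edges.to_csv(prefix.parent / (prefix.name + ".edges.tsv"), sep="\t", index=False)
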