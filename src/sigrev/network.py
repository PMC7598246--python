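"""Drug-target protein-protein interaction network analysis.

Builds a confidence-thresholded PPI graph from a STRING-style scored edge
list, computes per-node metrics (degree, local clustering, eigenvector
centrality, greedy-modularity community), tests edge-count enrichment
against a binomial background, selects the most central genes, and compares
alteration frequencies between patient groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import DegenerateInputError, FormatError, InvalidConfigError

__all__ = [
    "build_graph",
    "node_metrics",
    "eigencentrality",
    "ppi_enrichment",
    "top_central",
    "alteration_frequency",
]

DEFAULT_CHANNELS = ("experiments", "database", "neighborhood", "fusion")


def build_graph(targets: Iterable[str], edge_list: pd.DataFrame,
                threshold: float = 700,
                channels: Sequence[str] | None = None) -> nx.Graph:
    """Induced PPI graph around target genes from a scored edge list.

    ``edge_list`` columns: protein1, protein2, combined_score (0-1000) and
    optionally one column per evidence channel.  Edges are kept when
    combined_score >= threshold (the 0.700-and-above convention, inclusive)
    and, if channel columns exist, at least one allowed channel is non-zero.
    The graph is the union of retained edges touching a target gene, plus
    all target genes as (possibly isolated) nodes.
    """
    if threshold < 0:
        raise InvalidConfigError("threshold must be non-negative")
    required = {"protein1", "protein2", "combined_score"}
    if not required <= set(edge_list.columns):
        raise FormatError(f"edge list needs columns {sorted(required)}")
    channels = tuple(channels) if channels is not None else DEFAULT_CHANNELS
    chan_cols = [c for c in channels if c in edge_list.columns]

    targets = set(targets)
    g = nx.Graph()
    g.add_nodes_from(sorted(targets))
    for i, row in enumerate(edge_list.itertuples(index=False)):
        a, b, score = row.protein1, row.protein2, row.combined_score
        try:
            score = float(score)
        except (TypeError, ValueError):
            raise FormatError(f"edge list row {i}: non-numeric score {score!r}")
        if a == b or score < threshold:
            continue
        if chan_cols and not any(float(getattr(row, c)) > 0 for c in chan_cols):
            continue
        if a in targets or b in targets:
            g.add_edge(a, b, combined_score=score)
    return g


def eigencentrality(g: nx.Graph, tol: float = 1e-10, max_iter: int = 1000) -> dict:
    """Leading-eigenvector centrality by power iteration, normalized so the
    maximum entry within each connected component is 1."""
    cent: dict = {}
    for comp in nx.connected_components(g):
        nodes = sorted(comp)
        if len(nodes) == 1:
            cent[nodes[0]] = 1.0
            continue
        a = nx.to_numpy_array(g, nodelist=nodes)
        # iterate on A + I: same Perron vector on a connected component, but
        # immune to the +/-lambda oscillation of bipartite spectra
        a = a + np.eye(len(nodes))
        x = np.ones(len(nodes)) / np.sqrt(len(nodes))
        for _ in range(max_iter):
            x_new = a @ x
            norm = np.linalg.norm(x_new)
            if norm == 0:
                break
            x_new /= norm
            if np.linalg.norm(x_new - x) < tol:
                x = x_new
                break
            x = x_new
        else:
            raise DegenerateInputError(
                f"power iteration did not converge in {max_iter} iterations "
                f"(component of {len(nodes)} nodes, last iterate norm-change > {tol})")
        x = np.abs(x)
        x /= x.max()
        cent.update(dict(zip(nodes, x)))
    return cent


def _communities(g: nx.Graph) -> dict:
    """Greedy modularity communities; deterministic ids by smallest member."""
    if g.number_of_edges() == 0:
        return {n: i for i, n in enumerate(sorted(g.nodes))}
    comms = nx.algorithms.community.greedy_modularity_communities(g)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    out = {}
    for i, members in enumerate(comms):
        for n in members:
            out[n] = i
    return out


def node_metrics(g: nx.Graph) -> pd.DataFrame:
    """Degree, local clustering coefficient, eigenvector centrality and
    community id for every node."""
    if g.number_of_nodes() == 0:
        raise InvalidConfigError("empty graph")
    cent = eigencentrality(g)
    clustering = nx.clustering(g)
    comm = _communities(g)
    rows = {
        n: {
            "degree": g.degree(n),
            "clustering": clustering[n],
            "eigencentrality": cent[n],
            "community": comm[n],
        }
        for n in g.nodes
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "gene"
    return df.sort_index()


def ppi_enrichment(g: nx.Graph, background_density: float) -> float:
    """Binomial-tail p-value for observing at least the graph's edge count.

    Under the null each of the C(|V|, 2) pairs is an edge independently with
    probability ``background_density``; p = P(X >= observed edges).
    """
    if not 0 < background_density <= 1:
        if background_density == 0:
            if g.number_of_edges() > 0:
                warnings.warn("zero background density with observed edges", stacklevel=2)
                return 0.0
            return 1.0
        raise InvalidConfigError("background density must lie in (0, 1]")
    n_pairs = comb(g.number_of_nodes(), 2)
    observed = g.number_of_edges()
    if observed == 0:
        return 1.0
    return float(stats.binom.sf(observed - 1, n_pairs, background_density))


def top_central(metrics: pd.DataFrame, k: int = 100) -> list[str]:
    """Top-k genes by eigencentrality; ties broken by degree then gene id."""
    if k > len(metrics):
        warnings.warn(f"k={k} exceeds node count {len(metrics)}; returning all",
                      stacklevel=2)
        k = len(metrics)
    ordered = sorted(
        metrics.index,
        key=lambda g: (-metrics.at[g, "eigencentrality"], -metrics.at[g, "degree"], g),
    )
    return ordered[:k]


def alteration_frequency(patients: Mapping[str, set], genes: Sequence[str],
                         groups: Mapping[str, str]) -> dict[str, float]:
    """Per-group fraction of patients with >=1 altered gene from the list.

    ``patients`` maps patient id -> set of altered genes; ``groups`` maps
    patient id -> group label.
    """
    if not set(patients) <= set(groups):
        raise InvalidConfigError("groups do not cover all patients")
    gene_set = set(genes)
    tally: dict[str, list[int]] = {}
    for pid, altered in patients.items():
        hit = int(bool(altered & gene_set))
        tally.setdefault(groups[pid], []).append(hit)
    out = {}
    for level, hits in tally.items():
        if not hits:
            raise DegenerateInputError(f"group {level!r} is empty")
        out[level] = float(np.mean(hits))
    return out
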