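"""Correlation-profile clustering and pathogenic/commensal co-abundance networks.

Taxa are clustered by their factor-correlation profiles (hierarchical,
complete linkage, Euclidean distance) into three clusters ordered by mean
correlation with the nine factors (III strongest, I weakest).  The pathogenic
network keeps taxa significant (p < 0.001) against all nine factors, chooses
a correlation threshold so that roughly twenty species survive, connects
pairs with r >= 0.6, and reports "constellations": maximal cliques of at
least four taxa.  The commensal network instead keeps taxa that are *not*
associated with most factors and draws signed edges for |r| > 0.1, p < 0.05.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from .rmcorr import CorrelationScreen

__all__ = [
    "ConstellationNetwork",
    "cluster_taxa",
    "select_pathogenic",
    "build_network",
    "find_constellations",
    "expand_constellations",
    "select_commensal",
    "build_commensal_network",
    "is_numeric_name",
]

# placeholder identifiers from the profiler (genome/species bins, OTU-style
# labels) rather than Linnaean names; kept out of the networks
_NUMERIC_NAME = re.compile(
    r"(^|_)(GGB\d+|SGB\d+|OTU\d+|ASV\d+)($|_)|^bacterium([_ ]|$)|_bacterium_\d"
)


def is_numeric_name(name: str) -> bool:
    """True if a taxon is identified only by a numerical/bin identifier."""
    return bool(_NUMERIC_NAME.search(name))


@dataclass
class ConstellationNetwork:
    """Undirected weighted graph over taxa (and optionally factors)."""

    graph: nx.Graph
    constellations: list[tuple[str, ...]] = field(default_factory=list)
    edge_threshold: float = 0.6

    @property
    def taxa(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("type") == "taxon"]

    def audit_constellations(self) -> bool:
        """Independent pairwise check that every constellation is a clique."""
        for clique in self.constellations:
            for i, a in enumerate(clique):
                for b in clique[i + 1 :]:
                    if not self.graph.has_edge(a, b):
                        return False
                    if self.graph.edges[a, b]["r"] < self.edge_threshold - 1e-12:
                        return False
        return True

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)

    def to_edgelist_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\tr\tsign\n")
            for u, v, d in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{d['r']:.6g}\t{d.get('sign', 1)}\n")


def cluster_taxa(
    screen: CorrelationScreen,
    n_clusters: int = 3,
    metric: str = "euclidean",
    method: str = "complete",
) -> pd.Series:
    """Hierarchical clustering of taxa by factor-correlation profile.

    Returns roman-numeral labels ("I".."III" for the default three clusters)
    ordered so the cluster with the highest mean correlation to the factors
    is the last numeral and the lowest the first.
    """
    r = screen.r.dropna(axis=0, how="any")
    if len(r) < n_clusters:
        raise ValueError(f"need at least {n_clusters} taxa, got {len(r)}")
    Z = linkage(pdist(r.to_numpy(float), metric=metric), method=method)
    raw = fcluster(Z, t=n_clusters, criterion="maxclust")
    means = {c: r.to_numpy(float)[raw == c].mean() for c in np.unique(raw)}
    ordered = sorted(means, key=means.get)
    numerals = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    label_of = {c: numerals[rank] for rank, c in enumerate(ordered)}
    return pd.Series([label_of[c] for c in raw], index=r.index, name="cluster")


def select_pathogenic(
    screen: CorrelationScreen,
    p_threshold: float = 0.001,
    target_n: int = 20,
    edge_threshold_grid: np.ndarray | None = None,
) -> tuple[list[str], float]:
    """Taxa significantly associated with all nine factors, thresholded to ~20.

    Among named taxa with p < ``p_threshold`` for every factor, scan
    correlation thresholds on a 0.01 grid and keep the threshold whose count
    of taxa (minimum r across factors strictly above it) is closest to
    ``target_n``; ties break toward the larger threshold (fewer taxa).
    """
    named = [t for t in screen.taxa if not is_numeric_name(str(t))]
    r = screen.r.loc[named]
    p = screen.p.loc[named]
    passed = r.index[(p < p_threshold).all(axis=1)]
    if len(passed) == 0:
        import warnings

        warnings.warn("no taxon passes the p-value filter; empty pathogenic set")
        return [], float("nan")
    min_r = r.loc[passed].min(axis=1)
    grid = (
        np.round(np.arange(0.0, 1.0 + 1e-9, 0.01), 2)
        if edge_threshold_grid is None
        else np.asarray(edge_threshold_grid)
    )
    best_thr, best_gap = None, None
    for thr in grid:
        count = int((min_r > thr).sum())
        gap = abs(count - target_n)
        if best_gap is None or gap < best_gap or (gap == best_gap):
            # equal gap at a larger threshold wins (grid ascends)
            if best_gap is None or gap <= best_gap:
                best_thr, best_gap = float(thr), gap
    chosen = min_r.index[min_r > best_thr].tolist()
    return chosen, best_thr


def build_network(
    taxon_r: pd.DataFrame,
    edge_threshold: float = 0.6,
    screen: CorrelationScreen | None = None,
    include_factors: bool = False,
    clusters: pd.Series | None = None,
) -> ConstellationNetwork:
    """Thresholded co-abundance network: edge iff r >= ``edge_threshold``.

    ``taxon_r`` is the symmetric taxon-taxon repeated-measures correlation
    matrix.  Factor nodes (with taxon-factor edges from ``screen``) are added
    when ``include_factors`` is set.
    """
    if not taxon_r.index.equals(taxon_r.columns):
        raise ValueError("taxon-taxon matrix must be square with matching labels")
    A = taxon_r.to_numpy(float)
    if np.nanmax(np.abs(A - A.T)) > 1e-8:
        raise ValueError("taxon-taxon correlation matrix is not symmetric")
    g = nx.Graph()
    taxa = list(taxon_r.index)
    for t in taxa:
        g.add_node(t, type="taxon")
        if clusters is not None and t in clusters.index:
            g.nodes[t]["cluster"] = str(clusters[t])
    for i, a in enumerate(taxa):
        for j in range(i + 1, len(taxa)):
            r = A[i, j]
            if np.isfinite(r) and r >= edge_threshold:
                g.add_edge(a, taxa[j], r=float(r), sign=1)
    if include_factors:
        if screen is None:
            raise ValueError("include_factors requires a taxon-factor screen")
        for f in screen.factors:
            g.add_node(str(f), type="factor")
        sub = screen.r.reindex(index=taxa)
        for t in taxa:
            for f in screen.factors:
                r = sub.at[t, f]
                if np.isfinite(r) and r >= edge_threshold:
                    g.add_edge(t, str(f), r=float(r), sign=1)
    net = ConstellationNetwork(g, edge_threshold=edge_threshold)
    net.constellations = find_constellations(net)
    return net


def find_constellations(
    network: ConstellationNetwork, min_size: int = 4
) -> list[tuple[str, ...]]:
    """Maximal cliques of at least ``min_size`` taxa, largest first."""
    sub = network.graph.subgraph(network.taxa)
    cliques = [tuple(sorted(c)) for c in nx.find_cliques(sub) if len(c) >= min_size]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques


def expand_constellations(
    core_taxa,
    screen_r: pd.DataFrame,
    screen_p: pd.DataFrame,
    r_threshold: float = 0.5,
    p_threshold: float = 0.05,
) -> dict[str, list[str]]:
    """Taxa attached to a constellation core: r >= 0.5 and p < 0.05 with any member.

    ``screen_r``/``screen_p`` are taxon-taxon matrices.  Associated taxa are
    reported per core member union; they are not added to the clique.
    """
    core = [t for t in core_taxa if t in screen_r.index]
    out: dict[str, list[str]] = {}
    for member in core:
        r = screen_r[member].drop(index=core, errors="ignore")
        p = screen_p[member].drop(index=core, errors="ignore")
        hits = r.index[(r >= r_threshold) & (p < p_threshold)]
        out[member] = sorted(str(h) for h in hits if not is_numeric_name(str(h)))
    return out


def select_commensal(
    screen: CorrelationScreen,
    criterion: str = "p_gt_0.05",
    min_factors: int = 6,
) -> list[str]:
    """Taxa not tied to disease: meeting ``criterion`` for >= ``min_factors`` of nine.

    ``"p_gt_0.05"`` keeps taxa with non-significant correlations (p > 0.05);
    ``"negative_r"`` keeps taxa with negative correlation coefficients.
    """
    named = [t for t in screen.taxa if not is_numeric_name(str(t))]
    if criterion == "p_gt_0.05":
        hits = (screen.p.loc[named] > 0.05).sum(axis=1)
    elif criterion == "negative_r":
        hits = (screen.r.loc[named] < 0).sum(axis=1)
    else:
        raise ValueError(f"unknown commensal criterion: {criterion!r}")
    return hits.index[hits >= min_factors].tolist()


def build_commensal_network(
    taxon_r: pd.DataFrame,
    taxon_p: pd.DataFrame,
    edge_threshold: float = 0.1,
    p_threshold: float = 0.05,
) -> ConstellationNetwork:
    """Signed network over commensal taxa: edge iff |r| > 0.1 and p < 0.05."""
    if not taxon_r.index.equals(taxon_r.columns):
        raise ValueError("taxon-taxon matrix must be square with matching labels")
    g = nx.Graph()
    taxa = list(taxon_r.index)
    for t in taxa:
        g.add_node(t, type="taxon")
    R = taxon_r.to_numpy(float)
    P = taxon_p.to_numpy(float)
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            r, p = R[i, j], P[i, j]
            if np.isfinite(r) and abs(r) > edge_threshold and p < p_threshold:
                g.add_edge(taxa[i], taxa[j], r=float(r), sign=1 if r > 0 else -1)
    return ConstellationNetwork(g, constellations=[], edge_threshold=edge_threshold)
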