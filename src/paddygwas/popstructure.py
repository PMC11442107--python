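"""Population-structure diagnostics for an inbred diversity panel.

PCA on mean-imputed centred dosages, a Euclidean-distance neighbor-joining
tree with marker-bootstrap support, deterministic varietal-group cutting of
the tree, and geographic observed/expected enrichment of the groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import TreeNode, nj

from .variants import GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    """Scores (accession x component), eigenvalues of the accession
    covariance, and per-component contribution ratios (fractions of total
    variance; they sum to <= 1 over the computed components)."""

    scores: np.ndarray
    eigenvalues: np.ndarray
    contribution_ratios: np.ndarray


def pca(G: GenotypeMatrix, n_components: int = 10, scale: bool = False) -> PCAResult:
    """PCA of the dosage matrix.

    Missing dosages are mean-imputed per marker and columns centred (and
    optionally scaled to unit variance) before the eigendecomposition; the
    contribution ratio of component k is its eigenvalue over the total
    variance of the centred matrix.
    """
    if G.n_accessions < 2 or G.n_markers < 1:
        raise ValueError("need at least 2 accessions and 1 marker")
    if np.any(np.all(np.isnan(G.dosage), axis=0)):
        raise ValueError("all-missing marker present; filter markers first")
    X = G.imputed()
    X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd > 0, sd, 1.0)
    n_components = min(n_components, G.n_accessions - 1, G.n_markers)
    # SVD of the centred matrix == eigendecomposition of the covariance
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    eig = s**2 / (G.n_accessions - 1)
    total = X.var(axis=0, ddof=1).sum()
    scores = U[:, :n_components] * s[:n_components]
    return PCAResult(
        scores=scores,
        eigenvalues=eig[:n_components],
        contribution_ratios=eig[:n_components] / total,
    )


def euclidean_distance_matrix(
    G: GenotypeMatrix,
    marker_subset_size: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise Euclidean distances over mean-imputed dosage vectors.

    Markers are subsampled uniformly without replacement when
    ``marker_subset_size`` is given (the convention for reducing redundancy
    before tree building). Returns (distance matrix, subsampled marker
    indices).
    """
    if marker_subset_size is not None and marker_subset_size > G.n_markers:
        raise ValueError("marker_subset_size exceeds marker count")
    rng = np.random.default_rng(seed)
    if marker_subset_size is None:
        idx = np.arange(G.n_markers)
    else:
        idx = np.sort(rng.choice(G.n_markers, size=marker_subset_size, replace=False))
    X = G.imputed()[:, idx]
    D = squareform(pdist(X, metric="euclidean"))
    return D, idx


def neighbor_joining(D: np.ndarray, ids: list[str]) -> TreeNode:
    """Saitou–Nei neighbor joining on a symmetric distance matrix.

    Returns an unrooted tree (scikit-bio TreeNode, arbitrarily rooted for
    representation) whose leaves are ``ids``.
    """
    D = np.asarray(D, dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T):
        raise ValueError("distance matrix must be square and symmetric")
    if np.any(np.diag(D) != 0):
        raise ValueError("distance matrix diagonal must be zero")
    if D.shape[0] < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    return nj(DistanceMatrix(D, ids))


def _bipartitions(tree: TreeNode, ref: str) -> dict[frozenset, TreeNode]:
    """Non-trivial bipartitions keyed by the side NOT containing ``ref``.

    Each internal edge of the unrooted tree splits the leaves in two; the
    side without the reference taxon is a canonical key.
    """
    all_leaves = frozenset(l.name for l in tree.tips())
    out: dict[frozenset, TreeNode] = {}
    for node in tree.non_tips(include_self=False):
        below = frozenset(l.name for l in node.tips())
        side = below if ref not in below else all_leaves - below
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[side] = node
    return out


def bootstrap_support(
    G: GenotypeMatrix,
    tree: TreeNode,
    n_reps: int,
    marker_subset_size: int | None = None,
    seed: int = 0,
) -> TreeNode:
    """Marker-bootstrap support counts for the internal edges of ``tree``.

    Each replicate resamples marker columns with replacement (the same count
    as the subsample used for the tree), recomputes the Euclidean distance
    matrix and NJ tree, and tallies which original bipartitions reappear.
    Support counts (0..n_reps) are written to ``node.support`` on the
    original tree, which is returned.
    """
    leaf_names = sorted(l.name for l in tree.tips())
    if leaf_names != sorted(G.accession_ids):
        raise ValueError("tree leaves do not match accessions")
    ref = leaf_names[0]
    orig = _bipartitions(tree, ref)
    counts = {k: 0 for k in orig}
    rng = np.random.default_rng(seed)
    m = marker_subset_size if marker_subset_size is not None else G.n_markers
    X = G.imputed()
    for _ in range(n_reps):
        cols = rng.integers(0, G.n_markers, size=m)
        D = squareform(pdist(X[:, cols], metric="euclidean"))
        rep = nj(DistanceMatrix(D, list(G.accession_ids)))
        for bip in _bipartitions(rep, ref):
            if bip in counts:
                counts[bip] += 1
    for bip, node in orig.items():
        node.support = counts[bip]
    return tree


def cut_tree_groups(tree: TreeNode, k: int) -> pd.Series:
    """Cut the tree into ``k`` varietal groups by removing the k-1 longest
    internal edges.

    Ties are broken by a deterministic edge ordering (sorted leaf-name tuple
    below the edge). Connected leaf components become groups labelled
    VG1..VGk in decreasing size order. Returns accession -> label.
    """
    import networkx as nx

    leaves = [l.name for l in tree.tips()]
    if not (1 <= k <= len(leaves)):
        raise ValueError("k out of range")
    g = nx.Graph()
    ids = {}
    for i, node in enumerate(tree.traverse(include_self=True)):
        ids[id(node)] = i
        g.add_node(i, name=node.name if node.is_tip() else None)
    internal_edges = []
    for node in tree.traverse(include_self=False):
        u, v = ids[id(node.parent)], ids[id(node)]
        g.add_edge(u, v)
        if not node.is_tip() and node.parent is not None:
            length = node.length if node.length is not None else 0.0
            tiebreak = tuple(sorted(l.name for l in node.tips()))
            internal_edges.append((length, tiebreak, (u, v)))
    if k - 1 > len(internal_edges):
        raise ValueError(f"cannot cut {k} groups: only {len(internal_edges)} internal edges")
    internal_edges.sort(key=lambda t: (-t[0], t[1]))
    for _, _, (u, v) in internal_edges[: k - 1]:
        g.remove_edge(u, v)
    comps = []
    for comp in nx.connected_components(g):
        members = sorted(
            g.nodes[i]["name"] for i in comp if g.nodes[i]["name"] is not None
        )
        if members:
            comps.append(members)
    comps.sort(key=lambda ms: (-len(ms), ms[0]))
    labels = {}
    for gi, members in enumerate(comps, start=1):
        for a in members:
            labels[a] = f"VG{gi}"
    return pd.Series(labels, name="group").loc[leaves]


def region_enrichment(groups: pd.Series, origins: pd.DataFrame) -> pd.DataFrame:
    """Observed/expected geographic enrichment per (group, region).

    Expected counts are the contingency-margin product
    ``group_total * region_total / grand_total``; each group is assigned the
    region with the largest O/E ratio (ties: larger observed, then
    lexicographic region label). Returns the long-format table with an
    ``assigned`` flag.
    """
    origin_map = origins.set_index("accession_id")["region"]
    common = groups.index.intersection(origin_map.index)
    dropped = len(groups) - len(common)
    if dropped:
        logger.info("region_enrichment: dropped %d accessions without origins", dropped)
    if len(common) == 0:
        raise ValueError("no accessions shared between groups and origins")
    df = pd.DataFrame({"group": groups.loc[common], "region": origin_map.loc[common]})
    obs = pd.crosstab(df["group"], df["region"])
    grand = obs.to_numpy().sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / grand
    rows = []
    for gi, group in enumerate(obs.index):
        cand = []
        for ri, region in enumerate(obs.columns):
            o, e = int(obs.iloc[gi, ri]), float(expected[gi, ri])
            ratio = o / e if e > 0 else 0.0
            cand.append((region, o, e, ratio))
        assigned = sorted(cand, key=lambda t: (-t[3], -t[1], t[0]))[0][0]
        for region, o, e, ratio in cand:
            rows.append(
                {
                    "group": group,
                    "region": region,
                    "observed": o,
                    "expected": e,
                    "oe_ratio": ratio,
                    "assigned": region == assigned,
                }
            )
    return pd.DataFrame(rows)
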