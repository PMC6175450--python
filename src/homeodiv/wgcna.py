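"""Lightweight weighted co-expression module detection.

A self-contained re-implementation of the standard weighted co-expression
workflow at the configuration used here: soft-threshold adjacency
a_ij = |cor(x_i, x_j)|^beta with beta = 30, topological overlap similarity,
average-linkage clustering of 1 - TOM with a static tree cut, a minimum
module size of 30, and iterative merging of modules whose eigengenes are
highly correlated.  Profiles are typically pre-cluster mean vectors (the
network clusters clusters); genes inherit the module of their pre-cluster.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

log = logging.getLogger(__name__)

UNASSIGNED = -1


@dataclass
class CoexpressionNetwork:
    node_ids: list[str]
    adjacency: np.ndarray
    tom: np.ndarray | None = None


@dataclass
class ModuleSet:
    node_ids: list[str]
    labels: np.ndarray                       # module index per node, -1 unassigned
    eigengenes: dict[int, np.ndarray] = field(default_factory=dict)

    def members(self, label: int) -> list[str]:
        return [n for n, l in zip(self.node_ids, self.labels) if l == label]

    @property
    def module_labels(self) -> list[int]:
        return sorted({int(l) for l in self.labels if l != UNASSIGNED})


def soft_adjacency(
    profiles: np.ndarray,
    node_ids: list[str] | None = None,
    beta: float = 30.0,
    signed: bool = False,
) -> CoexpressionNetwork:
    """Soft-threshold correlation adjacency.

    Unsigned (default): a_ij = |cor(x_i, x_j)|^beta; signed:
    a_ij = ((1 + cor)/2)^beta.  Diagonal is set to 1 by convention.
    Zero-variance profiles cannot be correlated and are excluded.
    """
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 profiles")
    if node_ids is None:
        node_ids = [f"n{i}" for i in range(X.shape[0])]
    ok = X.std(axis=1) > 0
    if np.any(~ok):
        dropped = [n for n, o in zip(node_ids, ok) if not o]
        log.warning("excluding %d zero-variance profile(s): %s", len(dropped), dropped[:5])
        X = X[ok]
        node_ids = [n for n, o in zip(node_ids, ok) if o]
    cor = np.corrcoef(X)
    a = ((1 + cor) / 2) ** beta if signed else np.abs(cor) ** beta
    np.fill_diagonal(a, 1.0)
    a = (a + a.T) / 2  # enforce exact symmetry
    return CoexpressionNetwork(node_ids=list(node_ids), adjacency=a)


def topological_overlap(adjacency: np.ndarray) -> np.ndarray:
    """Topological overlap similarity.

    TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij) with
    connectivity k_i = sum_{u != i} a_iu; TOM_ii = 1.  The numerator's sum
    runs over u distinct from both i and j.
    """
    a = np.asarray(adjacency, dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    # with a zeroed diagonal the u == i and u == j terms vanish, so this is
    # exactly sum over shared neighbours u distinct from i and j
    shared = a @ a
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        tom = (shared + a) / (kmin + 1.0 - a)
    tom = np.nan_to_num(tom, nan=0.0)
    np.fill_diagonal(tom, 1.0)
    return (tom + tom.T) / 2


def _eigengene(profiles: np.ndarray) -> np.ndarray:
    """First principal component of member profiles over timepoints,
    sign-oriented so the mean correlation with members is positive."""
    X = np.asarray(profiles, dtype=float)
    Z = (X - X.mean(axis=1, keepdims=True))
    s = Z.std(axis=1)
    s[s == 0] = 1.0
    Z = Z / s[:, None]
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    pc = vt[0]
    cors = Z @ pc / (np.linalg.norm(pc) * np.sqrt(Z.shape[1]))
    if cors.mean() < 0:
        pc = -pc
    return pc


def detect_modules(
    network: CoexpressionNetwork,
    profiles: np.ndarray,
    min_size: int = 30,
    merge_correlation: float = 0.75,
    cut_height_quantile: float = 0.99,
) -> ModuleSet:
    """Average-linkage clustering of 1 - TOM with a static cut.

    Clusters smaller than ``min_size`` stay unassigned.  Module eigengenes
    (first PCs of member profiles) drive iterative merging: while any two
    modules have eigengene correlation >= ``merge_correlation``, the most
    correlated pair is merged; the count is monotonically non-increasing,
    so the loop reaches a fixed point.
    """
    tom = network.tom if network.tom is not None else topological_overlap(network.adjacency)
    network.tom = tom
    dissim = 1.0 - tom
    np.fill_diagonal(dissim, 0.0)
    n = dissim.shape[0]
    if n < 2:
        raise ValueError("need at least 2 nodes")
    Z = linkage(squareform(dissim, checks=False), method="average")
    heights = Z[:, 2]
    cut = float(np.quantile(heights, cut_height_quantile))
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = np.full(n, UNASSIGNED, dtype=int)
    next_label = 0
    for lab in np.unique(raw):
        idx = np.where(raw == lab)[0]
        if len(idx) >= min_size:
            labels[idx] = next_label
            next_label += 1
    if next_label == 0:
        log.warning("no module reached min_size=%d; all nodes unassigned", min_size)
        return ModuleSet(network.node_ids, labels)

    profiles = np.asarray(profiles, dtype=float)
    eig = {l: _eigengene(profiles[labels == l]) for l in range(next_label)}
    while len(eig) > 1:
        labs = sorted(eig)
        E = np.vstack([eig[l] for l in labs])
        C = np.corrcoef(E)
        np.fill_diagonal(C, -np.inf)
        i, j = np.unravel_index(np.argmax(C), C.shape)
        if C[i, j] < merge_correlation:
            break
        keep, drop = sorted((labs[i], labs[j]))
        labels[labels == drop] = keep
        eig.pop(drop)
        eig[keep] = _eigengene(profiles[labels == keep])
    # relabel compactly, ordered by first occurrence
    remap: dict[int, int] = {}
    out = np.full(n, UNASSIGNED, dtype=int)
    for pos, l in enumerate(labels):
        if l == UNASSIGNED:
            continue
        if l not in remap:
            remap[l] = len(remap)
        out[pos] = remap[l]
    eigengenes = {remap[l]: v for l, v in eig.items()}
    return ModuleSet(network.node_ids, out, eigengenes)


def genes_to_modules(
    gene_ids: list[str],
    precluster_labels: np.ndarray,
    modules: ModuleSet,
) -> pd.Series:
    """Gene -> module label via the gene's pre-cluster node.

    Pre-cluster c is assumed to be node ``modules.node_ids[c]``; genes in
    unassigned pre-clusters inherit ``UNASSIGNED``.
    """
    node_label = {nid: lab for nid, lab in zip(modules.node_ids, modules.labels)}
    vals = []
    for g, c in zip(gene_ids, precluster_labels):
        vals.append(int(node_label.get(f"c{c}", UNASSIGNED)))
    return pd.Series(vals, index=gene_ids, dtype=int)


def same_module_fraction(
    gene_modules: pd.Series,
    families: dict[str, list[str]],
) -> tuple[float, pd.DataFrame]:
    """Fraction of families whose expressed copies all share one module.

    ``gene_modules`` maps gene -> module label; genes missing a module are
    counted as their own singleton modules.  Families with < 2 genes
    present are ignored.  Returns (null-consistent fraction, per-family
    table with n copies and n distinct modules).
    """
    rows = []
    singleton = -1000
    for ref, members in sorted(families.items()):
        present = [g for g in members if g in gene_modules.index]
        if len(present) < 2:
            continue
        mods = []
        for g in present:
            m = int(gene_modules[g])
            if m == UNASSIGNED:
                singleton -= 1
                m = singleton
                log.debug("gene %s has no module; counted as singleton", g)
            mods.append(m)
        rows.append((ref, len(present), len(set(mods))))
    table = pd.DataFrame(rows, columns=["reference_gene_id", "n_expressed_copies", "n_distinct_modules"])
    if table.empty:
        return float("nan"), table
    frac = float((table["n_distinct_modules"] == 1).mean())
    return frac, table
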