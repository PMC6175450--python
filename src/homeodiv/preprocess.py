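"""Trace normalization and variance-explained pre-clustering.

Expression traces are z-normalized per gene so that clustering compares
temporal shape rather than absolute abundance.  The between-cluster /
total sum-of-squares ratio

    r(H) = sum_c N_c ||xbar_c - xbar||^2 / sum_g ||x_g - xbar||^2

measures how well H cluster means represent the trace set; it drives both
the hierarchical pre-clustering used to compress the data before network
analysis (target ratio 0.98) and the choice of self-organizing-map size
(target ratio 0.85).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage

log = logging.getLogger(__name__)


@dataclass
class ExpressionSeries:
    """One gene's expression trace in one tissue.

    ``fpkm_sd`` is the per-timepoint measurement uncertainty expressed as a
    standard deviation in FPKM units.
    """

    gene_id: str
    tissue: str
    days: np.ndarray
    fpkm: np.ndarray
    fpkm_sd: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.fpkm = np.asarray(self.fpkm, dtype=float)
        self.fpkm_sd = np.asarray(self.fpkm_sd, dtype=float)
        if not (len(self.days) == len(self.fpkm) == len(self.fpkm_sd)):
            raise ValueError("days, fpkm and fpkm_sd must have equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.fpkm_sd < 0):
            raise ValueError("fpkm_sd must be non-negative")


@dataclass
class ClusterAssignment:
    """Gene -> cluster labels plus per-cluster mean vectors."""

    gene_ids: list[str]
    labels: np.ndarray          # int label per gene, 0-based
    means: np.ndarray           # (n_clusters, n_timepoints)
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.bincount(self.labels, minlength=self.means.shape[0])

    @property
    def n_clusters(self) -> int:
        return self.means.shape[0]


def znormalize_matrix(
    X: np.ndarray, sd: np.ndarray | None = None, ddof: int = 0
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Z-normalize each row to mean 0, variance 1 (population variance).

    Returns ``(Z, sd_scaled, ok)`` where ``ok`` flags rows with non-zero
    variance; constant rows cannot be normalized and are returned as NaN
    with ``ok`` False.  Uncertainty rows are rescaled by the same factor as
    the trace.
    """
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=1, keepdims=True)
    s = X.std(axis=1, ddof=ddof, keepdims=True)
    ok = (s[:, 0] > 0) & np.isfinite(s[:, 0])
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = (X - mu) / s
    Z[~ok] = np.nan
    sd_scaled = None
    if sd is not None:
        with np.errstate(divide="ignore", invalid="ignore"):
            sd_scaled = np.asarray(sd, dtype=float) / s
        sd_scaled[~ok] = np.nan
    if np.any(~ok):
        log.warning("excluded %d constant trace(s) from normalization", int((~ok).sum()))
    return Z, sd_scaled, ok


def znormalize(series: ExpressionSeries, ddof: int = 0) -> ExpressionSeries:
    """Z-normalize one trace; raises on a constant trace."""
    Z, sd_scaled, ok = znormalize_matrix(
        series.fpkm[None, :], series.fpkm_sd[None, :], ddof=ddof
    )
    if not ok[0]:
        raise ValueError(f"constant trace cannot be normalized: {series.gene_id}")
    return ExpressionSeries(series.gene_id, series.tissue, series.days, Z[0], sd_scaled[0])


def variance_explained_ratio(labels: np.ndarray, X: np.ndarray) -> float:
    """Between-cluster over total sum of squares of trace vectors.

    0 when all genes share one cluster, 1 when every cluster is a single
    gene (or clusters are internally constant).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if X.shape[0] == 0:
        raise ValueError("no data")
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels must cover the data")
    xbar = X.mean(axis=0)
    tss = float(((X - xbar) ** 2).sum())
    if tss == 0:
        return 1.0
    bss = 0.0
    for lab in np.unique(labels):
        member = X[labels == lab]
        bss += member.shape[0] * float(((member.mean(axis=0) - xbar) ** 2).sum())
    return bss / tss


def hierarchical_precluster(
    X: np.ndarray,
    gene_ids: list[str] | None = None,
    target_ratio: float = 0.98,
) -> ClusterAssignment:
    """Complete-linkage Euclidean pre-clustering cut at the smallest H
    whose variance-explained ratio reaches ``target_ratio``.

    The returned cluster means stand in for their member genes in the
    downstream co-expression network, which keeps the network tractable
    while losing little temporal signal (ratio >= 0.98 by default).
    """
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 genes to pre-cluster")
    if not (0 < target_ratio <= 1):
        raise ValueError("target_ratio must be in (0, 1]")
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n)]
    Z = linkage(X, method="complete", metric="euclidean")
    labels = None
    for H in range(1, n + 1):
        lab = fcluster(Z, t=H, criterion="maxclust") - 1
        ratio = variance_explained_ratio(lab, X)
        if ratio >= target_ratio:
            labels = lab
            break
    if labels is None:  # target not reached below H=n; fall back to singletons
        labels = np.arange(n)
    k = labels.max() + 1
    means = np.vstack([X[labels == c].mean(axis=0) for c in range(k)])
    return ClusterAssignment(list(gene_ids), labels, means)
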