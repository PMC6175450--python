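"""Ensemble self-organizing-map classification of regulatory divergence.

The method asks whether the retained copies of a gene family share
temporal regulation, honouring the measurement uncertainty of each
expression value:

1.  a Kohonen self-organizing map (SOM) is trained on all z-normalized
    expression traces in a tissue; its size is chosen so the map nodes
    explain ~85% of the trace variance, and its rectangle matches the
    ratio of the first two principal-component eigenvalues;
2.  each gene's trace is resampled B times from a Gaussian observation
    model (mean = FPKM value, spread = the per-timepoint uncertainty),
    each draw re-normalized and assigned to its nearest map node, giving
    an empirical node-mapping distribution;
3.  the probability that two genes land on the same node,
    p = sum_c n1_c * n2_c / B^2, is averaged over an ensemble of M
    independently trained maps (mean mu_p, SD sigma_p);
4.  a soft threshold turns this into a clustering coefficient
    0.5 * (1 + erf((mu_p - theta) / (sigma_p * sqrt(2)))), where theta is
    the low mode of the per-map self-mapping probability density;
5.  coefficients are binarized at 0.5; regulatory modules are the maximal
    cliques of the binary graph, after removing genes that do not map
    robustly (binary self-coefficient 0);
6.  the module structure of each family is classified into one of five
    divergence patterns: redundant, distinct, gradated, unique or mixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats
from scipy.special import erf

from .preprocess import variance_explained_ratio, znormalize_matrix
from .util import derive_seed

log = logging.getLogger(__name__)

PATTERNS = ("redundant", "distinct", "gradated", "unique", "mixed")
THETA_FLOOR = 0.05


# ---------------------------------------------------------------------------
# SOM training
# ---------------------------------------------------------------------------

@dataclass
class SOMGrid:
    rows: int
    cols: int
    codebook: np.ndarray          # (rows * cols, n_timepoints)
    seed: int
    qe_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols


def _grid_coords(rows: int, cols: int) -> np.ndarray:
    ii, jj = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([ii.ravel(), jj.ravel()]).astype(float)


def best_rectangle(S: int, aspect: float) -> tuple[int, int]:
    """Integer rectangle rows x cols = S whose rows/cols ratio best matches
    ``aspect`` (>= 1); ties go to the squarer grid."""
    if S < 1:
        raise ValueError("S must be positive")
    if not np.isfinite(aspect):
        return S, 1
    best = None
    for c in range(1, int(np.sqrt(S)) + 1):
        if S % c:
            continue
        r = S // c
        d = abs(np.log(r / c) - np.log(max(aspect, 1.0)))
        if best is None or d < best[0] - 1e-12:
            best = (d, r, c)
    return best[1], best[2]


def bmu_assign(codebook: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Index of the nearest (best-matching) codebook vector per row of X."""
    d2 = (
        (X ** 2).sum(axis=1)[:, None]
        - 2.0 * X @ codebook.T
        + (codebook ** 2).sum(axis=1)[None, :]
    )
    return np.argmin(d2, axis=1)


def quantization_error(codebook: np.ndarray, X: np.ndarray) -> float:
    idx = bmu_assign(codebook, X)
    return float(np.linalg.norm(X - codebook[idx], axis=1).mean())


def train_som(
    X: np.ndarray,
    dims: tuple[int, int],
    seed: int = 0,
    mode: str = "batch",
    epochs: int = 30,
    iterations: int | None = None,
    lr_start: float = 0.05,
    lr_end: float = 0.01,
) -> SOMGrid:
    """Train a rectangular, non-toroidal SOM with Gaussian neighbourhood.

    ``mode='batch'`` (default) recomputes every codebook vector per epoch as
    the neighbourhood-weighted mean of the data; it is fast, deterministic
    given the seeded initialization, and what the ensemble uses.
    ``mode='online'`` performs classic sequential updates with a learning
    rate decaying linearly from ``lr_start`` to ``lr_end`` over
    ``iterations`` (default 100 x n_genes) steps.  In both modes the
    neighbourhood radius decays linearly from half the larger grid
    dimension to 1.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training data must be a non-empty 2-D array")
    rows, cols = dims
    S = rows * cols
    rng = np.random.default_rng(seed)
    init_idx = rng.choice(X.shape[0], size=S, replace=X.shape[0] < S)
    codebook = X[init_idx] + rng.standard_normal((S, X.shape[1])) * 1e-4
    coords = _grid_coords(rows, cols)
    grid_d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    sigma0 = max(max(rows, cols) / 2.0, 1.0)
    qe = []
    if S == 1:
        codebook = X.mean(axis=0, keepdims=True)
        return SOMGrid(rows, cols, codebook, seed, np.array([quantization_error(codebook, X)]))

    if mode == "batch":
        for e in range(epochs):
            frac = e / max(epochs - 1, 1)
            sigma = sigma0 + (1.0 - sigma0) * frac
            qe.append(quantization_error(codebook, X))
            idx = bmu_assign(codebook, X)
            H = np.exp(-grid_d2 / (2.0 * sigma ** 2))
            A = H[:, idx]                      # (S, N) neighbourhood weights
            den = A.sum(axis=1)
            num = A @ X
            upd = den > 1e-12
            codebook[upd] = num[upd] / den[upd, None]
        qe.append(quantization_error(codebook, X))
    elif mode == "online":
        n_iter = iterations if iterations is not None else 100 * X.shape[0]
        order = rng.integers(0, X.shape[0], size=n_iter)
        check = max(n_iter // 20, 1)
        for t, g in enumerate(order):
            frac = t / max(n_iter - 1, 1)
            sigma = sigma0 + (1.0 - sigma0) * frac
            lr = lr_start + (lr_end - lr_start) * frac
            x = X[g]
            b = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            h = np.exp(-grid_d2[:, b] / (2.0 * sigma ** 2))
            codebook += lr * h[:, None] * (x - codebook)
            if t % check == 0:
                qe.append(quantization_error(codebook, X))
        qe.append(quantization_error(codebook, X))
    else:
        raise ValueError(f"unknown training mode {mode!r}")
    if not np.all(np.isfinite(codebook)):
        raise FloatingPointError("non-finite codebook after training")
    return SOMGrid(rows, cols, codebook, seed, np.asarray(qe))


def choose_grid(
    X: np.ndarray,
    target_ratio: float = 0.85,
    seed: int = 0,
    max_nodes: int | None = None,
    epochs: int = 20,
) -> tuple[int, int]:
    """Smallest map size whose node assignment explains ``target_ratio`` of
    the trace variance; the grid rectangle matches the ratio of the first
    two principal-component eigenvalues of the data."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 traces to size a map")
    eigvals = np.linalg.eigvalsh(np.cov(X.T))[::-1]
    lam1, lam2 = float(eigvals[0]), float(eigvals[1]) if len(eigvals) > 1 else 0.0
    if lam2 <= 0:
        log.warning("degenerate covariance (lambda2 = 0); using a 1-row map")
        aspect = np.inf
    else:
        aspect = lam1 / lam2
    if max_nodes is None:
        max_nodes = min(n, max(16, (2 * n) // 3))
    # scan S upward, coarsening the stride for large maps
    candidates: list[int] = []
    S, stride = 1, 1
    while S <= max_nodes:
        candidates.append(S)
        if S >= 128:
            stride = 8
        elif S >= 64:
            stride = 4
        elif S >= 16:
            stride = 2
        S += stride
    last = (1, 1)
    for S in candidates:
        dims = best_rectangle(S, aspect)
        if S > 2 and np.isfinite(aspect):
            # skip sizes (e.g. large primes) whose only factorizations
            # distort the target aspect ratio badly
            distort = abs(np.log(dims[0] / dims[1]) - np.log(max(aspect, 1.0)))
            if distort > np.log(2.0):
                continue
        last = dims
        som = train_som(X, dims, seed=derive_seed(seed, S), epochs=epochs)
        labels = bmu_assign(som.codebook, X)
        if variance_explained_ratio(labels, X) >= target_ratio:
            return dims
    log.warning("target ratio %.2f not reached at max_nodes=%d", target_ratio, max_nodes)
    return last


# ---------------------------------------------------------------------------
# Resampling and mapping probabilities
# ---------------------------------------------------------------------------

def resample_counts_all(
    F: np.ndarray,
    SD: np.ndarray,
    codebook: np.ndarray,
    B: int,
    seed: int,
    noise_scale: str = "sd",
    chunk: int = 256,
) -> np.ndarray:
    """Node-mapping counts over B Gaussian draws for every gene.

    Each draw perturbs every timepoint of the *unnormalized* trace
    independently (mean = FPKM, spread per ``noise_scale``: 'sd' uses the
    uncertainty column as a standard deviation, 'variance' as a variance),
    re-normalizes the drawn trace to mean 0 / variance 1 and assigns it to
    the nearest codebook vector.  Returns an (n_genes, S) integer matrix
    whose rows sum to B.
    """
    F = np.asarray(F, dtype=float)
    SD = np.asarray(SD, dtype=float)
    if F.shape[1] == 0:
        raise ValueError("zero-length traces")
    if noise_scale == "sd":
        scale = SD
    elif noise_scale == "variance":
        scale = np.sqrt(SD)
    else:
        raise ValueError("noise_scale must be 'sd' or 'variance'")
    rng = np.random.default_rng(seed)
    S = codebook.shape[0]
    counts = np.zeros((F.shape[0], S), dtype=np.int64)
    cb2 = (codebook ** 2).sum(axis=1)
    for lo in range(0, F.shape[0], chunk):
        hi = min(lo + chunk, F.shape[0])
        draws = F[lo:hi, None, :] + rng.standard_normal((hi - lo, B, F.shape[1])) * scale[lo:hi, None, :]
        mu = draws.mean(axis=2, keepdims=True)
        s = draws.std(axis=2, keepdims=True)
        flat = s[:, :, 0] <= 0
        tries = 0
        while flat.any() and tries < 100:  # constant draw: re-draw (rare)
            gi, bi = np.nonzero(flat)
            log.debug("re-drawing %d constant trace draw(s)", len(gi))
            draws[gi, bi] = F[lo + gi] + rng.standard_normal((len(gi), F.shape[1])) * scale[lo + gi]
            mu = draws.mean(axis=2, keepdims=True)
            s = draws.std(axis=2, keepdims=True)
            flat = s[:, :, 0] <= 0
            tries += 1
        if flat.any():
            raise ValueError("constant traces cannot be assigned to the map")
        Z = (draws - mu) / s
        d2 = (Z ** 2).sum(axis=2)[:, :, None] - 2.0 * Z @ codebook.T + cb2[None, None, :]
        b = np.argmin(d2, axis=2)
        rows = np.repeat(np.arange(lo, hi), B)
        np.add.at(counts, (rows, b.ravel()), 1)
    return counts


def resample_assignments(
    fpkm: np.ndarray,
    fpkm_sd: np.ndarray,
    som: SOMGrid,
    B: int = 500,
    seed: int = 0,
    noise_scale: str = "sd",
) -> np.ndarray:
    """Single-gene convenience wrapper around :func:`resample_counts_all`."""
    return resample_counts_all(
        np.asarray(fpkm, float)[None, :],
        np.asarray(fpkm_sd, float)[None, :],
        som.codebook,
        B=B,
        seed=seed,
        noise_scale=noise_scale,
    )[0]


def co_mapping_probability(counts_g1: np.ndarray, counts_g2: np.ndarray, B: int) -> float:
    """Probability two genes' draws land on the same node: sum_c n1_c n2_c / B^2."""
    c1 = np.asarray(counts_g1, dtype=float)
    c2 = np.asarray(counts_g2, dtype=float)
    if c1.shape != c2.shape:
        raise ValueError("count vectors come from different maps")
    return float(c1 @ c2) / (B * B)


def self_mapping_probability(counts: np.ndarray, B: int = 500) -> float:
    """Consistency of a gene's own mapping: sum_c n_c^2 / B^2."""
    c = np.asarray(counts, dtype=float)
    return float(c @ c) / (B * B)


# ---------------------------------------------------------------------------
# Ensemble
# ---------------------------------------------------------------------------

@dataclass
class SOMEnsembleResult:
    """Per-pair and per-gene mapping probabilities over the map ensemble."""

    gene_ids: list[str]
    pair_index: dict[tuple[int, int], int]
    mu_pair: np.ndarray       # (n_pairs,)
    sigma_pair: np.ndarray
    self_mu: np.ndarray       # (n_genes,)
    self_sigma: np.ndarray
    self_per_map: np.ndarray  # (M, n_genes)
    theta: float
    B: int
    M: int
    dims: tuple[int, int]

    def pair_stats(self, i: int, j: int) -> tuple[float, float]:
        if i == j:
            return float(self.self_mu[i]), float(self.self_sigma[i])
        key = (min(i, j), max(i, j))
        k = self.pair_index[key]
        return float(self.mu_pair[k]), float(self.sigma_pair[k])


def derive_threshold(
    self_per_map: np.ndarray,
    floor: float = THETA_FLOOR,
    upper: float = 0.5,
    min_points: int = 10,
    min_fraction: float = 0.05,
) -> float:
    """Per-map low mode of the self-mapping probability density, averaged.

    The self-probability distribution is typically bimodal (a low mode from
    genes whose uncertainty spreads draws over many nodes, a mode at 1 from
    robust genes).  theta is the Gaussian-KDE (Silverman bandwidth) density
    argmax restricted to [0, ``upper``], averaged over maps.  A map only
    contributes when the window holds a genuine subpopulation (at least
    ``min_points`` genes and ``min_fraction`` of the cohort — a handful of
    node-boundary stragglers is not a mode); if no map qualifies, theta
    falls back to ``floor``.
    """
    self_per_map = np.atleast_2d(np.asarray(self_per_map, dtype=float))
    thetas = []
    grid = np.linspace(0.0, upper, 501)
    need = max(min_points, int(np.ceil(min_fraction * self_per_map.shape[1])))
    for row in self_per_map:
        vals = row[(row >= 0.0) & (row <= upper)]
        if len(vals) < need or np.ptp(vals) < 1e-12:
            continue
        try:
            kde = stats.gaussian_kde(vals, bw_method="silverman")
        except np.linalg.LinAlgError:
            continue
        thetas.append(float(grid[np.argmax(kde(grid))]))
    if not thetas:
        log.warning("no low self-probability mode; theta falls back to %.3f", floor)
        return floor
    return float(np.mean(thetas))


def ensemble_probabilities(
    F: np.ndarray,
    SD: np.ndarray,
    gene_ids: list[str],
    pairs: list[tuple[int, int]] | None = None,
    M: int = 100,
    B: int = 500,
    base_seed: int = 0,
    dims: tuple[int, int] | None = None,
    target_ratio: float = 0.85,
    noise_scale: str = "sd",
    epochs: int = 30,
    theta: float | None = None,
) -> SOMEnsembleResult:
    """Mean and SD of co-mapping probabilities over M independent maps.

    ``F`` / ``SD`` are unnormalized FPKM traces and uncertainties (genes x
    timepoints).  Maps are trained on the z-normalized traces; all M maps
    share one grid size (chosen from the data when ``dims`` is None).
    ``pairs`` are index pairs to evaluate (all pairs when None — quadratic,
    intended for small gene sets).  ``theta`` overrides the derived
    threshold (e.g. to reproduce a fixed tissue threshold).
    """
    F = np.asarray(F, dtype=float)
    SD = np.asarray(SD, dtype=float)
    n = F.shape[0]
    if n < 2:
        raise ValueError("need at least 2 genes")
    if M < 2:
        raise ValueError("need M >= 2 maps for a probability SD")
    Z, _, ok = znormalize_matrix(F, SD)
    if not ok.all():
        raise ValueError("constant traces must be filtered out before the SOM")
    if dims is None:
        dims = choose_grid(Z, target_ratio=target_ratio, seed=derive_seed(base_seed, 9999))
    if pairs is None:
        pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    pairs = [(min(i, j), max(i, j)) for i, j in pairs]
    pair_index = {p: k for k, p in enumerate(dict.fromkeys(pairs))}
    ii = np.array([p[0] for p in pair_index], dtype=int)
    jj = np.array([p[1] for p in pair_index], dtype=int)

    pair_per_map = np.empty((M, len(pair_index)))
    self_per_map = np.empty((M, n))
    for m in range(M):
        som = train_som(Z, dims, seed=derive_seed(base_seed, m, 0), epochs=epochs)
        counts = resample_counts_all(
            F, SD, som.codebook, B=B, seed=derive_seed(base_seed, m, 1),
            noise_scale=noise_scale,
        ).astype(float)
        self_per_map[m] = (counts * counts).sum(axis=1) / (B * B)
        pair_per_map[m] = (counts[ii] * counts[jj]).sum(axis=1) / (B * B)
    mu_pair = pair_per_map.mean(axis=0)
    sigma_pair = pair_per_map.std(axis=0, ddof=1)
    self_mu = self_per_map.mean(axis=0)
    self_sigma = self_per_map.std(axis=0, ddof=1)
    if theta is None:
        theta = derive_threshold(self_per_map)
    return SOMEnsembleResult(
        gene_ids=list(gene_ids),
        pair_index=pair_index,
        mu_pair=mu_pair,
        sigma_pair=sigma_pair,
        self_mu=self_mu,
        self_sigma=self_sigma,
        self_per_map=self_per_map,
        theta=float(theta),
        B=B,
        M=M,
        dims=dims,
    )


# ---------------------------------------------------------------------------
# Clustering coefficients, modules, patterns
# ---------------------------------------------------------------------------

def clustering_coefficient(mu_p, sigma_p, theta: float):
    """Soft-thresholded co-mapping probability in [0, 1].

    0.5 * (1 + erf((mu_p - theta) / (sigma_p * sqrt(2)))).  As sigma_p -> 0
    this approaches a step at theta; at sigma_p = 0 exactly it returns 1
    above theta, 0 below and 0.5 at theta.
    """
    mu_p = np.asarray(mu_p, dtype=float)
    sigma_p = np.asarray(sigma_p, dtype=float)
    if np.any(sigma_p < 0):
        raise ValueError("sigma_p must be >= 0")
    diff = mu_p - theta
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 0.5 * (1.0 + erf(diff / (sigma_p * np.sqrt(2.0))))
    zero = sigma_p == 0
    if np.ndim(out) == 0:
        if zero:
            out = 1.0 if diff > 0 else (0.0 if diff < 0 else 0.5)
        return float(out)
    out[zero] = np.where(diff[zero] > 0, 1.0, np.where(diff[zero] < 0, 0.0, 0.5))
    return out


def coefficient_matrix(result: SOMEnsembleResult, indices: list[int]) -> np.ndarray:
    """Symmetric clustering-coefficient matrix for a gene subset; the
    diagonal holds each gene's self (robustness) coefficient."""
    n = len(indices)
    C = np.empty((n, n))
    for a in range(n):
        for b in range(a, n):
            mu, sig = result.pair_stats(indices[a], indices[b])
            C[a, b] = C[b, a] = clustering_coefficient(mu, sig, result.theta)
    return C


def binarize_and_modularize(
    coeff: np.ndarray, gene_ids: list[str]
) -> tuple[list[list[str]], list[str]]:
    """Binary filter at 0.5 and maximal-clique regulatory modules.

    Genes whose self-coefficient is not above 0.5 do not map robustly and
    are removed first.  Modules are the maximal cliques of the remaining
    binary graph (a gene may sit in several); output is deterministic:
    members sorted, modules ordered by size (descending) then members.
    """
    coeff = np.asarray(coeff, dtype=float)
    if coeff.shape[0] != coeff.shape[1] or not np.allclose(coeff, coeff.T, atol=1e-9):
        raise ValueError("coefficient matrix must be symmetric")
    binary = coeff > 0.5
    robust = np.diag(binary)
    removed = [g for g, r in zip(gene_ids, robust) if not r]
    keep = [i for i, r in enumerate(robust) if r]
    G = nx.Graph()
    G.add_nodes_from(gene_ids[i] for i in keep)
    for a in range(len(keep)):
        for b in range(a + 1, len(keep)):
            if binary[keep[a], keep[b]]:
                G.add_edge(gene_ids[keep[a]], gene_ids[keep[b]])
    cliques = [sorted(c) for c in nx.find_cliques(G)]
    cliques.sort(key=lambda c: (-len(c), c))
    return cliques, removed


@dataclass
class PatternCall:
    reference_gene_id: str
    pattern: str | None           # None when < 2 robust genes remain
    modules: list[list[str]]
    removed: list[str]
    n_robust: int


def classify_pattern(
    modules: list[list[str]], robust_genes: list[str], reference_gene_id: str = ""
) -> PatternCall:
    """Five-way divergence pattern of a family's module structure.

    redundant: one module holding every robust gene.  unique: every module
    a singleton, one per gene.  distinct: >= 2 pairwise-disjoint modules,
    at least one with >= 2 genes.  gradated: >= 2 modules, every module
    overlapping some other.  mixed: >= 2 modules with at least one
    overlapping pair and at least one module disjoint from all others.
    """
    robust = sorted(set(robust_genes))
    removed = []
    if len(robust) < 2:
        return PatternCall(reference_gene_id, None, modules, removed, len(robust))
    sets = [set(m) for m in modules]
    if len(sets) == 1 and sets[0] == set(robust):
        return PatternCall(reference_gene_id, "redundant", modules, removed, len(robust))
    overlaps = np.zeros(len(sets), dtype=bool)
    any_overlap = False
    for a in range(len(sets)):
        for b in range(a + 1, len(sets)):
            if sets[a] & sets[b]:
                overlaps[a] = overlaps[b] = True
                any_overlap = True
    if not any_overlap:
        if all(len(s) == 1 for s in sets) and len(sets) == len(robust):
            pattern = "unique"
        else:
            pattern = "distinct"
    else:
        pattern = "gradated" if overlaps.all() else "mixed"
    return PatternCall(reference_gene_id, pattern, modules, removed, len(robust))


def classify_family(
    result: SOMEnsembleResult, member_ids: list[str], reference_gene_id: str
) -> PatternCall:
    """Coefficient matrix -> binary modules -> pattern, for one family."""
    index = {g: k for k, g in enumerate(result.gene_ids)}
    idx = [index[g] for g in member_ids]
    C = coefficient_matrix(result, idx)
    modules, removed = binarize_and_modularize(C, list(member_ids))
    robust = [g for g in member_ids if g not in removed]
    call = classify_pattern(modules, robust, reference_gene_id)
    call.removed = removed
    return call


def family_divergence_summary(
    calls_by_tissue: dict[str, list[PatternCall]],
    pairs: list[tuple[str, str]] | None = None,
) -> dict:
    """Cohort tables: per-tissue pattern percentages, per-pair same-module
    flags (members sharing >= 1 module) and the cross-tissue overlap."""
    out: dict = {"tissues": {}, "pairs": {}}
    same_by_tissue: dict[str, set[tuple[str, str]]] = {}
    for tissue, calls in calls_by_tissue.items():
        classified = [c for c in calls if c.pattern is not None]
        n = len(classified)
        pct = {
            p: (100.0 * sum(c.pattern == p for c in classified) / n if n else float("nan"))
            for p in PATTERNS
        }
        out["tissues"][tissue] = {
            "n_classified": n,
            "n_unclassifiable": len(calls) - n,
            "percent": pct,
        }
        if pairs:
            membership: dict[str, list[set[str]]] = {}
            for c in calls:
                for mod in c.modules:
                    ms = set(mod)
                    for g in mod:
                        membership.setdefault(g, []).append(ms)
            flags = {}
            for a, b in pairs:
                if a not in membership or b not in membership:
                    continue
                flags[(a, b)] = any(b in ms for ms in membership[a])
            n_eval = len(flags)
            n_same = sum(flags.values())
            same_by_tissue[tissue] = {p for p, f in flags.items() if f}
            out["pairs"][tissue] = {
                "n_pairs": n_eval,
                "n_same_module": n_same,
                "percent_same_module": (100.0 * n_same / n_eval) if n_eval else float("nan"),
            }
    if pairs and len(same_by_tissue) > 1:
        inter = set.intersection(*same_by_tissue.values())
        out["pairs"]["common_same_module_pairs"] = len(inter)
    return out
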