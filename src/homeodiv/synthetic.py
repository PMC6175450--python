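"""Synthetic inputs with the statistical structure the analysis assumes.

Every downstream stage (retention counting, co-expression modules, the
ensemble-SOM divergence classifier, the conservation scanner) is exercised
against data generated here, with known truth:

- expression families whose copies follow one of five divergence patterns
  (redundant / distinct / gradated / unique / mixed) over the sampled
  developmental time course (days 22-72);
- copy-number tables with an enriched ("preferentially retained") subset;
- directional hit tables in which every true homologous pair is a
  reciprocal best hit below the e-value threshold and decoys are not;
- nucleotide sequence pairs with planted conserved blocks on a divergent
  background.

All generators are bit-reproducible given (spec, seed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import ExpressionSeries
from .util import derive_seed

log = logging.getLogger(__name__)

#: the sampled time course: days after sowing; the plants sit in cold
#: (vernalization) conditions between day 22 and day 64.
DEFAULT_DAYS = (22.0, 43.0, 64.0, 65.0, 67.0, 69.0, 72.0)

PATTERNS = ("redundant", "distinct", "gradated", "unique", "mixed")


@dataclass
class FamilySpec:
    """A homologue family with a known divergence pattern.

    ``base_level`` sets the mean FPKM of each copy; template shapes are
    scaled to ``base_level / 3`` amplitude so traces stay non-negative.
    ``noise_sd`` is the per-observation Gaussian SD in FPKM units and is
    also written out as the per-timepoint uncertainty column.
    """

    reference_gene_id: str
    n_copies: int
    pattern: str
    n_timepoints: int = len(DEFAULT_DAYS)
    base_level: float = 10.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_timepoints < 3:
            raise ValueError("need at least 3 timepoints")
        if self.pattern in ("unique", "distinct", "gradated") and self.n_copies < 2:
            raise ValueError(f"pattern {self.pattern!r} requires n_copies >= 2")
        # a mixed family must support an overlapping chain (3 genes) plus a
        # module disjoint from it (>= 1 gene)
        if self.pattern == "mixed" and self.n_copies < 4:
            raise ValueError("pattern 'mixed' requires n_copies >= 4")
        if self.pattern == "unique" and self.n_copies > self.n_timepoints - 1:
            raise ValueError(
                "pattern 'unique' supports at most n_timepoints - 1 copies "
                "(mutually decorrelated templates)"
            )


@dataclass
class SyntheticFamily:
    """Generator output: the emitted traces plus their truth."""

    spec: FamilySpec
    members: list[ExpressionSeries]
    templates: np.ndarray  # (n_copies, n_timepoints), z-scale shapes

    @property
    def pattern(self) -> str:
        return self.spec.pattern

    @property
    def gene_ids(self) -> list[str]:
        return [m.gene_id for m in self.members]


def _orthogonal_templates(rng: np.random.Generator, n: int, T: int) -> np.ndarray:
    """``n`` mean-zero, unit-population-SD templates with exactly zero
    pairwise Pearson correlation (QR on centred random vectors)."""
    if n > T - 1:
        raise ValueError("cannot draw more decorrelated templates than T - 1")
    M = rng.standard_normal((T, n))
    M -= M.mean(axis=0, keepdims=True)
    Q, R = np.linalg.qr(M)
    Q = Q[:, :n] * np.sign(np.diag(R))[None, :]  # sign-fix: QR is otherwise ambiguous
    return (Q * np.sqrt(T)).T  # unit population SD per row


def _standardize(v: np.ndarray) -> np.ndarray:
    return (v - v.mean()) / v.std()


def _chain_templates(e: np.ndarray, k: int) -> np.ndarray:
    """Templates on a geodesic arc between two endpoint shapes.

    Each template is cos(phi_i) e0 + sin(phi_i) e1 for orthonormal shapes
    e0, e1, i.e. a rescaled convex combination of the arc endpoints; the
    correlation between templates i and j is exactly cos(phi_i - phi_j).
    Angular gaps are chosen so neighbouring templates are strongly
    correlated (~0.9-0.95) while the chain endpoints are not (<~0.6),
    mimicking a gradient of regulatory responses.
    """
    gap = np.deg2rad(25.0 if k == 3 else 54.0 / (k - 1))
    phi = np.arange(k) * gap
    return np.vstack([np.cos(p) * e[0] + np.sin(p) * e[1] for p in phi])


def generate_family(spec: FamilySpec) -> SyntheticFamily:
    """Emit one family of traces following the spec'd divergence pattern.

    Template construction (all templates are mean-0 / SD-1 shapes over the
    time course; correlations below are exact, before observation noise):

    - redundant: all copies share one template;
    - unique:    mutually uncorrelated templates, one per copy;
    - distinct:  two groups, identical within, uncorrelated between;
    - gradated:  templates on a convex path between two uncorrelated
                 endpoint shapes, giving a chain of high adjacent
                 similarity whose endpoints are uncorrelated;
    - mixed:     a 3-gene gradated chain plus a disjoint group on a third
                 uncorrelated shape.
    """
    n, T = spec.n_copies, spec.n_timepoints
    rng = np.random.default_rng(spec.seed)
    if spec.pattern == "redundant":
        base = _orthogonal_templates(rng, 1, T)
        templates = np.repeat(base, n, axis=0)
    elif spec.pattern == "unique":
        templates = _orthogonal_templates(rng, n, T)
    elif spec.pattern == "distinct":
        e = _orthogonal_templates(rng, 2, T)
        sizes = [n - n // 2, n // 2]
        templates = np.vstack([np.repeat(e[[0]], sizes[0], 0), np.repeat(e[[1]], sizes[1], 0)])
    elif spec.pattern == "gradated":
        templates = _chain_templates(_orthogonal_templates(rng, 2, T), n)
    else:  # mixed: an overlapping chain plus a module disjoint from it
        k = max(3, n - 2)
        e = _orthogonal_templates(rng, 3, T)
        chain = _chain_templates(e[:2], k)
        templates = np.vstack([chain, np.repeat(e[[2]], n - k, 0)])
    amplitude = spec.base_level / 3.0
    days = np.linspace(22.0, 72.0, T) if T != len(DEFAULT_DAYS) else np.array(DEFAULT_DAYS)
    members = []
    for i in range(n):
        noise = rng.standard_normal(T) * spec.noise_sd
        fpkm = spec.base_level + amplitude * templates[i] + noise
        clipped = fpkm < 0
        if clipped.any():
            log.debug("clipped %d negative FPKM values in %s", clipped.sum(), spec.reference_gene_id)
            fpkm = np.clip(fpkm, 0.0, None)
        members.append(
            ExpressionSeries(
                gene_id=f"{spec.reference_gene_id}_cp{i + 1}",
                tissue="apex",
                days=days,
                fpkm=fpkm,
                fpkm_sd=np.full(T, spec.noise_sd),
            )
        )
    return SyntheticFamily(spec, members, templates)


def generate_cohort(
    n_per_pattern: int,
    noise_sd: float,
    seed: int,
    copies: dict[str, int] | None = None,
    n_timepoints: int = len(DEFAULT_DAYS),
    base_level: float = 10.0,
    tissue: str = "apex",
) -> list[SyntheticFamily]:
    """A cohort of families, ``n_per_pattern`` per divergence pattern."""
    if copies is None:
        copies = {"redundant": 4, "distinct": 4, "gradated": 4, "unique": 4, "mixed": 6}
    families = []
    idx = 0
    for pattern in PATTERNS:
        for k in range(n_per_pattern):
            idx += 1
            fam = generate_family(
                FamilySpec(
                    reference_gene_id=f"REF{idx:05d}",
                    n_copies=copies[pattern],
                    pattern=pattern,
                    n_timepoints=n_timepoints,
                    base_level=base_level,
                    noise_sd=noise_sd,
                    seed=derive_seed(seed, idx),
                )
            )
            for m in fam.members:
                m.tissue = tissue
            families.append(fam)
    return families


def cohort_frame(families: list[SyntheticFamily]) -> pd.DataFrame:
    """Long-form expression table for a cohort (the pipeline's TSV format)."""
    rows = []
    for fam in families:
        for m in fam.members:
            for d, f, s in zip(m.days, m.fpkm, m.fpkm_sd):
                rows.append((m.gene_id, m.tissue, d, f, s))
    return pd.DataFrame(rows, columns=["gene_id", "tissue", "day", "fpkm", "fpkm_sd"])


@dataclass
class CopyNumberSpec:
    """Copy-count distribution with an enriched subset tilted high.

    ``copy_probabilities[k]`` is the probability a reference gene has k
    polyploid copies (k = 0..max).  Enriched-subset genes draw from the
    same distribution and then gain ``enrichment_shift`` extra copies
    (clipped at the maximum copy count), emulating preferential retention.
    """

    n_reference_genes: int
    copy_probabilities: tuple[float, ...]
    enriched_subset_fraction: float = 0.0
    enrichment_shift: int = 2

    def __post_init__(self) -> None:
        p = np.asarray(self.copy_probabilities, dtype=float)
        if np.any(p < 0) or np.any(p > 1) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("copy_probabilities must lie in [0,1] and sum to 1")
        if not (0 <= self.enriched_subset_fraction <= 1):
            raise ValueError("enriched_subset_fraction must be in [0,1]")
        if self.n_reference_genes < 1:
            raise ValueError("n_reference_genes must be positive")


def generate_copy_number_table(
    spec: CopyNumberSpec, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a gene map (one row per polyploid gene) plus per-reference truth.

    Returns ``(genemap, truth)``; ``truth`` has one row per reference gene
    with its drawn copy count and enrichment flag.  The enriched subset has
    deterministic size ``round(fraction * n)``.
    """
    rng = np.random.default_rng(seed)
    n = spec.n_reference_genes
    ref_ids = np.array([f"AT{i + 1:05d}" for i in range(n)])
    n_enriched = int(round(spec.enriched_subset_fraction * n))
    enriched = np.zeros(n, dtype=bool)
    enriched[rng.choice(n, size=n_enriched, replace=False)] = True
    p = np.asarray(spec.copy_probabilities, dtype=float)
    kmax = len(p) - 1
    counts = rng.choice(len(p), size=n, p=p)
    counts[enriched] = np.minimum(counts[enriched] + spec.enrichment_shift, kmax)
    rows = []
    for rid, c, flag in zip(ref_ids, counts, enriched):
        for j in range(int(c)):
            rows.append(
                (
                    f"Bn{rid}_{j + 1}",
                    rid,
                    float(rng.uniform(200, 800)),
                    float(10.0 ** rng.uniform(-180, -60)),
                    bool(flag),
                    False,
                    False,
                    True,
                )
            )
    genemap = pd.DataFrame(
        rows,
        columns=[
            "polyploid_gene_id", "reference_gene_id", "score", "evalue",
            "in_flowering_set", "in_tf_set", "in_circadian_set", "syntenic",
        ],
    )
    truth = pd.DataFrame(
        {"reference_gene_id": ref_ids, "n_copies": counts, "enriched": enriched}
    )
    return genemap, truth


def generate_hit_tables(
    pairs_truth: list[tuple[str, str]],
    decoy_rate: float,
    seed: int,
    evalue_threshold: float = 1e-50,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Directional A->C and C->A hit tables for reciprocal-best-hit calling.

    Every true pair is the top-scoring hit in both directions with an
    e-value below the threshold.  Decoys alternate between one-directional
    hits and reciprocal hits above the e-value threshold; a correct
    reciprocal-best-hit filter recovers exactly the truth set.
    """
    a_ids = [a for a, _ in pairs_truth]
    c_ids = [c for _, c in pairs_truth]
    if len(set(a_ids)) != len(a_ids) or len(set(c_ids)) != len(c_ids):
        raise ValueError("pair ids must be unique within each genome")
    rng = np.random.default_rng(seed)
    ab_rows, ba_rows = [], []
    for a, c in pairs_truth:
        top = float(rng.uniform(500, 900))
        ev = float(10.0 ** rng.uniform(-180, -60))
        ab_rows.append((a, c, float(rng.uniform(85, 100)), top, ev))
        ba_rows.append((c, a, float(rng.uniform(85, 100)), top - 1.0, ev))
        # sub-optimal cross-hits against other true genes (never the best)
        if len(pairs_truth) > 1 and rng.random() < 0.5:
            other = c_ids[int(rng.integers(len(c_ids)))]
            if other != c:
                ab_rows.append((a, other, 80.0, top - float(rng.uniform(50, 200)),
                                float(10.0 ** rng.uniform(-58, -51))))
    n_decoys = int(round(decoy_rate * len(pairs_truth)))
    for d in range(n_decoys):
        da, dc = f"decoyA{d + 1}", f"decoyC{d + 1}"
        score = float(rng.uniform(300, 600))
        if d % 2 == 0:  # one-directional: A->C only
            ab_rows.append((da, dc, 90.0, score, float(10.0 ** rng.uniform(-120, -60))))
        else:  # reciprocal but above the e-value threshold
            ev = float(10.0 ** rng.uniform(-45, -10))
            ab_rows.append((da, dc, 90.0, score, ev))
            ba_rows.append((dc, da, 90.0, score, ev))
    cols = ["query", "subject", "pident", "bitscore", "evalue"]
    return pd.DataFrame(ab_rows, columns=cols), pd.DataFrame(ba_rows, columns=cols)


@dataclass
class SequencePairTruth:
    seq_a: str
    seq_b: str
    blocks: list[tuple[int, int, float]] = field(default_factory=list)


def generate_sequence_pair(
    length: int,
    conserved_blocks: list[tuple[int, int, float]],
    background_identity: float,
    seed: int,
) -> SequencePairTruth:
    """Sequence pair with planted conserved blocks (no indels).

    Per-site substitution probability is ``1 - identity/100`` inside each
    block and ``1 - background_identity/100`` outside; substituted sites
    always change base, so block identities are exact in expectation.
    """
    blocks = sorted(conserved_blocks)
    for (s, e, ident) in blocks:
        if not (0 <= s < e <= length):
            raise ValueError(f"block ({s},{e}) outside [0,{length})")
        if not (0 <= ident <= 100):
            raise ValueError("block identity must be in [0,100]")
    for (s1, e1, _), (s2, _, _) in zip(blocks, blocks[1:]):
        if s2 < e1:
            raise ValueError("conserved blocks must not overlap")
    if not (0 <= background_identity <= 100):
        raise ValueError("background_identity must be in [0,100]")
    rng = np.random.default_rng(seed)
    alphabet = np.frombuffer(b"ACGT", dtype="S1")
    a = rng.integers(0, 4, size=length)
    p_sub = np.full(length, 1.0 - background_identity / 100.0)
    for (s, e, ident) in blocks:
        p_sub[s:e] = 1.0 - ident / 100.0
    subst = rng.random(length) < p_sub
    b = a.copy()
    b[subst] = (a[subst] + rng.integers(1, 4, size=int(subst.sum()))) % 4
    return SequencePairTruth(
        seq_a=alphabet[a].tobytes().decode(),
        seq_b=alphabet[b].tobytes().decode(),
        blocks=blocks,
    )
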