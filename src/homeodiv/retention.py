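"""Copy-number retention statistics and expression-based filtering.

After whole-genome multiplication an allopolyploid carries several copies
of most reference-genome genes.  This module quantifies that retention
(how many polyploid copies each reference gene keeps, and whether a gene
subset such as flowering-time regulators keeps more than the genome-wide
background), flags which copies are actually expressed, counts
tissue-specific expression, calls homologous pairs between the two
subgenomes as reciprocal best hits, and tallies two-fold expression bias
within pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

EVALUE_THRESHOLD = 1e-50
EXPRESSED_FPKM = 2.0

SUBSET_FILTERS = (
    "all",
    "flowering",
    "tf",
    "flowering_minus_tf",
    "flowering_minus_circadian",
    "syntenic",
    "non_syntenic",
    "expressed",
)


@dataclass
class CopyNumberDistribution:
    """Reference genes per copy count; denominator is genes with >= 1 copy."""

    counts: dict[int, int]
    denominator: int

    @property
    def proportions(self) -> dict[int, float]:
        if self.denominator == 0:
            return {}
        return {k: v / self.denominator for k, v in self.counts.items()}


@dataclass
class ProportionTestResult:
    p1: float
    p2: float
    x1: int
    n1: int
    x2: int
    n2: int
    statistic: float
    df: int
    pvalue: float


@dataclass
class TissueSpecificityResult:
    """4-way partition of a gene set by tissue expression plus the 2x3
    chi-square comparison of the subset's expressed split against the rest."""

    neither: int
    apex_only: int
    leaf_only: int
    both: int
    statistic: float | None = None
    df: int | None = None
    pvalue: float | None = None


def assign_best_hits(
    hits: pd.DataFrame, evalue_threshold: float = EVALUE_THRESHOLD
) -> pd.DataFrame:
    """Best reference hit per query under the e-value threshold.

    Hits with e-value above the threshold are discarded; per query the
    highest-bitscore hit is kept, ties broken by lower e-value then
    lexicographic subject id (fully deterministic).
    """
    kept = hits[hits["evalue"] <= evalue_threshold]
    if kept.empty:
        return kept.copy()
    ordered = kept.sort_values(
        ["query", "bitscore", "evalue", "subject"],
        ascending=[True, False, True, True],
        kind="mergesort",
    )
    return ordered.drop_duplicates("query", keep="first").reset_index(drop=True)


def _subset_mask(genemap: pd.DataFrame, subset_filter: str,
                 expressed: pd.Series | None = None) -> pd.Series:
    if subset_filter == "all":
        return pd.Series(True, index=genemap.index)
    if subset_filter == "flowering":
        return genemap["in_flowering_set"]
    if subset_filter == "tf":
        return genemap["in_tf_set"]
    if subset_filter == "flowering_minus_tf":
        return genemap["in_flowering_set"] & ~genemap["in_tf_set"]
    if subset_filter == "flowering_minus_circadian":
        return genemap["in_flowering_set"] & ~genemap["in_circadian_set"]
    if subset_filter == "syntenic":
        return genemap["syntenic"]
    if subset_filter == "non_syntenic":
        return ~genemap["syntenic"]
    if subset_filter == "expressed":
        if expressed is None:
            raise ValueError("'expressed' filter needs per-gene expressed flags")
        return genemap["polyploid_gene_id"].map(expressed).fillna(False).astype(bool)
    raise ValueError(f"unknown subset filter {subset_filter!r}; one of {SUBSET_FILTERS}")


def copy_number_distribution(
    genemap: pd.DataFrame,
    subset_filter: str = "all",
    expressed: pd.Series | None = None,
) -> CopyNumberDistribution:
    """Copy-count distribution over reference genes.

    Counts, per copy number k >= 1, the reference genes with exactly k
    polyploid copies among the filtered polyploid genes, divided by the
    number of reference genes represented by at least one copy.
    """
    mask = _subset_mask(genemap, subset_filter, expressed)
    sub = genemap[mask]
    if sub.empty:
        log.warning("empty subset %r: distribution undefined", subset_filter)
        return CopyNumberDistribution(counts={}, denominator=0)
    per_ref = sub.groupby("reference_gene_id", sort=True)["polyploid_gene_id"].nunique()
    counts = per_ref.value_counts().sort_index()
    return CopyNumberDistribution(
        counts={int(k): int(v) for k, v in counts.items()},
        denominator=int(len(per_ref)),
    )


def compare_proportions(x1: int, n1: int, x2: int, n2: int) -> ProportionTestResult:
    """Two-sample test for the equality of proportions, with Yates
    continuity correction (the R ``prop.test`` default), df = 1."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("counts must satisfy 0 <= x <= n")
    table = np.array([[x1, n1 - x1], [x2, n2 - x2]], dtype=float)
    if table.sum(axis=0).min() == 0:  # a margin is empty: test undefined
        raise ValueError("degenerate 2x2 table: empty margin")
    res = stats.chi2_contingency(table, correction=True)
    return ProportionTestResult(
        p1=x1 / n1, p2=x2 / n2, x1=x1, n1=n1, x2=x2, n2=n2,
        statistic=float(res.statistic), df=1, pvalue=float(res.pvalue),
    )


def filter_expressed(
    expression: pd.DataFrame, threshold: float = EXPRESSED_FPKM
) -> pd.DataFrame:
    """Per gene and tissue: expressed iff max FPKM over the time series
    reaches the threshold (inclusive)."""
    maxima = expression.groupby(["gene_id", "tissue"], sort=True)["fpkm"].max()
    out = (maxima >= threshold).rename("expressed").reset_index()
    out["max_fpkm"] = maxima.values
    return out


def expressed_flags(
    expression: pd.DataFrame, tissue: str, threshold: float = EXPRESSED_FPKM
) -> pd.Series:
    """Boolean Series gene_id -> expressed in ``tissue``."""
    flags = filter_expressed(expression, threshold)
    sub = flags[flags["tissue"] == tissue]
    return pd.Series(sub["expressed"].values, index=sub["gene_id"].values, dtype=bool)


def tissue_specificity(
    flags_apex: pd.Series,
    flags_leaf: pd.Series,
    subset: pd.Series | None = None,
    compare: str = "complement",
) -> TissueSpecificityResult:
    """4-way tissue-expression partition and the subset-vs-background
    chi-square on the 3-way expressed split (apex-only / leaf-only / both).

    ``compare`` selects the background: the subset's complement (default,
    standard contingency construction) or ``"all"`` genes.
    """
    genes = flags_apex.index.union(flags_leaf.index)
    a = flags_apex.reindex(genes, fill_value=False).astype(bool)
    l = flags_leaf.reindex(genes, fill_value=False).astype(bool)

    def split(mask: pd.Series) -> tuple[int, int, int, int]:
        am, lm = a[mask], l[mask]
        return (
            int((~am & ~lm).sum()),
            int((am & ~lm).sum()),
            int((~am & lm).sum()),
            int((am & lm).sum()),
        )

    if subset is None:
        neither, apex_only, leaf_only, both = split(pd.Series(True, index=genes))
        return TissueSpecificityResult(neither, apex_only, leaf_only, both)
    s = subset.reindex(genes, fill_value=False).astype(bool)
    if not s.any():
        raise ValueError("empty subset: test undefined")
    neither, apex_only, leaf_only, both = split(s)
    background = ~s if compare == "complement" else pd.Series(True, index=genes)
    _, b_apex, b_leaf, b_both = split(background)
    table = np.array([[apex_only, leaf_only, both], [b_apex, b_leaf, b_both]], dtype=float)
    res = stats.chi2_contingency(table, correction=False)
    return TissueSpecificityResult(
        neither, apex_only, leaf_only, both,
        statistic=float(res.statistic), df=int(res.dof), pvalue=float(res.pvalue),
    )


def chi2_on_table(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square (no correction) on a contingency table."""
    res = stats.chi2_contingency(np.asarray(table, dtype=float), correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def call_reciprocal_best_hits(
    hits_ab: pd.DataFrame,
    hits_ba: pd.DataFrame,
    evalue_threshold: float = EVALUE_THRESHOLD,
) -> pd.DataFrame:
    """Homologous pairs as reciprocal best hits under the e-value threshold.

    (a, c) is returned iff c is a's best hit in A->C and a is c's best hit
    in C->A, both below the threshold.  Best-hit ties break as in
    :func:`assign_best_hits`.
    """
    best_ab = assign_best_hits(hits_ab, evalue_threshold)
    best_ba = assign_best_hits(hits_ba, evalue_threshold)
    if best_ab.empty or best_ba.empty:
        return pd.DataFrame(columns=["a_gene_id", "c_gene_id"])
    fwd = best_ab[["query", "subject"]].rename(
        columns={"query": "a_gene_id", "subject": "c_gene_id"}
    )
    rev = best_ba[["query", "subject"]].rename(
        columns={"query": "c_gene_id", "subject": "a_gene_id"}
    )
    pairs = fwd.merge(rev, on=["a_gene_id", "c_gene_id"])
    return pairs.sort_values(["a_gene_id", "c_gene_id"]).reset_index(drop=True)


def expression_bias(
    pairs: pd.DataFrame,
    expression: pd.DataFrame,
    tissue: str,
    fold: float = 2.0,
    expressed_threshold: float = EXPRESSED_FPKM,
) -> pd.DataFrame:
    """Per-pair expression-bias call in one tissue.

    A pair is A-biased iff max-FPKM(A) >= fold * max-FPKM(C) (inclusive),
    symmetrically C-biased, else unbiased.  Pairs whose two maxima are both
    below the expressed threshold are excluded; pairs with a member absent
    from the expression table are skipped with a warning.
    """
    maxima = (
        expression[expression["tissue"] == tissue]
        .groupby("gene_id")["fpkm"]
        .max()
    )
    rows = []
    for a, c in pairs[["a_gene_id", "c_gene_id"]].itertuples(index=False):
        if a not in maxima.index or c not in maxima.index:
            log.warning("pair (%s, %s) missing from expression table; skipped", a, c)
            continue
        ma, mc = float(maxima[a]), float(maxima[c])
        if ma < expressed_threshold and mc < expressed_threshold:
            continue
        if ma >= fold * mc:
            call = "A-biased"
        elif mc >= fold * ma:
            call = "C-biased"
        else:
            call = "unbiased"
        rows.append((a, c, ma, mc, call))
    return pd.DataFrame(rows, columns=["a_gene_id", "c_gene_id", "max_a", "max_c", "bias"])


def expressed_vs_annotated(
    genemap: pd.DataFrame, expressed: pd.Series
) -> tuple[pd.DataFrame, float]:
    """Per reference gene: (n_annotated, n_expressed) copies, plus the
    fraction of reference genes with at least one unexpressed copy."""
    df = genemap.copy()
    df["expressed"] = (
        df["polyploid_gene_id"].map(expressed).fillna(False).astype(bool)
    )
    per_ref = df.groupby("reference_gene_id", sort=True).agg(
        n_annotated=("polyploid_gene_id", "nunique"),
        n_expressed=("expressed", "sum"),
    )
    per_ref["n_expressed"] = per_ref["n_expressed"].astype(int)
    frac = float((per_ref["n_expressed"] < per_ref["n_annotated"]).mean()) if len(per_ref) else 0.0
    return per_ref.reset_index(), frac
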