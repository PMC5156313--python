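"""Dormancy-signature derivation and cross-cohort comparison.

A two-group expression comparison (dormant-like vs cycling cells) yields a
per-gene table of log2 fold-changes and Benjamini-Hochberg FDRs; the
signature is the set of genes passing FDR <= 0.05 and |log2FC| > 1, split by
direction and ranked by significance.  Signatures from different cohorts are
compared three ways: exact hypergeometric overlap enrichment, fold-change
sign concordance, and a weighted running-sum rank enrichment with a
gene-permutation null.

The differential test is a library-size-normalized two-sided rank-sum test —
a deliberately self-contained substitute for read-level single-cell
pipelines, adequate for synthetic count matrices.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import ExpressionMatrix

__all__ = [
    "differential_expression",
    "Signature",
    "derive_signature",
    "OverlapResult",
    "overlap_test",
    "ConcordanceResult",
    "concordance",
    "EnrichmentScore",
    "rank_enrichment",
]


def _normalize(counts: np.ndarray) -> np.ndarray:
    """Counts-per-median-depth: scale each cell to the median library size."""
    depth = counts.sum(axis=0)
    depth = np.where(depth == 0, 1.0, depth)
    return counts * (np.median(depth) / depth)


def differential_expression(
    matrix, groups=None, group_a: str | None = None, group_b: str | None = None
) -> pd.DataFrame:
    """Per-gene two-group comparison on a count matrix.

    Accepts an :class:`~lrckit.simulate.ExpressionMatrix` or a genes x cells
    DataFrame plus a per-cell group Series.  Counts are library-size
    normalized (counts per median depth); each gene gets a two-sided
    Mann-Whitney rank-sum test, BH adjustment across genes, and a log2
    fold-change of group-A over group-B means with pseudocount 1.  All-zero
    genes are carried with p = FDR = 1 and log2FC = 0.

    Returns a DataFrame indexed by gene: log2fc, stat, pvalue, fdr.
    """
    if isinstance(matrix, ExpressionMatrix):
        counts, groups = matrix.counts, matrix.groups
    else:
        counts = matrix
        if groups is None:
            raise ValueError("pass a group Series alongside a raw count matrix")
    groups = pd.Series(groups)
    levels = pd.unique(groups)
    if group_a is None or group_b is None:
        if len(levels) != 2:
            raise ValueError(
                "groups must have exactly two levels, or name group_a/group_b"
            )
        group_a, group_b = levels[0], levels[1]
    mask_a = (groups == group_a).to_numpy()
    mask_b = (groups == group_b).to_numpy()
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("need at least two cells per group")
    raw = counts.to_numpy(dtype=float)
    if np.any(raw < 0):
        raise ValueError("counts must be non-negative")

    norm = _normalize(raw)
    a, b = norm[:, mask_a], norm[:, mask_b]

    nonzero = raw.sum(axis=1) > 0
    pvals = np.ones(raw.shape[0])
    statv = np.full(raw.shape[0], np.nan)
    if nonzero.any():
        res = stats.mannwhitneyu(
            a[nonzero], b[nonzero], axis=1, alternative="two-sided"
        )
        pvals[nonzero] = res.pvalue
        statv[nonzero] = res.statistic
    log2fc = np.where(
        nonzero,
        np.log2((a.mean(axis=1) + 1.0) / (b.mean(axis=1) + 1.0)),
        0.0,
    )
    fdr = multipletests(pvals, method="fdr_bh")[1]
    return pd.DataFrame(
        {"log2fc": log2fc, "stat": statv, "pvalue": pvals, "fdr": fdr},
        index=counts.index.rename("gene"),
    )


@dataclass
class Signature:
    """Directional gene signature ranked by significance.

    ``frame`` is indexed by gene with columns direction ('up'/'down'),
    log2fc, fdr, pvalue and rank (1 = most significant).
    """

    frame: pd.DataFrame
    fdr_max: float
    min_abs_log2fc: float

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def up(self) -> list[str]:
        return list(self.frame.index[self.frame["direction"] == "up"])

    @property
    def down(self) -> list[str]:
        return list(self.frame.index[self.frame["direction"] == "down"])

    def __len__(self) -> int:
        return len(self.frame)

    def to_frame(self) -> pd.DataFrame:
        return self.frame.copy()


def derive_signature(
    de: pd.DataFrame, fdr_max: float = 0.05, min_abs_log2fc: float = 1.0
) -> Signature:
    """Signature genes: FDR <= fdr_max and |log2FC| strictly > min_abs_log2fc.

    Genes are split by fold-change direction and ranked by p-value (ties by
    |log2FC| descending).  Tightening either threshold can only shrink the
    signature; an empty signature is a valid result.
    """
    required = {"log2fc", "fdr"}
    if not required.issubset(de.columns):
        raise ValueError(f"DE table needs columns {sorted(required)}")
    keep = (de["fdr"] <= fdr_max) & (de["log2fc"].abs() > min_abs_log2fc)
    sub = de.loc[keep].copy()
    sub["direction"] = np.where(sub["log2fc"] > 0, "up", "down")
    sort_cols = ["pvalue"] if "pvalue" in sub.columns else ["fdr"]
    sub["_abs_lfc"] = -sub["log2fc"].abs()
    sub = sub.sort_values(sort_cols + ["_abs_lfc"]).drop(columns="_abs_lfc")
    sub["rank"] = np.arange(1, len(sub) + 1)
    cols = [c for c in ("direction", "log2fc", "fdr", "pvalue", "rank") if c in sub]
    return Signature(frame=sub[cols], fdr_max=fdr_max, min_abs_log2fc=min_abs_log2fc)


def _gene_list(sig) -> list[str]:
    if isinstance(sig, Signature):
        return sig.genes
    return list(sig)


@dataclass(frozen=True)
class OverlapResult:
    """Hypergeometric overlap enrichment between two gene sets."""

    overlap: int
    size_a: int
    size_b: int
    universe_size: int
    expected: float
    pvalue: float


def overlap_test(
    sig_a, sig_b, universe_size: int | None = None, universe=None,
    directional: bool = False,
) -> OverlapResult:
    """Exact hypergeometric upper-tail test of gene-set overlap.

    With sets A and B drawn from a universe of N genes, the p-value is
    P(overlap >= observed) under uniform sampling of B.  The directional
    variant counts only same-direction overlap (up∩up plus down∩down, both
    arguments must be :class:`Signature`) against the same null, which is
    conservative for discordant sets.
    """
    genes_a, genes_b = _gene_list(sig_a), _gene_list(sig_b)
    set_a, set_b = set(genes_a), set(genes_b)
    if len(set_a) != len(genes_a) or len(set_b) != len(genes_b):
        raise ValueError("signature gene lists contain duplicates")
    if universe is not None:
        uni = set(universe)
        outside = (set_a | set_b) - uni
        if outside:
            raise ValueError(
                f"genes outside the universe: {sorted(outside)[:10]}"
            )
        universe_size = len(uni)
    if universe_size is None:
        raise ValueError("pass universe_size or an explicit universe")
    if universe_size < len(set_a | set_b):
        raise ValueError("universe_size smaller than the union of signatures")
    if directional:
        if not (isinstance(sig_a, Signature) and isinstance(sig_b, Signature)):
            raise ValueError("directional overlap requires Signature inputs")
        k = len(set(sig_a.up) & set(sig_b.up)) + len(
            set(sig_a.down) & set(sig_b.down)
        )
    else:
        k = len(set_a & set_b)
    n_a, n_b, n = len(set_a), len(set_b), universe_size
    pvalue = float(stats.hypergeom.sf(k - 1, n, n_a, n_b))
    return OverlapResult(
        overlap=k,
        size_a=n_a,
        size_b=n_b,
        universe_size=n,
        expected=n_a * n_b / n,
        pvalue=pvalue,
    )


@dataclass(frozen=True)
class ConcordanceResult:
    """Fold-change sign agreement between two DE tables on a gene set."""

    agreement: float
    n_genes: int
    n_agree: int
    pvalue: float


def concordance(
    de_a: pd.DataFrame, de_b: pd.DataFrame, gene_set
) -> ConcordanceResult:
    """Fraction of genes whose fold-change signs match, with a binomial test.

    Genes must appear in both tables; signs are compared via sign(log2fc)
    (an exact zero only matches another exact zero).  The two-sided binomial
    test is against chance agreement of 0.5.
    """
    genes = list(gene_set)
    if not genes:
        raise ValueError("gene_set is empty")
    missing = [g for g in genes if g not in de_a.index or g not in de_b.index]
    if missing:
        raise ValueError(f"genes absent from a DE table: {missing[:10]}")
    sign_a = np.sign(de_a.loc[genes, "log2fc"].to_numpy())
    sign_b = np.sign(de_b.loc[genes, "log2fc"].to_numpy())
    agree = int((sign_a == sign_b).sum())
    n = len(genes)
    pvalue = float(stats.binomtest(agree, n, 0.5, alternative="two-sided").pvalue)
    return ConcordanceResult(
        agreement=agree / n, n_genes=n, n_agree=agree, pvalue=pvalue
    )


@dataclass(frozen=True)
class EnrichmentScore:
    """Running-sum enrichment of a signature in a ranked gene list."""

    es: float
    pvalue: float
    n_permutations: int
    leading_edge_size: int


def _running_sum_es(
    in_set: np.ndarray, weights: np.ndarray
) -> tuple[float, int]:
    """Signed maximum deviation of the running sum.

    Hits advance by their (absolute) weight normalized to the in-set total;
    misses decrement uniformly.  Returns (ES, index of the extremum).
    """
    n = in_set.size
    n_hit = int(in_set.sum())
    w = np.where(in_set, weights, 0.0)
    total = w.sum()
    if total <= 0:  # unweighted fallback inside an all-zero-weight set
        w = in_set.astype(float)
        total = w.sum()
    p_hit = np.cumsum(w) / total
    p_miss = np.cumsum(~in_set) / (n - n_hit)
    rs = p_hit - p_miss
    idx = int(np.argmax(np.abs(rs)))
    return float(rs[idx]), idx


def rank_enrichment(
    signature,
    ranked_genes,
    gene_stats=None,
    weighted: bool = True,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> EnrichmentScore:
    """Weighted running-sum enrichment with a gene-permutation null.

    ``ranked_genes`` is the full gene list ordered by a DE statistic (most
    up-regulated first); ``gene_stats``, aligned with it, supplies the hit
    weights (|statistic|) in weighted mode.  The null redraws the signature
    as a random gene set of the same size; the p-value compares the observed
    score against the same-sign half of the permutation null (with the usual
    +1 correction), which keeps null p-values uniform.
    """
    genes = list(ranked_genes)
    sig_genes = set(_gene_list(signature))
    n = len(genes)
    if len(sig_genes) == 0:
        raise ValueError("signature is empty")
    if len(sig_genes) >= n:
        raise ValueError("signature must be a strict subset of the ranked list")
    index = {g: i for i, g in enumerate(genes)}
    missing = sig_genes - index.keys()
    if missing:
        raise ValueError(f"signature genes not in ranked list: {sorted(missing)[:10]}")
    if weighted:
        if gene_stats is None:
            raise ValueError("weighted mode needs gene_stats aligned to the list")
        weights = np.abs(np.asarray(gene_stats, dtype=float))
        if weights.size != n:
            raise ValueError("gene_stats must align with ranked_genes")
    else:
        weights = np.ones(n)

    in_set = np.zeros(n, dtype=bool)
    in_set[[index[g] for g in sig_genes]] = True
    es, idx = _running_sum_es(in_set, weights)
    leading = int(in_set[: idx + 1].sum()) if es >= 0 else int(in_set[idx:].sum())

    rng = np.random.default_rng(seed)
    k = len(sig_genes)
    exceed = same_side = 0
    for _ in range(n_permutations):
        perm = np.zeros(n, dtype=bool)
        perm[rng.choice(n, size=k, replace=False)] = True
        es_p, _ = _running_sum_es(perm, weights)
        # calibrate against the same-sign half of the permutation null
        if es >= 0:
            same_side += es_p >= 0
            exceed += es_p >= es
        else:
            same_side += es_p < 0
            exceed += es_p <= es
    pvalue = (1.0 + exceed) / (1.0 + same_side)
    return EnrichmentScore(
        es=es,
        pvalue=pvalue,
        n_permutations=n_permutations,
        leading_edge_size=leading,
    )
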