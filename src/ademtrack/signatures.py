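"""Gene-set signature scoring and gene-set comparison.

The module score of a gene set in a cell (or sample) is the mean
log-normalized expression of the set minus the mean of expression-matched
control genes: genes are binned into equal-frequency bins by their
dataset-average expression, and for each set gene ``n_ctrl`` controls are
drawn from the same bin.  Scores are therefore centered against genes of
comparable abundance, and a constant shift of the expression matrix
leaves them unchanged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import GeneSet, ValidationError

__all__ = ["SignatureScore", "OverlapResult", "module_score", "set_overlap",
           "fc_concordance"]


@dataclass
class SignatureScore:
    scores: pd.Series                  # per cell/sample
    set_name: str
    n_bins: int
    n_ctrl: int
    seed: int


@dataclass
class OverlapResult:
    intersection: list[str]
    n_a: int
    n_b: int
    n_intersection: int
    n_universe: int
    p_hypergeometric: float


def _expression_bins(avg: pd.Series, n_bins: int) -> pd.Series:
    """Equal-frequency bins of dataset-average expression (ties broken by order)."""
    ranks = avg.rank(method="first")
    return pd.Series(pd.qcut(ranks, q=n_bins, labels=False), index=avg.index)


def module_score(expr: pd.DataFrame, gene_set: GeneSet,
                 n_bins: int = 25, n_ctrl: int = 100,
                 seed: int = 0) -> SignatureScore:
    """Expression-matched signature score per cell.

    Parameters
    ----------
    expr
        Cell x gene matrix of normalized log expression.
    gene_set
        Signature to score; every member must be a column of ``expr``.
    n_bins, n_ctrl
        Number of average-expression bins and controls per set gene.
        Controls are drawn from the set gene's bin without replacement
        when the bin is large enough, with replacement otherwise; the set
        gene itself is never its own control.
    """
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    if n_ctrl < 1:
        raise ValidationError("n_ctrl must be >= 1")
    missing = [g for g in gene_set.members if g not in expr.columns]
    if missing:
        raise ValidationError(f"set gene(s) absent from expression matrix: {missing}")
    if len(gene_set) > expr.shape[1] / 2:
        warnings.warn(
            f"gene set {gene_set.name!r} covers more than half the gene universe; "
            "expression-matched controls will overlap the set heavily", stacklevel=2)
    # every bin must hold at least two genes so each set gene has a control pool
    n_bins = max(min(n_bins, expr.shape[1] // 2), 2)
    avg = expr.mean(axis=0)
    bins = _expression_bins(avg, n_bins)
    rng = np.random.default_rng(seed)

    control_genes: list[str] = []
    for gene in gene_set.members:
        pool = bins.index[(bins == bins[gene]) & (bins.index != gene)].to_numpy()
        if len(pool) == 0:
            raise ValidationError(f"no control candidates share a bin with {gene!r}")
        replace = len(pool) < n_ctrl
        control_genes.extend(rng.choice(pool, size=n_ctrl, replace=replace).tolist())

    set_mean = expr.loc[:, list(gene_set.members)].mean(axis=1)
    ctrl_mean = expr.loc[:, control_genes].mean(axis=1)  # duplicates weight the mean
    scores = (set_mean - ctrl_mean).rename(f"score_{gene_set.name}")
    return SignatureScore(scores, gene_set.name, n_bins, n_ctrl, seed)


def set_overlap(a: GeneSet, b: GeneSet, universe) -> OverlapResult:
    """Exact overlap counts and one-sided hypergeometric enrichment p.

    ``p`` is the probability of observing at least the seen intersection
    when ``|b|`` genes are drawn from the universe uniformly without
    replacement, ``|a|`` of which are marked.
    """
    uni = set(universe)
    for s in (a, b):
        outside = sorted(set(s.members) - uni)
        if outside:
            raise ValidationError(f"gene set {s.name!r} has member(s) outside the "
                                  f"universe: {outside[:5]}")
    inter = sorted(set(a.members) & set(b.members))
    n, big_k, small_n, k = len(uni), len(a), len(b), len(inter)
    p = float(stats.hypergeom.sf(k - 1, n, big_k, small_n))
    return OverlapResult(inter, big_k, small_n, k, n, p)


def fc_concordance(fc_a: pd.Series, fc_b: pd.Series):
    """Pearson r and OLS fit of the log2 fold changes of shared genes.

    Returns (pearson_r, p, slope, intercept, n_shared).
    """
    fc_a = pd.Series(fc_a)
    fc_b = pd.Series(fc_b)
    shared = fc_a.index.intersection(fc_b.index)
    if len(shared) < 3:
        raise ValidationError(f"need >= 3 shared genes, found {len(shared)}")
    x = fc_a.loc[shared].to_numpy(dtype=float)
    y = fc_b.loc[shared].to_numpy(dtype=float)
    fit = stats.linregress(x, y)
    return (float(fit.rvalue), float(fit.pvalue), float(fit.slope),
            float(fit.intercept), int(len(shared)))
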