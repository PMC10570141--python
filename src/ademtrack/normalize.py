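"""Library-size normalization, the low-expression filter, and FDR adjustment.

CPM divides each column by its total and rescales to one million; FPKM
further divides by transcript length in kilobases.  Genes whose mean FPKM
across all samples falls below 10 are excluded before any trend analysis,
mirroring standard bulk RNA-seq practice for sorted-cell time courses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionSeries, ValidationError

__all__ = ["normalize_counts", "filter_low_expression", "adjust_pvalues"]


def normalize_counts(series: ExpressionSeries, method: str = "cpm") -> pd.DataFrame:
    """Return a normalized gene x sample matrix of the same shape.

    Parameters
    ----------
    series
        Input counts with metadata.
    method
        ``"cpm"`` (counts per million) or ``"fpkm"`` (CPM divided by the
        per-gene transcript length in kb; requires ``gene_lengths_kb``).
    """
    if method not in {"cpm", "fpkm"}:
        raise ValidationError(f"unknown normalization method {method!r}")
    totals = series.counts.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(f"sample(s) with zero total counts: {list(zero.index)}")
    cpm = series.counts.div(totals, axis=1) * 1e6
    if method == "cpm":
        return cpm
    if series.gene_lengths_kb is None:
        raise ValidationError("FPKM normalization requires gene_lengths_kb")
    return cpm.div(series.gene_lengths_kb, axis=0)


def filter_low_expression(series: ExpressionSeries,
                          threshold_fpkm: float = 10.0,
                          ) -> tuple[ExpressionSeries, list[str]]:
    """Drop genes whose mean FPKM across all samples is below the threshold.

    Genes with mean FPKM >= ``threshold_fpkm`` are retained in their
    original order ("fewer than ``threshold``" is excluded).  Returns the
    filtered series and the list of removed gene ids.
    """
    fpkm = normalize_counts(series, "fpkm")
    mean_fpkm = fpkm.mean(axis=1)
    keep = mean_fpkm >= threshold_fpkm
    if not keep.any():
        raise ValidationError(
            f"low-expression filter at {threshold_fpkm} FPKM removed every gene")
    kept = series.subset_genes(list(series.gene_ids[keep]))
    removed = list(series.gene_ids[~keep])
    return kept, removed


def adjust_pvalues(p, method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment.

    Accepts any 1-D sequence of p-values in [0, 1]; returns the adjusted
    values in the original order.
    """
    if method != "bh":
        raise ValidationError(f"unknown adjustment method {method!r}")
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size == 0:
        raise ValidationError("p-values must be a non-empty 1-D sequence")
    if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]
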