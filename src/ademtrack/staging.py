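"""PCA embedding, contiguous stage segmentation, and trajectory-shape calls.

Staging replaces visual inspection of a PCA plot with an explicit
optimization: timepoint summaries (replicate-averaged PC coordinates,
ordered by age) are partitioned into contiguous blocks minimizing
within-stage sum of squares, and the number of stages is chosen by a
penalized criterion.  Summaries are standardized per dimension (overall
variance 1) so the criterion is scale-free:

    criterion(S) = SSE_z(S) + penalty * S * dim * log(T)

with ``penalty`` defaulting to 0.5.  Ties prefer fewer stages and
earlier boundaries, so results are deterministic.

Trajectory shape contrasts three nested models of a (age, value) summary
curve — constant, linear in age, and a single persistent step at an
interior timepoint — and selects by Gaussian BIC.  A "switch" verdict
with its changepoint age operationalizes an abrupt phenotype transition;
"gradual" a progressive one.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .containers import ExpressionSeries, StageAssignment, TrajectoryShape, ValidationError
from .normalize import normalize_counts

__all__ = ["PCAEmbedding", "pca_embed", "timepoint_summaries", "segment_stages",
           "classify_trajectory_shape"]


@dataclass
class PCAEmbedding:
    coordinates: pd.DataFrame          # sample x component scores
    explained_variance: np.ndarray
    explained_variance_ratio: np.ndarray
    components: pd.DataFrame           # component x gene loadings


def pca_embed(series: ExpressionSeries, n_components: int = 2) -> PCAEmbedding:
    """PCA of samples on log2(CPM+1) expression.

    Components are sign-fixed so the largest-magnitude gene loading of
    each component is positive, making coordinates stable across runs.
    """
    max_rank = min(series.n_genes, series.n_samples)
    if not 1 <= n_components <= max_rank:
        raise ValidationError(f"n_components must lie in [1, {max_rank}]")
    x = np.log2(normalize_counts(series, "cpm").to_numpy().T + 1.0)
    if np.allclose(x.var(axis=0).sum(), 0.0):
        raise ValidationError("expression matrix has zero variance; PCA undefined")
    model = PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(x)
    loadings = model.components_
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] *= -1.0
            scores[:, k] *= -1.0
    cols = [f"PC{k + 1}" for k in range(n_components)]
    return PCAEmbedding(
        pd.DataFrame(scores, index=series.sample_ids, columns=cols),
        model.explained_variance_,
        model.explained_variance_ratio_,
        pd.DataFrame(loadings, index=cols, columns=series.gene_ids),
    )


def timepoint_summaries(series: ExpressionSeries, embedding: PCAEmbedding) -> pd.DataFrame:
    """Replicate-average the PC coordinates per timepoint (rows ordered by age)."""
    coords = embedding.coordinates.copy()
    coords["age_months"] = series.meta["age_months"].to_numpy()
    return coords.groupby("age_months").mean().sort_index()


def _partition_sse(z: np.ndarray, bounds: tuple[int, ...]) -> float:
    """Within-block SSE of z (T x d) for blocks split before each index in bounds."""
    edges = (0, *bounds, z.shape[0])
    sse = 0.0
    for a, b in zip(edges, edges[1:]):
        block = z[a:b]
        sse += float(((block - block.mean(axis=0)) ** 2).sum())
    return sse


def segment_stages(summaries: pd.DataFrame | np.ndarray,
                   max_stages: int = 4,
                   penalty: float = 0.5) -> StageAssignment:
    """Optimal contiguous partition of ordered timepoint summaries.

    ``summaries``: one row per timepoint (ordered by age), columns are
    summary dimensions (e.g. PC coordinates).  Exhaustive search over all
    contiguous partitions for each candidate S <= ``max_stages``; the
    criterion is the standardized within-stage SSE plus
    ``penalty * S * dim * log(T)``.
    """
    if isinstance(summaries, pd.DataFrame):
        ages = [float(a) for a in summaries.index]
        x = summaries.to_numpy(dtype=float)
    else:
        x = np.atleast_2d(np.asarray(summaries, dtype=float))
        if x.shape[0] == 1 and x.shape[1] > 1:
            x = x.T
        ages = list(range(x.shape[0]))
    if x.ndim == 1:
        x = x[:, None]
    n_t, dim = x.shape
    if n_t < 2:
        raise ValidationError("need at least 2 timepoints to segment")
    if not 1 <= max_stages <= n_t:
        raise ValidationError(f"max_stages must lie in [1, {n_t}]")

    sd = x.std(axis=0)
    keep = sd > 0
    if not keep.any():
        labels = [1] * n_t
        return StageAssignment(ages, labels, 1, 0.0, {1: 0.0})
    z = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]

    log_t = np.log(n_t)
    best_bounds: tuple[int, ...] = ()
    best_crit = float("inf")
    best_s = 1
    trace: dict[int, float] = {}
    for s in range(1, max_stages + 1):
        s_best_sse = float("inf")
        s_best_bounds: tuple[int, ...] = ()
        for bounds in combinations(range(1, n_t), s - 1):
            sse = _partition_sse(z, bounds)
            if sse < s_best_sse - 1e-12:
                s_best_sse = sse
                s_best_bounds = bounds
        crit = s_best_sse + penalty * s * dim * log_t
        trace[s] = crit
        if crit < best_crit - 1e-12:
            best_crit = crit
            best_bounds = s_best_bounds
            best_s = s
    labels = np.ones(n_t, dtype=int)
    for b in best_bounds:
        labels[b:] += 1
    raw_sse = _partition_sse(x, best_bounds)
    return StageAssignment(ages, labels.tolist(), best_s, raw_sse, trace)


def _gaussian_bic(rss: float, n: int, k: int, floor: float) -> float:
    return n * np.log(max(rss, floor) / n) + k * np.log(n)


def classify_trajectory_shape(ages, values) -> TrajectoryShape:
    """Constant vs linear vs single-step model contest by Gaussian BIC.

    ``ages``/``values`` are ordered per-timepoint summaries (one value
    per timepoint, at least 4 timepoints).  The step model places one
    persistent jump before each interior timepoint and keeps the best.
    The changepoint age is the first post-step timepoint.  Ties prefer
    the simpler model (flat < gradual < switch).
    """
    ages = np.asarray(ages, dtype=float)
    values = np.asarray(values, dtype=float)
    n = ages.size
    if n < 4 or values.size != n:
        raise ValidationError("need >= 4 (age, value) pairs")
    if np.any(np.diff(ages) <= 0):
        raise ValidationError("ages must be strictly increasing")

    scale = float(values.var()) * n
    floor = max(scale, 1.0) * 1e-12

    mean = float(values.mean())
    rss_flat = float(((values - mean) ** 2).sum())
    bic_flat = _gaussian_bic(rss_flat, n, 1, floor)

    slope, intercept = np.polyfit(ages, values, 1)
    rss_lin = float(((values - (slope * ages + intercept)) ** 2).sum())
    bic_lin = _gaussian_bic(rss_lin, n, 2, floor)

    best_step = None
    for cp in range(1, n):                       # step occurs before index cp
        m1 = float(values[:cp].mean())
        m2 = float(values[cp:].mean())
        rss = float(((values[:cp] - m1) ** 2).sum() + ((values[cp:] - m2) ** 2).sum())
        if best_step is None or rss < best_step[0] - 1e-15:
            best_step = (rss, cp, m1, m2)
    rss_step, cp, m1, m2 = best_step
    bic_step = _gaussian_bic(rss_step, n, 3, floor)

    delta_bic = float(bic_lin - bic_step)
    order = [("flat", bic_flat), ("gradual", bic_lin), ("switch", bic_step)]
    shape = min(order, key=lambda t: t[1])[0]    # ties resolved toward simpler (list order)
    return TrajectoryShape(
        shape=shape,
        changepoint_age=float(ages[cp]) if shape == "switch" else None,
        delta_bic=delta_bic,
        linear_params=(float(slope), float(intercept)),
        step_params=(m1, m2) if shape == "switch" else None,
    )
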