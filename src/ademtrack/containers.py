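"""Core in-memory containers shared across the pipeline.

The central object is :class:`ExpressionSeries`: an integer gene-by-sample
count matrix with per-sample age metadata, ordered so that downstream
operations (neighbor-timepoint differential expression, staging, trend
calling) can rely on a well-defined age axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionSeries",
    "DEResult",
    "ADEMCall",
    "StageAssignment",
    "TrajectoryShape",
    "GeneSet",
    "TurnoverRecord",
    "TelomereAssay",
    "ShollProfile",
]


class ValidationError(ValueError):
    """Raised when an input container violates its documented invariants."""


@dataclass
class ExpressionSeries:
    """Gene x sample count matrix plus ordered per-sample age metadata.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integer counts, genes as rows (index =
        gene ids), samples as columns.
    meta
        DataFrame indexed by sample id with columns ``age_months``
        (positive real), ``sex`` ({"F", "M"}) and ``replicate`` (int).
        Must align one-to-one with the columns of ``counts``.
    gene_lengths_kb
        Optional per-gene transcript length in kilobases (required for
        FPKM normalization and the low-expression filter).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame
    gene_lengths_kb: pd.Series | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.counts, pd.DataFrame):
            raise ValidationError("counts must be a pandas DataFrame")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids: {dups[:5]}")
        vals = self.counts.to_numpy()
        if vals.size == 0:
            raise ValidationError("counts matrix is empty")
        if np.issubdtype(vals.dtype, np.floating):
            if not np.all(np.isfinite(vals)) or not np.all(vals == np.floor(vals)):
                raise ValidationError("non-integer counts detected; counts must be integers")
            self.counts = self.counts.astype(np.int64)
            vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValidationError("negative counts detected")

        required = {"age_months", "sex", "replicate"}
        missing = required - set(self.meta.columns)
        if missing:
            raise ValidationError(f"metadata missing column(s): {sorted(missing)}")
        extra = set(self.meta.index) - set(self.counts.columns)
        absent = set(self.counts.columns) - set(self.meta.index)
        if extra:
            raise ValidationError(f"metadata lists sample(s) absent from counts: {sorted(extra)}")
        if absent:
            raise ValidationError(f"counts column(s) missing from metadata: {sorted(absent)}")
        # align metadata row order to the count columns; canonical axis names
        self.meta = self.meta.loc[list(self.counts.columns)]
        self.counts.index.name = "gene_id"
        self.meta.index.name = "sample_id"
        ages = pd.to_numeric(self.meta["age_months"], errors="coerce")
        if ages.isna().any():
            bad = self.meta.index[ages.isna()].tolist()
            raise ValidationError(f"non-numeric age_months for sample(s): {bad}")
        if (ages <= 0).any():
            raise ValidationError("age_months must be positive")
        self.meta = self.meta.assign(age_months=ages.astype(float))

        if self.gene_lengths_kb is not None:
            gl = pd.Series(self.gene_lengths_kb)
            if not gl.index.equals(self.counts.index):
                gl = gl.reindex(self.counts.index)
            if gl.isna().any() or (gl <= 0).any():
                raise ValidationError("gene_lengths_kb must be positive and cover every gene")
            self.gene_lengths_kb = gl.astype(float)

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def timepoints(self) -> list[float]:
        """Distinct ages in increasing order."""
        return sorted(set(self.meta["age_months"].tolist()))

    def samples_at(self, age: float) -> list[str]:
        mask = self.meta["age_months"] == age
        return list(self.meta.index[mask])

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionSeries":
        lengths = None
        if self.gene_lengths_kb is not None:
            lengths = self.gene_lengths_kb.loc[list(genes)]
        return ExpressionSeries(self.counts.loc[list(genes)], self.meta.copy(), lengths)


@dataclass
class DEResult:
    """Per-gene differential-expression summary for one comparison.

    ``table`` has one row per gene with columns ``log2fc``, ``p``,
    ``p_adj``, ``mean_a`` and ``mean_b`` (library-size-normalized group
    means).  For multigroup tests ``log2fc`` is the maximum-|log2fc|
    pairwise contrast and the mean columns hold the extreme group means.
    """

    table: pd.DataFrame
    comparison: str

    def __post_init__(self) -> None:
        required = {"log2fc", "p", "p_adj", "mean_a", "mean_b"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"DE table missing column(s): {sorted(missing)}")


#: DEG gate from the source study: raw P < 0.05 and |log2FC| > log2(1.5)
DEG_P_THRESHOLD = 0.05
DEG_LOG2FC_THRESHOLD = math.log2(1.5)


def passes_deg_gate(p: float, log2fc: float,
                    p_threshold: float = DEG_P_THRESHOLD,
                    lfc_threshold: float = DEG_LOG2FC_THRESHOLD) -> bool:
    """Two-group DEG criterion: p below threshold and |log2fc| above log2(1.5)."""
    return (p < p_threshold) and (abs(log2fc) > lfc_threshold)


@dataclass
class ADEMCall:
    """Trend verdict for one gene.

    direction is ``"P-ADEM"`` (persistently up with age), ``"N-ADEM"``
    (persistently down) or ``"none"``.  ``run_start``/``run_end`` are
    timepoint indices (0-based, inclusive) of the reported monotone
    window; ``run_length`` counts timepoints in that window.
    """

    gene_id: str
    direction: str
    run_start: int
    run_end: int
    run_length: int
    n_significant_steps: int
    pearson_r: float
    pearson_p: float

    def __post_init__(self) -> None:
        if self.direction not in {"P-ADEM", "N-ADEM", "none"}:
            raise ValidationError(f"invalid direction {self.direction!r}")
        if self.direction != "none" and self.run_length != self.run_end - self.run_start + 1:
            raise ValidationError("run_length inconsistent with run window")


@dataclass
class StageAssignment:
    """Contiguous grouping of ordered timepoints into stages 1..S."""

    ages: list[float]
    labels: list[int]                      # stage label per timepoint, 1-based
    n_stages: int
    sse: float                             # within-stage SSE on the original scale
    criterion: dict[int, float] = field(default_factory=dict)  # candidate S -> criterion

    def __post_init__(self) -> None:
        if len(self.ages) != len(self.labels):
            raise ValidationError("ages and labels must align")
        if sorted(self.labels) != self.labels:
            raise ValidationError("stage labels must be non-decreasing with age")

    def boundaries(self) -> list[int]:
        """Indices where a new stage begins (excluding 0)."""
        return [i for i in range(1, len(self.labels)) if self.labels[i] != self.labels[i - 1]]


@dataclass
class TrajectoryShape:
    """Gradual vs switch-like vs flat verdict for a timepoint summary curve."""

    shape: str                             # "gradual" | "switch" | "flat"
    changepoint_age: float | None          # age of the first post-switch timepoint
    delta_bic: float                       # BIC(linear) - BIC(step); positive favors switch
    linear_params: tuple[float, float]     # (slope, intercept)
    step_params: tuple[float, float] | None  # (mean_before, mean_after)

    def __post_init__(self) -> None:
        if self.shape not in {"gradual", "switch", "flat"}:
            raise ValidationError(f"invalid shape {self.shape!r}")
        if self.shape == "switch" and self.changepoint_age is None:
            raise ValidationError("switch shape requires a changepoint age")


@dataclass(frozen=True)
class GeneSet:
    """Named gene set (e.g. the P-ADEM signature, DAM, ARM)."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.members)) != len(self.members):
            # dedup while preserving order
            seen: dict[str, None] = {}
            for m in self.members:
                seen.setdefault(m)
            object.__setattr__(self, "members", tuple(seen))

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class TurnoverRecord:
    """Per-round (residual density, recovered density) pairs, cells/mm^2."""

    rounds: list[tuple[float, float]]

    def __post_init__(self) -> None:
        if not self.rounds:
            raise ValidationError("turnover record must contain at least one round")
        for i, (res, rec) in enumerate(self.rounds):
            if res <= 0 or rec <= 0:
                raise ValidationError(f"round {i + 1}: densities must be positive")


@dataclass
class TelomereAssay:
    """qPCR quantification cycles for telomere and single-copy reference."""

    cq_target_tel: float
    cq_ref_tel: float
    cq_target_scr: float
    cq_ref_scr: float
    ref_length_kb: float

    def __post_init__(self) -> None:
        for name in ("cq_target_tel", "cq_ref_tel", "cq_target_scr", "cq_ref_scr"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValidationError(f"{name} must be finite and positive")
        if self.ref_length_kb <= 0:
            raise ValidationError("ref_length_kb must be positive")


@dataclass
class ShollProfile:
    """Sholl intersection counts on a uniform radius grid (micrometres)."""

    radii: np.ndarray
    intersections: np.ndarray
    density: float | None = None           # optional cells/mm^2 for the senescence index

    def __post_init__(self) -> None:
        self.radii = np.asarray(self.radii, dtype=float)
        self.intersections = np.asarray(self.intersections)
        if self.radii.ndim != 1 or self.radii.size != self.intersections.size:
            raise ValidationError("radii and intersections must be 1-D and equal length")
        steps = np.diff(self.radii)
        if self.radii.size >= 2:
            if (steps <= 0).any():
                raise ValidationError("radii must be strictly increasing")
            if not np.allclose(steps, steps[0]):
                raise ValidationError("radius grid must have a uniform step")
        if (np.asarray(self.intersections) < 0).any():
            raise ValidationError("intersection counts must be nonnegative")
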