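"""Synthetic data generators with known ground truth.

Every generator is a pure function of its parameters and a single integer
seed; all internal randomness derives from ``numpy.random.default_rng(seed)``.

``simulate_bulk_series`` emulates a sorted-microglia bulk RNA-seq time
course: seven ages (3-24 months by default), a handful of replicates per
age, negative-binomial counts (Var = mu + alpha mu^2, shared dispersion),
and four classes of trend genes — gradual risers/fallers that change by a
fixed log2 amount per adjacent timepoint, and switch genes that jump once
and stay, mimicking an abrupt phenotype transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionSeries, ShollProfile, TelomereAssay, TurnoverRecord, ValidationError

__all__ = [
    "BulkSimSpec",
    "SimTruth",
    "simulate_bulk_series",
    "simulate_cell_counts",
    "simulate_sholl_profiles",
    "simulate_qpcr_plate",
    "simulate_turnover_densities",
]

#: female-series ages (months) used throughout the study design
DEFAULT_TIMEPOINTS = (3.0, 6.0, 9.0, 12.0, 14.0, 16.0, 24.0)

GENE_LABELS = ("up_gradual", "down_gradual", "up_switch", "down_switch", "null")


@dataclass
class BulkSimSpec:
    """Design of a simulated bulk count time course.

    Effects are in log2 units per adjacent timepoint step (gradual genes)
    or as a single persistent jump at ``switch_timepoint`` (switch genes).
    ``baseline_log2_mean_range`` bounds the uniform draw of per-gene log2
    baseline means; ``lib_size_range`` bounds log-uniform per-sample
    library-size factors; counts are NB with shared dispersion ``alpha``
    (Var = mu + alpha mu^2).
    """

    n_genes: int = 2000
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    reps_per_timepoint: tuple[int, ...] | int = 3
    n_up_gradual: int = 100
    n_down_gradual: int = 100
    n_up_switch: int = 0
    n_down_switch: int = 0
    per_step_log2_effect: float = 0.3
    switch_log2_effect: float = 1.0
    switch_timepoint: int = 3
    dispersion: float = 0.1
    baseline_log2_mean_range: tuple[float, float] = (4.0, 10.0)
    lib_size_range: tuple[float, float] = (0.7, 1.3)
    sex: str = "F"
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.reps_per_timepoint, int):
            self.reps_per_timepoint = tuple([self.reps_per_timepoint] * len(self.timepoints))
        if self.n_genes < 1:
            raise ValidationError("n_genes must be positive")
        if len(self.reps_per_timepoint) != len(self.timepoints):
            raise ValidationError("reps_per_timepoint length must match timepoints")
        if any(r < 2 for r in self.reps_per_timepoint):
            raise ValidationError("reps_per_timepoint: every timepoint needs >= 2 replicates")
        tp = list(self.timepoints)
        if sorted(set(tp)) != tp:
            raise ValidationError("timepoints must be strictly increasing")
        n_trend = (self.n_up_gradual + self.n_down_gradual
                   + self.n_up_switch + self.n_down_switch)
        if any(n < 0 for n in (self.n_up_gradual, self.n_down_gradual,
                               self.n_up_switch, self.n_down_switch)):
            raise ValidationError("trend gene counts must be nonnegative")
        if n_trend > self.n_genes:
            raise ValidationError("trend-gene counts sum exceeds n_genes")
        if self.per_step_log2_effect < 0:
            raise ValidationError("per_step_log2_effect must be >= 0")
        if self.switch_log2_effect < 0:
            raise ValidationError("switch_log2_effect must be >= 0")
        if not 0 < self.switch_timepoint < len(self.timepoints):
            raise ValidationError("switch_timepoint must be an interior timepoint index")
        if self.dispersion <= 0:
            raise ValidationError("dispersion must be > 0")
        lo, hi = self.baseline_log2_mean_range
        if hi < lo:
            raise ValidationError("baseline_log2_mean_range must be (lo, hi) with lo <= hi")
        lo, hi = self.lib_size_range
        if lo <= 0 or hi < lo:
            raise ValidationError("lib_size_range must be positive with lo <= hi")


@dataclass
class SimTruth:
    """Ground truth attached to a simulated series."""

    labels: pd.Series                    # per-gene class label
    true_means: pd.DataFrame             # gene x timepoint expected normalized mean
    lib_sizes: pd.Series                 # per-sample library-size factor
    seed: int = 0

    def genes_with_label(self, label: str) -> list[str]:
        if label not in GENE_LABELS:
            raise ValidationError(f"unknown label {label!r}")
        return list(self.labels.index[self.labels == label])


def _trend_matrix(spec: BulkSimSpec, rng: np.random.Generator) -> tuple[pd.Series, np.ndarray]:
    n_t = len(spec.timepoints)
    steps = np.arange(n_t, dtype=float)
    jump = (steps >= spec.switch_timepoint).astype(float)
    labels = np.array(
        ["up_gradual"] * spec.n_up_gradual
        + ["down_gradual"] * spec.n_down_gradual
        + ["up_switch"] * spec.n_up_switch
        + ["down_switch"] * spec.n_down_switch
        + ["null"] * (spec.n_genes - spec.n_up_gradual - spec.n_down_gradual
                      - spec.n_up_switch - spec.n_down_switch))
    labels = labels[rng.permutation(spec.n_genes)]
    trend = np.zeros((spec.n_genes, n_t))
    trend[labels == "up_gradual"] = spec.per_step_log2_effect * steps
    trend[labels == "down_gradual"] = -spec.per_step_log2_effect * steps
    trend[labels == "up_switch"] = spec.switch_log2_effect * jump
    trend[labels == "down_switch"] = -spec.switch_log2_effect * jump
    return pd.Series(labels), trend


def simulate_bulk_series(spec: BulkSimSpec) -> tuple[ExpressionSeries, SimTruth]:
    """Draw a bulk NB count time course and its ground truth.

    Counts for gene g, timepoint t, replicate j are NB with mean
    ``2**(baseline_g + trend_g(t)) * lib_size_j`` and shared dispersion.
    """
    rng = np.random.default_rng(spec.seed)
    labels, trend = _trend_matrix(spec, rng)
    lo, hi = spec.baseline_log2_mean_range
    baseline = rng.uniform(lo, hi, spec.n_genes)
    gene_ids = [f"g{i:05d}" for i in range(spec.n_genes)]
    labels.index = pd.Index(gene_ids)
    true_means = pd.DataFrame(2.0 ** (baseline[:, None] + trend),
                              index=gene_ids, columns=list(spec.timepoints))

    sample_ids, ages, sexes, rep_nums = [], [], [], []
    for age, reps in zip(spec.timepoints, spec.reps_per_timepoint):
        for j in range(reps):
            sample_ids.append(f"{spec.sex}{age:g}m_r{j + 1}")
            ages.append(age)
            sexes.append(spec.sex)
            rep_nums.append(j + 1)
    llo, lhi = spec.lib_size_range
    lib = np.exp(rng.uniform(np.log(llo), np.log(lhi), len(sample_ids)))

    shape = 1.0 / spec.dispersion
    count_cols = []
    col = 0
    tm = true_means.to_numpy()
    for t_idx, reps in enumerate(spec.reps_per_timepoint):
        for _ in range(reps):
            mu = tm[:, t_idx] * lib[col]
            lam = rng.gamma(shape, mu / shape)
            count_cols.append(rng.poisson(lam))
            col += 1
    counts = pd.DataFrame(np.stack(count_cols, axis=1), index=gene_ids, columns=sample_ids)
    meta = pd.DataFrame({"age_months": ages, "sex": sexes, "replicate": rep_nums},
                        index=pd.Index(sample_ids, name="sample_id"))
    lengths = pd.Series(np.exp(rng.uniform(np.log(0.5), np.log(5.0), spec.n_genes)),
                        index=gene_ids, name="length_kb")
    series = ExpressionSeries(counts, meta, lengths)
    truth = SimTruth(labels, true_means,
                     pd.Series(lib, index=sample_ids), seed=spec.seed)
    return series, truth


def simulate_timepoint_summaries(true_values,
                                 ages=None,
                                 n_replicates: int = 3,
                                 noise_sd: float = 1.0 / 3.0,
                                 seed: int = 0) -> pd.DataFrame:
    """Replicate-averaged per-timepoint summary values around a true profile.

    Emulates what staging and shape classification actually consume: each
    timepoint contributes ``n_replicates`` noisy samples (Gaussian,
    ``noise_sd``) around its true value, and the summary is their mean —
    mirroring a design with a few animals per age group.  Returns a
    DataFrame indexed by age with a single ``summary`` column.
    """
    true_values = np.asarray(true_values, dtype=float)
    if ages is None:
        ages = list(DEFAULT_TIMEPOINTS)[: true_values.size]
    ages = [float(a) for a in ages]
    if len(ages) != true_values.size:
        raise ValidationError("ages and true_values must align")
    if n_replicates < 1:
        raise ValidationError("n_replicates must be >= 1")
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    noisy = true_values[None, :] + rng.normal(0.0, noise_sd,
                                              (n_replicates, true_values.size))
    return pd.DataFrame({"summary": noisy.mean(axis=0)},
                        index=pd.Index(ages, name="age_months"))


def simulate_cell_counts(n_cells_per_group: tuple[int, int],
                         n_genes: int,
                         signature_genes: list[str],
                         shift_log2: float,
                         seed: int = 0,
                         dispersion: float = 0.5,
                         ) -> tuple[pd.DataFrame, pd.Series]:
    """Single-cell-like counts with a group-specific gene-set shift.

    Two groups, ``control`` and ``shifted``; signature genes in the
    shifted group have their means scaled by ``2**shift_log2``.  Returns
    a cell x gene count DataFrame and a per-cell group label Series.
    Gene ids are ``c00000`` .. ``c{n_genes-1:05d}``.
    """
    gene_ids = [f"c{i:05d}" for i in range(n_genes)]
    unknown = [g for g in signature_genes if g not in set(gene_ids)]
    if unknown:
        raise ValidationError(f"signature gene(s) outside the gene universe: {unknown}")
    if len(n_cells_per_group) != 2 or any(n < 1 for n in n_cells_per_group):
        raise ValidationError("n_cells_per_group must be two positive counts")
    rng = np.random.default_rng(seed)
    base = np.exp(rng.uniform(np.log(0.2), np.log(20.0), n_genes))
    sig_mask = np.isin(np.array(gene_ids), np.array(signature_genes))
    n_ctrl_cells, n_shift_cells = n_cells_per_group
    mean_ctrl = base
    mean_shift = np.where(sig_mask, base * 2.0 ** shift_log2, base)
    shape = 1.0 / dispersion
    rows = []
    for mu_vec, n_cells in ((mean_ctrl, n_ctrl_cells), (mean_shift, n_shift_cells)):
        depth = np.exp(rng.uniform(np.log(0.7), np.log(1.3), n_cells))
        lam = rng.gamma(shape, (depth[:, None] * mu_vec[None, :]) / shape)
        rows.append(rng.poisson(lam))
    counts = pd.DataFrame(np.vstack(rows),
                          index=[f"cell{i:05d}" for i in range(n_ctrl_cells + n_shift_cells)],
                          columns=gene_ids)
    labels = pd.Series(["control"] * n_ctrl_cells + ["shifted"] * n_shift_cells,
                       index=counts.index, name="group")
    return counts, labels


def simulate_sholl_profiles(n_cells: int,
                            radii: np.ndarray | None = None,
                            peak_height: float = 10.0,
                            peak_radius: float = 20.0,
                            noise_sd: float = 0.0,
                            seed: int = 0,
                            width: float | None = None,
                            ) -> list[ShollProfile]:
    """Per-cell Sholl intersection curves around a unimodal template.

    The template is Gaussian in radius with the stated peak; per-cell
    peak heights jitter by ``noise_sd`` (truncated at 0) and counts are
    Poisson around the scaled template, so profiles are nonnegative
    integers.  The default grid starts at 5 um and steps by 5 um.
    """
    if radii is None:
        radii = np.arange(5.0, 65.0, 5.0)
    radii = np.asarray(radii, dtype=float)
    steps = np.diff(radii)
    if radii.size < 2 or (steps <= 0).any() or not np.allclose(steps, steps[0]):
        raise ValidationError("radii must be a uniform strictly increasing grid")
    if peak_height < 0:
        raise ValidationError("peak_height must be >= 0")
    w = width if width is not None else max(peak_radius / 2.0, 1e-6)
    template = np.exp(-0.5 * ((radii - peak_radius) / w) ** 2)
    rng = np.random.default_rng(seed)
    profiles = []
    for _ in range(n_cells):
        h = max(peak_height + rng.normal(0.0, noise_sd) if noise_sd > 0 else peak_height, 0.0)
        counts = rng.poisson(h * template) if h > 0 else np.zeros_like(radii, dtype=int)
        profiles.append(ShollProfile(radii.copy(), counts.astype(int)))
    return profiles


def simulate_qpcr_plate(true_length_ratio: float,
                        ref_length_kb: float = 100.0,
                        cq_noise_sd: float = 0.0,
                        seed: int = 0) -> TelomereAssay:
    """qPCR plate whose noiseless read-out reproduces ``true_length_ratio``.

    The telomere-formula exponent is (dCq_tel - dCq_scr) with dCq =
    Cq_target - Cq_reference, so the plate sets dCq_tel =
    log2(true_length_ratio) and dCq_scr = 0, plus optional Gaussian Cq
    noise on every well.
    """
    if true_length_ratio <= 0:
        raise ValidationError("true_length_ratio must be positive")
    if ref_length_kb <= 0:
        raise ValidationError("ref_length_kb must be positive")
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, cq_noise_sd, 4) if cq_noise_sd > 0 else np.zeros(4)
    cq_ref_tel = 20.0
    cq_target_tel = cq_ref_tel + float(np.log2(true_length_ratio))
    cq_ref_scr = 22.0
    cq_target_scr = 22.0
    return TelomereAssay(cq_target_tel + noise[0], cq_ref_tel + noise[1],
                         cq_target_scr + noise[2], cq_ref_scr + noise[3],
                         ref_length_kb)


def simulate_turnover_densities(n_rounds: int,
                                residual_fraction: float,
                                recovered_density: float = 220.0,
                                seed: int = 0,
                                noise_sd: float = 0.0,
                                ) -> tuple[TurnoverRecord, float]:
    """Depletion-repopulation density pairs with exact division truth.

    Each round leaves ``residual_fraction`` of the recovered density and
    repopulates back to ``recovered_density`` (optionally jittered on the
    log scale by ``noise_sd``).  The returned truth is the exact sum of
    per-round log2(recovered / residual) over the generated pairs.
    """
    if not 0.0 < residual_fraction < 1.0:
        raise ValidationError("residual_fraction must lie in (0, 1)")
    if n_rounds < 1:
        raise ValidationError("n_rounds must be >= 1")
    if recovered_density <= 0:
        raise ValidationError("recovered_density must be positive")
    rng = np.random.default_rng(seed)
    rounds = []
    for _ in range(n_rounds):
        jitter = np.exp(rng.normal(0.0, noise_sd, 2)) if noise_sd > 0 else np.ones(2)
        recovered = recovered_density * jitter[0]
        residual = recovered * residual_fraction * jitter[1]
        rounds.append((float(residual), float(recovered)))
    record = TurnoverRecord(rounds)
    truth = float(sum(np.log2(rec / res) for res, rec in rounds))
    return record, truth
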