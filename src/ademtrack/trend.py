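"""Age-dependent gene (ADEM) calling from neighbor-timepoint comparisons.

A gene is P-ADEM when its group-mean expression rises persistently over a
window of at least ``min_run`` consecutive timepoints (N-ADEM for
falling), and it passes a differential-expression gate.  Persistence is
assessed on log2 group means: within an up-window no step may fall by
more than a tolerance, and the window's net change must be positive.

The default tolerance is noise-adaptive: each step may move against the
trend by at most ``z`` standard errors of the between-timepoint log2 mean
difference (z = 1 by default), so a fixed expression scale is never
assumed.  A fixed tolerance (``epsilon``) and the strict rule
(``epsilon = 0``, ``step_tolerance_z = 0``) remain available.

The DEG gate defaults to membership in the multigroup DEG set (one-way NB
test across all timepoints, BH-adjusted P < 0.05 and at least one
pairwise |log2FC| > log2 1.5).  Alternatives: require a significant
neighbor step inside the window, or no gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ADEMCall,
    DEG_LOG2FC_THRESHOLD,
    DEG_P_THRESHOLD,
    DEResult,
    ExpressionSeries,
    ValidationError,
    passes_deg_gate,
)
from .de import estimate_dispersions, nb_de_multigroup, nb_de_pairwise, size_factors
from .normalize import normalize_counts

__all__ = ["NeighborScan", "AgeCorrelation", "neighbor_comparisons", "classify_adem",
           "age_correlation"]


@dataclass
class NeighborScan:
    """All adjacent-timepoint comparisons for one series.

    ``group_means``/``group_sems`` are gene x timepoint matrices of
    normalized (CPM-scale) means and their standard errors;
    ``comparisons[i]`` tests timepoint i vs i+1 (log2fc oriented later
    over earlier); ``multigroup`` is the one-way test over all
    timepoints used for the default DEG gate.
    """

    timepoints: list[float]
    group_means: pd.DataFrame
    group_sems: pd.DataFrame
    comparisons: list[DEResult]
    multigroup: DEResult | None = None

    def __post_init__(self) -> None:
        if len(self.comparisons) != len(self.timepoints) - 1:
            raise ValidationError("need exactly T-1 neighbor comparisons")
        tp = self.timepoints
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValidationError("timepoints must be strictly increasing")


@dataclass
class AgeCorrelation:
    """OLS of normalized expression on age for a single gene."""

    pearson_r: float
    pearson_p: float
    slope: float
    intercept: float
    slope_ci95: tuple[float, float]
    degenerate: bool = False


def neighbor_comparisons(series: ExpressionSeries,
                         with_multigroup: bool = True) -> NeighborScan:
    """Run the NB test between every pair of adjacent timepoints.

    The dispersion fit and size factors are estimated once from the full
    series (all timepoint groups) and shared across the pairwise tests,
    which both stabilizes the estimates and makes the scan internally
    consistent.
    """
    ages = series.timepoints()
    if len(ages) < 2:
        raise ValidationError("need at least 2 timepoints")
    groups = [series.samples_at(a) for a in ages]
    for a, g in zip(ages, groups):
        if len(g) < 2:
            raise ValidationError(f"timepoint {a} months has fewer than 2 replicates")

    counts = series.counts.to_numpy(dtype=float)
    sf = size_factors(series.counts)
    idx = [np.array([series.counts.columns.get_loc(s) for s in g]) for g in groups]
    disp = estimate_dispersions(counts, sf.to_numpy(), idx)

    norm = counts / sf.to_numpy()
    means = np.stack([norm[:, g].mean(axis=1) for g in idx], axis=1)
    # model-based SE of the group mean, Var(y/s) = q/s + alpha q^2, using the
    # moderated dispersion -- far more stable than a 2-df empirical SEM
    sf_arr = sf.to_numpy()
    sems = np.stack([
        np.sqrt((means[:, k] * np.mean(1.0 / sf_arr[g])
                 + disp.alpha * means[:, k] ** 2) / len(g))
        for k, g in enumerate(idx)
    ], axis=1)
    gm = pd.DataFrame(means, index=series.gene_ids, columns=ages)
    gs = pd.DataFrame(sems, index=series.gene_ids, columns=ages)

    comparisons = [
        nb_de_pairwise(series, groups[i], groups[i + 1],
                       dispersion=disp, sf=sf,
                       comparison=f"{ages[i + 1]:g}m_vs_{ages[i]:g}m")
        for i in range(len(ages) - 1)
    ]
    multigroup = None
    if with_multigroup and len(ages) >= 3:
        multigroup = nb_de_multigroup(series, groups, dispersion=disp, sf=sf,
                                      comparison="all_timepoints")
    return NeighborScan(ages, gm, gs, comparisons, multigroup)


def _best_window(diffs: np.ndarray, tol: np.ndarray, sign: int) -> tuple[int, int] | None:
    """Longest window of steps compatible with the signed trend.

    A step is compatible when sign*diff > -tol; the window's net signed
    change must be positive.  Returns (first_step, last_step) indices of
    the earliest longest window, or None.
    """
    n = len(diffs)
    best: tuple[int, int] | None = None
    best_len = 0
    s = sign * diffs
    for i in range(n):
        if s[i] <= -tol[i]:
            continue
        total = 0.0
        for j in range(i, n):
            if s[j] <= -tol[j]:
                break
            total += s[j]
            if total > 0 and (j - i + 1) > best_len:
                best_len = j - i + 1
                best = (i, j)
    return best


def _window_from_calls(gene: str, means: np.ndarray, sems: np.ndarray,
                       epsilon: float | None, z: float) -> tuple[str, tuple[int, int] | None]:
    log_means = np.log2(means + 0.5)
    diffs = np.diff(log_means)
    if epsilon is not None:
        tol = np.full(len(diffs), float(epsilon))
    else:
        se_log = sems / (means + 0.5) / np.log(2.0)
        tol = z * np.sqrt(se_log[:-1] ** 2 + se_log[1:] ** 2)
    up = _best_window(diffs, tol, +1)
    dn = _best_window(diffs, tol, -1)
    up_len = 0 if up is None else up[1] - up[0] + 1
    dn_len = 0 if dn is None else dn[1] - dn[0] + 1
    if up_len == dn_len == 0:
        return "none", None
    if up_len > dn_len:
        return "P-ADEM", up
    if dn_len > up_len:
        return "N-ADEM", dn
    # tie: larger absolute net change wins; earlier window on a further tie
    net_up = abs(diffs[up[0]:up[1] + 1].sum())
    net_dn = abs(diffs[dn[0]:dn[1] + 1].sum())
    if net_up > net_dn or (net_up == net_dn and up[0] <= dn[0]):
        return "P-ADEM", up
    return "N-ADEM", dn


def classify_adem(scan: NeighborScan,
                  min_run: int = 5,
                  require_deg: str = "multigroup",
                  epsilon: float | None = None,
                  step_tolerance_z: float = 1.0,
                  series: ExpressionSeries | None = None,
                  ) -> list[ADEMCall]:
    """Call P-ADEM / N-ADEM genes from a neighbor scan.

    Parameters
    ----------
    scan
        Output of :func:`neighbor_comparisons`.
    min_run
        Minimum number of consecutive timepoints in the monotone window
        (default 5, i.e. at least 4 persistent steps).
    require_deg
        ``"multigroup"`` (default): the gene must pass the multigroup DEG
        gate (BH-adjusted P < 0.05 and max |log2FC| > log2 1.5).
        ``"any_step_in_run"``: at least one neighbor comparison inside
        the window must pass the two-group DEG gate.  ``"none"``: no gate.
    epsilon
        Fixed log2 tolerance for counter-trend steps; ``None`` (default)
        uses the adaptive per-step tolerance ``step_tolerance_z`` standard
        errors.  ``epsilon = 0`` recovers strict monotonicity.
    series
        Optional series to attach per-gene age correlations (Pearson r/p
        on log2(CPM+1) across individual samples).
    """
    n_t = len(scan.timepoints)
    if min_run > n_t:
        raise ValidationError(f"min_run {min_run} exceeds the {n_t} available timepoints")
    if require_deg not in {"multigroup", "any_step_in_run", "none"}:
        raise ValidationError(f"unknown require_deg mode {require_deg!r}")
    if require_deg == "multigroup" and scan.multigroup is None:
        raise ValidationError("require_deg='multigroup' needs scan.multigroup "
                              "(rerun neighbor_comparisons with with_multigroup=True)")

    means = scan.group_means.to_numpy(dtype=float)
    sems = scan.group_sems.to_numpy(dtype=float)
    step_p = np.stack([c.table["p"].to_numpy() for c in scan.comparisons], axis=1)
    step_fc = np.stack([c.table["log2fc"].to_numpy() for c in scan.comparisons], axis=1)
    step_sig = (step_p < DEG_P_THRESHOLD) & (np.abs(step_fc) > DEG_LOG2FC_THRESHOLD)
    if scan.multigroup is not None:
        mg = scan.multigroup.table
        mg_pass = ((mg["p_adj"].to_numpy() < DEG_P_THRESHOLD)
                   & (np.abs(mg["log2fc"].to_numpy()) > DEG_LOG2FC_THRESHOLD))
    else:
        mg_pass = np.zeros(means.shape[0], dtype=bool)

    corr: dict[str, AgeCorrelation] = {}
    if series is not None:
        log_expr = np.log2(normalize_counts(series, "cpm") + 1.0)
        ages_per_sample = series.meta["age_months"].to_numpy(dtype=float)

    calls: list[ADEMCall] = []
    for gi, gene in enumerate(scan.group_means.index):
        direction, window = _window_from_calls(gene, means[gi], sems[gi],
                                               epsilon, step_tolerance_z)
        if window is not None:
            run_start, run_end = window[0], window[1] + 1  # timepoint indices
            run_length = run_end - run_start + 1
        else:
            run_start = run_end = 0
            run_length = 0
        n_sig = int(step_sig[gi, window[0]:window[1] + 1].sum()) if window else 0
        if run_length < min_run:
            direction = "none"
        elif require_deg == "multigroup" and not mg_pass[gi]:
            direction = "none"
        elif require_deg == "any_step_in_run" and n_sig == 0:
            direction = "none"
        if direction == "none":
            run_start = run_end = -1
            run_length = 0
            n_sig = 0
        r = p = float("nan")
        if series is not None:
            ac = age_correlation_values(log_expr.loc[gene].to_numpy(), ages_per_sample)
            r, p = ac.pearson_r, ac.pearson_p
        calls.append(ADEMCall(str(gene), direction, run_start, run_end,
                              run_length if direction != "none" else 0,
                              n_sig, r, p))
    return calls


def age_correlation_values(expr: np.ndarray, ages: np.ndarray) -> AgeCorrelation:
    """OLS/Pearson of an expression vector on sample ages."""
    expr = np.asarray(expr, dtype=float)
    ages = np.asarray(ages, dtype=float)
    if expr.size < 3 or len(set(ages.tolist())) < 2:
        raise ValidationError("need >= 3 samples with >= 2 distinct ages")
    if np.std(expr) == 0:
        return AgeCorrelation(0.0, 1.0, 0.0, float(expr[0]), (0.0, 0.0), degenerate=True)
    fit = stats.linregress(ages, expr)
    dof = expr.size - 2
    tcrit = stats.t.ppf(0.975, dof) if dof > 0 else float("inf")
    ci = (fit.slope - tcrit * fit.stderr, fit.slope + tcrit * fit.stderr)
    return AgeCorrelation(float(fit.rvalue), float(fit.pvalue),
                          float(fit.slope), float(fit.intercept), ci)


def age_correlation(series: ExpressionSeries, gene_id: str) -> AgeCorrelation:
    """Pearson correlation and linear fit of one gene's log2(CPM+1) vs age."""
    if gene_id not in series.gene_ids:
        raise ValidationError(f"unknown gene id {gene_id!r}")
    log_expr = np.log2(normalize_counts(series, "cpm").loc[gene_id].to_numpy() + 1.0)
    return age_correlation_values(log_expr, series.meta["age_months"].to_numpy())


def adem_table(calls: list[ADEMCall], timepoints: list[float]) -> pd.DataFrame:
    """Tabulate calls with run windows expressed as ages."""
    rows = []
    for c in calls:
        rows.append({
            "gene_id": c.gene_id,
            "direction": c.direction,
            "run_start_age": timepoints[c.run_start] if c.direction != "none" else np.nan,
            "run_end_age": timepoints[c.run_end] if c.direction != "none" else np.nan,
            "run_length": c.run_length,
            "n_significant_steps": c.n_significant_steps,
            "pearson_r": c.pearson_r,
            "pearson_p": c.pearson_p,
        })
    return pd.DataFrame(rows).set_index("gene_id")
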