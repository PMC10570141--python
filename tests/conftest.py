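import numpy as np
import pandas as pd
import pytest

from ademtrack import ExpressionSeries


@pytest.fixture
def toy_series() -> ExpressionSeries:
    """4 genes x 6 samples over 3 ages, hand-sized for exact checks."""
    rng = np.random.default_rng(42)
    counts = pd.DataFrame(
        rng.poisson(200, size=(4, 6)),
        index=["gA", "gB", "gC", "gD"],
        columns=[f"s{i}" for i in range(6)],
    )
    meta = pd.DataFrame(
        {"age_months": [3.0, 3.0, 12.0, 12.0, 24.0, 24.0],
         "sex": ["F"] * 6,
         "replicate": [1, 2, 1, 2, 1, 2]},
        index=pd.Index([f"s{i}" for i in range(6)], name="sample_id"),
    )
    lengths = pd.Series([1.0, 2.0, 0.5, 1.5], index=counts.index)
    return ExpressionSeries(counts, meta, lengths)


def make_series(counts: np.ndarray, ages: list[float],
                lengths: np.ndarray | None = None) -> ExpressionSeries:
    """Build a series from a raw matrix and per-sample ages."""
    counts = np.asarray(counts)
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{i}" for i in range(counts.shape[1])]
    reps: dict[float, int] = {}
    rep_ids = []
    for a in ages:
        reps[a] = reps.get(a, 0) + 1
        rep_ids.append(reps[a])
    meta = pd.DataFrame({"age_months": ages, "sex": ["F"] * len(ages),
                         "replicate": rep_ids},
                        index=pd.Index(samples, name="sample_id"))
    gl = None
    if lengths is not None:
        gl = pd.Series(np.asarray(lengths, dtype=float), index=genes)
    return ExpressionSeries(pd.DataFrame(counts, index=genes, columns=samples), meta, gl)
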