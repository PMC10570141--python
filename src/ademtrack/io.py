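"""Readers and writers for the on-disk formats the pipeline consumes.

Counts travel as a dense TSV (genes as rows, first column ``gene_id``,
sample ids as header) or as a Matrix Market triplet with sibling
``features.tsv``/``barcodes.tsv`` files; sample metadata as a TSV keyed
by ``sample_id``; gene sets as GMT; run configuration as YAML.  Readers
validate invariants (unique ids, aligned metadata, integer counts) and
raise :class:`~ademtrack.containers.ValidationError` with a specific
message rather than coercing silently.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as spio
from scipy import sparse

from .containers import ExpressionSeries, GeneSet, ValidationError

__all__ = [
    "read_expression_series", "write_expression_series",
    "read_gene_sets", "write_gene_sets",
    "read_mtx_counts", "write_mtx_counts",
    "load_config", "dump_json",
]


def _read_meta(meta_path: str | Path) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t")
    if "sample_id" not in meta.columns:
        raise ValidationError(f"{meta_path}: metadata must have a sample_id column")
    if meta["sample_id"].duplicated().any():
        dups = meta.loc[meta["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{meta_path}: duplicate sample id(s): {dups}")
    if "age_months" not in meta.columns:
        raise ValidationError(f"{meta_path}: metadata missing age_months column")
    return meta.set_index("sample_id")


def read_expression_series(counts_path: str | Path, meta_path: str | Path,
                           lengths_path: str | Path | None = None) -> ExpressionSeries:
    """Load counts + metadata (+ optional gene lengths) into an ExpressionSeries.

    ``counts_path`` may be a dense TSV (first column ``gene_id``) or a
    ``.mtx`` Matrix Market file with ``features.tsv`` and ``barcodes.tsv``
    next to it (one id per line).
    """
    counts_path = Path(counts_path)
    if counts_path.suffix == ".mtx":
        counts = read_mtx_counts(counts_path,
                                 counts_path.with_name("features.tsv"),
                                 counts_path.with_name("barcodes.tsv"))
    else:
        counts = pd.read_csv(counts_path, sep="\t")
        if counts.columns[0] != "gene_id":
            raise ValidationError(f"{counts_path}: first column must be gene_id")
        counts = counts.set_index("gene_id")
    meta = _read_meta(meta_path)
    lengths = None
    if lengths_path is not None:
        lt = pd.read_csv(lengths_path, sep="\t")
        if not {"gene_id", "length_kb"} <= set(lt.columns):
            raise ValidationError(f"{lengths_path}: need gene_id and length_kb columns")
        lengths = lt.set_index("gene_id")["length_kb"]
    return ExpressionSeries(counts, meta, lengths)


def write_expression_series(series: ExpressionSeries, counts_path: str | Path,
                            meta_path: str | Path,
                            lengths_path: str | Path | None = None) -> None:
    """Write the counts/metadata (and lengths if held) as TSV files."""
    series.counts.rename_axis("gene_id").to_csv(counts_path, sep="\t")
    series.meta.rename_axis("sample_id").to_csv(meta_path, sep="\t")
    if lengths_path is not None:
        if series.gene_lengths_kb is None:
            raise ValidationError("series holds no gene lengths to write")
        (series.gene_lengths_kb.rename("length_kb").rename_axis("gene_id")
         .to_csv(lengths_path, sep="\t"))


def read_mtx_counts(mtx_path: str | Path, features_path: str | Path,
                    barcodes_path: str | Path) -> pd.DataFrame:
    """Dense gene x cell DataFrame from a Matrix Market triplet."""
    mat = spio.mmread(str(mtx_path))
    genes = [ln.split("\t")[0] for ln in
             Path(features_path).read_text().splitlines() if ln.strip()]
    cells = [ln.split("\t")[0] for ln in
             Path(barcodes_path).read_text().splitlines() if ln.strip()]
    dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat)
    if dense.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"{mtx_path}: matrix is {dense.shape}, but features/barcodes list "
            f"{len(genes)} genes and {len(cells)} cells")
    if not np.all(dense == np.floor(dense)):
        raise ValidationError(f"{mtx_path}: non-integer counts")
    return pd.DataFrame(dense.astype(np.int64), index=genes, columns=cells)


def write_mtx_counts(counts: pd.DataFrame, mtx_path: str | Path,
                     features_path: str | Path, barcodes_path: str | Path) -> None:
    """Write a gene x cell count matrix as MTX + features/barcodes TSVs."""
    spio.mmwrite(str(mtx_path), sparse.coo_matrix(counts.to_numpy()))
    Path(features_path).write_text("".join(f"{g}\n" for g in counts.index))
    Path(barcodes_path).write_text("".join(f"{c}\n" for c in counts.columns))


def read_gene_sets(gmt_path: str | Path) -> list[GeneSet]:
    """Parse a GMT file (name TAB description TAB member...)."""
    sets = []
    for lineno, line in enumerate(Path(gmt_path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(
                f"{gmt_path}:{lineno}: malformed GMT line (need name, description "
                "and at least one member)")
        name, _desc, *members = parts
        members = [m for m in members if m]
        if not members:
            raise ValidationError(f"{gmt_path}:{lineno}: gene set {name!r} is empty")
        sets.append(GeneSet(name, tuple(members)))
    return sets


def write_gene_sets(sets: list[GeneSet], gmt_path: str | Path,
                    description: str = "ademtrack") -> None:
    lines = ["\t".join([s.name, description, *s.members]) for s in sets]
    Path(gmt_path).write_text("".join(f"{ln}\n" for ln in lines))


def load_config(path: str | Path) -> dict:
    """YAML run configuration as a plain dict (empty file -> empty dict)."""
    data = yaml.safe_load(Path(path).read_text())
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: config must be a YAML mapping")
    return data


def dump_json(obj, path: str | Path) -> None:
    """Write a JSON report with stable key order and trailing newline."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default) + "\n")
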