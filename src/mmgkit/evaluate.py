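"""Benchmarking harness: observed vs expected expression.

Compares count/FPKM tables — from this package's stage-1 counter or from
external quantifiers ingested as TSV — against simulated truth: Pearson
correlation of observed with expected FPKM, classification of grossly
under-/overestimated genes, and matrix exports for heatmap / clustering
workflows (rendering itself is out of scope).

Classification defaults are tied to the uniform 1000-pairs-per-gene design:
a gene is underestimated if some method assigns it fewer than 100 fragments,
overestimated if some method assigns more than 1900 — both strict
inequalities. For variable-depth designs use the ratio-based classifier.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "correlate",
    "classify_genes",
    "classify_genes_relative",
    "ClassificationSummary",
    "accuracy_heatmap_matrix",
    "corr_distance",
    "read_method_table",
]


def correlate(observed: pd.Series, expected: pd.Series) -> float:
    """Pearson r between observed and expected values, aligned on gene id.

    Raw (not log) values. Genes present in ``expected`` but missing from
    ``observed`` count as 0. Zero variance in either vector gives NaN.
    """
    obs = observed.reindex(expected.index).fillna(0.0)
    x = obs.to_numpy(dtype=float)
    y = expected.to_numpy(dtype=float)
    if len(x) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class ClassificationSummary:
    n_under: int
    n_over: int
    n_problematic: int  # union: under- or overestimated by >= 1 method
    n_zero: int  # assigned zero by >= 1 method


def _as_frame(results: Mapping[str, pd.Series] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        return results
    return pd.DataFrame(dict(results))


def classify_genes(
    results: Mapping[str, pd.Series] | pd.DataFrame,
    low: float = 100,
    high: float = 1900,
) -> tuple[pd.DataFrame, ClassificationSummary]:
    """Flag genes with grossly wrong counts in at least one method.

    ``results``: per-method gene counts (columns = methods). A gene is
    ``under`` if any method assigns it a count strictly below ``low``,
    ``over`` if any method assigns strictly above ``high``; the classes are
    not mutually exclusive. Genes at exactly the thresholds are neither.
    """
    frame = _as_frame(results)
    under = (frame < low).any(axis=1)
    over = (frame > high).any(axis=1)
    zero = (frame == 0).any(axis=1)
    verdicts = pd.DataFrame(
        {"under": under, "over": over, "zero": zero, "problematic": under | over}
    )
    summary = ClassificationSummary(
        n_under=int(under.sum()),
        n_over=int(over.sum()),
        n_problematic=int((under | over).sum()),
        n_zero=int(zero.sum()),
    )
    return verdicts, summary


def classify_genes_relative(
    observed: Mapping[str, pd.Series] | pd.DataFrame,
    expected: pd.Series,
    low_ratio: float = 0.1,
    high_ratio: float = 1.9,
) -> tuple[pd.DataFrame, ClassificationSummary]:
    """Ratio-based classification for variable-depth designs.

    A gene is under/over when observed/expected falls strictly below/above the
    ratio bounds for at least one method. Absolute thresholds are meaningless
    when true depth varies per gene.
    """
    frame = _as_frame(observed).reindex(expected.index).fillna(0.0)
    ratio = frame.div(expected, axis=0)
    return classify_genes(ratio, low=low_ratio, high=high_ratio)


def accuracy_heatmap_matrix(
    results: Mapping[str, pd.Series] | pd.DataFrame,
    verdicts: pd.DataFrame,
) -> pd.DataFrame:
    """Counts of problematic genes (rows, sorted by gene id) x methods."""
    frame = _as_frame(results)
    keep = verdicts.index[verdicts["problematic"]]
    return frame.loc[sorted(keep)]


def corr_distance(matrix: pd.DataFrame, axis: str = "rows") -> pd.DataFrame:
    """1 - Pearson correlation distance matrix over rows or columns.

    Input is typically log-FPM. A constant vector yields NaN in its cells
    (undefined correlation), not an error.
    """
    if axis not in ("rows", "columns"):
        raise ValueError("axis must be 'rows' or 'columns'")
    data = matrix if axis == "columns" else matrix.T
    if data.shape[1] < 2:
        raise ValueError("need at least two vectors to correlate")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    labels = data.columns
    return pd.DataFrame(1.0 - corr, index=labels, columns=labels)


def read_method_table(path, count_col: str = "count", fpkm_col: str = "fpkm") -> pd.DataFrame:
    """Ingest an external quantifier's TSV (columns: id, count and/or fpkm)."""
    df = pd.read_csv(path, sep="\t")
    if "id" not in df.columns:
        raise ValueError("method table must have an 'id' column")
    df = df.set_index("id")
    missing = [c for c in (count_col, fpkm_col) if c not in df.columns]
    if len(missing) == 2:
        raise ValueError("method table must have a 'count' or 'fpkm' column")
    return df
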