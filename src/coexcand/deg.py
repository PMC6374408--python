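"""Differential expression calling between two replicated genotypes.

Works on an FPKM matrix with a two-genotype design (a high-metabolite
"case" genotype contrasted against a low-metabolite "control"). The
conventions are deliberately simple and transparent:

* FPKM values below 1 are floored to 1 before any fold-change arithmetic,
  which suppresses spurious ratios between barely-detected transcripts.
* The fold change is the log2 ratio of genotype means of floored FPKM.
* Significance is a two-sided pooled-variance Student's t-test on
  log2(floored FPKM) across biological replicates, with no
  multiple-testing correction.
* A gene is differentially expressed at threshold ``t`` when
  ``|log2FC| >= t`` and ``p < alpha``; thresholds are nested, so the DEG
  set at a stricter threshold is always a subset of the looser one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExpressionMatrix",
    "floor_fpkm",
    "floored_log2fc",
    "replicate_test",
    "call_degs",
    "deg_set",
    "direction_summary",
]

#: Flooring constant applied to FPKM before fold-change computation.
FPKM_FLOOR = 1.0


@dataclass
class ExpressionMatrix:
    """FPKM matrix (genes x samples) with a two-genotype replicated design.

    Parameters
    ----------
    values
        DataFrame of non-negative FPKM values, index = gene ids,
        columns = sample ids.
    design
        DataFrame indexed by sample id with columns ``genotype`` and
        ``replicate``. Exactly two genotype labels must occur, each with
        at least two samples.
    case, control
        The genotype labels to treat as case (numerator of the fold
        change) and control (denominator).
    """

    values: pd.DataFrame
    design: pd.DataFrame
    case: str = "high"
    control: str = "low"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids in expression matrix")
        missing = set(self.values.columns) - set(self.design.index)
        if missing:
            raise ValueError(f"samples without a design entry: {sorted(missing)}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("negative FPKM values")
        genotypes = set(self.design.loc[list(self.values.columns), "genotype"])
        if genotypes != {self.case, self.control}:
            raise ValueError(
                f"design genotypes {sorted(genotypes)} do not match "
                f"case={self.case!r}/control={self.control!r}"
            )
        if len(self.case_samples) < 2 or len(self.control_samples) < 2:
            raise ValueError("each genotype needs at least 2 samples")

    def _samples_of(self, genotype: str) -> list[str]:
        keep = self.design.loc[list(self.values.columns), "genotype"] == genotype
        return [s for s, k in zip(self.values.columns, keep) if k]

    @property
    def case_samples(self) -> list[str]:
        return self._samples_of(self.case)

    @property
    def control_samples(self) -> list[str]:
        return self._samples_of(self.control)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def swapped(self) -> "ExpressionMatrix":
        """Return a copy with case and control labels exchanged."""
        return ExpressionMatrix(
            self.values, self.design, case=self.control, control=self.case
        )


def floor_fpkm(values: np.ndarray | Sequence[float]) -> np.ndarray:
    """Floor FPKM values at 1 (idempotent)."""
    return np.maximum(np.asarray(values, dtype=float), FPKM_FLOOR)


def floored_log2fc(
    case_values: Sequence[float], control_values: Sequence[float]
) -> float:
    """log2 fold change of genotype means after flooring each value at 1.

    Computed as ``log2(mean(floored case)) - log2(mean(floored control))``
    so that swapping the arguments negates the result exactly.
    """
    case_arr = np.asarray(case_values, dtype=float)
    control_arr = np.asarray(control_values, dtype=float)
    if case_arr.size == 0 or control_arr.size == 0:
        raise ValueError("empty value list")
    return float(
        np.log2(floor_fpkm(case_arr).mean()) - np.log2(floor_fpkm(control_arr).mean())
    )


def _pooled_t_pvalues(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Row-wise two-sided pooled-variance t-test p-values.

    Degenerate rows (zero pooled variance) return 1 when the group means
    are equal and 0 otherwise, instead of propagating NaN.
    """
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 values per group")
    ma, mb = a.mean(axis=1), b.mean(axis=1)
    va, vb = a.var(axis=1, ddof=1), b.var(axis=1, ddof=1)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * va + (n2 - 1) * vb) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    degenerate = sp2 == 0
    if degenerate.any():
        p = np.where(degenerate, np.where(ma == mb, 1.0, 0.0), p)
    return p


def replicate_test(
    case_values: Sequence[float],
    control_values: Sequence[float],
    scale: str = "log2",
) -> float:
    """Two-sided pooled-variance Student's t-test between replicate groups.

    By default the test is applied to log2 of the floored FPKM values;
    ``scale="raw"`` tests the values as given. When the pooled variance is
    zero the p-value is 1 for equal means and 0 otherwise.
    """
    a = np.asarray(case_values, dtype=float)
    b = np.asarray(control_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 values per group")
    if scale == "log2":
        a, b = np.log2(floor_fpkm(a)), np.log2(floor_fpkm(b))
    elif scale != "raw":
        raise ValueError(f"unknown scale {scale!r}")
    return float(_pooled_t_pvalues(a[None, :], b[None, :])[0])


def call_degs(
    matrix: ExpressionMatrix,
    alpha: float = 0.05,
    thresholds: Iterable[int] = (2, 3, 4, 5),
    scale: str = "log2",
) -> pd.DataFrame:
    """Call differential expression for every gene in the matrix.

    Returns a DataFrame indexed by gene with columns
    ``mean_floored_case``, ``mean_floored_control``, ``log2fc``,
    ``p_value``, one boolean column ``deg{t}`` per threshold, and
    ``direction`` in ``{"up", "down", "none"}`` (relative to the base,
    i.e. smallest, threshold).
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    thresholds = sorted(set(int(t) for t in thresholds))
    if not thresholds:
        raise ValueError("at least one fold-change threshold required")

    case_cols = matrix.case_samples
    control_cols = matrix.control_samples
    floored = floor_fpkm(matrix.values.to_numpy())
    case_idx = [matrix.values.columns.get_loc(c) for c in case_cols]
    control_idx = [matrix.values.columns.get_loc(c) for c in control_cols]

    mean_case = floored[:, case_idx].mean(axis=1)
    mean_control = floored[:, control_idx].mean(axis=1)
    log2fc = np.log2(mean_case) - np.log2(mean_control)

    if scale == "log2":
        x = np.log2(floored)
    elif scale == "raw":
        x = matrix.values.to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    p = _pooled_t_pvalues(x[:, case_idx], x[:, control_idx])

    table = pd.DataFrame(
        {
            "mean_floored_case": mean_case,
            "mean_floored_control": mean_control,
            "log2fc": log2fc,
            "p_value": p,
        },
        index=pd.Index(matrix.values.index, name="gene"),
    )
    significant = p < alpha
    for t in thresholds:
        table[f"deg{t}"] = (np.abs(log2fc) >= t) & significant
    base = table[f"deg{thresholds[0]}"].to_numpy()
    direction = np.where(
        base & (log2fc > 0), "up", np.where(base & (log2fc < 0), "down", "none")
    )
    table["direction"] = direction
    return table


def deg_set(table: pd.DataFrame, threshold: int) -> set[str]:
    """Gene ids called differentially expressed at ``threshold``."""
    col = f"deg{threshold}"
    if col not in table.columns:
        raise ValueError(f"threshold {threshold} not present in DEG table")
    return set(table.index[table[col]])


def direction_summary(table: pd.DataFrame, threshold: int) -> tuple[int, int, float]:
    """Count DEGs at a threshold split by fold-change sign.

    Returns ``(n_total, n_up, fraction_up)``; the fraction is 0.0 when no
    gene passes the threshold.
    """
    col = f"deg{threshold}"
    if col not in table.columns:
        raise ValueError(f"threshold {threshold} not present in DEG table")
    sub = table[table[col]]
    n_total = int(len(sub))
    n_up = int((sub["log2fc"] > 0).sum())
    fraction_up = n_up / n_total if n_total else 0.0
    return n_total, n_up, fraction_up
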