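"""Normalization policy: make heterogeneous cohorts comparable log2 matrices.

Public repositories ship expression matrices in mixed states (linear
intensities, log2 values, with or without quantile normalization), so each
cohort is inspected and corrected only where needed: background-correct and
log2-transform if the matrix is on a linear scale, then quantile-normalize if
the run's policy asks for it.  The whole chain is idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import ExpressionCohort


@dataclass
class HarmonizePolicy:
    """Which corrections a run applies and their knobs."""

    quantile: bool = True
    #: 99th-percentile cutoff above which a matrix is called linear-scale
    scale_cutoff: float = 30.0
    #: minimum value enforced before log2 (linear-scale matrices only)
    background_floor: float = 0.0
    log2_offset: float = 1.0


def detect_scale(matrix: pd.DataFrame, cutoff: float = 30.0) -> str:
    """Call a matrix ``"linear"`` iff its 99th percentile exceeds ``cutoff``.

    Log2 microarray/RNA-seq values rarely exceed ~25, linear intensities are
    in the hundreds to tens of thousands.
    """
    values = matrix.to_numpy(float)
    if values.size == 0:
        raise ValueError("empty matrix")
    if np.nanmax(values) == np.nanmin(values):
        warnings.warn("all-constant matrix; scale undecidable, assuming log2")
        return "log2"
    return "linear" if np.nanpercentile(values, 99) > cutoff else "log2"


def background_correct(matrix: pd.DataFrame, floor: float) -> tuple[pd.DataFrame, float]:
    """Shift the whole matrix up so its minimum is at least ``floor``.

    Returns the (possibly unchanged) matrix and the shift applied.
    """
    lo = float(matrix.to_numpy().min())
    if lo >= floor:
        return matrix, 0.0
    shift = floor - lo
    return matrix + shift, shift


def log2_transform(matrix: pd.DataFrame, offset: float = 1.0) -> pd.DataFrame:
    """Elementwise ``log2(x + offset)``; fails loudly on non-positive inputs."""
    shifted = matrix + offset
    if (shifted.to_numpy() <= 0).any():
        bad = shifted.stack()
        bad = bad[bad <= 0]
        gene, sample = bad.index[0]
        raise ValueError(
            f"log2 transform: non-positive value {bad.iloc[0]:g} + offset at gene {gene}, sample {sample}")
    return np.log2(shifted)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the mean order-statistic distribution.

    Ties within a column receive the mean of the reference values across
    their tied rank span, the common deterministic convention.
    """
    if matrix.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = matrix.to_numpy(float)
    if np.isnan(values).any():
        raise ValueError("quantile normalization requires complete data")
    order = np.argsort(values, axis=0, kind="stable")
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    n = values.shape[0]
    rows = np.arange(n)
    for j in range(values.shape[1]):
        col_sorted = values[order[:, j], j]
        # rank spans of tied values -> mean reference over the span
        ref_col = reference.copy()
        start = 0
        while start < n:
            stop = start + 1
            while stop < n and col_sorted[stop] == col_sorted[start]:
                stop += 1
            if stop - start > 1:
                ref_col[start:stop] = reference[start:stop].mean()
            start = stop
        out[order[:, j], j] = ref_col[rows]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def harmonize(cohort: ExpressionCohort, policy: HarmonizePolicy | None = None) -> ExpressionCohort:
    """Apply the "when needed" correction chain to one cohort.

    background-correct -> log2 (iff the matrix is linear-scale) ->
    quantile-normalize (iff the policy requests it and it has not been done).
    Idempotent; never changes dimensions or identifiers.
    """
    policy = policy or HarmonizePolicy()
    out = cohort.copy()
    state = out.normalization_state
    scale = detect_scale(out.matrix, policy.scale_cutoff)
    if scale == "linear":
        out.matrix, shift = background_correct(out.matrix, policy.background_floor)
        state["background_corrected"] = True
        state["background_shift"] = shift
        out.matrix = log2_transform(out.matrix, policy.log2_offset)
        state["log2_offset"] = policy.log2_offset
    state["log2"] = True
    if policy.quantile and not state.get("quantile_normalized", False):
        out.matrix = quantile_normalize(out.matrix)
        state["quantile_normalized"] = True
    return out
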