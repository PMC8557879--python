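"""Cross-experiment trimmed-mean scaling of an expression matrix.

Arrays collected across many experiments differ in overall intensity; to
make them comparable each sample (column) is rescaled so that its trimmed
mean (top and bottom 5% of values excluded by default) equals the
cross-experiment trimmed mean, taken here as the mean of the per-sample
trimmed means.  With that target the operation is exactly idempotent.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

DEFAULT_TRIM = 0.05


def trimmed_mean(values, trim_fraction: float = DEFAULT_TRIM) -> float:
    """Mean after removing ``floor(trim_fraction * n)`` values from each tail.

    The trim count is floored (no interpolation) so results are
    bit-reproducible; equivalent to :func:`scipy.stats.trim_mean`.
    """
    arr = np.asarray(values, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("trimmed_mean of an empty sequence")
    if not 0 <= trim_fraction < 0.5:
        raise ValueError(f"trim_fraction must be in [0, 0.5), got {trim_fraction}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("trimmed_mean requires finite values")
    k = math.floor(trim_fraction * arr.size)
    arr = np.sort(arr)
    return float(arr[k: arr.size - k].mean())


def scale_to_cross_experiment_trimmed_mean(
    matrix: pd.DataFrame, trim_fraction: float = DEFAULT_TRIM
) -> pd.DataFrame:
    """Rescale each sample column to the cross-experiment trimmed mean.

    Column ``j`` is multiplied by ``T / t_j`` where ``t_j`` is its trimmed
    mean and ``T`` is the mean of all ``t_j``.  After scaling every column's
    trimmed mean equals ``T``, and re-applying the operation is a no-op.
    """
    col_means = np.array(
        [trimmed_mean(matrix[c].to_numpy(), trim_fraction) for c in matrix.columns]
    )
    zero = [c for c, t in zip(matrix.columns, col_means) if t == 0]
    if zero:
        raise ValueError(
            "sample(s) with zero trimmed mean cannot be scaled: " + ", ".join(map(str, zero))
        )
    target = col_means.mean()
    return matrix * (target / col_means)
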