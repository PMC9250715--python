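"""Dynamic time warping distances between SOFA trajectories.

The distance between two sequences is the square root of the minimal
accumulated squared-difference cost over all monotone warping paths:

    D(i, j) = (x_i - y_j)^2 + min(D(i-1, j), D(i, j-1), D(i-1, j-1))

with full alignment (no band constraint) — trajectories here are length 12,
so each pair costs a 12x12 dynamic program. The result is symmetric and
nonnegative with d(x, x) = 0, but it is not a metric (no triangle
inequality). For equal-length sequences it is bounded above by the
Euclidean distance, since the diagonal path is one admissible warping.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def dtw_distance(x, y) -> float:
    """DTW distance between two 1-d sequences (see module docstring)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) == 0 or len(y) == 0:
        raise ValueError("dtw_distance requires two non-empty 1-d sequences")
    nx, ny = len(x), len(y)
    acc = np.full((nx + 1, ny + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, nx + 1):
        for j in range(1, ny + 1):
            cost = (x[i - 1] - y[j - 1]) ** 2
            acc[i, j] = cost + min(acc[i - 1, j], acc[i, j - 1], acc[i - 1, j - 1])
    return float(np.sqrt(acc[nx, ny]))


def _dtw_one_vs_many(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Squared accumulated DTW cost of ``x`` against every row of ``Y``."""
    m, ny = Y.shape
    nx = len(x)
    acc = np.full((nx + 1, ny + 1, m), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, nx + 1):
        for j in range(1, ny + 1):
            cost = (x[i - 1] - Y[:, j - 1]) ** 2
            acc[i, j] = cost + np.minimum(
                np.minimum(acc[i - 1, j], acc[i, j - 1]), acc[i - 1, j - 1]
            )
    return acc[nx, ny]


def pairwise_dtw(trajectories) -> pd.DataFrame:
    """Symmetric DTW distance matrix over trajectory rows.

    Parameters
    ----------
    trajectories
        DataFrame (patients x windows, e.g. the output of
        :func:`sofatraj.sofa.build_trajectories`) or a plain 2-d array.

    Returns
    -------
    DataFrame n x n with the patient ids as both index and columns; zero
    diagonal, symmetric by construction (each unordered pair computed once).
    """
    if isinstance(trajectories, pd.DataFrame):
        ids = list(trajectories.index)
        values = trajectories.to_numpy(dtype=float)
    else:
        values = np.asarray(trajectories, dtype=float)
        ids = list(range(values.shape[0]))
    n = values.shape[0]
    if n < 2:
        raise ValueError("pairwise_dtw requires at least two trajectories")
    if np.isnan(values).any():
        raise ValueError("trajectories must not contain missing values")
    D = np.zeros((n, n))
    for i in range(n - 1):
        D[i, i + 1 :] = np.sqrt(_dtw_one_vs_many(values[i], values[i + 1 :]))
    D = D + D.T
    return pd.DataFrame(D, index=pd.Index(ids), columns=pd.Index(ids))


def validate_distance_matrix(d: pd.DataFrame | np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Check symmetry, nonnegativity and zero diagonal; return the array."""
    values = d.to_numpy(dtype=float) if isinstance(d, pd.DataFrame) else np.asarray(d, float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("distance matrix must be square")
    if np.abs(values - values.T).max(initial=0.0) > tol:
        raise ValueError("distance matrix must be symmetric")
    if (values < 0).any():
        raise ValueError("distance matrix must be nonnegative")
    if np.abs(np.diag(values)).max(initial=0.0) > tol:
        raise ValueError("distance matrix must have a zero diagonal")
    return values
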