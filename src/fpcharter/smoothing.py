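"""Per-molecule rolling-mean smoothing of binary protection values.

Each molecule's binary protection calls are smoothed with a rolling mean
over a genomic window (default 40 bp) centred at each observed cytosine:
the smoothed value at position p is the mean of the molecule's observed
values at positions q with ``|q - p| <= window_bp / 2`` (closed at both
ends). Smoothing is evaluated at observed cytosines only — downstream
features are read at cytosines, so a dense per-bp grid adds nothing.
Missing values are excluded from the mean, never imputed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import RegionMatrix

DEFAULT_SMOOTH_WINDOW_BP = 40


@dataclass
class SmoothedMatrix:
    """Smoothed counterpart of a :class:`~fpcharter.io.RegionMatrix`.

    Same shape and missingness pattern; observed entries lie in [0, 1].
    """

    interval: object
    positions: np.ndarray
    molecule_ids: list[str]
    values: np.ndarray  # float64, NaN exactly where input was NaN
    window_bp: int = DEFAULT_SMOOTH_WINDOW_BP

    @property
    def in_window(self) -> np.ndarray:
        return (self.positions > self.interval.start) & (self.positions <= self.interval.end)


def smooth_molecule(
    positions: np.ndarray, values: np.ndarray, window_bp: int = DEFAULT_SMOOTH_WINDOW_BP
) -> np.ndarray:
    """Rolling mean of one molecule's values over a centred bp window.

    ``positions`` must be strictly increasing genomic coordinates of the
    molecule's observed cytosines and ``values`` the binary protection
    calls at those positions. Returns the smoothed value at each observed
    position; an empty input yields an empty output.
    """
    positions = np.asarray(positions, dtype=np.float64)
    values = np.asarray(values, dtype=np.float64)
    if positions.size == 0:
        return np.empty(0)
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    if positions.size > 1 and np.any(np.diff(positions) <= 0):
        raise ValueError("positions must be strictly increasing")
    half = window_bp / 2.0
    # closed window on both sides: indices in [lo, hi)
    lo = np.searchsorted(positions, positions - half, side="left")
    hi = np.searchsorted(positions, positions + half, side="right")
    csum = np.concatenate(([0.0], np.cumsum(values)))
    return (csum[hi] - csum[lo]) / (hi - lo)


def smooth_matrix(
    matrix: RegionMatrix, window_bp: int = DEFAULT_SMOOTH_WINDOW_BP
) -> SmoothedMatrix:
    """Apply :func:`smooth_molecule` independently to every molecule.

    Each molecule is smoothed over its own observed positions; NaN entries
    stay NaN.
    """
    out = np.full_like(matrix.protection, np.nan)
    for i in range(matrix.n_molecules):
        obs = ~np.isnan(matrix.protection[i])
        if obs.any():
            out[i, obs] = smooth_molecule(
                matrix.positions[obs], matrix.protection[i, obs], window_bp
            )
    return SmoothedMatrix(
        interval=matrix.interval,
        positions=matrix.positions,
        molecule_ids=list(matrix.molecule_ids),
        values=out,
        window_bp=window_bp,
    )
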