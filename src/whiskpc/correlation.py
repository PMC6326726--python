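"""Trial-by-trial correlation between simple-spike density and whisker angle.

Spike density functions (1 ms grid, 8 ms Gaussian kernel) and whisker epochs
are reduced to 10 ms bin means per trial, and every (spike bin i, whisker
bin j) pair is correlated across trials with Pearson's R, yielding a 40 x 40
matrix over -100..+300 ms around the puff.  The diagonal is the zero-lag
correlation trace; its 99% confidence band comes from trial-label
permutations.  The location of the maximal correlation, and its shift
between pre- and post-induction matrices, quantifies whether the simple
spikes lead or lag the whisker position.

Sign convention: ``lag_ms = whisker-bin time - spike-bin time`` at the
maximal cell, so a positive lag means the simple spikes lead the whisker
position (spike-time bin earlier than whisker-time bin).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .behavior import TrialEpochs

__all__ = [
    "SdfTrials",
    "CorrelationMatrix",
    "spike_density",
    "trial_correlation_matrix",
    "diagonal_with_ci",
    "pool_cells",
    "max_corr_shift",
]


@dataclass
class SdfTrials:
    """Trials x time spike-density matrix on a 1 ms grid (spikes/s)."""

    data: np.ndarray
    window: tuple[float, float]  # ms relative to onset
    kernel_sd: float = 8.0  # ms
    aligned: bool = False  # baseline mean subtracted per trial

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.window[0] + np.arange(self.data.shape[1])


@dataclass
class CorrelationMatrix:
    """Pearson R between spike bins (rows) and whisker bins (columns)."""

    R: np.ndarray
    bin_centers: np.ndarray  # ms, shared by rows and columns
    bin_width: float
    n_trials: int
    ci_low: np.ndarray | None = None  # per-diagonal-bin band
    ci_high: np.ndarray | None = None

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.R)

    @property
    def max_cell(self) -> tuple[int, int]:
        """(row, col) of the maximal R; NaN cells are excluded and ties are
        broken toward the smallest (row, col) lexicographically."""
        R = self.R
        if np.isnan(R).all():
            raise ValueError("correlation matrix is all-NaN")
        best = np.nanmax(R)
        rows, cols = np.nonzero(R == best)
        return int(rows[0]), int(cols[0])

    @property
    def lag_ms(self) -> float:
        """Whisker-bin time minus spike-bin time at the maximal cell;
        positive = spikes lead the whisker position."""
        r, c = self.max_cell
        return float(self.bin_centers[c] - self.bin_centers[r])


def spike_density(
    trial_spikes: list[np.ndarray],
    kernel_sd: float = 8.0,
    window: tuple[float, float] = (-100.0, 300.0),
    baseline_window: tuple[float, float] | None = None,
) -> SdfTrials:
    """Per-trial spike density on a 1 ms grid.

    ``trial_spikes`` holds spike times in ms relative to each trial's onset.
    Each trial's impulse train is convolved with a unit-area Gaussian
    (reflection padding), so the integral of an unaligned row equals its
    spike count in the window.  When ``baseline_window`` is given (it must
    lie inside ``window``), each trial's mean over it is subtracted
    ('aligned to the baseline').
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    n_bins = int(round(window[1] - window[0]))
    edges = window[0] + np.arange(n_bins + 1)
    rows = []
    for spikes in trial_spikes:
        counts, _ = np.histogram(np.asarray(spikes, dtype=float), bins=edges)
        rows.append(gaussian_filter1d(counts.astype(float), sigma=kernel_sd,
                                      mode="reflect", truncate=4.0))
    data = np.vstack(rows) * 1e3  # counts per 1 ms bin -> spikes/s
    sdf = SdfTrials(data=data, window=window, kernel_sd=kernel_sd)
    if baseline_window is not None:
        t = sdf.times
        mask = (t >= baseline_window[0]) & (t < baseline_window[1])
        if not mask.any():
            raise ValueError("baseline_window outside the SDF window")
        sdf.data = sdf.data - sdf.data[:, mask].mean(axis=1, keepdims=True)
        sdf.aligned = True
    return sdf


def _bin_trial_means(
    data: np.ndarray, times: np.ndarray,
    window: tuple[float, float], bin_width: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce trials x time to trials x bins of within-bin means."""
    n_bins = int(round((window[1] - window[0]) / bin_width))
    out = np.empty((data.shape[0], n_bins))
    centers = window[0] + bin_width * (np.arange(n_bins) + 0.5)
    for b in range(n_bins):
        lo = window[0] + b * bin_width
        mask = (times >= lo) & (times < lo + bin_width)
        if not mask.any():
            raise ValueError(f"no samples in bin starting at {lo} ms")
        out[:, b] = data[:, mask].mean(axis=1)
    return out, centers


def _standardize_columns(X: np.ndarray) -> np.ndarray:
    """Z-score each column across trials; zero-variance columns become NaN."""
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - mean) / sd
    Z[:, sd == 0] = np.nan
    return Z


def _pearson_grid(Xz: np.ndarray, Yz: np.ndarray) -> np.ndarray:
    """All-pairs Pearson R between standardized column sets."""
    n = Xz.shape[0]
    with np.errstate(invalid="ignore"):
        return (Xz.T @ Yz) / (n - 1)


def _binned_pair(
    sdf: SdfTrials, whisker: TrialEpochs,
    bin_width: float, window: tuple[float, float],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if sdf.n_trials != whisker.n_trials:
        raise ValueError("spike and whisker data must have equal trial counts")
    X, centers = _bin_trial_means(sdf.data, sdf.times, window, bin_width)
    Y, _ = _bin_trial_means(whisker.data, whisker.times, window, bin_width)
    return X, Y, centers


def trial_correlation_matrix(
    sdf: SdfTrials,
    whisker: TrialEpochs,
    bin_width: float = 10.0,
    window: tuple[float, float] = (-100.0, 300.0),
) -> CorrelationMatrix:
    """Cell (i, j) = Pearson R across trials between mean spike density in
    bin i and mean whisker angle in bin j (default 40 x 40 over -100..+300
    ms).  Cells with zero variance in either variable are stored as NaN,
    never silently 0, and excluded from the max search."""
    if sdf.n_trials < 10:
        raise ValueError("need at least 10 trials")
    X, Y, centers = _binned_pair(sdf, whisker, bin_width, window)
    R = _pearson_grid(_standardize_columns(X), _standardize_columns(Y))
    R = np.clip(R, -1.0, 1.0)
    return CorrelationMatrix(R=R, bin_centers=centers, bin_width=bin_width,
                             n_trials=sdf.n_trials)


def diagonal_with_ci(
    sdf: SdfTrials,
    whisker: TrialEpochs,
    n_perm: int = 1000,
    level: float = 99.0,
    seed: int | None = None,
    bin_width: float = 10.0,
    window: tuple[float, float] = (-100.0, 300.0),
) -> CorrelationMatrix:
    """Zero-lag correlation trace with a permutation confidence band.

    The band is the percentile interval of the per-bin diagonal R obtained
    by permuting whisker trial labels relative to the spike trials (the
    distribution-free null of no trial-by-trial coupling)."""
    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} < 100 yields an unstable confidence band",
            stacklevel=2,
        )
    X, Y, centers = _binned_pair(sdf, whisker, bin_width, window)
    Xz, Yz = _standardize_columns(X), _standardize_columns(Y)
    n = Xz.shape[0]
    R = np.clip(_pearson_grid(Xz, Yz), -1.0, 1.0)

    rng = np.random.default_rng(seed)
    null = np.empty((n_perm, Xz.shape[1]))
    for p in range(n_perm):
        perm = rng.permutation(n)
        null[p] = np.einsum("ij,ij->j", Xz, Yz[perm]) / (n - 1)
    alpha = (100.0 - level) / 2.0
    low = np.percentile(null, alpha, axis=0)
    high = np.percentile(null, 100.0 - alpha, axis=0)
    return CorrelationMatrix(R=R, bin_centers=centers, bin_width=bin_width,
                             n_trials=n, ci_low=low, ci_high=high)


def pool_cells(
    cells: list[tuple[SdfTrials, TrialEpochs]],
    bin_width: float = 10.0,
    window: tuple[float, float] = (-100.0, 300.0),
) -> CorrelationMatrix:
    """Pooled correlation matrix across cells.

    Both variables are standardized per cell (z-scored per bin across that
    cell's trials) before concatenating trials, so cells contribute on a
    common scale regardless of firing rate or movement amplitude."""
    if not cells:
        raise ValueError("need at least one cell")
    Xs, Ys = [], []
    centers = None
    for sdf, whisker in cells:
        X, Y, centers = _binned_pair(sdf, whisker, bin_width, window)
        Xs.append(_standardize_columns(X))
        Ys.append(_standardize_columns(Y))
    Xz = np.vstack(Xs)
    Yz = np.vstack(Ys)
    # pooled z-scores are already standardized per cell; renormalize the
    # pooled columns so R stays a correlation
    R = np.clip(_pearson_grid(_standardize_columns(Xz),
                              _standardize_columns(Yz)), -1.0, 1.0)
    return CorrelationMatrix(R=R, bin_centers=centers, bin_width=bin_width,
                             n_trials=Xz.shape[0])


def max_corr_shift(
    pre: CorrelationMatrix, post: CorrelationMatrix
) -> tuple[float, float, float]:
    """Shift of the maximal-correlation cell, post minus pre.

    Returns (Δrow ms, Δcol ms, Δlag ms) where rows index spike bins, columns
    whisker bins, and lag follows the module's sign convention (positive =
    spikes lead)."""
    r0, c0 = pre.max_cell
    r1, c1 = post.max_cell
    d_row = float(post.bin_centers[r1] - pre.bin_centers[r0])
    d_col = float(post.bin_centers[c1] - pre.bin_centers[c0])
    return d_row, d_col, post.lag_ms - pre.lag_ms
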