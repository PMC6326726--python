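"""Peri-stimulus time histograms and sensory-response characterization.

Raw PSTHs are built on a 1 ms grid as the percentage of trials in which at
least one spike fell in each bin.  For quantitative analysis the raw PSTH is
convolved with a unit-area Gaussian kernel (default sd 21 ms, truncated at
±4 sd, reflection padding so total mass is preserved).  A response is deemed
significant when the convolved PSTH leaves the band baseline mean ± 3 sd
within the response window (default 0–60 ms after stimulus onset); responses
may be facilitating, suppressive, or biphasic.  Recording stability is
visualized with time-shifted PSTH maps: one convolved PSTH per block of 20
trials, blocks advanced by 5 trials, each row expressed as percent change
from its own pre-stimulus baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "Psth",
    "ResponseCharacterization",
    "ShiftedPsthMap",
    "build_raw_psth",
    "gaussian_convolve",
    "characterize_response",
    "time_shifted_psth",
    "INTER_TRIAL_WINDOW_MS",
]

#: named preset for the inter-trial interval used as an alternative baseline
INTER_TRIAL_WINDOW_MS = (-500.0, -200.0)


@dataclass
class Psth:
    """Per-bin response, expressed as % of trials with >=1 spike per 1 ms bin.

    ``window`` is (start, end) in ms relative to stimulus onset; bins are
    half-open ``[t, t + bin_width)`` and indexed by their left edge.
    """

    values: np.ndarray
    window: tuple[float, float]
    n_trials: int
    bin_width: float = 1.0
    convolved: bool = False
    kernel_sd: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n_bins = int(round((self.window[1] - self.window[0]) / self.bin_width))
        if self.values.size != n_bins:
            raise ValueError(
                f"expected {n_bins} bins for window {self.window}, "
                f"got {self.values.size}"
            )

    @property
    def times(self) -> np.ndarray:
        """Left bin edges in ms relative to stimulus onset."""
        return self.window[0] + self.bin_width * np.arange(self.values.size)

    def slice(self, window: tuple[float, float]) -> np.ndarray:
        """Values of bins whose left edge falls in ``[start, end)``."""
        t = self.times
        mask = (t >= window[0]) & (t < window[1])
        if not mask.any():
            raise ValueError(f"window {window} outside PSTH window {self.window}")
        return self.values[mask]


@dataclass
class ResponseCharacterization:
    significant: bool
    polarity: str | None  # 'facilitation' | 'suppression' | 'biphasic'
    peak_amplitude: float | None  # convolved PSTH value at the peak, % trials/bin
    peak_latency: float | None  # ms from stimulus onset
    phases: list[tuple[float, str, float]]  # (onset ms, polarity, extremum)
    baseline_mean: float
    baseline_sd: float
    infinite_z: bool = False

    def to_dict(self) -> dict:
        return {
            "significant": bool(self.significant),
            "polarity": self.polarity,
            "peak_amplitude": self.peak_amplitude,
            "peak_latency_ms": self.peak_latency,
            "phases": [list(p) for p in self.phases],
            "baseline_mean": float(self.baseline_mean),
            "baseline_sd": float(self.baseline_sd),
            "infinite_z": bool(self.infinite_z),
        }


@dataclass
class ShiftedPsthMap:
    """Stability heat map: convolved PSTH per trial block, % change from the
    block's own baseline firing."""

    rows: np.ndarray  # n_rows x n_bins, percent change
    row_starts: np.ndarray  # first trial index of each block
    trials_per_row: int
    row_shift: int
    window: tuple[float, float]
    baseline_window: tuple[float, float]


def _relative_times_ms(spike_times: np.ndarray, onsets: np.ndarray,
                       window: tuple[float, float]) -> list[np.ndarray]:
    """Per-trial spike times in ms relative to each onset, clipped to window."""
    spike_times = np.asarray(spike_times, dtype=float)
    out = []
    for onset in np.asarray(onsets, dtype=float):
        lo, hi = onset + window[0] / 1e3, onset + window[1] / 1e3
        sel = spike_times[(spike_times >= lo) & (spike_times < hi)]
        out.append((sel - onset) * 1e3)
    return out


def build_raw_psth(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    window: tuple[float, float] = (-1000.0, 500.0),
    bin_width: float = 1.0,
) -> Psth:
    """Raw PSTH: bin b holds 100 x (trials with >=1 spike in b) / n_trials."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ValueError("need at least one stimulus onset")
    if window[1] <= window[0]:
        raise ValueError("window start must precede end")
    n_bins = int(round((window[1] - window[0]) / bin_width))
    edges = window[0] + bin_width * np.arange(n_bins + 1)
    hit = np.zeros(n_bins)
    for rel in _relative_times_ms(spike_times, onsets, window):
        counts, _ = np.histogram(rel, bins=edges)
        hit += counts > 0
    values = 100.0 * hit / onsets.size
    return Psth(values=values, window=window, n_trials=onsets.size,
                bin_width=bin_width, convolved=False)


def gaussian_convolve(
    psth: Psth,
    kernel_sd: float = 21.0,
    interpretation: str = "sd",
) -> Psth:
    """Convolve a raw PSTH with a unit-area Gaussian kernel.

    ``kernel_sd`` is in ms and read as the standard deviation by default;
    pass ``interpretation="fwhm"`` to read it as full width at half maximum
    (sd = fwhm / (2 sqrt(2 ln 2))).  The kernel is truncated at ±4 sd and the
    signal reflection-padded, which preserves total mass to better than 1e-9
    relative and maps a constant PSTH onto itself exactly.
    """
    if kernel_sd <= 0:
        raise ValueError("kernel_sd must be positive")
    if interpretation == "fwhm":
        sd_ms = kernel_sd / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    elif interpretation == "sd":
        sd_ms = kernel_sd
    else:
        raise ValueError("interpretation must be 'sd' or 'fwhm'")
    smoothed = gaussian_filter1d(
        psth.values, sigma=sd_ms / psth.bin_width, mode="reflect", truncate=4.0
    )
    return Psth(values=smoothed, window=psth.window, n_trials=psth.n_trials,
                bin_width=psth.bin_width, convolved=True, kernel_sd=sd_ms)


def characterize_response(
    conv: Psth,
    response_window: tuple[float, float] = (0.0, 60.0),
    baseline_window: tuple[float, float] = (-200.0, 0.0),
    k_sd: float = 3.0,
) -> ResponseCharacterization:
    """Apply the 3-sd significance criterion to a convolved PSTH.

    Baseline statistics are computed over the convolved baseline bins; the
    response is significant iff any response bin leaves
    ``mean ± k_sd * sd``.  The peak is the first (earliest) global extremum
    among significant excursions, reported as the PSTH value itself with its
    bin time as latency.  When excursions exist in both directions the
    response is biphasic, with up to two phases listed in temporal order.
    A flat PSTH with zero baseline sd is not significant; a zero baseline sd
    with any deviation is significant with an infinite-z flag.
    """
    if not conv.convolved:
        raise ValueError("characterize_response expects a convolved PSTH")
    baseline = conv.slice(baseline_window)
    resp = conv.slice(response_window)
    t = conv.times
    resp_t = t[(t >= response_window[0]) & (t < response_window[1])]

    mean = float(baseline.mean())
    sd = float(baseline.std(ddof=1)) if baseline.size > 1 else 0.0
    dev = resp - mean

    infinite_z = False
    if sd == 0.0:
        sig_mask = dev != 0.0
        infinite_z = bool(sig_mask.any())
    else:
        sig_mask = np.abs(dev) > k_sd * sd

    if not sig_mask.any():
        return ResponseCharacterization(
            significant=False, polarity=None, peak_amplitude=None,
            peak_latency=None, phases=[], baseline_mean=mean, baseline_sd=sd,
        )

    # earliest global extremum among significant bins
    absdev = np.where(sig_mask, np.abs(dev), -np.inf)
    peak_idx = int(np.argmax(absdev))  # argmax takes the first maximum
    has_up = bool((dev[sig_mask] > 0).any())
    has_down = bool((dev[sig_mask] < 0).any())

    phases: list[tuple[float, str, float]] = []
    # contiguous significant runs, collapsed into at most two phases in
    # temporal order (the earliest facilitation and the earliest suppression)
    run_start = None
    runs = []
    for i in range(sig_mask.size + 1):
        inside = i < sig_mask.size and sig_mask[i]
        if inside and run_start is None:
            run_start = i
        elif not inside and run_start is not None:
            runs.append((run_start, i))
            run_start = None
    for start, stop in runs:
        seg = dev[start:stop]
        pol = "facilitation" if seg[np.argmax(np.abs(seg))] > 0 else "suppression"
        if any(p[1] == pol for p in phases):
            continue
        ext_rel = int(np.argmax(np.abs(seg)))
        phases.append((float(resp_t[start]), pol, float(resp[start + ext_rel])))
        if len(phases) == 2:
            break

    polarity = "biphasic" if (has_up and has_down) else (
        "facilitation" if has_up else "suppression"
    )
    return ResponseCharacterization(
        significant=True,
        polarity=polarity,
        peak_amplitude=float(resp[peak_idx]),
        peak_latency=float(resp_t[peak_idx]),
        phases=phases,
        baseline_mean=mean,
        baseline_sd=sd,
        infinite_z=infinite_z,
    )


def time_shifted_psth(
    spike_times: np.ndarray,
    onsets: np.ndarray,
    trials_per_row: int = 20,
    row_shift: int = 5,
    kernel_sd: float = 21.0,
    baseline_window: tuple[float, float] = (-1000.0, -200.0),
    window: tuple[float, float] = (-1000.0, 500.0),
) -> ShiftedPsthMap:
    """Convolved simple-spike PSTH per trial block, advanced block by block.

    Row ``r`` covers trials ``[r * row_shift, r * row_shift + trials_per_row)``
    and is expressed as percent change relative to that row's own mean over
    ``baseline_window``; the number of rows is
    ``floor((n_trials - trials_per_row) / row_shift) + 1``.
    """
    onsets = np.asarray(onsets, dtype=float)
    n = onsets.size
    if n < trials_per_row:
        raise ValueError(
            f"need at least trials_per_row={trials_per_row} trials, got {n}"
        )
    n_rows = (n - trials_per_row) // row_shift + 1
    starts = row_shift * np.arange(n_rows)
    rows = []
    for s in starts:
        block = onsets[s:s + trials_per_row]
        conv = gaussian_convolve(
            build_raw_psth(spike_times, block, window=window), kernel_sd=kernel_sd
        )
        base = conv.slice(baseline_window).mean()
        if base == 0.0:
            rows.append(np.full(conv.values.size, np.nan))
        else:
            rows.append(100.0 * (conv.values - base) / base)
    return ShiftedPsthMap(
        rows=np.vstack(rows), row_starts=starts, trials_per_row=trials_per_row,
        row_shift=row_shift, window=window, baseline_window=baseline_window,
    )
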