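"""Whisker kinematics: epoching, trial metrics, complex-spike sorting and the
bootstrap test for reflex adaptation.

The air puff evokes a stereotyped retraction followed by an active
protraction (protraction positive by convention).  Trials are epoched on a
1 ms grid relative to stimulus onset and baseline-subtracted over the 200 ms
preceding the puff.  Adaptation of the reflex after the 4 Hz induction block
is tested against a null band built by repeatedly splitting the last 100
pre-induction trials into two random halves of 50: the 99% interval of those
split differences is the natural trial-to-trial variability, and the
post-minus-pre difference is significant wherever it leaves that band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "WhiskerTrace",
    "TrialEpochs",
    "BootstrapChangeResult",
    "CsSortedComparison",
    "epoch_trials",
    "trial_kinematics",
    "detect_spontaneous",
    "sort_by_cs",
    "bootstrap_change",
]


@dataclass
class WhiskerTrace:
    """Uniformly sampled whisker-angle time series (degrees, protraction
    positive)."""

    samples: np.ndarray
    sample_rate: float = 1000.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("whisker trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


@dataclass
class TrialEpochs:
    """Trials x time matrix of whisker angle aligned to stimulus onsets."""

    data: np.ndarray  # trials x n_samples
    window: tuple[float, float]  # ms relative to onset
    sample_rate: float = 1000.0
    baseline_subtracted: bool = False
    baseline_window: tuple[float, float] | None = None
    phase_labels: np.ndarray | None = None
    dropped_trials: list[int] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Sample times in ms relative to onset."""
        step = 1e3 / self.sample_rate
        return self.window[0] + step * np.arange(self.data.shape[1])

    def column_mask(self, window: tuple[float, float]) -> np.ndarray:
        t = self.times
        mask = (t >= window[0]) & (t < window[1])
        if not mask.any():
            raise ValueError(f"window {window} outside epoch window {self.window}")
        return mask

    def select(self, rows: np.ndarray) -> "TrialEpochs":
        return TrialEpochs(
            data=self.data[rows], window=self.window, sample_rate=self.sample_rate,
            baseline_subtracted=self.baseline_subtracted,
            baseline_window=self.baseline_window,
            phase_labels=None if self.phase_labels is None
            else np.asarray(self.phase_labels)[rows],
        )


@dataclass
class BootstrapChangeResult:
    null_low: np.ndarray
    null_high: np.ndarray
    observed: np.ndarray
    significant_mask: np.ndarray
    times: np.ndarray  # ms
    level: float
    n_boot: int
    max_abs_difference: float
    max_abs_difference_time: float
    warnings: list[str] = field(default_factory=list)


@dataclass
class CsSortedComparison:
    mean_with_cs: np.ndarray
    mean_without_cs: np.ndarray
    difference: np.ndarray
    times: np.ndarray
    n_with_cs: int
    n_without_cs: int
    peak_difference: float
    peak_difference_time: float  # ms
    cs_psth_peak_time: float  # ms
    lead: float  # ms; positive = complex spikes precede the whisker difference
    period_metrics: dict  # {'with': {'a','b','c'}, 'without': {...}}


def epoch_trials(
    trace: WhiskerTrace,
    onsets: np.ndarray,
    window: tuple[float, float] = (-200.0, 500.0),
    baseline: tuple[float, float] | None = (-200.0, 0.0),
    phase_labels: np.ndarray | None = None,
) -> TrialEpochs:
    """Cut the trace into onset-aligned trials, subtracting each trial's mean
    over the baseline window.  Onsets too close to the trace edges are
    dropped and recorded in ``dropped_trials``."""
    onsets = np.asarray(onsets, dtype=float)
    step = 1e3 / trace.sample_rate
    n_samples = int(round((window[1] - window[0]) / step))
    rows, kept_labels, dropped = [], [], []
    for i, onset in enumerate(onsets):
        start = int(round((onset - trace.t0 + window[0] / 1e3) * trace.sample_rate))
        stop = start + n_samples
        if start < 0 or stop > trace.samples.size:
            dropped.append(i)
            continue
        rows.append(trace.samples[start:stop])
        if phase_labels is not None:
            kept_labels.append(phase_labels[i])
    if not rows:
        raise ValueError("no trial fits inside the trace")
    data = np.vstack(rows)
    epochs = TrialEpochs(
        data=data, window=window, sample_rate=trace.sample_rate,
        phase_labels=np.asarray(kept_labels) if phase_labels is not None else None,
        dropped_trials=dropped,
    )
    if baseline is not None:
        mask = epochs.column_mask(baseline)
        epochs.data = epochs.data - epochs.data[:, mask].mean(axis=1, keepdims=True)
        epochs.baseline_subtracted = True
        epochs.baseline_window = baseline
    return epochs


def trial_kinematics(
    epochs: TrialEpochs,
    retraction_window: tuple[float, float] = (0.0, 50.0),
    protraction_window: tuple[float, float] = (50.0, 200.0),
    baseline_window: tuple[float, float] = (-200.0, 0.0),
) -> dict[str, np.ndarray]:
    """Per-trial baseline angle, maximal retraction (minimum angle in the
    retraction window) and maximal protraction (maximum in the protraction
    window)."""
    if retraction_window[1] <= retraction_window[0] or \
            protraction_window[1] <= protraction_window[0]:
        raise ValueError("kinematics windows must have positive length")
    if retraction_window[0] >= protraction_window[0]:
        raise ValueError(
            "retraction window must precede protraction window "
            "(windows appear swapped)"
        )
    base = epochs.data[:, epochs.column_mask(baseline_window)].mean(axis=1)
    retr = epochs.data[:, epochs.column_mask(retraction_window)].min(axis=1)
    prot = epochs.data[:, epochs.column_mask(protraction_window)].max(axis=1)
    return {"baseline": base, "max_retraction": retr, "max_protraction": prot}


def detect_spontaneous(
    epochs: TrialEpochs,
    pre_window: tuple[float, float] = (-200.0, 0.0),
    amplitude_threshold: float = 10.0,
) -> float:
    """Fraction of trials whose pre-stimulus peak-to-peak angle exceeds the
    threshold (spontaneous whisking)."""
    pre = epochs.data[:, epochs.column_mask(pre_window)]
    amp = pre.max(axis=1) - pre.min(axis=1)
    return float(np.mean(amp > amplitude_threshold))


def sort_by_cs(
    epochs: TrialEpochs,
    cs_times_per_trial: list[np.ndarray],
    cs_window: tuple[float, float] = (0.0, 100.0),
    cs_psth=None,
    search_window: tuple[float, float] = (0.0, 300.0),
    smooth_sd_ms: float = 8.0,
) -> CsSortedComparison:
    """Split trials on the presence of a complex spike in the first 100 ms
    after onset and compare the group-mean whisker traces.

    ``cs_times_per_trial`` holds complex-spike times in ms relative to each
    trial's onset.  The difference trace (with - without) peaks where the
    complex spike exerts its largest effect; the lead is that peak time minus
    the peak time of the convolved complex-spike PSTH (restricted to the
    search window).  The peak's location and amplitude are read off a
    lightly smoothed copy of the difference trace (Gaussian ``smooth_sd_ms``,
    the spike-density kernel width) so the extremum estimate is not inflated
    by the maximum of per-sample sensor noise; the stored ``difference``
    trace itself stays raw.
    """
    if len(cs_times_per_trial) != epochs.n_trials:
        raise ValueError("one CS list per trial required")
    has_cs = np.array([
        bool(np.count_nonzero((np.asarray(t) >= cs_window[0])
                              & (np.asarray(t) < cs_window[1])))
        for t in cs_times_per_trial
    ])
    if not has_cs.any() or has_cs.all():
        raise ValueError(
            "cannot compare: all trials fall in one group "
            f"({int(has_cs.sum())} with / {int((~has_cs).sum())} without a CS)"
        )
    with_cs = epochs.data[has_cs].mean(axis=0)
    without_cs = epochs.data[~has_cs].mean(axis=0)
    diff = with_cs - without_cs
    t = epochs.times
    if smooth_sd_ms > 0:
        from scipy.ndimage import gaussian_filter1d

        step_ms = 1e3 / epochs.sample_rate
        diff_smooth = gaussian_filter1d(diff, sigma=smooth_sd_ms / step_ms,
                                        mode="reflect")
    else:
        diff_smooth = diff
    search = (t >= search_window[0]) & (t < search_window[1])
    idx = int(np.flatnonzero(search)[np.argmax(np.abs(diff_smooth[search]))])
    peak_time = float(t[idx])

    cs_peak_time = float("nan")
    if cs_psth is not None:
        pv, pt = cs_psth.values, cs_psth.times
        m = (pt >= search_window[0]) & (pt < search_window[1])
        cs_peak_time = float(pt[m][np.argmax(pv[m])])

    def _periods(trace: np.ndarray) -> dict:
        a = float(trace[(t >= -200) & (t < 0)].mean())
        b = float(trace[(t >= 0) & (t < 50)].min())
        c = float(trace[(t >= 50) & (t < 200)].max())
        return {"a_pre_stimulus": a, "b_max_retraction": b, "c_max_protraction": c}

    return CsSortedComparison(
        mean_with_cs=with_cs,
        mean_without_cs=without_cs,
        difference=diff,
        times=t,
        n_with_cs=int(has_cs.sum()),
        n_without_cs=int((~has_cs).sum()),
        peak_difference=float(diff_smooth[idx]),
        peak_difference_time=peak_time,
        cs_psth_peak_time=cs_peak_time,
        lead=peak_time - cs_peak_time,
        period_metrics={"with": _periods(with_cs), "without": _periods(without_cs)},
    )


def bootstrap_change(
    pre_epochs: TrialEpochs,
    post_epochs: TrialEpochs,
    n_boot: int = 1000,
    level: float = 99.0,
    group_size: int = 50,
    seed: int | None = None,
    n_draw: int = 1,
) -> BootstrapChangeResult:
    """Null-band test for adaptation of the whisker reflex.

    The null distribution of mean-trace differences comes from ``n_boot``
    random splits (without replacement) of the pre-induction trials into two
    disjoint groups of ``group_size``; the per-timepoint ``level``% interval
    of those differences is the expected variability.  The observed
    difference uses ``group_size`` randomly chosen post trials minus
    ``group_size`` randomly chosen pre trials (a single draw by default;
    ``n_draw > 1`` averages several draws — a stabilized variant that goes
    beyond the single-draw procedure).  Requires at least ``2 * group_size``
    pre trials and ``group_size`` post trials; smaller inputs are rejected
    rather than silently shrunk.
    """
    if pre_epochs.data.shape[1] != post_epochs.data.shape[1]:
        raise ValueError("pre and post epochs must share the time grid")
    n_pre, n_post = pre_epochs.n_trials, post_epochs.n_trials
    if n_pre < 2 * group_size:
        raise ValueError(f"need >= {2 * group_size} pre trials, got {n_pre}")
    if n_post < group_size:
        raise ValueError(f"need >= {group_size} post trials, got {n_post}")

    warns: list[str] = []
    if n_boot < 100:
        warns.append(
            f"n_boot={n_boot} gives a degenerate null band; use >= 100"
        )
        warnings.warn(warns[-1], stacklevel=2)

    rng = np.random.default_rng(seed)
    pre = pre_epochs.data
    post = post_epochs.data

    # vectorized splits: signed indicator matrix S (n_boot x n_pre) with
    # +1/group_size on one half, -1/group_size on the other, 0 elsewhere
    S = np.zeros((n_boot, n_pre))
    for b in range(n_boot):
        perm = rng.permutation(n_pre)
        S[b, perm[:group_size]] = 1.0 / group_size
        S[b, perm[group_size:2 * group_size]] = -1.0 / group_size
    null_diffs = S @ pre  # n_boot x time

    alpha = (100.0 - level) / 2.0
    low = np.percentile(null_diffs, alpha, axis=0)
    high = np.percentile(null_diffs, 100.0 - alpha, axis=0)

    obs = np.zeros(pre.shape[1])
    for _ in range(max(1, n_draw)):
        pi = rng.choice(n_pre, size=group_size, replace=False)
        qi = rng.choice(n_post, size=group_size, replace=False)
        obs += post[qi].mean(axis=0) - pre[pi].mean(axis=0)
    obs /= max(1, n_draw)

    mask = (obs < low) | (obs > high)
    times = pre_epochs.times
    k = int(np.argmax(np.abs(obs)))
    return BootstrapChangeResult(
        null_low=low, null_high=high, observed=obs, significant_mask=mask,
        times=times, level=level, n_boot=n_boot,
        max_abs_difference=float(np.abs(obs[k])),
        max_abs_difference_time=float(times[k]),
        warnings=warns,
    )
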