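"""Synthetic sessions with planted, known parameters.

Every downstream analysis in this package is exercised on data from these
generators, which emulate the structure of awake-mouse Purkinje-cell
recordings during whisker-pad air-puff stimulation:

* a stimulus protocol of 0.5 Hz pre-induction puffs, an 80-puff 4 Hz
  induction block, and 0.5 Hz post-induction puffs;
* simple spikes as an inhomogeneous Poisson process (~65 Hz baseline) with a
  3 ms absolute refractory period, a biphasic stimulus-locked modulation,
  and a firing pause after every complex spike;
* complex spikes as rare background events (~1 Hz) plus one stimulus-locked
  spike per trial with configurable probability and latency jitter;
* a whisker trace (1 kHz, protraction positive) built from a
  retraction-then-protraction reflex template, optionally coupled to the
  unit's own simple-spike density with a configurable lag, an extra
  protraction on complex-spike trials, and a protraction gain for
  post-induction trials (the planted plasticity effect);
* dendrites x frames event matrices with a tunable fraction of coherent
  (shared) evoked events.

All draws come from one seeded generator per session; identical seeds give
identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .behavior import WhiskerTrace
from .coherence import EventMatrix, default_transient_template
from .qc import SpikeTrain

__all__ = [
    "StimulusProtocol",
    "UnitParams",
    "WhiskerParams",
    "PopulationParams",
    "gen_protocol",
    "gen_purkinje_unit",
    "gen_whisker_session",
    "gen_population_events",
    "sample_unit_population",
    "ss_rate_profile",
]

PHASES = ("pre", "induction", "post")


@dataclass
class StimulusProtocol:
    """Ordered air-puff onsets with phase labels and puff parameters."""

    onset_times: np.ndarray  # seconds, strictly increasing
    phase_labels: np.ndarray  # 'pre' | 'induction' | 'post' per onset
    puff_duration: float = 30.0  # ms
    pre_rate: float = 0.5  # Hz
    induction_rate: float = 4.0  # Hz
    post_rate: float = 0.5  # Hz

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.phase_labels = np.asarray(self.phase_labels)
        if self.onset_times.size != self.phase_labels.size:
            raise ValueError("one phase label per onset required")
        if self.onset_times.size > 1 and not np.all(np.diff(self.onset_times) > 0):
            raise ValueError("onsets must be strictly increasing")
        if not np.isin(self.phase_labels, PHASES).all():
            raise ValueError(f"phase labels must be one of {PHASES}")
        ind = np.flatnonzero(self.phase_labels == "induction")
        if ind.size and not np.array_equal(ind, np.arange(ind[0], ind[-1] + 1)):
            raise ValueError("induction onsets must form one contiguous block")

    def onsets(self, phase: str | None = None) -> np.ndarray:
        if phase is None:
            return self.onset_times
        return self.onset_times[self.phase_labels == phase]

    @property
    def duration(self) -> float:
        """Nominal recording duration: last onset plus a 2 s tail."""
        return float(self.onset_times[-1] + 2.0) if self.onset_times.size else 2.0

    def to_dict(self) -> dict:
        return {
            "onset_times_s": self.onset_times.tolist(),
            "phase_labels": self.phase_labels.tolist(),
            "puff_duration_ms": self.puff_duration,
            "pre_rate_hz": self.pre_rate,
            "induction_rate_hz": self.induction_rate,
            "post_rate_hz": self.post_rate,
        }


@dataclass
class UnitParams:
    """Generative parameters of one synthetic Purkinje cell.

    ``ss_response`` lists (latency ms, duration ms, gain) phases multiplying
    the baseline simple-spike rate after each puff; the default plants the
    commonly observed biphasic shape (brief suppression, then facilitation).
    ``plasticity_gain`` multiplies those gains on post-induction trials
    (1.0 plants no change, as in the LTP-deficient genotypes).
    """

    ss_baseline_rate: float = 65.0  # Hz
    ss_refractory: float = 3.0  # ms
    cs_baseline_rate: float = 1.0  # Hz
    cs_response_prob: float = 0.35  # per trial
    cs_response_latency_mean: float = 20.0  # ms
    cs_response_latency_sd: float = 5.0  # ms
    cs_pause: float = 10.0  # ms of simple-spike silence after each CS
    ss_response: tuple = ((2.0, 28.0, 0.6), (30.0, 70.0, 1.6))
    plasticity_gain: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if min(self.ss_baseline_rate, self.cs_baseline_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.cs_pause < 0 or self.ss_refractory < 0:
            raise ValueError("pause and refractory period must be non-negative")
        if not 0.0 <= self.cs_response_prob <= 1.0:
            raise ValueError("cs_response_prob must be in [0, 1]")
        for lat, dur, gain in self.ss_response:
            if gain <= 0:
                raise ValueError("ss_response gains must be positive")
            if dur <= 0:
                raise ValueError("ss_response durations must be positive")
        if self.plasticity_gain <= 0:
            raise ValueError("plasticity_gain must be positive")


@dataclass
class WhiskerParams:
    """Generative parameters of the reflexive whisker movement.

    The reflex template is a negative (retraction) Gaussian bump followed by
    a positive (protraction) bump.  ``coupling_gain`` links the unit's own
    simple-spike density (8 ms kernel), lagged by ``coupling_lag``
    (``post_coupling_lag`` on post-induction trials), to the angle;
    ``cs_trial_bonus`` adds extra protraction on trials with a complex spike
    in the first 100 ms; ``post_gain`` scales the protraction amplitude on
    post-induction trials (the planted behavioral adaptation).
    """

    retraction_amplitude: float = 5.0  # degrees
    retraction_peak_time: float = 25.0  # ms after onset
    retraction_width: float = 10.0  # Gaussian sd, ms
    protraction_amplitude: float = 10.0  # degrees
    protraction_peak_time: float = 80.0  # ms
    protraction_width: float = 40.0  # Gaussian sd, ms
    coupling_gain: float = 0.0  # degrees per (spikes/s)
    coupling_lag: float = 0.0  # ms; spike density leads the angle by this
    post_coupling_lag: float | None = None  # lag on post-induction trials
    cs_trial_bonus: float = 0.8  # degrees of extra protraction on CS trials
    post_gain: float = 1.0  # protraction multiplier post induction
    noise_sd: float = 1.5  # degrees
    sample_rate: float = 1000.0  # Hz
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


@dataclass
class PopulationParams:
    """Generative parameters of a multi-dendrite event matrix."""

    n_dendrites: int = 10
    n_frames: int = 2000
    frame_duration: float = 40.0  # ms
    baseline_event_prob: float = 0.04  # per dendrite per frame
    evoked_event_prob: float = 0.4  # per dendrite per stimulus frame
    coherent_fraction: float = 0.0  # P(evoked event shared by all dendrites)
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("baseline_event_prob", "evoked_event_prob",
                     "coherent_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_dendrites < 1 or self.n_frames < 1:
            raise ValueError("n_dendrites and n_frames must be positive")
        if self.frame_duration <= 0:
            raise ValueError("frame_duration must be positive")


def gen_protocol(
    n_pre: int = 100,
    n_induction: int = 80,
    n_post: int = 100,
    rates: tuple[float, float, float] = (0.5, 4.0, 0.5),
    seed: int | None = None,
    start_s: float = 5.0,
) -> StimulusProtocol:
    """Deterministic air-puff protocol: contiguous pre / induction / post
    blocks with inter-onset interval 1/rate inside each phase; the first
    onset of a phase follows the previous onset by its own phase's interval.
    ``seed`` is accepted for interface symmetry (the protocol is currently
    jitter-free, hence fully determined by its arguments)."""
    if min(n_pre, n_induction, n_post) < 0:
        raise ValueError("phase counts must be non-negative")
    if min(rates) <= 0:
        raise ValueError("rates must be positive")
    onsets, labels = [], []
    t = start_s
    for phase, n, rate in zip(PHASES, (n_pre, n_induction, n_post), rates):
        step = 1.0 / rate
        for i in range(n):
            if onsets:
                t = onsets[-1] + step
            onsets.append(t)
            labels.append(phase)
    if not onsets:
        raise ValueError("protocol needs at least one onset")
    return StimulusProtocol(
        onset_times=np.array(onsets), phase_labels=np.array(labels),
        pre_rate=rates[0], induction_rate=rates[1], post_rate=rates[2],
    )


def ss_rate_profile(
    t: np.ndarray, protocol: StimulusProtocol, params: UnitParams
) -> np.ndarray:
    """Planted simple-spike intensity (Hz) at times ``t`` (seconds).

    Baseline rate multiplied by the response-phase gain whenever ``t`` falls
    in ``[onset + latency, onset + latency + duration)`` of a trial; gains on
    post-induction trials are further multiplied by ``plasticity_gain``.
    Also serves as the closed-form oracle for planted-gain recovery tests.
    """
    t = np.asarray(t, dtype=float)
    gain = np.ones_like(t)
    onsets = protocol.onset_times
    labels = protocol.phase_labels
    # locate the most recent onset for each time point
    idx = np.searchsorted(onsets, t, side="right") - 1
    valid = idx >= 0
    rel_ms = np.full(t.shape, np.inf)
    rel_ms[valid] = (t[valid] - onsets[idx[valid]]) * 1e3
    is_post = np.zeros(t.shape, dtype=bool)
    is_post[valid] = labels[idx[valid]] == "post"
    for lat, dur, g in params.ss_response:
        in_phase = (rel_ms >= lat) & (rel_ms < lat + dur)
        g_eff = np.where(is_post, g * params.plasticity_gain, g)
        gain = np.where(in_phase, gain * g_eff, gain)
    return params.ss_baseline_rate * gain


def _thin_refractory(times: np.ndarray, refractory_s: float) -> np.ndarray:
    """Sequentially delete spikes closer than the refractory period to the
    last kept spike."""
    if times.size == 0 or refractory_s <= 0:
        return times
    kept = [times[0]]
    last = times[0]
    for t in times[1:]:
        if t - last >= refractory_s:
            kept.append(t)
            last = t
    return np.array(kept)


def gen_purkinje_unit(
    protocol: StimulusProtocol,
    params: UnitParams,
    unit_id: str = "synthetic",
    duration: float | None = None,
) -> SpikeTrain:
    """Simulate one Purkinje cell driven by the protocol.

    Simple spikes: inhomogeneous Poisson process at the planted rate profile
    (generated by thinning a homogeneous process at the peak rate), then
    sequential deletion of spikes violating the absolute refractory period.
    Complex spikes: homogeneous background at ``cs_baseline_rate`` plus, with
    probability ``cs_response_prob`` per trial, one stimulus-locked spike at
    a jittered latency.  Every complex spike is followed by a simple-spike
    free pause of at least ``cs_pause`` (simple spikes inside the pause are
    deleted), so default units satisfy the inclusion rules by construction.
    """
    rng = np.random.default_rng(params.seed)
    ss_rng, cs_rng = rng.spawn(2)
    if duration is None:
        duration = protocol.duration

    max_gain = max(
        [1.0] + [g * max(1.0, params.plasticity_gain) for _, _, g in
                 params.ss_response]
    )
    lam_max = params.ss_baseline_rate * max_gain
    ss = np.empty(0)
    if lam_max > 0:
        n_exp = ss_rng.poisson(lam_max * duration)
        cand = np.sort(ss_rng.uniform(0.0, duration, n_exp))
        accept = ss_rng.random(cand.size) < (
            ss_rate_profile(cand, protocol, params) / lam_max
        )
        ss = _thin_refractory(cand[accept], params.ss_refractory / 1e3)

    cs_parts = []
    if params.cs_baseline_rate > 0:
        n_bg = cs_rng.poisson(params.cs_baseline_rate * duration)
        cs_parts.append(cs_rng.uniform(0.0, duration, n_bg))
    if params.cs_response_prob > 0:
        fire = cs_rng.random(protocol.onset_times.size) < params.cs_response_prob
        lat = cs_rng.normal(
            params.cs_response_latency_mean, params.cs_response_latency_sd,
            protocol.onset_times.size,
        )
        lat = np.clip(lat, 0.0, None) / 1e3
        cs_parts.append((protocol.onset_times + lat)[fire])
    cs = np.sort(np.concatenate(cs_parts)) if cs_parts else np.empty(0)
    cs = cs[(cs >= 0) & (cs <= duration)]
    cs = np.unique(cs)

    # post-complex-spike pause: delete simple spikes within (cs, cs + pause]
    if cs.size and ss.size and params.cs_pause > 0:
        pause_s = params.cs_pause / 1e3
        drop = np.zeros(ss.size, dtype=bool)
        lo = np.searchsorted(ss, cs, side="right")
        hi = np.searchsorted(ss, cs + pause_s, side="right")
        for a, b in zip(lo, hi):
            drop[a:b] = True
        ss = ss[~drop]

    return SpikeTrain(unit_id=unit_id, ss_times=ss, cs_times=cs,
                      duration=duration)


def _gauss_bump(t_ms: np.ndarray, peak_ms: float, sd_ms: float) -> np.ndarray:
    return np.exp(-0.5 * ((t_ms - peak_ms) / sd_ms) ** 2)


def gen_whisker_session(
    protocol: StimulusProtocol,
    spike_train: SpikeTrain,
    params: WhiskerParams,
) -> WhiskerTrace:
    """Whisker angle trace coupled to the protocol and the unit's spiking.

    Each trial adds the retraction-then-protraction template (protraction
    scaled by ``post_gain`` on post-induction trials), complex-spike trials
    add ``cs_trial_bonus`` degrees of extra protraction, and the lagged,
    mean-centered simple-spike density contributes ``coupling_gain`` degrees
    per spikes/s; Gaussian sensor noise tops it off.
    """
    if spike_train.duration + 1e-9 < protocol.duration - 2.0:
        raise ValueError("spike train must cover the protocol duration")
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate
    n = int(round(spike_train.duration * fs)) + 1
    t_ms = np.arange(n) / fs * 1e3
    angle = np.zeros(n)

    tpl_len = int(round(0.5 * fs))  # 500 ms template support
    tpl_t = np.arange(tpl_len) / fs * 1e3
    retr = -params.retraction_amplitude * _gauss_bump(
        tpl_t, params.retraction_peak_time, params.retraction_width)
    prot = _gauss_bump(tpl_t, params.protraction_peak_time,
                       params.protraction_width)

    cs = spike_train.cs_times
    for onset, phase in zip(protocol.onset_times, protocol.phase_labels):
        i0 = int(round(onset * fs))
        i1 = min(i0 + tpl_len, n)
        if i0 >= n:
            continue
        pg = params.post_gain if phase == "post" else 1.0
        seg = retr + params.protraction_amplitude * pg * prot
        if params.cs_trial_bonus and np.any(
                (cs >= onset) & (cs < onset + 0.1)):
            seg = seg + params.cs_trial_bonus * prot
        angle[i0:i1] += seg[: i1 - i0]

    if params.coupling_gain:
        counts = np.bincount(
            np.clip((spike_train.ss_times * fs).astype(int), 0, n - 1),
            minlength=n,
        ).astype(float)
        density = gaussian_filter1d(counts, sigma=8.0 * fs / 1e3,
                                    mode="constant") * fs  # spikes/s
        density -= density.mean()

        def shifted(lag_ms: float) -> np.ndarray:
            shift = int(round(lag_ms * fs / 1e3))
            out = np.zeros(n)
            if shift >= 0:
                out[shift:] = density[:n - shift] if shift else density
            else:
                out[:shift] = density[-shift:]
            return out

        post_lag = (params.coupling_lag if params.post_coupling_lag is None
                    else params.post_coupling_lag)
        if post_lag == params.coupling_lag:
            angle += params.coupling_gain * shifted(params.coupling_lag)
        else:
            post_onsets = protocol.onsets("post")
            boundary = n if post_onsets.size == 0 else int(
                round((post_onsets[0] - 1.0) * fs))
            contrib = params.coupling_gain * shifted(params.coupling_lag)
            contrib_post = params.coupling_gain * shifted(post_lag)
            angle[:boundary] += contrib[:boundary]
            angle[boundary:] += contrib_post[boundary:]

    if params.noise_sd > 0:
        angle += rng.normal(0.0, params.noise_sd, n)
    return WhiskerTrace(samples=angle, sample_rate=fs, t0=0.0)


def gen_population_events(
    params: PopulationParams,
    stimulus_frames: np.ndarray,
    return_fluorescence: bool = False,
    fluorescence_noise_sd: float = 0.1,
):
    """Multi-dendrite event matrix with a planted coherent fraction.

    Baseline events are independent Bernoulli draws everywhere.  On each
    stimulus frame, with probability ``coherent_fraction`` the frame is
    'shared': one Bernoulli(evoked_event_prob) draw decides for all
    dendrites at once; otherwise each dendrite draws independently with the
    same probability.  Optionally synthesizes fluorescence traces (25 Hz
    frame rate implied by frame_duration) via the transient template plus
    Gaussian noise.
    """
    stimulus_frames = np.asarray(stimulus_frames, dtype=int)
    if stimulus_frames.size and (
            stimulus_frames.min() < 0
            or stimulus_frames.max() >= params.n_frames):
        raise ValueError("stimulus_frames outside [0, n_frames)")
    rng = np.random.default_rng(params.seed)
    n_d, n_f = params.n_dendrites, params.n_frames
    events = (rng.random((n_d, n_f)) < params.baseline_event_prob)

    for f in stimulus_frames:
        if rng.random() < params.coherent_fraction:
            if rng.random() < params.evoked_event_prob:
                events[:, f] = True
        else:
            events[:, f] |= rng.random(n_d) < params.evoked_event_prob

    matrix = EventMatrix(
        events=events.astype(np.uint8),
        frame_duration=params.frame_duration,
        stimulus_frames=stimulus_frames,
    )
    if not return_fluorescence:
        return matrix

    sample_rate = 1e3 / params.frame_duration
    template = default_transient_template(sample_rate)
    traces = np.zeros((n_d, n_f))
    for d in range(n_d):
        impulse = matrix.events[d].astype(float)
        traces[d] = np.convolve(impulse, template)[:n_f]
    traces += rng.normal(0.0, fluorescence_noise_sd, traces.shape)
    return matrix, traces


def sample_unit_population(
    n_units: int, seed: int | None = None, plasticity_gain: float = 1.0
) -> list[UnitParams]:
    """Heterogeneous unit parameters emulating the recorded population.

    Complex-spike response probability is drawn from a three-class mixture —
    roughly 10% non-responders, 56% weak and 34% strong responders — with
    jittered baseline rates and latencies.  Useful for clustering and
    population-level analyses.
    """
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_units):
        u = rng.random()
        if u < 0.10:
            prob = rng.uniform(0.0, 0.04)
        elif u < 0.66:
            prob = np.clip(rng.normal(0.20, 0.08), 0.05, 0.45)
        else:
            prob = np.clip(rng.normal(0.85, 0.07), 0.5, 1.0)
        out.append(UnitParams(
            ss_baseline_rate=float(rng.uniform(55.0, 80.0)),
            cs_response_prob=float(prob),
            cs_response_latency_mean=float(rng.uniform(15.0, 30.0)),
            plasticity_gain=plasticity_gain,
            seed=int(rng.integers(0, 2**31 - 1)),
        ))
    return out
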