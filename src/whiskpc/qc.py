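"""Single-unit Purkinje cell quality control and firing statistics.

A recording qualifies as a single Purkinje cell when it contains both spike
types, simple spikes never violate a 3 ms minimal inter-spike interval, every
complex spike is followed by a pause in simple-spike firing of at least 8 ms,
and the recording lasts at least 200 s.  Firing regularity is summarized by
the local coefficient of variation CV2 = 2|ISIn+1 - ISIn| / (ISIn+1 + ISIn),
which is 0 for clock-like firing and has expectation 1 for a Poisson train.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SpikeTrain", "QCReport", "validate_unit", "cv2_series", "firing_rate"]

#: numerical guard (seconds) so an ISI of exactly 3.000 ms never flips on
#: floating-point rounding: a violation requires isi < threshold - 1 us.
_ISI_GUARD_S = 1e-6


@dataclass
class SpikeTrain:
    """One unit's labelled spike times.

    Parameters
    ----------
    unit_id : str
        Free-form unit label.
    ss_times, cs_times : ndarray
        Simple-spike and complex-spike times in seconds, strictly increasing,
        all within ``[0, duration]``.
    duration : float
        Recording duration in seconds.
    metadata : dict
        Optional labels (genotype, recording location grid coordinates, ...).
    """

    unit_id: str
    ss_times: np.ndarray
    cs_times: np.ndarray
    duration: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ss_times = np.asarray(self.ss_times, dtype=float)
        self.cs_times = np.asarray(self.cs_times, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for name, t in (("ss_times", self.ss_times), ("cs_times", self.cs_times)):
            if t.ndim != 1:
                raise ValueError(f"{name} must be 1-D")
            if t.size and (t[0] < 0 or t[-1] > self.duration):
                raise ValueError(f"{name} outside [0, duration]")
            if t.size > 1 and not np.all(np.diff(t) > 0):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass
class QCReport:
    """Outcome of the single-unit inclusion rules plus firing statistics."""

    unit_id: str
    passed: bool
    reasons: list[str]
    ss_rate: float
    cs_rate: float
    cv2_mean: float
    cv2_values: np.ndarray
    n_isi_violations: int = 0
    n_pause_violations: int = 0
    n_simultaneous: int = 0

    def to_dict(self) -> dict:
        return {
            "unit_id": self.unit_id,
            "passed": bool(self.passed),
            "reasons": list(self.reasons),
            "ss_rate_hz": float(self.ss_rate),
            "cs_rate_hz": float(self.cs_rate),
            "cv2_mean": None if np.isnan(self.cv2_mean) else float(self.cv2_mean),
            "n_isi_violations": int(self.n_isi_violations),
            "n_pause_violations": int(self.n_pause_violations),
            "n_simultaneous": int(self.n_simultaneous),
        }


def cv2_series(ss_times: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-interval CV2 values and their mean.

    Value ``k`` is computed from consecutive intervals ``k`` and ``k+1`` as
    ``2|ISI_{k+1} - ISI_k| / (ISI_{k+1} + ISI_k)``; every value lies in
    ``[0, 2]``.  Fewer than 3 spikes yield an empty series and a NaN mean —
    the undefined case is signalled, never silently zero.
    """
    t = np.asarray(ss_times, dtype=float)
    if t.size < 3:
        return np.empty(0), float("nan")
    isi = np.diff(t)
    a, b = isi[:-1], isi[1:]
    values = 2.0 * np.abs(b - a) / (b + a)
    return values, float(values.mean())


def firing_rate(times: np.ndarray, window: tuple[float, float]) -> float:
    """Mean rate (Hz) = spike count in ``[start, end)`` / window length."""
    start, end = float(window[0]), float(window[1])
    if end <= start:
        raise ValueError("window must have positive length")
    t = np.asarray(times, dtype=float)
    count = int(np.count_nonzero((t >= start) & (t < end)))
    return count / (end - start)


def validate_unit(
    train: SpikeTrain,
    min_duration_s: float = 200.0,
    min_ss_isi_ms: float = 3.0,
    min_cs_pause_ms: float = 8.0,
) -> QCReport:
    """Apply the single-Purkinje-cell inclusion rules to one spike train.

    ``passed`` is true iff the recording is at least ``min_duration_s`` long,
    every consecutive simple-spike pair is at least ``min_ss_isi_ms`` apart,
    and no simple spike falls within ``min_cs_pause_ms`` strictly after any
    complex spike.  A simple spike sharing a timestamp with a complex spike
    is reported distinctly as a data error.  The report always carries rates
    and CV2, pass or fail.  The check is pure: the train is not modified.
    """
    reasons: list[str] = []
    ss, cs = train.ss_times, train.cs_times

    if train.duration < min_duration_s:
        reasons.append(
            f"duration {train.duration:.1f} s < {min_duration_s:.0f} s minimum"
        )

    n_isi = 0
    if ss.size == 0:
        reasons.append("no simple spikes")
    elif ss.size > 1:
        isi = np.diff(ss)
        n_isi = int(np.count_nonzero(isi < min_ss_isi_ms / 1e3 - _ISI_GUARD_S))
        if n_isi:
            reasons.append(
                f"{n_isi} simple-spike ISI(s) < {min_ss_isi_ms:g} ms"
            )

    n_pause = 0
    n_simult = 0
    if cs.size and ss.size:
        # first SS strictly after each CS; pause violated if it falls inside
        # (cs, cs + pause)
        idx = np.searchsorted(ss, cs, side="right")
        ok = idx < ss.size
        gaps = np.full(cs.shape, np.inf)
        gaps[ok] = ss[idx[ok]] - cs[ok]
        n_pause = int(np.count_nonzero(gaps < min_cs_pause_ms / 1e3 - _ISI_GUARD_S))
        n_simult = int(np.count_nonzero(np.isin(cs, ss)))
        if n_pause:
            reasons.append(
                f"{n_pause} complex spike(s) followed by a simple spike "
                f"within {min_cs_pause_ms:g} ms"
            )
        if n_simult:
            reasons.append(
                f"{n_simult} simple spike(s) share a timestamp with a complex "
                "spike (data error)"
            )

    values, cv2_mean = cv2_series(ss)
    return QCReport(
        unit_id=train.unit_id,
        passed=not reasons,
        reasons=reasons,
        ss_rate=ss.size / train.duration,
        cs_rate=cs.size / train.duration,
        cv2_mean=cv2_mean,
        cv2_values=values,
        n_isi_violations=n_isi,
        n_pause_violations=n_pause,
        n_simultaneous=n_simult,
    )
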