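"""Readers and writers for the plain-text session formats.

A session lives in one directory tied together by a JSON manifest with
per-file SHA-256 checksums: spike trains as 2-column TSV (time_s,
spike_type ∈ {SS, CS}), whisker traces as 2-column TSV (time_s, angle_deg),
event matrices as 0/1 TSV (dendrites x frames), and the protocol plus
generator parameters as JSON.  Plain text keeps fixtures diffable; a
container-format reader can be hooked in by constructing the domain objects
directly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import WhiskerTrace
from .coherence import EventMatrix
from .qc import SpikeTrain
from .synthetic import StimulusProtocol

__all__ = [
    "SessionBundle",
    "SessionIOError",
    "MissingFileError",
    "ChecksumMismatchError",
    "UnsortedTimesError",
    "SamplingRateError",
    "write_session",
    "read_session",
    "write_spike_tsv",
    "read_spike_tsv",
    "write_whisker_tsv",
    "read_whisker_tsv",
    "write_events_tsv",
    "read_events_tsv",
]


class SessionIOError(Exception):
    """Base class for session load/store failures."""


class MissingFileError(SessionIOError):
    pass


class ChecksumMismatchError(SessionIOError):
    pass


class UnsortedTimesError(SessionIOError):
    pass


class SamplingRateError(SessionIOError):
    pass


@dataclass
class SessionBundle:
    """One recording session: protocol, spike trains, whisker trace and an
    optional event matrix, sharing a common time base."""

    protocol: StimulusProtocol
    spike_trains: list[SpikeTrain]
    whisker: WhiskerTrace | None = None
    events: EventMatrix | None = None
    metadata: dict = dataclasses.field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_spike_tsv(train: SpikeTrain, path: Path) -> None:
    rows = [(t, "SS") for t in train.ss_times] + \
           [(t, "CS") for t in train.cs_times]
    rows.sort()
    df = pd.DataFrame(rows, columns=["time_s", "spike_type"])
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_spike_tsv(path: Path, unit_id: str, duration: float) -> SpikeTrain:
    df = pd.read_csv(path, sep="\t", skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    types = df["spike_type"].str.strip()
    ss = np.sort(df.loc[types == "SS", "time_s"].to_numpy(dtype=float))
    cs = np.sort(df.loc[types == "CS", "time_s"].to_numpy(dtype=float))
    for name, t in (("SS", ss), ("CS", cs)):
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise UnsortedTimesError(
                f"{path}: duplicate or unsorted {name} times"
            )
    try:
        return SpikeTrain(unit_id=unit_id, ss_times=ss, cs_times=cs,
                          duration=duration)
    except ValueError as exc:
        raise UnsortedTimesError(f"{path}: {exc}") from exc


def write_whisker_tsv(trace: WhiskerTrace, path: Path) -> None:
    t = trace.t0 + np.arange(trace.samples.size) / trace.sample_rate
    pd.DataFrame({"time_s": t, "angle_deg": trace.samples}).to_csv(
        path, sep="\t", index=False, float_format="%.6f")


def read_whisker_tsv(path: Path, expected_rate: float | None = None
                     ) -> WhiskerTrace:
    df = pd.read_csv(path, sep="\t", skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    t = df["time_s"].to_numpy(dtype=float)
    if t.size < 2:
        raise SessionIOError(f"{path}: whisker trace too short")
    steps = np.diff(t)
    if not np.allclose(steps, steps[0], atol=1e-6):
        raise SamplingRateError(f"{path}: non-uniform sampling")
    rate = 1.0 / steps.mean()
    if expected_rate is not None and abs(rate - expected_rate) > 0.5:
        raise SamplingRateError(
            f"{path}: sampling rate {rate:.1f} Hz != expected "
            f"{expected_rate:.1f} Hz"
        )
    return WhiskerTrace(samples=df["angle_deg"].to_numpy(dtype=float),
                        sample_rate=rate, t0=float(t[0]))


def write_events_tsv(events: EventMatrix, path: Path) -> None:
    pd.DataFrame(events.events).to_csv(path, sep="\t", index=False,
                                       header=False)


def read_events_tsv(path: Path, frame_duration: float = 40.0,
                    stimulus_frames=None) -> EventMatrix:
    data = pd.read_csv(path, sep="\t", header=None).to_numpy(dtype=int)
    return EventMatrix(events=data, frame_duration=frame_duration,
                       stimulus_frames=stimulus_frames)


def write_session(bundle: SessionBundle, out_dir: Path) -> Path:
    """Write all session members plus a checksummed manifest; returns the
    manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}

    proto_path = out_dir / "protocol.json"
    proto_path.write_text(json.dumps(bundle.protocol.to_dict(), indent=1))
    files["protocol"] = {"path": proto_path.name}

    units = []
    for train in bundle.spike_trains:
        p = out_dir / f"spikes_{train.unit_id}.tsv"
        write_spike_tsv(train, p)
        units.append({"path": p.name, "unit_id": train.unit_id,
                      "duration_s": train.duration})
    files["spike_trains"] = units

    if bundle.whisker is not None:
        p = out_dir / "whisker.tsv"
        write_whisker_tsv(bundle.whisker, p)
        files["whisker"] = {"path": p.name,
                            "sample_rate_hz": bundle.whisker.sample_rate}
    if bundle.events is not None:
        p = out_dir / "events.tsv"
        write_events_tsv(bundle.events, p)
        files["events"] = {
            "path": p.name,
            "frame_duration_ms": bundle.events.frame_duration,
            "stimulus_frames":
                None if bundle.events.stimulus_frames is None
                else bundle.events.stimulus_frames.tolist(),
        }

    def add_checksums(entry):
        entry["sha256"] = _sha256(out_dir / entry["path"])

    add_checksums(files["protocol"])
    for entry in files["spike_trains"]:
        add_checksums(entry)
    for key in ("whisker", "events"):
        if key in files:
            add_checksums(files[key])

    manifest = {"format": "whiskpc-session/1", "files": files,
                "metadata": bundle.metadata}
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_session(manifest_path: Path) -> SessionBundle:
    """Load and fully validate a session from its manifest.

    Checksum mismatches, unsorted spike times and sampling-rate mismatches
    each raise their own named error; all domain-type invariants are
    enforced at load."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise MissingFileError(f"manifest not found: {manifest_path}")
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    files = manifest["files"]

    def check(entry) -> Path:
        p = root / entry["path"]
        if not p.exists():
            raise MissingFileError(f"missing session file: {p}")
        if "sha256" in entry and _sha256(p) != entry["sha256"]:
            raise ChecksumMismatchError(f"checksum mismatch for {p}")
        return p

    proto_raw = json.loads(check(files["protocol"]).read_text())
    protocol = StimulusProtocol(
        onset_times=np.asarray(proto_raw["onset_times_s"]),
        phase_labels=np.asarray(proto_raw["phase_labels"]),
        puff_duration=proto_raw.get("puff_duration_ms", 30.0),
        pre_rate=proto_raw.get("pre_rate_hz", 0.5),
        induction_rate=proto_raw.get("induction_rate_hz", 4.0),
        post_rate=proto_raw.get("post_rate_hz", 0.5),
    )

    trains = [
        read_spike_tsv(check(e), e["unit_id"], e["duration_s"])
        for e in files["spike_trains"]
    ]
    whisker = None
    if "whisker" in files:
        whisker = read_whisker_tsv(check(files["whisker"]),
                                   files["whisker"].get("sample_rate_hz"))
    events = None
    if "events" in files:
        sf = files["events"].get("stimulus_frames")
        events = read_events_tsv(
            check(files["events"]),
            frame_duration=files["events"].get("frame_duration_ms", 40.0),
            stimulus_frames=None if sf is None else np.asarray(sf),
        )
    return SessionBundle(protocol=protocol, spike_trains=trains,
                         whisker=whisker, events=events,
                         metadata=manifest.get("metadata", {}))
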