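"""Preprocessing of multi-subject sensor recordings.

Turns raw channels-by-samples recordings into band-limited, pause-free,
timeslot-segmented, per-channel standardized matrices ready for multiset CCA:

1. zero-phase band-pass to one of the canonical low-frequency bands
   (delta 0.5-4 Hz, theta 4-8 Hz, alpha 8-12 Hz),
2. removal of inter-statement pauses (analysis uses only the samples during
   which a statement was playing),
3. split of the pause-free stream into ``n_slots`` contiguous equal-length
   timeslots (beginning / middle / end),
4. per-channel standardization (zero mean, unit population variance).

Filtering is applied to the continuous recording *before* pause removal so
that concatenation splices never pass through the filter.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal

__all__ = [
    "Event",
    "SubjectRecording",
    "BandDefinition",
    "BANDS",
    "TimeslotData",
    "SLOT_NAMES",
    "bandpass",
    "remove_pauses",
    "split_timeslots",
    "standardize",
    "preprocess_group",
    "statement_sample_count",
]

logger = logging.getLogger(__name__)

SLOT_NAMES = ("beginning", "middle", "end")


class Event(NamedTuple):
    start: int
    stop: int  # exclusive
    label: str  # "statement" | "pause"


@dataclass
class SubjectRecording:
    """One subject's channels × samples recording with event annotations."""

    data: np.ndarray
    sampling_rate: float
    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels × samples")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.events = [Event(int(s), int(e), str(lab)) for s, e, lab in self.events]
        prev_stop = 0
        for ev in self.events:
            if not (0 <= ev.start < ev.stop <= self.n_samples):
                raise ValueError(f"event {ev} outside [0, {self.n_samples})")
            if ev.start < prev_stop:
                raise ValueError("events must be sorted and non-overlapping")
            prev_stop = ev.stop

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band with [low, high] edges in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("require 0 < low < high")


BANDS: dict[str, BandDefinition] = {
    "delta": BandDefinition("delta", 0.5, 4.0),
    "theta": BandDefinition("theta", 4.0, 8.0),
    "alpha": BandDefinition("alpha", 8.0, 12.0),
}


@dataclass
class TimeslotData:
    """Standardized per-subject matrices for one timeslot of one group."""

    slot: str
    data: list[np.ndarray]  # per subject, channels × samples

    def __post_init__(self) -> None:
        lengths = {x.shape[1] for x in self.data}
        if len(lengths) > 1:
            raise ValueError("all subjects must share the same sample count")

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def n_samples(self) -> int:
        return self.data[0].shape[1]


def _design_bandpass(band: BandDefinition, fs: float, order: int = 4):
    nyq = fs / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band high edge {band.high} Hz must be below Nyquist {nyq} Hz"
        )
    return signal.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")


def bandpass(recording: SubjectRecording, band: BandDefinition, order: int = 4) -> SubjectRecording:
    """Zero-phase Butterworth band-pass of every channel.

    Forward-backward application (``sosfiltfilt``) cancels the phase response;
    the squared magnitude response of an order-4 Butterworth comfortably meets
    a 20 dB stop-band one octave outside the pass band. Edges are padded by
    reflection over at least three times the low-edge period.
    """
    sos = _design_bandpass(band, recording.sampling_rate, order)
    padlen = min(recording.n_samples - 1, int(3 * recording.sampling_rate / band.low))
    filtered = signal.sosfiltfilt(sos, recording.data, axis=1, padtype="even", padlen=padlen)
    return replace(recording, data=np.ascontiguousarray(filtered))


def remove_pauses(recording: SubjectRecording) -> SubjectRecording:
    """Concatenate the statement segments, dropping pauses.

    The returned recording's events are rewritten onto the new sample grid
    (statement segments only, back to back).
    """
    stmts = [ev for ev in recording.events if ev.label == "statement"]
    if not stmts:
        raise ValueError("recording has no statement events; nothing to keep")
    pieces = [recording.data[:, ev.start : ev.stop] for ev in stmts]
    new_events = []
    pos = 0
    for ev, piece in zip(stmts, pieces):
        new_events.append(Event(pos, pos + piece.shape[1], "statement"))
        pos += piece.shape[1]
    return SubjectRecording(
        data=np.concatenate(pieces, axis=1),
        sampling_rate=recording.sampling_rate,
        events=new_events,
    )


def statement_sample_count(events: Sequence[Event]) -> int:
    """Total statement samples implied by an event table (pause-free length)."""
    return sum(ev.stop - ev.start for ev in events if ev.label == "statement")


def split_timeslots(recording: SubjectRecording, n_slots: int = 3) -> list[np.ndarray]:
    """Split a pause-free recording into ``n_slots`` contiguous equal slots.

    Each slot has ``T // n_slots`` samples; the trailing remainder is
    discarded. Boundaries depend only on the sample count, so they are
    identical across subjects of a group.
    """
    T = recording.n_samples
    if T < n_slots:
        raise ValueError(f"cannot split {T} samples into {n_slots} slots")
    L = T // n_slots
    return [recording.data[:, i * L : (i + 1) * L].copy() for i in range(n_slots)]


def standardize(data: np.ndarray, atol: float = 1e-12) -> np.ndarray:
    """Per-channel zero mean, unit population variance (divisor T).

    Channels with (numerically) zero variance cannot be brought to unit
    variance; they are dropped with a warning and the returned matrix has
    correspondingly fewer rows.
    """
    data = np.asarray(data, dtype=float)
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)  # population convention
    keep = sd[:, 0] > atol
    if not np.all(keep):
        dropped = np.flatnonzero(~keep)
        warnings.warn(f"dropping constant channels {dropped.tolist()}", stacklevel=2)
        logger.warning("standardize: dropped constant channels %s", dropped.tolist())
        data, mean, sd = data[keep], mean[keep], sd[keep]
    return (data - mean) / sd


def preprocess_group(
    recordings: Sequence[SubjectRecording],
    band: BandDefinition,
    n_slots: int = 3,
) -> list[TimeslotData]:
    """Full preprocessing chain for all subjects of one group.

    Band-pass → pause removal → timeslot split → per-channel standardization,
    returning one :class:`TimeslotData` per slot with all subjects aligned.
    """
    per_subject_slots: list[list[np.ndarray]] = []
    for rec in recordings:
        clean = remove_pauses(bandpass(rec, band))
        per_subject_slots.append([standardize(x) for x in split_timeslots(clean, n_slots)])
    slots = []
    for s in range(n_slots):
        name = SLOT_NAMES[s] if n_slots == 3 else f"slot{s}"
        slots.append(TimeslotData(slot=name, data=[subj[s] for subj in per_subject_slots]))
    return slots
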