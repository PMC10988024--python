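"""Synthetic multi-subject datasets with planted alignment and behavior.

The generator emulates the study design the analysis pipeline assumes: three
intervention groups (paradoxical n=39, inconsistent n=40, control n=41)
listening to 22 auditory statements of 11–18 s separated by short pauses
(~9-minute paradigm), with band-limited neural recordings at each sensor.

The latent model is deliberately minimal — the weakest structure under which
multiset CCA's objective is well-posed: per group and per timeslot a single
rank-1 shared source, mixed into each subject's sensors through a
subject-specific unit-norm mixing vector and scaled by a per-subject coupling
in [0, 1], on top of independent (optionally band-limited) Gaussian channel
noise. Entries of ``shared_snr_schedule`` are per-channel RMS
signal-to-noise standard-deviation ratios, so their meaning does not depend
on the channel count. Pauses contain noise only.

The behavioral generator plants (i) per-group linear trends in mean
agreement across the three timeslots, (ii) a target correlation between the
ground-truth subject coupling and the feeling-thermometer T2−T1 change in
the designated group, and (iii) a correlation between the agreement
end−beginning change and the measures-against T2−T1 change. All other
questionnaire deltas are pure noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from ._rng import substream_rng
from .behavior import (
    BehaviorTable,
    EMOTION_ITEMS,
    EMOTION_RANGE,
    GROUPS,
    SCALES,
)
from .preprocess import Event, SubjectRecording, statement_sample_count

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "MultiSubjectDataset",
    "generate_shared_source",
    "generate_events",
    "generate_latents",
    "generate_dataset",
    "generate_behavior",
]


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic cohort.

    ``shared_snr_schedule[g][s]`` is group g's per-channel RMS SNR in
    timeslot s; the defaults plant the build-up observed in the paradoxical
    group (alignment emerging toward the end of the intervention) and no
    shared signal in the control conditions. ``agreement_trend`` gives each
    group's slope of mean agreement per timeslot step on the 1–3 scale;
    agreement declines in the two intervention groups and is flat for the
    neutral control.
    """

    n_groups: int = 3
    group_sizes: tuple[int, ...] = (39, 40, 41)
    n_channels: int = 64
    sampling_rate: float = 150.0
    n_statements: int = 22
    statement_duration_range: tuple[float, float] = (11.0, 18.0)
    pause_duration: float = 3.0
    n_timeslots: int = 3
    shared_snr_schedule: tuple[tuple[float, ...], ...] = (
        (0.0, 0.03, 0.08),
        (0.0, 0.0, 0.0),
        (0.0, 0.0, 0.0),
    )
    source_band: tuple[float, float] = (0.5, 4.0)
    band_limited_noise: bool = True
    coupling_range: tuple[float, float] = (0.2, 1.0)
    behavior_effect: float = 0.436
    behavior_group: int = 0
    agreement_effect: float = 0.474
    agreement_trend: tuple[float, ...] = (-0.4, -0.25, 0.0)
    agreement_baseline: tuple[float, ...] = (2.4, 2.0, 2.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.group_sizes) != self.n_groups:
            raise ValueError("group_sizes length must equal n_groups")
        if len(self.shared_snr_schedule) != self.n_groups:
            raise ValueError("shared_snr_schedule needs one row per group")
        for row in self.shared_snr_schedule:
            if len(row) != self.n_timeslots:
                raise ValueError("shared_snr_schedule rows need one entry per timeslot")
            if any(v < 0 for v in row):
                raise ValueError("shared_snr_schedule entries must be >= 0")
        lo, hi = self.statement_duration_range
        if not 0 < lo <= hi:
            raise ValueError("statement durations must be positive, lo <= hi")
        if self.pause_duration < 0:
            raise ValueError("pause_duration must be >= 0")
        lo, hi = self.source_band
        if not 0 < lo < hi < self.sampling_rate / 2:
            raise ValueError("source_band must satisfy 0 < low < high < Nyquist")
        if not -1 <= self.behavior_effect <= 1:
            raise ValueError("behavior_effect must lie in [-1, 1]")
        if not -1 <= self.agreement_effect <= 1:
            raise ValueError("agreement_effect must lie in [-1, 1]")
        if len(self.agreement_trend) != self.n_groups or len(self.agreement_baseline) != self.n_groups:
            raise ValueError("agreement_trend/baseline need one entry per group")
        lo, hi = self.coupling_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("coupling_range must lie within [0, 1]")

    @property
    def group_names(self) -> tuple[str, ...]:
        return GROUPS[: self.n_groups]


@dataclass
class GroundTruth:
    """Planted latent structure, kept for recovery tests.

    ``shared_source[g][s]`` is group g's unit-variance source over timeslot
    s's samples (on the pause-free grid); ``mixing_vectors[g][i]`` the
    subject's unit-norm channel mixing; ``subject_coupling[g][i]`` in [0, 1]
    scales the source for that subject; ``true_agreement_means[g]`` is the
    subjects × timeslots matrix of planted mean agreement.
    """

    shared_source: list[list[np.ndarray]]
    mixing_vectors: list[np.ndarray]  # per group: (M, C)
    subject_coupling: list[np.ndarray]  # per group: (M,)
    true_agreement_means: list[np.ndarray]  # per group: (M, n_timeslots)
    slot_boundaries: list[tuple[int, int]]  # on the pause-free grid
    events: list[Event]
    shared_source_full: list[np.ndarray]  # per group, full pause-free grid


@dataclass
class MultiSubjectDataset:
    """Aligned recordings for all subjects of one group."""

    group: str
    recordings: list[SubjectRecording]

    def __post_init__(self) -> None:
        shapes = {rec.data.shape[1] for rec in self.recordings}
        if len(shapes) > 1:
            raise ValueError("subjects of a group must share the sample grid")

    @property
    def n_subjects(self) -> int:
        return len(self.recordings)

    @property
    def sampling_rate(self) -> float:
        return self.recordings[0].sampling_rate

    @property
    def events(self) -> list[Event]:
        return self.recordings[0].events


def generate_shared_source(
    duration: float, band: tuple[float, float], sampling_rate: float, seed: int
) -> np.ndarray:
    """Band-limited, zero-mean, unit-variance source signal.

    White Gaussian noise passed through a zero-phase order-4 Butterworth
    band-pass (out-of-band power down by far more than 20 dB after the
    forward-backward pass), then exactly standardized. The filter runs on a
    longer sequence and only the interior is kept, so the returned series is
    stationary: filter edge transients would otherwise give every generated
    source the same inflated-variance edge profile, which biases
    alignment-statistic null calibration.
    """
    lo, hi = band
    if not 0 < lo < hi < sampling_rate / 2:
        raise ValueError("require 0 < low < high < Nyquist")
    n = int(round(duration * sampling_rate))
    pad = int(np.ceil(3 * sampling_rate / lo))
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n + 2 * pad)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sampling_rate, output="sos")
    x = signal.sosfiltfilt(sos, white)[pad : pad + n]
    x = x - x.mean()
    return x / x.std()


def generate_events(config: SimulationConfig, rng: np.random.Generator) -> list[Event]:
    """Statement/pause event table on the raw sample grid (pauses between
    statements only); statement durations uniform within the configured range."""
    fs = config.sampling_rate
    lo, hi = config.statement_duration_range
    durs = rng.uniform(lo, hi, size=config.n_statements)
    events: list[Event] = []
    pos = 0
    pause = int(round(config.pause_duration * fs))
    for i, d in enumerate(durs):
        n = int(round(d * fs))
        events.append(Event(pos, pos + n, "statement"))
        pos += n
        if i < config.n_statements - 1 and pause > 0:
            events.append(Event(pos, pos + pause, "pause"))
            pos += pause
    return events


def _slot_boundaries(T_statement: int, n_slots: int) -> list[tuple[int, int]]:
    L = T_statement // n_slots
    return [(s * L, (s + 1) * L) for s in range(n_slots)]


def _band_noise(rng: np.random.Generator, shape, config: SimulationConfig) -> np.ndarray:
    """Unit-variance channel noise, optionally band-limited to the source band.

    As in :func:`generate_shared_source`, filtering happens on padded
    sequences and only the stationary interior is kept.
    """
    if not config.band_limited_noise:
        return rng.standard_normal(shape)
    lo = config.source_band[0]
    pad = int(np.ceil(3 * config.sampling_rate / lo))
    padded = rng.standard_normal(shape[:-1] + (shape[-1] + 2 * pad,))
    sos = signal.butter(
        4, list(config.source_band), btype="bandpass",
        fs=config.sampling_rate, output="sos",
    )
    noise = signal.sosfiltfilt(sos, padded, axis=-1)[..., pad : pad + shape[-1]]
    return noise / noise.std(axis=-1, keepdims=True)


def generate_latents(config: SimulationConfig) -> GroundTruth:
    """Draw the latent structure only: events, shared sources, mixing vectors,
    subject couplings and planted agreement means — no sensor noise. Cheap
    enough for behavioral Monte-Carlo studies that never touch neural data.
    """
    events = generate_events(config, substream_rng(config.seed, "events"))
    T_stmt = statement_sample_count(events)
    bounds = _slot_boundaries(T_stmt, config.n_timeslots)
    gt_sources_full: list[np.ndarray] = []
    gt_sources: list[list[np.ndarray]] = []
    gt_mixing: list[np.ndarray] = []
    gt_coupling: list[np.ndarray] = []
    for g, size in enumerate(config.group_sizes):
        source = generate_shared_source(
            T_stmt / config.sampling_rate, config.source_band,
            config.sampling_rate, int(substream_rng(config.seed, f"source{g}").integers(2**31)),
        )[:T_stmt]
        gt_sources_full.append(source)
        gt_sources.append([source[a:b].copy() for a, b in bounds])
        rng_g = substream_rng(config.seed, f"latent{g}")
        mixing = rng_g.standard_normal((size, config.n_channels))
        mixing /= np.linalg.norm(mixing, axis=1, keepdims=True)
        gt_mixing.append(mixing)
        gt_coupling.append(rng_g.uniform(*config.coupling_range, size=size))
    return GroundTruth(
        shared_source=gt_sources,
        mixing_vectors=gt_mixing,
        subject_coupling=gt_coupling,
        true_agreement_means=_true_agreement_means(config),
        slot_boundaries=bounds,
        events=events,
        shared_source_full=gt_sources_full,
    )


def generate_dataset(
    config: SimulationConfig,
) -> tuple[list[MultiSubjectDataset], GroundTruth, list[Event]]:
    """Simulate all groups' sensor recordings with planted shared sources.

    Every subject's recording is coupling × SNR × √C × (mixing ⊗ source)
    plus unit-variance channel noise during statements, noise only during
    pauses; the SNR factor follows the group's per-timeslot schedule on the
    pause-free grid (remainder samples after the last full slot keep the last
    slot's level). The event table is shared by all groups so the sample
    grids align.
    """
    gt = generate_latents(config)
    events = gt.events
    T_total = events[-1].stop
    T_stmt = statement_sample_count(events)
    stmt_mask = np.zeros(T_total, dtype=bool)
    for ev in events:
        if ev.label == "statement":
            stmt_mask[ev.start : ev.stop] = True
    sqrtC = np.sqrt(config.n_channels)
    datasets: list[MultiSubjectDataset] = []
    for g, (name, size) in enumerate(zip(config.group_names, config.group_sizes)):
        rng_g = substream_rng(config.seed, f"noise{g}")
        source = gt.shared_source_full[g]
        scale = np.full(T_stmt, config.shared_snr_schedule[g][-1], dtype=float)
        for s, (a, b) in enumerate(gt.slot_boundaries):
            scale[a:b] = config.shared_snr_schedule[g][s]
        recs = []
        for i in range(size):
            data = _band_noise(rng_g, (config.n_channels, T_total), config)
            data[:, stmt_mask] += (
                gt.subject_coupling[g][i] * sqrtC
                * np.outer(gt.mixing_vectors[g][i], scale * source)
            )
            recs.append(SubjectRecording(data=data, sampling_rate=config.sampling_rate,
                                         events=list(events)))
        datasets.append(MultiSubjectDataset(group=name, recordings=recs))
    return datasets, gt, events


def _true_agreement_means(config: SimulationConfig) -> list[np.ndarray]:
    out = []
    for g, size in enumerate(config.group_sizes):
        rng = substream_rng(config.seed, f"agreement{g}")
        base = config.agreement_baseline[g] + rng.normal(0, 0.15, size=size)
        slopes = config.agreement_trend[g]
        means = base[:, None] + slopes * np.arange(config.n_timeslots)[None, :]
        out.append(np.clip(means, 1.0, 3.0))
    return out


def _planted_delta(
    rng: np.random.Generator, driver: np.ndarray, effect: float, sd: float
) -> np.ndarray:
    """Continuous delta with corr(driver, delta) == effect in expectation."""
    z = (driver - driver.mean()) / driver.std() if driver.std() > 0 else np.zeros_like(driver)
    noise = rng.standard_normal(len(driver))
    return sd * (effect * z + np.sqrt(max(0.0, 1 - effect**2)) * noise)


def generate_behavior(
    ground_truth: GroundTruth, config: SimulationConfig, seed: int | None = None
) -> BehaviorTable:
    """Simulate the behavioral table consistent with the planted neural truth.

    Agreement ratings are integer 1–3 draws around each subject's planted
    per-slot mean (statements mapped to slots by segment midpoint). In the
    designated group, the feeling-thermometer T2−T1 change correlates with
    the subject coupling at ``behavior_effect`` (before integer rounding and
    range clipping), and the measures-against change correlates with the
    agreement end−beginning change at ``agreement_effect``; every other
    scale's change is noise.
    """
    from .behavior import map_statements_to_slots  # local to avoid cycle at import time

    seed = config.seed if seed is None else seed
    slot_map = map_statements_to_slots(ground_truth.events, config.n_timeslots)
    rows = []
    subject_id = 0
    for g, name in enumerate(config.group_names):
        rng = substream_rng(seed, f"behavior{g}")
        size = config.group_sizes[g]
        means = ground_truth.true_agreement_means[g]
        agreement = np.clip(
            np.rint(means[:, slot_map] + rng.normal(0, 0.5, size=(size, config.n_statements))),
            1, 3,
        ).astype(int)
        # scale items: stable individual baselines, noise-only test-retest change
        items_t1: dict[str, np.ndarray] = {}
        items_t2: dict[str, np.ndarray] = {}

        def draw_items(scale: str, n_items: int, lo: int, hi: int) -> None:
            mid = (lo + hi) / 2.0
            span = (hi - lo) / 2.0
            base = rng.normal(mid, span / 2.5, size=size)
            for j in range(n_items):
                t1 = base + rng.normal(0, span / 4, size=size)
                t2 = t1 + rng.normal(0, span / 6, size=size)
                key = f"{scale}{j + 1}" if n_items > 1 else scale
                items_t1[key] = np.clip(np.rint(t1), lo, hi).astype(int)
                items_t2[key] = np.clip(np.rint(t2), lo, hi).astype(int)

        for scale, (n_items, lo, hi, rev) in SCALES.items():
            if scale == "feeling_thermometer":
                continue
            draw_items(scale, n_items, lo, hi)
        lo_e, hi_e = EMOTION_RANGE
        for name_e in EMOTION_ITEMS:
            draw_items(f"emotion_{name_e}", 1, lo_e, hi_e)

        # reverse-keyed negativity items are stored in the reversed direction
        n_items, lo, hi, rev = SCALES["negativity"]
        for j in rev:
            items_t1[f"negativity{j + 1}"] = lo + hi - items_t1[f"negativity{j + 1}"]
            items_t2[f"negativity{j + 1}"] = lo + hi - items_t2[f"negativity{j + 1}"]

        # feeling thermometer: planted coupling -> T2−T1 link in the target group
        lo, hi = SCALES["feeling_thermometer"][1:3]
        t1 = np.clip(np.rint(rng.normal((lo + hi) / 2, 1.8, size=size)), lo, hi)
        effect = config.behavior_effect if g == config.behavior_group else 0.0
        delta = _planted_delta(rng, ground_truth.subject_coupling[g], effect, sd=1.6)
        items_t1["feeling_thermometer"] = t1.astype(int)
        items_t2["feeling_thermometer"] = np.clip(np.rint(t1 + delta), lo, hi).astype(int)

        # measures-against: planted link to the agreement end−beginning change
        ag_slot0 = agreement[:, slot_map == 0].mean(axis=1)
        ag_slot_last = agreement[:, slot_map == config.n_timeslots - 1].mean(axis=1)
        ag_diff = ag_slot_last - ag_slot0
        eff2 = config.agreement_effect if g == config.behavior_group else 0.0
        n_items, lo, hi, _ = SCALES["measures_against"]
        shift = _planted_delta(rng, ag_diff, eff2, sd=1.2)
        for j in range(n_items):
            base = items_t1[f"measures_against{j + 1}"].astype(float)
            items_t2[f"measures_against{j + 1}"] = np.clip(
                np.rint(base + shift + rng.normal(0, 0.4, size=size)), lo, hi
            ).astype(int)

        for i in range(size):
            row: dict[str, object] = {"subject_id": f"S{subject_id:03d}", "group": name}
            for s_i in range(config.n_statements):
                row[f"agreement_s{s_i + 1}"] = int(agreement[i, s_i])
            for key, vals in items_t1.items():
                row[f"{key}_t1"] = int(vals[i])
            for key, vals in items_t2.items():
                row[f"{key}_t2"] = int(vals[i])
            rows.append(row)
            subject_id += 1
    return BehaviorTable(pd.DataFrame(rows), n_statements=config.n_statements)
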