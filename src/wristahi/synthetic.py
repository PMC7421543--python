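"""Synthetic overnight wrist-recording generator.

Builds (Recording, AnnotationSet, GroundTruth) triples with the statistical
structure the estimator relies on, so the full pipeline can be exercised and
validated without clinical data:

* a hypnogram drawn from a stage-transition chain (~80-85% sleep efficiency);
* a pulse train whose mean inter-beat interval and variability depend on the
  sleep stage, with respiratory sinus modulation of both the IBI and the
  pulse amplitude at the recording's breathing rate;
* respiratory events placed only during sleep, each imposing a reduced
  respiratory modulation of the pulse amplitude during the event and a
  post-event heart-rate response (IBI dip) -- the event-locked signature the
  classifier must learn;
* limb movements adding accelerometer bursts, wake adding sustained movement
  (which also drives the activity-count truncation and the sleep stager);
* artefact intervals corrupting the waveform and degrading pulse quality;
* AASM-style scored annotations (events CSV + 30-s hypnogram) and a ground
  truth whose per-epoch labels use the same RE-epoch rule as the labeller.

The generator emulates the statistical structure only, not raw-PPG optics or
obstruction mechanics; central/mixed/obstructive events share one waveform
signature and differ only in their annotation type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .io_core import (
    AnnotationSet,
    Channel,
    EpochGrid,
    EventType,
    Recording,
    ScoredEvent,
    SleepStage,
    make_epoch_grid,
)
from .labeling import label_re_epochs

STAGE_ORDER = (SleepStage.W, SleepStage.N1, SleepStage.N2, SleepStage.N3, SleepStage.REM)
#: stage-transition chain per 30-s epoch; rows follow STAGE_ORDER
STAGE_TRANSITIONS = np.array(
    [
        [0.75, 0.25, 0.00, 0.00, 0.00],  # W
        [0.05, 0.40, 0.50, 0.00, 0.05],  # N1
        [0.03, 0.03, 0.75, 0.12, 0.07],  # N2
        [0.02, 0.00, 0.18, 0.80, 0.00],  # N3
        [0.05, 0.05, 0.10, 0.00, 0.80],  # REM
    ]
)
#: mean IBI (s) per stage: faster heart rate in wake/REM, slower in deep sleep
STAGE_MEAN_IBI = {
    SleepStage.W: 0.78,
    SleepStage.N1: 0.88,
    SleepStage.N2: 0.92,
    SleepStage.N3: 0.98,
    SleepStage.REM: 0.86,
}


@dataclass
class SimConfig:
    """Generator settings; defaults emulate a hypopnea-dominant clinical mix."""

    duration_h: float = 8.0
    target_ahi: float = 15.0
    ahi_range: tuple[float, float] = (0.0, 60.0)  # cohort draw
    event_mix: dict = field(
        default_factory=lambda: {
            EventType.HYPOPNEA: 0.84,
            EventType.OBSTRUCTIVE_APNEA: 0.08,
            EventType.MIXED_APNEA: 0.04,
            EventType.CENTRAL_APNEA: 0.04,
        }
    )
    event_duration_range: tuple[float, float] = (10.0, 60.0)
    min_event_gap_s: float = 10.0
    limb_movement_rate_per_h: float = 5.0
    artefact_rate_per_h: float = 2.0
    artefact_duration_range: tuple[float, float] = (5.0, 20.0)
    rppg_rate: float = 32.0
    accel_rate: float = 128.0
    breath_rate_range: tuple[float, float] = (0.2, 0.3)  # Hz
    amp_mod_depth: float = 0.25  # respiratory modulation of pulse amplitude
    event_amp_drop: float = 0.30  # fraction of modulation depth lost in events
    rsa_depth_s: float = 0.03  # respiratory modulation of the IBI
    ibi_dip_fraction: float = 0.15  # post-event tachycardic dip
    ibi_dip_duration_s: float = 10.0
    ibi_jitter_s: float = 0.01
    waveform_noise: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if sum(self.event_mix.values()) > 1.0 + 1e-9:
            raise ValueError("event mix fractions must sum to at most 1")
        if self.event_duration_range[0] < 10.0:
            raise ValueError("respiratory events must last at least 10 s")
        if min(self.limb_movement_rate_per_h, self.artefact_rate_per_h) < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class GroundTruth:
    events: list[ScoredEvent]
    hypnogram: list[SleepStage]
    true_ahi: float
    true_tst_minutes: float
    re_labels: np.ndarray
    artefact_intervals: list[tuple[float, float]]
    beat_times: np.ndarray
    beat_amplitudes: np.ndarray
    breath_rate_hz: float


def _simulate_hypnogram(n_epochs: int, rng: np.random.Generator) -> list[SleepStage]:
    stages = [SleepStage.W]
    idx = 0
    for _ in range(n_epochs - 1):
        idx = rng.choice(5, p=STAGE_TRANSITIONS[idx])
        stages.append(STAGE_ORDER[idx])
    return stages


def _sleep_intervals(hypnogram: Sequence[SleepStage], epoch_len: float = 30.0):
    asleep = np.array([s != SleepStage.W for s in hypnogram])
    intervals = []
    start = None
    for k, a in enumerate(asleep):
        if a and start is None:
            start = k
        elif not a and start is not None:
            intervals.append((start * epoch_len, k * epoch_len))
            start = None
    if start is not None:
        intervals.append((start * epoch_len, len(asleep) * epoch_len))
    return intervals


def _place_events(
    cfg: SimConfig,
    n_events: int,
    intervals: list[tuple[float, float]],
    rng: np.random.Generator,
) -> list[ScoredEvent]:
    if n_events == 0:
        return []
    durations = rng.uniform(*cfg.event_duration_range, size=n_events)
    lengths = np.array([b - a for a, b in intervals])
    capacity = lengths - cfg.min_event_gap_s
    if durations.sum() + n_events * cfg.min_event_gap_s > 0.95 * capacity.sum():
        raise ValueError("infeasible event density: events do not fit in sleep time")

    types = list(cfg.event_mix.keys())
    probs = np.array(list(cfg.event_mix.values()), dtype=float)
    probs = probs / probs.sum()
    type_draws = rng.choice(len(types), size=n_events, p=probs)

    # greedy best-fit: each event goes to the sleep interval with the most
    # remaining slack; each interval's events are then spread with random gaps
    order = rng.permutation(n_events)
    di = durations[order]
    ti = type_draws[order]
    remaining = capacity.copy()
    assigned: list[list[int]] = [[] for _ in intervals]
    for j in range(n_events):
        need = di[j] + cfg.min_event_gap_s
        i = int(np.argmax(remaining))
        if remaining[i] < need:
            raise ValueError("infeasible event density: could not place all events")
        assigned[i].append(j)
        remaining[i] -= need

    events: list[ScoredEvent] = []
    for (a, b), idx in zip(intervals, assigned):
        if not idx:
            continue
        d = di[idx]
        k = len(idx)
        slack = (b - a) - d.sum() - k * cfg.min_event_gap_s
        cuts = np.sort(rng.uniform(0, max(slack, 0.0), size=k))
        t = a
        prev_cut = 0.0
        for j, ev_j in enumerate(idx):
            t += (cuts[j] - prev_cut) + cfg.min_event_gap_s / 2.0
            prev_cut = cuts[j]
            events.append(ScoredEvent(types[ti[ev_j]], round(t, 2), round(d[j], 2)))
            t += d[j] + cfg.min_event_gap_s / 2.0
    return sorted(events, key=lambda e: e.onset)


def _smooth_noise(n: int, rng: np.random.Generator, rho: float = 0.98, sd: float = 1.0):
    x = np.zeros(n)
    eps = rng.normal(0.0, 1.0, size=n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + eps[i]
    x *= sd * np.sqrt(1 - rho**2)
    return x


def _in_intervals(t: float, starts: np.ndarray, ends: np.ndarray) -> bool:
    i = np.searchsorted(starts, t, side="right") - 1
    return i >= 0 and t < ends[i]


def simulate_recording(
    config: SimConfig, seed: Optional[int] = None
) -> tuple[Recording, AnnotationSet, GroundTruth]:
    """Simulate one overnight recording with its annotations and ground truth.

    Deterministic given (config, seed).  The true AHI equals the number of
    respiratory events divided by the true total sleep time.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    duration = cfg.duration_h * 3600.0
    grid = make_epoch_grid(duration)
    hypnogram = _simulate_hypnogram(grid.n_epochs, rng)
    intervals = _sleep_intervals(hypnogram)
    tst_minutes = 0.5 * sum(s != SleepStage.W for s in hypnogram)
    tst_hours = tst_minutes / 60.0
    n_events = int(round(cfg.target_ahi * tst_hours))
    events = _place_events(cfg, n_events, intervals, rng)
    true_ahi = n_events / tst_hours if tst_hours > 0 else 0.0

    ev_starts = np.array([e.onset for e in events])
    ev_ends = np.array([e.end for e in events])
    dip_starts = ev_ends
    dip_ends = ev_ends + cfg.ibi_dip_duration_s

    # limb movements: Poisson over sleep, 3-15 s
    n_limb = rng.poisson(cfg.limb_movement_rate_per_h * cfg.duration_h)
    limb_events = []
    if intervals and n_limb:
        total = sum(b - a for a, b in intervals)
        for _ in range(n_limb):
            u = rng.uniform(0, total)
            for a, b in intervals:
                if u <= b - a:
                    limb_events.append(
                        ScoredEvent(
                            EventType.LIMB_MOVEMENT,
                            round(a + u, 2),
                            round(rng.uniform(3.0, 15.0), 2),
                        )
                    )
                    break
                u -= b - a
    # the annotation contract forbids nested same-type events
    limb_events.sort(key=lambda e: (e.onset, -e.duration))
    pruned = []
    for ev in limb_events:
        if any(ev.onset >= p.onset and ev.end <= p.end for p in pruned):
            continue
        pruned.append(ev)
    limb_events = pruned
    # arousals terminating a share of respiratory events (AASM hypopnea rule)
    arousals = [
        ScoredEvent(EventType.AROUSAL, round(e.end, 2), 5.0)
        for e in events
        if rng.random() < 0.6 and e.end + 5.0 < duration
    ]

    # artefact intervals (technical signal loss)
    n_art = rng.poisson(cfg.artefact_rate_per_h * cfg.duration_h)
    artefacts = []
    for _ in range(n_art):
        d = rng.uniform(*cfg.artefact_duration_range)
        a = rng.uniform(0, duration - d)
        artefacts.append((a, a + d))
    artefacts.sort()

    # ---- beat train -------------------------------------------------------
    breath_rate = rng.uniform(*cfg.breath_rate_range)
    phase = rng.uniform(0, 2 * np.pi)
    slow = _smooth_noise(int(duration) + 2, rng, rho=0.995, sd=0.02)
    beat_times = []
    beat_amps = []
    t = float(rng.uniform(0.0, 0.5))
    while t < duration:
        stage = hypnogram[min(int(t // 30.0), grid.n_epochs - 1)]
        mean_ibi = STAGE_MEAN_IBI[stage] * (1.0 + slow[int(t)])
        if len(ev_ends) and _in_intervals(t, dip_starts, dip_ends):
            mean_ibi *= 1.0 - cfg.ibi_dip_fraction
        ibi = (
            mean_ibi
            + cfg.rsa_depth_s * np.sin(2 * np.pi * breath_rate * t + phase)
            + rng.normal(0.0, cfg.ibi_jitter_s)
        )
        ibi = float(np.clip(ibi, 0.4, 1.8))
        depth = cfg.amp_mod_depth
        amp_scale = 1.0
        if len(ev_starts) and _in_intervals(t, ev_starts, ev_ends):
            depth *= 1.0 - cfg.event_amp_drop
            amp_scale = 1.0 - 0.5 * cfg.event_amp_drop
        amp = amp_scale * (
            1.0 + depth * np.sin(2 * np.pi * breath_rate * t + phase)
        ) * (1.0 + 0.05 * slow[int(t)])
        beat_times.append(t)
        beat_amps.append(max(amp, 0.1))
        t += ibi
    beat_times = np.asarray(beat_times)
    beat_amps = np.asarray(beat_amps)

    # ---- rPPG waveform ----------------------------------------------------
    fs = cfg.rppg_rate
    n_samp = int(duration * fs)
    rppg = np.zeros(n_samp)
    tt = np.concatenate([beat_times, [duration]])
    for i in range(len(beat_times)):
        n0 = int(np.ceil(tt[i] * fs))
        n1 = min(int(np.ceil(tt[i + 1] * fs)), n_samp)
        if n1 <= n0:
            continue
        tau = (np.arange(n0, n1) / fs - tt[i]) / (tt[i + 1] - tt[i])
        # asymmetric pulse: fast systolic rise to 30% of the cycle, slow decay
        shape = np.where(
            tau < 0.3,
            np.sin(np.pi * tau / 0.6) ** 2,
            np.exp(-(tau - 0.3) / 0.25) * np.sin(np.pi * 0.5) ** 2,
        )
        rppg[n0:n1] += beat_amps[i] * shape
    rppg += rng.normal(0.0, cfg.waveform_noise, size=n_samp)
    for a, b in artefacts:
        i0, i1 = int(a * fs), min(int(b * fs), n_samp)
        rppg[i0:i1] = rng.normal(0.0, 2.0, size=i1 - i0)

    # ---- accelerometer ----------------------------------------------------
    fa = cfg.accel_rate
    n_acc = int(duration * fa)
    accel = rng.normal(0.0, 0.002, size=(n_acc, 3))
    accel[:, 2] += 1.0  # gravity
    def add_burst(t0: float, dur: float, amp: float) -> None:
        i0 = int(t0 * fa)
        i1 = min(int((t0 + dur) * fa), n_acc)
        if i1 > i0:
            accel[i0:i1] += rng.normal(0.0, amp, size=(i1 - i0, 3))
    for k, stage in enumerate(hypnogram):
        if stage == SleepStage.W and rng.random() < 0.8:
            add_burst(k * 30.0 + rng.uniform(0, 20), rng.uniform(3, 10), rng.uniform(0.3, 0.8))
    for lm in limb_events:
        add_burst(lm.onset, lm.duration, 0.5)

    recording = Recording(
        id=f"sim-{cfg.seed if seed is None else seed}",
        rppg=Channel(rppg, fs, "PPG wrist"),
        accel=Channel(accel, fa, "accel"),
    )
    all_events = sorted(events + limb_events + arousals, key=lambda e: e.onset)
    annotations = AnnotationSet(
        events=all_events, hypnogram=list(hypnogram), reference_ahi=true_ahi
    )
    truth = GroundTruth(
        events=events,
        hypnogram=list(hypnogram),
        true_ahi=true_ahi,
        true_tst_minutes=tst_minutes,
        re_labels=label_re_epochs(events, grid),
        artefact_intervals=artefacts,
        beat_times=beat_times,
        beat_amplitudes=beat_amps,
        breath_rate_hz=breath_rate,
    )
    return recording, annotations, truth


def simulate_cohort(
    config: SimConfig, n: int, base_seed: int = 0
) -> list[tuple[Recording, AnnotationSet, GroundTruth]]:
    """Simulate ``n`` recordings; per-recording target AHI drawn uniformly from
    ``config.ahi_range`` and seeds ``base_seed + index``."""
    if n < 1:
        raise ValueError("need n >= 1")
    out = []
    for i in range(n):
        rng = np.random.default_rng(base_seed + i)
        target = float(rng.uniform(*config.ahi_range))
        cfg = replace(config, target_ahi=target)
        out.append(simulate_recording(cfg, seed=base_seed + i))
    return out
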