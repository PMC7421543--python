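"""Per-epoch reference labels derived from scored annotations.

A 30-s epoch is a respiratory-event epoch (RE-epoch, positive class) when it
contains at least 10 s of a single respiratory event, or when its start falls
within 5 s after the end of a respiratory event (the post-event
cardiovascular response spills into the next epoch).  Arousals and limb
movements never make an epoch positive on their own.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_core import (
    EpochGrid,
    EventType,
    RESPIRATORY_EVENT_TYPES,
    ScoredEvent,
)

MIN_OVERLAP_S = 10.0  # rule (a): one event must contribute at least this much
POST_EVENT_S = 5.0  # rule (b): epoch start strictly within this after event end
_EPS = 1e-9  # float tolerance at rule boundaries (>= 10 inclusive, < 5 strict)
LIMB_MIN_DURATION_S = 3.0
ZERO_WEIGHT_COVERAGE = 80.0  # % undefined features above which an epoch has weight 0
MAX_ECTOPIC_PERCENT = 5.0
MIN_FEATURE_COVERAGE_FRACTION = 0.5


@dataclass
class EpochLabels:
    re_label: np.ndarray  # bool per epoch
    predominant_event: list  # Optional[EventType] per epoch
    limb_flag: np.ndarray  # bool per epoch
    weight: np.ndarray  # {0., 1.} per epoch


def _overlap(onset: float, end: float, start: float, stop: float) -> float:
    return max(0.0, min(end, stop) - max(onset, start))


def merge_abutting_events(events: Sequence[ScoredEvent]) -> list[ScoredEvent]:
    """Merge same-type events whose intervals touch or overlap.

    An event split into abutting pieces is physiologically one event; merging
    first makes the labels invariant to such splits (otherwise the interior
    boundary would spuriously trigger the post-event rule).
    """
    out: list[ScoredEvent] = []
    for ev in sorted(events, key=lambda e: (e.type.value, e.onset)):
        if (
            out
            and out[-1].type == ev.type
            and ev.onset <= out[-1].end + _EPS
            and ev.end > out[-1].end
        ):
            out[-1] = ScoredEvent(ev.type, out[-1].onset, ev.end - out[-1].onset)
        elif out and out[-1].type == ev.type and ev.end <= out[-1].end:
            continue  # fully contained
        else:
            out.append(ev)
    return sorted(out, key=lambda e: e.onset)


def label_re_epochs(
    events: Sequence[ScoredEvent],
    grid: EpochGrid,
    pool_events: bool = False,
) -> np.ndarray:
    """Boolean RE-epoch label per epoch.

    Positive iff (a) overlap with a single respiratory event is >= 10 s
    (with ``pool_events`` the overlaps of all respiratory events in the epoch
    are pooled instead), or (b) a respiratory event ends at ``e`` with
    ``0 <= epoch_start - e < 5``.  Abutting same-type events are merged first.
    """
    n = grid.n_epochs
    L = grid.epoch_length
    labels = np.zeros(n, dtype=bool)
    pooled = np.zeros(n) if pool_events else None
    merged = merge_abutting_events(
        [e for e in events if e.type in RESPIRATORY_EVENT_TYPES]
    )
    for ev in merged:
        k0 = max(0, int(np.floor(ev.onset / L)))
        k1 = min(n - 1, int(np.floor(max(ev.end - 1e-12, 0.0) / L)))
        for k in range(k0, k1 + 1):
            ov = _overlap(ev.onset, ev.end, k * L, (k + 1) * L)
            if pool_events:
                pooled[k] += ov
            elif ov >= MIN_OVERLAP_S - _EPS:
                labels[k] = True
        # rule (b): epochs starting within [end, end + 5)
        kb0 = int(np.ceil(ev.end / L)) - 1
        kb1 = int(np.ceil((ev.end + POST_EVENT_S) / L))
        for k in range(max(0, kb0), min(n - 1, kb1) + 1):
            d = k * L - ev.end
            if -_EPS <= d < POST_EVENT_S - _EPS:
                labels[k] = True
    if pool_events:
        labels |= pooled >= MIN_OVERLAP_S - _EPS
    return labels


def attribute_events(
    events: Sequence[ScoredEvent], grid: EpochGrid
) -> tuple[list, np.ndarray]:
    """Predominant respiratory event per epoch and the limb-movement flag.

    The respiratory event with the longest total duration among those
    overlapping an epoch gives the epoch its event type (ties broken by
    earlier onset).  ``limb_flag`` is true iff a limb movement is the longest
    event of any type in the epoch and lasts more than 3 s.
    """
    n = grid.n_epochs
    L = grid.epoch_length
    predominant: list[Optional[EventType]] = [None] * n
    limb_flag = np.zeros(n, dtype=bool)
    best_resp = np.full(n, -np.inf)
    best_resp_onset = np.full(n, np.inf)
    best_any = np.full(n, -np.inf)
    best_any_onset = np.full(n, np.inf)
    longest_any: list[Optional[ScoredEvent]] = [None] * n

    for ev in events:
        k0 = max(0, int(np.floor(ev.onset / L)))
        k1 = min(n - 1, int(np.floor(max(ev.end - 1e-12, 0.0) / L)))
        for k in range(k0, k1 + 1):
            if _overlap(ev.onset, ev.end, k * L, (k + 1) * L) <= 0:
                continue
            key = (ev.duration, -ev.onset)
            if ev.type in RESPIRATORY_EVENT_TYPES:
                if key > (best_resp[k], -best_resp_onset[k]):
                    best_resp[k] = ev.duration
                    best_resp_onset[k] = ev.onset
                    predominant[k] = ev.type
            if key > (best_any[k], -best_any_onset[k]):
                best_any[k] = ev.duration
                best_any_onset[k] = ev.onset
                longest_any[k] = ev
    for k in range(n):
        ev = longest_any[k]
        limb_flag[k] = (
            ev is not None
            and ev.type == EventType.LIMB_MOVEMENT
            and ev.duration > LIMB_MIN_DURATION_S
        )
    return predominant, limb_flag


def zero_weight_mask(coverage_feature: np.ndarray) -> np.ndarray:
    """Per-epoch loss/AHI weight: 0 where more than 80% of features are
    undefined (strict inequality), 1 otherwise."""
    coverage = np.asarray(coverage_feature, dtype=float)
    if np.any((coverage < 0) | (coverage > 100)):
        raise ValueError("coverage must lie in [0, 100] percent")
    return np.where(coverage > ZERO_WEIGHT_COVERAGE, 0.0, 1.0)


def make_epoch_labels(
    events: Sequence[ScoredEvent],
    grid: EpochGrid,
    coverage_feature: np.ndarray,
    pool_events: bool = False,
) -> EpochLabels:
    predominant, limb = attribute_events(events, grid)
    return EpochLabels(
        re_label=label_re_epochs(events, grid, pool_events=pool_events),
        predominant_event=predominant,
        limb_flag=limb,
        weight=zero_weight_mask(coverage_feature),
    )


def select_training_recordings(
    ectopic_percent: Sequence[float],
    feature_coverage_fraction: Sequence[float],
) -> np.ndarray:
    """Eligibility flags for the training/validation pool.

    A recording qualifies when fewer than 5% of its detected beats are
    suspected ectopic (from ECG when available, else the IBI ectopic flags)
    and features are defined for at least 50% of its duration.
    """
    ect = np.asarray(ectopic_percent, dtype=float)
    cov = np.asarray(feature_coverage_fraction, dtype=float)
    return (ect < MAX_ECTOPIC_PERCENT) & (cov >= MIN_FEATURE_COVERAGE_FRACTION)
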