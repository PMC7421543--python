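"""AHI estimation from positive epochs, with quality gating.

The apnea-hypopnea index is estimated as the number of positively classified
30-s epochs during sleep divided by the total sleep time, multiplied by a
correction coefficient.  The coefficient compensates for the mismatch between
counting event-influenced *epochs* and counting *events*: it is the
through-origin regression slope of the reference AHI on the epoch-based AHI
computed from reference labels, fitted on training recordings only.

Epochs with more than 80% undefined features (weight 0) are excluded from the
count; sleep/wake comes from the argmax of the sleep-stage probabilities.
Recording-level rPPG quality is summarised by six per-epoch metrics averaged
over the night, gated against thresholds derived as the 10th percentile of
the training recordings' means.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_core import EpochGrid
from .pulse import IBISeries, PulseSeries

SEVERITY_NAMES = ("none", "mild", "moderate", "severe")
SEVERITY_EDGES = (5.0, 15.0, 30.0)
MIN_TST_MINUTES = 30.0
QUALITY_METRIC_NAMES = (
    "ibi_coverage_percent",
    "mean_pulse_quality",
    "median_pulse_quality",
    "percent_quality_above_0_6",
    "q25_pulse_quality",
    "q75_pulse_quality",
)
#: recording-exclusion minimums reported for the clinically trained system;
#: packages trained on other data should derive their own via
#: :func:`derive_quality_thresholds`
REFERENCE_QUALITY_THRESHOLDS = {
    "ibi_coverage_percent": 83.0,
    "mean_pulse_quality": 0.85,
    "median_pulse_quality": 0.90,
    "percent_quality_above_0_6": 89.0,
    "q25_pulse_quality": 0.80,
    "q75_pulse_quality": 0.96,
}


@dataclass
class AHIResult:
    estimated_ahi: float
    severity: str
    tst_minutes: float
    n_positive_sleep_epochs: int
    n_excluded_epochs: int
    correction_coefficient: float


@dataclass
class QualityReport:
    metrics: dict
    thresholds: dict
    pass_flags: dict
    overall_pass: bool


def estimate_tst(stage_probs: np.ndarray) -> tuple[float, np.ndarray]:
    """Total sleep time (minutes) and the per-epoch sleep mask.

    An epoch is asleep iff the argmax of its stage probabilities is not Wake
    (class 0).  Recordings with less than 30 min of estimated sleep are
    rejected, mirroring the minimum-sleep exclusion applied to the cohort.
    """
    stage_probs = np.asarray(stage_probs, dtype=float)
    sleep_mask = (np.argmax(stage_probs, axis=1) != 0).astype(float)
    tst = 0.5 * float(sleep_mask.sum())
    if tst < MIN_TST_MINUTES:
        raise ValueError(
            f"estimated sleep duration {tst:.1f} min is shorter than "
            f"{MIN_TST_MINUTES:.0f} min; recording rejected"
        )
    return tst, sleep_mask


def fit_correction_coefficient(
    reference_ahis: Sequence[float], raw_epoch_ahis: Sequence[float]
) -> float:
    """Through-origin least-squares slope of reference AHI on the epoch-based
    AHI computed from reference labels (training recordings only)."""
    ref = np.asarray(reference_ahis, dtype=float)
    raw = np.asarray(raw_epoch_ahis, dtype=float)
    if len(ref) != len(raw) or len(ref) == 0:
        raise ValueError("need paired, non-empty AHI vectors")
    denom = float(np.sum(raw**2))
    if denom == 0:
        raise ValueError("all raw epoch-based AHI values are zero; cannot fit")
    return float(np.sum(ref * raw) / denom)


def reference_epoch_ahi(
    re_labels: np.ndarray, sleep_mask: np.ndarray, weights: np.ndarray, tst_minutes: float
) -> float:
    """Epoch-based AHI from reference labels: positive sleeping epochs with
    weight 1 per hour of sleep (the regressor of the correction fit)."""
    pos = int(np.sum((np.asarray(re_labels) > 0) & (sleep_mask > 0) & (weights > 0)))
    return pos / (tst_minutes / 60.0)


def estimate_ahi(
    probabilities: np.ndarray,
    threshold: float,
    sleep_mask: np.ndarray,
    weights: np.ndarray,
    tst_minutes: float,
    coefficient: float = 1.0,
) -> AHIResult:
    """Estimated AHI = coefficient x (positive sleeping weight-1 epochs) / TST.

    Zero-weight epochs (more than 80% undefined features) are excluded from
    the count even when their probability clears the threshold.
    """
    if tst_minutes < MIN_TST_MINUTES:
        raise ValueError("total sleep time below the 30-min minimum")
    p = np.asarray(probabilities, dtype=float)
    sm = np.asarray(sleep_mask, dtype=float)
    w = np.asarray(weights, dtype=float)
    contributing = (sm > 0) & (w > 0)
    positives = int(np.sum((p >= threshold) & contributing))
    excluded = int(np.sum((sm > 0) & (w == 0)))
    ahi = coefficient * positives / (tst_minutes / 60.0)
    return AHIResult(
        estimated_ahi=ahi,
        severity=classify_severity(ahi),
        tst_minutes=tst_minutes,
        n_positive_sleep_epochs=positives,
        n_excluded_epochs=excluded,
        correction_coefficient=coefficient,
    )


def classify_severity(ahi: float) -> str:
    """Canonical OSA severity: none <5, mild [5,15), moderate [15,30), severe >=30."""
    if ahi < 0:
        raise ValueError("AHI must be >= 0")
    return SEVERITY_NAMES[int(np.digitize(ahi, SEVERITY_EDGES))]


def severity_index(ahi: float) -> int:
    if ahi < 0:
        raise ValueError("AHI must be >= 0")
    return int(np.digitize(ahi, SEVERITY_EDGES))


def quality_report(
    pulses: PulseSeries,
    ibis: IBISeries,
    grid: EpochGrid,
    thresholds: Optional[dict] = None,
) -> QualityReport:
    """Per-recording rPPG quality summary.

    Six metrics are computed for each 30-s epoch and averaged over the
    recording: accepted-IBI coverage (%), mean / median / 25th / 75th
    percentile pulse quality, and the percentage of pulses with quality above
    0.6.  Quality statistics average over epochs that contain pulses; IBI
    coverage averages over all epochs.  Each metric is gated against its
    threshold; the recording passes only if every metric does.
    """
    thresholds = dict(thresholds or REFERENCE_QUALITY_THRESHOLDS)
    n = grid.n_epochs
    L = grid.epoch_length
    if len(pulses) == 0:
        metrics = {name: 0.0 for name in QUALITY_METRIC_NAMES}
        flags = {name: False for name in QUALITY_METRIC_NAMES}
        return QualityReport(metrics, thresholds, flags, False)

    q = pulses.quality_indices
    if q is None:
        q = np.ones(len(pulses))
    epoch_of_pulse = np.clip((pulses.pulse_times // L).astype(int), 0, n - 1)

    cov = np.zeros(n)
    at, av = ibis.accepted_times(), ibis.accepted_values()
    starts = at - av
    for k in range(n):
        lo, hi = k * L, (k + 1) * L
        sel = (at > lo) & (starts < hi)
        if np.any(sel):
            cov[k] = np.sum(np.minimum(at[sel], hi) - np.maximum(starts[sel], lo))
    cov_pct = 100.0 * cov / L

    means, medians, above, q25, q75 = [], [], [], [], []
    for k in range(n):
        qe = q[epoch_of_pulse == k]
        if len(qe) == 0:
            continue
        means.append(qe.mean())
        medians.append(np.median(qe))
        above.append(100.0 * np.mean(qe > 0.6))
        q25.append(np.percentile(qe, 25))
        q75.append(np.percentile(qe, 75))

    metrics = {
        "ibi_coverage_percent": float(np.mean(cov_pct)),
        "mean_pulse_quality": float(np.mean(means)),
        "median_pulse_quality": float(np.mean(medians)),
        "percent_quality_above_0_6": float(np.mean(above)),
        "q25_pulse_quality": float(np.mean(q25)),
        "q75_pulse_quality": float(np.mean(q75)),
    }
    flags = {name: metrics[name] >= thresholds[name] for name in QUALITY_METRIC_NAMES}
    return QualityReport(metrics, thresholds, flags, all(flags.values()))


def derive_quality_thresholds(reports: Sequence[QualityReport]) -> dict:
    """Per-metric thresholds = 10th percentile of the training recordings'
    per-recording means (linear interpolation between closest ranks)."""
    if len(reports) == 0:
        raise ValueError("cannot derive thresholds from an empty training set")
    if len(reports) < 10:
        import warnings

        warnings.warn(
            f"only {len(reports)} recordings; quality thresholds will be coarse",
            stacklevel=2,
        )
    return {
        name: float(np.percentile([r.metrics[name] for r in reports], 10))
        for name in QUALITY_METRIC_NAMES
    }
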