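"""Beat-level analysis of the wrist rPPG signal.

The chain implemented here: band-pass the raw rPPG, segment it into cardiac
pulses (foot/peak per cycle), score every pulse against a local morphological
template (one-hour blocks), form inter-beat intervals (IBIs) between
good-quality consecutive pulses with an ectopic-pair rejection rule, and build
a surrogate respiratory signal from the pulse-amplitude series, from which
individual breaths (length, amplitude) are delimited.

The ectopic rule: whenever two IBIs that share a pulse have a ratio larger
than 1.5 (in either direction), both are rejected as suspected ectopic beats.
The adjacency requirement (sharing a pulse) makes the filter idempotent:
IBIs that only become neighbours after a rejection are never compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps

PULSE_BAND = (0.4, 8.0)  # Hz, cardiac band for pulse segmentation
IBI_BAND = (0.3, 2.0)  # s, physiological inter-beat-interval band
ECTOPIC_RATIO = 1.5
DEFAULT_QUALITY_THRESHOLD = 0.6
TEMPLATE_BLOCK_S = 3600.0  # non-overlapping one-hour template blocks
TEMPLATE_LEN = 50  # samples per time-normalised pulse
MIN_TEMPLATE_PULSES = 30
RESP_FS = 4.0  # Hz, uniform rate of the interpolated amplitude series
RESP_BAND = (0.1, 0.5)  # Hz, adult respiratory band
MAX_PULSE_GAP_S = 5.0  # amplitude-series samples further than this from a pulse are invalid
BREATH_MIN_EXCURSION_FRAC = 0.10  # of the median pulse amplitude; below is noise

FLAG_ACCEPTED = 0
FLAG_REJECTED_QUALITY = 1
FLAG_REJECTED_ECTOPIC = 2


@dataclass
class PulseSeries:
    """Detected pulses: foot times (s), amplitudes (peak - foot) and quality."""

    pulse_times: np.ndarray
    pulse_amplitudes: np.ndarray
    quality_indices: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        self.pulse_amplitudes = np.asarray(self.pulse_amplitudes, dtype=float)
        if np.any(np.diff(self.pulse_times) <= 0):
            raise ValueError("pulse times must be strictly increasing")
        if np.any(self.pulse_amplitudes < 0):
            raise ValueError("pulse amplitudes must be >= 0")
        if self.quality_indices is not None:
            self.quality_indices = np.asarray(self.quality_indices, dtype=float)
            if np.any((self.quality_indices < 0) | (self.quality_indices > 1)):
                raise ValueError("quality indices must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.pulse_times)


@dataclass
class IBISeries:
    """Inter-beat intervals with per-IBI acceptance flags.

    ``ibi_times`` is the time of the terminating pulse; an IBI spans
    ``[t - ibi, t]``.  Flags: 0 accepted, 1 rejected (quality / out of band),
    2 rejected as suspected ectopic.
    """

    ibi_values: np.ndarray
    ibi_times: np.ndarray
    flags: np.ndarray

    def __post_init__(self) -> None:
        self.ibi_values = np.asarray(self.ibi_values, dtype=float)
        self.ibi_times = np.asarray(self.ibi_times, dtype=float)
        self.flags = np.asarray(self.flags, dtype=int)

    @property
    def accepted(self) -> np.ndarray:
        return self.flags == FLAG_ACCEPTED

    def accepted_values(self) -> np.ndarray:
        return self.ibi_values[self.accepted]

    def accepted_times(self) -> np.ndarray:
        return self.ibi_times[self.accepted]

    def __len__(self) -> int:
        return len(self.ibi_values)


@dataclass
class RespSurrogate:
    """Surrogate respiratory signal and the breaths delimited on it."""

    sample_times: np.ndarray
    amplitude_values: np.ndarray
    valid: np.ndarray
    breath_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    breath_lengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    breath_amplitudes: np.ndarray = field(default_factory=lambda: np.empty(0))

    def n_breaths(self) -> int:
        return len(self.breath_times)


def _bandpass(x: np.ndarray, fs: float, band: tuple[float, float], order: int = 2) -> np.ndarray:
    nyq = fs / 2.0
    hi = min(band[1], nyq * 0.95)
    sos = sps.butter(order, [band[0] / nyq, hi / nyq], btype="band", output="sos")
    return sps.sosfiltfilt(sos, x)


def segment_pulses(rppg: np.ndarray, rate: float) -> PulseSeries:
    """Segment the rPPG waveform into cardiac pulses.

    Peaks are located on the band-passed signal with an amplitude-adaptive
    prominence threshold and a refractory distance of 0.3 s; each pulse foot is
    the trough preceding its peak.  A flat signal yields an empty series.
    """
    if rate < 16:
        raise ValueError("rPPG sampling rate must be >= 16 Hz")
    rppg = np.asarray(rppg, dtype=float)
    if len(rppg) < int(rate):
        return PulseSeries(np.empty(0), np.empty(0), np.empty(0))
    bp = _bandpass(rppg, rate, PULSE_BAND)
    scale = np.percentile(np.abs(bp), 90)
    if scale <= 0:
        return PulseSeries(np.empty(0), np.empty(0), np.empty(0))
    peaks, _ = sps.find_peaks(bp, distance=int(0.3 * rate), prominence=0.3 * scale)
    if len(peaks) < 2:
        return PulseSeries(np.empty(0), np.empty(0), np.empty(0))

    # foot of pulse i: minimum of bp between the previous peak (or a window of
    # one refractory period) and peak i
    feet = np.empty(len(peaks), dtype=int)
    for i, p in enumerate(peaks):
        lo = peaks[i - 1] if i > 0 else max(0, p - int(1.5 * rate))
        lo = max(lo, p - int(1.5 * rate))
        if lo >= p:
            lo = max(0, p - 1)
        feet[i] = lo + int(np.argmin(bp[lo:p])) if p > lo else lo
    amplitudes = bp[peaks] - bp[feet]
    keep = amplitudes > 0
    feet, amplitudes = feet[keep], amplitudes[keep]
    keep2 = np.concatenate([[True], np.diff(feet) > 0])
    feet, amplitudes = feet[keep2], amplitudes[keep2]
    return PulseSeries(feet / rate, amplitudes, None)


def _normalised_segments(
    pulses: PulseSeries, rppg: np.ndarray, rate: float
) -> np.ndarray:
    """Each pulse resampled to TEMPLATE_LEN points, foot-to-next-foot."""
    bp = _bandpass(np.asarray(rppg, dtype=float), rate, PULSE_BAND)
    t = pulses.pulse_times
    n = len(t)
    ends = np.empty(n)
    ends[:-1] = t[1:]
    med_ibi = float(np.median(np.diff(t))) if n > 1 else 1.0
    ends[-1] = min(t[-1] + med_ibi, (len(bp) - 1) / rate)
    out = np.zeros((n, TEMPLATE_LEN))
    grid = np.linspace(0.0, 1.0, TEMPLATE_LEN)
    ramp = grid - grid.mean()
    for i in range(n):
        a, b = int(round(t[i] * rate)), int(round(ends[i] * rate))
        if b - a < 4:
            continue
        seg = bp[a : b + 1]
        res = np.interp(grid, np.linspace(0.0, 1.0, len(seg)), seg)
        # remove the linear baseline so filter-edge ramps do not dominate
        out[i] = res - ramp * (res @ ramp) / (ramp @ ramp)
    return out


def pulse_quality_index(pulses: PulseSeries, rppg: np.ndarray, rate: float) -> np.ndarray:
    """Morphological quality index in [0, 1] per pulse.

    The template of each non-overlapping one-hour block (anchored at the
    recording start) is the point-wise median of the time-normalised pulses it
    contains; the index is the Pearson correlation between a pulse and its
    block template, negatives clipped to 0.  Blocks with fewer than
    ``MIN_TEMPLATE_PULSES`` pulses give all their pulses index 0; recordings
    shorter than one hour fall into a single block.
    """
    if len(pulses) == 0:
        return np.empty(0)
    segs = _normalised_segments(pulses, rppg, rate)
    blocks = np.floor(pulses.pulse_times / TEMPLATE_BLOCK_S).astype(int)
    quality = np.zeros(len(pulses))
    for b in np.unique(blocks):
        idx = np.where(blocks == b)[0]
        if len(idx) < MIN_TEMPLATE_PULSES:
            continue
        template = np.median(segs[idx], axis=0)
        tc = template - template.mean()
        tn = np.linalg.norm(tc)
        if tn == 0:
            continue
        sc = segs[idx] - segs[idx].mean(axis=1, keepdims=True)
        sn = np.linalg.norm(sc, axis=1)
        ok = sn > 0
        r = np.zeros(len(idx))
        r[ok] = (sc[ok] @ tc) / (sn[ok] * tn)
        quality[idx] = np.clip(r, 0.0, 1.0)
    return quality


def analyse_rppg(
    rppg: np.ndarray, rate: float, quality_threshold: float = DEFAULT_QUALITY_THRESHOLD
) -> PulseSeries:
    """Convenience wrapper: segment pulses and attach quality indices."""
    pulses = segment_pulses(rppg, rate)
    if len(pulses) == 0:
        return pulses
    q = pulse_quality_index(pulses, rppg, rate)
    return PulseSeries(pulses.pulse_times, pulses.pulse_amplitudes, q)


def filter_ectopic(
    ibi_values: np.ndarray, ibi_times: np.ndarray, ratio: float = ECTOPIC_RATIO
) -> np.ndarray:
    """Boolean mask of IBIs rejected by the ectopic-pair rule.

    Two IBIs are compared only when they share a pulse, i.e. the start time of
    the later one equals the end time of the earlier one.  Whenever
    ``max(a/b, b/a) > ratio`` both members of the pair are marked rejected.
    """
    ibi_values = np.asarray(ibi_values, dtype=float)
    ibi_times = np.asarray(ibi_times, dtype=float)
    rejected = np.zeros(len(ibi_values), dtype=bool)
    for i in range(1, len(ibi_values)):
        start_i = ibi_times[i] - ibi_values[i]
        if abs(start_i - ibi_times[i - 1]) > 1e-6:
            continue  # not contiguous beats
        a, b = ibi_values[i - 1], ibi_values[i]
        if max(a / b, b / a) > ratio:
            rejected[i - 1] = True
            rejected[i] = True
    return rejected


def extract_ibis(
    pulses: PulseSeries,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
    band: tuple[float, float] = IBI_BAND,
) -> IBISeries:
    """Form the IBI series from good-quality pulses and reject ectopic pairs.

    An IBI is a candidate only when both delimiting pulses have quality at or
    above ``quality_threshold`` and its duration lies in the physiological
    band; candidates failing either test are flagged rejected-quality.  The
    ectopic-pair scan then flags both members of any contiguous accepted pair
    with ratio > 1.5.
    """
    n = len(pulses)
    if n < 2:
        return IBISeries(np.empty(0), np.empty(0), np.empty(0, dtype=int))
    q = pulses.quality_indices
    if q is None:
        q = np.ones(n)
    t = pulses.pulse_times
    values = np.diff(t)
    times = t[1:]
    good = (q[:-1] >= quality_threshold) & (q[1:] >= quality_threshold)
    in_band = (values >= band[0]) & (values <= band[1])
    flags = np.where(good & in_band, FLAG_ACCEPTED, FLAG_REJECTED_QUALITY)

    acc = np.where(flags == FLAG_ACCEPTED)[0]
    ect = filter_ectopic(values[acc], times[acc])
    flags[acc[ect]] = FLAG_REJECTED_ECTOPIC
    return IBISeries(values, times, flags)


def respiratory_surrogate(
    pulses: PulseSeries,
    quality_threshold: float = DEFAULT_QUALITY_THRESHOLD,
    fs: float = RESP_FS,
    band: tuple[float, float] = RESP_BAND,
) -> RespSurrogate:
    """Surrogate respiratory signal from the pulse-amplitude series.

    Amplitudes of good-quality sinus-rhythm pulses (quality >= threshold and
    not delimiting an ectopic-flagged IBI) are interpolated to a uniform
    ``fs`` grid, band-limited to the respiratory band and cut into breaths at
    upward zero crossings.  Per breath: length = cycle duration, amplitude =
    peak-to-trough excursion within the cycle.  Cycles whose span touches a
    pulse gap longer than ``MAX_PULSE_GAP_S`` or whose excursion is below the
    noise floor (1% of the median contributing pulse amplitude) are discarded.
    """
    n = len(pulses)
    q = pulses.quality_indices if pulses.quality_indices is not None else np.ones(n)
    contributing = q >= quality_threshold

    ibis = extract_ibis(pulses, quality_threshold)
    ect = ibis.flags == FLAG_REJECTED_ECTOPIC
    if np.any(ect):
        # IBI i spans pulses i and i+1
        bad = np.zeros(n, dtype=bool)
        idx = np.where(ect)[0]
        bad[idx] = True
        bad[idx + 1] = True
        contributing &= ~bad

    t = pulses.pulse_times[contributing]
    a = pulses.pulse_amplitudes[contributing]
    if len(t) < 2:
        e = np.empty(0)
        return RespSurrogate(e, e, np.empty(0, dtype=bool))

    grid = np.arange(t[0], t[-1], 1.0 / fs)
    amp = np.interp(grid, t, a)
    # samples further than MAX_PULSE_GAP_S from any contributing pulse are invalid
    nearest = np.searchsorted(t, grid)
    nearest = np.clip(nearest, 1, len(t) - 1)
    dist = np.minimum(np.abs(grid - t[nearest - 1]), np.abs(grid - t[nearest]))
    valid = dist <= MAX_PULSE_GAP_S

    if len(grid) < int(4 * fs / band[0]):
        return RespSurrogate(grid, amp, valid)
    filt = _bandpass(amp - amp.mean(), fs, band, order=2)

    # breaths: consecutive upward zero crossings; a cycle counts as a breath
    # only when its excursion clears both an absolute noise floor (a fraction
    # of the median pulse amplitude, rejecting beat-sampling jitter) and a
    # relative one (25% of the median cycle excursion, rejecting filter
    # ringing inside apnoeic gaps)
    sgn = filt >= 0
    up = np.where(~sgn[:-1] & sgn[1:])[0] + 1
    floor = BREATH_MIN_EXCURSION_FRAC * float(np.median(a))
    cycles = []
    for s, e in zip(up[:-1], up[1:]):
        if not np.all(valid[s : e + 1]):
            continue
        length = (e - s) / fs
        if not (1.0 / band[1] <= length <= 2.0 / band[0]):
            continue
        exc = float(filt[s:e].max() - filt[s:e].min())
        cycles.append((s, length, exc))
    rel_floor = 0.25 * float(np.median([c[2] for c in cycles])) if cycles else 0.0
    bt, bl, ba = [], [], []
    for s, length, exc in cycles:
        if exc < floor or exc < rel_floor:
            continue
        bt.append(grid[s])
        bl.append(length)
        ba.append(exc)
    return RespSurrogate(
        grid, filt, valid, np.asarray(bt), np.asarray(bl), np.asarray(ba)
    )
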