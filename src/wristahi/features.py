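"""Per-epoch feature extraction from the beat- and breath-level series.

Every cardiorespiratory feature is computed over a feature-specific window
centred on the centre of each 30-s epoch and associated with that epoch.  A
heart-rate-variability (HRV) feature is undefined for an epoch when accepted
IBIs cover less than half of its window; a respiratory feature is undefined
when fewer than three breaths fall in its window; windows extending past the
recording edges are undefined.  Undefined values never enter the
normalization fit and are zero-filled after normalization, with the
percentage of undefined features per epoch kept as a feature of its own
("coverage") and used downstream to give unreliable epochs zero weight.

The default registry covers a representative subset of the feature families
used in cardiorespiratory sleep monitoring: IBI time statistics, spectral
powers (with 120-s short-window variants), detrended fluctuation analysis,
sample entropy, breath amplitude/length statistics, dominant respiratory
frequency and surrogate variance, accelerometer activity counts, sleep-stage
probabilities and coverage.  Further families can be registered by adding a
``FeatureSpec`` with a callable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats
from sklearn.linear_model import LogisticRegression

from .io_core import EpochGrid, SleepStage, stage_class_index
from .pulse import IBISeries, PulseSeries, RespSurrogate

logger = logging.getLogger("wristahi")

TACHOGRAM_FS = 4.0  # Hz, uniform resampling rate of the IBI tachogram
TUKEY_LADDER = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)
HRV_MIN_COVERAGE = 0.5  # fraction of window accepted IBIs must cover
RESP_MIN_BREATHS = 3
FAMILIES = {
    "time_stats",
    "frequency",
    "dfa",
    "sample_entropy",
    "resp_amplitude",
    "resp_time",
    "resp_frequency",
    "resp_variance",
    "activity",
}

#: HRV feature subset (plus activity counts) feeding the reference sleep stager
STAGE_FEATURE_SUBSET = (
    "hrv_mean_ibi_30",
    "hrv_sdnn_30",
    "hrv_rmssd_30",
    "hrv_lf_hf_120",
    "activity_counts",
)


@dataclass(frozen=True)
class FeatureSpec:
    """One registered feature: its family, window length and data source."""

    name: str
    family: str
    window: float  # seconds, centred on the epoch centre
    source: str  # "ibi" | "resp" | "accel"
    short_variant: bool = False

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown feature family {self.family!r}")
        if self.window <= 0:
            raise ValueError("window must be positive")


def default_registry() -> list[FeatureSpec]:
    F = FeatureSpec
    return [
        F("hrv_mean_ibi", "time_stats", 300, "ibi"),
        F("hrv_sdnn", "time_stats", 300, "ibi"),
        F("hrv_rmssd", "time_stats", 300, "ibi"),
        F("hrv_pnn50", "time_stats", 300, "ibi"),
        F("hrv_mean_ibi_30", "time_stats", 30, "ibi", True),
        F("hrv_sdnn_30", "time_stats", 30, "ibi", True),
        F("hrv_rmssd_30", "time_stats", 30, "ibi", True),
        F("hrv_vlf_power", "frequency", 300, "ibi"),
        F("hrv_lf_power", "frequency", 300, "ibi"),
        F("hrv_hf_power", "frequency", 300, "ibi"),
        F("hrv_lf_hf", "frequency", 300, "ibi"),
        F("hrv_total_power", "frequency", 300, "ibi"),
        F("hrv_peak_freq", "frequency", 300, "ibi"),
        F("hrv_lf_power_120", "frequency", 120, "ibi", True),
        F("hrv_hf_power_120", "frequency", 120, "ibi", True),
        F("hrv_lf_hf_120", "frequency", 120, "ibi", True),
        F("hrv_dfa_alpha1", "dfa", 360, "ibi"),
        F("hrv_dfa_alpha2", "dfa", 360, "ibi"),
        F("hrv_sampen", "sample_entropy", 300, "ibi"),
        F("hrv_sampen_30", "sample_entropy", 30, "ibi", True),
        F("resp_amp_mean", "resp_amplitude", 150, "resp"),
        F("resp_amp_sd", "resp_amplitude", 150, "resp"),
        F("resp_len_mean", "resp_time", 30, "resp"),
        F("resp_len_sd", "resp_time", 30, "resp"),
        F("resp_dom_freq", "resp_frequency", 30, "resp"),
        F("resp_var", "resp_variance", 30, "resp"),
        F("activity_counts", "activity", 30, "accel"),
    ]


@dataclass
class EpochFeatureMatrix:
    """Per-epoch feature values with their defined-mask and context features."""

    values: np.ndarray  # n_epochs x n_features
    defined_mask: np.ndarray  # same shape, bool
    feature_names: list[str]
    stage_probs: Optional[np.ndarray] = None  # n_epochs x 4 (W, N1/N2, N3, REM)
    epoch_weights: Optional[np.ndarray] = None

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def coverage_feature(self) -> np.ndarray:
        """Percentage of undefined features per epoch."""
        return 100.0 * (~self.defined_mask).sum(axis=1) / self.defined_mask.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]


# ---------------------------------------------------------------------------
# scalar feature kernels
# ---------------------------------------------------------------------------


def sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    """Sample entropy with Chebyshev distance and tolerance ``r_frac * sd``."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < m + 2:
        return np.nan
    r = r_frac * np.std(x)
    def count(mm: int) -> int:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(emb[:, None, :] - emb[None, :, :]), axis=-1)
        iu = np.triu_indices(len(emb), k=1)
        return int(np.sum(d[iu] <= r))
    b = count(m)
    a = count(m + 1)
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


def dfa_exponent(x: np.ndarray, scales: Sequence[int]) -> float:
    """Detrended fluctuation analysis scaling exponent over the given box sizes."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    scales = [s for s in scales if n // s >= 2]
    if len(scales) < 3:
        return np.nan
    y = np.cumsum(x - x.mean())
    flucts = []
    for s in scales:
        nb = n // s
        segs = y[: nb * s].reshape(nb, s)
        t = np.arange(s)
        # linear detrend per box via least squares
        tm = t - t.mean()
        beta = segs @ tm / (tm @ tm)
        resid = segs - segs.mean(axis=1, keepdims=True) - beta[:, None] * tm
        flucts.append(np.sqrt(np.mean(resid**2)))
    f = np.asarray(flucts)
    if np.any(f <= 0):
        return np.nan
    slope, _ = np.polyfit(np.log(scales), np.log(f), 1)
    return float(slope)


DFA_SCALES_ALPHA1 = (4, 5, 6, 8, 10, 13, 16)
DFA_SCALES_ALPHA2 = (16, 20, 25, 32, 40, 50, 64)


def band_power(freqs: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    sel = (freqs >= band[0]) & (freqs < band[1])
    if not np.any(sel):
        return np.nan
    return float(np.trapezoid(psd[sel], freqs[sel]))


def _window_psd(seg: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    seg = sps.detrend(seg, type="linear")
    return sps.periodogram(seg, fs=fs, window="hann")


# ---------------------------------------------------------------------------
# per-epoch window machinery
# ---------------------------------------------------------------------------


def _windows(grid: EpochGrid, window: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    centers = grid.centers()
    lo = centers - window / 2.0
    hi = centers + window / 2.0
    inside = (lo >= 0) & (hi <= grid.duration)
    return lo, hi, inside


def _ibi_coverage(ibis: IBISeries, lo: float, hi: float) -> float:
    """Seconds of the window [lo, hi) covered by accepted IBIs."""
    t = ibis.accepted_times()
    v = ibis.accepted_values()
    starts = t - v
    sel = (t > lo) & (starts < hi)
    if not np.any(sel):
        return 0.0
    return float(np.sum(np.minimum(t[sel], hi) - np.maximum(starts[sel], lo)))


def compute_hrv_features(
    ibis: IBISeries, grid: EpochGrid, registry: Sequence[FeatureSpec]
) -> EpochFeatureMatrix:
    """HRV features for every ``source == "ibi"`` spec in the registry.

    A feature value for epoch k is computed on the accepted IBIs whose
    terminating beat falls in the window centred on epoch k; it is undefined
    when accepted IBIs cover less than half of that window (or the window
    leaves the recording).
    """
    specs = [s for s in registry if s.source == "ibi"]
    n = grid.n_epochs
    values = np.full((n, len(specs)), np.nan)
    mask = np.zeros((n, len(specs)), dtype=bool)
    at = ibis.accepted_times()
    av = ibis.accepted_values()

    # uniform tachogram for spectral features, interpolated over accepted IBIs
    if len(at) >= 2:
        tgrid = np.arange(at[0], at[-1], 1.0 / TACHOGRAM_FS)
        tach = np.interp(tgrid, at, av)
    else:
        tgrid = np.empty(0)
        tach = np.empty(0)

    window_cov: dict[float, np.ndarray] = {}
    for j, spec in enumerate(specs):
        lo, hi, inside = _windows(grid, spec.window)
        if spec.window not in window_cov:
            window_cov[spec.window] = np.array(
                [_ibi_coverage(ibis, a, b) for a, b in zip(lo, hi)]
            )
        cov_ok = window_cov[spec.window] / spec.window >= HRV_MIN_COVERAGE
        for k in range(n):
            if not (inside[k] and cov_ok[k]):
                continue
            i0, i1 = np.searchsorted(at, (lo[k], hi[k]))
            seg = av[i0:i1]
            if spec.family == "time_stats":
                if len(seg) < 2:
                    continue
                if spec.name.startswith("hrv_mean_ibi"):
                    values[k, j] = seg.mean()
                elif spec.name.startswith("hrv_sdnn"):
                    values[k, j] = seg.std(ddof=1)
                elif spec.name.startswith("hrv_rmssd"):
                    values[k, j] = float(np.sqrt(np.mean(np.diff(seg) ** 2)))
                elif spec.name.startswith("hrv_pnn50"):
                    values[k, j] = 100.0 * np.mean(np.abs(np.diff(seg)) > 0.05)
            elif spec.family == "frequency":
                g0, g1 = np.searchsorted(tgrid, (lo[k], hi[k]))
                tseg = tach[g0:g1]
                if len(tseg) < TACHOGRAM_FS * spec.window * HRV_MIN_COVERAGE:
                    continue
                freqs, psd = _window_psd(tseg, TACHOGRAM_FS)
                if spec.name.startswith("hrv_vlf"):
                    values[k, j] = band_power(freqs, psd, (0.003, 0.04))
                elif spec.name.startswith("hrv_lf_power"):
                    values[k, j] = band_power(freqs, psd, (0.04, 0.15))
                elif spec.name.startswith("hrv_hf_power"):
                    values[k, j] = band_power(freqs, psd, (0.15, 0.4))
                elif spec.name.startswith("hrv_total"):
                    values[k, j] = band_power(freqs, psd, (0.04, 0.4))
                elif spec.name.startswith("hrv_lf_hf"):
                    lf = band_power(freqs, psd, (0.04, 0.15))
                    hf = band_power(freqs, psd, (0.15, 0.4))
                    values[k, j] = lf / hf if hf > 0 else np.nan
                elif spec.name.startswith("hrv_peak_freq"):
                    sel = (freqs >= 0.04) & (freqs < 0.5)
                    if np.any(sel) and np.any(psd[sel] > 0):
                        values[k, j] = float(freqs[sel][np.argmax(psd[sel])])
            elif spec.family == "dfa":
                scales = (
                    DFA_SCALES_ALPHA1 if spec.name.endswith("alpha1") else DFA_SCALES_ALPHA2
                )
                values[k, j] = dfa_exponent(seg, scales)
            elif spec.family == "sample_entropy":
                values[k, j] = sample_entropy(seg)
        mask[:, j] = np.isfinite(values[:, j])
    values[~mask] = np.nan
    return EpochFeatureMatrix(values, mask, [s.name for s in specs])


def compute_resp_features(
    resp: RespSurrogate, grid: EpochGrid, registry: Sequence[FeatureSpec]
) -> EpochFeatureMatrix:
    """Respiratory features; undefined when fewer than 3 breaths fall in the
    window (or the window leaves the recording)."""
    specs = [s for s in registry if s.source == "resp"]
    n = grid.n_epochs
    values = np.full((n, len(specs)), np.nan)
    mask = np.zeros((n, len(specs)), dtype=bool)
    bt = resp.breath_times
    for j, spec in enumerate(specs):
        lo, hi, inside = _windows(grid, spec.window)
        for k in range(n):
            if not inside[k]:
                continue
            i0, i1 = np.searchsorted(bt, (lo[k], hi[k]))
            if i1 - i0 < RESP_MIN_BREATHS:
                continue
            lens = resp.breath_lengths[i0:i1]
            amps = resp.breath_amplitudes[i0:i1]
            if spec.family == "resp_amplitude":
                values[k, j] = amps.mean() if spec.name.endswith("mean") else amps.std(ddof=1)
            elif spec.family == "resp_time":
                values[k, j] = lens.mean() if spec.name.endswith("mean") else lens.std(ddof=1)
            elif spec.family == "resp_frequency":
                s0, s1 = np.searchsorted(resp.sample_times, (lo[k], hi[k]))
                seg = resp.amplitude_values[s0:s1]
                if len(seg) < 16:
                    continue
                freqs, psd = _window_psd(seg, TACHOGRAM_FS)
                sel = (freqs >= 0.05) & (freqs <= 0.6)
                if np.any(sel) and np.any(psd[sel] > 0):
                    values[k, j] = float(freqs[sel][np.argmax(psd[sel])])
            elif spec.family == "resp_variance":
                s0, s1 = np.searchsorted(resp.sample_times, (lo[k], hi[k]))
                seg = resp.amplitude_values[s0:s1]
                if len(seg) >= 2:
                    values[k, j] = float(np.var(seg, ddof=1))
        mask[:, j] = np.isfinite(values[:, j])
    values[~mask] = np.nan
    return EpochFeatureMatrix(values, mask, [s.name for s in specs])


def activity_counts(accel: np.ndarray, rate: float, grid: EpochGrid) -> np.ndarray:
    """Per-epoch activity counts from the tri-axial accelerometer.

    Each axis is band-passed to the body-movement band, the magnitude of the
    dynamic acceleration is rectified and integrated per epoch.  A constant
    signal (gravity only) gives count 0.
    """
    accel = np.asarray(accel, dtype=float)
    if accel.ndim != 2 or accel.shape[1] != 3:
        raise ValueError("accel must be an n x 3 array")
    nyq = rate / 2.0
    sos = sps.butter(2, [0.5 / nyq, min(11.0, 0.95 * nyq) / nyq], btype="band", output="sos")
    dyn = sps.sosfiltfilt(sos, accel, axis=0)
    mag = np.sqrt(np.sum(dyn**2, axis=1))
    counts = np.zeros(grid.n_epochs)
    spe = int(round(grid.epoch_length * rate))
    for k in range(grid.n_epochs):
        counts[k] = np.sum(mag[k * spe : (k + 1) * spe]) / rate
    return counts


# ---------------------------------------------------------------------------
# sleep-stage probabilities (pluggable; simple multinomial reference stager)
# ---------------------------------------------------------------------------


class StageClassifier:
    """Reference 4-class sleep stager (W, N1/N2, N3, REM).

    Multinomial logistic regression on a declared HRV-feature subset plus
    activity counts; a stand-in for a full cardiorespiratory sleep-staging
    model, adequate for sleep/wake separation on data where wake shows high
    activity and shorter IBIs.  Any object with the same ``predict_proba``
    surface can be plugged in instead.
    """

    def __init__(self, feature_subset: Sequence[str] = STAGE_FEATURE_SUBSET):
        self.feature_subset = list(feature_subset)
        self._clf = LogisticRegression(max_iter=2000, C=1.0)
        self._mu: Optional[np.ndarray] = None
        self._sd: Optional[np.ndarray] = None

    def _design(self, matrix: EpochFeatureMatrix) -> tuple[np.ndarray, np.ndarray]:
        cols = [matrix.feature_names.index(f) for f in self.feature_subset]
        x = matrix.values[:, cols].copy()
        m = matrix.defined_mask[:, cols]
        x[~m] = 0.0
        return x, m.any(axis=1)

    def fit(
        self,
        matrices: Sequence[EpochFeatureMatrix],
        hypnograms: Sequence[Sequence[SleepStage]],
    ) -> "StageClassifier":
        xs, ys = [], []
        for mat, hyp in zip(matrices, hypnograms):
            x, any_defined = self._design(mat)
            y = np.array([stage_class_index(s) for s in hyp])[: mat.n_epochs]
            xs.append(x[any_defined])
            ys.append(y[any_defined])
        x = np.vstack(xs)
        y = np.concatenate(ys)
        self._mu = x.mean(axis=0)
        self._sd = x.std(axis=0)
        self._sd[self._sd == 0] = 1.0
        self._clf.fit((x - self._mu) / self._sd, y)
        return self

    def predict_proba(self, matrix: EpochFeatureMatrix) -> np.ndarray:
        x, any_defined = self._design(matrix)
        probs = np.full((matrix.n_epochs, 4), 0.25)
        if self._mu is None:
            raise RuntimeError("stage classifier is not fitted")
        if np.any(any_defined):
            p = self._clf.predict_proba((x[any_defined] - self._mu) / self._sd)
            full = np.zeros((p.shape[0], 4))
            for i, cls in enumerate(self._clf.classes_):
                full[:, int(cls)] = p[:, i]
            probs[any_defined] = full
        return probs


def sleep_stage_probabilities(
    matrix: EpochFeatureMatrix, classifier: StageClassifier
) -> np.ndarray:
    """Per-epoch (W, N1/N2, N3, REM) probabilities, rows summing to 1.

    Epochs where every feature of the classifier's subset is undefined get
    uniform probabilities.
    """
    probs = classifier.predict_proba(matrix)
    probs = probs / probs.sum(axis=1, keepdims=True)
    return probs


# ---------------------------------------------------------------------------
# normalization (Tukey ladder + z-score, fitted on training data only)
# ---------------------------------------------------------------------------


@dataclass
class NormalizationParams:
    lambdas: np.ndarray  # per-feature Tukey-ladder exponent
    means: np.ndarray
    sds: np.ndarray
    floors: np.ndarray  # positive clamp applied before power/log transforms
    excluded: np.ndarray  # bool per feature: dropped from the model input
    feature_names: list[str]


def _tukey(x: np.ndarray, lam: float, floor: float) -> np.ndarray:
    if lam == 1.0:
        return x
    x = np.maximum(x, floor)
    if lam == 0.0:
        return np.log(x)
    if lam > 0:
        return x**lam
    return -(x**lam)  # negative exponents flip order; minus restores it


def fit_normalization(matrix: EpochFeatureMatrix) -> NormalizationParams:
    """Fit per-feature Tukey-ladder exponents and z-score moments.

    Only defined training values enter the fit.  The ladder exponent is chosen
    from a fixed grid by minimising the absolute skewness of the transformed
    values (ties resolved toward the identity).  Features with fewer than two
    defined values or zero variance after transform are excluded.
    """
    nf = matrix.values.shape[1]
    lambdas = np.ones(nf)
    means = np.zeros(nf)
    sds = np.ones(nf)
    floors = np.full(nf, 1e-12)
    excluded = np.zeros(nf, dtype=bool)
    for j in range(nf):
        vals = matrix.values[matrix.defined_mask[:, j], j]
        if len(vals) < 2 or np.ptp(vals) == 0:
            excluded[j] = True
            continue
        pos = vals[vals > 0]
        floors[j] = float(pos.min()) if len(pos) else 1e-12
        best = (np.inf, np.inf, 1.0)
        for lam in TUKEY_LADDER:
            t = _tukey(vals, lam, floors[j])
            if not np.all(np.isfinite(t)) or np.ptp(t) == 0:
                continue
            score = abs(float(spstats.skew(t)))
            cand = (score, abs(lam - 1.0), lam)
            if cand < best:
                best = cand
        lam = best[2]
        t = _tukey(vals, lam, floors[j])
        sd = float(np.std(t, ddof=1))
        if not np.isfinite(sd) or sd == 0:
            excluded[j] = True
            continue
        lambdas[j] = lam
        means[j] = float(np.mean(t))
        sds[j] = sd
    if np.any(excluded):
        names = [matrix.feature_names[j] for j in np.where(excluded)[0]]
        logger.warning("features excluded from normalization: %s", names)
    return NormalizationParams(
        lambdas, means, sds, floors, excluded, list(matrix.feature_names)
    )


def apply_normalization(
    matrix: EpochFeatureMatrix, params: NormalizationParams
) -> EpochFeatureMatrix:
    """Transform defined entries with the fitted parameters; undefined entries
    (and excluded feature columns) become exactly 0."""
    if list(matrix.feature_names) != params.feature_names:
        raise ValueError("feature columns do not match the fitted parameters")
    out = np.zeros_like(matrix.values)
    mask = matrix.defined_mask.copy()
    for j in range(out.shape[1]):
        if params.excluded[j]:
            mask[:, j] = False
            continue
        m = matrix.defined_mask[:, j]
        if not np.any(m):
            continue
        vals = matrix.values[m, j]
        lam = params.lambdas[j]
        if lam != 1.0 and np.any(vals < params.floors[j]):
            logger.warning(
                "values below transform domain clamped for feature %s",
                matrix.feature_names[j],
            )
        t = _tukey(vals, lam, params.floors[j])
        out[m, j] = (t - params.means[j]) / params.sds[j]
    return EpochFeatureMatrix(
        out,
        mask,
        list(matrix.feature_names),
        stage_probs=matrix.stage_probs,
        epoch_weights=matrix.epoch_weights,
    )


# ---------------------------------------------------------------------------
# movement-based truncation
# ---------------------------------------------------------------------------


def truncate_recording(
    counts: np.ndarray,
    grid: EpochGrid,
    min_run: int = 4,
    percentile: float = 90.0,
    threshold: Optional[float] = None,
) -> tuple[int, int]:
    """Epoch range remaining after trimming prolonged movement at the edges.

    A leading (trailing) run of at least ``min_run`` consecutive epochs with
    activity counts above the threshold -- the recording's ``percentile`` by
    default, or an absolute ``threshold`` when given -- is removed; interior
    movement is untouched.  Returns the half-open epoch range ``(start,
    stop)``; raises when nothing is left.
    """
    counts = np.asarray(counts, dtype=float)
    if len(counts) != grid.n_epochs:
        raise ValueError("counts length must equal the epoch-grid length")
    thresh = np.percentile(counts, percentile) if threshold is None else threshold
    high = counts > thresh
    start, stop = 0, grid.n_epochs
    lead = 0
    while lead < grid.n_epochs and high[lead]:
        lead += 1
    if lead >= min_run:
        start = lead
    trail = 0
    while trail < grid.n_epochs and high[grid.n_epochs - 1 - trail]:
        trail += 1
    if trail >= min_run:
        stop = grid.n_epochs - trail
    if start >= stop:
        raise ValueError("no rest period found after movement truncation")
    return start, stop


# ---------------------------------------------------------------------------
# assembly
# ---------------------------------------------------------------------------


def combine_matrices(parts: Sequence[EpochFeatureMatrix]) -> EpochFeatureMatrix:
    values = np.hstack([p.values for p in parts])
    mask = np.hstack([p.defined_mask for p in parts])
    names = [n for p in parts for n in p.feature_names]
    return EpochFeatureMatrix(values, mask, names)


def build_feature_matrix(
    ibis: IBISeries,
    resp: RespSurrogate,
    counts: np.ndarray,
    grid: EpochGrid,
    registry: Sequence[FeatureSpec] | None = None,
) -> EpochFeatureMatrix:
    """The full per-epoch cardiorespiratory + activity feature matrix."""
    registry = list(registry) if registry is not None else default_registry()
    for spec in registry:
        if spec.family not in FAMILIES:
            raise ValueError(f"unknown feature family {spec.family!r}")
    hrv = compute_hrv_features(ibis, grid, registry)
    rsp = compute_resp_features(resp, grid, registry)
    act = EpochFeatureMatrix(
        counts[:, None], np.ones((grid.n_epochs, 1), dtype=bool), ["activity_counts"]
    )
    return combine_matrices([hrv, rsp, act])


def model_input(matrix: EpochFeatureMatrix) -> np.ndarray:
    """Stack normalized feature values, stage probabilities and coverage into
    the classifier input (undefined entries are already zero)."""
    if matrix.stage_probs is None:
        raise ValueError("stage probabilities missing from the feature matrix")
    cov = matrix.coverage_feature[:, None] / 100.0
    return np.hstack([matrix.values, matrix.stage_probs, cov])
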