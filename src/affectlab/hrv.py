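"""ECG R-peak detection and heart-rate-variability feature extraction.

The feature set comprises 26 values spanning the time domain (mean RR, SDNN,
RMSSD, pNN50, triangular index, TINN), the frequency domain (peak frequency,
absolute and relative power in the VLF/LF/HF bands, normalized units, LF/HF
ratio, total power) and nonlinear dynamics (Poincare SD1/SD2, approximate and
sample entropy, DFA scaling exponents, correlation dimension).

Undefined features (too little data, degenerate input) are reported as NaN
markers, never as silent zeros; callers decide how to impute.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import interpolate, signal, sparse
from scipy.sparse.linalg import spsolve
from scipy.spatial.distance import pdist

__all__ = [
    "RRSeries",
    "DetectionError",
    "HRV_FEATURE_NAMES",
    "detect_r_peaks",
    "detrend_rr",
    "correct_ectopics",
    "hrv_time_features",
    "hrv_freq_features",
    "poincare_features",
    "entropy_features",
    "dfa_features",
    "correlation_dimension",
    "hrv_features",
]

#: Canonical order of the 26 HRV features produced by :func:`hrv_features`.
HRV_FEATURE_NAMES = [
    "mean_rr", "std_rr", "rmssd", "pnn50", "rr_tri_index", "tinn",
    "vlf_peak", "lf_peak", "hf_peak",
    "vlf_pow", "lf_pow", "hf_pow", "total_pow",
    "vlf_pct", "lf_pct", "hf_pct",
    "lf_nu", "hf_nu", "lf_hf",
    "sd1", "sd2", "apen", "sampen", "dfa_a1", "dfa_a2", "d2",
]

VLF_BAND = (0.0, 0.04)
LF_BAND = (0.04, 0.15)
#: HF band as used throughout: 0.12-0.4 Hz (overlaps LF below 0.15 Hz).
HF_BAND = (0.12, 0.40)
#: Conventional alternative available through ``hf_band=HF_BAND_CONVENTIONAL``.
HF_BAND_CONVENTIONAL = (0.15, 0.40)


class DetectionError(RuntimeError):
    """QRS detection failed (flat, too short, or otherwise degenerate ECG)."""


@dataclass
class RRSeries:
    """Beat times (s) and RR intervals (ms) with per-interval quality flags."""

    beat_times: np.ndarray
    intervals: np.ndarray
    corrected_flags: np.ndarray = field(default=None)  # type: ignore[assignment]
    source_fs: float | None = None

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.corrected_flags is None:
            self.corrected_flags = np.zeros(len(self.intervals), dtype=bool)
        else:
            self.corrected_flags = np.asarray(self.corrected_flags, dtype=bool)
        if len(self.beat_times) == 0 and len(self.intervals) == 0:
            pass  # empty series allowed (e.g. a window containing no beats)
        elif len(self.beat_times) != len(self.intervals) + 1:
            raise ValueError("need len(beat_times) == len(intervals) + 1")
        if len(self.intervals) and np.any(self.intervals <= 0):
            raise ValueError("all RR intervals must be positive")
        if len(self.beat_times) > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise ValueError("beat times must be strictly increasing")

    @classmethod
    def from_intervals(cls, intervals_ms, t0: float = 0.0, **kw) -> "RRSeries":
        intervals_ms = np.asarray(intervals_ms, dtype=float)
        beat_times = t0 + np.concatenate(([0.0], np.cumsum(intervals_ms) / 1000.0))
        return cls(beat_times=beat_times, intervals=intervals_ms, **kw)

    def __len__(self) -> int:
        return len(self.intervals)

    @property
    def duration(self) -> float:
        """Span of the series in seconds."""
        if len(self.beat_times) < 2:
            return 0.0
        return float(self.beat_times[-1] - self.beat_times[0])

    def window(self, t_start: float, t_stop: float) -> "RRSeries":
        """Sub-series of beats falling inside ``[t_start, t_stop)``."""
        keep = (self.beat_times >= t_start) & (self.beat_times < t_stop)
        idx = np.flatnonzero(keep)
        if len(idx) < 2:
            return RRSeries(beat_times=self.beat_times[idx][:1],
                            intervals=np.array([]), source_fs=self.source_fs)
        bt = self.beat_times[idx]
        return RRSeries(
            beat_times=bt,
            intervals=np.diff(bt) * 1000.0,
            corrected_flags=self.corrected_flags[idx[0]: idx[-1]],
            source_fs=self.source_fs,
        )


# ---------------------------------------------------------------------------
# QRS detection (Pan-Tompkins)
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: np.ndarray, fs: float) -> RRSeries:
    """Detect R peaks with the Pan-Tompkins cascade and return the RR series.

    Stages: band-pass 5-15 Hz, five-point derivative, squaring, 150 ms
    moving-window integration, adaptive dual thresholds with a 200 ms
    refractory period and RR-based search-back.  Each detection is refined to
    the raw-signal maximum in a +/-75 ms neighbourhood.
    """
    ecg = np.asarray(ecg, dtype=float)
    if fs < 128:
        raise ValueError("sampling rate must be >= 128 Hz")
    if ecg.ndim != 1 or len(ecg) < 10 * fs:
        raise DetectionError(f"need >= 10 s of ECG, got {len(ecg) / fs:.2f} s")
    if np.ptp(ecg) < 1e-9:
        raise DetectionError("flat ECG signal: no QRS complexes detectable")

    sos = signal.butter(2, [5.0, 15.0], btype="band", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, ecg)
    deriv = np.convolve(bp, np.array([1, 2, 0, -2, -1]) * (fs / 8.0), mode="same")
    squared = deriv ** 2
    win = max(int(round(0.150 * fs)), 1)
    mwi = np.convolve(squared, np.ones(win) / win, mode="same")

    refractory = int(round(0.200 * fs))
    peaks, _ = signal.find_peaks(mwi, distance=refractory)
    if len(peaks) == 0:
        raise DetectionError("no candidate peaks in integrated signal")

    # Adaptive thresholding (classic SPKI/NPKI recursion).
    init = mwi[: int(2 * fs)]
    spki = 0.6 * float(np.max(init))
    npki = 0.5 * float(np.mean(init))
    thr1 = npki + 0.25 * (spki - npki)

    qrs: list[int] = []
    noise_peaks: list[int] = []
    rr_hist: list[float] = []
    for p in peaks:
        missed = None
        if qrs and rr_hist:
            rr_avg = float(np.mean(rr_hist[-8:]))
            if (p - qrs[-1]) > 1.66 * rr_avg and noise_peaks:
                # search-back among rejected peaks at the lower threshold
                cand = [q for q in noise_peaks if qrs[-1] + refractory < q < p]
                cand = [q for q in cand if mwi[q] > 0.5 * thr1]
                if cand:
                    missed = max(cand, key=lambda q: mwi[q])
        if missed is not None:
            rr_hist.append(missed - qrs[-1])
            qrs.append(missed)
            spki = 0.25 * mwi[missed] + 0.75 * spki
        if mwi[p] > thr1:
            if qrs:
                rr_hist.append(p - qrs[-1])
            qrs.append(p)
            spki = 0.125 * mwi[p] + 0.875 * spki
        else:
            noise_peaks.append(p)
            npki = 0.125 * mwi[p] + 0.875 * npki
        thr1 = npki + 0.25 * (spki - npki)

    if len(qrs) < 2:
        raise DetectionError("fewer than two QRS complexes detected")

    # Refine to the raw-signal maximum near each integrated-signal peak.
    half = int(round(0.075 * fs))
    refined = []
    for p in qrs:
        lo, hi = max(p - half, 0), min(p + half + 1, len(ecg))
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    refined = np.unique(refined)
    refined = refined[np.concatenate(([True], np.diff(refined) > refractory / 2))]

    beat_times = refined / fs
    return RRSeries(beat_times=beat_times, intervals=np.diff(beat_times) * 1000.0,
                    source_fs=fs)


# ---------------------------------------------------------------------------
# RR conditioning
# ---------------------------------------------------------------------------

def detrend_rr(rr: RRSeries, lam: float = 500.0) -> RRSeries:
    """Remove slow trends with the smoothness-priors method.

    The trend is the ridge fit ``(I + lam^2 D2'D2)^-1 z`` with a
    second-difference penalty; the residual is returned with the original mean
    level restored so that mean-RR information is preserved.
    """
    if lam <= 0:
        raise ValueError("smoothing parameter lambda must be positive")
    z = rr.intervals
    n = len(z)
    if n < 10:
        raise ValueError("need at least 10 intervals to detrend")
    d2 = sparse.diags_array(
        [np.ones(n - 2), -2 * np.ones(n - 2), np.ones(n - 2)],
        offsets=[0, 1, 2], shape=(n - 2, n), format="csc",
    )
    a = sparse.eye_array(n, format="csc") + (lam ** 2) * (d2.T @ d2)
    trend = spsolve(a, z)
    resid = z - trend + float(np.mean(z))
    resid = np.maximum(resid, 1.0)  # intervals must stay positive
    return RRSeries.from_intervals(resid, t0=rr.beat_times[0],
                                   corrected_flags=rr.corrected_flags.copy(),
                                   source_fs=rr.source_fs)


def correct_ectopics(rr: RRSeries, threshold: float = 0.25,
                     window: int = 11) -> RRSeries:
    """Flag intervals deviating from the local median and spline-interpolate.

    An interval is ectopic/artifactual when it deviates from the median of its
    ``window``-beat neighbourhood by more than ``threshold`` (fractional).
    Flagged intervals are replaced by cubic-spline interpolation over the
    clean beats.  >20% flagged raises a warning, >50% an error.
    """
    x = rr.intervals.astype(float).copy()
    n = len(x)
    if n < 5:
        raise ValueError("need at least 5 intervals")
    half = window // 2
    med = np.empty(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        med[i] = np.median(x[lo:hi])
    flags = np.abs(x - med) > threshold * med
    frac = flags.mean()
    if frac > 0.5:
        raise RuntimeError(f"{frac:.0%} of intervals flagged as ectopic; "
                           "series unusable")
    if frac > 0.2:
        warnings.warn(f"{frac:.0%} of intervals flagged as ectopic",
                      RuntimeWarning, stacklevel=2)
    if flags.any():
        good = np.flatnonzero(~flags)
        if len(good) >= 4:
            spl = interpolate.CubicSpline(good, x[good])
        else:
            spl = interpolate.interp1d(good, x[good], fill_value="extrapolate")
        x[flags] = spl(np.flatnonzero(flags))
        x = np.maximum(x, 1.0)
    return RRSeries.from_intervals(x, t0=rr.beat_times[0],
                                   corrected_flags=flags,
                                   source_fs=rr.source_fs)


# ---------------------------------------------------------------------------
# Time domain
# ---------------------------------------------------------------------------

_TRI_BIN_MS = 1000.0 / 128.0  # histogram bin width 1/128 s


def hrv_time_features(rr: RRSeries) -> dict[str, float]:
    """Mean RR, SDNN, RMSSD, NN50/pNN50, triangular index and TINN."""
    x = rr.intervals
    out = {k: np.nan for k in
           ("mean_rr", "std_rr", "rmssd", "nn50", "pnn50",
            "rr_tri_index", "tinn")}
    if len(x) == 0:
        return out
    out["mean_rr"] = float(np.mean(x))
    if len(x) < 2:
        return out
    out["std_rr"] = float(np.std(x, ddof=1))
    d = np.diff(x)
    out["rmssd"] = float(np.sqrt(np.mean(d ** 2)))
    out["nn50"] = float(np.sum(np.abs(d) > 50.0))
    out["pnn50"] = float(out["nn50"] / len(d) * 100.0)

    lo = np.floor(x.min() / _TRI_BIN_MS) * _TRI_BIN_MS
    hi = np.ceil(x.max() / _TRI_BIN_MS) * _TRI_BIN_MS
    nbins = max(int(round((hi - lo) / _TRI_BIN_MS)), 1)
    counts, edges = np.histogram(x, bins=nbins, range=(lo, lo + nbins * _TRI_BIN_MS))
    out["rr_tri_index"] = float(len(x) / counts.max())
    out["tinn"] = _tinn(counts, edges)
    return out


def _tinn(counts: np.ndarray, edges: np.ndarray) -> float:
    """Baseline width (ms) of the least-squares triangle fit to the histogram."""
    centers = 0.5 * (edges[:-1] + edges[1:])
    k = int(np.argmax(counts))
    y_peak = counts[k]
    if len(counts) < 3:
        return float(edges[-1] - edges[0])
    best = (np.inf, edges[0], edges[-1])
    left_cands = range(0, k + 1)
    right_cands = range(k, len(counts))
    for li in left_cands:
        n_ms = edges[li]
        for ri in right_cands:
            m_ms = edges[ri + 1]
            q = np.zeros_like(counts, dtype=float)
            rising = (centers > n_ms) & (centers <= centers[k])
            if centers[k] > n_ms:
                q[rising] = y_peak * (centers[rising] - n_ms) / (centers[k] - n_ms)
            falling = (centers > centers[k]) & (centers < m_ms)
            if m_ms > centers[k]:
                q[falling] = y_peak * (m_ms - centers[falling]) / (m_ms - centers[k])
            err = float(np.sum((counts - q) ** 2))
            if err < best[0]:
                best = (err, n_ms, m_ms)
    return float(best[2] - best[1])


# ---------------------------------------------------------------------------
# Frequency domain
# ---------------------------------------------------------------------------

def hrv_freq_features(rr: RRSeries, resample_fs: float = 4.0,
                      hf_band: tuple[float, float] = HF_BAND,
                      welch_window_s: float = 150.0) -> dict[str, float]:
    """Spectral HRV features from the cubic-resampled tachogram.

    The tachogram is interpolated to ``resample_fs`` (4 Hz), mean-subtracted
    and analysed with Welch's method (150 s Hann segments or the full length
    if shorter, 50% overlap).  Normalized units use the total power minus VLF
    as denominator; total power is the sum of the three band powers.
    """
    keys = ("vlf_peak", "lf_peak", "hf_peak", "vlf_pow", "lf_pow", "hf_pow",
            "total_pow", "vlf_pct", "lf_pct", "hf_pct", "lf_nu", "hf_nu",
            "lf_hf")
    out = {k: np.nan for k in keys}
    if rr.duration < 60.0 or len(rr) < 4:
        return out
    t = rr.beat_times[1:]
    spl = interpolate.CubicSpline(t, rr.intervals)
    tt = np.arange(t[0], t[-1], 1.0 / resample_fs)
    y = spl(tt)
    y = y - np.mean(y)
    nperseg = min(int(round(welch_window_s * resample_fs)), len(y))
    f, psd = signal.welch(y, fs=resample_fs, window="hann", nperseg=nperseg,
                          noverlap=nperseg // 2, detrend=False)

    bands = {"vlf": VLF_BAND, "lf": LF_BAND, "hf": hf_band}
    for name, (lo, hi) in bands.items():
        mask = (f >= lo) & (f < hi)
        if not mask.any():
            continue
        out[f"{name}_pow"] = float(np.trapezoid(psd[mask], f[mask]))
        out[f"{name}_peak"] = float(f[mask][np.argmax(psd[mask])])
    total = out["vlf_pow"] + out["lf_pow"] + out["hf_pow"]
    out["total_pow"] = total
    if total > 0:
        for name in bands:
            out[f"{name}_pct"] = out[f"{name}_pow"] / total * 100.0
        denom = total - out["vlf_pow"]
        if denom > 0:
            out["lf_nu"] = out["lf_pow"] / denom * 100.0
            out["hf_nu"] = out["hf_pow"] / denom * 100.0
    if out["hf_pow"] > 0:
        out["lf_hf"] = out["lf_pow"] / out["hf_pow"]
    return out


# ---------------------------------------------------------------------------
# Nonlinear
# ---------------------------------------------------------------------------

def poincare_features(rr: RRSeries) -> dict[str, float]:
    """Poincare-plot descriptors.

    SD1 is computed as RMSSD/sqrt(2) (exact identity by construction); SD2 as
    sqrt(2 var(RR) - SD1^2), floored at 0, with the population variance.
    """
    x = rr.intervals
    if len(x) < 3:
        return {"sd1": np.nan, "sd2": np.nan}
    d = np.diff(x)
    sd1 = float(np.sqrt(np.mean(d ** 2) / 2.0))
    sd2_sq = 2.0 * float(np.var(x)) - sd1 ** 2
    return {"sd1": sd1, "sd2": float(np.sqrt(max(sd2_sq, 0.0)))}


def _embed(x: np.ndarray, m: int, delay: int = 1) -> np.ndarray:
    n = len(x) - (m - 1) * delay
    return np.lib.stride_tricks.sliding_window_view(x, (m - 1) * delay + 1)[:n, ::delay]


def entropy_features(rr: RRSeries, m: int = 2, r: float = 0.2) -> dict[str, float]:
    """Approximate and sample entropy by direct template counting.

    Tolerance is ``r`` times the series SD; Chebyshev distance. Both are NaN
    for constant series (degenerate tolerance) or fewer than 100 intervals.
    """
    x = rr.intervals
    out = {"apen": np.nan, "sampen": np.nan}
    if len(x) < 100:
        return out
    sd = float(np.std(x))
    if sd == 0:
        return out
    tol = r * sd

    def _counts(mm: int, with_self: bool) -> np.ndarray:
        xm = _embed(x, mm)
        d = np.max(np.abs(xm[:, None, :] - xm[None, :, :]), axis=-1)
        within = d <= tol
        if not with_self:
            np.fill_diagonal(within, False)
        return within.sum(axis=1).astype(float)

    # ApEn: self-matches included, log of per-template fraction.
    n = len(x)
    phi = []
    for mm in (m, m + 1):
        c = _counts(mm, with_self=True) / (n - mm + 1)
        phi.append(np.mean(np.log(c)))
    out["apen"] = float(phi[0] - phi[1])

    # SampEn: self-matches excluded, templates truncated to equal count.
    xm = _embed(x, m)[: n - m]
    d = np.max(np.abs(xm[:, None, :] - xm[None, :, :]), axis=-1)
    b = (d <= tol).sum() - len(xm)
    xm1 = _embed(x, m + 1)
    d1 = np.max(np.abs(xm1[:, None, :] - xm1[None, :, :]), axis=-1)
    a = (d1 <= tol).sum() - len(xm1)
    if a > 0 and b > 0:
        out["sampen"] = float(-np.log(a / b))
    return out


def dfa_features(rr: RRSeries) -> dict[str, float]:
    """Detrended fluctuation analysis exponents alpha1 (4-16) and alpha2 (16-64)."""
    x = rr.intervals
    out = {"dfa_a1": np.nan, "dfa_a2": np.nan}
    n = len(x)
    if n < 32 or np.std(x) == 0:
        return out
    y = np.cumsum(x - np.mean(x))

    def _fluct(box: int) -> float:
        k = n // box
        segs = y[: k * box].reshape(k, box)
        t = np.arange(box)
        tm = t - t.mean()
        denom = float(np.sum(tm ** 2))
        slopes = segs @ tm / denom
        fits = segs.mean(axis=1)[:, None] + slopes[:, None] * tm[None, :]
        return float(np.sqrt(np.mean((segs - fits) ** 2)))

    def _alpha(lo: int, hi: int) -> float:
        boxes = np.array([b for b in range(lo, hi + 1) if n // b >= 2])
        if len(boxes) < 3:
            return np.nan
        fl = np.array([_fluct(b) for b in boxes])
        ok = fl > 0
        if ok.sum() < 3:
            return np.nan
        return float(np.polyfit(np.log(boxes[ok]), np.log(fl[ok]), 1)[0])

    out["dfa_a1"] = _alpha(4, 16)
    if n >= 130:
        out["dfa_a2"] = _alpha(16, 64)
    return out


def correlation_dimension(rr: RRSeries, m: int = 10) -> float:
    """Grassberger-Procaccia correlation-dimension estimate (embedding ``m``).

    Correlation sums over log-spaced radii between the 5th and 50th
    percentiles of pairwise embedding distances; D2 is the log-log slope.
    """
    x = rr.intervals
    if len(x) < 200 or np.std(x) == 0:
        return np.nan
    emb = _embed(x, m)
    if len(emb) > 600:  # cap pair count; deterministic decimation
        emb = emb[np.linspace(0, len(emb) - 1, 600).astype(int)]
    d = pdist(emb)
    d = d[d > 0]
    if len(d) < 100:
        return np.nan
    r_lo, r_hi = np.percentile(d, [5, 50])
    if r_lo <= 0 or r_hi <= r_lo:
        return np.nan
    radii = np.geomspace(r_lo, r_hi, 16)
    c = np.array([np.mean(d < r) for r in radii])
    ok = c > 0
    if ok.sum() < 4:
        return np.nan
    return float(np.polyfit(np.log(radii[ok]), np.log(c[ok]), 1)[0])


# ---------------------------------------------------------------------------
# Full feature vector
# ---------------------------------------------------------------------------

def hrv_features(rr: RRSeries, lam: float = 500.0,
                 hf_band: tuple[float, float] = HF_BAND,
                 entropy_m: int = 2, entropy_r: float = 0.2,
                 d2_m: int = 10) -> dict[str, float]:
    """Compute the full 26-feature HRV vector for one (corrected) RR series.

    Time-domain features use the corrected intervals as-is; frequency and
    nonlinear features operate on the smoothness-priors-detrended series
    (trend removal would otherwise distort mean-level information).
    """
    out: dict[str, float] = {}
    time_f = hrv_time_features(rr)
    time_f.pop("nn50", None)
    out.update(time_f)

    try:
        det = detrend_rr(rr, lam=lam) if len(rr) >= 10 else rr
    except ValueError:
        det = rr
    out.update(hrv_freq_features(det, hf_band=hf_band))
    out.update(poincare_features(det))
    out.update(entropy_features(det, m=entropy_m, r=entropy_r))
    out.update(dfa_features(det))
    out["d2"] = correlation_dimension(det, m=d2_m)
    return {k: out.get(k, np.nan) for k in HRV_FEATURE_NAMES}
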