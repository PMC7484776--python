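"""Heart-rate-variability analysis: ECG to the seven autonomic indices.

The chain mirrors standard short-term HRV practice: band-pass the raw ECG
(0.05-40 Hz, zero phase), detect R peaks (derivative-square-integrate with
an adaptive threshold and a 0.2 s refractory period), form the RR-interval
series, resample it evenly at 4 Hz by cubic spline, and average
Blackman-windowed 256-point periodograms.  Spectral indices are the LF
(0.045-0.15 Hz, sympathetic-dominated) and HF (0.15-0.4 Hz,
parasympathetic) band powers and their normalized fractions of LF+HF.

Two further indices come from a principal-dynamic-mode (PDM)
decomposition: a Volterra-Laguerre model of the interval dynamics is
estimated, its kernel matrix eigendecomposed, and the principal modes are
classified as sympathetic or parasympathetic by their dominant frequency;
each index is the power of the series projected through the corresponding
mode set.
"""
from __future__ import annotations

import warnings

import numpy as np
from scipy import signal
from scipy.interpolate import CubicSpline

from .datatypes import ECGRecord, HRVIndices, InvalidInputError, RRSeries

__all__ = [
    "bandpass_ecg",
    "detect_r_peaks",
    "select_clean_window",
    "build_rr",
    "mean_heart_rate",
    "hrv_spectrum",
    "band_powers",
    "pdm_indices",
    "hrv_indices",
    "LF_BAND",
    "HF_BAND",
]

LF_BAND = (0.045, 0.15)
HF_BAND = (0.15, 0.4)

REFRACTORY_S = 0.2


def bandpass_ecg(ecg: ECGRecord, low: float = 0.05, high: float = 40.0) -> ECGRecord:
    """Zero-phase Butterworth band-pass to remove drift and EMG noise."""
    if not 0 < low < high < ecg.fs / 2:
        raise InvalidInputError("band must satisfy 0 < low < high < fs/2")
    sos = signal.butter(4, [low, high], btype="bandpass", fs=ecg.fs, output="sos")
    # the 0.05 Hz corner has a multi-second transient: pad generously
    padlen = min(ecg.samples.size - 1, int(round(3.0 * ecg.fs / low)))
    filtered = signal.sosfiltfilt(sos, ecg.samples, padlen=padlen)
    return ECGRecord(samples=filtered, fs=ecg.fs, truth_beat_times=ecg.truth_beat_times)


def detect_r_peaks(ecg: ECGRecord) -> np.ndarray:
    """R-peak times from a (filtered) ECG.

    Derivative -> squaring -> 150 ms moving-window integration, then peak
    picking on the integrated energy with an adaptive threshold and a
    0.2 s refractory period; each detection is refined to the local
    maximum of the ECG itself, so timing is sample-accurate.  Detection is
    invariant to overall amplitude scaling.
    """
    x = ecg.samples
    fs = ecg.fs
    deriv = np.gradient(x)
    energy = deriv * deriv
    win = max(int(round(0.15 * fs)), 1)
    integrated = np.convolve(energy, np.ones(win) / win, mode="same")

    threshold = 0.3 * np.quantile(integrated, 0.99)
    if threshold <= 0:
        warnings.warn("flat signal: no beats found", stacklevel=2)
        return np.array([])
    distance = max(int(round(REFRACTORY_S * fs)), 1)
    # zero-pad so maxima at the record edges are still treated as peaks
    padded = np.concatenate([[0.0], integrated, [0.0]])
    peaks, _ = signal.find_peaks(padded, height=threshold, distance=distance)
    peaks = peaks - 1
    if peaks.size == 0:
        warnings.warn("no beats found above the adaptive threshold", stacklevel=2)
        return np.array([])

    # refine each energy peak to the nearest ECG maximum (the R wave)
    half = max(int(round(0.08 * fs)), 1)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, x.size)
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    # re-apply refractory after refinement
    out = [refined[0]]
    for r in refined[1:]:
        if r - out[-1] >= distance:
            out.append(r)
    return np.asarray(out) / fs


def select_clean_window(beat_times: np.ndarray, duration: float = 240.0) -> np.ndarray:
    """Pick the ``duration``-long stretch of beats with fewest anomalies.

    An anomaly is an interval outside [0.3, 2.0] s or one differing from
    its predecessor by more than 30%.  Windows are scanned at 1 s steps;
    earliest window wins ties.  If the recording is not longer than
    ``duration``, all beats are returned.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 2 or beat_times[-1] - beat_times[0] <= duration:
        return beat_times
    iv = np.diff(beat_times)
    bad = (iv < 0.3) | (iv > 2.0)
    rel = np.abs(np.diff(iv)) / iv[:-1]
    bad[1:] |= rel > 0.3
    starts = np.arange(beat_times[0], beat_times[-1] - duration + 1e-9, 1.0)
    best_start, best_count = starts[0], np.inf
    for s in starts:
        mask = (beat_times[1:] >= s) & (beat_times[1:] <= s + duration)
        count = int(bad[mask].sum())
        if count < best_count:
            best_start, best_count = s, count
    keep = np.flatnonzero(
        (beat_times >= best_start) & (beat_times <= best_start + duration)
    )
    # widen by one beat each side so the kept span covers >= duration
    lo = max(keep[0] - 1, 0)
    hi = min(keep[-1] + 1, beat_times.size - 1)
    return beat_times[lo : hi + 1]


def build_rr(beat_times: np.ndarray, resample_fs: float = 4.0) -> RRSeries:
    """RR series with cubic-spline resampling onto a uniform grid.

    Intervals are anchored at the time of the beat that closes them; the
    grid spans [first beat, last beat] at ``resample_fs``.
    """
    beat_times = np.asarray(beat_times, dtype=float)
    if beat_times.size < 4:
        raise InvalidInputError("need >= 4 beats for cubic-spline resampling")
    if np.any(np.diff(beat_times) <= 0):
        raise InvalidInputError("beat times must be strictly increasing")
    intervals = np.diff(beat_times)
    spline = CubicSpline(beat_times[1:], intervals)
    span = beat_times[-1] - beat_times[0]
    n = int(np.floor(span * resample_fs)) + 1
    grid = beat_times[0] + np.arange(n) / resample_fs
    return RRSeries(
        beat_times=beat_times,
        intervals=intervals,
        resampled=spline(grid),
        resample_fs=resample_fs,
    )


def mean_heart_rate(rr: RRSeries) -> float:
    """Mean heart rate in beats/min: 60 / mean RR interval."""
    return 60.0 / float(np.mean(rr.intervals))


def hrv_spectrum(rr: RRSeries, nperseg: int = 256) -> tuple[np.ndarray, np.ndarray]:
    """Averaged Blackman-windowed power spectral density of the RR series.

    The mean-subtracted resampled series is split into ``nperseg``-sample
    segments with 50% overlap; each is Blackman-windowed and its
    periodogram normalized by the window power; segment spectra are
    averaged (Welch).  Returns (frequencies Hz, PSD s^2/Hz).
    """
    x = rr.resampled
    if x.size < nperseg:
        need = nperseg / rr.resample_fs
        raise InvalidInputError(
            f"resampled series has {x.size} samples; >= {nperseg} "
            f"({need:.0f} s at {rr.resample_fs:g} Hz) required"
        )
    x = x - np.mean(x)
    freqs, psd = signal.welch(
        x,
        fs=rr.resample_fs,
        window="blackman",
        nperseg=nperseg,
        noverlap=nperseg // 2,
        detrend=False,
        scaling="density",
    )
    return freqs, psd


def band_powers(freqs: np.ndarray, psd: np.ndarray) -> tuple[float, float, float, float]:
    """(lf, hf, nlf, nhf): band integrals of the PSD and their fractions.

    LF integrates [0.045, 0.15) Hz, HF [0.15, 0.4] Hz; normalized indices
    are fractions of LF+HF, so they sum to one.
    """
    freqs = np.asarray(freqs, dtype=float)
    psd = np.asarray(psd, dtype=float)
    if freqs[-1] < 0.4:
        raise InvalidInputError("psd must cover frequencies up to 0.4 Hz")
    df = freqs[1] - freqs[0]
    lf_mask = (freqs >= LF_BAND[0]) & (freqs < LF_BAND[1])
    hf_mask = (freqs >= HF_BAND[0]) & (freqs <= HF_BAND[1])
    lf = float(np.sum(psd[lf_mask]) * df)
    hf = float(np.sum(psd[hf_mask]) * df)
    total = lf + hf
    if total <= 0:
        raise InvalidInputError("zero LF+HF power: normalized indices undefined")
    return lf, hf, lf / total, hf / total


# ---------------------------------------------------------------------------
# Principal dynamic modes


def _laguerre_basis(n_funcs: int, alpha: float, memory: int) -> np.ndarray:
    """Discrete orthonormal Laguerre functions, shape (n_funcs, memory)."""
    basis = np.zeros((n_funcs, memory))
    sq = np.sqrt(alpha)
    root = np.sqrt(1.0 - alpha)
    basis[0, 0] = root
    for m in range(1, memory):
        basis[0, m] = sq * basis[0, m - 1]
    for j in range(1, n_funcs):
        basis[j, 0] = sq * basis[j - 1, 0]
        for m in range(1, memory):
            basis[j, m] = sq * basis[j, m - 1] + sq * basis[j - 1, m] - basis[j - 1, m - 1]
    return basis


def _dominant_frequency(x: np.ndarray, fs: float, nfft: int = 4096) -> float:
    """Frequency of the periodogram peak of ``x`` (mean removed)."""
    x = x - np.mean(x)
    spec = np.abs(np.fft.rfft(x, max(nfft, x.size))) ** 2
    freqs = np.fft.rfftfreq(max(nfft, x.size), d=1.0 / fs)
    return float(freqs[np.argmax(spec)])


def pdm_indices(
    rr: RRSeries,
    *,
    n_laguerre: int = 8,
    laguerre_alpha: float = 0.5,
    memory_s: float = 16.0,
    n_modes_per_branch: int = 3,
) -> tuple[float, float]:
    """Sympathetic / parasympathetic principal-dynamic-mode indices.

    A Volterra model of the mean-subtracted resampled interval series is
    estimated on an orthonormal Laguerre basis (first-order kernel plus
    second-order self terms).  The symmetric kernel matrix in Laguerre
    coordinates is eigendecomposed; each principal mode is an impulse
    response in lag space, and the component it extracts from the series
    (the mode-filtered output) determines its branch by dominant
    frequency — LF band -> sympathetic, HF band -> parasympathetic.  Up
    to ``n_modes_per_branch`` modes per branch, ranked by |eigenvalue|,
    are retained.  Each index is the eigenvalue-weighted output power of
    the series filtered through its branch's modes; both are >= 0.
    """
    if rr.duration < 240:
        raise InvalidInputError("PDM indices require >= 240 s of beats")
    fs = rr.resample_fs
    x = rr.resampled - np.mean(rr.resampled)
    memory = int(round(memory_s * fs))
    basis = _laguerre_basis(n_laguerre, laguerre_alpha, memory)

    # Laguerre convolutions of the strictly-past series (one-step-ahead
    # autoregressive Volterra model: lag 0 excluded so the kernel cannot
    # collapse onto the identity)
    past = np.concatenate([[0.0], x[:-1]])
    v = np.empty((n_laguerre, x.size))
    for j in range(n_laguerre):
        v[j] = signal.lfilter(basis[j], [1.0], past)
    v = v[:, memory:]  # drop the filter warm-up
    y = x[memory:]

    # least squares: y(t) ~ c0 + sum_j c_j v_j + sum_j c_jj v_j^2
    design = np.vstack([np.ones_like(y), v, v * v]).T
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    c1 = coef[1 : 1 + n_laguerre]
    c2 = coef[1 + n_laguerre :]

    # symmetric kernel matrix in (constant + Laguerre) coordinates
    q = np.zeros((n_laguerre + 1, n_laguerre + 1))
    q[0, 1:] = q[1:, 0] = c1 / 2.0
    q[np.arange(1, n_laguerre + 1), np.arange(1, n_laguerre + 1)] = c2
    eigval, eigvec = np.linalg.eigh(q)
    if np.max(np.abs(eigval)) <= 0 or not np.all(np.isfinite(eigval)):
        raise InvalidInputError("rank-deficient kernel matrix: degenerate dynamics")

    order = np.argsort(np.abs(eigval))[::-1]
    branch_powers = {"symp": [], "para": []}
    for idx in order:
        mode = eigvec[1:, idx] @ basis  # impulse response in lag space
        if np.allclose(mode, 0):
            continue
        out = signal.lfilter(mode, [1.0], x)[memory:]
        fdom = _dominant_frequency(out, fs)
        if LF_BAND[0] <= fdom < LF_BAND[1]:
            branch = "symp"
        elif HF_BAND[0] <= fdom <= HF_BAND[1]:
            branch = "para"
        else:
            continue
        if len(branch_powers[branch]) >= n_modes_per_branch:
            continue
        branch_powers[branch].append(abs(eigval[idx]) * float(np.mean(out * out)))
    pdmi_symp = float(np.sum(branch_powers["symp"]))
    pdmi_para = float(np.sum(branch_powers["para"]))
    return pdmi_symp, pdmi_para


def hrv_indices(rr: RRSeries) -> HRVIndices:
    """All seven HRV parameters from one beat-interval series."""
    freqs, psd = hrv_spectrum(rr)
    lf, hf, nlf, nhf = band_powers(freqs, psd)
    pdmi_symp, pdmi_para = pdm_indices(rr)
    return HRVIndices(
        lf=lf,
        hf=hf,
        nlf=nlf,
        nhf=nhf,
        pdmi_symp=pdmi_symp,
        pdmi_para=pdmi_para,
        mean_hr=mean_heart_rate(rr),
    )


def ecg_to_rr(ecg: ECGRecord, *, window_s: float = 240.0, resample_fs: float = 4.0) -> RRSeries:
    """Full front end: filter, detect beats, select a clean window, resample."""
    filtered = bandpass_ecg(ecg)
    beats = detect_r_peaks(filtered)
    beats = select_clean_window(beats, duration=window_s)
    return build_rr(beats, resample_fs=resample_fs)
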