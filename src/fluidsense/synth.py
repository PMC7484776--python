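"""Synthetic generators for every input the pipeline consumes.

Three generators with known ground truth make the full analysis testable
without clinical recordings:

* ``gen_spectrum`` — Cole arcs at the 16 study frequencies (10-999 kHz)
  with additive complex Gaussian noise;
* ``gen_rr`` / ``gen_ecg`` — beat-interval series with controllable
  sympathetic-band (~0.1 Hz) and parasympathetic-band (~0.25 Hz)
  sinusoidal modulation, and an ECG built by placing a stereotyped QRS
  template at those beat times;
* ``gen_cohort`` — per-recording 15-feature tables drawn from per-group
  means/SDs, defaulting to the published cohort values, with an option to
  give a subset of subjects a recording in two groups.

All generators are deterministic under a fixed seed.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cole import cole_impedance
from .datatypes import (
    FEATURE_NAMES,
    CohortDataset,
    ECGRecord,
    ImpedanceSpectrum,
    InvalidInputError,
)

__all__ = [
    "SpectrumSpec",
    "RRSpec",
    "GroupSpec",
    "gen_spectrum",
    "gen_rr",
    "gen_ecg",
    "gen_cohort",
    "default_frequencies",
    "default_group_specs",
    "COHORT_REFERENCE",
]

#: Published per-group feature means and SDs (rows in canonical feature
#: order) used as default generative parameters, with group sizes
#: control n=32, baseline n=23, discharge n=17.
COHORT_REFERENCE: dict[str, dict] = {
    "control": {
        "n": 32,
        "means": [38.1, 52.0, 4.08e-8, 0.609, 6.11e-4, 334.0, 21.5, 16.6,
                  3.5, 7.4, 0.225, 0.255, 11.8, 13.2, 72.3],
        "sds": [10.8, 17.0, 2.96e-8, 0.0881, 3.45e-4, 669.0, 6.0, 6.1,
                4.2, 14.4, 0.134, 0.154, 5.52, 5.47, 11.9],
    },
    "baseline": {
        "n": 23,
        "means": [26.5, 52.0, 4.60e-8, 0.716, 5.34e-4, 232.0, 17.0, 9.54,
                  19.3, 32.9, 0.178, 0.391, 17.2, 17.1, 74.1],
        "sds": [12.8, 24.7, 1.71e-8, 0.121, 1.51e-4, 389.0, 7.5, 6.0,
                43.4, 55.7, 0.092, 0.134, 12.4, 10.4, 18.0],
    },
    "discharge": {
        "n": 17,
        "means": [34.2, 54.3, 4.42e-8, 0.646, 5.07e-4, 347.0, 20.3, 13.9,
                  19.2, 34.6, 0.127, 0.371, 15.3, 17.9, 74.7],
        "sds": [17.4, 23.3, 1.85e-8, 0.144, 1.72e-4, 374.0, 9.1, 8.8,
                51.3, 57.0, 0.085, 0.129, 5.98, 7.56, 15.9],
    },
}

#: Number of baseline subjects who also have a discharge recording.
DEFAULT_DUAL_MEMBERSHIP = 12


def default_frequencies(n: int = 16, f_lo: float = 10e3, f_hi: float = 999e3) -> np.ndarray:
    """The measurement grid: 16 log-spaced frequencies, 10 kHz to 999 kHz."""
    return np.geomspace(f_lo, f_hi, n)


@dataclass(frozen=True)
class SpectrumSpec:
    """Generative parameters for one Cole arc."""

    r0: float = 38.1
    r_inf: float = 21.5
    alpha: float = 0.609
    fc: float = 4.5e4
    noise_sd: float = 0.2  # Ohm, per real/imag component
    frequencies: np.ndarray = field(default_factory=default_frequencies)
    seed: int = 0

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        object.__setattr__(self, "frequencies", f)
        if not 0 < self.r_inf < self.r0:
            raise InvalidInputError("requires 0 < r_inf < r0")
        if not 0 < self.alpha <= 1:
            raise InvalidInputError("alpha must lie in (0, 1]")
        if not self.fc > 0:
            raise InvalidInputError("fc must be > 0")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise InvalidInputError("frequencies must be > 0 and strictly increasing")


@dataclass(frozen=True)
class RRSpec:
    """Sinusoidally modulated beat-interval process.

    RR_k = mean_rr + a_lf*sin(2*pi*f_lf*t_k) + a_hf*sin(2*pi*f_hf*t_k) + eps_k,
    with t_k the cumulative beat time and eps_k ~ N(0, noise_sd^2).
    """

    mean_rr: float = 0.83  # ~72 beats/min, the cohort's mean heart rate
    a_lf: float = 0.03
    f_lf: float = 0.1
    a_hf: float = 0.03
    f_hf: float = 0.25
    noise_sd: float = 0.005
    duration: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.mean_rr > 0:
            raise InvalidInputError("mean_rr must be > 0")
        if self.a_lf < 0 or self.a_hf < 0:
            raise InvalidInputError("modulation amplitudes must be >= 0")
        if not 0.045 <= self.f_lf < 0.15:
            raise InvalidInputError("f_lf must lie in the LF band [0.045, 0.15)")
        if not 0.15 <= self.f_hf <= 0.4:
            raise InvalidInputError("f_hf must lie in the HF band [0.15, 0.4]")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be >= 0")
        if self.duration < 2 * self.mean_rr:
            raise InvalidInputError("duration too short for >= 2 beats")


@dataclass(frozen=True)
class GroupSpec:
    """One cohort group: label, size and per-feature Gaussian parameters."""

    label: str
    n: int
    means: np.ndarray
    sds: np.ndarray
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.asarray(self.means, dtype=float)
        sds = np.asarray(self.sds, dtype=float)
        object.__setattr__(self, "means", means)
        object.__setattr__(self, "sds", sds)
        if self.n < 2:
            raise InvalidInputError("group size n must be >= 2")
        if means.shape != (len(FEATURE_NAMES),) or sds.shape != (len(FEATURE_NAMES),):
            raise InvalidInputError(
                f"means and sds must be {len(FEATURE_NAMES)}-vectors in canonical order"
            )
        if np.any(sds < 0):
            raise InvalidInputError("sds must be >= 0")


def default_group_specs(seed: int = 0) -> list[GroupSpec]:
    """GroupSpecs with the published cohort means/SDs and group sizes."""
    return [
        GroupSpec(label=name, n=ref["n"], means=ref["means"], sds=ref["sds"],
                  seed=seed + i)
        for i, (name, ref) in enumerate(COHORT_REFERENCE.items())
    ]


def gen_spectrum(spec: SpectrumSpec) -> ImpedanceSpectrum:
    """Cole arc at the requested frequencies plus complex Gaussian noise."""
    rng = np.random.default_rng(spec.seed)
    z = cole_impedance(spec.r0, spec.r_inf, spec.alpha, spec.fc, spec.frequencies)
    noise = rng.normal(0.0, spec.noise_sd, size=(2, spec.frequencies.size))
    z = z + noise[0] + 1j * noise[1]
    return ImpedanceSpectrum(frequencies=spec.frequencies, impedance=z)


def _rr_sequence(spec: RRSpec, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Sequential draw of beat times and intervals until duration is filled."""
    beat_times = [0.0]
    intervals = []
    n_clipped = 0
    t = 0.0
    while t < spec.duration:
        rr = (
            spec.mean_rr
            + spec.a_lf * np.sin(2 * np.pi * spec.f_lf * t)
            + spec.a_hf * np.sin(2 * np.pi * spec.f_hf * t)
            + (rng.normal(0.0, spec.noise_sd) if spec.noise_sd > 0 else 0.0)
        )
        if rr <= 0:
            n_clipped += 1
            rr = 0.2  # refractory floor
        elif rr < 0.2:
            rr = 0.2
        intervals.append(rr)
        t += rr
        beat_times.append(t)
    if n_clipped > 0.01 * len(intervals):
        raise InvalidInputError(
            f"{n_clipped}/{len(intervals)} beats non-positive before clipping (> 1%); "
            "reduce modulation amplitudes or noise_sd"
        )
    return np.asarray(beat_times), np.asarray(intervals)


def gen_rr(spec: RRSpec):
    """Beat-interval series from the modulated RR process.

    Returns an :class:`~fluidsense.datatypes.RRSeries` (resampled at 4 Hz
    by cubic spline, the same representation the analysis uses).
    """
    from .hrv import build_rr  # deferred: hrv depends on datatypes only

    rng = np.random.default_rng(spec.seed)
    beat_times, _ = _rr_sequence(spec, rng)
    return build_rr(beat_times)


def _qrs_template(fs: float, width: float = 0.08) -> tuple[np.ndarray, int]:
    """Fixed biphasic pulse of ``width`` seconds; returns (shape, peak index).

    One sine cycle tapered by a Hann window: a dominant positive lobe
    (the R wave) followed by a negative lobe (S-like), peak amplitude 1 mV.
    """
    n = max(int(round(width * fs)), 5)
    if n % 2 == 0:
        n += 1
    t = np.linspace(0.0, 1.0, n)
    shape = np.sin(2 * np.pi * t) * np.hanning(n)
    shape /= shape.max()
    return shape, int(np.argmax(shape))


def gen_ecg(rr_spec: RRSpec, fs: float = 256.0, amp_noise_sd: float = 0.02) -> ECGRecord:
    """Synthetic single-lead ECG: QRS template train on the RR process.

    The template peak is centred on each ground-truth beat time; the truth
    is stored on the returned record for detector validation.  The train
    starts 0.1 s into the record (recordings begin mid-cycle) and a beat
    is only placed — and counted as truth — if its whole template fits,
    so every truth beat is a complete QRS.  Additive Gaussian amplitude
    noise (``amp_noise_sd`` mV) emulates sensor noise.
    """
    if fs < 128:
        raise InvalidInputError("fs must be >= 128 Hz")
    rng = np.random.default_rng(rr_spec.seed)
    beat_times, _ = _rr_sequence(rr_spec, rng)
    if beat_times.size < 2:
        raise InvalidInputError("duration too short for >= 2 beats")
    beat_times = beat_times + 0.1
    n_samples = int(np.ceil(rr_spec.duration * fs)) + 1
    samples = np.zeros(n_samples)
    shape, peak = _qrs_template(fs)
    kept_beats = []
    for bt in beat_times:
        center = int(round(bt * fs))
        start = center - peak
        stop = start + shape.size
        if start < 0 or stop > n_samples:
            continue
        samples[start:stop] += shape
        kept_beats.append(center / fs)  # truth snapped to the placed peak sample
    if amp_noise_sd > 0:
        samples = samples + rng.normal(0.0, amp_noise_sd, size=n_samples)
    return ECGRecord(samples=samples, fs=fs, truth_beat_times=np.asarray(kept_beats))


def gen_cohort(
    groups=None,
    *,
    dual_membership: int | None = None,
    seed: int = 0,
    correlation: np.ndarray | None = None,
) -> CohortDataset:
    """Draw a cohort feature table from per-group Gaussian specs.

    Parameters
    ----------
    groups : list of GroupSpec, optional
        Defaults to the published cohort (control 32 / baseline 23 /
        discharge 17).
    dual_membership : int, optional
        Number of subjects given a recording in both the baseline and
        discharge groups (study default: 12).  Only meaningful when both
        groups are present; ``None`` with the default groups uses 12,
        pass 0 to disable.
    correlation : (15, 15) array, optional
        Feature correlation matrix; default draws features independently.
    """
    if groups is None:
        groups = default_group_specs(seed=seed)
        if dual_membership is None:
            dual_membership = DEFAULT_DUAL_MEMBERSHIP
    labels = [g.label for g in groups]
    if len(set(labels)) != len(labels):
        raise InvalidInputError("duplicate group labels")
    dual_membership = int(dual_membership or 0)
    if dual_membership:
        by_label = {g.label: g for g in groups}
        if "baseline" not in by_label or "discharge" not in by_label:
            raise InvalidInputError("dual membership requires baseline and discharge groups")
        cap = min(by_label["baseline"].n, by_label["discharge"].n)
        if dual_membership > cap:
            raise InvalidInputError(f"dual_membership {dual_membership} exceeds group sizes")

    if correlation is not None:
        correlation = np.asarray(correlation, dtype=float)
        if correlation.shape != (len(FEATURE_NAMES),) * 2:
            raise InvalidInputError("correlation must be a 15x15 matrix")
        chol = np.linalg.cholesky(correlation)

    rows = []
    subject_counter = 0
    baseline_ids: list[str] = []
    for g in groups:
        label_tag = zlib.crc32(g.label.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng(np.random.SeedSequence([seed, g.seed, label_tag]))
        if correlation is None:
            draws = g.means + rng.standard_normal((g.n, len(FEATURE_NAMES))) * g.sds
        else:
            z = rng.standard_normal((g.n, len(FEATURE_NAMES))) @ chol.T
            draws = g.means + z * g.sds
        for i in range(g.n):
            if g.label == "discharge" and i < dual_membership:
                subject = baseline_ids[i]
            else:
                subject = f"S{subject_counter:03d}"
                subject_counter += 1
            if g.label == "baseline":
                baseline_ids.append(subject)
            rows.append({"subject_id": subject, "group": g.label,
                         **dict(zip(FEATURE_NAMES, draws[i]))})
    return CohortDataset(table=pd.DataFrame(rows))
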