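"""Core data containers shared across the pipeline.

All containers are lightweight frozen dataclasses around numpy arrays /
pandas frames; invariants are checked at construction so downstream code
can rely on them.
"""
from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np
import pandas as pd

#: Canonical order of the 15 per-recording features: the 8 transthoracic
#: bioimpedance parameters followed by the 7 heart-rate-variability indices.
FEATURE_NAMES: tuple[str, ...] = (
    "r0",
    "r_i",
    "cm",
    "alpha",
    "fc",
    "fitting_error",
    "r_inf",
    "r0_minus_rinf",
    "lf_hrv",
    "nlf_hrv",
    "hf_hrv",
    "nhf_hrv",
    "pdmi_symp",
    "pdmi_para",
    "mean_hr",
)

GROUP_LABELS: tuple[str, ...] = ("control", "baseline", "discharge")


class InvalidInputError(ValueError):
    """Raised when an input violates a documented precondition."""


@dataclass(frozen=True)
class ImpedanceSpectrum:
    """Complex impedance of one recording over a frequency sweep.

    Real part is resistance (Ω), imaginary part reactance (Ω); for a
    capacitive tissue arc the reactance is negative.
    """

    frequencies: np.ndarray  # Hz, strictly increasing
    impedance: np.ndarray  # complex Ω

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        z = np.asarray(self.impedance, dtype=complex)
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "impedance", z)
        if f.ndim != 1 or z.shape != f.shape:
            raise InvalidInputError("frequencies and impedance must be 1-D and equal length")
        if f.size < 5:
            raise InvalidInputError("spectrum needs >= 5 points to constrain 4 parameters")
        if np.any(f <= 0):
            raise InvalidInputError("frequencies must be > 0")
        if np.any(np.diff(f) <= 0):
            raise InvalidInputError("frequencies must be strictly increasing")
        if np.any(z.real <= 0):
            raise InvalidInputError("resistance (real part) must be > 0")

    @property
    def resistance(self) -> np.ndarray:
        return self.impedance.real

    @property
    def reactance(self) -> np.ndarray:
        return self.impedance.imag


@dataclass(frozen=True)
class CircleFit:
    """A circle in the resistance-reactance plane."""

    center_x: float
    center_y: float
    radius: float

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise InvalidInputError("radius must be > 0")

    @property
    def crosses_real_axis(self) -> bool:
        return self.radius**2 > self.center_y**2


@dataclass(frozen=True)
class ColeParameters:
    """Fitted Cole tissue-model parameters of one recording.

    ``r_inf`` is the parallel combination of the extracellular branch
    ``r0`` and the intracellular branch ``r_i``; ``fitting_error`` is the
    sum of squared complex residuals (Ω²) at the optimum.
    """

    r0: float
    r_i: float
    r_inf: float
    r0_minus_rinf: float
    alpha: float
    fc: float
    cm: float
    fitting_error: float

    def __post_init__(self) -> None:
        if not (0 < self.r_inf < self.r0):
            raise InvalidInputError("requires 0 < r_inf < r0")
        if abs(self.r0_minus_rinf - (self.r0 - self.r_inf)) > 1e-9 * self.r0:
            raise InvalidInputError("r0_minus_rinf must equal r0 - r_inf")
        if not (0 < self.alpha <= 1):
            raise InvalidInputError("alpha must lie in (0, 1]")
        if not self.fc > 0:
            raise InvalidInputError("fc must be > 0")
        if not self.cm > 0:
            raise InvalidInputError("cm must be > 0")
        if self.fitting_error < 0:
            raise InvalidInputError("fitting_error must be >= 0")
        par = self.r0 * self.r_i / (self.r0 + self.r_i)
        if abs(par - self.r_inf) > 1e-9 * self.r_inf:
            raise InvalidInputError("r_inf must equal r0*r_i/(r0+r_i)")

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "r0": self.r0,
                "r_i": self.r_i,
                "cm": self.cm,
                "alpha": self.alpha,
                "fc": self.fc,
                "fitting_error": self.fitting_error,
                "r_inf": self.r_inf,
                "r0_minus_rinf": self.r0_minus_rinf,
            }
        )


@dataclass(frozen=True)
class ECGRecord:
    """Single-lead ECG samples (mV) at a fixed sampling rate."""

    samples: np.ndarray
    fs: float
    truth_beat_times: np.ndarray | None = None  # set by the generator

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        object.__setattr__(self, "samples", s)
        if not self.fs > 0:
            raise InvalidInputError("fs must be > 0")
        if s.size < 2 * self.fs:
            raise InvalidInputError("ECG must span at least 2 seconds")
        if self.truth_beat_times is not None:
            object.__setattr__(
                self, "truth_beat_times", np.asarray(self.truth_beat_times, dtype=float)
            )

    @property
    def duration(self) -> float:
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.fs


@dataclass(frozen=True)
class RRSeries:
    """Beat-interval series with its evenly resampled counterpart."""

    beat_times: np.ndarray  # s, strictly increasing
    intervals: np.ndarray  # s, first differences of beat_times
    resampled: np.ndarray  # s, uniform grid at resample_fs
    resample_fs: float = 4.0

    def __post_init__(self) -> None:
        bt = np.asarray(self.beat_times, dtype=float)
        iv = np.asarray(self.intervals, dtype=float)
        rs = np.asarray(self.resampled, dtype=float)
        object.__setattr__(self, "beat_times", bt)
        object.__setattr__(self, "intervals", iv)
        object.__setattr__(self, "resampled", rs)
        if np.any(np.diff(bt) <= 0):
            raise InvalidInputError("beat times must be strictly increasing")
        if np.any(iv <= 0):
            raise InvalidInputError("intervals must be > 0")
        span = bt[-1] - bt[0]
        expected = int(np.floor(span * self.resample_fs)) + 1
        if rs.size != expected:
            raise InvalidInputError(
                f"resampled length {rs.size} != floor(span*fs)+1 = {expected}"
            )

    @property
    def duration(self) -> float:
        return float(self.beat_times[-1] - self.beat_times[0])


@dataclass(frozen=True)
class HRVIndices:
    """The seven heart-rate-variability parameters of one recording."""

    lf: float
    hf: float
    nlf: float
    nhf: float
    pdmi_symp: float
    pdmi_para: float
    mean_hr: float

    def __post_init__(self) -> None:
        if self.lf < 0 or self.hf < 0:
            raise InvalidInputError("band powers must be >= 0")
        if not (0 <= self.nlf <= 1 and 0 <= self.nhf <= 1):
            raise InvalidInputError("normalized indices must lie in [0, 1]")
        if abs(self.nlf + self.nhf - 1.0) > 1e-9:
            raise InvalidInputError("nlf + nhf must equal 1")
        if not self.mean_hr > 0:
            raise InvalidInputError("mean heart rate must be > 0")

    def as_series(self) -> pd.Series:
        return pd.Series(
            {
                "lf_hrv": self.lf,
                "nlf_hrv": self.nlf,
                "hf_hrv": self.hf,
                "nhf_hrv": self.nhf,
                "pdmi_symp": self.pdmi_symp,
                "pdmi_para": self.pdmi_para,
                "mean_hr": self.mean_hr,
            }
        )


@dataclass(frozen=True)
class CohortDataset:
    """Per-recording 15-feature table with subject IDs and group labels."""

    table: pd.DataFrame  # columns: subject_id, group, *FEATURE_NAMES

    def __post_init__(self) -> None:
        required = ["subject_id", "group", *FEATURE_NAMES]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise InvalidInputError(f"cohort table missing columns: {missing}")
        object.__setattr__(self, "table", self.table[required].reset_index(drop=True))

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.table["group"]))

    @property
    def features(self) -> pd.DataFrame:
        return self.table[list(FEATURE_NAMES)]

    def binary_labels(self) -> pd.Series:
        """with_fluid (baseline) vs without_fluid (control ∪ discharge)."""
        return self.table["group"].map(
            lambda g: "with_fluid" if g == "baseline" else "without_fluid"
        )

    def labels(self, task: str) -> pd.Series:
        if task == "three_class":
            return self.table["group"]
        if task == "two_class":
            return self.binary_labels()
        raise InvalidInputError(f"unknown task {task!r}")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-normalized confusion matrix (percent of each actual class)."""

    labels: tuple[str, ...]
    row_counts: np.ndarray  # int, actual x predicted
    row_percent: np.ndarray  # float, rows sum to 100 (NaN for empty rows)

    def to_frame(self, percent: bool = True) -> pd.DataFrame:
        data = self.row_percent if percent else self.row_counts
        return pd.DataFrame(data, index=list(self.labels), columns=list(self.labels))


@dataclass(frozen=True)
class CVResult:
    """Outcome of one cross-validated classifier evaluation."""

    family: str
    features: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray
    accuracy: float
    labels: tuple[str, ...]
    n_folds: int
    n_skipped_folds: int = 0
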