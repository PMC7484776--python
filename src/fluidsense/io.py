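"""CSV readers/writers for every interchange format the pipeline uses.

All formats are plain CSV.  Pipeline outputs may carry leading ``#``
comment lines (seed and config hash for reproducibility); every reader
here skips them.
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    FEATURE_NAMES,
    CohortDataset,
    ColeParameters,
    ECGRecord,
    HRVIndices,
    ImpedanceSpectrum,
    InvalidInputError,
)

__all__ = [
    "write_spectrum",
    "read_spectrum",
    "write_ecg",
    "read_ecg",
    "write_rr",
    "read_rr",
    "write_cohort",
    "read_cohort",
    "cole_frame",
    "hrv_frame",
]

COLE_COLUMNS = ("r0", "r_i", "r_inf", "r0_minus_rinf", "fc", "cm", "alpha", "fitting_error")
HRV_COLUMNS = ("lf_hrv", "nlf_hrv", "hf_hrv", "nhf_hrv", "pdmi_symp", "pdmi_para", "mean_hr")


def _write_csv(frame: pd.DataFrame, path, header_comment: str | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def write_spectrum(spectrum: ImpedanceSpectrum, path, header_comment: str | None = None) -> None:
    frame = pd.DataFrame(
        {
            "frequency_hz": spectrum.frequencies,
            "resistance_ohm": spectrum.impedance.real,
            "reactance_ohm": spectrum.impedance.imag,
        }
    )
    _write_csv(frame, path, header_comment)


def read_spectrum(path) -> ImpedanceSpectrum:
    frame = pd.read_csv(path, comment="#")
    required = {"frequency_hz", "resistance_ohm", "reactance_ohm"}
    if not required.issubset(frame.columns):
        raise InvalidInputError(f"spectrum CSV must have columns {sorted(required)}")
    return ImpedanceSpectrum(
        frequencies=frame["frequency_hz"].to_numpy(),
        impedance=frame["resistance_ohm"].to_numpy()
        + 1j * frame["reactance_ohm"].to_numpy(),
    )


def write_ecg(ecg: ECGRecord, path, header_comment: str | None = None) -> None:
    """ECG samples as one-column CSV plus a ``.meta`` sidecar with fs_hz."""
    path = Path(path)
    _write_csv(pd.DataFrame({"sample_mv": ecg.samples}), path, header_comment)
    meta = [f"fs_hz={ecg.fs:g}"]
    if ecg.truth_beat_times is not None:
        meta.append("truth_beat_times_s=" + ",".join(f"{t:.10g}" for t in ecg.truth_beat_times))
    Path(str(path) + ".meta").write_text("\n".join(meta) + "\n")


def read_ecg(path) -> ECGRecord:
    path = Path(path)
    frame = pd.read_csv(path, comment="#")
    if "sample_mv" not in frame.columns:
        raise InvalidInputError("ECG CSV must have a sample_mv column")
    meta_path = Path(str(path) + ".meta")
    if not meta_path.exists():
        raise InvalidInputError(f"missing ECG sidecar header {meta_path.name}")
    fs = None
    truth = None
    for line in meta_path.read_text().splitlines():
        key, _, value = line.partition("=")
        if key == "fs_hz":
            fs = float(value)
        elif key == "truth_beat_times_s" and value:
            truth = np.array([float(v) for v in value.split(",")])
    if fs is None:
        raise InvalidInputError("ECG sidecar must define fs_hz")
    return ECGRecord(samples=frame["sample_mv"].to_numpy(), fs=fs, truth_beat_times=truth)


def write_rr(beat_times, path, header_comment: str | None = None) -> None:
    beat_times = np.asarray(beat_times, dtype=float)
    frame = pd.DataFrame(
        {"beat_time_s": beat_times[1:], "rr_s": np.diff(beat_times)}
    )
    _write_csv(frame, path, header_comment)


def read_rr(path) -> np.ndarray:
    """Beat times from a two-column beat_time_s,rr_s CSV."""
    frame = pd.read_csv(path, comment="#")
    if not {"beat_time_s", "rr_s"}.issubset(frame.columns):
        raise InvalidInputError("RR CSV must have beat_time_s and rr_s columns")
    first = frame["beat_time_s"].iloc[0] - frame["rr_s"].iloc[0]
    return np.concatenate([[first], frame["beat_time_s"].to_numpy()])


def write_cohort(dataset: CohortDataset, path, header_comment: str | None = None) -> None:
    _write_csv(dataset.table, path, header_comment)


def read_cohort(path) -> CohortDataset:
    return CohortDataset(table=pd.read_csv(path, comment="#"))


def cole_frame(params: dict[str, ColeParameters]) -> pd.DataFrame:
    """One row per recording id, the 8 bioimpedance parameters as columns."""
    rows = {rid: p.as_series()[list(COLE_COLUMNS)] for rid, p in params.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "recording_id"
    return frame.reset_index()


def hrv_frame(indices: dict[str, HRVIndices]) -> pd.DataFrame:
    """One row per recording id, the 7 HRV parameters as columns."""
    rows = {rid: h.as_series()[list(HRV_COLUMNS)] for rid, h in indices.items()}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "recording_id"
    return frame.reset_index()
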