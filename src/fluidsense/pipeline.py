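"""End-to-end orchestration: signals in, statistics and classification out.

A run is described by a :class:`RunConfig` (plain YAML key-value file).
``run_all`` executes the stages

    simulate (optional) -> fit-cole -> hrv -> assemble -> stats -> classify

and writes a manifest (config, seed, package versions, per-stage row
counts) that makes re-runs bit-identical: every output CSV carries a
header comment with the seed and the config hash.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as fio
from .classify import confusion, subset_search, train_eval
from .cole import characteristic_frequency, fit_cole
from .datatypes import FEATURE_NAMES, CohortDataset, InvalidInputError
from .hrv import ecg_to_rr, hrv_indices
from .stats import compare_all, comparisons_frame
from .synth import COHORT_REFERENCE, RRSpec, SpectrumSpec, gen_ecg, gen_spectrum

logger = logging.getLogger("fluidsense.pipeline")

__all__ = ["RunConfig", "assemble_features", "run_all", "simulate_recordings"]


@dataclass(frozen=True)
class RunConfig:
    """Everything a reproducible run needs, with the study's constants."""

    out_dir: str = "fluidsense_run"
    spectra_dir: str | None = None  # None => produced by the simulate stage
    ecg_dir: str | None = None
    labels_csv: str | None = None
    seed: int = 0
    simulate: bool = True
    group_sizes: dict = field(
        default_factory=lambda: {"control": 32, "baseline": 23, "discharge": 17}
    )
    ecg_duration_s: float = 300.0
    ecg_fs: float = 256.0
    # HRV constants
    band_low_hz: float = 0.045
    band_split_hz: float = 0.15
    band_high_hz: float = 0.4
    resample_fs: float = 4.0
    spectrum_window: int = 256
    # Cole optimizer
    ftol_rel: float = 1e-10
    max_iterations: int = 2000
    # classifier settings
    families: tuple = ("svm_cubic",)
    task: str = "two_class"
    features: tuple = ("r0", "r_i", "cm", "lf_hrv", "pdmi_para", "mean_hr")
    svm_c: float = 1.0
    svm_gamma: float = 2.6
    run_subset_search: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        for key in ("families", "features"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stamp(self) -> str:
        return f"seed={self.seed} config_hash={self.hash()}"


def _group_signal_specs(config: RunConfig) -> dict[str, dict]:
    """Per-group generative parameters for the simulate stage.

    Cole parameters follow the published group means/SDs; the
    characteristic frequency is implied by the published C_m and circuit
    resistances.  RR modulation echoes the groups' autonomic profile:
    heart-failure groups get a larger HF (parasympathetic-band) amplitude,
    matching their higher normalized HF power.
    """
    feats = {name: i for i, name in enumerate(FEATURE_NAMES)}
    specs = {}
    for group, ref in COHORT_REFERENCE.items():
        means, sds = np.asarray(ref["means"]), np.asarray(ref["sds"])
        r0_m = means[feats["r0"]]
        rinf_m = means[feats["r_inf"]]
        fc_m = characteristic_frequency(r0_m, rinf_m, means[feats["cm"]])
        specs[group] = {
            "r0": (r0_m, sds[feats["r0"]]),
            "rinf_ratio": (rinf_m / r0_m, 0.05),
            "alpha": (means[feats["alpha"]], sds[feats["alpha"]]),
            "fc": (fc_m, 0.2 * fc_m),
            "mean_rr": 60.0 / means[feats["mean_hr"]],
            "a_lf": 0.03,
            "a_hf": 0.035 if group in ("baseline", "discharge") else 0.02,
        }
    return specs


def simulate_recordings(config: RunConfig, out_dir: Path) -> pd.DataFrame:
    """Write per-recording spectrum and ECG CSVs plus a labels table.

    Returns the labels frame (recording_id, subject_id, group).  Subject
    IDs are unique per recording except that the first 12 discharge
    recordings reuse baseline subjects, as in the study cohort.
    """
    rng = np.random.default_rng(config.seed)
    spectra_dir = out_dir / "spectra"
    ecg_dir = out_dir / "ecg"
    spectra_dir.mkdir(parents=True, exist_ok=True)
    ecg_dir.mkdir(parents=True, exist_ok=True)
    gspecs = _group_signal_specs(config)
    stamp = config.stamp()

    rows = []
    counter = 0
    baseline_subjects: list[str] = []
    for group, n in config.group_sizes.items():
        gs = gspecs[group]
        for i in range(n):
            rid = f"{group}_{i:03d}"
            if group == "discharge" and i < min(12, len(baseline_subjects)):
                subject = baseline_subjects[i]
            else:
                subject = f"S{counter:03d}"
                counter += 1
            if group == "baseline":
                baseline_subjects.append(subject)

            r0 = max(rng.normal(*gs["r0"]), 8.0)
            ratio = np.clip(rng.normal(*gs["rinf_ratio"]), 0.3, 0.85)
            alpha = float(np.clip(rng.normal(*gs["alpha"]), 0.35, 0.98))
            fc = max(rng.normal(*gs["fc"]), 5e3)
            sp = SpectrumSpec(
                r0=r0, r_inf=r0 * ratio, alpha=alpha, fc=fc,
                noise_sd=0.2, seed=int(rng.integers(2**31)),
            )
            fio.write_spectrum(gen_spectrum(sp), spectra_dir / f"{rid}.csv", stamp)

            rr = RRSpec(
                mean_rr=float(np.clip(rng.normal(gs["mean_rr"], 0.08), 0.5, 1.4)),
                a_lf=gs["a_lf"], a_hf=gs["a_hf"],
                noise_sd=0.005, duration=config.ecg_duration_s,
                seed=int(rng.integers(2**31)),
            )
            fio.write_ecg(gen_ecg(rr, fs=config.ecg_fs), ecg_dir / f"{rid}.csv", stamp)
            rows.append({"recording_id": rid, "subject_id": subject, "group": group})
    labels = pd.DataFrame(rows)
    fio._write_csv(labels, out_dir / "labels.csv", stamp)
    return labels


def assemble_features(
    cole_df: pd.DataFrame, hrv_df: pd.DataFrame, labels: pd.DataFrame
) -> CohortDataset:
    """Join Cole and HRV rows into the canonical 15-feature cohort table.

    Recordings missing either side are dropped (count logged); duplicate
    recording ids are rejected.
    """
    for name, df in (("cole", cole_df), ("hrv", hrv_df), ("labels", labels)):
        if df["recording_id"].duplicated().any():
            raise InvalidInputError(f"duplicate recording ids in {name} table")
    merged = labels.merge(cole_df, on="recording_id", how="inner").merge(
        hrv_df, on="recording_id", how="inner"
    )
    n_dropped = len(labels) - len(merged)
    if n_dropped:
        logger.info("assemble_features: dropped %d recordings missing a side", n_dropped)
    return CohortDataset(table=merged[["subject_id", "group", *FEATURE_NAMES]])


def run_all(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = config.stamp()
    manifest: dict = {
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "versions": _versions(),
        "stages": {},
    }

    stage = "simulate"
    try:
        if config.simulate:
            labels = simulate_recordings(config, out_dir)
            spectra_dir, ecg_dir = out_dir / "spectra", out_dir / "ecg"
        else:
            for key in ("spectra_dir", "ecg_dir", "labels_csv"):
                value = getattr(config, key)
                if value is None or not Path(value).exists():
                    raise InvalidInputError(f"config {key} missing or does not exist")
            spectra_dir, ecg_dir = Path(config.spectra_dir), Path(config.ecg_dir)
            labels = pd.read_csv(config.labels_csv, comment="#")
        manifest["stages"]["simulate"] = {"n_recordings": len(labels)}

        stage = "fit-cole"
        cole_params = {}
        for path in sorted(spectra_dir.glob("*.csv")):
            cole_params[path.stem] = fit_cole(
                fio.read_spectrum(path),
                ftol_rel=config.ftol_rel, maxiter=config.max_iterations,
            )
        cole_df = fio.cole_frame(cole_params)
        fio._write_csv(cole_df, out_dir / "cole_params.csv", stamp)
        manifest["stages"]["fit-cole"] = {"n_rows": len(cole_df)}

        stage = "hrv"
        hrv_vals = {}
        for path in sorted(ecg_dir.glob("*.csv")):
            rr = ecg_to_rr(fio.read_ecg(path), resample_fs=config.resample_fs)
            hrv_vals[path.stem] = hrv_indices(rr)
        hrv_df = fio.hrv_frame(hrv_vals)
        fio._write_csv(hrv_df, out_dir / "hrv_indices.csv", stamp)
        manifest["stages"]["hrv"] = {"n_rows": len(hrv_df)}

        stage = "assemble"
        cohort = assemble_features(cole_df, hrv_df, labels)
        fio.write_cohort(cohort, out_dir / "cohort.csv", stamp)
        manifest["stages"]["assemble"] = {"n_rows": len(cohort.table)}

        stage = "stats"
        comparisons = comparisons_frame(compare_all(cohort))
        fio._write_csv(comparisons, out_dir / "comparisons.csv", stamp)
        manifest["stages"]["stats"] = {"n_rows": len(comparisons)}

        stage = "classify"
        reports = {}
        for family in config.families:
            if config.run_subset_search:
                result = subset_search(
                    cohort, family, task=config.task,
                    c=config.svm_c, gamma=config.svm_gamma,
                )
            else:
                result = train_eval(
                    family, cohort, config.features, task=config.task,
                    c=config.svm_c, gamma=config.svm_gamma,
                )
            cm = confusion(result)
            reports[family] = {
                "features": list(result.features),
                "accuracy": result.accuracy,
                "labels": list(cm.labels),
                "confusion_counts": cm.row_counts.tolist(),
                "confusion_percent": np.round(cm.row_percent, 1).tolist(),
            }
        (out_dir / "classification.json").write_text(
            json.dumps({"stamp": stamp, "reports": reports}, indent=2) + "\n"
        )
        manifest["stages"]["classify"] = {"n_models": len(reports)}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("run complete: %s", out_dir / "manifest.json")
    return manifest


def _versions() -> dict[str, str]:
    import scipy
    import sklearn
    import statsmodels

    from . import __version__

    return {
        "fluidsense": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "sklearn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }
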