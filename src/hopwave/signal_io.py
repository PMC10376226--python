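"""Trial, manifest and result file input/output.

Storage dialect
---------------
Each trial is stored as three sibling text files sharing a stem:

``<stem>_emg.csv``    one header row; columns ``time_s, GM, GL, TA, VM,
                      RF, BF, ST, vGRF`` on the EMG clock (3000 Hz by
                      default).
``<stem>_mocap.csv``  columns ``time_s, ankle_vz, knee_flexion`` on the
                      motion-capture clock (125 Hz by default).
``<stem>_meta.json``  subject/group/limb labels and the two sampling
                      rates.

Two clocks, two files: nothing is resampled in storage.  Classification
results and cohort manifests are JSON with an explicit schema version.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TrialFormatError

__all__ = ["MUSCLES", "TrialRecording", "read_trial", "write_trial", "write_results", "read_results"]

MUSCLES = ("GM", "GL", "TA", "VM", "RF", "BF", "ST")
GROUPS = ("ACLR", "Control")
LIMBS = ("index", "contralateral")  # "index" is the surgical limb in ACLR subjects

RESULTS_SCHEMA_VERSION = 1


@dataclass
class TrialRecording:
    """One hop trial: synchronized EMG, force and kinematic channels.

    ``emg`` is a DataFrame with exactly the seven muscle columns in
    canonical order, in millivolts at ``fs_emg``; ``vgrf`` is vertical
    ground reaction force (N) on the same clock; ``ankle_vz`` (m/s) and
    ``knee_flexion`` (deg) are on the slower motion-capture clock.
    """

    subject_id: str
    group: str
    limb: str
    emg: pd.DataFrame
    vgrf: np.ndarray
    ankle_vz: np.ndarray
    knee_flexion: np.ndarray
    fs_emg: float = 3000.0
    fs_mocap: float = 125.0
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise TrialFormatError(f"unknown group label {self.group!r}")
        if self.limb not in LIMBS:
            raise TrialFormatError(f"unknown limb label {self.limb!r}")
        missing = [m for m in MUSCLES if m not in self.emg.columns]
        if missing:
            raise TrialFormatError(f"missing EMG channel column(s): {', '.join(missing)}")
        self.emg = self.emg[list(MUSCLES)]
        self.vgrf = np.asarray(self.vgrf, dtype=float)
        n = len(self.emg)
        if self.vgrf.size != n:
            raise TrialFormatError(
                f"vGRF length {self.vgrf.size} does not match EMG length {n}"
            )
        self.ankle_vz = np.asarray(self.ankle_vz, dtype=float)
        self.knee_flexion = np.asarray(self.knee_flexion, dtype=float)
        if self.ankle_vz.size != self.knee_flexion.size:
            raise TrialFormatError("ankle_vz and knee_flexion lengths differ")

    @property
    def n_samples(self) -> int:
        return len(self.emg)

    @property
    def clock_ratio(self) -> int:
        """EMG samples per motion-capture sample (24 under defaults)."""
        return int(round(self.fs_emg / self.fs_mocap))


def write_trial(trial: TrialRecording, stem: str | Path) -> list[Path]:
    """Write one trial in the three-file dialect; returns paths written."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    n = trial.n_samples
    emg = pd.DataFrame({"time_s": np.arange(n) / trial.fs_emg})
    for m in MUSCLES:
        emg[m] = trial.emg[m].to_numpy()
    emg["vGRF"] = trial.vgrf
    emg_path = stem.with_name(stem.name + "_emg.csv")
    emg.to_csv(emg_path, index=False, float_format="%.10g")

    nm = trial.ankle_vz.size
    mocap = pd.DataFrame(
        {
            "time_s": np.arange(nm) / trial.fs_mocap,
            "ankle_vz": trial.ankle_vz,
            "knee_flexion": trial.knee_flexion,
        }
    )
    mocap_path = stem.with_name(stem.name + "_mocap.csv")
    mocap.to_csv(mocap_path, index=False, float_format="%.10g")

    meta_path = stem.with_name(stem.name + "_meta.json")
    meta = {
        "subject_id": trial.subject_id,
        "group": trial.group,
        "limb": trial.limb,
        "fs_emg": trial.fs_emg,
        "fs_mocap": trial.fs_mocap,
        "trial_index": trial.trial_index,
    }
    meta_path.write_text(json.dumps(meta, indent=1))
    return [emg_path, mocap_path, meta_path]


def read_trial(stem: str | Path) -> TrialRecording:
    """Read a trial written by :func:`write_trial` (lossless round trip)."""
    stem = Path(stem)
    emg_path = stem.with_name(stem.name + "_emg.csv")
    mocap_path = stem.with_name(stem.name + "_mocap.csv")
    meta_path = stem.with_name(stem.name + "_meta.json")
    for p in (emg_path, mocap_path, meta_path):
        if not p.exists():
            raise TrialFormatError(f"missing trial file {p}")
    try:
        emg = pd.read_csv(emg_path)
        mocap = pd.read_csv(mocap_path)
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise TrialFormatError(f"malformed trial file near {stem}: {exc}") from exc
    if emg.empty:
        raise TrialFormatError(f"empty EMG file {emg_path}")
    missing = [m for m in MUSCLES if m not in emg.columns]
    if missing:
        raise TrialFormatError(f"missing EMG channel column(s): {', '.join(missing)}")
    if "vGRF" not in emg.columns:
        raise TrialFormatError("missing vGRF column")
    for col in ("ankle_vz", "knee_flexion"):
        if col not in mocap.columns:
            raise TrialFormatError(f"missing motion-capture column {col}")
    meta = json.loads(meta_path.read_text())
    return TrialRecording(
        subject_id=meta["subject_id"],
        group=meta["group"],
        limb=meta["limb"],
        emg=emg[list(MUSCLES)],
        vgrf=emg["vGRF"].to_numpy(),
        ankle_vz=mocap["ankle_vz"].to_numpy(),
        knee_flexion=mocap["knee_flexion"].to_numpy(),
        fs_emg=float(meta["fs_emg"]),
        fs_mocap=float(meta["fs_mocap"]),
        trial_index=int(meta.get("trial_index", 0)),
    )


def write_results(results, path: str | Path, verdicts=None) -> Path:
    """Serialize classification results (and optional verdicts) to JSON.

    ``results`` is an iterable of ClassificationResult.  Rates are
    re-derived from the stored counts on read, so the counts are the
    source of truth.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records = []
    for i, res in enumerate(results):
        rec = {
            "muscle": res.muscle,
            "comparison": res.comparison,
            "phase_scope": res.phase_scope,
            "n_correct": int(res.n_correct),
            "n_total": int(res.n_total),
            "rate_percent": res.rate_percent,
        }
        if verdicts is not None:
            v = verdicts[i]
            rec["significant"] = bool(v.significant)
            rec["threshold_percent"] = v.threshold_percent
            rec["method"] = v.method
        records.append(rec)
    doc = {"schema_version": RESULTS_SCHEMA_VERSION, "results": records}
    path.write_text(json.dumps(doc, indent=1))
    return path


def read_results(path: str | Path) -> list[dict]:
    """Read a results JSON document back as a list of dicts."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != RESULTS_SCHEMA_VERSION:
        raise TrialFormatError(f"unsupported results schema version in {path}")
    return doc["results"]
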