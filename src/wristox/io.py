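"""Plain-text persistence: PPG CSVs with JSON sidecars, study bundles,
report JSON.

A record is a CSV with columns time_s, red, infrared, green, acc_x,
acc_y, acc_z plus a sidecar ``<name>.meta.json`` holding the sampling
rate, seed, subject parameters, motion-burst intervals and the
ground-truth saturation trajectory.  A study bundle is one directory per
subject (two record CSVs and one blood-sample CSV) under a top-level
``manifest.json``.  All formats round-trip to full stored precision.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .protocol import BloodSample, HypoxiaProtocol, HypoxiaStudy, SubjectStudy, Trajectory, Stage
from .synth import PPGRecord, SubjectParams

_FLOAT_FMT = "%.10g"


def write_record(record: PPGRecord, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(
        {
            "time_s": record.t,
            "red": record.red,
            "infrared": record.infrared,
            "green": record.green,
            "acc_x": record.acc_x,
            "acc_y": record.acc_y,
            "acc_z": record.acc_z,
        }
    )
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    meta = dict(record.meta)
    subject = meta.get("subject")
    sidecar = {
        "fs": record.fs,
        "t0": record.t0,
        "seed": meta.get("seed"),
        "wrist": meta.get("wrist"),
        "subject_id": meta.get("subject_id"),
        "true_lag_s": meta.get("true_lag_s"),
        "subject_params": dataclasses.asdict(subject) if subject is not None else None,
        "motion_bursts": meta.get("motion_bursts", []),
        "truth_t": np.asarray(meta.get("truth_t", [])).tolist(),
        "truth_s": np.asarray(meta.get("truth_s", [])).tolist(),
    }
    path.with_suffix(".meta.json").write_text(json.dumps(sidecar))


def read_record(path: str | Path) -> PPGRecord:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = json.loads(path.with_suffix(".meta.json").read_text())
    meta = {
        "seed": sidecar.get("seed"),
        "fs": sidecar["fs"],
        "wrist": sidecar.get("wrist"),
        "subject_id": sidecar.get("subject_id"),
        "true_lag_s": sidecar.get("true_lag_s"),
        "motion_bursts": [tuple(b) for b in sidecar.get("motion_bursts", [])],
        "truth_t": np.asarray(sidecar.get("truth_t", [])),
        "truth_s": np.asarray(sidecar.get("truth_s", [])),
    }
    if sidecar.get("subject_params"):
        meta["subject"] = SubjectParams(**sidecar["subject_params"])
    return PPGRecord(
        fs=float(sidecar["fs"]),
        t0=float(sidecar["t0"]),
        red=df["red"].to_numpy(),
        infrared=df["infrared"].to_numpy(),
        green=df["green"].to_numpy(),
        acc_x=df["acc_x"].to_numpy(),
        acc_y=df["acc_y"].to_numpy(),
        acc_z=df["acc_z"].to_numpy(),
        meta=meta,
    )


def write_samples(samples: list[BloodSample], path: str | Path) -> None:
    pd.DataFrame(
        {
            "t_s": [s.t for s in samples],
            "sao2_pct": [s.sao2 for s in samples],
            "run": [s.run_index for s in samples],
            "plateau": [s.plateau_index for s in samples],
        }
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_samples(path: str | Path) -> list[BloodSample]:
    df = pd.read_csv(path)
    return [
        BloodSample(t=float(r.t_s), sao2=float(r.sao2_pct), run_index=int(r.run), plateau_index=int(r.plateau))
        for r in df.itertuples()
    ]


def write_study(study: HypoxiaStudy, out_dir: str | Path, config_hash: str = "") -> None:
    """Write a study bundle: manifest + one directory per subject."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format": "wristox-study-v1",
        "config_hash": config_hash,
        "seed": study.seed,
        "protocol": dataclasses.asdict(study.protocol),
        "n_subjects": len(study.subjects),
        "subjects": [],
    }
    for subj in study.subjects:
        sdir = out / f"subject_{subj.subject_id:02d}"
        sdir.mkdir(exist_ok=True)
        for wrist, rec in subj.records.items():
            write_record(rec, sdir / f"{wrist}.csv")
        write_samples(subj.samples, sdir / "blood_samples.csv")
        np.savetxt(
            sdir / "trajectory.csv",
            np.column_stack([subj.trajectory.t, subj.trajectory.sao2]),
            delimiter=",",
            header="t_s,sao2_pct",
            comments="",
            fmt=_FLOAT_FMT,
        )
        manifest["subjects"].append(
            {
                "id": subj.subject_id,
                "dir": sdir.name,
                "lags": subj.lags,
                "params": dataclasses.asdict(subj.params),
                "stages": [dataclasses.asdict(st) for st in subj.trajectory.stages],
            }
        )
    (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))


def read_study(bundle_dir: str | Path) -> HypoxiaStudy:
    out = Path(bundle_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    if manifest.get("format") != "wristox-study-v1":
        raise ValueError("not a study bundle: bad or missing manifest format")
    protocol = HypoxiaProtocol(
        **{**manifest["protocol"], "plateau_targets": tuple(manifest["protocol"]["plateau_targets"])}
    )
    subjects = []
    for entry in manifest["subjects"]:
        sdir = out / entry["dir"]
        traj_raw = np.loadtxt(sdir / "trajectory.csv", delimiter=",", skiprows=1)
        trajectory = Trajectory(
            t=traj_raw[:, 0],
            sao2=traj_raw[:, 1],
            stages=[Stage(**st) for st in entry["stages"]],
        )
        records = {w: read_record(sdir / f"{w}.csv") for w in entry["lags"]}
        subjects.append(
            SubjectStudy(
                subject_id=entry["id"],
                params=SubjectParams(**entry["params"]),
                trajectory=trajectory,
                samples=read_samples(sdir / "blood_samples.csv"),
                records=records,
                lags={k: float(v) for k, v in entry["lags"].items()},
            )
        )
    return HypoxiaStudy(protocol=protocol, subjects=subjects, seed=manifest["seed"])


def write_report(payload: dict, path: str | Path) -> None:
    """Deterministic JSON: sorted keys, fixed float rounding upstream."""
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")
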