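"""Synthetic clinical-study generation and tidy dataset I/O.

Emulates the structure of the clinical PK studies used for CYP2D6 DGI model
development: arms defined by activity score (0-3) or traditional phenotype
(EM/PM), single- or multiple-dose oral/IV regimens, sparse sampling grids,
log-normal between-subject variability (BSV) on model parameters,
allometric body-weight variability, combined proportional + additive
residual error, and censoring below a lower limit of quantification (LLOQ).

The generator knows its own truth (the generating model and parameters are
retained on the dataset), which makes it the oracle for parameter-recovery
and end-to-end pipeline tests.  What it does not emulate: digitization
error of literature profiles, dropout/missingness patterns, covariate
effects beyond body weight, and study-to-study assay differences.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import engine as eng
from .drugs import model_for_cyp2d6_status
from .errors import DomainError, ValidationError
from .scaling import ScalingCurve

__all__ = [
    "StudyArm",
    "StudyDesign",
    "NoiseSpec",
    "StudyDataset",
    "generate_study",
    "summarize_arms",
    "write_dataset",
    "read_dataset",
]

REQUIRED_COLUMNS = ("subject_id", "arm", "analyte", "time_h", "conc")
_PHENOTYPES = ("EM", "PM", "IM", "NM", "UM")


@dataclass(frozen=True)
class StudyArm:
    label: str
    cyp2d6_status: float | str  # activity score or phenotype label
    n_subjects: int
    regimen: eng.DosingRegimen
    sampling_times: tuple[float, ...]  # h

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValidationError(f"arm {self.label}: n_subjects must be >= 1")
        t = np.asarray(self.sampling_times, float)
        if t.size < 1 or np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValidationError(
                f"arm {self.label}: sampling times must be strictly increasing and >= 0"
            )
        s = self.cyp2d6_status
        if isinstance(s, str):
            if s.upper() not in _PHENOTYPES:
                raise ValidationError(f"arm {self.label}: unknown CYP2D6 status {s!r}")
        elif not (np.isfinite(s) and s >= 0):
            raise ValidationError(f"arm {self.label}: activity score must be >= 0")


@dataclass(frozen=True)
class StudyDesign:
    study_id: str
    arms: tuple[StudyArm, ...]
    weight_range: tuple[float, float] | None = None  # kg

    def __post_init__(self) -> None:
        labels = [a.label for a in self.arms]
        if len(set(labels)) != len(labels):
            raise ValidationError(f"duplicate arm labels: {labels}")

    def arm(self, label: str) -> StudyArm:
        for a in self.arms:
            if a.label == label:
                return a
        raise ValidationError(f"no arm labeled {label!r}")

    def to_dict(self) -> dict:
        return {
            "study_id": self.study_id,
            "weight_range": list(self.weight_range) if self.weight_range else None,
            "arms": [
                {
                    "label": a.label,
                    "cyp2d6_status": a.cyp2d6_status,
                    "n_subjects": a.n_subjects,
                    "regimen": dataclasses.asdict(a.regimen),
                    "sampling_times": list(a.sampling_times),
                }
                for a in self.arms
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyDesign":
        arms = tuple(
            StudyArm(
                label=a["label"],
                cyp2d6_status=a["cyp2d6_status"],
                n_subjects=a["n_subjects"],
                regimen=eng.DosingRegimen(**a["regimen"]),
                sampling_times=tuple(a["sampling_times"]),
            )
            for a in d["arms"]
        )
        wr = d.get("weight_range")
        return cls(study_id=d["study_id"], arms=arms, weight_range=tuple(wr) if wr else None)


@dataclass(frozen=True)
class NoiseSpec:
    """Between-subject and residual variability specification."""

    bsv_cvs: Mapping[str, float] = field(default_factory=dict)  # parameter path -> CV
    residual_proportional_cv: float = 0.0
    residual_additive_sd: float = 0.0  # µg/L
    lloq: float = 0.0  # µg/L
    seed: int = 0

    def __post_init__(self) -> None:
        for path, cv in self.bsv_cvs.items():
            if cv < 0:
                raise ValidationError(f"BSV CV for {path} must be >= 0")
        if self.residual_proportional_cv < 0 or self.residual_additive_sd < 0 or self.lloq < 0:
            raise ValidationError("noise magnitudes must be >= 0")


@dataclass
class StudyDataset:
    """Arm-structured observed (or simulated-observed) concentration data."""

    design: StudyDesign
    records: pd.DataFrame  # subject_id, arm, analyte, time_h, conc, bql_flag
    truth: dict | None = None  # generating parameters, if synthetic

    def __post_init__(self) -> None:
        missing = [c for c in REQUIRED_COLUMNS if c not in self.records.columns]
        if missing:
            raise ValidationError(f"records missing required columns: {missing}")
        arm_labels = {a.label for a in self.design.arms}
        bad = set(self.records["arm"].unique()) - arm_labels
        if bad:
            raise ValidationError(f"records reference undeclared arms: {sorted(bad)}")
        if (self.records["time_h"] < 0).any():
            raise ValidationError("negative times in records")
        if "bql_flag" in self.records.columns:
            ok = self.records["bql_flag"] | (self.records["conc"] >= 0)
            if not ok.all():
                raise ValidationError("negative concentrations without BQL flag")


def generate_study(
    design: StudyDesign,
    truth_model: eng.PBPKModel,
    curve: ScalingCurve,
    noise: NoiseSpec,
    em_reduction_fraction: float = 0.3,
    duration_pad: float = 0.0,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> StudyDataset:
    """Simulate a clinical study from a known truth model.

    Per subject: draw median-preserving log-normal parameter factors and a
    body weight, apply the arm's CYP2D6 status through the scaling curve,
    simulate the individual, then corrupt the simulated concentrations with
    combined proportional + additive residual error and censor below the
    LLOQ (BQL rows are retained, flagged, with the noisy value clipped at
    zero).  Byte-identical output for identical seeds.
    """
    rng = np.random.default_rng(noise.seed)
    bsv_paths = sorted(noise.bsv_cvs)
    rows = []
    for arm in design.arms:
        arm_model = model_for_cyp2d6_status(
            truth_model, curve, arm.cyp2d6_status, em_reduction_fraction
        )
        duration = max(arm.sampling_times) + duration_pad
        analytes = arm_model.compound_names
        for subj in range(arm.n_subjects):
            m = arm_model
            if design.weight_range is not None:
                lo, hi = design.weight_range
                bw = float(rng.uniform(lo, hi))
                m = dataclasses.replace(m, physiology=m.physiology.scaled_to_weight(bw))
            updates = {}
            for path in bsv_paths:
                cv = noise.bsv_cvs[path]
                if cv > 0:
                    sigma = float(np.sqrt(np.log1p(cv * cv)))
                    updates[path] = m.get_param(path) * float(np.exp(rng.normal(0, sigma)))
            if updates:
                m = m.with_params(updates)
            res = eng.simulate(
                m, arm.regimen, duration, times=arm.sampling_times, rtol=rtol, atol=atol
            )
            for analyte in analytes:
                clean = np.asarray(res.profile(analyte).concentrations)
                eps_p = rng.normal(0.0, noise.residual_proportional_cv, clean.size)
                eps_a = rng.normal(0.0, noise.residual_additive_sd, clean.size)
                obs = clean * (1.0 + eps_p) + eps_a
                obs = np.maximum(obs, 0.0)
                bql = obs < noise.lloq
                for t, c, flag in zip(arm.sampling_times, obs, bql):
                    rows.append(
                        {
                            "subject_id": f"{arm.label}-{subj + 1:03d}",
                            "arm": arm.label,
                            "analyte": analyte,
                            "time_h": float(t),
                            "conc": float(c),
                            "bql_flag": bool(flag),
                        }
                    )
    records = pd.DataFrame(rows)
    truth = {
        "parameters": {
            f"processes.{p.name}.kcat" if p.kind == "michaelis_menten" else f"processes.{p.name}.cl_linear": (
                p.kcat if p.kind == "michaelis_menten" else p.cl_linear
            )
            for p in truth_model.processes
        },
        "seed": noise.seed,
    }
    return StudyDataset(design=design, records=records, truth=truth)


def summarize_arms(dataset: StudyDataset) -> pd.DataFrame:
    """Arithmetic mean ± sample SD per (arm, analyte, time).

    BQL observations are excluded from the summary; timepoints where every
    observation is BQL are flagged missing (NaN mean) with ``n_bql`` noted.
    """
    df = dataset.records.copy()
    if df.empty:
        raise DomainError("empty dataset")
    if "bql_flag" not in df.columns:
        df["bql_flag"] = False
    out = []
    for (arm, analyte, t), grp in df.groupby(["arm", "analyte", "time_h"], sort=True):
        usable = grp.loc[~grp["bql_flag"], "conc"]
        out.append(
            {
                "arm": arm,
                "analyte": analyte,
                "time_h": t,
                "mean": float(usable.mean()) if len(usable) else float("nan"),
                "sd": float(usable.std(ddof=1)) if len(usable) > 1 else 0.0,
                "n": int(len(usable)),
                "n_bql": int(grp["bql_flag"].sum()),
            }
        )
    return pd.DataFrame(out)


def write_dataset(dataset: StudyDataset, path: str | Path) -> None:
    """Write records as tidy CSV with a JSON design sidecar (lossless)."""
    path = Path(path)
    dataset.records.to_csv(path, index=False)
    sidecar = path.with_suffix(".design.json")
    payload = {"design": dataset.design.to_dict(), "truth": dataset.truth}
    sidecar.write_text(json.dumps(payload, indent=1))


def read_dataset(path: str | Path) -> StudyDataset:
    """Read a tidy CSV + design sidecar written by :func:`write_dataset`."""
    path = Path(path)
    records = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns: {missing}")
    if "bql_flag" in records.columns:
        records["bql_flag"] = records["bql_flag"].astype(bool)
    sidecar = path.with_suffix(".design.json")
    if not sidecar.exists():
        raise ValidationError(f"design sidecar {sidecar} not found")
    payload = json.loads(sidecar.read_text())
    design = StudyDesign.from_dict(payload["design"])
    return StudyDataset(design=design, records=records, truth=payload.get("truth"))
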