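"""Concrete drug model builders and the steady-state DGI application.

Three packaged templates implement the metabolic topologies of the modeled
CYP2D6 substrates:

* **paroxetine** — CYP2D6 + CYP3A4 + unspecific hepatic clearance +
  glomerular filtration, with mechanism-based auto-inhibition of CYP2D6 and
  CYP3A4 (the inactivator is its own substrate, so repeated dosing
  suppresses its own clearance).
* **atomoxetine** — CYP2D6 + CYP2C19 + glomerular filtration; CYP2D6
  carries ~90% of oral clearance in AS = 2 populations.
* **risperidone** — parent-metabolite model: CYP2D6 and CYP3A4 each form
  the active metabolite 9-hydroxyrisperidone and other metabolites; 9-OH
  carries its own unspecific hepatic clearance.  DGI exposure is assessed
  on the active moiety (parent + 9-OH, summed in molar units).

Template kinetic parameters other than the optimized AS = 2 CYP2D6 k_cat
baselines are calibration placeholders, not reproductions of any published
parameter table; they are sized so that the qualitative clearance structure
above holds.

``apply_activity_score`` rescales every CYP2D6 k_cat via the fitted scaling
curve while leaving K_M, the CYP2D6 reference concentration and all other
parameters untouched.
"""

from __future__ import annotations

import copy
import dataclasses
import importlib.resources
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import engine as eng
from .errors import DomainError, ValidationError
from .physiology import PhysiologyTable, reference_adult
from .scaling import ScalingCurve, traditional_em_kcat

__all__ = [
    "DRUG_NAMES",
    "DGIScenario",
    "DGIResult",
    "load_template",
    "make_drug_model",
    "standard_regimen",
    "em_reduction",
    "apply_activity_score",
    "model_for_cyp2d6_status",
    "run_dgi_scenario",
]

DRUG_NAMES = ("paroxetine", "atomoxetine", "risperidone")

#: Required process structure per template, checked after assembly:
#: (kind, enzyme or None) -> expected count; plus inactivation targets.
_REQUIRED = {
    "paroxetine": {
        "processes": {
            ("michaelis_menten", "CYP2D6"): 1,
            ("michaelis_menten", "CYP3A4"): 1,
            ("first_order_hepatic", None): 1,
            ("glomerular_filtration", None): 1,
        },
        "inactivation_targets": {"CYP2D6", "CYP3A4"},
        "n_compounds": 1,
    },
    "atomoxetine": {
        "processes": {
            ("michaelis_menten", "CYP2D6"): 1,
            ("michaelis_menten", "CYP2C19"): 1,
            ("glomerular_filtration", None): 1,
        },
        "inactivation_targets": set(),
        "n_compounds": 1,
    },
    "risperidone": {
        "processes": {
            ("michaelis_menten", "CYP2D6"): 2,
            ("michaelis_menten", "CYP3A4"): 2,
            ("first_order_hepatic", None): 1,
        },
        "inactivation_targets": set(),
        "n_compounds": 2,
    },
}


def load_template(name: str) -> dict:
    """Load the packaged YAML template for one of the model drugs."""
    if name not in DRUG_NAMES:
        raise ValidationError(f"unknown drug {name!r}; choose from {DRUG_NAMES}")
    ref = importlib.resources.files("pbpkdgi.data.drugs") / f"{name}.yaml"
    with importlib.resources.as_file(ref) as path:
        with open(path) as fh:
            return yaml.safe_load(fh)


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if isinstance(val, Mapping) and isinstance(out.get(key), dict):
            out[key] = _deep_merge(out[key], val)
        else:
            out[key] = copy.deepcopy(val)
    return out


def _merge_overrides(cfg: dict, parameter_config: Mapping | None) -> dict:
    """Apply overrides; process/compound lists are merged entry-wise by name."""
    if not parameter_config:
        return cfg
    cfg = copy.deepcopy(cfg)
    for key, val in parameter_config.items():
        if key in ("processes", "compounds", "inactivations") and isinstance(val, Mapping):
            entries = {e["name"]: e for e in cfg.get(key, [])}
            for name, patch in val.items():
                if name not in entries:
                    raise ValidationError(f"override for unknown {key[:-1]} {name!r}")
                entries[name] = _deep_merge(entries[name], patch)
            cfg[key] = list(entries.values())
        elif isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key] = _deep_merge(cfg[key], val)
        else:
            cfg[key] = val
    return cfg


def _build_from_config(cfg: dict, physiology: PhysiologyTable | None) -> eng.PBPKModel:
    name = cfg.get("name", "?")
    try:
        compounds = [
            eng.CompoundProperties(
                name=c["name"],
                molecular_weight=c["molecular_weight"],
                fraction_unbound=c["fraction_unbound"],
                lipophilicity=c.get("lipophilicity", 2.0),
                blood_plasma_ratio=c.get("blood_plasma_ratio", 1.0),
                partition_coefficients=c.get("partition_coefficients", {}),
            )
            for c in cfg.get("compounds", [])
        ]
        processes = [
            eng.ClearanceProcess(
                kind=p["kind"],
                compound=p["compound"],
                name=p["name"],
                enzyme_label=p.get("enzyme_label"),
                kcat=p.get("kcat", 0.0),
                km=p.get("km", 1.0),
                cl_linear=p.get("cl_linear", 0.0),
                product_links=tuple((m, f) for m, f in p.get("product_links", [])),
            )
            for p in cfg.get("processes", [])
        ]
        inactivations = [
            eng.InactivationProcess(
                inhibitor_compound=i["inhibitor_compound"],
                target_enzyme_label=i["target_enzyme_label"],
                kinact=i["kinact"],
                ki=i["ki"],
                name=i.get("name", ""),
            )
            for i in cfg.get("inactivations", []) or []
        ]
    except KeyError as exc:
        raise ValidationError(f"{name}: missing required parameter {exc} in config") from exc
    if not compounds:
        raise ValidationError(f"{name}: config declares no compounds")
    return eng.build_model(
        physiology or reference_adult(), compounds, processes, inactivations
    )


def _check_topology(name: str, model: eng.PBPKModel) -> None:
    req = _REQUIRED[name]
    counts: dict[tuple[str, str | None], int] = {}
    for p in model.processes:
        key = (p.kind, p.enzyme_label if p.kind == "michaelis_menten" else None)
        counts[key] = counts.get(key, 0) + 1
    for key, n_expected in req["processes"].items():
        kind, enz = key
        label = f"{kind}" + (f"[{enz}]" if enz else "")
        if counts.get(key, 0) != n_expected:
            raise ValidationError(
                f"{name}: pathway {label} requires exactly {n_expected} process(es), "
                f"found {counts.get(key, 0)}"
            )
    extra_2d6 = counts.get(("michaelis_menten", "CYP2D6"), 0) - req["processes"].get(
        ("michaelis_menten", "CYP2D6"), 0
    )
    if extra_2d6 > 0:
        raise ValidationError(f"{name}: extra CYP2D6 processes are not allowed")
    targets = {i.target_enzyme_label for i in model.inactivations}
    if targets != req["inactivation_targets"]:
        raise ValidationError(
            f"{name}: inactivation targets must be {sorted(req['inactivation_targets'])}, "
            f"found {sorted(targets)}"
        )
    if len(model.compounds) != req["n_compounds"]:
        raise ValidationError(
            f"{name}: expected {req['n_compounds']} compound(s), found {len(model.compounds)}"
        )
    if name == "risperidone":
        if "9-hydroxyrisperidone" not in model.compound_names:
            raise ValidationError("risperidone: metabolite 9-hydroxyrisperidone missing")
        hep = [p for p in model.processes if p.kind == "first_order_hepatic"]
        if not any(p.compound == "9-hydroxyrisperidone" for p in hep):
            raise ValidationError(
                "risperidone: 9-hydroxyrisperidone requires an unspecific hepatic clearance"
            )


def make_drug_model(
    name: str,
    parameter_config: Mapping | None = None,
    physiology: PhysiologyTable | None = None,
) -> eng.PBPKModel:
    """Build a validated drug model from its packaged template.

    ``parameter_config`` overrides template entries (processes/compounds
    keyed by name, e.g. ``{"processes": {"ATO_CYP2D6": {"km": 3.0}}}``).
    The assembled model must carry exactly the template's pathway structure;
    extra CYP2D6 processes are rejected.
    """
    cfg = _merge_overrides(load_template(name), parameter_config)
    model = _build_from_config(cfg, physiology)
    _check_topology(name, model)
    return model


def standard_regimen(name: str, **overrides) -> eng.DosingRegimen:
    """The template's steady-state dosing regimen, with optional overrides."""
    cfg = dict(load_template(name)["standard_regimen"])
    cfg.update(overrides)
    return eng.DosingRegimen(**cfg)


def em_reduction(name: str) -> float:
    """Compound-specific k_cat reduction of traditional EM arms vs AS = 1.25."""
    return float(load_template(name)["em_reduction"])


def apply_activity_score(
    model: eng.PBPKModel, curve: ScalingCurve, score: float
) -> eng.PBPKModel:
    """Rescale every CYP2D6 k_cat to an activity score.

    k_cat(AS) = kcat_rel(AS) * baseline(AS = 2); K_M, the enzyme reference
    concentration and all non-CYP2D6 parameters are untouched.  Idempotent
    for a fixed score and inverted by reapplying score 2.
    """
    if not model.cyp2d6_baselines:
        raise ValidationError("model has no CYP2D6 Michaelis-Menten process")
    rel = curve.kcat_rel(score)
    updates = {
        f"processes.{name}.kcat": rel * baseline
        for name, baseline in model.cyp2d6_baselines.items()
    }
    # mark the score first so with_params preserves the AS = 2 baselines
    marked = dataclasses.replace(model, applied_activity_score=float(score))
    return marked.with_params(updates)


def model_for_cyp2d6_status(
    model: eng.PBPKModel,
    curve: ScalingCurve,
    status: float | str,
    em_reduction_fraction: float = 0.3,
) -> eng.PBPKModel:
    """Parameterize a model for an activity score or a phenotype label.

    Numeric statuses use the scaling curve directly; ``"PM"`` maps to
    AS = 0; ``"EM"`` applies the compound-specific reduction below the
    AS = 1.25 k_cat (traditional extensive-metabolizer arms pool
    heterogeneous genotypes and sit below AS 1.25 activity).
    """
    if isinstance(status, str):
        label = status.upper()
        if label == "PM":
            return apply_activity_score(model, curve, 0.0)
        if label == "EM":
            if not model.cyp2d6_baselines:
                raise ValidationError("model has no CYP2D6 Michaelis-Menten process")
            updates = {
                f"processes.{name}.kcat": traditional_em_kcat(
                    curve.scale_kcat(baseline, 1.25), em_reduction_fraction
                )
                for name, baseline in model.cyp2d6_baselines.items()
            }
            # NaN marker: phenotype-applied, AS = 2 baselines must survive
            marked = dataclasses.replace(model, applied_activity_score=float("nan"))
            return marked.with_params(updates)
        raise ValidationError(f"unknown CYP2D6 status label {status!r}")
    return apply_activity_score(model, curve, float(status))


@dataclass(frozen=True)
class DGIScenario:
    """Steady-state exposure comparison across CYP2D6 activity scores."""

    drug: str
    regimen: eng.DosingRegimen
    activity_scores: tuple[float, ...]
    reference_score: float = 2.0
    active_moiety: bool = False
    parameter_config: Mapping | None = None

    def __post_init__(self) -> None:
        if self.reference_score not in self.activity_scores:
            raise ValidationError("reference score must be among the activity scores")


@dataclass
class DGIResult:
    """Per-score steady-state AUC and ratio versus the reference score."""

    table: pd.DataFrame  # activity_score, analyte, auc_ss, ratio_vs_ref
    window: tuple[float, float]
    warnings: list[str] = field(default_factory=list)

    def ratio(self, score: float, analyte: str | None = None) -> float:
        df = self.table
        if analyte is not None:
            df = df[df["analyte"] == analyte]
        row = df[np.isclose(df["activity_score"], score)]
        if row.empty:
            raise DomainError(f"no result for activity score {score}")
        return float(row["ratio_vs_ref"].iloc[0])


def run_dgi_scenario(
    scenario: DGIScenario,
    curve: ScalingCurve,
    duration: float = 28 * 24.0,
    window: tuple[float, float] = (24 * 24.0, 28 * 24.0),
    grid: float = 0.5,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> DGIResult:
    """Simulate multiple dosing to steady state for each activity score.

    AUC_ss is the trapezoidal AUC over the window (default days 24-28).
    For active-moiety scenarios the parent and metabolite profiles are
    summed in molar units before integration.  The ratio at the reference
    score is exactly 1.
    """
    import warnings as _warnings

    base = make_drug_model(scenario.drug, scenario.parameter_config)
    analyte = (
        f"{scenario.drug} active moiety" if scenario.active_moiety else base.compound_names[0]
    )
    aucs: dict[float, float] = {}
    collected: list[str] = []
    for score in scenario.activity_scores:
        m = apply_activity_score(base, curve, score)
        res = eng.simulate(m, scenario.regimen, duration, grid=grid, rtol=rtol, atol=atol)
        if scenario.active_moiety:
            conc = sum(
                res.plasma_concentration(c) for c in base.compound_names
            )  # µmol/L molar sum
            prof = eng.ConcentrationTimeProfile(
                analyte, tuple(res.times), tuple(np.maximum(conc, 0.0)),
                dose_context=scenario.regimen, units="umol_per_L",
            )
        else:
            prof = res.profile(base.compound_names[0])
        with _warnings.catch_warnings(record=True) as caught:
            _warnings.simplefilter("always", eng.NonStationaryWarning)
            aucs[score] = eng.steady_state_window_auc(prof, window)
            collected.extend(
                f"AS {score}: {w.message}" for w in caught
                if issubclass(w.category, eng.NonStationaryWarning)
            )
    ref = aucs[scenario.reference_score]
    rows = [
        {
            "activity_score": s,
            "analyte": analyte,
            "auc_ss": aucs[s],
            "ratio_vs_ref": 1.0 if s == scenario.reference_score else aucs[s] / ref,
        }
        for s in scenario.activity_scores
    ]
    return DGIResult(table=pd.DataFrame(rows), window=window, warnings=collected)
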