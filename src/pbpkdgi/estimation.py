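"""Staged model fitting and local sensitivity analysis.

Base models are built sequentially, freezing parameters stage by stage:

1. **partition_selection** — choose among candidate partition-coefficient
   sets by smallest residual error (IV data preferred when present).
2. **absorption** — fit the first-order absorption rate against
   oral-solution arms.
3. **non_cyp2d6** — fit CYP2D6-independent clearance parameters against
   poor-metabolizer arms (where CYP2D6 is genuinely absent).
4. **cyp2d6** — fit the CYP2D6 k_cat baselines against AS = 2 or
   extensive-metabolizer arms.

Stages lacking the data they need are skipped with a report entry rather
than failing.  The objective is the sum of squared residuals on log10
concentrations by default (concentration data span decades); a linear-scale
option is retained.

The optimizer is a seeded, contracting log-multiplicative random search —
candidate parameters are drawn multiplicatively around the incumbent within
bounds, with the search width contracted on a fixed schedule — followed by
a deterministic Nelder-Mead polish in log space.  It never returns a loss
above its starting loss and is bit-reproducible for a fixed seed.

Local sensitivity follows the one-at-a-time convention: a +100% parameter
perturbation, S = (dAUC/AUC0) / (dp/p0) on the AUC over 0-24 h of a single
standard dose; |S| > 0.5 flags a sensitive parameter.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from . import engine as eng
from .drugs import model_for_cyp2d6_status
from .errors import DomainError, FitError, PairingError
from .metrics import auc_last
from .scaling import ScalingCurve
from .synthdata import StudyArm, StudyDataset

__all__ = [
    "FittingStage",
    "OptimizeResult",
    "StageReport",
    "SequentialFitResult",
    "SensitivityResult",
    "objective_value",
    "monte_carlo_optimize",
    "sequential_fit",
    "local_sensitivity",
]


def _split_params(params: Mapping[str, float]) -> tuple[dict, dict]:
    model_p = {k: v for k, v in params.items() if not k.startswith("regimen.")}
    reg_p = {k.split(".", 1)[1]: v for k, v in params.items() if k.startswith("regimen.")}
    return model_p, reg_p


def _arm_status_is_pm(arm: StudyArm) -> bool:
    s = arm.cyp2d6_status
    return (isinstance(s, str) and s.upper() == "PM") or (
        not isinstance(s, str) and float(s) == 0.0
    )


def _arm_status_is_reference(arm: StudyArm) -> bool:
    s = arm.cyp2d6_status
    return (isinstance(s, str) and s.upper() == "EM") or (
        not isinstance(s, str) and float(s) == 2.0
    )


def objective_value(
    model: eng.PBPKModel,
    curve: ScalingCurve,
    datasets: Sequence[StudyDataset],
    params: Mapping[str, float] | None = None,
    scale: str = "sse_log",
    arm_filter: Callable[[StudyArm], bool] | None = None,
    em_reduction_fraction: float = 0.3,
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> float:
    """Sum of squared residuals of model predictions against study records.

    Every non-BQL, positive observation of an analyte the model carries
    contributes one residual; predictions are computed per arm at the arm's
    sampling times with the arm's CYP2D6 status applied.  ``params`` may
    override model parameters (dotted paths) and regimen fields
    (``regimen.<field>``, applied to every arm).
    """
    if scale not in ("sse_log", "sse_linear"):
        raise DomainError(f"unknown objective scale {scale!r}")
    if not datasets:
        raise PairingError("no datasets supplied")
    model_p, reg_p = _split_params(params or {})
    if model_p:
        model = model.with_params(model_p)
    sse = 0.0
    matched = 0
    for ds in datasets:
        for arm in ds.design.arms:
            if arm_filter is not None and not arm_filter(arm):
                continue
            recs = ds.records[ds.records["arm"] == arm.label]
            if recs.empty:
                continue
            arm_model = model_for_cyp2d6_status(
                model, curve, arm.cyp2d6_status, em_reduction_fraction
            )
            regimen = (
                dataclasses.replace(arm.regimen, **reg_p) if reg_p else arm.regimen
            )
            res = eng.simulate(
                arm_model,
                regimen,
                duration=max(arm.sampling_times),
                times=arm.sampling_times,
                rtol=rtol,
                atol=atol,
            )
            t_grid = np.asarray(arm.sampling_times)
            for analyte in arm_model.compound_names:
                sub = recs[recs["analyte"] == analyte]
                if sub.empty:
                    continue
                pred_c = np.asarray(res.profile(analyte).concentrations)
                bql = (
                    sub["bql_flag"]
                    if "bql_flag" in sub.columns
                    else np.zeros(len(sub), dtype=bool)
                )
                obs = sub[(~np.asarray(bql)) & (sub["conc"] > 0)]
                pred = np.interp(obs["time_h"].to_numpy(), t_grid, pred_c)
                y = obs["conc"].to_numpy()
                if scale == "sse_log":
                    pos = pred > 0
                    resid = np.log10(np.maximum(pred[pos], 1e-300)) - np.log10(y[pos])
                    # predictions at exactly zero: maximal penalty per point
                    sse += float(np.sum(resid**2)) + 1e4 * int(np.sum(~pos))
                    matched += int(np.sum(pos))
                else:
                    resid = pred - y
                    sse += float(np.sum(resid**2))
                    matched += len(y)
    if matched == 0:
        raise PairingError("no matched timepoints between model and datasets")
    return sse


@dataclass
class OptimizeResult:
    params: dict[str, float]
    loss: float
    initial_loss: float
    n_evaluations: int
    trace: list[tuple[int, float]] = field(repr=False, default_factory=list)


def monte_carlo_optimize(
    objective: Callable[[Mapping[str, float]], float],
    initial: Mapping[str, float],
    bounds: Mapping[str, tuple[float, float]],
    iterations: int = 300,
    seed: int = 0,
    contraction: float = 0.7,
    block: int = 30,
    polish: bool = True,
) -> OptimizeResult:
    """Seeded contracting random search over positive parameters.

    Candidates are drawn log-multiplicatively around the incumbent within
    ``bounds``; the proposal width starts at the full bound width and is
    multiplied by ``contraction`` every ``block`` iterations.  An optional
    deterministic Nelder-Mead polish in log space refines the best point.
    The result never exceeds the initial loss.
    """
    keys = sorted(initial)
    if not keys:
        raise FitError("empty parameter set")
    if iterations < 1:
        raise FitError("iterations must be >= 1")
    for k in keys:
        lo, hi = bounds[k]
        if not (0 < lo <= hi) or not np.isfinite(hi):
            raise FitError(f"bounds for {k} must be positive and finite")
    rng = np.random.default_rng(seed)
    log_lo = np.array([np.log(bounds[k][0]) for k in keys])
    log_hi = np.array([np.log(bounds[k][1]) for k in keys])
    x = np.clip(np.log([initial[k] for k in keys]), log_lo, log_hi)

    def f(logx: np.ndarray) -> float:
        return float(objective({k: float(np.exp(v)) for k, v in zip(keys, logx)}))

    n_eval = 1
    best_x, best_f = x.copy(), f(x)
    initial_loss = best_f
    trace = [(0, best_f)]
    width0 = log_hi - log_lo
    for i in range(1, iterations + 1):
        w = width0 * contraction ** (i // block)
        cand = np.clip(best_x + rng.uniform(-0.5, 0.5, len(keys)) * w, log_lo, log_hi)
        fc = f(cand)
        n_eval += 1
        if fc < best_f:
            best_x, best_f = cand, fc
            trace.append((i, fc))
    if polish:
        def f_clip(z: np.ndarray) -> float:
            return f(np.clip(z, log_lo, log_hi))

        res = minimize(
            f_clip,
            best_x,
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-12, "maxfev": 120 * len(keys)},
        )
        n_eval += res.nfev
        z = np.clip(res.x, log_lo, log_hi)
        fz = f(z)
        n_eval += 1
        if fz < best_f:
            best_x, best_f = z, fz
            trace.append((iterations + res.nfev, fz))
    return OptimizeResult(
        params={k: float(np.exp(v)) for k, v in zip(keys, best_x)},
        loss=best_f,
        initial_loss=initial_loss,
        n_evaluations=n_eval,
        trace=trace,
    )


@dataclass(frozen=True)
class FittingStage:
    """One stage of the sequential workflow."""

    name: str  # partition_selection | absorption | non_cyp2d6 | cyp2d6
    free_parameters: tuple[str, ...]
    objective: str = "sse_log"
    arm_predicate: Callable[[StudyArm], bool] | None = None


@dataclass
class StageReport:
    name: str
    status: str  # "fitted" | "skipped"
    detail: str = ""
    params: dict[str, float] = field(default_factory=dict)
    initial_loss: float = float("nan")
    final_loss: float = float("nan")


@dataclass
class SequentialFitResult:
    model: eng.PBPKModel
    regimen_overrides: dict[str, float]
    stages: list[StageReport]

    def fitted_param(self, path: str) -> float:
        if path.startswith("regimen."):
            return self.regimen_overrides[path.split(".", 1)[1]]
        return self.model.get_param(path)


def _default_bounds(value: float, factor: float) -> tuple[float, float]:
    return (value / factor, value * factor)


def sequential_fit(
    template_model: eng.PBPKModel,
    curve: ScalingCurve,
    datasets: Sequence[StudyDataset],
    non_cyp2d6_parameters: Sequence[str] = (),
    partition_candidates: Sequence[Mapping[str, Mapping[str, float]]] = (),
    fit_ka: bool = True,
    iterations: int = 250,
    seed: int = 0,
    bound_factor: float = 30.0,
    em_reduction_fraction: float = 0.3,
    scale: str = "sse_log",
    rtol: float = 1e-6,
    atol: float = 1e-9,
) -> SequentialFitResult:
    """Run the four-stage sequential fitting workflow.

    Parameters fixed by earlier stages stay frozen in later stages.  Stages
    whose data requirement is not met (no IV/solution arms, no PM arms, no
    AS = 2/EM arms) are skipped with a report entry.  Deterministic for a
    fixed seed.
    """
    model = template_model
    reg_overrides: dict[str, float] = {}
    reports: list[StageReport] = []

    def obj_for(free: Mapping[str, float], predicate) -> float:
        return objective_value(
            model,
            curve,
            datasets,
            params={**free, **{f"regimen.{k}": v for k, v in reg_overrides.items()}},
            scale=scale,
            arm_filter=predicate,
            em_reduction_fraction=em_reduction_fraction,
            rtol=rtol,
            atol=atol,
        )

    def arms_exist(predicate) -> bool:
        return any(
            predicate(arm) and not ds.records[ds.records["arm"] == arm.label].empty
            for ds in datasets
            for arm in ds.design.arms
        )

    # stage 1: partition selection among candidate sets
    if len(partition_candidates) > 1:
        def is_iv(arm: StudyArm) -> bool:
            return arm.regimen.route == "iv_infusion"

        predicate = is_iv if arms_exist(is_iv) else None
        losses = []
        for cand in partition_candidates:
            comps = tuple(
                dataclasses.replace(c, partition_coefficients=dict(cand.get(c.name, c.partition_coefficients)))
                for c in model.compounds
            )
            m = dataclasses.replace(model, compounds=comps)
            losses.append(
                objective_value(
                    m, curve, datasets, scale=scale, arm_filter=predicate,
                    em_reduction_fraction=em_reduction_fraction, rtol=rtol, atol=atol,
                )
            )
        best = int(np.argmin(losses))
        comps = tuple(
            dataclasses.replace(c, partition_coefficients=dict(partition_candidates[best].get(c.name, c.partition_coefficients)))
            for c in model.compounds
        )
        model = dataclasses.replace(model, compounds=comps)
        reports.append(
            StageReport(
                "partition_selection", "fitted",
                detail=f"selected candidate {best} of {len(partition_candidates)}",
                initial_loss=float(losses[0]), final_loss=float(losses[best]),
            )
        )
    else:
        reports.append(
            StageReport("partition_selection", "skipped", detail="fewer than 2 candidate sets")
        )

    # stage 2: absorption (ka) against oral-solution arms
    def is_solution(arm: StudyArm) -> bool:
        return arm.regimen.route == "oral_solution"

    if fit_ka and arms_exist(is_solution):
        ka0 = next(
            arm.regimen.ka
            for ds in datasets for arm in ds.design.arms if is_solution(arm)
        )
        res = monte_carlo_optimize(
            lambda p: objective_value(
                model, curve, datasets, params=dict(p),
                scale=scale, arm_filter=is_solution,
                em_reduction_fraction=em_reduction_fraction, rtol=rtol, atol=atol,
            ),
            initial={"regimen.ka": ka0},
            bounds={"regimen.ka": _default_bounds(ka0, 10.0)},
            iterations=iterations,
            seed=seed,
        )
        reg_overrides["ka"] = res.params["regimen.ka"]
        reports.append(
            StageReport("absorption", "fitted", params=dict(res.params),
                        initial_loss=res.initial_loss, final_loss=res.loss)
        )
    else:
        reports.append(
            StageReport("absorption", "skipped", detail="no oral-solution arms (or fit_ka=False)")
        )

    # stage 3: CYP2D6-independent clearance against PM arms
    if non_cyp2d6_parameters and arms_exist(_arm_status_is_pm):
        initial = {p: model.get_param(p) for p in non_cyp2d6_parameters}
        res = monte_carlo_optimize(
            lambda p: obj_for(p, _arm_status_is_pm),
            initial=initial,
            bounds={k: _default_bounds(v, bound_factor) for k, v in initial.items()},
            iterations=iterations,
            seed=seed + 1,
        )
        model = model.with_params(res.params)
        reports.append(
            StageReport("non_cyp2d6", "fitted", params=dict(res.params),
                        initial_loss=res.initial_loss, final_loss=res.loss)
        )
    else:
        reports.append(
            StageReport("non_cyp2d6", "skipped",
                        detail="no poor-metabolizer arms or no free parameters")
        )

    # stage 4: CYP2D6 k_cat baselines against AS = 2 / EM arms
    cyp2d6_paths = tuple(f"processes.{n}.kcat" for n in sorted(model.cyp2d6_baselines))
    if cyp2d6_paths and arms_exist(_arm_status_is_reference):
        initial = {p: model.get_param(p) for p in cyp2d6_paths}
        res = monte_carlo_optimize(
            lambda p: obj_for(p, _arm_status_is_reference),
            initial=initial,
            bounds={k: _default_bounds(v, bound_factor) for k, v in initial.items()},
            iterations=iterations,
            seed=seed + 2,
        )
        model = model.with_params(res.params)
        reports.append(
            StageReport("cyp2d6", "fitted", params=dict(res.params),
                        initial_loss=res.initial_loss, final_loss=res.loss)
        )
    else:
        reports.append(
            StageReport("cyp2d6", "skipped", detail="no AS = 2 or EM arms")
        )
    return SequentialFitResult(model=model, regimen_overrides=reg_overrides, stages=reports)


@dataclass(frozen=True)
class SensitivityResult:
    parameter_path: str
    perturbation: float
    sensitivity: float
    sensitive_flag: bool
    skipped: bool = False
    detail: str = ""


def _auc_0_t(
    model: eng.PBPKModel,
    regimen: eng.DosingRegimen,
    analyte: str,
    window: tuple[float, float],
    grid: float,
    rtol: float,
    atol: float,
) -> float:
    res = eng.simulate(model, regimen, duration=window[1], grid=grid, rtol=rtol, atol=atol)
    prof = res.profile(analyte)
    return auc_last(prof.times, prof.concentrations, window[0], window[1])


def local_sensitivity(
    model: eng.PBPKModel,
    regimen: eng.DosingRegimen,
    parameters: Sequence[str],
    perturbation: float = 1.0,
    analyte: str | None = None,
    window: tuple[float, float] = (0.0, 24.0),
    threshold: float = 0.5,
    grid: float = 0.1,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> list[SensitivityResult]:
    """One-at-a-time local sensitivity of AUC to relative parameter changes.

    S = ((AUC_p - AUC_0)/AUC_0) / ((p - p_0)/p_0) with a default +100%
    perturbation; the base model is left untouched (each probe works on a
    copy).  Parameters at exactly zero are reported as skipped (a relative
    perturbation is undefined there).  |S| > ``threshold`` flags a
    sensitive parameter.
    """
    if perturbation == 0:
        raise DomainError("perturbation must be nonzero")
    analyte = analyte or model.compound_names[0]
    auc0 = _auc_0_t(model, regimen, analyte, window, grid, rtol, atol)
    if auc0 <= 0:
        raise DomainError("base AUC is zero; sensitivity undefined")
    results = []
    for path in parameters:
        if path.startswith("regimen."):
            fld = path.split(".", 1)[1]
            p0 = float(getattr(regimen, fld))
        else:
            p0 = model.get_param(path)
        if p0 == 0.0:
            results.append(
                SensitivityResult(path, perturbation, float("nan"), False, True,
                                  "base value is zero; relative perturbation undefined")
            )
            continue
        p_new = p0 * (1.0 + perturbation)
        if path.startswith("regimen."):
            reg_p = dataclasses.replace(regimen, **{path.split(".", 1)[1]: p_new})
            auc_p = _auc_0_t(model, reg_p, analyte, window, grid, rtol, atol)
        else:
            auc_p = _auc_0_t(model.with_params({path: p_new}), regimen, analyte, window, grid, rtol, atol)
        s = ((auc_p - auc0) / auc0) / perturbation
        results.append(SensitivityResult(path, perturbation, float(s), abs(s) > threshold))
    return results
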