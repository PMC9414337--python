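"""Model-evaluation statistics for PK profiles and exposure ratios.

Implements the standard goodness-of-prediction suite used for PBPK model
qualification:

* ``auc_last`` — linear trapezoidal AUC between the first and last observation.
* ``mrd`` — mean relative deviation, 10 raised to the root-mean-square
  log10 prediction error of plasma concentrations.
* ``gmfe`` — geometric mean fold error, 10 raised to the mean absolute
  log10 fold error of summary PK parameters (AUC_last, C_max) across studies.
* ``dgi_ratio`` — drug-gene-interaction PK ratio, variant over reference
  (AS = 2 or the extensive-metabolizer arm).
* ``guest_limits`` — ratio-dependent prediction-success band (Guest et al.):
  1.25-fold acceptance near a ratio of 1, widening asymptotically to 2-fold.
* ``two_fold_fraction`` — fraction of predictions within 2-fold (inclusive).

All log-scale metrics require strictly positive values; below-quantification
or zero observations must be excluded upstream (``evaluate_study`` does this
and reports the excluded count).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, PairingError

__all__ = [
    "PredictionObservationSet",
    "StudyPKPair",
    "GuestLimit",
    "EvaluationReport",
    "auc_last",
    "cmax",
    "mrd",
    "gmfe",
    "dgi_ratio",
    "guest_limits",
    "two_fold_fraction",
    "evaluate_study",
]


@dataclass(frozen=True)
class PredictionObservationSet:
    """Paired observed/predicted concentrations at common timepoints."""

    times: tuple[float, ...]
    observed: tuple[float, ...]
    predicted: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.times) == len(self.observed) == len(self.predicted)):
            raise DomainError("times, observed and predicted must have equal length")

    @property
    def k(self) -> int:
        return len(self.observed)


@dataclass(frozen=True)
class StudyPKPair:
    """One study-level PK parameter pair (AUC_last or C_max)."""

    study_id: str
    metric: str  # "auc_last" | "cmax"
    observed: float
    predicted: float

    def __post_init__(self) -> None:
        if self.observed <= 0 or self.predicted <= 0:
            raise DomainError(
                f"study {self.study_id}: PK values must be > 0 "
                f"(observed={self.observed}, predicted={self.predicted})"
            )


@dataclass(frozen=True)
class GuestLimit:
    """Prediction-success band around an observed interaction ratio."""

    observed_ratio: float
    delta: float
    lower: float
    upper: float

    def contains(self, predicted_ratio: float) -> bool:
        return self.lower <= predicted_ratio <= self.upper


def auc_last(
    times: Sequence[float],
    concentrations: Sequence[float],
    t_first: float | None = None,
    t_last: float | None = None,
) -> float:
    """Linear trapezoidal AUC over [t_first, t_last] (default: full range).

    The profile is linearly interpolated at the window boundaries, matching
    the convention of evaluating predictions at observed timepoints.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise DomainError("times must be a strictly increasing vector of length >= 2")
    lo = t[0] if t_first is None else float(t_first)
    hi = t[-1] if t_last is None else float(t_last)
    if not (lo < hi):
        raise DomainError(f"require t_first < t_last, got [{lo}, {hi}]")
    if lo < t[0] or hi > t[-1]:
        raise DomainError(
            f"window [{lo}, {hi}] outside profile range [{t[0]}, {t[-1]}]"
        )
    grid = np.unique(np.concatenate([[lo, hi], t[(t > lo) & (t < hi)]]))
    if grid.size < 2:
        raise DomainError("fewer than 2 points in the AUC window")
    vals = np.interp(grid, t, c)
    return float(np.trapezoid(vals, grid))


def cmax(concentrations: Sequence[float]) -> float:
    """Maximum concentration of a profile."""
    c = np.asarray(concentrations, dtype=float)
    if c.size == 0:
        raise DomainError("empty profile")
    return float(np.max(c))


def _check_positive_pairs(observed: np.ndarray, predicted: np.ndarray) -> None:
    bad = np.flatnonzero((observed <= 0) | (predicted <= 0))
    if bad.size:
        raise DomainError(
            f"log-scale metric requires positive concentrations; offending indices: {bad.tolist()}"
        )


def mrd(pairs: PredictionObservationSet, root: bool = True) -> float:
    """Mean relative deviation of predicted vs observed concentrations.

    With ``root=True`` (default) this is 10**sqrt(mean(squared log10 error)),
    so a single uniform 2-fold error yields exactly 2.0.  ``root=False``
    computes 10**mean(squared log10 error), the literal reading of some
    printed formulas; both are >= 1.
    """
    if pairs.k < 1:
        raise DomainError("MRD requires at least one pair")
    obs = np.asarray(pairs.observed, dtype=float)
    pred = np.asarray(pairs.predicted, dtype=float)
    _check_positive_pairs(obs, pred)
    sq = (np.log10(pred) - np.log10(obs)) ** 2
    x = float(np.mean(sq))
    return float(10.0 ** (np.sqrt(x) if root else x))


def gmfe(pairs: Sequence[StudyPKPair]) -> float:
    """Geometric mean fold error across study-level PK parameter pairs."""
    if len(pairs) < 1:
        raise DomainError("GMFE requires at least one study pair")
    folds = np.array([abs(np.log10(p.predicted / p.observed)) for p in pairs])
    return float(10.0 ** np.mean(folds))


def dgi_ratio(pk_variant: float, pk_reference: float) -> float:
    """Variant-over-reference PK ratio (Eq. PK_DGI / PK_reference)."""
    if pk_reference <= 0:
        raise DomainError(f"reference PK value must be > 0, got {pk_reference}")
    return pk_variant / pk_reference


def guest_limits(observed_ratio: float, delta: float = 1.25) -> GuestLimit:
    """Ratio-dependent prediction-success limits of Guest et al.

    With R~ = max(R, 1/R) the fold-acceptance is L = (delta + 2 (R~ - 1)) / R~;
    the band is [R/L, R*L].  L equals ``delta`` at R = 1 and tends to 2 for
    extreme ratios, reproducing the curved limits of interaction-ratio
    comparison plots.
    """
    if observed_ratio <= 0:
        raise DomainError(f"observed ratio must be > 0, got {observed_ratio}")
    if delta < 1:
        raise DomainError(f"delta must be >= 1, got {delta}")
    r = float(observed_ratio)
    r_sym = max(r, 1.0 / r)
    limit = (delta + 2.0 * (r_sym - 1.0)) / r_sym
    return GuestLimit(observed_ratio=r, delta=delta, lower=r / limit, upper=r * limit)


def two_fold_fraction(pairs: PredictionObservationSet) -> float:
    """Fraction of predictions within [0.5, 2]-fold of their observation.

    Boundaries are inclusive: a prediction at exactly 2-fold counts as inside.
    """
    if pairs.k < 1:
        raise DomainError("two-fold fraction requires at least one pair")
    obs = np.asarray(pairs.observed, dtype=float)
    pred = np.asarray(pairs.predicted, dtype=float)
    _check_positive_pairs(obs, pred)
    ratio = pred / obs
    return float(np.mean((ratio >= 0.5) & (ratio <= 2.0)))


@dataclass
class EvaluationReport:
    """Per-arm and aggregate model-performance summary for one study."""

    arm_table: pd.DataFrame  # arm, analyte, auc_obs, auc_pred, cmax_obs, cmax_pred, mrd, ...
    ratio_table: pd.DataFrame  # arm, metric, ratio_obs, ratio_pred, guest_lower/upper, guest_pass
    summary: Mapping[str, float]
    excluded_points: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_json_dict(self) -> dict:
        return {
            "summary": dict(self.summary),
            "excluded_points": self.excluded_points,
            "warnings": list(self.warnings),
            "arms": self.arm_table.to_dict(orient="records"),
            "ratios": self.ratio_table.to_dict(orient="records"),
        }


def _interp_prediction(pred_t, pred_c, obs_t) -> np.ndarray:
    pred_t = np.asarray(pred_t, float)
    pred_c = np.asarray(pred_c, float)
    return np.interp(np.asarray(obs_t, float), pred_t, pred_c)


def evaluate_study(
    predicted: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    observed: Mapping[str, tuple[Sequence[float], Sequence[float]]],
    reference_arm: str | None = None,
    delta: float = 1.25,
    study_id: str = "study",
) -> EvaluationReport:
    """Evaluate predicted against observed mean profiles, arm by arm.

    Parameters
    ----------
    predicted, observed:
        Mapping ``arm label -> (times_h, concentrations)``.  Predicted
        profiles are linearly interpolated at the observed timepoints.
    reference_arm:
        Arm used as the denominator of DGI ratios.  Defaults to ``"AS2"``,
        ``"2"``, ``"2.0"`` or ``"EM"`` if present; if none is found, ratios
        are omitted.

    Observed non-positive concentrations are excluded from log-scale metrics
    and counted in ``excluded_points``.
    """
    arms = sorted(observed)
    missing = [a for a in arms if a not in predicted]
    if missing:
        raise PairingError(f"arms without predictions: {missing}")
    if reference_arm is None:
        for cand in ("AS2", "2", "2.0", "EM"):
            if cand in arms:
                reference_arm = cand
                break
    elif reference_arm not in arms:
        raise PairingError(f"reference arm {reference_arm!r} not in observed arms {arms}")

    excluded = 0
    arm_rows = []
    all_obs: list[float] = []
    all_pred: list[float] = []
    auc_pairs: list[StudyPKPair] = []
    cmax_pairs: list[StudyPKPair] = []
    per_arm: dict[str, dict[str, float]] = {}
    for arm in arms:
        obs_t, obs_c = (np.asarray(v, float) for v in observed[arm])
        pred_t, pred_c = (np.asarray(v, float) for v in predicted[arm])
        pred_at_obs = _interp_prediction(pred_t, pred_c, obs_t)
        keep = obs_c > 0
        excluded += int(np.sum(~keep))
        if np.sum(keep) < 2:
            raise PairingError(f"arm {arm!r}: fewer than 2 positive observations")
        pset = PredictionObservationSet(
            tuple(obs_t[keep]), tuple(obs_c[keep]), tuple(pred_at_obs[keep])
        )
        arm_auc_obs = auc_last(obs_t[keep], obs_c[keep])
        arm_auc_pred = auc_last(obs_t[keep], pred_at_obs[keep])
        arm_cmax_obs = cmax(obs_c[keep])
        arm_cmax_pred = cmax(pred_at_obs[keep])
        arm_mrd = mrd(pset)
        per_arm[arm] = {
            "auc_obs": arm_auc_obs,
            "auc_pred": arm_auc_pred,
            "cmax_obs": arm_cmax_obs,
            "cmax_pred": arm_cmax_pred,
        }
        all_obs.extend(obs_c[keep].tolist())
        all_pred.extend(pred_at_obs[keep].tolist())
        auc_pairs.append(StudyPKPair(f"{study_id}:{arm}", "auc_last", arm_auc_obs, arm_auc_pred))
        cmax_pairs.append(StudyPKPair(f"{study_id}:{arm}", "cmax", arm_cmax_obs, arm_cmax_pred))
        arm_rows.append({"arm": arm, "mrd": arm_mrd, **per_arm[arm]})

    ratio_rows = []
    warnings: list[str] = []
    if reference_arm is not None:
        ref = per_arm[reference_arm]
        for arm in arms:
            if arm == reference_arm:
                continue
            for metric, okey, pkey in (
                ("auc_last", "auc_obs", "auc_pred"),
                ("cmax", "cmax_obs", "cmax_pred"),
            ):
                r_obs = dgi_ratio(per_arm[arm][okey], ref[okey])
                r_pred = dgi_ratio(per_arm[arm][pkey], ref[pkey])
                lim = guest_limits(r_obs, delta=delta)
                ratio_rows.append(
                    {
                        "arm": arm,
                        "metric": metric,
                        "ratio_obs": r_obs,
                        "ratio_pred": r_pred,
                        "guest_lower": lim.lower,
                        "guest_upper": lim.upper,
                        "guest_pass": lim.contains(r_pred),
                    }
                )
    else:
        warnings.append("no reference arm found; DGI ratios omitted")

    pooled = PredictionObservationSet(
        tuple(range(len(all_obs))), tuple(all_obs), tuple(all_pred)
    )
    ratio_df = pd.DataFrame(
        ratio_rows,
        columns=["arm", "metric", "ratio_obs", "ratio_pred", "guest_lower", "guest_upper", "guest_pass"],
    )
    summary = {
        "mrd": mrd(pooled),
        "gmfe_auc_last": gmfe(auc_pairs),
        "gmfe_cmax": gmfe(cmax_pairs),
        "two_fold_fraction": two_fold_fraction(pooled),
        "n_arms": float(len(arms)),
        "guest_pass_fraction": (
            float(ratio_df["guest_pass"].mean()) if len(ratio_df) else float("nan")
        ),
    }
    return EvaluationReport(
        arm_table=pd.DataFrame(arm_rows),
        ratio_table=ratio_df,
        summary=summary,
        excluded_points=excluded,
        warnings=warnings,
    )
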