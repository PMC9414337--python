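"""CYP2D6 activity-score scaling of enzymatic turnover.

The CYP2D6 activity score (AS) translates a diplotype into a graded measure
of enzyme activity (0 = no activity, 2 = two fully functional alleles).
Published PBPK models of the probe substrates metoprolol and dextromethorphan
report CYP2D6 catalytic rate constants (k_cat) per activity score, expressed
relative to AS = 2.  Pooling those relative values and fitting a quadratic
polynomial through the origin yields a substrate-independent scaling law

    kcat_rel(AS) = (a * AS**2 + b * AS) / f(2),       f(2) = 4 a + 2 b,

which converts any drug's optimized AS = 2 k_cat into the k_cat for an
arbitrary activity score.  K_M and the enzyme reference concentration are
left untouched by the scaling: the k_cat acts as a lumped surrogate for
expression- and turnover-level differences between genotypes.

The origin constraint encodes the biology: a poor metabolizer (AS = 0)
expresses no functional CYP2D6, so the relative activity is exactly zero.
"""

from __future__ import annotations

import enum
import importlib.resources
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, FitError

__all__ = [
    "GRID_SCORES",
    "TABLE2_BASELINES",
    "KcatRelPoint",
    "ScalingCurve",
    "KcatTable",
    "Phenotype",
    "load_reference_points",
    "fit_kcat_rel_polynomial",
    "kcat_rel",
    "scale_kcat",
    "build_kcat_table",
    "phenotype_from_activity_score",
    "traditional_em_kcat",
]

#: Activity scores with published relative-k_cat support.
GRID_SCORES: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0, 3.0)

#: Optimized AS = 2 baseline k_cat values (1/min) per CYP2D6 pathway:
#: paroxetine, atomoxetine, risperidone -> 9-OH-risperidone and
#: risperidone -> other metabolites.
TABLE2_BASELINES: Mapping[str, float] = {
    "PAR": 4.09,
    "ATO": 103.82,
    "RIS_9HR": 3.19,
    "RIS_other": 1.94,
}


def is_on_grid(score: float, tol: float = 1e-9) -> bool:
    """True if ``score`` is one of the activity scores with published support."""
    return any(abs(score - g) <= tol for g in GRID_SCORES)


def _check_score(score: float) -> float:
    score = float(score)
    if not np.isfinite(score) or score < 0:
        raise DomainError(f"activity score must be a finite number >= 0, got {score}")
    return score


@dataclass(frozen=True)
class KcatRelPoint:
    """One relative-k_cat observation: (activity score, % of the AS = 2 value)."""

    activity_score: float
    kcat_rel: float  # percent of the AS = 2 value
    source_substrate: str = "other"  # "metoprolol" | "dextromethorphan" | other

    def __post_init__(self) -> None:
        _check_score(self.activity_score)
        if not np.isfinite(self.kcat_rel) or self.kcat_rel < 0:
            raise DomainError(f"kcat_rel must be >= 0, got {self.kcat_rel}")


@dataclass(frozen=True)
class ScalingCurve:
    """Fitted quadratic-through-origin scaling law on the percent scale.

    Attributes
    ----------
    a, b:
        Coefficients of AS**2 and AS (%/AS**2 and %/AS).
    normalization_value:
        Fitted polynomial evaluated at AS = 2 (percent); relative values for
        k_cat scaling are poly(AS)/normalization_value so that AS = 2 maps to
        exactly 1.
    r_squared:
        Coefficient of determination under the no-intercept convention
        (total sum of squares taken about zero).
    """

    a: float
    b: float
    normalization_value: float
    fit_points: tuple[KcatRelPoint, ...] = field(repr=False, default=())
    r_squared: float = float("nan")

    def poly(self, score: float) -> float:
        """Polynomial value in percent at an activity score."""
        s = _check_score(score)
        return self.a * s * s + self.b * s

    def kcat_rel(self, score: float) -> float:
        """Relative k_cat as a fraction of the AS = 2 value (1.0 at AS = 2)."""
        s = _check_score(score)
        if s == 0.0:
            return 0.0  # poor metabolizers carry no functional enzyme
        return self.poly(s) / self.normalization_value

    def scale_kcat(self, baseline_kcat_as2: float, score: float) -> float:
        """Scale an AS = 2 baseline k_cat (any rate unit) to another score."""
        if baseline_kcat_as2 < 0:
            raise DomainError(f"baseline k_cat must be >= 0, got {baseline_kcat_as2}")
        return self.kcat_rel(score) * baseline_kcat_as2


class Phenotype(enum.Enum):
    """CYP2D6 metabolizer phenotype categories.

    The first four are the consensus activity-score bins; EXTENSIVE is the
    older, traditionally phenotyped category that overlaps but does not equal
    NORMAL and cannot be derived from an activity score.
    """

    POOR = "poor"
    INTERMEDIATE = "intermediate"
    NORMAL = "normal"
    ULTRARAPID = "ultrarapid"
    EXTENSIVE = "extensive"


def load_reference_points() -> list[KcatRelPoint]:
    """Load the packaged metoprolol/dextromethorphan relative-k_cat values.

    Returns the pooled list of finite entries including the (0, 0) anchors,
    the input of the substrate-independent regression.
    """
    ref = importlib.resources.files("pbpkdgi.data") / "kcat_rel_table2.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    points: list[KcatRelPoint] = []
    for _, row in df.iterrows():
        for col, label in (("met_rel", "metoprolol"), ("dex_rel", "dextromethorphan")):
            if pd.notna(row[col]):
                points.append(
                    KcatRelPoint(float(row["activity_score"]), float(row[col]), label)
                )
    return points


def fit_kcat_rel_polynomial(points: Iterable[KcatRelPoint]) -> ScalingCurve:
    """Fit the degree-2, no-intercept OLS polynomial to relative k_cat points.

    Minimizes sum((y - a x**2 - b x)**2) over the pooled points.  Requires at
    least three distinct activity scores, at least one of them nonzero.
    """
    pts = tuple(points)
    x = np.array([p.activity_score for p in pts], dtype=float)
    y = np.array([p.kcat_rel for p in pts], dtype=float)
    if len(set(x.tolist())) < 3:
        raise FitError(
            f"need >= 3 distinct activity scores for a degree-2 fit, got {len(set(x.tolist()))}"
        )
    if np.all(x == 0):
        raise FitError("singular design: all activity scores are zero")
    design = np.column_stack([x * x, x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < 2:
        raise FitError("singular design matrix in no-intercept quadratic fit")
    a, b = float(coef[0]), float(coef[1])
    normalization = a * 4.0 + b * 2.0
    if normalization <= 0:
        raise FitError(f"fitted curve non-positive at AS = 2 ({normalization:.4g})")
    residuals = y - design @ coef
    ss_res = float(residuals @ residuals)
    ss_tot = float(y @ y)  # no-intercept convention: total SS about zero
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return ScalingCurve(a=a, b=b, normalization_value=normalization, fit_points=pts, r_squared=r2)


def kcat_rel(curve: ScalingCurve, score: float) -> float:
    """Relative k_cat (fraction of AS = 2) for ``score`` under ``curve``."""
    return curve.kcat_rel(score)


def scale_kcat(curve: ScalingCurve, baseline_kcat_as2: float, score: float) -> float:
    """k_cat (same unit as the baseline) at ``score`` given the AS = 2 baseline."""
    return curve.scale_kcat(baseline_kcat_as2, score)


@dataclass(frozen=True)
class KcatTable:
    """Activity-score grid of relative and absolute CYP2D6 k_cat values."""

    table: pd.DataFrame  # index: activity_score; kcat_rel_pct, on_grid, kcat_<pathway>
    baselines: Mapping[str, float]

    def kcat(self, pathway: str, score: float) -> float:
        return float(self.table.loc[score, f"kcat_{pathway}"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="activity_score")


def build_kcat_table(
    curve: ScalingCurve,
    baselines: Mapping[str, float] | None = None,
    scores: Sequence[float] = GRID_SCORES,
) -> KcatTable:
    """Tabulate scaled k_cat values per pathway over an activity-score grid.

    The AS = 0 row is exactly zero and the AS = 2 row equals the baselines
    exactly (the scaling is normalized at AS = 2).  Scores without published
    support are flagged via the ``on_grid`` column.
    """
    if baselines is None:
        baselines = TABLE2_BASELINES
    scores = [float(s) for s in scores]
    if not scores:
        raise DomainError("empty activity-score grid")
    for name, kb in baselines.items():
        if kb < 0:
            raise DomainError(f"baseline k_cat for {name} must be >= 0, got {kb}")
    rows = []
    for s in scores:
        rel = curve.kcat_rel(s)
        row = {"kcat_rel_pct": rel * 100.0, "on_grid": is_on_grid(s)}
        for name, kb in baselines.items():
            row[f"kcat_{name}"] = rel * kb
        rows.append(row)
    df = pd.DataFrame(rows, index=pd.Index(scores, name="activity_score"))
    return KcatTable(table=df, baselines=dict(baselines))


def phenotype_from_activity_score(score: float) -> Phenotype:
    """Consensus phenotype bin for an activity score.

    poor iff AS = 0; intermediate iff 0 < AS <= 1; normal iff 1 < AS <= 2.25;
    ultrarapid iff AS > 2.25.
    """
    s = _check_score(score)
    if s == 0.0:
        return Phenotype.POOR
    if s <= 1.0:
        return Phenotype.INTERMEDIATE
    if s <= 2.25:
        return Phenotype.NORMAL
    return Phenotype.ULTRARAPID


def traditional_em_kcat(kcat_at_1_25: float, reduction_fraction: float) -> float:
    """k_cat for a traditionally phenotyped extensive-metabolizer population.

    Study arms reported only as "EM" pool heterogeneous genotypes; their
    effective k_cat sits below the AS = 1.25 value by a compound-specific
    reduction fraction.
    """
    if kcat_at_1_25 < 0:
        raise DomainError(f"k_cat must be >= 0, got {kcat_at_1_25}")
    if not (0.0 <= reduction_fraction < 1.0):
        raise DomainError(
            f"reduction fraction must be in [0, 1), got {reduction_fraction}"
        )
    return kcat_at_1_25 * (1.0 - reduction_fraction)
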