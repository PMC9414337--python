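"""Whole-body PBPK ODE engine.

The engine integrates drug amounts (µmol) over a reduced, perfusion-limited
circulatory topology (see :mod:`pbpkdgi.physiology`): cardiac output passes
venous blood through the lung to arterial blood; tissues equilibrate with
their perfusing blood and drain back to the venous pool, the gut via the
portal vein into the liver.  Concentrations are treated as plasma-equivalent
throughout; partition coefficients are tissue:plasma ratios.

Clearance processes:

* Michaelis-Menten enzymatic clearance in the liver,
  v = kcat * E * S / (K_M + S), with S the unbound liver concentration
  (f_u * C_liver / Kp_liver) and E the active hepatic enzyme amount
  (reference concentration x liver volume).  kcat is accepted in 1/min and
  converted to 1/h internally.
* First-order hepatic clearance on the unbound liver concentration.
* Glomerular filtration, GFR * f_u * C_kidney/Kp_kidney.
* Generic linear transport acting on venous plasma (surrogate for e.g.
  efflux-transporter-mediated elimination).

Mechanism-based inactivation adds one state per targeted enzyme:
dE/dt = kdeg * (E0 - E) - kinact * I_u / (K_I + I_u) * E, with I_u the
unbound liver concentration of the inhibitor.  MM processes read the current
active amount, so multiple dosing of an inactivator suppresses its own (and
co-substrates') metabolism over time.

Doses are exact-time events: oral doses are impulses into a first-order
absorption depot feeding the gut wall (bioavailable fraction applied at
depot entry), IV administrations are boluses or zero-order infusions into
venous blood.  Integration restarts at every dose boundary (LSODA, rtol
1e-8 / atol 1e-10 by default), and per-compound cumulative elimination and
metabolic formation are co-integrated so that mass balance can be audited:
amount in body + eliminated = administered + formed.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import DomainError, IntegrationError, ValidationError
from .physiology import DIRECT_TISSUES, PhysiologyTable

__all__ = [
    "CompoundProperties",
    "ClearanceProcess",
    "InactivationProcess",
    "DosingRegimen",
    "ConcentrationTimeProfile",
    "VariabilitySpec",
    "PBPKModel",
    "SimulationResult",
    "PopulationResult",
    "build_model",
    "default_partition_set",
    "simulate",
    "simulate_population",
    "steady_state_window_auc",
    "mass_balance_error",
]

MIN_PER_H = 60.0


def default_partition_set(lipophilicity: float) -> dict[str, float]:
    """Heuristic tissue:plasma partition coefficients from a logP-like scalar.

    Kp = 1 + f_lipid * (10**logP)**0.6, capped at 30.  A coarse fallback:
    drug templates normally supply measured/calibrated coefficients directly.
    """
    lipid = {
        "lung": 0.06,
        "liver": 0.08,
        "gut": 0.06,
        "kidney": 0.05,
        "adipose": 0.80,
        "muscle": 0.05,
        "rest": 0.05,
    }
    p_eff = (10.0**lipophilicity) ** 0.6
    kps = {name: min(1.0 + f * p_eff, 30.0) for name, f in lipid.items()}
    kps["venous_blood"] = 1.0
    kps["arterial_blood"] = 1.0
    kps["central"] = 1.0
    return kps


@dataclass(frozen=True)
class CompoundProperties:
    name: str
    molecular_weight: float  # g/mol
    fraction_unbound: float
    lipophilicity: float = 2.0  # logP-like scalar, drives the default Kp heuristic
    blood_plasma_ratio: float = 1.0
    pka: float | None = None  # metadata only
    partition_coefficients: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.molecular_weight <= 0:
            raise ValidationError(f"{self.name}: molecular weight must be > 0")
        if not (0 < self.fraction_unbound <= 1):
            raise ValidationError(f"{self.name}: fraction unbound must be in (0, 1]")
        if self.blood_plasma_ratio <= 0:
            raise ValidationError(f"{self.name}: blood:plasma ratio must be > 0")

    def partition(self, compartment: str, default: float = 1.0) -> float:
        if compartment in ("venous_blood", "arterial_blood", "central"):
            return 1.0
        if compartment in self.partition_coefficients:
            return float(self.partition_coefficients[compartment])
        return float(default_partition_set(self.lipophilicity).get(compartment, default))


@dataclass(frozen=True)
class ClearanceProcess:
    """One elimination (or biotransformation) pathway of a compound."""

    kind: str  # michaelis_menten | first_order_hepatic | glomerular_filtration | linear_transport
    compound: str
    name: str
    enzyme_label: str | None = None  # MM only
    kcat: float = 0.0  # 1/min (MM only); for CYP2D6 this is the AS = 2 baseline
    km: float = 1.0  # µmol/L (MM only)
    cl_linear: float = 0.0  # L/h (first-order kinds)
    product_links: tuple[tuple[str, float], ...] = ()  # (metabolite, stoichiometric fraction)

    KINDS = ("michaelis_menten", "first_order_hepatic", "glomerular_filtration", "linear_transport")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"process {self.name}: unknown kind {self.kind!r}")
        if self.kind == "michaelis_menten":
            if self.enzyme_label is None:
                raise ValidationError(f"process {self.name}: MM requires an enzyme label")
            if self.kcat < 0:
                raise ValidationError(f"process {self.name}: kcat must be >= 0")
            if self.km <= 0:
                raise ValidationError(f"process {self.name}: K_M must be > 0")
        elif self.cl_linear < 0:
            raise ValidationError(f"process {self.name}: cl_linear must be >= 0")
        frac = sum(f for _, f in self.product_links)
        if frac > 1.0 + 1e-12 or any(f < 0 for _, f in self.product_links):
            raise ValidationError(
                f"process {self.name}: stoichiometric fractions must be >= 0 and sum to <= 1"
            )


@dataclass(frozen=True)
class InactivationProcess:
    """Mechanism-based (irreversible) inactivation of a hepatic enzyme."""

    inhibitor_compound: str
    target_enzyme_label: str
    kinact: float  # 1/h
    ki: float  # µmol/L
    name: str = ""

    def __post_init__(self) -> None:
        if self.kinact < 0:
            raise ValidationError(f"inactivation {self.name}: kinact must be >= 0")
        if self.ki <= 0:
            raise ValidationError(f"inactivation {self.name}: K_I must be > 0")


@dataclass(frozen=True)
class DosingRegimen:
    route: str  # oral_solution | oral_tablet | iv_infusion
    dose: float  # mg
    n_doses: int = 1
    interval: float = 24.0  # h
    ka: float = 1.0  # 1/h (oral)
    infusion_duration: float = 0.0  # h (IV; 0 = bolus)
    lag: float = 0.0  # h (oral tablet dissolution lag)
    bioavailable_fraction_released: float = 1.0
    compound: str | None = None  # defaults to the model's first compound

    ROUTES = ("oral_solution", "oral_tablet", "iv_infusion")

    def __post_init__(self) -> None:
        if self.route not in self.ROUTES:
            raise ValidationError(f"unknown route {self.route!r}")
        if self.dose <= 0:
            raise ValidationError("dose must be > 0")
        if self.n_doses < 1:
            raise ValidationError("n_doses must be >= 1")
        if self.n_doses > 1 and self.interval <= 0:
            raise ValidationError("interval must be > 0 for multiple dosing")
        if self.route.startswith("oral") and self.ka <= 0:
            raise ValidationError("oral dosing requires ka > 0")
        if not (0 < self.bioavailable_fraction_released <= 1):
            raise ValidationError("bioavailable fraction must be in (0, 1]")

    @property
    def is_oral(self) -> bool:
        return self.route.startswith("oral")

    def dose_times(self) -> np.ndarray:
        return self.lag + self.interval * np.arange(self.n_doses)


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """A plasma concentration-time series for one analyte."""

    analyte: str
    times: tuple[float, ...]  # h
    concentrations: tuple[float, ...]  # µg/L (or µmol/L if units says so)
    dose_context: DosingRegimen | None = None
    statistic: str = "individual"  # individual | population_mean | population_sd
    units: str = "ug_per_L"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        if t.size and np.any(np.diff(t) <= 0):
            raise ValidationError("profile times must be strictly increasing")
        if any(c < 0 for c in self.concentrations):
            raise ValidationError("profile concentrations must be >= 0")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times, float), np.asarray(self.concentrations, float)


@dataclass(frozen=True)
class VariabilitySpec:
    """Log-normal between-subject variability + body-weight demographics."""

    parameter_cvs: Mapping[str, float] = field(default_factory=dict)
    weight_range: tuple[float, float] | None = None  # kg, sampled uniformly
    seed: int = 0

    def __post_init__(self) -> None:
        for path, cv in self.parameter_cvs.items():
            if cv < 0:
                raise ValidationError(f"CV for {path} must be >= 0")
        if self.weight_range is not None:
            lo, hi = self.weight_range
            if not (0 < lo <= hi):
                raise ValidationError("weight range must satisfy 0 < lo <= hi")


@dataclass(frozen=True)
class PBPKModel:
    """Validated compartment topology + compounds + kinetic processes."""

    physiology: PhysiologyTable
    compounds: tuple[CompoundProperties, ...]
    processes: tuple[ClearanceProcess, ...]
    inactivations: tuple[InactivationProcess, ...] = ()
    #: AS = 2 baseline kcat per CYP2D6 MM process (recorded at build time).
    cyp2d6_baselines: Mapping[str, float] = field(default_factory=dict)
    applied_activity_score: float | None = None

    @property
    def compound_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.compounds)

    def compound(self, name: str) -> CompoundProperties:
        for c in self.compounds:
            if c.name == name:
                return c
        raise ValidationError(f"no compound named {name!r}")

    def process(self, name: str) -> ClearanceProcess:
        for p in self.processes:
            if p.name == name:
                return p
        raise ValidationError(f"no process named {name!r}")

    @property
    def enzyme_state_labels(self) -> tuple[str, ...]:
        """Enzymes with a dynamic (inactivatable) amount state."""
        return tuple(sorted({i.target_enzyme_label for i in self.inactivations}))

    @property
    def state_dimension(self) -> int:
        """Dynamical state count: compartments x compounds + enzyme states.

        Dosing depots and cumulative elimination/formation accumulators are
        appended at simulation time and are not part of the model dimension.
        """
        return len(self.physiology.compartments) * len(self.compounds) + len(
            self.enzyme_state_labels
        )

    # -- parameter access (dotted paths) ------------------------------------

    def get_param(self, path: str) -> float:
        kind, *rest = path.split(".")
        if kind == "physiology":
            return float(getattr(self.physiology, rest[0]))
        if kind == "compounds":
            name, attr = rest
            return float(getattr(self.compound(name), attr))
        if kind == "processes":
            name, attr = rest
            return float(getattr(self.process(name), attr))
        if kind == "inactivations":
            name, attr = rest
            for i in self.inactivations:
                if i.name == name:
                    return float(getattr(i, attr))
            raise ValidationError(f"no inactivation named {name!r}")
        raise ValidationError(f"unrecognized parameter path {path!r}")

    def with_params(self, updates: Mapping[str, float]) -> "PBPKModel":
        """Return a copy with dotted-path parameters replaced.

        Setting a CYP2D6 kcat while the model is at its as-built / AS = 2
        state also updates the recorded AS = 2 baseline, so that subsequent
        activity-score application scales from the new value.
        """
        model = self
        for path, value in updates.items():
            kind, *rest = path.split(".")
            value = float(value)
            if kind == "physiology":
                phys = dataclasses.replace(model.physiology, **{rest[0]: value})
                model = dataclasses.replace(model, physiology=phys)
            elif kind == "compounds":
                name, attr = rest
                comps = tuple(
                    dataclasses.replace(c, **{attr: value}) if c.name == name else c
                    for c in model.compounds
                )
                model.compound(name)  # existence check
                model = dataclasses.replace(model, compounds=comps)
            elif kind == "processes":
                name, attr = rest
                model.process(name)
                procs = tuple(
                    dataclasses.replace(p, **{attr: value}) if p.name == name else p
                    for p in model.processes
                )
                baselines = dict(model.cyp2d6_baselines)
                if (
                    attr == "kcat"
                    and name in baselines
                    and model.applied_activity_score in (None, 2.0)
                ):
                    baselines[name] = value
                model = dataclasses.replace(model, processes=procs, cyp2d6_baselines=baselines)
            elif kind == "inactivations":
                name, attr = rest
                if name not in {i.name for i in model.inactivations}:
                    raise ValidationError(f"no inactivation named {name!r}")
                inacts = tuple(
                    dataclasses.replace(i, **{attr: value}) if i.name == name else i
                    for i in model.inactivations
                )
                model = dataclasses.replace(model, inactivations=inacts)
            else:
                raise ValidationError(f"unrecognized parameter path {path!r}")
        return model


def build_model(
    physiology: PhysiologyTable,
    compounds: Sequence[CompoundProperties],
    processes: Sequence[ClearanceProcess] = (),
    inactivations: Sequence[InactivationProcess] = (),
) -> PBPKModel:
    """Assemble and validate a PBPK model.

    Checks that every process and inactivation references a declared
    compound/enzyme, that metabolite links point at declared compounds and
    that names are unique.  With no clearance processes the system is closed
    (mass-conserving).
    """
    compounds = tuple(compounds)
    names = [c.name for c in compounds]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate compound names: {names}")
    proc_names = [p.name for p in processes]
    if len(set(proc_names)) != len(proc_names):
        raise ValidationError(f"duplicate process names: {proc_names}")
    for p in processes:
        if p.compound not in names:
            raise ValidationError(f"process {p.name}: unknown compound {p.compound!r}")
        if p.kind == "michaelis_menten" and p.enzyme_label not in physiology.enzyme_pools:
            raise ValidationError(
                f"process {p.name}: enzyme {p.enzyme_label!r} has no pool in the physiology"
            )
        for met, _ in p.product_links:
            if met not in names:
                raise ValidationError(f"process {p.name}: unknown metabolite {met!r}")
    inacts = []
    for i, inact in enumerate(inactivations):
        if inact.inhibitor_compound not in names:
            raise ValidationError(
                f"inactivation: unknown inhibitor {inact.inhibitor_compound!r}"
            )
        if inact.target_enzyme_label not in physiology.enzyme_pools:
            raise ValidationError(
                f"inactivation: enzyme {inact.target_enzyme_label!r} has no pool"
            )
        if not inact.name:
            inact = dataclasses.replace(
                inact, name=f"{inact.inhibitor_compound}:{inact.target_enzyme_label}"
            )
        inacts.append(inact)
    baselines = {
        p.name: p.kcat
        for p in processes
        if p.kind == "michaelis_menten" and p.enzyme_label == "CYP2D6"
    }
    return PBPKModel(
        physiology=physiology,
        compounds=compounds,
        processes=tuple(processes),
        inactivations=tuple(inacts),
        cyp2d6_baselines=baselines,
    )


# ---------------------------------------------------------------------------
# compiled simulation
# ---------------------------------------------------------------------------


class _Compiled:
    """Precomputed index maps and constants for the ODE right-hand side."""

    def __init__(self, model: PBPKModel, regimen: DosingRegimen):
        phys = model.physiology
        self.model = model
        self.regimen = regimen
        self.comp_names = phys.names
        self.n_comp = len(self.comp_names)
        self.circulatory = phys.is_circulatory
        self.idx = {n: i for i, n in enumerate(self.comp_names)}
        self.volumes = np.array([c.volume for c in phys.compartments])
        self.n_cpd = len(model.compounds)
        self.per_cpd = self.n_comp + 3  # + depot, eliminated, formed
        self.depot_off = self.n_comp
        self.elim_off = self.n_comp + 1
        self.formed_off = self.n_comp + 2
        self.enzymes = model.enzyme_state_labels
        self.enz_idx = {e: self.n_cpd * self.per_cpd + i for i, e in enumerate(self.enzymes)}
        self.n_states = self.n_cpd * self.per_cpd + len(self.enzymes)
        self.cpd_idx = {c.name: i for i, c in enumerate(model.compounds)}

        if self.circulatory:
            self.liver_name, self.kidney_name = "liver", "kidney"
            self.co = phys.compartment("lung").blood_flow
            self.q = {n: phys.compartment(n).blood_flow for n in self.comp_names}
        else:
            self.liver_name = self.kidney_name = self.comp_names[0]
        self.liver_i = self.idx[self.liver_name]
        self.kidney_i = self.idx[self.kidney_name]
        self.liver_vol = self.volumes[self.liver_i]
        # per-compound partition vector
        defaults = [c.default_partition for c in phys.compartments]
        self.kp = np.array(
            [
                [cpd.partition(n, d) for n, d in zip(self.comp_names, defaults)]
                for cpd in model.compounds
            ]
        )
        self.fu = np.array([c.fraction_unbound for c in model.compounds])
        self.bp = np.array([c.blood_plasma_ratio for c in model.compounds])
        self.mw = np.array([c.molecular_weight for c in model.compounds])
        # enzyme pool totals (µmol) referenced to liver volume
        self.e0 = {
            label: pool.reference_concentration * self.liver_vol
            for label, pool in phys.enzyme_pools.items()
        }
        self.kdeg = {
            label: pool.turnover_kdeg for label, pool in phys.enzyme_pools.items()
        }
        self.gfr = phys.gfr
        self.dosed_cpd = self.cpd_idx[regimen.compound or model.compound_names[0]]
        self.ka = regimen.ka if regimen.is_oral else 0.0

    def base(self, ci: int) -> int:
        return ci * self.per_cpd

    def initial_state(self) -> np.ndarray:
        y = np.zeros(self.n_states)
        for e in self.enzymes:
            y[self.enz_idx[e]] = self.e0[e]
        return y

    def rhs(self, t: float, y: np.ndarray, infusion: np.ndarray) -> np.ndarray:
        dy = np.zeros_like(y)
        m = self.model
        liver_i, kidney_i = self.liver_i, self.kidney_i
        # unbound liver concentration per compound (plasma-equivalent)
        c_liv_u = np.empty(self.n_cpd)
        for ci in range(self.n_cpd):
            b = self.base(ci)
            a = y[b : b + self.n_comp]
            c_liv_u[ci] = max(
                self.fu[ci] * a[liver_i] / (self.volumes[liver_i] * self.kp[ci, liver_i]), 0.0
            )
        # enzyme dynamics
        active = {}
        for e in self.enzymes:
            active[e] = max(y[self.enz_idx[e]], 0.0)
        for inact in m.inactivations:
            e = inact.target_enzyme_label
            iu = c_liv_u[self.cpd_idx[inact.inhibitor_compound]]
            hazard = inact.kinact * iu / (inact.ki + iu)
            dy[self.enz_idx[e]] += (
                self.kdeg[e] * (self.e0[e] - y[self.enz_idx[e]]) - hazard * active[e]
            )
        # circulation + dosing per compound
        for ci in range(self.n_cpd):
            b = self.base(ci)
            a = y[b : b + self.n_comp]
            d = dy[b : b + self.n_comp]
            kp = self.kp[ci]
            if self.circulatory:
                iv, ia = self.idx["venous_blood"], self.idx["arterial_blood"]
                il, ig = self.idx["liver"], self.idx["gut"]
                c_ven = a[iv] / self.volumes[iv]
                c_art = a[ia] / self.volumes[ia]
                c_out = a / (self.volumes * kp)  # tissue venous-outflow concentrations
                co = self.co
                d[self.idx["lung"]] += co * (c_ven - c_out[self.idx["lung"]])
                d[ia] += co * c_out[self.idx["lung"]]
                total_q = 0.0
                for name in DIRECT_TISSUES:
                    i = self.idx[name]
                    qn = self.q[name]
                    d[i] += qn * (c_art - c_out[i])
                    d[iv] += qn * c_out[i]
                    total_q += qn
                q_gut, q_ha = self.q["gut"], self.q["liver"]
                d[ig] += q_gut * (c_art - c_out[ig])
                d[il] += q_ha * c_art + q_gut * c_out[ig] - (q_ha + q_gut) * c_out[il]
                d[iv] += (q_ha + q_gut) * c_out[il] - co * c_ven
                d[ia] -= (total_q + q_gut + q_ha) * c_art
                absorb_target = ig
                iv_target = iv
            else:
                absorb_target = 0
                iv_target = 0
            # dosing inputs
            if ci == self.dosed_cpd:
                if self.regimen.is_oral:
                    depot = y[b + self.depot_off]
                    rate = self.ka * depot
                    dy[b + self.depot_off] -= rate
                    d[absorb_target] += rate
                else:
                    d[iv_target] += infusion[ci]
            # clearance processes
            for p in m.processes:
                pc = self.cpd_idx[p.compound]
                if pc != ci:
                    continue
                if p.kind == "michaelis_menten":
                    e_amt = active.get(p.enzyme_label, self.e0[p.enzyme_label])
                    s = c_liv_u[ci]
                    v = (p.kcat * MIN_PER_H) * e_amt * s / (p.km + s)
                    d[liver_i] -= v
                elif p.kind == "first_order_hepatic":
                    v = p.cl_linear * c_liv_u[ci]
                    d[liver_i] -= v
                elif p.kind == "glomerular_filtration":
                    c_kid = max(
                        a[kidney_i] / (self.volumes[kidney_i] * kp[kidney_i]), 0.0
                    )
                    v = self.gfr * self.fu[ci] * c_kid
                    d[kidney_i] -= v
                else:  # linear_transport: acts on venous plasma
                    src = self.idx.get("venous_blood", 0)
                    c_src = max(a[src] / self.volumes[src], 0.0)
                    v = p.cl_linear * self.fu[ci] * c_src
                    d[src] -= v
                dy[b + self.elim_off] += v
                for met, frac in p.product_links:
                    mb = self.base(self.cpd_idx[met])
                    dy[mb + liver_i] += frac * v
                    dy[mb + self.formed_off] += frac * v
        return dy


@dataclass
class SimulationResult:
    """Trajectories of a single simulation, with unit-converting accessors."""

    times: np.ndarray  # h
    states: np.ndarray  # (n_times, n_states)
    model: PBPKModel
    regimen: DosingRegimen
    _compiled: _Compiled

    def _slice(self, compound: str) -> tuple[int, int]:
        ci = self._compiled.cpd_idx[compound]
        return ci, self._compiled.base(ci)

    def plasma_concentration(self, compound: str) -> np.ndarray:
        """Venous plasma concentration in µmol/L."""
        c = self._compiled
        ci, b = self._slice(compound)
        i = c.idx.get("venous_blood", 0)
        return np.maximum(self.states[:, b + i] / c.volumes[i], 0.0) / c.bp[ci]

    def profile(self, compound: str, units: str = "ug_per_L") -> ConcentrationTimeProfile:
        c = self._compiled
        ci, _ = self._slice(compound)
        conc = self.plasma_concentration(compound)
        if units == "ug_per_L":
            conc = conc * c.mw[ci]
        elif units != "umol_per_L":
            raise DomainError(f"unknown units {units!r}")
        return ConcentrationTimeProfile(
            analyte=compound,
            times=tuple(self.times),
            concentrations=tuple(conc),
            dose_context=self.regimen,
            units=units,
        )

    def total_amount(self, compound: str) -> np.ndarray:
        """Drug in body (compartments + depot), µmol."""
        c = self._compiled
        _, b = self._slice(compound)
        return self.states[:, b : b + c.n_comp].sum(axis=1) + self.states[:, b + c.depot_off]

    def eliminated(self, compound: str) -> np.ndarray:
        c = self._compiled
        _, b = self._slice(compound)
        return self.states[:, b + c.elim_off]

    def formed(self, compound: str) -> np.ndarray:
        c = self._compiled
        _, b = self._slice(compound)
        return self.states[:, b + c.formed_off]

    def administered(self, compound: str) -> np.ndarray:
        """Cumulative administered amount (µmol) on the output grid."""
        c = self._compiled
        ci, _ = self._slice(compound)
        out = np.zeros_like(self.times)
        if ci != c.dosed_cpd:
            return out
        reg = self.regimen
        dose_umol = reg.dose * 1000.0 / c.mw[ci]
        if reg.is_oral:
            dose_umol *= reg.bioavailable_fraction_released
            for td in reg.dose_times():
                out += np.where(self.times >= td - 1e-12, dose_umol, 0.0)
        elif reg.infusion_duration > 0:
            rate = dose_umol / reg.infusion_duration
            for td in reg.dose_times():
                out += rate * np.clip(self.times - td, 0.0, reg.infusion_duration)
        else:
            for td in reg.dose_times():
                out += np.where(self.times >= td - 1e-12, dose_umol, 0.0)
        return out

    def enzyme_amount(self, label: str) -> np.ndarray:
        c = self._compiled
        if label not in c.enz_idx:
            raise ValidationError(f"enzyme {label!r} has no dynamic state")
        return self.states[:, c.enz_idx[label]]


def simulate(
    model: PBPKModel,
    regimen: DosingRegimen,
    duration: float,
    grid: float = 0.1,
    times: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the model under a dosing regimen and sample plasma profiles.

    Parameters
    ----------
    duration:
        Total simulated time (h); must cover every dose.
    grid:
        Uniform output step (h), ignored when ``times`` is given.
    times:
        Explicit output timepoints (h), e.g. a sparse clinical sampling grid.
    """
    if rtol <= 0 or atol <= 0:
        raise DomainError("solver tolerances must be positive")
    comp = _Compiled(model, regimen)
    reg = regimen
    if reg.compound is not None and reg.compound not in model.compound_names:
        raise ValidationError(f"regimen compound {reg.compound!r} not in model")
    dose_times = reg.dose_times()
    if dose_times[-1] > duration + 1e-9:
        raise DomainError("duration does not cover all doses")
    if times is not None:
        t_out = np.asarray(times, dtype=float)
        if np.any(np.diff(t_out) <= 0) or t_out[0] < 0 or t_out[-1] > duration + 1e-9:
            raise DomainError("output times must be strictly increasing within [0, duration]")
    else:
        t_out = np.arange(0.0, duration + grid / 2, grid)

    ci = comp.dosed_cpd
    dose_umol = reg.dose * 1000.0 / comp.mw[ci]
    impulses: dict[float, float] = {}
    infusion_windows: list[tuple[float, float, float]] = []
    if reg.is_oral:
        for td in dose_times:
            impulses[td] = impulses.get(td, 0.0) + dose_umol * reg.bioavailable_fraction_released
    elif reg.infusion_duration > 0:
        rate = dose_umol / reg.infusion_duration
        for td in dose_times:
            infusion_windows.append((td, td + reg.infusion_duration, rate))
    else:
        for td in dose_times:
            impulses[td] = impulses.get(td, 0.0) + dose_umol

    breaks = {0.0, float(duration)}
    breaks.update(float(t) for t in impulses if t <= duration)
    for a, b_, _ in infusion_windows:
        breaks.update((float(a), float(min(b_, duration))))
    seg_bounds = sorted(breaks)

    y = comp.initial_state()
    out_states = np.empty((t_out.size, comp.n_states))
    filled = np.zeros(t_out.size, dtype=bool)
    for s0, s1 in zip(seg_bounds[:-1], seg_bounds[1:]):
        if s0 in impulses:
            # boundary samples belong to the starting segment: post-dose
            if reg.is_oral:
                y[comp.base(ci) + comp.depot_off] += impulses[s0]
            else:
                y[comp.base(ci) + comp.idx.get("venous_blood", 0)] += impulses[s0]
        inf = np.zeros(comp.n_cpd)
        for a, b_, rate in infusion_windows:
            if a <= s0 + 1e-12 and s1 <= b_ + 1e-12:
                inf[ci] += rate
        last_segment = s1 == seg_bounds[-1]
        mask = ~filled & (t_out >= s0) & ((t_out <= s1) if last_segment else (t_out < s1))
        t_eval = np.unique(np.concatenate([t_out[mask], [s1]]))
        sol = solve_ivp(
            comp.rhs,
            (s0, s1),
            y,
            method=method,
            t_eval=t_eval,
            rtol=rtol,
            atol=atol,
            args=(inf,),
            dense_output=False,
        )
        if not sol.success:
            raise IntegrationError(
                f"ODE solver failed on [{s0}, {s1}]: {sol.message}"
            )
        if mask.any():
            cols = np.searchsorted(t_eval, t_out[mask])
            out_states[mask] = sol.y.T[cols]
            filled |= mask
        y = sol.y[:, -1].copy()
    if not filled.all():
        raise IntegrationError("internal error: unsampled output times")
    return SimulationResult(times=t_out, states=out_states, model=model, regimen=reg, _compiled=comp)


def mass_balance_error(result: SimulationResult, compound: str) -> float:
    """Max relative gap of (in body + eliminated) vs (administered + formed)."""
    total = result.total_amount(compound) + result.eliminated(compound)
    ref = result.administered(compound) + result.formed(compound)
    scale = max(float(np.max(ref)), 1e-30)
    return float(np.max(np.abs(total - ref)) / scale)


@dataclass
class PopulationResult:
    times: np.ndarray
    mean: Mapping[str, ConcentrationTimeProfile]
    sd: Mapping[str, ConcentrationTimeProfile]
    individuals: list[SimulationResult]


def simulate_population(
    model: PBPKModel,
    regimen: DosingRegimen,
    n: int,
    variability: VariabilitySpec,
    duration: float,
    grid: float = 0.25,
    times: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> PopulationResult:
    """Simulate a virtual population and summarize as arithmetic mean ± SD.

    Each individual receives median-preserving log-normal multiplicative
    factors on the listed parameter paths (sigma**2 = ln(1 + CV**2)) and,
    if a weight range is given, an allometrically rescaled physiology.
    Deterministic for a fixed seed.  With n = 1 the SD is zero by convention.
    """
    if n < 1:
        raise DomainError("population size must be >= 1")
    rng = np.random.default_rng(variability.seed)
    paths = sorted(variability.parameter_cvs)
    individuals: list[SimulationResult] = []
    for _ in range(n):
        m = model
        if variability.weight_range is not None:
            lo, hi = variability.weight_range
            bw = float(rng.uniform(lo, hi))
            m = dataclasses.replace(m, physiology=m.physiology.scaled_to_weight(bw))
        updates = {}
        for path in paths:
            cv = variability.parameter_cvs[path]
            if cv > 0:
                sigma = np.sqrt(np.log1p(cv * cv))
                updates[path] = m.get_param(path) * float(
                    np.exp(rng.normal(0.0, sigma))
                )
        if updates:
            m = m.with_params(updates)
        individuals.append(
            simulate(m, regimen, duration, grid=grid, times=times, rtol=rtol, atol=atol)
        )
    t = individuals[0].times
    mean_profiles: dict[str, ConcentrationTimeProfile] = {}
    sd_profiles: dict[str, ConcentrationTimeProfile] = {}
    for name in model.compound_names:
        mat = np.vstack([ind.profile(name).concentrations for ind in individuals])
        mu = mat.mean(axis=0)
        sd = mat.std(axis=0, ddof=1) if n > 1 else np.zeros_like(mu)
        mean_profiles[name] = ConcentrationTimeProfile(
            name, tuple(t), tuple(mu), dose_context=regimen, statistic="population_mean"
        )
        sd_profiles[name] = ConcentrationTimeProfile(
            name, tuple(t), tuple(sd), dose_context=regimen, statistic="population_sd"
        )
    return PopulationResult(times=t, mean=mean_profiles, sd=sd_profiles, individuals=individuals)


class NonStationaryWarning(UserWarning):
    """Steady-state AUC window shows > 2% drift between dosing intervals."""


def steady_state_window_auc(
    profile: ConcentrationTimeProfile,
    window: tuple[float, float],
    interval: float | None = None,
) -> float:
    """Trapezoidal AUC over a steady-state window (e.g. days 24-28).

    If the dosing interval is known (from the profile's dose context or the
    ``interval`` argument), the AUCs of the last two complete intervals in
    the window are compared and a :class:`NonStationaryWarning` is emitted
    when they differ by more than 2%.
    """
    from .metrics import auc_last  # local import to avoid a cycle

    t0, t1 = float(window[0]), float(window[1])
    t = np.asarray(profile.times, float)
    if t0 >= t1:
        raise DomainError("window must satisfy t_start < t_end")
    if t0 < t[0] or t1 > t[-1]:
        raise DomainError(f"window [{t0}, {t1}] outside simulated range [{t[0]}, {t[-1]}]")
    auc = auc_last(profile.times, profile.concentrations, t0, t1)
    tau = interval
    if tau is None and profile.dose_context is not None and profile.dose_context.n_doses > 1:
        tau = profile.dose_context.interval
    if tau is not None and (t1 - t0) >= 2 * tau:
        a_last = auc_last(profile.times, profile.concentrations, t1 - tau, t1)
        a_prev = auc_last(profile.times, profile.concentrations, t1 - 2 * tau, t1 - tau)
        if a_prev > 0 and abs(a_last / a_prev - 1.0) > 0.02:
            warnings.warn(
                f"steady-state window not stationary: last two interval AUCs differ by "
                f"{abs(a_last / a_prev - 1) * 100:.1f}%",
                NonStationaryWarning,
                stacklevel=2,
            )
    return auc
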