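"""Reduced reference physiology for the whole-body PBPK engine.

One documented reference adult (73 kg) with nine perfusion-limited
compartments: venous blood, arterial blood, lung, liver, gut, kidney,
adipose, muscle and a lumped rest-of-body compartment.  The gut drains into
the liver (portal flow); all other tissues drain into venous blood; cardiac
output passes through the lung.  Volumes and flows are rounded textbook
values for a standard adult; they are deliberately coarse — the engine's
analysis targets (exposure ratios between activity scores) depend on the
relative magnitude of clearance processes, not on fine anatomical detail.

Population variability scales volumes linearly with body weight and flows
plus glomerular filtration with body weight to the 0.75 power (allometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import ValidationError

__all__ = ["Compartment", "EnzymePool", "PhysiologyTable", "reference_adult", "one_compartment"]

#: Compartment names recognized by the circulatory topology.
CIRCULATORY = (
    "venous_blood",
    "arterial_blood",
    "lung",
    "liver",
    "gut",
    "kidney",
    "adipose",
    "muscle",
    "rest",
)
#: Tissues perfused from arterial blood and draining directly to venous blood.
DIRECT_TISSUES = ("kidney", "adipose", "muscle", "rest")


@dataclass(frozen=True)
class Compartment:
    name: str
    volume: float  # L
    blood_flow: float  # L/h (0 for blood nodes; lung flow = cardiac output)
    default_partition: float = 1.0  # tissue:plasma, dimensionless

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValidationError(f"compartment {self.name}: volume must be > 0")
        if self.blood_flow < 0:
            raise ValidationError(f"compartment {self.name}: blood flow must be >= 0")
        if self.default_partition <= 0:
            raise ValidationError(f"compartment {self.name}: partition must be > 0")


@dataclass(frozen=True)
class EnzymePool:
    """Hepatic enzyme pool: reference concentration and turnover."""

    reference_concentration: float  # µmol per L of liver tissue
    turnover_kdeg: float = 0.03  # 1/h, first-order degradation/synthesis turnover

    def __post_init__(self) -> None:
        if self.reference_concentration <= 0:
            raise ValidationError("enzyme reference concentration must be > 0")
        if self.turnover_kdeg <= 0:
            raise ValidationError("enzyme turnover kdeg must be > 0")


@dataclass(frozen=True)
class PhysiologyTable:
    compartments: tuple[Compartment, ...]
    gfr: float  # L/h
    hematocrit: float = 0.45
    enzyme_pools: Mapping[str, EnzymePool] = field(default_factory=dict)
    body_weight: float = 73.0  # kg

    def __post_init__(self) -> None:
        names = [c.name for c in self.compartments]
        if len(set(names)) != len(names):
            raise ValidationError(f"duplicate compartment names: {names}")
        if self.gfr <= 0:
            raise ValidationError("GFR must be > 0")
        if not (0 < self.hematocrit < 1):
            raise ValidationError("hematocrit must be in (0, 1)")
        if self.body_weight <= 0:
            raise ValidationError("body weight must be > 0")
        if self.is_circulatory:
            co = self.compartment("lung").blood_flow
            inflow = sum(
                self.compartment(n).blood_flow for n in ("liver", "gut", *DIRECT_TISSUES)
            )
            if abs(inflow - co) > 1e-6 * co:
                raise ValidationError(
                    f"tissue inflows ({inflow:.4g} L/h) must sum to cardiac output ({co:.4g} L/h)"
                )

    @property
    def is_circulatory(self) -> bool:
        """True for the whole-body topology, False for the 1-compartment reduction."""
        return set(c.name for c in self.compartments) >= set(CIRCULATORY)

    def compartment(self, name: str) -> Compartment:
        for c in self.compartments:
            if c.name == name:
                return c
        raise ValidationError(f"no compartment named {name!r}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.compartments)

    def scaled_to_weight(self, body_weight: float) -> "PhysiologyTable":
        """Allometric rescaling: volumes ~ BW, flows and GFR ~ BW**0.75."""
        if body_weight <= 0:
            raise ValidationError("body weight must be > 0")
        fv = body_weight / self.body_weight
        fq = fv**0.75
        comps = tuple(
            replace(c, volume=c.volume * fv, blood_flow=c.blood_flow * fq)
            for c in self.compartments
        )
        return replace(self, compartments=comps, gfr=self.gfr * fq, body_weight=body_weight)


def reference_adult() -> PhysiologyTable:
    """The packaged 73 kg reference adult (cardiac output 390 L/h)."""
    comps = (
        Compartment("venous_blood", 3.70, 0.0),
        Compartment("arterial_blood", 1.80, 0.0),
        Compartment("lung", 0.55, 390.0),
        Compartment("liver", 1.80, 25.0),  # hepatic-artery share; portal adds gut flow
        Compartment("gut", 1.10, 66.0),
        Compartment("kidney", 0.31, 74.0),
        Compartment("adipose", 13.0, 20.0),
        Compartment("muscle", 29.0, 66.0),
        Compartment("rest", 22.0, 139.0),
    )
    pools = {
        "CYP2D6": EnzymePool(reference_concentration=0.40),
        "CYP3A4": EnzymePool(reference_concentration=4.32),
        "CYP2C19": EnzymePool(reference_concentration=0.76),
    }
    return PhysiologyTable(compartments=comps, gfr=7.5, enzyme_pools=pools)


def one_compartment(
    volume: float = 40.0,
    gfr: float = 7.5,
    enzyme_pools: Mapping[str, EnzymePool] | None = None,
    body_weight: float = 73.0,
) -> PhysiologyTable:
    """Single well-stirred compartment, for closed-form checks and fast fits.

    All clearance processes act on the central compartment; enzyme amounts
    use the central volume as the reference tissue volume.
    """
    pools = dict(enzyme_pools) if enzyme_pools else {
        "CYP2D6": EnzymePool(reference_concentration=0.40),
        "CYP3A4": EnzymePool(reference_concentration=4.32),
        "CYP2C19": EnzymePool(reference_concentration=0.76),
    }
    return PhysiologyTable(
        compartments=(Compartment("central", volume, 0.0),),
        gfr=gfr,
        enzyme_pools=pools,
        body_weight=body_weight,
    )
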