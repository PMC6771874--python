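"""Deterministic reference-dose derivation and drinking-water guideline math.

Human equivalent dose (HED) by BW^(3/4) allometric scaling of daily oral
dose, composite uncertainty factors under the half-log convention (a "3"
stands for 10^0.5, so UF sets like {3, 10, 3} compose to 100, not 90),
the reference dose RfD = HED / composite UF, and the maximum contaminant
level goal MCLG = RfD × BW × RSC / drinking-water intake.

Reported reference-dose values are conventionally rounded to one
significant figure; both raw and reported values are returned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .datasets import BenchmarkResponse

__all__ = [
    "PointOfDeparture",
    "UncertaintyFactorSet",
    "GuidelineInputs",
    "RfdResult",
    "SPECIES_DEFAULT_BW_KG",
    "hed",
    "composite_uf",
    "derive_rfd",
    "mclg",
    "round_1sf",
]

# Reference body weights (kg) for common study designs; informational
# defaults only — reproduction of a published HED must state the weight used.
SPECIES_DEFAULT_BW_KG = {
    "rat_chronic": 0.25,
    "rat_subchronic": 0.20,
    "mouse_chronic": 0.035,
    "mouse_subchronic": 0.03,
    "human": 70.0,
}


@dataclass(frozen=True)
class PointOfDeparture:
    """A point of departure (POD) from dose-response analysis, mg/kg/day."""

    value: float
    basis: str = "BMDL"  # BMDL, BMD, NOAEL or LOAEL
    bmr: BenchmarkResponse | None = None
    endpoint: str = ""
    species: str = ""

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError("POD must be positive")
        if self.basis not in ("BMDL", "BMD", "NOAEL", "LOAEL"):
            raise ValueError(f"unknown POD basis {self.basis!r}")


@dataclass(frozen=True)
class UncertaintyFactorSet:
    """Uncertainty factors, each 1, 3 or 10; composed in log10 space.

    uf_a: interspecies (animal → human, residual after allometric scaling)
    uf_h: human (intraspecies) variability
    uf_s: subchronic → chronic extrapolation
    uf_d: database completeness
    """

    uf_a: int = 1
    uf_h: int = 1
    uf_s: int = 1
    uf_d: int = 1

    def __post_init__(self) -> None:
        for name in ("uf_a", "uf_h", "uf_s", "uf_d"):
            if getattr(self, name) not in (1, 3, 10):
                raise ValueError(f"{name} must be 1, 3 or 10 (3 means a half-log, 10^0.5)")

    @property
    def log10_halves(self) -> float:
        half = {1: 0.0, 3: 0.5, 10: 1.0}
        return sum(half[f] for f in (self.uf_a, self.uf_h, self.uf_s, self.uf_d))

    @property
    def composite(self) -> float:
        """10^(sum of half-log exponents): {3,10,3} → 100, not the literal 90."""
        return 10.0 ** self.log10_halves


@dataclass(frozen=True)
class GuidelineInputs:
    """Adult drinking-water exposure defaults for guideline derivation."""

    body_weight: float = 70.0          # kg
    drinking_water_intake: float = 2.0  # L/day
    rsc: float = 0.2                   # relative source contribution

    def __post_init__(self) -> None:
        if self.body_weight <= 0 or self.drinking_water_intake <= 0:
            raise ValueError("body weight and intake must be positive")
        if not (0.0 < self.rsc <= 1.0):
            raise ValueError("relative source contribution must be in (0, 1]")


@dataclass(frozen=True)
class RfdResult:
    """Provenance-preserving deterministic RfD."""

    pod: PointOfDeparture
    animal_bw: float
    human_bw: float
    hed: float
    ufs: UncertaintyFactorSet
    rfd_raw: float
    rfd_reported: float


def round_1sf(x: float) -> float:
    """Round to one significant figure (reference doses are reported this way)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def hed(pod: PointOfDeparture | float, animal_bw: float, human_bw: float = 70.0) -> float:
    """Human equivalent dose by allometric BW^(3/4) scaling of daily dose.

    HED = POD × (BW_animal / BW_human)^(1/4): equipotent daily doses are
    assumed to scale with the 3/4 power of body weight, so the per-kg dose
    carries a quarter-power weight ratio.
    """
    if animal_bw <= 0 or human_bw <= 0:
        raise ValueError("body weights must be positive")
    value = pod.value if isinstance(pod, PointOfDeparture) else float(pod)
    return value * (animal_bw / human_bw) ** 0.25


def composite_uf(ufs: UncertaintyFactorSet) -> float:
    """Composite uncertainty factor under the half-log convention."""
    return ufs.composite


def derive_rfd(
    hed_value: float,
    ufs: UncertaintyFactorSet,
    pod: PointOfDeparture | None = None,
    animal_bw: float = float("nan"),
    human_bw: float = 70.0,
) -> RfdResult:
    """RfD = HED / composite UF, with the reported value at one significant figure."""
    if hed_value <= 0:
        raise ValueError("HED must be positive")
    raw = hed_value / ufs.composite
    return RfdResult(
        pod=pod if pod is not None else PointOfDeparture(hed_value, basis="BMDL"),
        animal_bw=animal_bw,
        human_bw=human_bw,
        hed=hed_value,
        ufs=ufs,
        rfd_raw=raw,
        rfd_reported=round_1sf(raw),
    )


def mclg(rfd: float, inputs: GuidelineInputs = GuidelineInputs()) -> float:
    """Maximum contaminant level goal in µg/L.

    MCLG = RfD [mg/kg/day] × BW [kg] × RSC / intake [L/day], converted from
    mg/L to µg/L.
    """
    if rfd <= 0:
        raise ValueError("RfD must be positive")
    mg_per_l = rfd * inputs.body_weight * inputs.rsc / inputs.drinking_water_intake
    return mg_per_l * 1000.0
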