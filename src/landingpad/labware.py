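"""Robotic plating geometry and serial-dilution planning.

Gellan-gum plates solidify too quickly for precise volumetric dispensing,
so the gel height is recovered from the poured plate's mass:

    height_mm = weight_g / (area_mm2 * density_g_per_mm3)

and the dispensing z position sits a fixed clearance (default 1 mm) above
the gel surface. The dilution planner converts a geometric chain of
dilution factors (e.g. neat, 1:3, 1:9, 1:27) into per-step transfer and
diluent volumes for a liquid handler. Both are pure functions usable by
any deck-control layer.
"""

from __future__ import annotations

from dataclasses import dataclass


def gel_height(weight_g: float, area_mm2: float,
               density_g_per_mm3: float) -> float:
    """Gel height (mm) from plate mass, plate area and gel density."""
    for name, value in (("weight", weight_g), ("area", area_mm2),
                        ("density", density_g_per_mm3)):
        if value <= 0:
            raise ValueError(f"{name} must be > 0, got {value}")
    return weight_g / (area_mm2 * density_g_per_mm3)


def z_offset(weight_g: float, area_mm2: float, density_g_per_mm3: float,
             tip_clearance_mm: float = 1.0) -> float:
    """Dispensing z position: gel height plus the tip clearance (1 mm)."""
    return gel_height(weight_g, area_mm2, density_g_per_mm3) + tip_clearance_mm


@dataclass(frozen=True)
class PlateGeometry:
    """Geometry of one poured plate, with derived height and z position."""

    gel_weight: float
    plate_area: float
    gel_density: float
    tip_clearance: float = 1.0

    @property
    def gel_height(self) -> float:
        return gel_height(self.gel_weight, self.plate_area, self.gel_density)

    @property
    def z_offset(self) -> float:
        return self.gel_height + self.tip_clearance


@dataclass(frozen=True)
class DilutionStep:
    """One serial transfer realizing a constant step ratio."""

    cumulative_factor: float
    transfer_volume: float
    diluent_volume: float


@dataclass(frozen=True)
class DilutionPlan:
    factors: tuple[float, ...]
    working_volume: float
    steps: tuple[DilutionStep, ...]

    def simulate(self) -> list[float]:
        """Recompute the cumulative factors a handler would realize."""
        realized = [1.0]
        for step in self.steps:
            ratio = (step.transfer_volume + step.diluent_volume) \
                / step.transfer_volume
            realized.append(realized[-1] * ratio)
        return realized


def dilution_plan(target_factors, working_volume: float) -> DilutionPlan:
    """Plan serial transfers realizing ``target_factors`` (e.g. 1,3,9,27).

    The factors must form a geometric chain starting at 1: each step is
    realized by transferring v = working_volume/r into d = working_volume
    - v diluent, where r is the constant step ratio. Non-geometric chains
    cannot be realized by serial transfer and are rejected.
    """
    factors = [float(f) for f in target_factors]
    if not factors or factors[0] != 1.0:
        raise ValueError("dilution factors must start at 1 (neat)")
    if any(b <= a for a, b in zip(factors, factors[1:])):
        raise ValueError("dilution factors must be strictly increasing")
    if working_volume <= 0:
        raise ValueError("working volume must be > 0")
    if len(factors) == 1:
        return DilutionPlan(tuple(factors), working_volume, ())
    ratios = [b / a for a, b in zip(factors, factors[1:])]
    if any(abs(r - ratios[0]) > 1e-9 for r in ratios):
        raise ValueError(
            f"factors {factors} are not a geometric chain; serial transfer "
            "cannot realize them"
        )
    r = ratios[0]
    transfer = working_volume / r
    diluent = working_volume - transfer
    steps = tuple(
        DilutionStep(cumulative_factor=f, transfer_volume=transfer,
                     diluent_volume=diluent)
        for f in factors[1:]
    )
    return DilutionPlan(tuple(factors), working_volume, steps)
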