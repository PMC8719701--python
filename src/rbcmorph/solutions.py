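"""Solution chemistry, osmotic response, and condition presets.

Covers the experimental design: RBCs suspended in plasma, PBS, Alsever's
solution (AS), or mixtures of NaCl (0-0.75% w/v) with glucose or mannitol.
Osmolarity is computed ideally (full dissociation, no osmotic coefficient);
measured osmolality, when known, can be carried as a preset override.

The empirical shape response is a lookup, not a membrane model: plasma and
AS keep cells biconcave; PBS and NaCl alone sphere them; NaCl + glucose or
NaCl + mannitol inside empirically determined concentration windows restore
biconcavity, with the high-NaCl mannitol band giving cells flatter than in
plasma ("hyper-flat").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MOLAR_MASS_NACL",
    "MOLAR_MASS_GLUCOSE",
    "MOLAR_MASS_MANNITOL",
    "SERUM_OSMOLALITY_RANGE",
    "ISO_OSMOLALITY",
    "SolutionSpec",
    "ShapeResponse",
    "ConditionPreset",
    "ideal_osmolarity",
    "osmotic_volume",
    "shape_response",
    "RESPONSE_REGIMES",
    "BICONCAVE_REGIONS",
    "named_preset",
    "preset_from_solution",
    "NAMED_MEDIA",
]

MOLAR_MASS_NACL = 58.44  # g/mol, nu = 2
MOLAR_MASS_GLUCOSE = 180.16  # g/mol, nu = 1
MOLAR_MASS_MANNITOL = 182.17  # g/mol, nu = 1

#: normal serum osmolality reference range, mOsm/kg H2O
SERUM_OSMOLALITY_RANGE = (275.0, 295.0)
#: isotonic anchor used by the osmotic volume response, mOsm/kg
ISO_OSMOLALITY = 294.0
#: osmotically inactive fraction: classic Ponder result, ~57% of the
#: isotonic volume is osmotically active water
DEFAULT_WATER_FRACTION = 0.57

NAMED_MEDIA = ("plasma", "PBS", "AS")


@dataclass
class SolutionSpec:
    """Composition of a suspension solution.

    Concentrations: ``nacl_pct`` and ``mannitol_pct`` in % w/v (== g/dL),
    ``glucose_gdl`` in g/dL.  ``extra_solutes`` lists additional components
    as ``(name, g_per_L, molar_mass_g_mol, dissociation_count)``.
    """

    nacl_pct: float = 0.0
    glucose_gdl: float = 0.0
    mannitol_pct: float = 0.0
    extra_solutes: list[tuple[str, float, float, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if min(self.nacl_pct, self.glucose_gdl, self.mannitol_pct) < 0:
            raise ValueError("concentrations must be non-negative")
        for name, g_per_l, molar_mass, nu in self.extra_solutes:
            if g_per_l < 0:
                raise ValueError(f"negative concentration for {name}")
            if not molar_mass or molar_mass <= 0:
                raise ValueError(f"solute {name!r} needs a positive molar mass")
            if nu < 1:
                raise ValueError(f"solute {name!r} needs dissociation count >= 1")


def ideal_osmolarity(solution: SolutionSpec) -> float:
    """Ideal osmolarity in mOsm/L assuming full dissociation.

    Sum over solutes of (g/L / molar mass) * dissociation count * 1000.
    % w/v converts to g/L by a factor of 10.  This ignores osmotic
    coefficients (NaCl's is ~0.93), so values run slightly above osmometer
    readings; presets may carry measured osmolality overrides.
    """
    total = 0.0
    total += (solution.nacl_pct * 10.0) / MOLAR_MASS_NACL * 2.0
    total += (solution.glucose_gdl * 10.0) / MOLAR_MASS_GLUCOSE
    total += (solution.mannitol_pct * 10.0) / MOLAR_MASS_MANNITOL
    for _name, g_per_l, molar_mass, nu in solution.extra_solutes:
        total += g_per_l / molar_mass * nu
    return total * 1000.0


def osmotic_volume(
    v_iso_fl: float,
    osmolality: float,
    water_fraction: float = DEFAULT_WATER_FRACTION,
    iso_osmolality: float = ISO_OSMOLALITY,
) -> float:
    """Boyle-van 't Hoff equilibrium volume at the given osmolality.

    V = V_iso * (Rw * iso/osm + (1 - Rw)) — the osmotically active water
    fraction Rw scales inversely with osmolality; the rest (hemoglobin,
    membrane, bound water) is incompressible.
    """
    if osmolality <= 0:
        raise ValueError("osmolality must be positive")
    if not 0.0 < water_fraction <= 1.0:
        raise ValueError("water_fraction must lie in (0, 1]")
    return v_iso_fl * (water_fraction * iso_osmolality / osmolality + (1.0 - water_fraction))


@dataclass(frozen=True)
class ShapeResponse:
    """Sphering-index distribution implied by a solution condition."""

    s_mean: float
    s_sd: float
    regime: str  # "biconcave" | "spherical" | "hyper-flat"


#: sphering-index draws per regime (mean, sd); hyper-flat sits slightly
#: below the plasma draw, matching cells flatter than in plasma
RESPONSE_REGIMES = {
    "biconcave": ShapeResponse(0.05, 0.03, "biconcave"),
    "spherical": ShapeResponse(0.97, 0.02, "spherical"),
    "hyper-flat": ShapeResponse(0.02, 0.015, "hyper-flat"),
}

#: empirical biconcavity windows; bounds inclusive, units % w/v NaCl and
#: g/dL sugar.  The glucose window is as reported; the mannitol window at
#: 0.45-0.75% NaCl has unreported sugar bounds and uses 2.5-3.5%.
BICONCAVE_REGIONS = {
    "glucose": {"nacl": (0.3, 0.45), "sugar": (2.63, 3.92)},
    "mannitol": {"nacl": (0.3, 0.75), "sugar": (2.5, 3.5)},
    "mannitol_hyperflat_nacl_min": 0.45,
}


def _in_window(value: float, window: tuple[float, float]) -> bool:
    lo, hi = window
    return lo <= value <= hi


def shape_response(solution: str | SolutionSpec) -> ShapeResponse:
    """Empirical shape-response rule for a named medium or NaCl mixture.

    Raises
    ------
    ValueError
        For an unknown named medium.
    """
    if isinstance(solution, str):
        if solution in ("plasma", "AS"):
            return RESPONSE_REGIMES["biconcave"]
        if solution == "PBS":
            return RESPONSE_REGIMES["spherical"]
        raise ValueError(f"unknown medium {solution!r}; expected one of {NAMED_MEDIA}")

    if solution.glucose_gdl > 0:
        reg = BICONCAVE_REGIONS["glucose"]
        if _in_window(solution.nacl_pct, reg["nacl"]) and _in_window(
            solution.glucose_gdl, reg["sugar"]
        ):
            return RESPONSE_REGIMES["biconcave"]
        return RESPONSE_REGIMES["spherical"]
    if solution.mannitol_pct > 0:
        reg = BICONCAVE_REGIONS["mannitol"]
        if _in_window(solution.nacl_pct, reg["nacl"]) and _in_window(
            solution.mannitol_pct, reg["sugar"]
        ):
            if solution.nacl_pct >= BICONCAVE_REGIONS["mannitol_hyperflat_nacl_min"]:
                return RESPONSE_REGIMES["hyper-flat"]
            return RESPONSE_REGIMES["biconcave"]
        return RESPONSE_REGIMES["spherical"]
    # NaCl alone (any concentration, including pure water): spherical
    return RESPONSE_REGIMES["spherical"]


@dataclass
class ConditionPreset:
    """Everything the simulator needs to emulate one solution condition."""

    name: str
    solution: str | SolutionSpec
    s_mean: float
    s_sd: float
    volume_mean_fl: float
    volume_sd_fl: float
    cell_ri_mean: float = 1.40
    cell_ri_sd: float = 0.005
    medium_ri: float = 1.337
    noise_sd: float = 0.004
    cells_per_field: int = 40
    regime: str = "biconcave"

    def __post_init__(self) -> None:
        if not 20.0 < self.volume_mean_fl < 200.0:
            raise ValueError("volume mean must lie in (20, 200) fL")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.cells_per_field < 1:
            raise ValueError("cells_per_field must be >= 1")
        if not 0.0 <= self.s_mean <= 1.0:
            raise ValueError("s_mean must lie in [0, 1]")


#: group means +/- SD measured for the three media (n = 40 cells each)
_NAMED_VOLUME = {
    "plasma": (88.06, 8.43),
    "PBS": (81.77, 8.51),
    "AS": (89.27, 9.48),
}


def named_preset(medium: str, **overrides) -> ConditionPreset:
    """Preset for one of the named media (plasma, PBS, AS)."""
    if medium not in NAMED_MEDIA:
        raise ValueError(f"unknown medium {medium!r}; expected one of {NAMED_MEDIA}")
    resp = shape_response(medium)
    v_mean, v_sd = _NAMED_VOLUME[medium]
    params = dict(
        name=medium,
        solution=medium,
        s_mean=resp.s_mean,
        s_sd=resp.s_sd,
        volume_mean_fl=v_mean,
        volume_sd_fl=v_sd,
        regime=resp.regime,
    )
    params.update(overrides)
    return ConditionPreset(**params)


def preset_from_solution(
    name: str,
    solution: SolutionSpec,
    v_iso_fl: float = 89.5,
    measured_osmolality: float | None = None,
    **overrides,
) -> ConditionPreset:
    """Derive a preset for an arbitrary NaCl/glucose/mannitol mixture.

    The volume mean follows the Boyle-van 't Hoff response at the solution's
    (measured, else ideal) osmolality; the sphering distribution follows the
    empirical shape-response table.  ``v_iso_fl`` defaults to the subjects'
    mean cell volume.
    """
    resp = shape_response(solution)
    osm = measured_osmolality if measured_osmolality is not None else ideal_osmolarity(solution)
    v_mean = osmotic_volume(v_iso_fl, osm)
    v_mean = float(np.clip(v_mean, 30.0, 180.0))
    params = dict(
        name=name,
        solution=solution,
        s_mean=resp.s_mean,
        s_sd=resp.s_sd,
        volume_mean_fl=v_mean,
        volume_sd_fl=0.1 * v_mean,
        regime=resp.regime,
    )
    params.update(overrides)
    return ConditionPreset(**params)
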