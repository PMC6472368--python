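"""Correction of standard reaction energies to in-situ deep-sea conditions.

Two corrections are applied to a standard-state (298.15 K, 1 M, pH 0)
reaction energy:

* temperature, by Gibbs-Helmholtz integration at constant reaction enthalpy:
  ``dG(T) = dG0 * T/T0 + dH0 * (1 - T/T0)`` with T0 = 298.15 K;
* concentrations, by the reaction-quotient term ``R*T*sum_i nu_i ln a_i``,
  where the proton activity is ``10**-pH``, water and other pure liquids
  have unit activity, and every other species defaults to its 1 M (or 1 atm)
  standard state unless a concentration is supplied.

Hydrostatic pressure is recorded as a condition but not applied by default:
for dilute-solution reactions with no net gas volume change its effect over
a few hundred atmospheres is within the uncertainty of the formation
constants, and published deep-sea reaction energies are matched by the
temperature and activity corrections alone.  An optional ideal-gas
compression term ``R*T*nu_gas*ln(P)`` can be switched on.

The default :meth:`Conditions.deep_sea` condition set (4 degC, 300 atm,
pH 8, 2 mM bicarbonate) represents cold, deep (~3 km) marine sediment
porewater.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np

from .thermo import Phase, Reaction, SpeciesTable, T_REF

#: Gas constant, kJ mol^-1 K^-1.
R_KJ = 8.314e-3

PROTON = "H+"


@dataclass(frozen=True)
class Conditions:
    """Environmental conditions for an in-situ energy calculation.

    ``concentrations`` maps species name -> mol/L (or atm for gas-phase
    species); anything absent defaults to activity 1 (the standard state).
    The proton is controlled exclusively by ``pH`` and must not appear in
    ``concentrations``; water activity is fixed at 1.
    """

    temperature: float = T_REF          # K
    pressure_atm: float = 1.0
    pH: float = 0.0
    concentrations: Mapping[str, float] = field(default_factory=dict)
    water_activity: float = 1.0

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError(f"temperature must be positive, got {self.temperature}")
        if self.pressure_atm <= 0:
            raise ValueError(f"pressure must be positive, got {self.pressure_atm}")
        if PROTON in self.concentrations:
            raise ValueError("proton activity is set by pH; do not list H+ in concentrations")
        bad = {n: c for n, c in self.concentrations.items() if not c > 0}
        if bad:
            raise ValueError(f"concentrations must be positive: {bad}")

    @property
    def proton_activity(self) -> float:
        return 10.0 ** (-self.pH)

    def activity(self, species_name: str, db: SpeciesTable) -> float:
        """Activity of one species under these conditions (1 for pure liquids)."""
        if species_name == PROTON:
            return self.proton_activity
        if db.get(species_name).phase is Phase.LIQUID:
            return self.water_activity
        return float(self.concentrations.get(species_name, 1.0))

    def replace_concentrations(self, **overrides: float) -> "Conditions":
        merged = dict(self.concentrations)
        merged.update(overrides)
        return Conditions(self.temperature, self.pressure_atm, self.pH, merged, self.water_activity)

    @classmethod
    def deep_sea(cls, **concentrations: float) -> "Conditions":
        """Deep-sea sediment porewater defaults: 4 degC, 300 atm, pH 8, 2 mM HCO3-."""
        base = {"HCO3-": 2e-3}
        base.update(concentrations)
        return cls(temperature=277.15, pressure_atm=300.0, pH=8.0, concentrations=base)


def temperature_correct(dG0: float, dH0: float, temperature: float) -> float:
    """Gibbs-Helmholtz temperature correction at constant reaction enthalpy (kJ)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    ratio = temperature / T_REF
    return dG0 * ratio + dH0 * (1.0 - ratio)


def reaction_quotient_term(reaction: Reaction, conditions: Conditions, db: SpeciesTable) -> float:
    """``R*T*sum_i nu_i ln a_i`` in kJ; pure-liquid species contribute zero."""
    total = 0.0
    for name, nu in reaction.coefficients.items():
        if db.get(name).phase is Phase.LIQUID:
            continue
        a = conditions.activity(name, db)
        if not a > 0:
            raise ValueError(f"species {name!r} has non-positive activity {a}")
        total += float(nu) * math.log(a)
    return R_KJ * conditions.temperature * total


def _net_gas_stoichiometry(reaction: Reaction, db: SpeciesTable) -> float:
    return float(sum(nu for name, nu in reaction.coefficients.items() if db.get(name).phase is Phase.GAS))


@dataclass(frozen=True)
class EnergyRecord:
    """Standard, temperature-corrected and in-situ energies for one reaction."""

    reaction_id: str
    dG0: float
    dH0: float
    dG_T: float
    rtlnQ: float
    dG_insitu: float
    conditions: Conditions
    pressure_term: float = 0.0


def insitu_energy(
    reaction: Reaction,
    dG0: float,
    dH0: float,
    conditions: Conditions,
    db: SpeciesTable,
    apply_pressure_term: bool = False,
) -> EnergyRecord:
    """In-situ reaction energy: temperature correction plus quotient term.

    With ``apply_pressure_term`` an ideal-gas compression term
    ``R*T*nu_gas*ln(P_atm)`` is added for reactions with net gas-phase
    stoichiometry (off by default; see module docstring).
    """
    dG_T = temperature_correct(dG0, dH0, conditions.temperature)
    rtlnq = reaction_quotient_term(reaction, conditions, db)
    p_term = 0.0
    if apply_pressure_term:
        p_term = (R_KJ * conditions.temperature * _net_gas_stoichiometry(reaction, db)
                  * math.log(conditions.pressure_atm))
    return EnergyRecord(
        reaction_id=reaction.id,
        dG0=dG0,
        dH0=dH0,
        dG_T=dG_T,
        rtlnQ=rtlnq,
        dG_insitu=dG_T + rtlnq + p_term,
        conditions=conditions,
        pressure_term=p_term,
    )


@dataclass(frozen=True)
class FeasibilityGrid:
    """In-situ energy surface over a 2-D grid of concentrations.

    ``dG[i, j]`` is the in-situ energy at ``y_grid[i]``, ``x_grid[j]``.
    ``zero_contour`` lists (x, y) concentration pairs where the energy
    crosses zero, interpolated linearly in log10 concentration.
    """

    reaction_id: str
    x_species: str
    y_species: str
    x_grid: np.ndarray
    y_grid: np.ndarray
    dG: np.ndarray
    zero_contour: tuple[tuple[float, float], ...]

    def to_long_frame(self):
        import pandas as pd

        xx, yy = np.meshgrid(self.x_grid, self.y_grid)
        return pd.DataFrame(
            {
                "x_species": self.x_species,
                "x_conc": xx.ravel(),
                "y_species": self.y_species,
                "y_conc": yy.ravel(),
                "dG_kJ": self.dG.ravel(),
            }
        )

    def contour_frame(self):
        import pandas as pd

        return pd.DataFrame(self.zero_contour, columns=[self.x_species, self.y_species])


def _interp_log_zero(c_lo: float, c_hi: float, g_lo: float, g_hi: float) -> float:
    t = g_lo / (g_lo - g_hi)
    return 10.0 ** (math.log10(c_lo) + t * (math.log10(c_hi) - math.log10(c_lo)))


def feasibility_window(
    reaction: Reaction,
    dG0: float,
    dH0: float,
    base: Conditions,
    var_x: tuple[str, Sequence[float]],
    var_y: tuple[str, Sequence[float]],
    db: SpeciesTable,
) -> FeasibilityGrid:
    """Map the in-situ energy of ``reaction`` over a grid of two concentrations.

    ``var_x``/``var_y`` are ``(species_name, concentration_grid)`` pairs; the
    grids must be positive and sorted ascending, and both species must
    participate in the reaction.  The zero contour is located by sign change
    between adjacent grid points (scanning both axes) with linear
    interpolation in log10 concentration.
    """
    x_name, x_grid = var_x
    y_name, y_grid = var_y
    for name in (x_name, y_name):
        if name not in reaction.coefficients:
            raise ValueError(f"varied species {name!r} does not participate in reaction {reaction.id!r}")
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    for name, grid in ((x_name, x_grid), (y_name, y_grid)):
        if grid.ndim != 1 or grid.size == 0 or not (grid > 0).all():
            raise ValueError(f"grid for {name!r} must be a positive 1-D vector")
        if not (np.diff(grid) > 0).all():
            raise ValueError(f"grid for {name!r} must be sorted ascending")

    # dG is affine in ln(a) of each varied species: evaluate once at base and
    # add the nu*R*T*ln(c) increments on the grid.
    base_cond = base.replace_concentrations(**{x_name: 1.0, y_name: 1.0})
    g_base = insitu_energy(reaction, dG0, dH0, base_cond, db).dG_insitu
    rt = R_KJ * base.temperature
    nu_x = float(reaction.coefficients[x_name])
    nu_y = float(reaction.coefficients[y_name])
    gx = nu_x * rt * np.log(x_grid)
    gy = nu_y * rt * np.log(y_grid)
    dG = g_base + gy[:, None] + gx[None, :]

    contour: list[tuple[float, float]] = []
    for j in range(x_grid.size):  # scan along y
        col = dG[:, j]
        for i in range(y_grid.size - 1):
            if col[i] == 0.0:
                contour.append((float(x_grid[j]), float(y_grid[i])))
            elif col[i] * col[i + 1] < 0:
                contour.append(
                    (float(x_grid[j]), _interp_log_zero(y_grid[i], y_grid[i + 1], col[i], col[i + 1]))
                )
    for i in range(y_grid.size):  # scan along x
        row = dG[i, :]
        for j in range(x_grid.size - 1):
            if row[j] * row[j + 1] < 0:
                contour.append(
                    (_interp_log_zero(x_grid[j], x_grid[j + 1], row[j], row[j + 1]), float(y_grid[i]))
                )
    return FeasibilityGrid(
        reaction_id=reaction.id,
        x_species=x_name,
        y_species=y_name,
        x_grid=x_grid,
        y_grid=y_grid,
        dG=dG,
        zero_contour=tuple(dict.fromkeys(contour)),
    )
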