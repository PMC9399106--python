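"""Alpha-particle stopping power and one-dimensional energy-loss transport.

Mass stopping powers are tabulated on a log-spaced 0.1-6 MeV grid and
interpolated log-log, which is monotone between nodes.  ``transport``
integrates the continuous-slowing-down equation dE/dx = -S(E) stepwise
along a piecewise-homogeneous path; a particle whose energy falls below
the lower grid edge (0.1 MeV, residual range well under a micron) is
reported as stopped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._stopping_data import (
    DENSITY_G_CM3,
    ENERGY_GRID_MEV,
    MASS_STOPPING_AIR,
    MASS_STOPPING_MYLAR,
    MASS_STOPPING_WATER,
)

__all__ = [
    "STOPPED",
    "StoppingPowerTable",
    "let_water",
    "transport",
    "water_table",
]

#: Sentinel returned by :func:`transport` when the particle runs out of energy.
STOPPED = object()

_BUILTIN = {
    "water": MASS_STOPPING_WATER,
    "mylar": MASS_STOPPING_MYLAR,
    "air": MASS_STOPPING_AIR,
}

KEV_PER_JOULE = 1.0 / 1.602176634e-16


@dataclass(frozen=True)
class StoppingPowerTable:
    """Tabulated total mass stopping power for one medium.

    Parameters
    ----------
    medium
        Name of the medium (``water``, ``mylar`` or ``air`` for the
        built-in tables).
    energy_grid
        Strictly increasing kinetic energies, MeV.
    mass_stopping_power
        Total mass stopping power at the grid nodes, MeV cm^2/g.
    density
        Bulk density, g/cm^3.
    """

    medium: str
    energy_grid: np.ndarray
    mass_stopping_power: np.ndarray
    density: float

    _log_e: np.ndarray = field(init=False, repr=False, compare=False)
    _log_s: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energy_grid, dtype=float)
        s = np.asarray(self.mass_stopping_power, dtype=float)
        if e.ndim != 1 or e.size < 2 or np.any(np.diff(e) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if s.shape != e.shape or np.any(s <= 0):
            raise ValueError("stopping powers must be positive, one per node")
        if self.density <= 0:
            raise ValueError("density must be positive")
        object.__setattr__(self, "energy_grid", e)
        object.__setattr__(self, "mass_stopping_power", s)
        object.__setattr__(self, "_log_e", np.log(e))
        object.__setattr__(self, "_log_s", np.log(s))

    @classmethod
    def from_builtin(cls, medium: str) -> "StoppingPowerTable":
        try:
            table = _BUILTIN[medium]
        except KeyError:
            raise ValueError(f"unknown medium {medium!r}") from None
        return cls(medium, ENERGY_GRID_MEV, table, DENSITY_G_CM3[medium])

    @property
    def e_min(self) -> float:
        return float(self.energy_grid[0])

    @property
    def e_max(self) -> float:
        return float(self.energy_grid[-1])

    def mass_stopping(self, energy_mev) -> np.ndarray:
        """Interpolated mass stopping power, MeV cm^2/g (no extrapolation)."""
        e = np.asarray(energy_mev, dtype=float)
        if np.any(e < self.e_min) or np.any(e > self.e_max):
            raise ValueError(
                f"energy outside table range [{self.e_min}, {self.e_max}] MeV"
            )
        return np.exp(np.interp(np.log(e), self._log_e, self._log_s))

    def linear_stopping_mev_um(self, energy_mev) -> np.ndarray:
        """Linear stopping power S = rho * (S/rho), MeV/um."""
        return self.mass_stopping(energy_mev) * self.density * 1e-4

    def let_kev_um(self, energy_mev) -> np.ndarray:
        """Linear energy transfer in this medium, keV/um."""
        return self.linear_stopping_mev_um(energy_mev) * 1e3


_TABLE_CACHE: dict[str, StoppingPowerTable] = {}


def _table(medium: str) -> StoppingPowerTable:
    if medium not in _TABLE_CACHE:
        _TABLE_CACHE[medium] = StoppingPowerTable.from_builtin(medium)
    return _TABLE_CACHE[medium]


def water_table() -> StoppingPowerTable:
    return _table("water")


def let_water(energy_mev) -> np.ndarray:
    """LET of an alpha particle in liquid water, keV/um.

    Raises ``ValueError`` outside the tabulated 0.1-6 MeV interval.
    """
    return _table("water").let_kev_um(energy_mev)


def transport(
    energy_mev: float,
    path: list[tuple[str, float]],
    *,
    max_rel_loss: float = 0.01,
    max_step_um: float = 0.5,
):
    """Slow an alpha particle down along a piecewise-homogeneous path.

    Parameters
    ----------
    energy_mev
        Kinetic energy at the start of the path, MeV.
    path
        Sequence of ``(medium, length_um)`` segments.
    max_rel_loss, max_step_um
        Step control: each midpoint step is limited both geometrically and
        so that the predicted fractional energy loss stays below
        ``max_rel_loss``.

    Returns
    -------
    Residual energy in MeV, or the :data:`STOPPED` sentinel if the energy
    is exhausted (falls below the table's lower edge) before the path ends.
    """
    if energy_mev <= 0:
        raise ValueError("energy must be positive")
    e = float(energy_mev)
    for medium, length in path:
        table = _table(medium)  # raises for unknown medium
        if length < 0:
            raise ValueError("path lengths must be non-negative")
        remaining = float(length)
        while remaining > 0:
            if e <= table.e_min:
                return STOPPED
            s0 = float(table.linear_stopping_mev_um(e))
            step = min(remaining, max_step_um, max_rel_loss * e / s0)
            # midpoint (RK2) step of dE/dx = -S(E)
            e_mid = e - 0.5 * step * s0
            if e_mid <= table.e_min:
                return STOPPED
            s_mid = float(table.linear_stopping_mev_um(e_mid))
            de = step * s_mid
            if e - de <= table.e_min:
                return STOPPED
            e -= de
            remaining -= step
    return e
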