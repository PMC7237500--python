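"""Underdamped Langevin dynamics for one MD stage at fixed protonation state.

BAOAB splitting; with friction = 0 the scheme reduces exactly to velocity
Verlet, which is what the NVE energy-conservation checks use.  Time is
counted in MD steps; the uniform bead mass is a numerical device chosen so
that the stiffest bond oscillation stays well resolved by the timestep
(omega*dt ~ 0.3), see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .constants import kbt
from .topology_energy import ProtonationState, Topology


@dataclass
class MDSettings:
    temperature: float = 323.0   # K
    friction: float = 2.0        # 1/time (reduced)
    timestep: float = 0.1        # reduced time units
    tau: int = 100_000           # MD steps per stage
    mass: float = None           # uniform bead mass; None = auto from bond k
    ev_list_cutoff: float = 1.8  # nm, pair-list radius for excluded volume
    ev_rebuild_every: int = 20

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.friction < 0:
            raise ValueError("friction must be non-negative")
        if self.tau < 1:
            raise ValueError("tau must be >= 1")

    def effective_mass(self, top: Topology) -> float:
        if self.mass is not None:
            return float(self.mass)
        kmax = float(top.bond_k.max()) if len(top.bond_k) else 100.0
        # omega*dt <= 0.3 for the stiffest bond (reduced mass m/2)
        return max(100.0, 2.0 * kmax * self.timestep ** 2 / 0.09)


def draw_velocities(n: int, settings: MDSettings, top: Topology,
                    rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities at the configured temperature."""
    m = settings.effective_mass(top)
    return rng.standard_normal((n, 3)) * np.sqrt(kbt(settings.temperature) / m)


def run_stage(R, V, H: ProtonationState, top: Topology,
              settings: MDSettings, rng: np.random.Generator):
    """Advance tau MD steps; returns (R', V', kinetic_temperature).

    The protonation state is held fixed for the whole stage.  The stage is
    deterministic given the generator state (one 31-bit seed is drawn from
    ``rng`` for the thermostat noise).
    """
    R = np.ascontiguousarray(R, dtype=float).copy()
    V = np.ascontiguousarray(V, dtype=float).copy()
    if not np.isfinite(R).all():
        raise FloatingPointError("non-finite coordinates entering MD stage")
    mass = settings.effective_mass(top)
    seed = int(rng.integers(2 ** 31 - 1))
    args = top.kernel_args(H)
    try:
        ke_sum, ke_n = _kernels.baoab_stage(
            R, V, settings.tau, settings.timestep, settings.friction,
            kbt(settings.temperature), mass, seed,
            settings.ev_rebuild_every, settings.ev_list_cutoff, *args)
    except (ZeroDivisionError, OverflowError) as exc:
        raise FloatingPointError(
            f"numerical overflow within a {settings.tau}-step stage: {exc}")
    if not np.isfinite(R).all() or not np.isfinite(V).all():
        raise FloatingPointError(
            f"coordinate/velocity overflow within a {settings.tau}-step stage"
        )
    n_dof = 3 * R.shape[0]
    kinetic_T = 2.0 * (ke_sum / ke_n) / (n_dof * 0.0019872)
    return R, V, kinetic_T
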