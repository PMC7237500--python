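"""Orchestration of the alternating MC/MD schedule.

A run is one equilibration MD stage followed by ``rounds`` alternations of
(MD stage, MC stage).  The MD stage advances the structure at fixed
protonation state; the MC stage re-equilibrates the half-channels with their
reservoirs and attempts proton transfers at fixed structure.  Everything is
driven by a single seeded RNG stream (MD noise and MC draws interleave in a
fixed order), so a run is bit-reproducible from its config.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .langevin_md import MDSettings, draw_velocities, run_stage
from .proton_mc import (HopKinetics, ReservoirSpec, events_to_frame, mc_stage)
from .structure_io import build_ideal_fixture, load_calpha, set_ring_reference
from .topology_energy import (
    ROLE_CARRIER, MembraneGeometry, ProtonationState, Topology,
    TopologyParams, make_topology,
)


@dataclass
class RunConfig:
    """Thermodynamic parameters, kinetic constants, schedule and seed.

    Defaults are the wild-type synthesis-mode condition: pH 7.0 (IMS) /
    8.0 (matrix), membrane potential 150 mV, pKa(cE59) = 8.0,
    pKa(aE223) = 6.0, pKa(aE162) = 9.0, eps_mem = 10 kcal/mol, no external
    torque, 3000 rounds of tau = 1e5-step MD stages at 323 K.
    """

    structure: str = "fixture"        # "fixture" or a PDB path
    fixture_kwargs: dict = field(default_factory=dict)
    pH_ims: float = 7.0
    pH_matrix: float = 8.0
    delta_psi_mv: float = 150.0
    pka: dict = field(default_factory=lambda: {"cE59": 8.0, "aE223": 6.0,
                                               "aE162": 9.0})
    eps_mem: float = 10.0
    border_angles_deg: tuple = (51.2, -69.6)
    mem_d: float = 0.4
    torque_pn_nm: float = 0.0         # positive = hydrolysis direction
    mutations: tuple = ()
    temperature: float = 323.0
    friction: float = 2.0
    timestep: float = 0.1
    tau: int = 100_000
    rounds: int = 3000
    seed: int = 0
    mass: float = None
    kinetics: HopKinetics = field(default_factory=HopKinetics)
    mc_enabled: bool = True           # False: frozen protonation (FES runs)
    checkpoint_path: str = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "kinetics" in raw:
            raw["kinetics"] = HopKinetics(**raw["kinetics"])
        for key in ("mutations", "border_angles_deg"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = self.__dict__.copy()
        d["kinetics"] = self.kinetics.__dict__
        d["mutations"] = list(self.mutations)
        d["border_angles_deg"] = list(self.border_angles_deg)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    def md_settings(self) -> MDSettings:
        return MDSettings(temperature=self.temperature,
                          friction=self.friction,
                          timestep=self.timestep, tau=self.tau,
                          mass=self.mass)

    def reservoirs(self) -> dict:
        return {
            "IMS": ReservoirSpec("IMS", self.pH_ims, self.delta_psi_mv,
                                 self.pka["aE223"], self.temperature),
            "matrix": ReservoirSpec("matrix", self.pH_matrix,
                                    self.delta_psi_mv, self.pka["aE162"],
                                    self.temperature),
        }


@dataclass
class RunResult:
    config: RunConfig
    topology: Topology
    angles_deg: np.ndarray            # cumulative rotation angle per stage
    events: list
    occupancy: np.ndarray             # (rounds + 1, n_sites) after each stage
    summary: dict
    R: np.ndarray
    V: np.ndarray
    H: ProtonationState

    @property
    def event_frame(self) -> pd.DataFrame:
        return events_to_frame(self.events)


def build_system(config: RunConfig):
    """(structure, topology) for a config, with mutations applied."""
    if config.structure == "fixture":
        st = build_ideal_fixture(seed=config.seed, **config.fixture_kwargs)
        params = TopologyParams.fixture()
    else:
        st = load_calpha(config.structure)
        raise ValueError(
            "PDB input additionally requires chain roles and site residue "
            "numbers; use structure_io.load_calpha + annotate metadata and "
            "topology_energy.make_topology directly")
    membrane = MembraneGeometry(tuple(config.border_angles_deg),
                                config.mem_d, config.eps_mem)
    top = make_topology(st, params=params, membrane=membrane,
                        torque_pn_nm=config.torque_pn_nm, pka=config.pka)
    for m in config.mutations:
        top = apply_mutation(top, m)
    return st, top


def apply_mutation(top: Topology, name: str) -> Topology:
    """aR176A: neutralize the gate arginine and disable its blocking factor.
    c<k>E59A: remove carrier k from the protonatable registry (the bead
    becomes neutral and the protonation vector shrinks by one).
    """
    if name == "aR176A":
        q = top.fixed_charges.copy()
        q[top.r176_bead] = 0.0
        return replace(top, fixed_charges=q, r176_blocking=False,
                       mutations=top.mutations + (name,))
    m = re.fullmatch(r"c(\d+)E59A", name)
    if m:
        sub = int(m.group(1))
        keep = [s for s in range(top.n_sites)
                if not (top.site_roles[s] == ROLE_CARRIER
                        and top.carrier_subunit[s] == sub)]
        if len(keep) == top.n_sites:
            raise ValueError(f"no carrier for subunit {sub}")
        return replace(
            top,
            site_beads=top.site_beads[keep],
            site_roles=top.site_roles[keep],
            site_pka=top.site_pka[keep],
            site_labels=[top.site_labels[s] for s in keep],
            carrier_subunit=top.carrier_subunit[keep],
            carrier_neighbors=top.carrier_neighbors[keep],
            site_theta0=top.site_theta0[keep],
            mutations=top.mutations + (name,),
        )
    raise ValueError(
        f"unknown mutation {name!r}; supported: 'aR176A', 'c<k>E59A'")


def _azimuth_deg(R, bead) -> float:
    x, y = R[bead, 0], R[bead, 1]
    if x * x + y * y < 1e-12:
        raise ValueError("angle-tracking bead lies on the z-axis")
    return float(np.degrees(np.arctan2(y, x)))


def run(config: RunConfig) -> RunResult:
    """Execute the hybrid MC/MD schedule and return all observables."""
    st, top = build_system(config)
    settings = config.md_settings()
    rng = np.random.default_rng(config.seed)
    kin = config.kinetics
    reservoirs = config.reservoirs()

    H = top.initial_protonation()
    R = st.coords.copy()
    V = draw_velocities(st.n_beads, settings, top, rng)

    az0 = _azimuth_deg(R, top.angle_bead)
    angles = np.zeros(config.rounds + 1)
    occupancy = np.zeros((config.rounds + 1, top.n_sites), dtype=np.int8)
    events = []
    reservoir_in = {"IMS": 0, "matrix": 0}
    reservoir_out = {"IMS": 0, "matrix": 0}
    h_init = H.n_protons

    prev_az = az0
    cum = 0.0

    def advance_angle(R):
        nonlocal prev_az, cum
        az = _azimuth_deg(R, top.angle_bead)
        d = az - prev_az
        d = (d + 180.0) % 360.0 - 180.0
        cum += d
        prev_az = az
        return cum

    stage = 0
    try:
        # equilibration MD stage
        R, V, _ = run_stage(R, V, H, top, settings, rng)
        angles[0] = advance_angle(R)
        occupancy[0] = H.occupancy
        for r in range(1, config.rounds + 1):
            stage = r
            if config.mc_enabled:
                H, ev = mc_stage(R, H, top, kin, reservoirs, rng, stage=r,
                                 temperature=config.temperature)
                for e in ev:
                    if e.kind == "reservoir" and e.accepted:
                        if e.donor in reservoir_in:
                            reservoir_in[e.donor] += 1
                        else:
                            reservoir_out[e.acceptor] += 1
                events.extend(ev)
            R, V, _ = run_stage(R, V, H, top, settings, rng)
            angles[r] = advance_angle(R)
            occupancy[r] = H.occupancy
    except Exception:
        if config.checkpoint_path:
            np.savez(config.checkpoint_path, R=R, V=V,
                     occupancy=H.occupancy, stage=stage)
        raise

    gains = reservoir_in["IMS"] + reservoir_in["matrix"]
    losses = reservoir_out["IMS"] + reservoir_out["matrix"]
    summary = {
        "rotation_deg": float(angles[-1]),
        "revolutions": float(angles[-1] / 360.0),
        "reservoir_in_IMS": reservoir_in["IMS"],
        "reservoir_in_matrix": reservoir_in["matrix"],
        "reservoir_out_IMS": reservoir_out["IMS"],
        "reservoir_out_matrix": reservoir_out["matrix"],
        "proton_balance": h_init + gains - losses - H.n_protons,
        "n_md_stages": config.rounds + 1,
        "n_mc_stages": config.rounds if config.mc_enabled else 0,
    }
    return RunResult(config, top, angles, events, occupancy, summary,
                     R, V, H)


def run_scan(base: RunConfig, grid: dict, seeds) -> pd.DataFrame:
    """Expand a parameter grid x seeds, run each config, one summary row per
    run (the Fig.-5-style batch driver).  ``grid`` maps RunConfig field
    names to lists of values; nested pKa entries use 'pka.aE162' keys.
    """
    import itertools

    keys = list(grid)
    rows = []
    for values in itertools.product(*(grid[k] for k in keys)):
        cfg = replace(base)
        for k, v in zip(keys, values):
            if k.startswith("pka."):
                cfg.pka = dict(cfg.pka, **{k.split(".", 1)[1]: v})
            else:
                setattr(cfg, k, v)
        for seed in seeds:
            cfg_s = replace(cfg, seed=int(seed))
            res = run(cfg_s)
            row = {k: v for k, v in zip(keys, values)}
            row["seed"] = int(seed)
            row.update(res.summary)
            from .analysis import classify_itineraries
            counts = classify_itineraries(
                res.events, res.angles_deg,
                initial_occupancy_labels=_initial_labels(res))
            row.update({f"n_{k}": v for k, v in counts["counts"].items()})
            rows.append(row)
    return pd.DataFrame(rows)


def _initial_labels(res: RunResult):
    occ0 = res.occupancy[0]
    return [res.topology.site_labels[i] for i in range(len(occ0))
            if occ0[i] == 1]
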