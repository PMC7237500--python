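"""Monte-Carlo stage: reservoir exchange at the half-channels and Metropolis
proton transfers between the c-ring carriers and the a-subunit sites.

Each MC stage (protein structure frozen):

1. The two half-channel glutamates re-equilibrate with their aqueous
   reservoirs: the IMS-side site with probability
   P = exp(-eps/kBT) / (1 + exp(-eps/kBT)) where
   eps = (ln 10) kB T (pH - pKa) -/+ dPsi/2
   (minus for the IMS side, plus for the matrix side; the sites sit at
   mid-membrane so each sees half the membrane potential).
2. Every proton is visited in random order; a transfer to a deprotonated
   site on the other body (c-ring <-> a-subunit only) is attempted with
   probability (1 - exp(-k*tau*w)) * min(1, exp(-dE/kBT)), where the kinetic
   weight w = f(r) g(theta) h_R176 encodes donor/acceptor geometry and the
   gate arginine blocks transfers that would pass it in y.

w is symmetric under donor/acceptor exchange, so together with the
Metropolis factor the transfer step satisfies detailed balance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import COULOMB_K, LN10, kbt, mv_to_kcal_mol
from .topology_energy import (
    ROLE_CARRIER, ROLE_IMS, ROLE_MATRIX,
    ProtonationState, Topology, hop_angle, v_mem_switch,
)


@dataclass
class ReservoirSpec:
    """One aqueous proton reservoir coupled to a half-channel site."""

    side: str                  # "IMS" or "matrix"
    pH: float
    delta_psi_mv: float = 150.0   # matrix at -dPsi relative to IMS
    pka: float = 6.0
    temperature: float = 323.0

    def epsilon(self) -> float:
        """Effective protonation free energy of the site (kcal/mol)."""
        e = LN10 * kbt(self.temperature) * (self.pH - self.pka)
        half_psi = 0.5 * mv_to_kcal_mol(self.delta_psi_mv)
        if self.side == "IMS":
            return e - half_psi
        elif self.side == "matrix":
            return e + half_psi
        raise ValueError(f"unknown reservoir side {self.side!r}")


def boundary_protonation_probability(res: ReservoirSpec) -> float:
    """Equilibrium protonation probability of a half-channel site."""
    z = -res.epsilon() / kbt(res.temperature)
    # logistic, numerically safe for large |z|
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z))
    ez = math.exp(z)
    return ez / (1.0 + ez)


@dataclass
class HopKinetics:
    """Geometric kinetic weight parameters for proton hopping."""

    r0: float = 0.8        # nm: plateau distance (side-chain tips in contact)
    dr: float = 0.4        # nm: exponential decay length beyond r0
    sigma_deg: float = 36.0  # Gaussian width of the orientation factor
    k_tau: float = 1.0     # overall rate x stage length (dimensionless)

    def __post_init__(self):
        if min(self.r0, self.dr, self.sigma_deg, self.k_tau) <= 0:
            raise ValueError("all hop-kinetics parameters must be positive")


def transfer_weight(r: float, theta_deg: float, kin: HopKinetics,
                    theta0_deg: float = 0.0) -> float:
    """w(r, theta) = f(r) g(theta); the h_R176 gate is applied separately.

    f is 1 up to r0 and decays exponentially beyond; g is a Gaussian in the
    angle between the donor->acceptor vector and the carrier side-chain
    surrogate vector, peaked at the reference-structure angle theta0.
    A NaN angle (degenerate surrogate geometry) falls back to g = 1.
    """
    if r <= 0:
        raise ValueError("distance must be positive")
    f = 1.0 if r <= kin.r0 else math.exp(-(r - kin.r0) / kin.dr)
    if math.isnan(theta_deg) or math.isnan(theta0_deg):
        g = 1.0
    else:
        g = math.exp(-((theta_deg - theta0_deg) ** 2)
                     / (2.0 * kin.sigma_deg ** 2))
    return f * g


def arg_blocking_factor(y_r176: float, y_donor: float, y_acceptor: float) -> int:
    """0 when the gate arginine lies strictly between donor and acceptor in
    y (transfer would leak past the gate), 1 otherwise."""
    lo, hi = min(y_donor, y_acceptor), max(y_donor, y_acceptor)
    return 0 if lo < y_r176 < hi else 1


@dataclass
class ProtonEvent:
    stage: int
    kind: str          # "reservoir" or "hop"
    donor: str         # site label or reservoir side
    acceptor: str
    accepted: bool
    dE: float = float("nan")
    w: float = float("nan")


def events_to_frame(events) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.stage, e.kind, e.donor, e.acceptor, e.accepted, e.dE, e.w)
         for e in events],
        columns=["stage", "kind", "donor", "acceptor", "accepted", "dE", "w"],
    )


# ---------------------------------------------------------------------------
# energy differences at fixed R (V_non-es cancels; only Coulomb, membrane
# and pKa terms change with H)
# ---------------------------------------------------------------------------

def _delta_coulomb(R, q, bi, bj, dqi, dqj, partners, dielectric):
    """Coulomb energy change when charges on beads bi, bj change by dqi, dqj."""
    dE = 0.0
    for k in partners:
        if k == bi or k == bj:
            continue
        if q[k] == 0.0:
            continue
        if dqi != 0.0:
            dE += dqi * q[k] / np.linalg.norm(R[bi] - R[k])
        if dqj != 0.0:
            dE += dqj * q[k] / np.linalg.norm(R[bj] - R[k])
    rij = np.linalg.norm(R[bi] - R[bj])
    dE += ((q[bi] + dqi) * (q[bj] + dqj) - q[bi] * q[bj]) / rij
    return COULOMB_K * dE / dielectric


def _membrane_v(R, top: Topology, bead: int) -> float:
    nsc = top.membrane.normals()
    xb = max(float(nsc[b, 0] * R[bead, 0] + nsc[b, 1] * R[bead, 1])
             for b in range(2))
    return v_mem_switch(xb, top.membrane.d,
                        printed_form=top.membrane.printed_switch)


def transfer_delta_energy(R, H: ProtonationState, top: Topology,
                          donor: int, acceptor: int,
                          temperature: float) -> float:
    """dE (kcal/mol) for moving a proton from site ``donor`` to ``acceptor``.

    Computed by component difference: donor charge 0 -> -1, acceptor
    -1 -> 0; membrane penalty follows the carrier charges; the pKa term
    changes by (ln 10) kB T (pKa_donor - pKa_acceptor).
    """
    q = top.charges(H)
    bi = int(top.site_beads[donor])
    bj = int(top.site_beads[acceptor])
    partners = top.chargeable
    dE = _delta_coulomb(R, q, bi, bj, -1.0, +1.0, partners, top.dielectric)
    if top.site_roles[donor] == ROLE_CARRIER:
        dE += top.membrane.eps_mem * _membrane_v(R, top, bi)
    if top.site_roles[acceptor] == ROLE_CARRIER:
        dE -= top.membrane.eps_mem * _membrane_v(R, top, bj)
    dE += LN10 * kbt(temperature) * (top.site_pka[donor] - top.site_pka[acceptor])
    return float(dE)


def _pair_geometry(R, top: Topology, site_a: int, site_b: int):
    """(r, theta, theta0) for a carrier/channel pair, orientation from the
    carrier side-chain surrogate."""
    ba, bb = int(top.site_beads[site_a]), int(top.site_beads[site_b])
    r = float(np.linalg.norm(R[ba] - R[bb]))
    carrier = site_a if top.site_roles[site_a] == ROLE_CARRIER else site_b
    channel = site_b if carrier == site_a else site_a
    theta = hop_angle(R, int(top.site_beads[carrier]),
                      top.carrier_neighbors[carrier],
                      int(top.site_beads[channel]))
    return r, theta, float(top.site_theta0[channel])


def mc_stage(R, H: ProtonationState, top: Topology,
             kinetics: HopKinetics, reservoirs: dict,
             rng: np.random.Generator, stage: int = 0,
             temperature: float = 323.0):
    """One MC stage at frozen coordinates; returns (H', events).

    ``reservoirs`` maps {"IMS": ReservoirSpec, "matrix": ReservoirSpec};
    pass None to disable boundary exchange (closed system, transfers only).
    """
    H = H.copy()
    occ = H.occupancy
    events = []
    beta = 1.0 / kbt(temperature)

    # --- 1. boundary exchange at the half-channel sites ---
    if reservoirs is not None:
        for s in range(top.n_sites):
            role = top.site_roles[s]
            if role == ROLE_CARRIER:
                continue
            side = "IMS" if role == ROLE_IMS else "matrix"
            res = reservoirs[side]
            p = boundary_protonation_probability(res)
            new = 1 if rng.random() < p else 0
            if new != occ[s]:
                if new == 1:
                    events.append(ProtonEvent(stage, "reservoir", side,
                                              top.site_labels[s], True))
                else:
                    events.append(ProtonEvent(stage, "reservoir",
                                              top.site_labels[s], side, True))
                occ[s] = new

    # --- 2. transfers between c-ring and a-subunit sites ---
    proton_sites = [s for s in range(top.n_sites) if occ[s] == 1]
    rng.shuffle(proton_sites)
    for s in proton_sites:
        if occ[s] != 1:
            continue
        donor_is_c = top.site_roles[s] == ROLE_CARRIER
        acceptors = [a for a in range(top.n_sites)
                     if occ[a] == 0
                     and (top.site_roles[a] == ROLE_CARRIER) != donor_is_c]
        rng.shuffle(acceptors)
        for a in acceptors:
            r, theta, theta0 = _pair_geometry(R, top, s, a)
            w = transfer_weight(r, theta, kinetics, theta0)
            if top.r176_blocking and top.r176_bead >= 0:
                w *= arg_blocking_factor(
                    R[top.r176_bead, 1],
                    R[int(top.site_beads[s]), 1],
                    R[int(top.site_beads[a]), 1])
            if w == 0.0:
                continue
            p_geom = 1.0 - math.exp(-kinetics.k_tau * w)
            if rng.random() >= p_geom:
                continue
            dE = transfer_delta_energy(R, H, top, s, a, temperature)
            acc = dE <= 0 or rng.random() < math.exp(-beta * dE)
            events.append(ProtonEvent(stage, "hop", top.site_labels[s],
                                      top.site_labels[a], acc, dE, w))
            if acc:
                occ[s] = 0
                occ[a] = 1
                break   # at most one accepted move per proton per stage
    return H, events
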