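"""Reduced-model oracles for the stochastic engine.

The surrogate collapses the motor onto one angular coordinate within a
36-degree cell and the four printed deprotonation patterns
DEP(c1,c2) / DEP(c1,c2,c3) / DEP(c2,c3) / DEP(c2).  Angular motion is an
overdamped Metropolis walk on state-dependent wells (10-fold periodic once
unrolled over windings); protonation chemistry uses the same
boundary-probability and transfer-acceptance code paths as the full engine
(`proton_mc.boundary_protonation_probability`, `proton_mc.transfer_weight`,
the (1 - e^{-k tau w}) min(1, e^{-dE/kBT}) acceptance).  Because the state
space is tiny, the exact stationary behaviour is available from a direct
master-equation solve, which is the quantitative oracle the simulated
fluxes are checked against.

Also provides a synthetic event-log/angle-series generator used to unit
test the itinerary and pathway analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import LN10, kbt, pn_nm_to_kcal_mol
from .proton_mc import (HopKinetics, ProtonEvent, ReservoirSpec,
                        boundary_protonation_probability, transfer_weight)

# states
A, B, C, D = 0, 1, 2, 3          # DEP(c1,c2), DEP(c1,c2,c3), DEP(c2,c3), DEP(c2)
STATE_NAMES = ["DEP(c1,c2)", "DEP(c1,c2,c3)", "DEP(c2,c3)", "DEP(c2)"]


@dataclass
class SurrogateModel:
    """Parameters of the reduced motor model."""

    nb: int = 24                 # angle bins per 36-degree cell
    n_prop: int = 8              # Metropolis angle proposals per round
    kw: float = 0.004            # well stiffness, kcal/mol/deg^2
    dB: float = 0.3              # offset of DEP(c1,c2,c3), kcal/mol
    dD: float = 1.5              # offset of DEP(c2), kcal/mol
    x_A: float = 18.0            # well centres (deg, cell coordinates)
    x_B: float = 21.0
    x_C: float = 54.0            # = x_A + 36: the post-step well
    x_D: float = 21.0
    x_matrix: float = 20.0       # alignment angle of the matrix-side hop
    x_ims: float = 22.0          # alignment angle of the IMS-side hop
    gap_nm: float = 0.55         # carrier-channel gap at alignment
    ring_radius_nm: float = 2.6
    pH_ims: float = 7.0
    pH_matrix: float = 8.0
    delta_psi_mv: float = 150.0
    pka_c: float = 8.0
    pka_223: float = 6.0
    pka_162: float = 9.0
    temperature: float = 323.0
    torque_pn_nm: float = 0.0    # positive = hydrolysis (clockwise) direction
    kinetics: HopKinetics = field(default_factory=HopKinetics)

    # -- geometry-derived pieces -------------------------------------------
    def cell_width(self) -> float:
        return 36.0

    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.nb) + 0.5) * 36.0 / self.nb

    def potential(self, s: int, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        c = [self.x_A, self.x_B, self.x_C, self.x_D][s]
        off = [0.0, self.dB, 0.0, self.dD][s]
        return 0.5 * self.kw * (x - c) ** 2 + off

    def tilt(self, dx_deg: float) -> float:
        """Energy change of the applied torque for an angle move (kcal/mol).
        Positive torque opposes counterclockwise (positive) motion."""
        return pn_nm_to_kcal_mol(self.torque_pn_nm) * math.radians(dx_deg)

    def hop_weight(self, side: str, x: float) -> float:
        x0 = self.x_ims if side == "IMS" else self.x_matrix
        delta = x - x0
        r = math.sqrt(self.gap_nm ** 2
                      + (2.0 * self.ring_radius_nm
                         * math.sin(math.radians(delta) / 2.0)) ** 2)
        return transfer_weight(r, delta, self.kinetics, 0.0)

    def channel_prob(self, side: str) -> float:
        if side == "IMS":
            res = ReservoirSpec("IMS", self.pH_ims, self.delta_psi_mv,
                                self.pka_223, self.temperature)
        else:
            res = ReservoirSpec("matrix", self.pH_matrix, self.delta_psi_mv,
                                self.pka_162, self.temperature)
        return boundary_protonation_probability(res)

    # chemical moves: (target state, side, needs_channel_proton,
    #                  pKa_donor, pKa_acceptor, d_to_matrix, d_from_ims)
    def moves_from(self, s: int):
        pc, p223, p162 = self.pka_c, self.pka_223, self.pka_162
        if s == A:
            return [(B, "matrix", False, pc, p162, +1, 0),
                    (D, "IMS", True, p223, pc, 0, +1)]
        if s == B:
            return [(C, "IMS", True, p223, pc, 0, +1),
                    (A, "matrix", True, p162, pc, -1, 0)]
        if s == C:
            return [(B, "IMS", False, pc, p223, 0, -1),
                    (D, "matrix", True, p162, pc, -1, 0)]
        return [(C, "matrix", False, pc, p162, +1, 0),
                (A, "IMS", False, pc, p223, 0, -1)]

    def move_probability(self, s: int, x: float, target: int, side: str,
                         pka_donor: float, pka_acceptor: float) -> float:
        """Shared acceptance formula at fixed channel occupancy."""
        w = self.hop_weight(side, x)
        dE = (float(self.potential(target, x) - self.potential(s, x))
              + LN10 * kbt(self.temperature) * (pka_donor - pka_acceptor))
        p_geom = 1.0 - math.exp(-self.kinetics.k_tau * w)
        metro = min(1.0, math.exp(-dE / kbt(self.temperature)))
        return p_geom * metro


# ---------------------------------------------------------------------------
# stochastic simulation
# ---------------------------------------------------------------------------

def surrogate_run(params: SurrogateModel, seed: int, rounds: int = 20000):
    """Simulate the reduced model; returns angle series, event log and
    per-round flux counters (same sign conventions as the engine: positive
    proton flux = IMS -> matrix)."""
    rng = np.random.default_rng(seed)
    m = params
    dx = 36.0 / m.nb
    beta = 1.0 / kbt(m.temperature)
    p_i = m.channel_prob("IMS")
    p_m = m.channel_prob("matrix")

    b = m.nb // 2
    s = A
    winding = 0
    to_matrix = 0
    from_ims = 0
    angles = np.zeros(rounds + 1)
    events = []
    angles[0] = 36.0 * winding + (b + 0.5) * dx

    for rnd in range(1, rounds + 1):
        # --- angular sweep (overdamped Metropolis walk) ---
        for _ in range(m.n_prop):
            step = 1 if rng.random() < 0.5 else -1
            nb_, ns, dwind = b + step, s, 0
            if nb_ < 0:
                if s == A:
                    ns, nb_, dwind = C, m.nb - 1, -1
                else:
                    continue
            elif nb_ >= m.nb:
                if s == C:
                    ns, nb_, dwind = A, 0, +1
                else:
                    continue
            x_old = (b + 0.5) * dx
            x_new = (nb_ + 0.5) * dx + 36.0 * dwind
            dU = (float(m.potential(ns, (nb_ + 0.5) * dx)
                        - m.potential(s, x_old))
                  + m.tilt(x_new - x_old))
            if dU <= 0 or rng.random() < math.exp(-beta * dU):
                b, s = nb_, ns
                winding += dwind
        # --- chemistry (channels resampled, one move max) ---
        i223 = rng.random() < p_i
        m162 = rng.random() < p_m
        x = (b + 0.5) * dx
        moves = m.moves_from(s)
        order = rng.permutation(len(moves))
        for oi in order:
            tgt, side, needs, pd_, pa_, dtm, dfi = moves[oi]
            have = i223 if side == "IMS" else m162
            if needs != have:
                continue
            p = m.move_probability(s, x, tgt, side, pd_, pa_)
            if rng.random() < p:
                events.append(ProtonEvent(
                    rnd, "hop", STATE_NAMES[s], STATE_NAMES[tgt], True))
                s = tgt
                to_matrix += dtm
                from_ims += dfi
                break
        angles[rnd] = 36.0 * winding + (b + 0.5) * dx
    return {
        "angles_deg": angles,
        "events": events,
        "winding": winding,
        "to_matrix": to_matrix,
        "from_ims": from_ims,
        "rotation_per_round_deg": (angles[-1] - angles[0]) / rounds,
        "flux_to_matrix_per_round": to_matrix / rounds,
    }


# ---------------------------------------------------------------------------
# exact master-equation oracle
# ---------------------------------------------------------------------------

def _chem_kernel(m: SurrogateModel):
    """(T_chem, flux_matrix, flux_ims) marginalized over channel sampling
    and the random move order — exact probabilities of the simulation's
    chemistry step."""
    nb = m.nb
    n = 4 * nb
    T = np.zeros((n, n))
    f_tm = np.zeros(n)
    f_fi = np.zeros(n)
    p_i = m.channel_prob("IMS")
    p_m = m.channel_prob("matrix")
    for s in range(4):
        moves = m.moves_from(s)
        for b in range(nb):
            x = (b + 0.5) * 36.0 / nb
            i = s * nb + b
            stay = 0.0
            # marginalize over the 4 channel-occupancy combinations
            for i223 in (0, 1):
                for m162 in (0, 1):
                    pc = ((p_i if i223 else 1 - p_i)
                          * (p_m if m162 else 1 - p_m))
                    ps = []
                    for tgt, side, needs, pd_, pa_, dtm, dfi in moves:
                        have = i223 if side == "IMS" else m162
                        p = (m.move_probability(s, x, tgt, side, pd_, pa_)
                             if bool(needs) == bool(have) else 0.0)
                        ps.append((tgt, p, dtm, dfi))
                    # random order of two candidate moves, first success wins
                    (t1, p1, dtm1, dfi1), (t2, p2, dtm2, dfi2) = ps
                    q1 = p1 * (1.0 - 0.5 * p2)
                    q2 = p2 * (1.0 - 0.5 * p1)
                    T[i, t1 * nb + b] += pc * q1
                    T[i, t2 * nb + b] += pc * q2
                    stay += pc * (1.0 - q1 - q2)
                    f_tm[i] += pc * (q1 * dtm1 + q2 * dtm2)
                    f_fi[i] += pc * (q1 * dfi1 + q2 * dfi2)
            T[i, i] += stay
    return T, f_tm, f_fi


def _diff_kernel(m: SurrogateModel):
    """(T_diff, winding_flux) for a single Metropolis angle proposal."""
    nb = m.nb
    n = 4 * nb
    dx = 36.0 / nb
    beta = 1.0 / kbt(m.temperature)
    T = np.zeros((n, n))
    f_w = np.zeros(n)
    for s in range(4):
        for b in range(nb):
            i = s * nb + b
            stay = 0.0
            for step in (-1, 1):
                nb_, ns, dwind = b + step, s, 0
                if nb_ < 0:
                    if s == A:
                        ns, nb_, dwind = C, nb - 1, -1
                    else:
                        stay += 0.5
                        continue
                elif nb_ >= nb:
                    if s == C:
                        ns, nb_, dwind = A, 0, +1
                    else:
                        stay += 0.5
                        continue
                x_old = (b + 0.5) * dx
                dU = (float(m.potential(ns, (nb_ + 0.5) * dx)
                            - m.potential(s, x_old))
                      + m.tilt(step * dx))
                acc = min(1.0, math.exp(-beta * dU))
                T[i, ns * nb + nb_] += 0.5 * acc
                stay += 0.5 * (1.0 - acc)
                f_w[i] += 0.5 * acc * dwind
            T[i, i] += stay
    return T, f_w


def master_equation(m: SurrogateModel) -> dict:
    """Exact stationary per-round rates of the surrogate chain.

    Returns rotation (deg/round), winding flux (cells/round) and proton
    fluxes, from the stationary distribution of the exact round kernel
    T_round = T_diff^n_prop . T_chem (diffusion sweep, then chemistry, as
    in the simulation)."""
    T_d, f_w = _diff_kernel(m)
    T_c, f_tm, f_fi = _chem_kernel(m)
    T_round = np.linalg.matrix_power(T_d, m.n_prop) @ T_c
    # stationary distribution (row vector pi with pi = pi T)
    w, v = np.linalg.eig(T_round.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi) / np.abs(pi).sum()
    # winding accumulates over the n_prop proposals within a round
    wind_rate = 0.0
    p = pi.copy()
    for _ in range(m.n_prop):
        wind_rate += p @ f_w
        p = p @ T_d
    to_matrix_rate = p @ f_tm
    from_ims_rate = p @ f_fi
    return {
        "stationary": pi,
        "winding_per_round": float(wind_rate),
        "rotation_per_round_deg": float(36.0 * wind_rate),
        "flux_to_matrix_per_round": float(to_matrix_rate),
        "flux_from_ims_per_round": float(from_ims_rate),
        "protons_per_36deg": float(to_matrix_rate / wind_rate)
        if wind_rate != 0 else np.nan,
    }


# ---------------------------------------------------------------------------
# synthetic event-log generator for the analysis unit tests
# ---------------------------------------------------------------------------

def make_synthetic_logs(spec: dict, seed: int = 0):
    """Emit an (angle series, event log) pair realizing prescribed proton
    itineraries exactly.

    ``spec`` = {"angles": [...cumulative angle per stage...],
                "protons": [{"side_in", "stage_in", "carrier",
                             "board_stage", "unboard_stage",
                             "side_out", "stage_out"}, ...]}

    Conventions match the engine: the MC events of stage s act on the
    geometry of angle index s - 1.
    """
    angles = np.asarray(spec["angles"], dtype=float)
    channel = {"IMS": "aE223", "matrix": "aE162"}
    events = []
    for p in spec["protons"]:
        s_in, s_out = p["stage_in"], p["stage_out"]
        s_b = p.get("board_stage", s_in)
        s_u = p.get("unboard_stage", s_out)
        if not (s_in <= s_b <= s_u <= s_out):
            raise ValueError(
                f"inconsistent itinerary (exit before entry): {p}")
        ch_in = channel[p["side_in"]]
        ch_out = channel[p["side_out"]]
        events.append(ProtonEvent(s_in, "reservoir", p["side_in"], ch_in, True))
        events.append(ProtonEvent(s_b, "hop", ch_in, p["carrier"], True))
        events.append(ProtonEvent(s_u, "hop", p["carrier"], ch_out, True))
        events.append(ProtonEvent(s_out, "reservoir", ch_out,
                                  p["side_out"], True))
    events.sort(key=lambda e: e.stage)
    return angles, events
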