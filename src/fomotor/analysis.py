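"""Observables: rotation angles, 36-degree step census, proton-itinerary
classification (transport / leak / idle), pathway census, protonation-state
conditioned free-energy curves, stall torque and transduction efficiency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import LN10, kbt, pn_nm_to_kcal_mol


# ---------------------------------------------------------------------------
# rotation angle
# ---------------------------------------------------------------------------

def rotation_angle(frame, bead_index: int, initial_azimuth_deg: float) -> float:
    """Signed xy-azimuth (deg) of a tracked bead relative to its initial
    azimuth; counterclockwise viewed from the matrix side is positive."""
    x, y = frame[bead_index, 0], frame[bead_index, 1]
    if x * x + y * y < 1e-12:
        raise ValueError("tracked bead lies on the z-axis")
    d = np.degrees(np.arctan2(y, x)) - initial_azimuth_deg
    return float((d + 180.0) % 360.0 - 180.0)


def unwrap_cumulative(angles_deg) -> np.ndarray:
    """Standard phase unwrapping of a wrapped angle series (degrees)."""
    a = np.asarray(angles_deg, dtype=float)
    if len(a) == 0:
        raise ValueError("empty angle series")
    jumps = np.abs((np.diff(a) + 180.0) % 360.0 - 180.0)
    if (jumps >= 179.5).any():
        warnings.warn("angle jump >= 180 deg between samples; series is "
                      "undersampled and unwrapping is ambiguous")
    return np.degrees(np.unwrap(np.radians(a)))


# ---------------------------------------------------------------------------
# proton itineraries: transport / leak / idle
# ---------------------------------------------------------------------------

@dataclass
class ProtonItinerary:
    entry_side: str
    entry_stage: int
    exit_side: str = None
    exit_stage: int = None
    bound_rotation_deg: float = 0.0
    rode_carrier: bool = False
    carrier_sites: list = field(default_factory=list)

    @property
    def completed(self) -> bool:
        return self.exit_side is not None


def reconstruct_itineraries(events, angles_deg,
                            initial_occupancy_labels=()):
    """Follow every proton through the event log.

    Reservoir events create/destroy protons at the half-channel sites; hops
    move them between channel and carrier sites.  While a proton sits on a
    carrier it accumulates the ring rotation of its residence interval.
    Protons present at t = 0 have no reservoir entry and are kept but marked
    with entry_side = "initial".
    """
    angles = np.asarray(angles_deg, dtype=float)
    on_site = {}      # site label -> ProtonItinerary
    done, unclosed = [], []
    for lab in initial_occupancy_labels:
        on_site[lab] = ProtonItinerary("initial", 0)

    by_stage = {}
    for e in events:
        if not e.accepted:
            continue
        by_stage.setdefault(e.stage, []).append(e)

    last = len(angles) - 1

    def aidx(stage):
        # the MC stage r acts on the geometry produced by MD stage r-1
        return max(0, min(stage - 1, last))

    for stage in sorted(by_stage):
        for e in by_stage[stage]:
            if e.kind == "reservoir":
                if e.donor in ("IMS", "matrix"):
                    on_site[e.acceptor] = ProtonItinerary(e.donor, stage)
                else:
                    it = on_site.pop(e.donor, None)
                    if it is not None:
                        it.exit_side = e.acceptor
                        it.exit_stage = stage
                        done.append(it)
            elif e.kind == "hop":
                it = on_site.pop(e.donor, None)
                if it is None:       # proton of unknown origin (shouldn't happen)
                    it = ProtonItinerary("initial", stage)
                if _is_carrier(e.acceptor):
                    it.rode_carrier = True
                    it.carrier_sites.append(e.acceptor)
                    it._board_stage = stage
                elif _is_carrier(e.donor):
                    s0 = getattr(it, "_board_stage", stage)
                    it.bound_rotation_deg += angles[aidx(stage)] - angles[aidx(s0)]
                on_site[e.acceptor] = it
    # still on a site at the end of the run
    for lab, it in on_site.items():
        if _is_carrier(lab):
            s0 = getattr(it, "_board_stage", last + 1)
            it.bound_rotation_deg += angles[last] - angles[aidx(s0)]
        unclosed.append(it)
    return done, unclosed


def _is_carrier(label: str) -> bool:
    return label.startswith("c") and label.endswith("E59")


def classify_itineraries(events, angles_deg, initial_occupancy_labels=(),
                         transport_threshold_deg: float = 180.0) -> dict:
    """Label completed itineraries and tally per class and direction.

    transport: entry and exit sides differ and the proton rode the ring the
    long way (|bound rotation| >= threshold, ~36 x 8 in a tightly coupled
    step); leak: sides differ, short way past the a-subunit (~36 x 2);
    idle: exit side equals entry side (~360 of riding).  Channel-only visits
    (never boarded a carrier) are tallied separately as 'flicker'.
    """
    done, unclosed = reconstruct_itineraries(events, angles_deg,
                                             initial_occupancy_labels)
    counts = {"transport_ims_to_matrix": 0, "transport_matrix_to_ims": 0,
              "leak_ims_to_matrix": 0, "leak_matrix_to_ims": 0,
              "idle": 0, "flicker": 0}
    labelled = []
    for it in done:
        if it.entry_side == "initial":
            continue
        if not it.rode_carrier:
            counts["flicker"] += 1
            continue
        if it.entry_side == it.exit_side:
            lab = "idle"
        else:
            direction = ("ims_to_matrix" if it.entry_side == "IMS"
                         else "matrix_to_ims")
            kind = ("transport"
                    if abs(it.bound_rotation_deg) >= transport_threshold_deg
                    else "leak")
            lab = f"{kind}_{direction}"
        counts[lab] += 1
        labelled.append((it, lab))

    total_rot = abs(float(np.asarray(angles_deg)[-1]
                          - np.asarray(angles_deg)[0]))
    revs = total_rot / 360.0
    per_rev = {k: (v / revs if revs > 0 else np.nan)
               for k, v in counts.items() if k != "flicker"}
    net_ims_to_matrix = (
        counts["transport_ims_to_matrix"] + counts["leak_ims_to_matrix"]
        - counts["transport_matrix_to_ims"] - counts["leak_matrix_to_ims"])
    return {"counts": counts, "per_revolution": per_rev,
            "net_ims_to_matrix": net_ims_to_matrix,
            "itineraries": labelled, "n_unclosed": len(unclosed)}


# ---------------------------------------------------------------------------
# 36-degree step census
# ---------------------------------------------------------------------------

def step_census(angles_deg, bandwidth_deg: float = 3.0,
                grid_deg: float = 1.0, depth: float = 0.7) -> dict:
    """Histogram of the angle mod 360 with von Mises smoothing; minima are
    the low-population gaps separating the 36-degree steps.

    A local minimum is significant when its density is below ``depth`` times
    the geometric mean of the flanking maxima.  Returns the density grid,
    minima locations, their count and mean spacing.
    """
    a = np.asarray(angles_deg, dtype=float)
    if len(a) == 0:
        raise ValueError("empty angle series")
    theta = np.radians(a % 360.0)
    grid = np.radians(np.arange(0.0, 360.0, grid_deg))
    kappa = 1.0 / np.radians(bandwidth_deg) ** 2
    dens = np.exp(kappa * (np.cos(grid[:, None] - theta[None, :]) - 1.0)).sum(axis=1)
    dens /= dens.sum() * np.radians(grid_deg)

    n = len(grid)
    minima = []
    for i in range(n):
        if dens[i] < dens[(i - 1) % n] and dens[i] <= dens[(i + 1) % n]:
            # flanking maxima
            j = i
            while dens[(j - 1) % n] >= dens[j % n] and (i - j) < n:
                j -= 1
            k = i
            while dens[(k + 1) % n] >= dens[k % n] and (k - i) < n:
                k += 1
            flank = np.sqrt(dens[j % n] * dens[k % n])
            if flank > 0 and dens[i] < depth * flank:
                minima.append(np.degrees(grid[i]))
    minima = np.array(sorted(minima))
    if len(minima) > 1:
        gaps = np.diff(np.concatenate([minima, [minima[0] + 360.0]]))
        spacing = float(gaps.mean())
    else:
        spacing = np.nan
    return {"grid_deg": np.degrees(grid), "density": dens,
            "minima_deg": minima, "n_minima": len(minima),
            "mean_spacing_deg": spacing}


# ---------------------------------------------------------------------------
# pathway census (Paths 1-7)
# ---------------------------------------------------------------------------

def _rolling_slot(subunit: int, k_step: int, n_c: int) -> int:
    """Molecular subunit -> rolling slot after k CCW 36-degree steps.

    Subunits are numbered clockwise; after one CCW step the former c2
    occupies the c1 slot.
    """
    return ((subunit - 1 - k_step) % n_c) + 1


#: printed pathway templates: ordered (action, slot, partner-side) tokens;
#: 'theta_min' distinguishes Path 3 (late protonation) from Path 1.
PATH_TEMPLATES = {
    1: {"step": +1, "tokens": [("deprot", 3, "matrix"), ("prot", 1, "IMS")],
        "theta_max": 10.0},
    2: {"step": +1, "tokens": [("prot", 1, "IMS"), ("deprot", 3, "matrix")]},
    3: {"step": +1, "tokens": [("deprot", 3, "matrix"), ("prot", 1, "IMS")],
        "theta_min": 10.0},
    4: {"step": -1, "tokens": [("deprot", 1, "IMS"), ("prot", 3, "matrix")]},
    5: {"step": -1, "tokens": [("prot", 3, "matrix"), ("deprot", 1, "IMS")]},
    6: {"step": -1, "tokens": [("prot", 3, "IMS"), ("deprot", 1, "matrix")]},
    7: {"step": 0, "tokens": [("prot", 1, "IMS"), ("deprot", 1, "matrix")]},
}


def pathway_census(events, angles_deg, n_c: int = 10) -> dict:
    """Count 36-degree step windows matching the printed Paths 1-7.

    Within each completed step window the ordered carrier
    protonation-change tokens (action, rolling slot, partner side) are
    matched as a subsequence against each template; the first match wins,
    unmatched windows with events count as 'other'.  Path 7 (leak without
    net rotation) is matched inside windows that do not complete a step.
    """
    angles = np.asarray(angles_deg, dtype=float)
    tokens = []      # (stage, action, subunit, side, theta_local)
    for e in events:
        if not e.accepted or e.kind != "hop":
            continue
        if _is_carrier(e.donor):
            sub = int(e.donor[1:-3])
            side = "IMS" if e.acceptor == "aE223" else "matrix"
            tokens.append((e.stage, "deprot", sub, side))
        elif _is_carrier(e.acceptor):
            sub = int(e.acceptor[1:-3])
            side = "IMS" if e.donor == "aE223" else "matrix"
            tokens.append((e.stage, "prot", sub, side))

    k_of = np.floor((angles + 18.0) / 36.0).astype(int)
    counts = {p: 0 for p in PATH_TEMPLATES}
    counts["other"] = 0
    # split stages into maximal constant-k windows
    boundaries = [0] + [i for i in range(1, len(k_of))
                        if k_of[i] != k_of[i - 1]] + [len(k_of)]
    for w in range(len(boundaries) - 1):
        lo, hi = boundaries[w], boundaries[w + 1]
        k = int(k_of[lo])
        step = 0
        if hi < len(k_of):
            step = int(np.sign(k_of[hi] - k))
        wtok = []
        for (st, act, sub, side) in tokens:
            gi = max(0, min(st - 1, len(angles) - 1))
            if lo <= gi < hi:
                slot = _rolling_slot(sub, k, n_c)
                theta = angles[gi] - 36.0 * k
                wtok.append((act, slot, side, theta))
        if not wtok:
            continue
        matched = None
        for p, tpl in PATH_TEMPLATES.items():
            if tpl["step"] != step:
                continue
            if _match_subsequence(wtok, tpl):
                matched = p
                break
        if matched is None:
            counts["other"] += 1
        else:
            counts[matched] += 1
    return counts


def _match_subsequence(wtok, tpl) -> bool:
    pos = 0
    need = tpl["tokens"]
    for (act, slot, side, theta) in wtok:
        want = need[pos]
        if (act, slot, side) == want:
            if act == "prot" and "theta_max" in tpl and theta > tpl["theta_max"]:
                continue
            if act == "prot" and "theta_min" in tpl and theta < tpl["theta_min"]:
                continue
            pos += 1
            if pos == len(need):
                return True
    return False


# ---------------------------------------------------------------------------
# protonation-state conditioned free-energy curves
# ---------------------------------------------------------------------------

def state_conditioned_fes(angle_samples_deg, bins=72, angle_range=None,
                          temperature: float = 323.0,
                          energy_offset: float = 0.0,
                          torque_pn_nm: float = 0.0) -> dict:
    """F(theta) = -kBT ln P(theta) + offset, from frozen-protonation sampling.

    ``energy_offset`` aligns curves of different protonation states within a
    comparison set (the H-dependent energy terms); a nonzero torque adds the
    analytic tilt -tau * theta.  Empty bins are masked (NaN), not zero.
    """
    a = np.asarray(angle_samples_deg, dtype=float)
    if angle_range is None:
        angle_range = (a.min(), a.max())
    hist, edges = np.histogram(a, bins=bins, range=angle_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    F = np.full(len(hist), np.nan)
    ok = hist > 0
    F[ok] = -kbt(temperature) * np.log(hist[ok] / hist.sum())
    F += energy_offset
    if torque_pn_nm:
        F -= pn_nm_to_kcal_mol(torque_pn_nm) * np.radians(centers)
    F -= np.nanmin(F)
    return {"angle_deg": centers, "free_energy_kcal_mol": F}


# ---------------------------------------------------------------------------
# stall torque and efficiency
# ---------------------------------------------------------------------------

def stall_torque_scan(torques_pn_nm, rates, rate_errors=None) -> dict:
    """Interpolate the mean net rotation rate vs opposing torque to zero.

    ``rates`` is the signed rotation rate (positive = synthesis direction)
    at each torque.  With no sign change only a bound is reported.
    """
    t = np.asarray(torques_pn_nm, dtype=float)
    r = np.asarray(rates, dtype=float)
    order = np.argsort(t)
    t, r = t[order], r[order]
    if rate_errors is not None:
        rate_errors = np.asarray(rate_errors, dtype=float)[order]
    for i in range(len(t) - 1):
        if r[i] > 0 and r[i + 1] < 0:
            stall = t[i] + (t[i + 1] - t[i]) * r[i] / (r[i] - r[i + 1])
            err = np.nan
            if rate_errors is not None:
                slope = (r[i] - r[i + 1]) / (t[i + 1] - t[i])
                err = float(np.hypot(rate_errors[i], rate_errors[i + 1])
                            / (2 * abs(slope)))
            return {"stall_pn_nm": float(stall), "kind": "interpolated",
                    "bracket": (float(t[i]), float(t[i + 1])),
                    "uncertainty_pn_nm": err}
    if (r > 0).all():
        return {"stall_pn_nm": np.nan, "kind": "lower_bound",
                "bound_pn_nm": float(t.max())}
    return {"stall_pn_nm": np.nan, "kind": "upper_bound",
            "bound_pn_nm": float(t.min())}


def efficiency(stall_torque_pn_nm: float, ph_ims: float, ph_matrix: float,
               delta_psi_mv: float, temperature: float = 323.0,
               n_c: int = 10) -> dict:
    """Free-energy transduction efficiency of the motor.

    Work per proton = tau_stall * 2 pi / n_c; proton-motive free energy per
    proton = kB T ln 10 (pH_matrix - pH_IMS) + |e| dPsi.  Unit conversions:
    1 kcal/mol = 6.9477 pN nm = 0.04337 eV.
    """
    work_pn_nm = stall_torque_pn_nm * 2.0 * np.pi / n_c
    work_kcal = pn_nm_to_kcal_mol(work_pn_nm)
    pmf_ph = LN10 * kbt(temperature) * (ph_matrix - ph_ims)
    pmf_psi = (delta_psi_mv / 1000.0) / 0.04337
    pmf = pmf_ph + pmf_psi
    if pmf <= 0:
        raise ValueError("proton-motive free energy must be positive")
    return {
        "work_per_proton_pn_nm": float(work_pn_nm),
        "work_per_proton_kcal_mol": float(work_kcal),
        "pmf_ph_kcal_mol": float(pmf_ph),
        "pmf_psi_kcal_mol": float(pmf_psi),
        "pmf_total_kcal_mol": float(pmf),
        "eta": float(work_kcal / pmf),
    }


def net_flux(events, stage_min: int = 0) -> dict:
    """Net proton exchange with each reservoir from the event log.

    Positive ``net_to_matrix`` counts protons delivered to the matrix side
    (reservoir exits minus entries at the matrix channel); positive
    ``net_from_ims`` counts protons taken up from the IMS.  In steady state
    both equal the net IMS -> matrix flux; unlike the per-itinerary
    classification this is meaningful for runs shorter than the ~288-degree
    transit of a single proton.  ``stage_min`` discards early stages so a
    steady-state rate can be formed without the one-time flush of the
    protons initially bound to the ring.
    """
    out = {"IMS": 0, "matrix": 0}
    inn = {"IMS": 0, "matrix": 0}
    for e in events:
        if e.kind != "reservoir" or not e.accepted or e.stage < stage_min:
            continue
        if e.donor in inn:
            inn[e.donor] += 1
        else:
            out[e.acceptor] += 1
    return {
        "net_to_matrix": out["matrix"] - inn["matrix"],
        "net_from_ims": inn["IMS"] - out["IMS"],
    }
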