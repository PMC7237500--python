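"""Protonation-state-dependent energy function of the a/c-ring model.

V_total(R, H+) = V_non-es(R) + V_es(R, H+) + V_pKa(H+)

* V_non-es: a C-alpha structure-based (Go-like) potential biased to the
  reference structure — harmonic bonds/angles, periodic dihedrals, 10-12
  native-contact wells (intra-chain and between neighbouring c-subunits
  only), and residue-size-dependent excluded volume between the a-subunit
  and the ring (no attractive a/ring contacts, so ring symmetry is not
  broken).
* V_es = Coulomb (uniform dielectric 10, no cutoff) + the implicit-membrane
  penalty eps_mem charged carriers pay for facing the lipid phase.
* V_pKa = -(ln 10) kB T sum_i pKa_i h_i: the intrinsic protonation
  preference of each site.

Restraints (ring-axis circle fit, a-subunit anchors) and the external torque
on the ring top are bookkept here as well, since they act through the same
force kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from .constants import COULOMB_K, LN10, kbt, pn_nm_to_kcal_mol
from .structure_io import CGStructure

# Residue hard-sphere diameters (nm) for the excluded-volume term
# (standard coarse-grained residue sizes; pair sigma is the arithmetic mean).
RESIDUE_SIGMA = {
    "ALA": 0.504, "ARG": 0.656, "ASN": 0.568, "ASP": 0.558, "CYS": 0.548,
    "GLN": 0.602, "GLU": 0.592, "GLY": 0.450, "HIS": 0.608, "ILE": 0.618,
    "LEU": 0.618, "LYS": 0.636, "MET": 0.618, "PHE": 0.636, "PRO": 0.556,
    "SER": 0.518, "THR": 0.562, "TRP": 0.678, "TYR": 0.646, "VAL": 0.586,
}

POSITIVE_RESIDUES = {"ARG", "LYS"}
NEGATIVE_RESIDUES = {"ASP", "GLU"}

ROLE_CARRIER = 0
ROLE_IMS = 1
ROLE_MATRIX = 2

DEFAULT_PKA = {"cE59": 8.0, "aE223": 6.0, "aE162": 9.0}


@dataclass
class ProtonationState:
    """Binary occupancy over the protonatable sites (1 = protonated)."""

    occupancy: np.ndarray
    labels: list = None

    def __post_init__(self):
        occ = np.asarray(self.occupancy)
        if not np.isin(occ, (0, 1)).all():
            raise ValueError("occupancy entries must be 0 or 1")
        self.occupancy = occ.astype(np.int8)

    def __len__(self):
        return len(self.occupancy)

    @property
    def n_protons(self) -> int:
        return int(self.occupancy.sum())

    def charges(self) -> np.ndarray:
        """Site charges q_i = h_i - 1 (deprotonated glutamate carries -1)."""
        return self.occupancy.astype(float) - 1.0

    def copy(self) -> "ProtonationState":
        return ProtonationState(self.occupancy.copy(), self.labels)


@dataclass
class MembraneGeometry:
    """Implicit membrane: angular wedge facing the a-subunit has no penalty.

    The two border planes contain the z-axis at the given angles from +x;
    the lipid region is the complement of the wedge (which contains the
    a-subunit, i.e. the +x axis).  x(r) is the normal coordinate of each
    border, positive on the lipid side; the switch rises from 0 to 1 over
    width d.
    """

    border_angles_deg: tuple = (51.2, -69.6)
    d: float = 0.4              # nm
    eps_mem: float = 10.0       # kcal/mol
    printed_switch: bool = False  # legacy (discontinuous) switch form

    def normals(self) -> np.ndarray:
        """(2, 2) in-plane unit normals pointing into the lipid."""
        a1 = np.deg2rad(self.border_angles_deg[0])
        a2 = np.deg2rad(self.border_angles_deg[1])
        # x1 = rho*sin(phi - a1) = -sin(a1)*x + cos(a1)*y   (lipid at phi > a1)
        # x2 = rho*sin(a2 - phi) =  sin(a2)*x - cos(a2)*y   (lipid at phi < a2)
        return np.array([[-np.sin(a1), np.cos(a1)],
                         [np.sin(a2), -np.cos(a2)]])


def v_mem_switch(x: float, d: float, printed_form: bool = False):
    """Membrane switching function: 0 at the interface, 1 in the lipid.

    The smooth monotone form (1 - cos(pi x / d)) / 2 is used by default; the
    legacy piecewise form (1 + cos(x / d)) / 2 is retained behind a flag for
    comparison (it is discontinuous at x = d and non-monotone, so it is not
    used in production runs).
    """
    x = np.asarray(x, dtype=float)
    if d <= 0:
        raise ValueError("switch width d must be positive")
    if printed_form:
        mid = 0.5 * (1.0 + np.cos(x / d))
    else:
        mid = 0.5 * (1.0 - np.cos(np.pi * x / d))
    out = np.where(x <= 0.0, 0.0, np.where(x >= d, 1.0, mid))
    return float(out) if out.ndim == 0 else out


def pka_energy(H: ProtonationState, pka: np.ndarray, temperature: float) -> float:
    """V_pKa = -(ln 10) kB T sum_i pKa_i h_i  (kcal/mol)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return float(-LN10 * kbt(temperature) * np.dot(pka, H.occupancy))


@dataclass
class TopologyParams:
    """Force-field constants of the structure-based potential.

    Defaults are standard C-alpha Go-model values (energies kcal/mol,
    lengths nm).  The synthetic fixture uses a softer bond constant so that
    rotational diffusion is reachable at desk scale (see docs/methods.md);
    the reference-biasing role of every term is unchanged.
    """

    bond_k: float = 1.0e4          # kcal/mol/nm^2  (= 100 kcal/mol/A^2)
    angle_k: float = 20.0          # kcal/mol/rad^2
    dihedral_k1: float = 1.0
    dihedral_k3: float = 0.5
    contact_eps: float = 0.3
    contact_cutoff: float = 0.65   # nm between C-alpha pairs
    contact_min_dist: float = 0.35  # closer reference pairs are excluded
    contact_min_seqsep: int = 4
    interface_cutoff: float = 0.65  # c-subunit/c-subunit interface pairs
    ev_eps: float = 0.2
    dielectric: float = 10.0
    k_ring_restraint: float = 100.0   # kcal/mol/nm^2 (= 1 kcal/mol/A^2)
    k_anchor: float = 100.0
    k_zcom: float = 1.0

    @classmethod
    def fixture(cls) -> "TopologyParams":
        """Parameter set for the synthetic fixture.

        The idealized hairpins have far fewer native contacts per residue
        than a real helical bundle, so the per-contact depth and the local
        dihedral stiffness are raised to keep the ring a rigid body at
        323 K, and the bond constant is softened so that a light bead mass
        (hence desk-scale rotational diffusion) still resolves the stiffest
        bond with the default timestep.
        """
        return cls(bond_k=400.0, interface_cutoff=1.35, contact_eps=1.2,
                   dihedral_k1=2.0, dihedral_k3=1.0, angle_k=30.0)


@dataclass
class Topology:
    """All interaction terms, the protonatable-site registry, restraints
    and the torque specification for one a/c-ring system."""

    n_beads: int
    # bonded / contact / excluded-volume arrays
    bonds: np.ndarray
    bond_k: np.ndarray
    bond_r0: np.ndarray
    angles: np.ndarray
    angle_k: np.ndarray
    angle_t0: np.ndarray
    dihedrals: np.ndarray
    dihedral_k1: np.ndarray
    dihedral_k3: np.ndarray
    dihedral_p0: np.ndarray
    contacts: np.ndarray
    contact_eps: np.ndarray
    contact_r0: np.ndarray
    ev_pairs: np.ndarray
    ev_sigma: np.ndarray
    ev_eps: float
    # electrostatics
    fixed_charges: np.ndarray         # per bead, protonatable sites excluded
    coulomb_pairs: np.ndarray
    dielectric: float
    # protonatable-site registry
    site_beads: np.ndarray            # bead index per site
    site_roles: np.ndarray            # ROLE_CARRIER / ROLE_IMS / ROLE_MATRIX
    site_pka: np.ndarray
    site_labels: list
    carrier_subunit: np.ndarray       # subunit number for carriers, -1 else
    carrier_neighbors: np.ndarray     # (n_sites, 2) chain neighbours, -1 if n/a
    site_theta0: np.ndarray           # reference hop angle (deg) for channels
    r176_bead: int
    r176_blocking: bool
    # membrane
    membrane: MembraneGeometry
    # restraints & torque
    level_beads: tuple                # two tuples of ring bead indices
    level_center_z: np.ndarray
    ring_beads: np.ndarray
    ring_zref: float
    anchor_beads: np.ndarray
    anchor_ref: np.ndarray
    torque_beads: np.ndarray
    torque_pn_nm: float = 0.0
    params: TopologyParams = field(default_factory=TopologyParams)
    angle_bead: int = -1              # bead whose azimuth defines the rotation angle
    mutations: tuple = ()
    _ref_coords: np.ndarray = None    # reference coordinates (nm)

    # -- derived helpers ----------------------------------------------------
    @property
    def n_sites(self) -> int:
        return len(self.site_beads)

    def charges(self, H: ProtonationState) -> np.ndarray:
        """Per-bead charge vector for protonation state H."""
        if len(H) != self.n_sites:
            raise ValueError(
                f"protonation state has {len(H)} entries, registry has "
                f"{self.n_sites} sites")
        q = self.fixed_charges.copy()
        q[self.site_beads] = H.charges()
        return q

    def site_index(self, label: str) -> int:
        return self.site_labels.index(label)

    @property
    def chargeable(self) -> np.ndarray:
        """Beads that can carry charge (fixed or protonatable)."""
        if getattr(self, "_chargeable_cache", None) is None:
            self._chargeable_cache = (np.unique(self.coulomb_pairs)
                                      if len(self.coulomb_pairs)
                                      else np.zeros(0, dtype=np.int64))
        return self._chargeable_cache

    def initial_protonation(self) -> ProtonationState:
        """Default initial state: deprotonate the two wedge-facing carriers
        on the IMS side of the a-subunit interface plus the matrix channel
        site; everything else holds a proton.  (The steady state does not
        depend on this choice — protonation equilibrates quickly.)
        """
        occ = np.ones(self.n_sites, dtype=np.int8)
        lo = min(self.membrane.border_angles_deg)
        hi = max(self.membrane.border_angles_deg)
        wedge = []
        for s in range(self.n_sites):
            if self.site_roles[s] == ROLE_CARRIER:
                az = azim_of(self._ref_coords[self.site_beads[s]])
                if lo < az < hi:
                    wedge.append((az, s))
        wedge.sort(reverse=True)   # IMS channel sits at the high-angle border
        for _, s in wedge[:2]:
            occ[s] = 0
        for s in range(self.n_sites):
            if self.site_roles[s] == ROLE_MATRIX:
                occ[s] = 0
        return ProtonationState(occ, list(self.site_labels))

    def kernel_args(self, H: ProtonationState):
        """Static argument tuple for the numba kernels (charges included)."""
        q = self.charges(H)
        mem_sites = self.site_beads[self.site_roles == ROLE_CARRIER]
        mem_w = np.abs(q[mem_sites])
        lvl_beads = np.concatenate([np.asarray(l, dtype=np.int64)
                                    for l in self.level_beads])
        lvl_ptr = np.array(
            [0, len(self.level_beads[0]),
             len(self.level_beads[0]) + len(self.level_beads[1])],
            dtype=np.int64)
        return (
            self.bonds, self.bond_k, self.bond_r0,
            self.angles, self.angle_k, self.angle_t0,
            self.dihedrals, self.dihedral_k1, self.dihedral_k3,
            self.dihedral_p0,
            self.contacts, self.contact_eps, self.contact_r0,
            self.ev_pairs, self.ev_sigma, self.ev_eps,
            q, self.coulomb_pairs, self.dielectric,
            mem_sites.astype(np.int64), mem_w, self.membrane.normals(),
            self.membrane.d, self.membrane.eps_mem,
            lvl_beads, lvl_ptr, self.level_center_z,
            self.params.k_ring_restraint,
            self.ring_beads, self.ring_zref, self.params.k_zcom,
            self.anchor_beads, self.anchor_ref, self.params.k_anchor,
            self.torque_beads, pn_nm_to_kcal_mol(self.torque_pn_nm),
        )


def azim_of(xyz) -> float:
    return float(np.rad2deg(np.arctan2(xyz[1], xyz[0])))


# ---------------------------------------------------------------------------
# Topology construction
# ---------------------------------------------------------------------------

def build_topology(structure: CGStructure,
                   params: TopologyParams = None,
                   membrane: MembraneGeometry = None,
                   torque_pn_nm: float = 0.0,
                   pka: dict = None) -> Topology:
    """Build the full interaction topology from a prepared structure.

    The structure must carry a site registry in ``metadata`` (the synthetic
    fixture provides one; for a real structure use
    :func:`annotate_sites` first).
    """
    md = structure.metadata
    required = ("carrier_beads", "aE223", "aE162", "aR176", "c_chains",
                "a_chain", "torque_beads", "anchor_beads", "ring_level_beads")
    for key in required:
        if key not in md:
            raise ValueError(f"structure metadata lacks '{key}'; "
                             "annotate sites before building a topology")
    if params is None:
        params = (TopologyParams.fixture()
                  if md.get("kind") == "ideal_fixture" else TopologyParams())
    if membrane is None:
        membrane = MembraneGeometry()
    pka = dict(DEFAULT_PKA, **(pka or {}))

    ref = structure.reference_coords
    n = structure.n_beads
    chains = structure.chain_id
    c_chains = list(md["c_chains"])
    a_chain = md["a_chain"]

    # ---- bonded terms along each chain ----
    bonds, angles, dihedrals = [], [], []
    for chain in structure.chains:
        idx = np.where(chains == chain)[0]
        for a, b in zip(idx[:-1], idx[1:]):
            bonds.append((a, b))
        for a, b, c in zip(idx[:-2], idx[1:-1], idx[2:]):
            angles.append((a, b, c))
        for a, b, c, d in zip(idx[:-3], idx[1:-2], idx[2:-1], idx[3:]):
            dihedrals.append((a, b, c, d))
    bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    angles = np.array(angles, dtype=np.int64).reshape(-1, 3)
    dihedrals = np.array(dihedrals, dtype=np.int64).reshape(-1, 4)

    def _dist(i, j):
        return float(np.linalg.norm(ref[i] - ref[j]))

    bond_r0 = np.array([_dist(i, j) for i, j in bonds])
    angle_t0 = np.array([_angle(ref, *ijk) for ijk in angles])
    dihe_p0 = np.array([_dihedral(ref, *ijkl) for ijkl in dihedrals])

    # ---- native contacts ----
    con = []
    seq_pos = np.zeros(n, dtype=int)
    for chain in structure.chains:
        idx = np.where(chains == chain)[0]
        seq_pos[idx] = np.arange(len(idx))
    # intra-chain
    for chain in structure.chains:
        idx = np.where(chains == chain)[0]
        for ii in range(len(idx)):
            for jj in range(ii + params.contact_min_seqsep, len(idx)):
                i, j = idx[ii], idx[jj]
                if params.contact_min_dist < _dist(i, j) < params.contact_cutoff:
                    con.append((i, j))
    # neighbouring c-subunit interfaces (ring order with wrap-around)
    nc = len(c_chains)
    for k in range(nc):
        ca, cb = c_chains[k], c_chains[(k + 1) % nc]
        ia = np.where(chains == ca)[0]
        ib = np.where(chains == cb)[0]
        for i in ia:
            for j in ib:
                if params.contact_min_dist < _dist(i, j) < params.interface_cutoff:
                    con.append((i, j))
    contacts = np.array(sorted(set(map(tuple, con))), dtype=np.int64).reshape(-1, 2)
    contact_r0 = np.array([_dist(i, j) for i, j in contacts])

    # ---- excluded volume: a-subunit <-> ring only ----
    a_idx = np.where(chains == a_chain)[0]
    ring_idx = np.where(chains != a_chain)[0]
    sigma = np.array([RESIDUE_SIGMA.get(rn, 0.55)
                      for rn in structure.residue_name])
    ev_pairs = np.array([(i, j) for i in a_idx for j in ring_idx],
                        dtype=np.int64).reshape(-1, 2)
    ev_sigma = 0.5 * (sigma[ev_pairs[:, 0]] + sigma[ev_pairs[:, 1]])

    # ---- charges and the protonatable-site registry ----
    carrier_beads = list(md["carrier_beads"])
    site_beads = np.array(carrier_beads + [md["aE223"], md["aE162"]],
                          dtype=np.int64)
    site_roles = np.array([ROLE_CARRIER] * len(carrier_beads)
                          + [ROLE_IMS, ROLE_MATRIX], dtype=np.int64)
    site_labels = [f"c{k + 1}E59" for k in range(len(carrier_beads))] \
        + ["aE223", "aE162"]
    site_pka = np.array([pka["cE59"]] * len(carrier_beads)
                        + [pka["aE223"], pka["aE162"]])
    carrier_subunit = np.array(
        list(range(1, len(carrier_beads) + 1)) + [-1, -1], dtype=np.int64)

    fixed_q = np.zeros(n)
    prot_set = set(site_beads.tolist())
    for i in range(n):
        if i in prot_set:
            continue
        rn = structure.residue_name[i]
        if rn in POSITIVE_RESIDUES:
            fixed_q[i] = 1.0
        elif rn in NEGATIVE_RESIDUES:
            fixed_q[i] = -1.0

    chargeable = sorted(set(np.where(fixed_q != 0.0)[0]) | prot_set)
    coulomb_pairs = np.array(
        [(i, j) for ai, i in enumerate(chargeable)
         for j in chargeable[ai + 1:]], dtype=np.int64).reshape(-1, 2)

    # ---- carrier side-chain surrogate neighbours and reference hop angles --
    neighbors = np.full((len(site_beads), 2), -1, dtype=np.int64)
    for s, b in enumerate(site_beads):
        if site_roles[s] != ROLE_CARRIER:
            continue
        chain = chains[b]
        idx = np.where(chains == chain)[0]
        pos = int(np.where(idx == b)[0][0])
        if 0 < pos < len(idx) - 1:
            neighbors[s] = (idx[pos - 1], idx[pos + 1])

    theta0 = np.zeros(len(site_beads))
    for s, b in enumerate(site_beads):
        if site_roles[s] == ROLE_CARRIER:
            continue
        # nearest carrier in the reference structure defines theta0
        d = [np.linalg.norm(ref[b] - ref[cb]) for cb in carrier_beads]
        cs = int(np.argmin(d))
        theta0[s] = hop_angle(ref, carrier_beads[cs], neighbors[cs], b)

    # ---- restraints / torque ----
    lvl_lo, lvl_hi = md["ring_level_beads"]
    level_center_z = np.array([
        float(np.mean(ref[list(lvl_lo), 2])),
        float(np.mean(ref[list(lvl_hi), 2])),
    ])
    anchor_beads = np.asarray(md["anchor_beads"], dtype=np.int64)

    angle_carrier = min(2, len(carrier_beads) - 1)   # c3 carrier by default
    return Topology(
        n_beads=n,
        bonds=bonds, bond_k=np.full(len(bonds), params.bond_k),
        bond_r0=bond_r0,
        angles=angles, angle_k=np.full(len(angles), params.angle_k),
        angle_t0=angle_t0,
        dihedrals=dihedrals,
        dihedral_k1=np.full(len(dihedrals), params.dihedral_k1),
        dihedral_k3=np.full(len(dihedrals), params.dihedral_k3),
        dihedral_p0=dihe_p0,
        contacts=contacts, contact_eps=np.full(len(contacts), params.contact_eps),
        contact_r0=contact_r0,
        ev_pairs=ev_pairs, ev_sigma=ev_sigma, ev_eps=params.ev_eps,
        fixed_charges=fixed_q, coulomb_pairs=coulomb_pairs,
        dielectric=params.dielectric,
        site_beads=site_beads, site_roles=site_roles, site_pka=site_pka,
        site_labels=site_labels, carrier_subunit=carrier_subunit,
        carrier_neighbors=neighbors, site_theta0=theta0,
        r176_bead=int(md["aR176"]), r176_blocking=True,
        membrane=membrane,
        level_beads=(tuple(lvl_lo), tuple(lvl_hi)),
        level_center_z=level_center_z,
        ring_beads=ring_idx.astype(np.int64),
        ring_zref=float(np.mean(ref[ring_idx, 2])),
        anchor_beads=anchor_beads, anchor_ref=ref[anchor_beads].copy(),
        torque_beads=np.asarray(md["torque_beads"], dtype=np.int64),
        torque_pn_nm=torque_pn_nm,
        params=params,
        angle_bead=carrier_beads[angle_carrier],
        _ref_coords=structure.reference_coords.copy(),
    )


#: main entry point (alias)
make_topology = build_topology


def _angle(x, i, j, k):
    a = x[i] - x[j]
    b = x[k] - x[j]
    ct = np.dot(a, b) / (np.linalg.norm(a) * np.linalg.norm(b))
    return float(np.arccos(np.clip(ct, -1.0, 1.0)))


def _dihedral(x, i, j, k, l):
    b1, b2, b3 = x[j] - x[i], x[k] - x[j], x[l] - x[k]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    return float(np.arctan2(np.dot(n1, b3) * np.linalg.norm(b2),
                            np.dot(n1, n2)))


def hop_angle(coords, carrier_bead, carrier_neighbors, channel_bead) -> float:
    """Angle (deg) between the donor->acceptor vector and the side-chain
    surrogate vector (midpoint of the carrier's chain neighbours -> carrier).

    Returns NaN when the neighbour beads are unavailable (terminal carrier);
    the kinetic factor g then falls back to 1.
    """
    if carrier_neighbors[0] < 0 or carrier_neighbors[1] < 0:
        return float("nan")
    v1 = coords[channel_bead] - coords[carrier_bead]
    mid = 0.5 * (coords[carrier_neighbors[0]] + coords[carrier_neighbors[1]])
    v2 = coords[carrier_bead] - mid
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-9 or n2 < 1e-9:
        return float("nan")
    ct = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.rad2deg(np.arccos(ct)))


# ---------------------------------------------------------------------------
# Energy / force evaluation
# ---------------------------------------------------------------------------

def _eval(R, H, top: Topology):
    R = np.ascontiguousarray(R, dtype=float)
    if not np.isfinite(R).all():
        raise ValueError("non-finite coordinates")
    f = np.zeros_like(R)
    args = top.kernel_args(H)
    ev_pairs = top.ev_pairs
    ev_act = np.arange(len(ev_pairs), dtype=np.int64)
    # overlap guard for the Coulomb singularity
    q = args[16]
    cp = top.coulomb_pairs
    if len(cp):
        qq = q[cp[:, 0]] * q[cp[:, 1]]
        live = qq != 0.0
        if live.any():
            d = np.linalg.norm(R[cp[live, 0]] - R[cp[live, 1]], axis=1)
            if (d < 1e-6).any():
                raise ValueError("overlapping charged beads (r < 1e-6 nm)")
    e = _kernels._forces(
        R, f, *args[0:13], ev_act, len(ev_act), *args[13:16],
        *args[16:])
    return f, e


def total_energy(R, H: ProtonationState, top: Topology,
                 temperature: float = 323.0) -> dict:
    """Energy breakdown {non_es, coulomb, membrane, pka, restraints, total}.

    The torque is a non-conservative applied force and does not contribute
    a term here.
    """
    _, (e_non, e_coul, e_mem, e_res) = _eval(R, H, top)
    e_pka = pka_energy(H, top.site_pka, temperature)
    out = {
        "non_es": e_non, "coulomb": e_coul, "membrane": e_mem,
        "pka": e_pka, "restraints": e_res,
    }
    out["total"] = sum(out.values())
    return out


def total_forces(R, H: ProtonationState, top: Topology) -> np.ndarray:
    """Forces from every term (incl. restraints, torque) at fixed H."""
    f, _ = _eval(R, H, top)
    return f


def structure_forces(R, top: Topology, include_ev: bool = True) -> np.ndarray:
    """Forces of the structure-based terms only (bonds, angles, dihedrals,
    contacts, and optionally the a/ring excluded volume) — no
    electrostatics, restraints or torque.  The reference structure is the
    minimum of the bonded + contact terms (forces vanish there); the
    excluded volume is repulsive-only and need not vanish at the reference.
    """
    stripped = replace(
        top,
        fixed_charges=np.zeros(top.n_beads),
        torque_pn_nm=0.0,
        params=replace(top.params, k_ring_restraint=0.0, k_anchor=0.0,
                       k_zcom=0.0),
        **({} if include_ev else dict(
            ev_pairs=np.zeros((0, 2), dtype=np.int64), ev_sigma=np.zeros(0))),
    )
    H = ProtonationState(np.ones(top.n_sites, dtype=np.int8))
    f, _ = _eval(R, H, stripped)
    return f


def restraint_and_torque_forces(R, top: Topology) -> np.ndarray:
    """Forces of the ring-axis/anchor restraints and the applied torque."""
    if top.torque_pn_nm != 0.0:
        rho = np.linalg.norm(np.asarray(R)[top.torque_beads, :2], axis=1)
        if (rho < 0.1).any():
            raise ValueError("torque bead within 0.1 nm of the z-axis; "
                             "tangent direction ill-defined")
    stripped = replace(
        top,
        bonds=np.zeros((0, 2), dtype=np.int64), bond_k=np.zeros(0),
        bond_r0=np.zeros(0),
        angles=np.zeros((0, 3), dtype=np.int64), angle_k=np.zeros(0),
        angle_t0=np.zeros(0),
        dihedrals=np.zeros((0, 4), dtype=np.int64),
        dihedral_k1=np.zeros(0), dihedral_k3=np.zeros(0),
        dihedral_p0=np.zeros(0),
        contacts=np.zeros((0, 2), dtype=np.int64), contact_eps=np.zeros(0),
        contact_r0=np.zeros(0),
        ev_pairs=np.zeros((0, 2), dtype=np.int64), ev_sigma=np.zeros(0),
        fixed_charges=np.zeros(top.n_beads),
    )
    stripped._ref_coords = top._ref_coords
    H = ProtonationState(np.ones(top.n_sites, dtype=np.int8))
    f, _ = _eval(R, H, stripped)
    return f


def net_torque_z(R, forces, beads) -> float:
    """Net z-torque (energy units per radian) of ``forces`` on ``beads``."""
    R = np.asarray(R)
    t = 0.0
    for i in beads:
        t += R[i, 0] * forces[i, 1] - R[i, 1] * forces[i, 0]
    return float(t)
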