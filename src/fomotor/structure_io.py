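"""Coarse-grained structure preparation for the F_O motor (a-subunit + c-ring).

Reads standard PDB files and reduces each residue to a single bead at the
C-alpha position, prepares the symmetrized reference c-subunit used to build
the structure-based topology, and generates an idealized synthetic a/c10
geometry so that the whole simulator can be exercised without any structure
download.

Internal units are nm (PDB Angstroms are converted on read).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import biotite.structure as struc
import biotite.structure.io.pdb as pdb
from scipy.spatial.transform import Rotation


@dataclass
class CGStructure:
    """One bead per residue (C-alpha representation).

    coords / reference_coords are (n, 3) arrays in nm.  Beads are ordered by
    (chain, residue index).  ``metadata`` carries bead-index registries for
    synthetic fixtures (site positions, torque/anchor beads, geometry
    parameters).
    """

    coords: np.ndarray
    chain_id: np.ndarray          # str per bead
    residue_name: np.ndarray      # 3-letter code per bead
    residue_index: np.ndarray     # int per bead
    reference_coords: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.reference_coords is None:
            self.reference_coords = self.coords.copy()
        self.reference_coords = np.asarray(self.reference_coords, dtype=float)
        if self.coords.shape != self.reference_coords.shape:
            raise ValueError("reference_coords must match coords in shape")

    @property
    def n_beads(self) -> int:
        return len(self.coords)

    @property
    def chains(self) -> list:
        """Chain ids in order of first appearance."""
        seen = []
        for c in self.chain_id:
            if c not in seen:
                seen.append(c)
        return seen

    def chain_mask(self, chain: str) -> np.ndarray:
        return self.chain_id == chain

    def copy(self) -> "CGStructure":
        return CGStructure(
            self.coords.copy(), self.chain_id.copy(), self.residue_name.copy(),
            self.residue_index.copy(), self.reference_coords.copy(),
            dict(self.metadata),
        )


def load_calpha(pdb_source) -> CGStructure:
    """Extract one C-alpha bead per residue from PDB text or a file path.

    Residues carrying atoms but no C-alpha are a hard error (they would leave
    a hole in the chain topology); altloc duplicates keep the
    highest-occupancy conformer with a warning.
    """
    if hasattr(pdb_source, "read"):
        pdbfile = pdb.PDBFile.read(pdb_source)
    elif isinstance(pdb_source, str) and "\n" in pdb_source:
        pdbfile = pdb.PDBFile.read(io.StringIO(pdb_source))
    else:
        pdbfile = pdb.PDBFile.read(str(pdb_source))
    atoms = pdbfile.get_structure(model=1, altloc="occupancy", extra_fields=["occupancy"])
    atoms = atoms[struc.filter_amino_acids(atoms) | (atoms.atom_name == "CA")]
    if atoms.array_length() == 0:
        raise ValueError("no amino-acid atoms found in PDB source")

    # detect residues lacking a C-alpha
    missing = []
    for chain in np.unique(atoms.chain_id):
        sub = atoms[atoms.chain_id == chain]
        for rid in np.unique(sub.res_id):
            res = sub[sub.res_id == rid]
            if not np.any(res.atom_name == "CA"):
                missing.append(f"{chain}/{res.res_name[0]}{rid}")
    if missing:
        raise ValueError(
            "residue(s) lacking a C-alpha atom: " + ", ".join(missing)
        )

    ca = atoms[atoms.atom_name == "CA"]
    order = np.lexsort((ca.res_id, ca.chain_id))
    ca = ca[order]
    return CGStructure(
        coords=ca.coord / 10.0,   # A -> nm
        chain_id=ca.chain_id.astype("U4"),
        residue_name=ca.res_name.astype("U3"),
        residue_index=ca.res_id.astype(int),
    )


def write_pdb(structure: CGStructure, path, use_reference: bool = False) -> None:
    """Write the bead model as a CA-only PDB file (nm converted to Angstrom)."""
    n = structure.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = (structure.reference_coords if use_reference
                   else structure.coords) * 10.0
    atoms.chain_id = structure.chain_id
    atoms.res_id = structure.residue_index
    atoms.res_name = structure.residue_name
    atoms.atom_name = np.full(n, "CA")
    atoms.element = np.full(n, "C")
    atoms.hetero = np.full(n, False)
    pdbfile = pdb.PDBFile()
    pdbfile.set_structure(atoms)
    pdbfile.write(str(path))


def trim_c_chains(structure: CGStructure, c_chains: list) -> CGStructure:
    """Trim C-terminal residues so all listed c-chains have equal length.

    Mirrors the reference-model preparation in which one C-terminal residue
    is removed from the (slightly longer) chains so the ring becomes
    10-fold uniform.
    """
    lengths = {c: int(np.sum(structure.chain_mask(c))) for c in c_chains}
    n_min = min(lengths.values())
    keep = np.ones(structure.n_beads, dtype=bool)
    for c in c_chains:
        idx = np.where(structure.chain_mask(c))[0]
        if len(idx) > n_min:
            # beads are sorted by residue index: drop from the C-terminus
            keep[idx[n_min:]] = False
    return CGStructure(
        structure.coords[keep], structure.chain_id[keep],
        structure.residue_name[keep], structure.residue_index[keep],
        structure.reference_coords[keep], dict(structure.metadata),
    )


def _kabsch_fit(mobile: np.ndarray, target: np.ndarray):
    """Least-RMSD rigid superposition of ``mobile`` onto ``target``.

    Returns the transformed copy of ``mobile``.
    """
    mc = mobile.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, mobile - mc)
    return rot.apply(mobile - mc) + tc


def make_reference_c_subunit(ring: CGStructure, c_chains: list = None) -> CGStructure:
    """Average the c-subunit conformation over all chains of the ring.

    Each chain is first superposed onto the first chain by a least-RMSD
    (Kabsch) fit; the bead-wise average of the aligned chains is returned as
    a single-chain structure.  Averaging without superposition would collapse
    the ring onto its axis, which is physically meaningless.
    """
    if c_chains is None:
        c_chains = ring.chains
    lengths = {c: int(np.sum(ring.chain_mask(c))) for c in c_chains}
    if len(set(lengths.values())) != 1:
        raise ValueError(
            f"c-chains have unequal lengths {lengths}; trim first "
            "(trim_c_chains) so the ring is uniform"
        )
    first = ring.coords[ring.chain_mask(c_chains[0])]
    acc = np.zeros_like(first)
    for c in c_chains:
        chain_xyz = ring.coords[ring.chain_mask(c)]
        acc += _kabsch_fit(chain_xyz, first)
    avg = acc / len(c_chains)
    mask = ring.chain_mask(c_chains[0])
    return CGStructure(
        coords=avg,
        chain_id=np.full(len(avg), c_chains[0], dtype=ring.chain_id.dtype),
        residue_name=ring.residue_name[mask].copy(),
        residue_index=ring.residue_index[mask].copy(),
    )


def set_ring_reference(ring: CGStructure, c_chains: list,
                       reference_subunit: CGStructure = None) -> CGStructure:
    """Install the averaged c-subunit as the reference of every c-chain.

    The averaged subunit is fitted (least-RMSD) back onto each chain's actual
    coordinates, so the reference keeps the ring geometry while each subunit
    shares one internal conformation.
    """
    if reference_subunit is None:
        reference_subunit = make_reference_c_subunit(ring, c_chains)
    out = ring.copy()
    for c in c_chains:
        idx = np.where(ring.chain_mask(c))[0]
        out.reference_coords[idx] = _kabsch_fit(
            reference_subunit.coords, ring.coords[idx])
    return out


# ---------------------------------------------------------------------------
# Synthetic idealized fixture
# ---------------------------------------------------------------------------

#: default geometry of the synthetic a/c-ring model (nm / degrees)
FIXTURE_DEFAULTS = dict(
    r_inner=2.0,           # inner helix strand radius
    r_outer=2.5,           # outer (carrier) strand radius
    r_channel=3.15,        # half-channel glutamate radius
    r_arg=3.05,            # gate arginine radius (close to the ring: the
                           # deprotonated carrier pairs with the arginine)
    r_wall=3.6,            # a-subunit scaffold column radius
    z_spacing=0.38,        # bead spacing along z (C-alpha like)
    zigzag=0.1,            # radial zigzag emulating helical Ca geometry
    phi_aE223=30.0,        # azimuth of the IMS half-channel site (deg)
    phi_aE162=-50.0,       # azimuth of the matrix half-channel site (deg)
    phi_aR176=0.0,         # azimuth of the gate arginine (deg)
    wall_azimuths=(-50.0, -20.0, 15.0, 45.0),
)


def build_ideal_fixture(n_c: int = 10, radius: float = None,
                        n_res_per_c: int = 10, seed: int = 0,
                        **geometry) -> CGStructure:
    """Build an idealized n_c-fold symmetric c-ring plus a mock a-subunit.

    Each c-subunit is a helical hairpin: an inner strand and an outer strand
    of beads stacked along z.  The middle bead of the outer strand is the
    proton-carrier glutamate (E59-like), at mid-membrane height (z = 0)
    facing outward.  The a-subunit block carries the two half-channel
    glutamates (aE223-like on the IMS side, aE162-like on the matrix side)
    flanking the gate arginine (aR176-like, on the +x axis) on opposite y
    sides; all protonatable sites share z = 0.

    Subunits are numbered 1..n_c clockwise (decreasing azimuth) starting from
    the subunit nearest the IMS channel, matching the convention used for the
    rotation-step bookkeeping.
    """
    geo = dict(FIXTURE_DEFAULTS)
    geo.update(geometry)
    if radius is not None:
        shift = radius - geo["r_outer"]
        geo["r_outer"] = radius
        geo["r_inner"] = radius - 0.5
        geo["r_channel"] += shift
        geo["r_arg"] += shift
        geo["r_wall"] += shift
    if n_c < 3:
        raise ValueError("n_c must be >= 3")
    if n_res_per_c % 2 != 0 or n_res_per_c < 6:
        raise ValueError("n_res_per_c must be even and >= 6")
    n_strand = n_res_per_c // 2
    if n_strand % 2 == 0:
        raise ValueError(
            "n_res_per_c must give an odd number of beads per strand so the "
            "carrier sits at mid-membrane (z=0); use n_res_per_c in {6,10,14,...}")
    if geo["r_inner"] < 0.3 * n_c * 0.25:
        raise ValueError(
            f"radius {geo['r_inner']:.2f} nm too small for {n_c} subunits")

    dz = geo["z_spacing"]
    half = (n_strand - 1) // 2
    z_levels = np.arange(-half, half + 1) * dz

    coords, chains, resnames, resids = [], [], [], []
    carrier_beads, torque_beads, level_lo, level_hi = [], [], [], []

    chain_letters = [chr(ord("A") + k) for k in range(n_c)]
    spacing = 360.0 / n_c
    for s in range(n_c):
        phi = np.deg2rad((1 - s) * spacing)  # s=0 -> c1 at +36 deg for n_c=10
        c, s_ = np.cos(phi), np.sin(phi)
        rid = 52
        zig = geo["zigzag"]
        # inner strand, bottom -> top; radial zigzag avoids collinear triples
        for iz, z in enumerate(z_levels):
            r = geo["r_inner"] + (zig if iz % 2 == 0 else -zig)
            coords.append([r * c, r * s_, z])
            chains.append(chain_letters[s])
            resnames.append("SER" if iz == len(z_levels) - 1 else "ALA")
            resids.append(rid)
            if iz == len(z_levels) - 1:
                torque_beads.append(len(coords) - 1)   # ring-top bead (S38-like)
            if iz == half - 1:
                level_lo.append(len(coords) - 1)
            if iz == half + 1:
                level_hi.append(len(coords) - 1)
            rid += 1
        # outer strand, top -> bottom (hairpin); the mid-membrane carrier
        # bead bulges outward so the neighbour-midpoint surrogate vector
        # points along the radial (side-chain) direction
        for iz, z in enumerate(z_levels[::-1]):
            is_carrier = abs(z) < 1e-9
            r = geo["r_outer"] + (zig if iz % 2 == 0 else -zig)
            coords.append([r * c, r * s_, z])
            chains.append(chain_letters[s])
            resnames.append("GLU" if is_carrier else "ALA")
            resids.append(rid)
            if is_carrier:
                carrier_beads.append(len(coords) - 1)
            rid += 1

    # ----- a-subunit block (chain "K") -----
    a_chain = chr(ord("A") + n_c)
    anchor_beads = []
    rid = 100
    for ci, az in enumerate(geo["wall_azimuths"]):
        phi = np.deg2rad(az)
        c, s_ = np.cos(phi), np.sin(phi)
        for iz, z in enumerate(z_levels):
            r = geo["r_wall"] + (geo["zigzag"] if iz % 2 == 0 else -geo["zigzag"])
            coords.append([r * c, r * s_, z])
            chains.append(a_chain)
            resnames.append("ALA")
            resids.append(rid)
            if (ci, iz) in [(0, 0), (1, len(z_levels) - 1), (3, 0)]:
                anchor_beads.append(len(coords) - 1)
            rid += 1

    def add_site(phi_deg, r, name):
        phi = np.deg2rad(phi_deg)
        coords.append([r * np.cos(phi), r * np.sin(phi), 0.0])
        chains.append(a_chain)
        resnames.append(name)
        nonlocal rid
        resids.append(rid)
        rid += 1
        return len(coords) - 1

    i_223 = add_site(geo["phi_aE223"], geo["r_channel"], "GLU")
    i_176 = add_site(geo["phi_aR176"], geo["r_arg"], "ARG")
    i_162 = add_site(geo["phi_aE162"], geo["r_channel"], "GLU")

    st = CGStructure(
        coords=np.array(coords),
        chain_id=np.array(chains, dtype="U4"),
        residue_name=np.array(resnames, dtype="U3"),
        residue_index=np.array(resids, dtype=int),
    )
    st.metadata.update(
        kind="ideal_fixture", n_c=n_c, n_res_per_c=n_res_per_c, geometry=geo,
        c_chains=chain_letters, a_chain=a_chain,
        carrier_beads=carrier_beads,          # ordered c1..c_nc
        aE223=i_223, aE162=i_162, aR176=i_176,
        torque_beads=torque_beads,
        anchor_beads=anchor_beads,
        ring_level_beads=(level_lo, level_hi),
        carrier_spacing_deg=spacing,
    )
    return st
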