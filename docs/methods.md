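# Methods

`fomotor` simulates proton-transfer-coupled rotation of the membrane
(F_O) portion of ATP synthase — the a-subunit plus the ring of ten
c-subunits — with a hybrid scheme that alternates coarse-grained Langevin
dynamics of the protein with Monte-Carlo moves of the protonation state.

## Model

Each residue is one bead at its C-alpha position. The total energy at
coordinates R and protonation state H (a binary vector over the n_p
protonatable glutamates: 10 ring carriers cE59, the IMS half-channel site
aE223 and the matrix half-channel site aE162) is

    V(R, H) = V_struct(R) + V_coulomb(R, H) + V_mem(R, H) + V_pKa(H)

* **V_struct** — a structure-based (Go-like) potential biased to the
  reference structure: harmonic bonds and angles, periodic dihedrals
  (k1(1−cos Δφ) + k3(1−cos 3Δφ)), 10-12 native-contact wells for
  intra-chain pairs and for interfaces between *neighbouring* c-subunits
  only, and residue-size-dependent repulsive excluded volume between the
  a-subunit and the ring. The a/ring interface deliberately has no
  attractive terms, so nothing in V_struct breaks the ring's 10-fold
  rotational symmetry.
* **V_coulomb** — unscreened Coulomb with uniform dielectric 10 (a
  membrane-interior average), no cutoff. Fixed charges: +1 Arg/Lys, −1
  Asp/Glu; a protonatable site carries q = h − 1 (deprotonated glutamate
  −1, protonated 0).
* **V_mem** — an implicit-membrane penalty: a deprotonated (charged)
  carrier facing the lipid pays eps_mem = 10 kcal/mol. Two half-planes
  through the z-axis at 51.2° and −69.6° from +x bound the a-subunit-facing
  wedge; outside it a smooth switch ½(1−cos(πx/d)) with width d = 0.4 nm
  turns the penalty on (x is the distance past the border, positive on the
  lipid side; with two borders the larger switch value is used). This term
  is the ratchet pawl: deprotonated carriers cannot leave the wedge.
* **V_pKa** = −(ln 10) kB T Σ pKa_i h_i with pKa(cE59) = 8.0,
  pKa(aE223) = 6.0, pKa(aE162) = 9.0.

Restraints keep the reduced system assembled: a per-level circle-fit
restraint (two rings of ten beads at the quarter heights; harmonic in each
bead's distance to the fitted circle, which is invariant under rigid
rotation about z), three positional anchors on the a-subunit, and a weak
restraint on the ring's mean z (the axial positioning that the peripheral
stalk and F1 would provide). An external torque is applied as tangential
forces τ/(10 ρ_i) on the ten ring-top serine beads, positive values acting
in the hydrolysis (clockwise-from-matrix) direction.

## Dynamics and chemistry

MD stages use BAOAB Langevin integration at 323 K with friction 2.0 (reduced
units) and timestep 0.1; with zero friction the integrator is exactly
velocity Verlet, which is how energy conservation is verified. The uniform
bead mass is a numerical device set so the stiffest bond satisfies
ω·dt ≈ 0.3; all times are reported in MD steps and never mapped to seconds.

Each MC stage (structure frozen) first re-equilibrates the two half-channel
sites with their reservoirs,

    P_prot = 1 / (1 + e^{+eps/kBT}),
    eps_223 = (ln10) kBT (pH_IMS − pKa_223) − ΔΨ/2,
    eps_162 = (ln10) kBT (pH_matrix − pKa_162) + ΔΨ/2,

(the sites sit at mid-membrane, hence half the membrane potential each;
ΔΨ = 150 mV, pH 7.0/8.0 by default), then visits every proton in random
order and attempts one transfer between the c-ring and the a-subunit with
probability

    p = (1 − e^{−kτ w}) · min(1, e^{−ΔE/kBT}),    kτ = 1,

where ΔE is the change in the H-dependent energy terms and the kinetic
weight w = f(r) g(θ) h_R176 encodes geometry: f plateaus at 1 below
r0 = 0.8 nm and decays with length 0.4 nm; g is a Gaussian (σ = 36°) in
the angle between the donor→acceptor vector and a side-chain surrogate
vector (carrier bead minus the midpoint of its chain neighbours), peaked at
the reference-structure value; h_R176 is 0 whenever the gate arginine's
y-coordinate lies strictly between donor and acceptor (the leak gate), and
is removed for the aR176A mutant. w is symmetric in donor/acceptor, so the
move satisfies detailed balance.

A run is one equilibration MD stage followed by `rounds` alternations of
MD and MC, driven by a single seeded RNG stream (bit-reproducible).

## Synthetic structure

The bundled generator builds an idealized, exactly 10-fold-symmetric ring
of helical-hairpin subunits (two zigzag strands of beads; the mid-membrane
outer bead is the carrier glutamate and bulges outward so the side-chain
surrogate vector points radially) plus a minimal a-subunit: four scaffold
columns, the two channel glutamates at radius 3.15 nm flanking the gate
arginine in y, and the arginine at radius 3.05 nm on the +x axis — closer
to the passing carriers than to either channel, so that a deprotonated
carrier next to it is electrostatically stabilized (the salt-bridge role of
the conserved arginine; with the arginine equidistant from carrier and
channel the transfer merely swaps which site is charged and no
stabilization survives). All twelve protonatable sites share z = 0.

The fixture uses its own force-constant set (bond 400 kcal/mol/nm²,
angle 30 kcal/mol/rad², dihedrals 2.0/1.0, contact depth 1.2 kcal/mol,
inter-subunit interface cutoff 1.35 nm): the minimal hairpins have far
fewer contacts per residue than a real helix bundle and melt at 323 K with
standard per-contact depths, and softer bonds admit a light bead mass and
hence desk-scale rotational diffusion. Structures read from PDB files get
the standard Cα Go-model constants (bond 100 kcal/mol/Å², angle 20,
dihedral 1.0/0.5, contact depth 0.3 kcal/mol at a 6.5 Å cutoff with ≥4
sequence separation). What the fixture does *not* emulate: real helix
packing, sequence-specific electrostatics beyond the five charged sites,
the exact channel geometry of the cryo-EM structure, and membrane
deformability — so quantitative agreement of, e.g., absolute rates with
experiments is out of reach by design; the fixture probes mechanism
(direction, coupling stoichiometry, mutant phenotypes), not rates.

## Reduced simulation protocol

The reference protocol (MD stages of τ = 1e5 steps, 3000 rounds, 10
replicates) is far beyond interactive scale. Tests and the acceptance
script therefore run the fixture with shorter MD stages — τ = 5000 for
synthesis-mode runs, τ = 250 under the strong (86.2 pN·nm) torque,
τ = 2000 for the stall scan — and hundreds to thousands of rounds over a
few seeds. The stage length is reduced *together with* the fixture's higher
rotational mobility so that protonation chemistry remains fast relative to
rotation, the regime the method assumes; with long stages the driven ring
out-runs its chemistry and slips. Thermodynamic conditions (pH, ΔΨ, pKa,
eps_mem, temperature, friction, torque values) are never scaled.

## Observables

Rotation is the unwrapped azimuth of the c3 carrier bead relative to its
start (counterclockwise from the matrix side positive). The analysis module
provides: the angle census (von Mises-smoothed histogram; the low-population
gaps every ~36° are the step boundaries), per-proton itinerary
reconstruction from the event log with transport / leak / idle
classification (entry and exit side plus ring rotation while bound;
threshold 180° separates the productive ~288° ride from the ~72° leak
path), a census of the printed step pathways (deprotonation-first vs
protonation-first orderings in the rolling frame), protonation-state
conditioned free-energy curves F(θ) = −kBT ln P(θ) from frozen-state runs
(offset by the state's pKa term; an applied torque adds the analytic tilt
−τθ), net reservoir flux (meaningful even for runs shorter than one full
proton transit), stall-torque interpolation over a torque grid, and the
transduction efficiency η = (τ_stall·2π/10) / (kBT ln10 ΔpH + eΔΨ).

The surrogate model (`synthetic_validation`) collapses the motor to one
angular coordinate per 36° cell and the four observed deprotonation
patterns, re-using the engine's boundary-probability and transfer-
acceptance code. Its exact stationary solution (a 96-state master equation)
is the quantitative oracle for the MC formulas; the well depths of its
angle potential are a test-harness calibration (10 wells at equilibrium),
not a claim about the physical landscape.

## Numerical choices and limitations

* Angle forces use a sin-clamped harmonic (clamp 0.05); fixture strands are
  zigzagged so no reference angle is near 180°.
* Excluded volume is a truncated-shifted r^-12 at pair cutoff 2σ with a
  20-step pair list (1.8 nm list radius).
* Coulomb pairs carry no exclusions; reference pairs closer than 0.35 nm
  are excluded from the contact list.
* The Metropolis ΔE for proton moves is computed by component difference
  (Coulomb, membrane, pKa); V_struct cancels at fixed R.
* Ties when a proton has several eligible acceptors are broken by random
  order, first acceptance wins; at most one accepted move per proton per
  stage.
* The membrane switch's two-border maximum has a derivative discontinuity
  only where both switches saturate (zero force), so energy conservation is
  unaffected.
* Known limitations: the fixture under-stabilizes the arginine-carrier pair
  relative to the cryo-EM geometry, so pumping against the *full* PMF is
  leak-dominated (the zero-PMF pump and all sign/stoichiometry behaviours
  are reproduced); the c2E59A gap admits some extra forward protons while
  it passes the a-subunit; free-energy curves are reconstructed by direct
  frozen-state sampling (no umbrella reweighting).
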