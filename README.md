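# fomotor

Hybrid Monte-Carlo / molecular-dynamics simulation of the membrane-embedded
rotary motor of ATP synthase (the F_O region: a-subunit + c10-ring).

The motor couples proton flow across the inner mitochondrial membrane to
rotation of the c-ring. Each c-subunit carries a protonatable glutamate
(cE59) at mid-membrane height; two half-channels in the a-subunit connect
the ring to the intermembrane space (via aE223) and to the matrix (via
aE162), separated by a conserved arginine (aR176). `fomotor` represents
the protein as one bead per residue with a structure-based potential and a
protonation-state-dependent energy

    V(R, H) = V_struct(R) + V_coulomb(R, H) + V_mem(R, H) + V_pKa(H)

where H is the binary protonation vector of the 12 glutamates, V_mem makes
a deprotonated carrier pay 10 kcal/mol for facing the lipid, and V_pKa =
−(ln 10) kB T Σ pKa_i h_i. Dynamics alternate Langevin MD stages (structure
moves, H fixed) with Monte-Carlo stages (structure fixed): the half-channel
sites re-equilibrate with their reservoirs according to pH, pKa and the
membrane potential ΔΨ, and protons hop between ring and a-subunit with
probability (1 − e^{−kτw}) · min(1, e^{−ΔE/kBT}), where the geometric
weight w = f(r) g(θ) h_R176 gates hops on donor–acceptor distance,
side-chain orientation, and the arginine leak gate.

Driven by a proton-motive force (ΔpH = 1, ΔΨ = 150 mV) the model rotates
counterclockwise in ~36° steps, one proton per step; an external torque in
the hydrolysis direction reverses it into a proton pump. Mutants
(aR176A, c2E59A), parameter scans (pH, ΔΨ, pKa, torque, membrane borders),
stall-torque and free-energy-surface analyses are built in. Everything runs
on a bundled idealized a/c10 structure, so no structure download is needed;
real PDB input is supported through the same topology builder.

## Worked example

```python
from fomotor import RunConfig, run, analysis

cfg = RunConfig(tau=5000, rounds=300, seed=1)   # wild-type synthesis mode
res = run(cfg)
print(round(res.angles_deg[-1], 1))             # 263.8
print(analysis.net_flux(res.events))            # {'net_to_matrix': 8, 'net_from_ims': 8}
```

The ring turned +263.8° (counterclockwise, the ATP-synthesis direction,
about 7 steps of 36°) while 8 protons were delivered to the matrix side and
8 taken up from the IMS — tight coupling of about one proton per step, i.e.
~10 per revolution for the 10-subunit ring. The energetics of that
coupling:

```python
print(analysis.efficiency(50.0, 7.0, 8.0, 150.0, 323.0))
# work_per_proton_pn_nm: 31.4  (= 4.52 kcal/mol)
# pmf_ph_kcal_mol: 1.48, pmf_psi_kcal_mol: 3.46, pmf_total: 4.94
# eta: 0.92
```

A stall torque of ~50 pN·nm converts to 31.4 pN·nm of work per proton
against a proton-motive free energy of 4.94 kcal/mol — a transduction
efficiency around 90%.

A command-line interface mirrors the library:

```
fomotor fixture --out fixture.pdb
fomotor run --rounds 300 --tau 5000 --seed 1 --out-prefix wt
fomotor analyze wt
fomotor scan --grid '{"torque_pn_nm": [0, 8.6, 43.0, 51.6, 86.2]}' --seeds 1,2,3
```

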