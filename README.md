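# helimem

Analysis toolkit for coarse-grained simulations of helical peptides —
typically antimicrobial peptides (AMPs) — interacting with planar lipid
bilayers. It covers the two workflows such studies need:

1. **Unbiased-trajectory descriptors** — per-frame helix orientation (tilt
   and spin angles, hydrophobic-dipole decomposition), peptide–lipid contact
   fingerprints, z-density profiles, and Rayleigh-fit lateral diffusion
   coefficients.
2. **Metadynamics thermodynamics** — reconstruction of well-tempered
   free-energy surfaces from Gaussian deposition (HILLS) records, Boltzmann
   projection to 1D potentials of mean force, and conversion into
   standard-state adsorption free energies ΔG⁰ and membrane-to-membrane
   transfer free energies ΔΔG⁰.

A synthetic-data module generates every input with known ground truth
(ideal helices, two-leaflet bilayers of healthy/bacterial/cancer model
compositions, scheduled trajectories, Brownian walks, analytic free-energy
surfaces with closed-form partition coefficients), so the whole pipeline is
testable end-to-end without running any simulation.

## The model

For a rigid helix near a membrane whose plane is xy, with `NC = r_N − r_C`
the axis vector and α = −1/+1 for the upper/lower leaflet:

- **Tilt** cos φ = NC_z / (|NC| α), so φ = 0° always means "N-terminus
  toward the nearer leaflet".
- **Hydrophobic dipole moment** μ = Σᵢ μᵢ rᵢ with μᵢ the Fauchère–Pliska
  hydrophobicity and rᵢ the backbone-bead position relative to the centre
  of mass; decomposed into μ_L ∥ NC and μ_⊥ = μ − μ_L.
- **Spin** ξ = arccos(t̂·μ̂_⊥), lifted to [0°, 360°) by the sign of
  NĈ·(t̂×μ_⊥), where t̂ ∝ NĈ×(NĈ×n̂) is the in-plane tilt reference;
  ξ = 180° means the hydrophobic face points at the membrane.
- **Lateral diffusion**: in-plane displacement magnitudes over a lag Δt
  follow the Rayleigh law P(r, Δt) = r/(2DΔt)·exp(−r²/4DΔt); the maximum-
  likelihood estimate is D = ⟨r²⟩/(4Δt), with a block-bootstrap CI.
- **Adsorption thermodynamics**: κ = (2λ)⁻¹∫₀^λ∫₋₁¹ e^{−βW(z,cosφ)} dz dcosφ
  (or its 1D analogue on the projected PMF), κ⁰ = κλ/V₀^{1/3} with
  V₀ = 1.660 nm³ (1 M standard state), ΔG⁰ = −kT ln κ⁰, and
  ΔΔG⁰ = ΔG⁰_C − ΔG⁰_M, which is independent of the aqueous reference.

## Worked example

```python
import numpy as np
from helimem import synthetic_data as synth, peptide_geometry as pg, fes_thermo as ft

pep = synth.make_helix(synth.PEPTIDE_SEQUENCES["2MAG"])   # magainin-2
fp = pg.composition_fingerprint(pg.classify_residues(pep.sequence))

bilayer = synth.make_bilayer("bacterial_pe_pg", lipids_per_leaflet=64, seed=0)
sched = synth.Schedule([0.0, 50.0], [4.0, 1.8], [45.0, 90.0], [90.0, 180.0])
traj = synth.make_trajectory(pep, bilayer, sched, frame_times=np.linspace(0, 50, 6))
series = pg.orientation_series(traj, pep, bilayer)

fes, kappa_exact = synth.make_analytic_fes(
    "square_well", {"eps": 20.0, "z1": 1.0, "z2": 2.0, "ramp": 0.4},
    n_z=8001, n_cos=11)
res = ft.kappa_from_2d(fes, lam=4.0)
```

prints (formatting as in the repository's doc snippet):

```
magainin-2: 23 residues, net charge +3
composition: 21.7% basic, 4.3% acidic, 13.0% polar, 60.9% hydrophobic
t=  0.0 ns  z= 4.00 nm  tilt=  45.0 deg  spin=  90.0 deg
t= 50.0 ns  z= 1.80 nm  tilt=  90.0 deg  spin= 180.0 deg
kappa = 228.2  kappa0 = 771  dG0 = -16.58 kJ/mol
closed form kappa = 228.2
```

The descriptor series recovers the prescribed approach schedule exactly
(the peptide ends membrane-parallel, hydrophobic face down — the
equilibrium orientation of amphipathic AMPs), and the Boltzmann integral
over the analytic 20 kJ/mol square well matches its closed-form partition
coefficient; ΔG⁰ = −16.58 kJ/mol is the corresponding 1 M standard-state
adsorption free energy.

## Command line

```bash
helimem synth --what trajectory --seed 4 --out traj.txt
helimem descriptors --trajectory traj.txt --peptide 2MAG --out desc.tsv
helimem contacts    --trajectory traj.txt --peptide 2MAG --out contacts.tsv
helimem diffusion   --trajectory traj.txt --windows 0.2,2,100 --out diff.tsv
helimem thermo      --fes fes.dat --lam auto --out thermo.json
helimem transfer    --a thermoM.json --b thermoC.json --out ddg.json
```

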