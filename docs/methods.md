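# Methods

This note documents the models implemented in helimem, the conventions that
had to be pinned where more than one reading was possible, the defaults and
their rationale, and what the synthetic-data generators do and do not
emulate.

## Orientation descriptors

The peptide is treated as a rigid helix represented by one backbone bead
per residue; the membrane plane is xy and the membrane normal is z.

**Tilt.** The helix axis is the terminus-to-terminus vector, pinned as
NC = r_N − r_C (C→N). With the leaflet factor α (−1 when the peptide is
nearer the upper leaflet, +1 for the lower), the tilt is
cos φ = NC_z/(|NC|·α). This sign pairing is the only one for which φ = 0°
means "N-terminus toward the nearer leaflet" on *both* sides of the
bilayer; the leaflet side itself is decided from the minimum-image z
displacement of the peptide COM from the membrane centre.

**Hydrophobic dipole moment.** μ = Σᵢ μᵢ rᵢ, with μᵢ the Fauchère–Pliska
side-chain hydrophobicity (shipped as `data/fauchere_pliska.tsv`) and rᵢ
the backbone-bead position relative to the *unweighted* backbone centre of
mass. Summing over backbone beads only (one per residue) is the simplest
reading consistent with per-residue weights; the same beads define the COM,
which makes μ exactly translation-invariant. The moment is split into
μ_L = (μ·NĈ)NĈ and μ_⊥ = μ − μ_L.

**Spin.** n̂ = α ẑ is the unit vector from the peptide toward the nearer
leaflet, and the tilt-reference vector is t̂ ∝ NĈ×(NĈ×n̂) — the in-plane
direction obtained by projecting n̂ perpendicular to the axis. Then
ξ = arccos(t̂·μ̂_⊥), lifted to [0°, 360°) by the sign of the triple product
NĈ·(t̂×μ_⊥) (positive for ξ < 180°). With these choices ξ = 180° iff μ_⊥
points at the membrane, on either leaflet. The grammar of the defining
sentence for t̂ admits another reading (n̂ perpendicular to something other
than the axis); the implemented reading is the one that reproduces the
ξ = 180° ⇔ "hydrophobic face down" contract.

Degenerate cases are signalled, not guessed: |μ_⊥| < 1e−8 or a helix axis
parallel to z (|sin φ| < 1e−6, so t̂ is undefined) raise an
undefined-spin error, which the per-frame series records as NaN with a
`spin_defined` flag.

Two symmetry facts worth recording because they are easy to get wrong:
negating μ_⊥ *advances* the spin by 180° (it does not reflect it); the
360°−ξ map corresponds to reflecting μ_⊥ across the (t̂, axis) plane. And a
literal mirror of the configuration through the bilayer midplane flips
chirality, so it preserves the tilt and cos ξ but maps ξ → 360°−ξ; the
physically meaningful upper↔lower move is a proper rotation (180° about an
in-plane axis), under which tilt and spin are both exactly invariant. The
property tests assert exactly these statements.

**Residue classes.** basic {K, R, H}, acidic {D, E}, polar {S, T, N, Q, Y},
hydrophobic {G, A, V, L, I, P, F, M, W, C}. Tyrosine is classed polar: its
hydroxyl H-bonds like S/T, and this assignment is the one consistent with
the full set of composition fingerprints of the five study peptides
(43.2% hydrophobic for LL37, no polar residues in CM15, 12–13% polar and
60–67% hydrophobic for the others).

## Contacts and densities

A contact is a peptide-bead/lipid-bead pair with minimum-image distance
≤ 0.6 nm (orthorhombic boxes, periodic in all three dimensions), counted
pairwise — not boolean per residue — and aggregated by residue class ×
lipid species. The accelerated path is a periodic k-d tree; a brute-force
all-pairs scan is kept as the test oracle and the two must agree exactly.
Frame-averaged counts over a trailing window are normalised once by the
total number of peptide beads of each residue class (residues of different
size become comparable); a `normalized` flag makes double normalisation an
error rather than a silent bug. Density profiles are plain bead-count
z-histograms (default bin 0.1 nm) of headgroup+linker beads, tail beads and
peptide beads, wrapped into one box height centred on the bilayer COM.

## Lateral diffusion

Displacement magnitudes of the in-plane COM over a lag Δt are collected on
an overlapping start grid (stride = one frame) after periodic unwrapping
(a per-frame jump exceeding half the box is a wrap event). For 2D Brownian
motion these follow the Rayleigh law P(r, Δt) = r/(2DΔt)·e^{−r²/4DΔt},
whose maximum-likelihood estimator is the closed form D = ⟨r²⟩/(4Δt); this
avoids the histogram-binning choices a curve fit would need. The 95% CI
comes from a moving-block bootstrap of start times (block ≈ √n) because
overlapping windows are autocorrelated. Default windows are 0.2, 2 and
100 ns. No stationarity correction is applied: on confined or interacting
trajectories the estimate genuinely decreases with the window length, and
it is reported per window exactly as defined. Units: estimates are kept in
nm²/ns and reported in cm²/s (1 nm²/ns = 10⁻¹⁴ cm²/10⁻⁹ s = 10⁻⁵ cm²/s —
the test encodes this dimensional chain rather than a remembered constant).

## Free-energy surfaces and thermodynamics

**Reconstruction.** HILLS records (one file per walker, merged and
time-sorted on read) are summed as V(s) = Σ hᵢ exp(−Σ_cv (s−cᵢ)²/2σᵢ²),
with minimum-image distances on periodic axes (spin: period 2π; z and
cos φ non-periodic). Deposited heights are assumed already tempered — the
common on-disk convention — so the surface estimate is
W = −γ/(γ−1)·V, shifted to min 0; a flag switches to the un-tempered
convention. Well-tempered defaults follow the study conditions: height
2.2 kJ/mol, σ_z = 0.03 nm, σ_cosφ = 0.01, σ_spin = 0.01 rad, γ = 50, six
walkers. Sampling walls are half-harmonic, ½κ(z−bound)² outside [0, 8] nm
with κ = 50000 kJ·mol⁻¹·nm⁻².

**Projection.** W₁(s) = −β⁻¹ ln ∫ e^{−βW(s,u)} du with composite-trapezoid
weights inside a log-sum-exp, so minima hundreds of kT deep cannot
overflow.

**Partition coefficient and standard state.**
κ = (2λ)⁻¹ ∫₀^λ ∫₋₁¹ e^{−βW(z,c)} dz dc in 2D, κ = λ⁻¹ ∫₀^λ e^{−βW(z)} dz
in 1D; the 1/(2λ) vs 1/λ factors reflect the width-2 measure of cos φ, and
the two routes agree to 1e−6 on smooth surfaces (asserted). λ is the
distance beyond which the interaction is negligible; when not given it is
chosen as the smallest z beyond which |W| stays under 0.5 kT. Before
integration the surface is anchored so the free region (z ≥ λ) averages
zero — the only choice for which a non-interacting system gives κ = 1 — with
a flatness check (warn above 0.25 kT deviation); with anchoring disabled,
adding a constant c to W multiplies κ by e^{−βc} exactly (asserted). The
1 M standard state uses V₀ = 1.660 nm³ (the volume per molecule at 1 M;
the test derives it from Avogadro's number), κ⁰ = κλ/V₀^{1/3},
ΔG⁰ = −kT ln κ⁰ with k = 0.0083145 kJ·mol⁻¹·K⁻¹ and T = 300 K by default.
ΔΔG⁰ = ΔG⁰_C − ΔG⁰_M is antisymmetric and independent of any common
offset of the underlying PMFs — the property that makes it robust to the
(unphysical) helical-in-water reference state.

**Uncertainty.** Convergence is judged from time-ordered PMF snapshots:
the pointwise standard deviation over the trailing 30% of them (each
re-anchored at the shared reference window) estimates the PMF uncertainty,
and the standard deviation of ΔG⁰ recomputed per trailing snapshot
propagates it to the free energy.

## Synthetic data: what it does and does not emulate

Generators produce geometric/statistical structure with known truth, not
physics: helices are ideal (0.15 nm rise, 0.23 nm radius, 100°/residue);
bilayers are jittered lattices (0.64 nm² per lipid, 4 nm head-plane
separation — typical fluid-bilayer numbers) with species counts from
largest-remainder rounding of the three study compositions (POPC 100%;
POPE 10%/POPG 90%; CHOL 28.4%/DOPE 20%/DOPC 20%/DPSM 18.4%/DOPS 13.2%;
250 lipids per leaflet by default); trajectories place the peptide rigidly
per a (z, tilt, spin) waypoint schedule plus optional Gaussian positional
noise over a static bilayer; lateral walks are exact Brownian or
Ornstein–Uhlenbeck discretisations; analytic surfaces (flat, square well
with optional linear edge ramps, truncated harmonic well, tilt-dependent
slab) carry closed-form κ via error-function integrals. The square-well
ramp exists because a genuinely discontinuous integrand limits trapezoid
quadrature to first order at the edges; with ramps the closed form remains
exact and the quadrature converges at second order, so tight agreement is
a meaningful check of the integrator rather than of a lucky grid.
`make_hills` inverts reconstruction by greedy matching pursuit: it deposits
capped-height Gaussians at the residual maximum until the residual bias
falls below tolerance, yielding records that re-sum to the target within
the deposition granularity (≤ 0.5 kJ/mol in the round-trip test).

Passing tests on these inputs therefore validate the *analysis* — the
conventions, estimators and integrals — not force fields or sampling.
Real trajectories add conformational flexibility, membrane deformation,
finite sampling noise and non-orthorhombic boxes (unsupported), none of
which the generators model.

All generators are deterministic under a fixed seed, with independent child
streams per call.

## Problem sizes

Default test and acceptance runs use desk-scale sizes chosen to make the
statistical assertions sharp: 10⁵ samples for estimator-recovery checks,
10³ hills × 10⁴ grid points for the reconstruction oracle, ≤ 500-bead
systems for exact contact-oracle equality, and z-grids of 8k–32k points
where 1e−6 quadrature agreement is asserted.

## Known limitations

- Orthorhombic boxes only; no triclinic minimum image.
- The peptide is rigid and fully helical by construction; no secondary-
  structure or helicity analysis.
- Electrostatic dipole moments are out of scope (they need partial
  charges); net charge is simple bookkeeping (+1 K/R, −1 D/E, H neutral,
  zwitterionic termini).
- Bias reweighting other than direct Gaussian summation (e.g.
  time-dependent tempering corrections) is not implemented.
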