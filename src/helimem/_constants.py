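"""Physical constants and pinned defaults shared across the package."""

#: Boltzmann constant in kJ mol^-1 K^-1 (molar gas constant).
KB_KJ_PER_MOL_K = 0.0083145

#: Default absolute temperature (K) of the simulated NPT ensemble.
DEFAULT_TEMPERATURE_K = 300.0

#: Standard-state volume per molecule at 1 M, nm^3 (1660 A^3).
DEFAULT_V0_NM3 = 1.660

#: Contact-counting distance cutoff, nm.
DEFAULT_CONTACT_CUTOFF_NM = 0.6

#: Default lateral-diffusion time windows, ns.
DEFAULT_DIFFUSION_WINDOWS_NS = (0.2, 2.0, 100.0)

#: Unit conversion: 1 nm^2/ns = 1e-14 cm^2 / 1e-9 s = 1e-5 cm^2/s.
NM2_PER_NS_TO_CM2_PER_S = 1e-5

#: Half-harmonic sampling-wall defaults: bounds (nm) and force constant
#: (kJ mol^-1 nm^-2) restricting the peptide-membrane distance coordinate.
DEFAULT_WALL_BOUNDS_NM = (0.0, 8.0)
DEFAULT_WALL_KAPPA = 50000.0

#: Well-tempered deposition defaults: Gaussian height (kJ/mol), widths per
#: collective variable, and bias factor.
DEFAULT_HILL_HEIGHT_KJ_MOL = 2.2
DEFAULT_SIGMA_Z_NM = 0.03
DEFAULT_SIGMA_COS_TILT = 0.01
DEFAULT_SIGMA_SPIN_RAD = 0.01
DEFAULT_BIAS_FACTOR = 50.0
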