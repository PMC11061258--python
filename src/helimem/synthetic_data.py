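"""Ground-truth generators for every input of the analysis pipeline.

Nothing here is physically dynamic: the generators produce the *statistical
and geometric structure* the analysis modules consume — ideal helices,
planar two-leaflet bilayers of the three study compositions, trajectories
with prescribed approach/orientation schedules, Brownian and tethered
lateral walks with known diffusion coefficients, analytic free-energy
surfaces with closed-form partition coefficients, and Gaussian deposition
records that reconstruct to a known target surface.  Every generator is
deterministic under a fixed seed; each call derives its own child stream so
adding one call does not shift another's output.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import erf, erfi

from ._constants import (
    DEFAULT_BIAS_FACTOR,
    DEFAULT_HILL_HEIGHT_KJ_MOL,
    DEFAULT_TEMPERATURE_K,
    KB_KJ_PER_MOL_K,
)
from .core import (
    BilayerModel,
    CVAxis,
    FESGrid,
    HillsRecord,
    NumericalError,
    Peptide,
    Trajectory,
    ValidationError,
)
from .peptide_geometry import classify_residues, decompose_moment

__all__ = [
    "PEPTIDE_SEQUENCES",
    "COMPOSITIONS",
    "fauchere_pliska_weights",
    "martini_bead_counts",
    "Schedule",
    "make_helix",
    "make_bilayer",
    "make_trajectory",
    "make_brownian_walk",
    "make_tethered_walk",
    "make_analytic_fes",
    "make_hills",
    "largest_remainder_counts",
]

#: Study peptides by PDB code (idealised fully-helical forms).
PEPTIDE_SEQUENCES = {
    "2MAG": "GIGKFLHSAKKFGKAFVGEIMNS",  # magainin-2
    "1Z64": "GWGSFFKKAAHVGKHVGKAALTHYL",  # pleurocidin
    "2JMY": "KWKLFKKIGAVLKVL",  # CM15
    "2K6O": "LLGDFFRKSKEKIGKEFKRIVQRIKDFLRNLVPRTES",  # LL37
    "6C41": "VFQFLGKIIHHVGNFVHGFSHVF",  # clavanin
}

#: The three study bilayer compositions (mole %), addressed by label.
COMPOSITIONS = {
    "healthy_popc": {"POPC": 100.0},
    "bacterial_pe_pg": {"POPE": 10.0, "POPG": 90.0},
    "cancer_5comp": {"CHOL": 28.4, "DOPE": 20.0, "DOPC": 20.0,
                     "DPSM": 18.4, "DOPS": 13.2},
}

#: Coarse-grained beads per residue (backbone + side chain), Martini 2.2-like.
_BEAD_COUNTS = {
    "G": 1, "A": 1, "V": 2, "L": 2, "I": 2, "P": 2, "M": 2, "C": 2,
    "S": 2, "T": 2, "N": 2, "Q": 2, "D": 2, "E": 2, "K": 3, "R": 3,
    "H": 4, "F": 4, "Y": 4, "W": 5,
}

_FP_CACHE: dict[str, float] | None = None


def fauchere_pliska_weights() -> dict[str, float]:
    """Per-residue hydrophobicity scale, loaded from the packaged table."""
    global _FP_CACHE
    if _FP_CACHE is None:
        text = resources.files("helimem.data").joinpath("fauchere_pliska.tsv").read_text()
        table = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("residue"):
                continue
            aa, w = line.split("\t")
            table[aa] = float(w)
        _FP_CACHE = table
    return dict(_FP_CACHE)


def martini_bead_counts(sequence: str) -> np.ndarray:
    return np.array([_BEAD_COUNTS[aa] for aa in sequence.upper()], dtype=int)


def _net_charge(sequence: str, charged_termini: bool = True) -> int:
    # K/R +1, D/E -1, H neutral; zwitterionic termini contribute net zero.
    q = sum(+1 for aa in sequence if aa in "KR") - sum(1 for aa in sequence if aa in "DE")
    return q


# ------------------------------------------------------------------- helix

def make_helix(
    sequence: str,
    rise: float = 0.15,
    radius: float = 0.23,
    turn_deg: float = 100.0,
    seed: int | None = None,
    charged_termini: bool = True,
) -> Peptide:
    """Backbone beads of an ideal alpha-helix, one bead per residue.

    The helix axis is local z with the N-terminus (residue 0) at the origin;
    defaults are the canonical alpha-helix rise (0.15 nm/residue), radius
    (0.23 nm) and 100 deg turn.  ``seed`` is accepted for interface symmetry
    with the other generators; the construction itself is deterministic.
    """
    if not sequence:
        raise ValidationError("empty sequence")
    seq = sequence.upper()
    classes = classify_residues(seq)  # rejects unknown codes
    weights = fauchere_pliska_weights()
    n = len(seq)
    i = np.arange(n)
    theta = np.deg2rad(turn_deg) * i
    pos = np.column_stack([radius * np.cos(theta), radius * np.sin(theta), rise * i])
    if n == 1:
        pos = np.zeros((1, 3))
    return Peptide(
        sequence=seq,
        backbone_positions=pos,
        bead_counts=martini_bead_counts(seq),
        residue_class=classes,
        hydrophobic_weight=np.array([weights[aa] for aa in seq]),
        net_charge=_net_charge(seq, charged_termini),
        n_term_index=0,
        c_term_index=n - 1,
    )


# ----------------------------------------------------------------- bilayer

def largest_remainder_counts(percentages: dict[str, float], total: int) -> dict[str, int]:
    """Integer lipid counts matching mole percentages by largest remainder."""
    if abs(sum(percentages.values()) - 100.0) > 0.1:
        raise ValidationError("composition percentages must sum to 100")
    raw = {k: v * total / 100.0 for k, v in percentages.items()}
    counts = {k: int(math.floor(v)) for k, v in raw.items()}
    short = total - sum(counts.values())
    order = sorted(raw, key=lambda k: (counts[k] - raw[k], k))  # largest remainder first
    for k in order[:short]:
        counts[k] += 1
    return counts


def make_bilayer(
    composition,
    lipids_per_leaflet: int = 250,
    area_per_lipid: float = 0.64,
    head_separation: float = 4.0,
    box_z: float = 12.0,
    jitter: float = 0.05,
    seed: int | None = None,
) -> BilayerModel:
    """Two planar leaflets of lipids on a jittered lattice.

    ``composition`` is a label from :data:`COMPOSITIONS` or an explicit
    name -> mole % map summing to 100.  Each lipid contributes a headgroup
    bead at +/- head_separation/2 from the bilayer centre, a linker bead and
    two tail beads toward the midplane.  Species counts per leaflet are the
    largest-remainder rounding of the percentages.
    """
    if isinstance(composition, str):
        if composition not in COMPOSITIONS:
            raise ValidationError(
                f"unknown composition {composition!r}; have {sorted(COMPOSITIONS)}"
            )
        comp = COMPOSITIONS[composition]
    else:
        comp = dict(composition)
    counts = largest_remainder_counts(comp, lipids_per_leaflet)
    rng = np.random.default_rng(seed)
    box_xy = math.sqrt(lipids_per_leaflet * area_per_lipid)
    center_z = box_z / 2.0
    n_side = int(math.ceil(math.sqrt(lipids_per_leaflet)))
    spacing = box_xy / n_side
    half = head_separation / 2.0
    # per-bead z offsets from the bilayer centre, top leaflet (mirrored below)
    bead_template = [("headgroup", half), ("linker", 0.65 * half),
                     ("tail", 0.35 * half), ("tail", 0.1 * half)]

    species = [name for name, c in sorted(counts.items()) for _ in range(c)]
    rows = []
    lipid_id = 0
    for leaflet, sign in (("upper", +1), ("lower", -1)):
        order = rng.permutation(len(species))
        for site, k in enumerate(order):
            gx, gy = divmod(site, n_side)
            x0 = (gx + 0.5) * spacing
            y0 = (gy + 0.5) * spacing
            name = species[k]
            dx, dy = rng.normal(0.0, jitter, size=2)
            for role, dz in bead_template:
                z = center_z + sign * dz + rng.normal(0.0, jitter)
                rows.append(
                    (lipid_id, name, leaflet, role,
                     (x0 + dx) % box_xy, (y0 + dy) % box_xy,
                     min(max(z, 0.0), box_z))
                )
            lipid_id += 1
    beads = pd.DataFrame(
        rows, columns=["lipid_id", "lipid_name", "leaflet", "role", "x", "y", "z"]
    )
    return BilayerModel(
        beads=beads,
        composition=comp,
        membrane_center_z=center_z,
        box=np.array([box_xy, box_xy, box_z]),
    )


# -------------------------------------------------------------- trajectory

@dataclass
class Schedule:
    """Waypoints of the prescribed peptide kinematics (linear interpolation).

    ``z`` is the COM height above the membrane centre (positive: upper
    side); ``tilt_deg``/``spin_deg`` are the target descriptor values.
    ``spin_deg`` may be None when the tilt passes through 0/180 deg, where
    the spin is undefined.
    """

    times: np.ndarray
    z: np.ndarray
    tilt_deg: np.ndarray
    spin_deg: np.ndarray | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValidationError("schedule waypoint times must increase")
        self.z = np.asarray(self.z, dtype=float)
        self.tilt_deg = np.asarray(self.tilt_deg, dtype=float)
        if self.spin_deg is not None:
            self.spin_deg = np.asarray(self.spin_deg, dtype=float)

    def at(self, t: np.ndarray):
        z = np.interp(t, self.times, self.z)
        tilt = np.interp(t, self.times, self.tilt_deg)
        spin = None if self.spin_deg is None else np.interp(t, self.times, self.spin_deg)
        return z, tilt, spin


def _orientation_basis(tilt_deg: float, spin_deg: float | None, alpha: int):
    """Target (NC_hat, mu_perp_hat) directions realising tilt and spin.

    The helix axis is placed in the xz-plane; cos(tilt) = NC_z / alpha fixes
    NC_z, and the spin angle is laid off from the tilt-reference vector
    about the axis with the handedness of the sign convention.
    """
    phi = math.radians(tilt_deg)
    nc = np.array([math.sin(phi), 0.0, alpha * math.cos(phi)])
    n_hat = np.array([0.0, 0.0, float(alpha)])
    t = np.cross(nc, np.cross(nc, n_hat))
    t_norm = np.linalg.norm(t)
    if t_norm < 1e-9:  # axis parallel to z: spin undefined, pick any basis
        t_hat = np.array([1.0, 0.0, 0.0])
        xi = 0.0 if spin_deg is None else math.radians(spin_deg)
    else:
        t_hat = t / t_norm
        xi = math.radians(180.0 if spin_deg is None else spin_deg)
    mu_hat = math.cos(xi) * t_hat + math.sin(xi) * np.cross(nc, t_hat)
    return nc, mu_hat


def make_trajectory(
    peptide: Peptide,
    bilayer: BilayerModel,
    schedule: Schedule,
    noise: float = 0.0,
    seed: int | None = None,
    frame_times=None,
) -> Trajectory:
    """Rigidly place the peptide per schedule over a static bilayer.

    At each frame the canonical helix is rotated so that its axis and the
    direction of its transversal hydrophobic moment realise the scheduled
    tilt and spin, translated to the scheduled height above the membrane
    centre, and optionally blurred with isotropic Gaussian positional noise
    of standard deviation ``noise`` (nm).
    """
    from .peptide_geometry import hydrophobic_moment

    times = np.asarray(schedule.times if frame_times is None else frame_times, dtype=float)
    z_t, tilt_t, spin_t = schedule.at(times)
    box = bilayer.box
    if np.any(bilayer.membrane_center_z + z_t >= box[2]) or np.any(
        bilayer.membrane_center_z + z_t <= 0
    ):
        raise ValidationError("schedule z exceeds the box height")

    # canonical frame of the as-built helix
    u_loc = peptide.n_term_position - peptide.c_term_position
    u_loc = u_loc / np.linalg.norm(u_loc)
    mu = hydrophobic_moment(peptide)
    mu_perp = decompose_moment(mu, u_loc).transversal
    mu_norm = np.linalg.norm(mu_perp)
    if spin_t is not None and mu_norm < 1e-8:
        raise ValidationError(
            "cannot realise a spin schedule: transversal hydrophobic moment vanishes"
        )
    p_loc = mu_perp / mu_norm if mu_norm >= 1e-8 else _any_perp(u_loc)
    basis_local = np.column_stack([u_loc, p_loc, np.cross(u_loc, p_loc)])

    rng = np.random.default_rng(seed)
    rel = peptide.backbone_positions - peptide.center_of_mass
    n_res = peptide.n_residues
    lip_xyz = bilayer.positions
    n_beads = n_res + lip_xyz.shape[0]
    coords = np.empty((times.size, n_beads, 3))
    x0, y0 = box[0] / 2.0, box[1] / 2.0
    for f, t in enumerate(times):
        alpha = -1 if z_t[f] >= 0 else +1
        nc_hat, mu_hat = _orientation_basis(
            tilt_t[f], None if spin_t is None else float(spin_t[f]), alpha
        )
        basis_target = np.column_stack([nc_hat, mu_hat, np.cross(nc_hat, mu_hat)])
        rot = basis_target @ basis_local.T
        com = np.array([x0, y0, bilayer.membrane_center_z + z_t[f]])
        pep = rel @ rot.T + com
        if noise > 0:
            pep = pep + rng.normal(0.0, noise, size=pep.shape)
        coords[f, :n_res] = pep
        coords[f, n_res:] = lip_xyz

    pep_meta = pd.DataFrame(
        {
            "bead_id": np.arange(n_res),
            "group": "peptide",
            "residue_index": np.arange(n_res),
            "residue_name": list(peptide.sequence),
            "residue_class": peptide.residue_class,
            "lipid_name": "",
            "leaflet": "",
            "role": "backbone",
        }
    )
    lip_meta = pd.DataFrame(
        {
            "bead_id": np.arange(n_res, n_beads),
            "group": "lipid",
            "residue_index": -1,
            "residue_name": "",
            "residue_class": "",
            "lipid_name": bilayer.beads["lipid_name"].to_numpy(),
            "leaflet": bilayer.beads["leaflet"].to_numpy(),
            "role": bilayer.beads["role"].to_numpy(),
        }
    )
    beads = pd.concat([pep_meta, lip_meta], ignore_index=True)
    return Trajectory(times=times, coords=coords, box=box.copy(), beads=beads)


def _any_perp(u: np.ndarray) -> np.ndarray:
    trial = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(trial, u)) > 0.9:
        trial = np.array([0.0, 1.0, 0.0])
    p = trial - np.dot(trial, u) * u
    return p / np.linalg.norm(p)


# ------------------------------------------------------------ lateral walks

def _walk_trajectory(times, xy, z0, box) -> Trajectory:
    box = np.asarray(box, dtype=float)
    coords = np.zeros((times.size, 1, 3))
    coords[:, 0, :2] = np.mod(xy, box[:2])
    coords[:, 0, 2] = z0
    beads = pd.DataFrame(
        {
            "bead_id": [0], "group": ["peptide"], "residue_index": [0],
            "residue_name": ["X"], "residue_class": ["hydrophobic"],
            "lipid_name": [""], "leaflet": [""], "role": ["com"],
        }
    )
    return Trajectory(times=times, coords=coords, box=box, beads=beads)


def make_brownian_walk(
    D: float, dt: float, n_steps: int, box=(12.65, 12.65, 12.0),
    seed: int | None = None, z0: float = 6.0,
) -> Trajectory:
    """2D Brownian COM track: i.i.d. Gaussian steps of variance 2 D dt per axis.

    ``D`` in nm^2/ns, ``dt`` in ns; positions are wrapped into the box
    (periodic), which :func:`lateral_diffusion.unwrap_track` undoes.
    """
    if D < 0 or dt <= 0:
        raise ValidationError("need D >= 0 and dt > 0")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, math.sqrt(2.0 * D * dt), size=(n_steps, 2)) if D > 0 else np.zeros((n_steps, 2))
    xy = np.vstack([[0.0, 0.0], np.cumsum(steps, axis=0)]) + np.asarray(box[:2]) / 2.0
    times = dt * np.arange(n_steps + 1)
    return _walk_trajectory(times, xy, z0, box)


def make_tethered_walk(
    D: float, tau: float, dt: float, n_steps: int, box=(12.65, 12.65, 12.0),
    seed: int | None = None, z0: float = 6.0,
) -> Trajectory:
    """Harmonically confined (Ornstein-Uhlenbeck) lateral walk.

    Short-lag displacements diffuse with coefficient ``D``; beyond the
    relaxation time ``tau`` (ns) the mean-square displacement plateaus at
    4 D tau, so the apparent windowed diffusion coefficient decreases with
    the window length.  Exact discretisation (a = exp(-dt/tau)).
    """
    if D <= 0 or tau <= 0 or dt <= 0:
        raise ValidationError("need D, tau, dt > 0")
    rng = np.random.default_rng(seed)
    a = math.exp(-dt / tau)
    sigma_eq = math.sqrt(D * tau)
    xy = np.empty((n_steps + 1, 2))
    xy[0] = rng.normal(0.0, sigma_eq, size=2)
    kick = sigma_eq * math.sqrt(1.0 - a * a)
    noise = rng.normal(0.0, kick, size=(n_steps, 2))
    for i in range(n_steps):
        xy[i + 1] = xy[i] * a + noise[i]
    xy += np.asarray(box[:2]) / 2.0
    times = dt * np.arange(n_steps + 1)
    return _walk_trajectory(times, xy, z0, box)


# ------------------------------------------------------------- analytic FES

def make_analytic_fes(
    form: str,
    params: dict,
    z_range=(0.0, 8.0),
    n_z: int = 801,
    n_cos: int = 41,
    temperature: float = DEFAULT_TEMPERATURE_K,
):
    """Closed-form 2D free-energy surface W(z, cos_tilt) plus its exact kappa.

    Returns ``(fes, kappa_exact)`` where ``kappa_exact(lam)`` evaluates the
    analytic partition coefficient.  Forms:

    ``flat``
        W = 0; kappa = 1.
    ``square_well``
        W = -eps on z in [z1, z2] (all tilts), with optional linear edge
        ramps of width ``ramp`` (default 0, i.e. sharp edges).
    ``harmonic_well``
        W = k/2 (z - z0)^2 - eps where negative, 0 elsewhere (tilt
        independent); kappa from the Gaussian-integral error function.
    ``tilted_well``
        W = -eps * cos_tilt^2 on z in [z1, z2]; kappa via the imaginary
        error function.
    """
    beta = 1.0 / (KB_KJ_PER_MOL_K * temperature)
    z = np.linspace(z_range[0], z_range[1], n_z)
    c = np.linspace(-1.0, 1.0, n_cos)
    zz = z[:, None]

    if form == "flat":
        w = np.zeros((n_z, n_cos))

        def kappa_exact(lam: float) -> float:
            return 1.0

    elif form == "square_well":
        eps, z1, z2 = params["eps"], params["z1"], params["z2"]
        ramp = params.get("ramp", 0.0)
        if not (z_range[0] <= z1 < z2 <= z_range[1]):
            raise ValidationError("square well outside grid")
        prof = np.zeros(n_z)
        core = (z >= z1 + ramp) & (z <= z2 - ramp)
        prof[core] = -eps
        if ramp > 0:
            up = (z > z1) & (z < z1 + ramp)
            prof[up] = -eps * (z[up] - z1) / ramp
            down = (z > z2 - ramp) & (z < z2)
            prof[down] = -eps * (z2 - z[down]) / ramp
        w = np.repeat(prof[:, None], n_cos, axis=1)

        def kappa_exact(lam: float) -> float:
            d = z2 - z1
            core_len = d - 2.0 * ramp
            ramp_int = 2.0 * ramp * (math.exp(beta * eps) - 1.0) / (beta * eps) if ramp > 0 else 0.0
            return ((lam - d) + core_len * math.exp(beta * eps) + ramp_int) / lam

    elif form == "harmonic_well":
        eps, k, z0 = params["eps"], params["k"], params["z0"]
        a = math.sqrt(2.0 * eps / k)
        if z0 - a < z_range[0] or z0 + a > z_range[1]:
            raise ValidationError("harmonic well extends outside grid")
        prof = np.minimum(0.5 * k * (z - z0) ** 2 - eps, 0.0)
        w = np.repeat(prof[:, None], n_cos, axis=1)

        def kappa_exact(lam: float) -> float:
            if lam < z0 + a:
                raise ValidationError("lambda must clear the well")
            gauss = math.exp(beta * eps) * math.sqrt(2.0 * math.pi / (beta * k)) * erf(
                a * math.sqrt(beta * k / 2.0)
            )
            return ((lam - 2.0 * a) + gauss) / lam

    elif form == "tilted_well":
        eps, z1, z2 = params["eps"], params["z1"], params["z2"]
        slab = (zz >= z1) & (zz <= z2)
        w = np.where(slab, -eps * c[None, :] ** 2, 0.0)

        def kappa_exact(lam: float) -> float:
            d = z2 - z1
            inner = math.sqrt(math.pi / (beta * eps)) * erfi(math.sqrt(beta * eps))
            return (2.0 * (lam - d) + d * inner) / (2.0 * lam)

    else:
        raise ValidationError(f"unknown analytic FES form {form!r}")

    fes = FESGrid(
        axes=[CVAxis("z", z, unit="nm"), CVAxis("cos_tilt", c)],
        values=w,
        temperature=temperature,
    )
    return fes, kappa_exact


# ----------------------------------------------------------------- hills

def make_hills(
    target_fes: FESGrid,
    sigma=None,
    height: float = DEFAULT_HILL_HEIGHT_KJ_MOL,
    bias_factor: float = DEFAULT_BIAS_FACTOR,
    tol: float = 0.25,
    max_hills: int = 50000,
    n_walkers: int = 6,
    time_step: float = 1.0,
    seed: int | None = None,
) -> HillsRecord:
    """Deposit Gaussians whose tempered sum reconstructs a target surface.

    Greedy matching pursuit on the target bias V = (gamma-1)/gamma *
    (max(W) - W): each step deposits a Gaussian (width ``sigma`` per axis,
    height capped at ``height``) at the grid point of largest residual until
    the residual drops below ``tol`` (kJ/mol, on the bias scale).  The
    record reproduces the target up to the deposition granularity when
    re-summed by :func:`fes_thermo.reconstruct_fes`.
    """
    gamma = bias_factor
    if gamma <= 1:
        raise ValidationError("bias factor must exceed 1")
    axes = target_fes.axes
    if sigma is None:
        sigma = [4.0 * float(np.mean(np.diff(ax.values))) for ax in axes]
    sigma = np.asarray(sigma, dtype=float)
    mesh = np.meshgrid(*[ax.values for ax in axes], indexing="ij")
    flat = [m.ravel() for m in mesh]
    w = target_fes.values.ravel()
    v_target = (gamma - 1.0) / gamma * (w.max() - w)
    residual = v_target.copy()
    centers, heights = [], []
    rng = np.random.default_rng(seed)
    for _ in range(max_hills):
        i = int(np.argmax(residual))
        r_max = residual[i]
        if r_max <= tol:
            break
        h = min(height, r_max)
        center = np.array([flat[d][i] for d in range(len(axes))])
        expo = np.zeros_like(residual)
        for d, ax in enumerate(axes):
            delta = flat[d] - center[d]
            if ax.periodic:
                delta -= ax.period * np.round(delta / ax.period)
            expo += (delta / sigma[d]) ** 2
        residual -= h * np.exp(-0.5 * expo)
        centers.append(center)
        heights.append(h)
    else:
        raise NumericalError(
            f"deposition did not converge in {max_hills} hills; "
            f"max residual {residual.max():.3g} kJ/mol > tol {tol}"
        )
    n = len(heights)
    if n == 0:
        return HillsRecord(
            [ax.name for ax in axes], np.empty(0), np.empty((0, len(axes))),
            np.empty((0, len(axes))), np.empty(0), gamma, np.empty(0, dtype=int),
        )
    return HillsRecord(
        cv_names=[ax.name for ax in axes],
        times=time_step * np.arange(n, dtype=float),
        centers=np.asarray(centers),
        sigmas=np.tile(sigma, (n, 1)),
        heights=np.asarray(heights),
        bias_factor=gamma,
        walker_ids=np.arange(n) % n_walkers,
    )
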