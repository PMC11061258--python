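"""Helix orientation descriptors relative to a planar bilayer.

A rigid helical peptide near a membrane whose plane is xy is described by
three per-frame quantities:

* the signed z-distance between the peptide centre of mass and the membrane
  centre;
* the tilt angle phi between the helix axis (the vector from the C-terminus
  to the N-terminus) and the membrane normal, signed through a leaflet factor
  alpha so that phi = 0 deg always means "N-terminus toward the nearer
  leaflet" regardless of which side the peptide is on;
* the spin angle xi, the azimuthal rotation of the helix about its own axis,
  measured between the in-plane tilt-reference vector t_hat and the
  transversal component of the hydrophobic dipole moment.  xi = 180 deg means
  the hydrophobic face points at the membrane.

The hydrophobic dipole moment is mu = sum_i mu_i r_i with mu_i the
Fauchere-Pliska hydrophobicity of residue i and r_i the backbone-bead
position relative to the (unweighted) backbone centre of mass; it is
decomposed into components parallel and perpendicular to the helix axis.

Conventions (pinned once, used everywhere):

* NC = r_N - r_C, pointing from the C- to the N-terminus.
* alpha = -1 when the peptide is nearer the upper leaflet, +1 for the lower.
* n_hat = alpha * z_hat is the unit vector from the peptide toward the
  nearer leaflet; t_hat = normalize(NC_hat x (NC_hat x n_hat)).
* cos(phi) = NC_z / (|NC| * alpha).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import (
    BilayerModel,
    Peptide,
    Trajectory,
    UndefinedSpinError,
    ValidationError,
    minimum_image,
)

__all__ = [
    "RESIDUE_CLASSES",
    "classify_residues",
    "composition_fingerprint",
    "CompositionFingerprint",
    "HelixFrame",
    "helix_frame",
    "tilt_angle",
    "hydrophobic_moment",
    "HydrophobicMoment",
    "decompose_moment",
    "spin_angle",
    "OrientationSeries",
    "orientation_series",
    "write_orientation_tsv",
]

#: Residue-class assignment for the four-way composition fingerprints.
#: Basic carries a positive (or protonatable) side chain, acidic a negative
#: one; polar groups side chains with uncharged H-bonding heteroatoms
#: (including the tyrosine hydroxyl); everything else is hydrophobic.
RESIDUE_CLASSES: dict[str, str] = {}
for _aa in "KRH":
    RESIDUE_CLASSES[_aa] = "basic"
for _aa in "DE":
    RESIDUE_CLASSES[_aa] = "acidic"
for _aa in "STNQY":
    RESIDUE_CLASSES[_aa] = "polar"
for _aa in "GAVLIPFMWC":
    RESIDUE_CLASSES[_aa] = "hydrophobic"

_SPIN_MOMENT_TOL = 1e-8
_SPIN_SIN_TILT_TOL = 1e-6


def classify_residues(sequence: str) -> list[str]:
    """Map each one-letter residue code to its four-way class.

    Raises :class:`ValidationError` naming the first offending position if a
    code is not a standard amino-acid letter.
    """
    classes = []
    for i, code in enumerate(sequence):
        cls = RESIDUE_CLASSES.get(code.upper())
        if cls is None:
            raise ValidationError(f"unknown residue code {code!r} at position {i}")
        classes.append(cls)
    return classes


@dataclass(frozen=True)
class CompositionFingerprint:
    percent_basic: float
    percent_acidic: float
    percent_polar: float
    percent_hydrophobic: float

    def as_dict(self) -> dict[str, float]:
        return {
            "basic": self.percent_basic,
            "acidic": self.percent_acidic,
            "polar": self.percent_polar,
            "hydrophobic": self.percent_hydrophobic,
        }


def composition_fingerprint(classes: list[str]) -> CompositionFingerprint:
    """Percentages of the four residue classes in a classified sequence."""
    if not classes:
        raise ValidationError("empty class list")
    n = len(classes)
    pct = {c: 100.0 * classes.count(c) / n for c in ("basic", "acidic", "polar", "hydrophobic")}
    return CompositionFingerprint(pct["basic"], pct["acidic"], pct["polar"], pct["hydrophobic"])


@dataclass(frozen=True)
class HelixFrame:
    """Orientation frame of one peptide configuration relative to the bilayer.

    ``tilt_reference`` (t_hat) is None when the helix axis is parallel to z,
    in which case the spin angle is undefined.
    """

    nc_vector: np.ndarray
    nc_unit: np.ndarray
    leaflet_side: str  # 'upper' | 'lower'
    alpha: int  # -1 upper, +1 lower
    membrane_normal_to_membrane: np.ndarray  # n_hat, from peptide toward nearer leaflet
    tilt_reference: np.ndarray | None  # t_hat


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def helix_frame(
    n_term_position,
    c_term_position,
    com_z: float,
    membrane_center_z: float = 0.0,
    box_z: float | None = None,
) -> HelixFrame:
    """Build the orientation frame for one configuration.

    ``com_z`` is the peptide centre-of-mass z used only to decide which
    leaflet is nearer (minimum image if ``box_z`` is given).
    """
    n_pos = np.asarray(n_term_position, dtype=float)
    c_pos = np.asarray(c_term_position, dtype=float)
    nc = n_pos - c_pos
    norm = np.linalg.norm(nc)
    if norm < 1e-12:
        raise ValidationError("coincident termini: helix axis undefined")
    nc_unit = nc / norm
    dz = float(minimum_image(com_z - membrane_center_z, box_z))
    side = "upper" if dz >= 0 else "lower"
    alpha = -1 if side == "upper" else +1
    n_hat = np.array([0.0, 0.0, float(alpha)])
    # t_hat lies in the plane of (axis, z), perpendicular to the axis.
    w = np.cross(nc_unit, n_hat)
    t = np.cross(nc_unit, w)
    t_norm = np.linalg.norm(t)
    sin_tilt = np.linalg.norm(np.cross(nc_unit, np.array([0.0, 0.0, 1.0])))
    t_hat = t / t_norm if sin_tilt > _SPIN_SIN_TILT_TOL else None
    return HelixFrame(nc, nc_unit, side, alpha, n_hat, t_hat)


def tilt_angle(frame: HelixFrame) -> float:
    """Tilt angle phi in degrees, cos(phi) = NC_z / (|NC| alpha).

    0 deg: N-terminus points toward the nearer leaflet along z; 180 deg: the
    C-terminus does.
    """
    cos_phi = frame.nc_unit[2] / frame.alpha
    return math.degrees(math.acos(max(-1.0, min(1.0, cos_phi))))


@dataclass(frozen=True)
class HydrophobicMoment:
    total: np.ndarray
    longitudinal: np.ndarray
    transversal: np.ndarray


def hydrophobic_moment(peptide: Peptide) -> np.ndarray:
    """Hydrophobic dipole moment mu = sum_i mu_i r_i (dimensionless * nm).

    Positions are taken relative to the unweighted backbone centre of mass,
    which makes the result translation-invariant.
    """
    w = peptide.hydrophobic_weight
    if w.shape[0] != peptide.n_residues or not np.all(np.isfinite(w)):
        raise ValidationError("every residue needs a finite hydrophobic weight")
    rel = peptide.backbone_positions - peptide.center_of_mass
    return (w[:, None] * rel).sum(axis=0)


def decompose_moment(moment, nc_unit) -> HydrophobicMoment:
    """Split mu into its projection on the helix axis and the remainder."""
    mu = np.asarray(moment, dtype=float)
    u = np.asarray(nc_unit, dtype=float)
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        raise ValidationError("zero helix-axis vector")
    if abs(norm - 1.0) > 1e-6:
        u = u / norm
    longitudinal = np.dot(mu, u) * u
    return HydrophobicMoment(mu, longitudinal, mu - longitudinal)


def spin_angle(transversal, frame: HelixFrame) -> float:
    """Spin angle xi in degrees, in [0, 360).

    xi = arccos(t_hat . mu_perp_hat), lifted to [0, 360) by the sign of
    NC_hat . (t_hat x mu_perp): positive for xi < 180, negative for xi > 180.
    xi = 180 deg iff the transversal moment points toward the nearer leaflet.
    """
    mu_perp = np.asarray(transversal, dtype=float)
    norm = np.linalg.norm(mu_perp)
    if norm < _SPIN_MOMENT_TOL:
        raise UndefinedSpinError("transversal hydrophobic moment vanishes")
    if frame.tilt_reference is None:
        raise UndefinedSpinError("helix axis parallel to z: tilt reference undefined")
    t_hat = frame.tilt_reference
    cos_xi = float(np.dot(t_hat, mu_perp) / norm)
    xi = math.degrees(math.acos(max(-1.0, min(1.0, cos_xi))))
    sign = float(np.dot(frame.nc_unit, np.cross(t_hat, mu_perp)))
    if sign < 0:
        xi = 360.0 - xi
    return xi % 360.0


@dataclass
class OrientationSeries:
    """Per-frame orientation descriptors along a trajectory."""

    times: np.ndarray  # ns
    com_distance: np.ndarray  # signed z-distance to membrane centre, nm
    tilt_deg: np.ndarray  # [0, 180]
    spin_deg: np.ndarray  # [0, 360); NaN where undefined
    spin_defined: np.ndarray  # bool

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ns": self.times,
                "com_distance_nm": self.com_distance,
                "tilt_deg": self.tilt_deg,
                "spin_deg": self.spin_deg,
                "spin_defined": self.spin_defined,
            }
        )


def orientation_series(
    trajectory: Trajectory,
    peptide: Peptide,
    bilayer: BilayerModel | None = None,
) -> OrientationSeries:
    """Compute COM distance, tilt and spin for every trajectory frame.

    Peptide backbone beads are identified in the trajectory metadata
    (group == 'peptide') and matched to ``peptide`` residues by order; the
    membrane centre is taken from ``bilayer`` when given, otherwise from the
    mean z of the lipid beads of each frame.
    """
    if trajectory.n_frames == 0:
        raise ValidationError("empty trajectory")
    pep_idx = trajectory.peptide_indices()
    if pep_idx.size != peptide.n_residues:
        raise ValidationError(
            f"trajectory has {pep_idx.size} peptide beads, peptide has "
            f"{peptide.n_residues} residues"
        )
    box_z = float(trajectory.box[2]) if trajectory.box[2] > 0 else None
    mu_w = peptide.hydrophobic_weight

    n_f = trajectory.n_frames
    dist = np.empty(n_f)
    tilt = np.empty(n_f)
    spin = np.full(n_f, np.nan)
    defined = np.zeros(n_f, dtype=bool)
    for f in range(n_f):
        pos = trajectory.coords[f, pep_idx]
        if bilayer is not None:
            center_z = bilayer.membrane_center_z
        else:
            center_z = float(trajectory.coords[f, trajectory.lipid_indices(), 2].mean())
        com = pos.mean(axis=0)
        dz = float(minimum_image(com[2] - center_z, box_z))
        frame = helix_frame(
            pos[peptide.n_term_index], pos[peptide.c_term_index], com[2], center_z, box_z
        )
        dist[f] = dz
        tilt[f] = tilt_angle(frame)
        mu = (mu_w[:, None] * (pos - com)).sum(axis=0)
        comp = decompose_moment(mu, frame.nc_unit)
        try:
            spin[f] = spin_angle(comp.transversal, frame)
            defined[f] = True
        except UndefinedSpinError:
            pass
    return OrientationSeries(trajectory.times.copy(), dist, tilt, spin, defined)


def write_orientation_tsv(series: OrientationSeries, path) -> None:
    series.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
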