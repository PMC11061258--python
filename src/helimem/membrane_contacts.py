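"""Peptide-lipid contact fingerprints and z-density profiles.

A contact is a peptide-bead / lipid-bead pair whose minimum-image distance
is at or below a cutoff (default 0.6 nm).  Raw counts are aggregated into a
residue-class x lipid-species matrix, averaged over a trailing time window,
and normalised by the total number of peptide beads of each residue class so
that residues of different size are comparable.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import Peptide, Trajectory, ValidationError
from ._constants import DEFAULT_CONTACT_CUTOFF_NM

__all__ = [
    "ContactFingerprint",
    "count_contacts",
    "normalize_fingerprint",
    "average_fingerprint",
    "DensityProfile",
    "density_profile",
    "write_fingerprint_tsv",
    "write_density_tsv",
]


@dataclass
class ContactFingerprint:
    """Residue-class x lipid-name contact matrix.

    ``normalized`` guards against dividing by per-class bead counts twice.
    """

    matrix: pd.DataFrame  # rows: residue class, columns: lipid name
    cutoff: float
    window: tuple[float, float] | None = None
    normalized: bool = False

    def __post_init__(self):
        vals = self.matrix.to_numpy(dtype=float)
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValidationError("contact matrix entries must be finite and >= 0")


def count_contacts(
    peptide_positions,
    peptide_classes,
    lipid_positions,
    lipid_names,
    box,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
) -> pd.DataFrame:
    """Raw residue-class x lipid-name contact counts for one frame.

    Counts bead-bead pairs within ``cutoff`` under the 3D minimum-image
    convention (orthorhombic box), using a periodic k-d tree.
    """
    if cutoff <= 0:
        raise ValidationError("cutoff must be positive")
    pep = np.asarray(peptide_positions, dtype=float)
    lip = np.asarray(lipid_positions, dtype=float)
    if pep.size == 0 or lip.size == 0:
        raise ValidationError("empty peptide or lipid selection")
    if not (np.all(np.isfinite(pep)) and np.all(np.isfinite(lip))):
        raise ValidationError("positions must be finite")
    box = np.asarray(box, dtype=float)
    classes = np.asarray(peptide_classes)
    names = np.asarray(lipid_names)

    # cKDTree with boxsize needs coordinates inside the primary cell.
    pep_w = np.mod(pep, box)
    lip_w = np.mod(lip, box)
    tree = cKDTree(lip_w, boxsize=box)
    neighbours = tree.query_ball_point(pep_w, r=cutoff)

    class_order = sorted(set(classes.tolist()))
    name_order = sorted(set(names.tolist()))
    mat = pd.DataFrame(0.0, index=class_order, columns=name_order)
    for i, hits in enumerate(neighbours):
        if hits:
            cls = classes[i]
            for name, cnt in zip(*np.unique(names[hits], return_counts=True)):
                mat.loc[cls, name] += cnt
    return mat


def normalize_fingerprint(raw, peptide: Peptide, cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
                          window=None) -> ContactFingerprint:
    """Divide each residue-class row by the total peptide beads of that class."""
    if isinstance(raw, ContactFingerprint):
        if raw.normalized:
            raise ValidationError("fingerprint already normalized")
        matrix, cutoff, window = raw.matrix, raw.cutoff, raw.window
    else:
        matrix = raw
    beads_per_class = {}
    for cls, n_beads in zip(peptide.residue_class, peptide.bead_counts):
        beads_per_class[cls] = beads_per_class.get(cls, 0) + int(n_beads)
    out = {}
    for cls in matrix.index:
        n = beads_per_class.get(cls, 0)
        if n == 0:
            if matrix.loc[cls].abs().sum() > 0:
                raise ValidationError(
                    f"contacts reported for class {cls!r} with zero peptide beads"
                )
            continue  # class absent from peptide: row dropped
        out[cls] = matrix.loc[cls] / n
    return ContactFingerprint(pd.DataFrame(out).T, cutoff=cutoff, window=window, normalized=True)


def average_fingerprint(
    trajectory: Trajectory,
    peptide: Peptide,
    cutoff: float = DEFAULT_CONTACT_CUTOFF_NM,
    window: tuple[float, float] | None = None,
) -> ContactFingerprint:
    """Frame-averaged, per-class-bead-normalised contact fingerprint.

    ``window`` defaults to the full trajectory span; typical use is the
    trailing microsecond of an adsorption run.
    """
    if window is None:
        window = (float(trajectory.times.min()), float(trajectory.times.max()))
    frames = trajectory.frame_indices_in(*window)
    if frames.size == 0:
        raise ValidationError(f"no frames in window {window}")
    pep_idx = trajectory.peptide_indices()
    lip_idx = trajectory.lipid_indices()
    classes = trajectory.beads["residue_class"].to_numpy()[pep_idx]
    names = trajectory.beads["lipid_name"].to_numpy()[lip_idx]
    acc = None
    for f in frames:
        mat = count_contacts(
            trajectory.coords[f, pep_idx], classes,
            trajectory.coords[f, lip_idx], names,
            trajectory.box, cutoff,
        )
        acc = mat if acc is None else acc.add(mat, fill_value=0.0)
    mean = acc / frames.size
    return normalize_fingerprint(
        ContactFingerprint(mean, cutoff=cutoff, window=window), peptide
    )


@dataclass
class DensityProfile:
    """z-histograms of lipid headgroups, lipid tails and peptide beads."""

    z_edges: np.ndarray  # nm, bin edges (centred on the bilayer COM z)
    heads: np.ndarray  # bead counts x frames per bin
    tails: np.ndarray
    peptide: np.ndarray
    window: tuple[float, float]

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "z_center_nm": self.z_centers,
                "heads": self.heads,
                "tails": self.tails,
                "peptide": self.peptide,
            }
        )


def density_profile(
    trajectory: Trajectory,
    window: tuple[float, float] | None = None,
    bin_width: float = 0.1,
) -> DensityProfile:
    """Bead-count z-profiles over a trailing window, wrapped into the box.

    Bins cover one box height, centred so that the bilayer centre of mass
    sits mid-range; headgroup and linker beads count as heads.
    """
    if bin_width <= 0:
        raise ValidationError("bin_width must be positive")
    box_z = float(trajectory.box[2])
    if box_z <= 0:
        raise ValidationError("zero-thickness box")
    if window is None:
        window = (float(trajectory.times.min()), float(trajectory.times.max()))
    frames = trajectory.frame_indices_in(*window)
    if frames.size == 0:
        raise ValidationError(f"no frames in window {window}")

    beads = trajectory.beads
    lip = (beads["group"] == "lipid").to_numpy()
    role = beads["role"].astype(str).to_numpy()
    idx_heads = np.nonzero(lip & np.isin(role, ["headgroup", "linker"]))[0]
    idx_tails = np.nonzero(lip & (role == "tail"))[0]
    idx_pep = np.nonzero((beads["group"] == "peptide").to_numpy())[0]

    center = float(trajectory.coords[frames][:, lip, 2].mean()) if lip.any() else box_z / 2
    n_bins = max(2, int(round(box_z / bin_width)))
    z_edges = np.linspace(center - box_z / 2, center + box_z / 2, n_bins + 1)

    def hist(indices):
        if indices.size == 0:
            return np.zeros(n_bins)
        z = trajectory.coords[frames][:, indices, 2].ravel()
        z = np.mod(z - z_edges[0], box_z) + z_edges[0]  # wrap into the bin range
        h, _ = np.histogram(z, bins=z_edges)
        return h.astype(float)

    return DensityProfile(z_edges, hist(idx_heads), hist(idx_tails), hist(idx_pep), window)


def write_fingerprint_tsv(fp: ContactFingerprint, path) -> None:
    fp.matrix.to_csv(path, sep="\t", index_label="residue_class", float_format="%.6f")


def write_density_tsv(profile: DensityProfile, path) -> None:
    profile.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")
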