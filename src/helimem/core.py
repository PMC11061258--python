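"""Core in-memory containers shared by every analysis module.

The containers are deliberately thin: peptides, bilayers and trajectories are
plain dataclasses wrapping NumPy arrays plus a pandas bead-metadata table, so
that each analysis module can select beads by role without re-parsing files.
All coordinates are in nm, times in ns, energies in kJ/mol.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HelimemError",
    "InputError",
    "ValidationError",
    "NumericalError",
    "UndefinedSpinError",
    "Peptide",
    "BilayerModel",
    "Trajectory",
    "CVAxis",
    "FESGrid",
    "PMFProfile",
    "HillsRecord",
    "minimum_image",
]


class HelimemError(Exception):
    """Base class for package errors."""


class InputError(HelimemError):
    """Missing or unparseable input."""


class ValidationError(HelimemError):
    """Input parsed but violates a documented precondition."""


class NumericalError(HelimemError):
    """A numerical procedure failed to converge or produced non-finite values."""


class UndefinedSpinError(ValidationError):
    """Spin angle undefined: vanishing transversal moment or axis parallel to z."""


RESIDUE_CLASS_NAMES = ("basic", "acidic", "polar", "hydrophobic")


def minimum_image(delta, box_length):
    """Minimum-image displacement(s) for an orthorhombic box edge."""
    delta = np.asarray(delta, dtype=float)
    if box_length is None or box_length <= 0:
        return delta
    return delta - box_length * np.round(delta / box_length)


@dataclass
class Peptide:
    """A rigid helical coarse-grained peptide, one backbone bead per residue.

    ``bead_counts`` stores the total CG bead count of each residue (backbone +
    side chain); it is what the per-class contact normalisation divides by.
    """

    sequence: str
    backbone_positions: np.ndarray  # (n, 3) nm
    bead_counts: np.ndarray  # (n,) int
    residue_class: list[str]
    hydrophobic_weight: np.ndarray  # (n,) dimensionless
    net_charge: int = 0
    n_term_index: int = 0
    c_term_index: int = -1

    def __post_init__(self):
        n = len(self.sequence)
        if not 1 <= n <= 1000:
            raise ValidationError(f"sequence length {n} outside [1, 1000]")
        self.backbone_positions = np.asarray(self.backbone_positions, dtype=float)
        if self.backbone_positions.shape != (n, 3):
            raise ValidationError("backbone_positions must be (n_residues, 3)")
        if not np.all(np.isfinite(self.backbone_positions)):
            raise ValidationError("backbone_positions must be finite")
        self.bead_counts = np.asarray(self.bead_counts, dtype=int)
        self.hydrophobic_weight = np.asarray(self.hydrophobic_weight, dtype=float)
        if self.c_term_index == -1:
            self.c_term_index = n - 1
        if n > 1 and self.n_term_index == self.c_term_index:
            raise ValidationError("termini indices must differ")
        bad = [c for c in self.residue_class if c not in RESIDUE_CLASS_NAMES]
        if bad:
            raise ValidationError(f"unknown residue classes: {sorted(set(bad))}")

    @property
    def n_residues(self) -> int:
        return len(self.sequence)

    @property
    def center_of_mass(self) -> np.ndarray:
        """Unweighted mean of the backbone beads."""
        return self.backbone_positions.mean(axis=0)

    @property
    def n_term_position(self) -> np.ndarray:
        return self.backbone_positions[self.n_term_index]

    @property
    def c_term_position(self) -> np.ndarray:
        return self.backbone_positions[self.c_term_index]

    def translated(self, offset) -> "Peptide":
        return replace(self, backbone_positions=self.backbone_positions + np.asarray(offset, float))


@dataclass
class BilayerModel:
    """Planar two-leaflet bilayer: per-bead table plus target composition.

    ``beads`` columns: lipid_id, lipid_name, leaflet ('upper'/'lower'),
    role ('headgroup'/'linker'/'tail'), x, y, z.
    """

    beads: pd.DataFrame
    composition: dict[str, float]  # lipid_name -> mole %
    membrane_center_z: float
    box: np.ndarray  # (3,) nm

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=float)
        total = sum(self.composition.values())
        if abs(total - 100.0) > 0.1:
            raise ValidationError(f"composition sums to {total}, not 100")
        leaflets = set(self.beads["leaflet"].unique())
        if leaflets != {"upper", "lower"}:
            raise ValidationError("bilayer must have upper and lower leaflets")
        xyz = self.beads[["x", "y", "z"]].to_numpy()
        if np.any(xyz < -1e-9) or np.any(xyz > self.box + 1e-9):
            raise ValidationError("bilayer bead positions outside box")

    @property
    def positions(self) -> np.ndarray:
        return self.beads[["x", "y", "z"]].to_numpy(dtype=float)

    def realized_composition(self) -> dict[str, float]:
        counts = self.beads.groupby("lipid_name")["lipid_id"].nunique()
        return (100.0 * counts / counts.sum()).to_dict()


@dataclass
class Trajectory:
    """Time-stamped frames of peptide and/or bilayer beads in one box.

    ``beads`` metadata columns: bead_id, group ('peptide'/'lipid'),
    residue_index, residue_name, residue_class, lipid_name, leaflet, role.
    Irrelevant columns may hold NaN/empty strings for the other group.
    """

    times: np.ndarray  # (F,) ns
    coords: np.ndarray  # (F, N, 3) nm
    box: np.ndarray  # (3,) nm
    beads: pd.DataFrame

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[0] != self.times.size:
            raise ValidationError("coords must be (n_frames, n_beads, 3)")
        if len(self.beads) != self.coords.shape[1]:
            raise ValidationError("bead metadata length mismatch")

    @property
    def n_frames(self) -> int:
        return self.times.size

    def frame_indices_in(self, t_start: float, t_end: float) -> np.ndarray:
        return np.nonzero((self.times >= t_start - 1e-12) & (self.times <= t_end + 1e-12))[0]

    def peptide_indices(self) -> np.ndarray:
        idx = np.nonzero((self.beads["group"] == "peptide").to_numpy())[0]
        if idx.size == 0:
            raise ValidationError("trajectory contains no peptide beads")
        return idx

    def lipid_indices(self) -> np.ndarray:
        idx = np.nonzero((self.beads["group"] == "lipid").to_numpy())[0]
        if idx.size == 0:
            raise ValidationError("trajectory contains no lipid beads")
        return idx


@dataclass
class CVAxis:
    """One collective-variable axis of a free-energy grid."""

    name: str
    values: np.ndarray  # (m,) monotonically increasing grid
    periodic: bool = False
    period: float = 0.0
    unit: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 2:
            raise ValidationError(f"axis {self.name}: need >= 2 grid points")
        if np.any(np.diff(self.values) <= 0):
            raise ValidationError(f"axis {self.name}: grid must increase")
        if self.periodic and self.period <= 0:
            raise ValidationError(f"axis {self.name}: periodic axis needs period > 0")


@dataclass
class FESGrid:
    """Rectangular free-energy surface over named CV axes, kJ/mol."""

    axes: list[CVAxis]
    values: np.ndarray
    temperature: float = 300.0
    bias_factor: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        shape = tuple(ax.values.size for ax in self.axes)
        if self.values.shape != shape:
            raise ValidationError(f"FES values shape {self.values.shape} != grid {shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("FES values must be finite")

    def axis(self, name: str) -> int:
        for i, ax in enumerate(self.axes):
            if ax.name == name:
                return i
        raise ValidationError(f"no axis named {name!r}; have {[a.name for a in self.axes]}")

    def shifted_to_zero_min(self) -> "FESGrid":
        return replace(self, values=self.values - self.values.min())


@dataclass
class PMFProfile:
    """1D potential of mean force along one CV, kJ/mol."""

    axis_name: str
    grid: np.ndarray
    values: np.ndarray
    uncertainty: np.ndarray | None = None
    reference_window: tuple[float, float] | None = None

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.grid.shape != self.values.shape:
            raise ValidationError("PMF grid/values shape mismatch")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("PMF values must be finite")
        if self.uncertainty is not None:
            self.uncertainty = np.asarray(self.uncertainty, dtype=float)
            if np.any(self.uncertainty < 0):
                raise ValidationError("PMF uncertainty must be >= 0")


@dataclass
class HillsRecord:
    """Time-ordered Gaussian bias depositions, possibly merged from walkers."""

    cv_names: list[str]
    times: np.ndarray  # (M,) ns
    centers: np.ndarray  # (M, ncv)
    sigmas: np.ndarray  # (M, ncv)
    heights: np.ndarray  # (M,) kJ/mol
    bias_factor: float
    walker_ids: np.ndarray  # (M,) int

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.sigmas = np.atleast_2d(np.asarray(self.sigmas, dtype=float))
        self.heights = np.asarray(self.heights, dtype=float)
        self.walker_ids = np.asarray(self.walker_ids, dtype=int)
        if self.n_hills and np.any(self.sigmas <= 0):
            raise ValidationError("hill widths must be positive")
        if self.n_hills and np.any(self.heights < 0):
            raise ValidationError("hill heights must be non-negative")
        if self.n_hills and np.any(np.diff(self.times) < 0):
            raise ValidationError("hill times must be non-decreasing after merge")

    @property
    def n_hills(self) -> int:
        return self.heights.size
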