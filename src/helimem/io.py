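"""Coordinate and trajectory readers/writers.

GRO/PDB/XTC handling is delegated to MDAnalysis; the plain columnar text
trajectory (time_ns, bead_id, x, y, z with a commented bead-metadata
header) is this package's own fixture format and is parsed here.
GRO coordinates are nm; PDB coordinates are Angstrom and converted to nm.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .core import InputError, Trajectory, ValidationError

__all__ = [
    "write_columnar_trajectory",
    "read_columnar_trajectory",
    "write_gro",
    "read_md_trajectory",
]

_META_COLS = ["bead_id", "group", "residue_index", "residue_name",
              "residue_class", "lipid_name", "leaflet", "role"]


def write_columnar_trajectory(traj: Trajectory, path) -> None:
    """Plain-text frames: header comments carry the box and bead metadata."""
    with open(path, "w") as fh:
        fh.write("# box " + " ".join(f"{x:.6f}" for x in traj.box) + "\n")
        fh.write("# beads " + " ".join(_META_COLS) + "\n")
        for _, row in traj.beads.iterrows():
            vals = [str(row[c]) if str(row[c]) != "" else "-" for c in _META_COLS]
            fh.write("# bead " + " ".join(vals) + "\n")
        fh.write("time_ns bead_id x y z\n")
        for f in range(traj.n_frames):
            t = traj.times[f]
            for b in range(traj.coords.shape[1]):
                x, y, z = traj.coords[f, b]
                fh.write(f"{t:.6f} {b} {x:.6f} {y:.6f} {z:.6f}\n")


def read_columnar_trajectory(path) -> Trajectory:
    box = None
    meta_rows = []
    data = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].split()
                if parts and parts[0] == "box":
                    box = np.array([float(x) for x in parts[1:4]])
                elif parts and parts[0] == "bead":
                    meta_rows.append([p if p != "-" else "" for p in parts[1:]])
                continue
            if line.startswith("time_ns"):
                continue
            t, b, x, y, z = line.split()
            data.append((float(t), int(b), float(x), float(y), float(z)))
    if box is None or not meta_rows or not data:
        raise InputError(f"{path}: incomplete columnar trajectory")
    beads = pd.DataFrame(meta_rows, columns=_META_COLS)
    beads["bead_id"] = beads["bead_id"].astype(int)
    beads["residue_index"] = beads["residue_index"].astype(int)
    arr = np.asarray(data)
    times = np.unique(arr[:, 0])
    n_beads = len(beads)
    if arr.shape[0] != times.size * n_beads:
        raise InputError(f"{path}: ragged frames")
    coords = np.empty((times.size, n_beads, 3))
    t_index = {t: i for i, t in enumerate(times)}
    for t, b, x, y, z in data:
        coords[t_index[t], int(b)] = (x, y, z)
    return Trajectory(times=times, coords=coords, box=box, beads=beads)


def write_gro(traj: Trajectory, path, frame: int = 0) -> None:
    """Write one frame as GRO via MDAnalysis (positions nm -> Angstrom)."""
    import MDAnalysis as mda

    n = traj.coords.shape[1]
    u = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n),
                           trajectory=True)
    names, resnames = [], []
    for _, row in traj.beads.iterrows():
        if row["group"] == "peptide":
            names.append("BB")
            resnames.append(str(row["residue_name"]) or "PEP")
        else:
            role = str(row["role"])
            names.append({"headgroup": "HD", "linker": "LK", "tail": "TL"}.get(role, "BD"))
            resnames.append(str(row["lipid_name"]) or "LIP")
    u.add_TopologyAttr("names", names)
    u.add_TopologyAttr("resnames", resnames)
    u.add_TopologyAttr("resids", np.arange(1, n + 1))
    u.atoms.positions = traj.coords[frame] * 10.0
    u.dimensions = [traj.box[0] * 10, traj.box[1] * 10, traj.box[2] * 10, 90, 90, 90]
    u.atoms.write(str(path))


def read_md_trajectory(topology, trajectory=None, peptide_selection: str = "name BB BAS",
                       lipid_names=("POPC", "POPE", "POPG", "CHOL", "DOPE",
                                    "DOPC", "DPSM", "DOPS", "LIP"),
                       head_names=("HD", "PO4", "NC3", "GL1", "GL2", "LK"),
                       time_unit_ps: bool = True) -> Trajectory:
    """Load GRO/PDB (+ optional XTC) via MDAnalysis into a Trajectory.

    Beads whose residue name is a known lipid species become lipid beads
    (headgroup vs tail decided by ``head_names``); everything else is
    treated as a peptide backbone bead.  MDAnalysis reports Angstrom and ps;
    values are converted to nm and ns.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(topology)) if trajectory is None else mda.Universe(
        str(topology), str(trajectory))
    resnames = u.atoms.resnames
    names = u.atoms.names
    is_lipid = np.isin(resnames, list(lipid_names))
    rows = []
    pep_count = 0
    for i in range(len(u.atoms)):
        if is_lipid[i]:
            role = "headgroup" if names[i] in head_names else "tail"
            rows.append((i, "lipid", -1, "", "", resnames[i], "", role))
        else:
            rows.append((i, "peptide", pep_count, resnames[i], "", "", "", "backbone"))
            pep_count += 1
    beads = pd.DataFrame(rows, columns=_META_COLS)
    frames, times = [], []
    for ts in u.trajectory:
        frames.append(u.atoms.positions / 10.0)
        times.append(ts.time / 1000.0 if time_unit_ps else ts.time)
    if u.dimensions is None:
        raise ValidationError("structure has no box dimensions")
    box = np.asarray(u.dimensions[:3], dtype=float) / 10.0
    return Trajectory(times=np.asarray(times), coords=np.asarray(frames),
                      box=box, beads=beads)
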