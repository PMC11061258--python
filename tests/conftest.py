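import numpy as np
import pandas as pd
import pytest

from helimem import synthetic_data as sd
from helimem.core import Trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def magainin():
    return sd.make_helix(sd.PEPTIDE_SEQUENCES["2MAG"])


@pytest.fixture
def small_bilayer():
    return sd.make_bilayer("bacterial_pe_pg", lipids_per_leaflet=36, seed=7)


def make_minimal_trajectory(times, coords, box, classes=None, lipid_names=None):
    """Hand-built trajectory: first beads peptide, remainder lipids."""
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[1]
    classes = classes or []
    n_pep = len(classes)
    lipid_names = lipid_names or [""] * (n - n_pep)
    rows = []
    for i in range(n_pep):
        rows.append((i, "peptide", i, "X", classes[i], "", "", "backbone"))
    for j, name in enumerate(lipid_names):
        rows.append((n_pep + j, "lipid", -1, "", "", name, "upper", "headgroup"))
    beads = pd.DataFrame(
        rows,
        columns=["bead_id", "group", "residue_index", "residue_name",
                 "residue_class", "lipid_name", "leaflet", "role"],
    )
    return Trajectory(times=np.asarray(times, float), coords=coords,
                      box=np.asarray(box, float), beads=beads)
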