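import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pumplipid import membrane as mem
from pumplipid import synthetic as syn

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")

#: study-condition seed for the zero-strength null bilayer
NULL_SEED = 11


@pytest.fixture(scope="session")
def null_membrane():
    """Unbiased 10:90 PS:PC bilayer at the simulated-system scale:
    524 lipids (262 per leaflet), 2000 frames, no hotspots."""
    cfg = syn.MembraneGenConfig(n_frames=2000, seed=NULL_SEED)
    traj, top, truth = syn.gen_membrane_trajectory(cfg)
    return cfg, traj, top, truth


@pytest.fixture(scope="session")
def null_profile(null_membrane):
    _, traj, top, _ = null_membrane
    return mem.contact_probabilities(traj, top)


def make_random_system(rng, n_res=10, beads_per_res=3, n_lipids=30, box=(10.0, 10.0, 8.0)):
    """A random bead system for oracle comparisons: ``n_res`` residues of
    ``beads_per_res`` beads and lipids with one headgroup + two tail beads,
    all uniformly placed in the box."""
    rows = []
    bead = 1
    for rid in range(1, n_res + 1):
        for b in range(beads_per_res):
            rows.append((bead, 1, "protein", rid, f"B{b}", "protein"))
            bead += 1
    for mol in range(2, n_lipids + 2):
        sp = "PS" if mol % 3 == 0 else "PC"
        rows.append((bead, mol, sp, 0, "HEAD", "headgroup"))
        bead += 1
        for tname in ("T1", "T2"):
            rows.append((bead, mol, sp, 0, tname, "tail"))
            bead += 1
    table = pd.DataFrame(rows, columns=mem.BeadTopology.COLUMNS)
    topology = mem.BeadTopology(table)
    coords = rng.uniform(0, 1, size=(len(table), 3)) * np.asarray(box)
    return coords, np.asarray(box, float), table, topology
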