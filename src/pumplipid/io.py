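"""Readers and writers for the package's on-disk formats.

Traces travel as CSV (time_s, fluorescence) with a JSON sidecar holding the
reagent-addition events; bead topologies as TSV; trajectories as multi-frame
GRO (one block per frame, hand-parsed because standard readers take only the
first block of a GRO file) or multi-MODEL PDB via MDAnalysis. Densities are
exported as sparse TSV plus a JSON header (2-D) or OpenDX text (3-D).
All coordinates are nanometres in memory; PDB files are Angstrom on disk.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError
from .kinetics import Trace
from .membrane import BeadTopology, DensityGrid3D, DensityMap2D, Trajectory, concatenate

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_topology_tsv",
    "read_topology_tsv",
    "write_trajectory",
    "read_trajectory",
    "write_density2d",
    "write_dx",
    "write_ground_truth",
]


# ---------------------------------------------------------------------------
# traces


def _events_path(path: Path) -> Path:
    return path.with_suffix(".events.json")


def write_trace_csv(trace: Trace, path: str | Path) -> Path:
    """CSV (time_s, fluorescence) plus a .events.json sidecar; returns the
    sidecar path."""
    path = Path(path)
    pd.DataFrame({"time_s": trace.time, "fluorescence": trace.fluorescence}).to_csv(
        path, index=False
    )
    sidecar = _events_path(path)
    sidecar.write_text(json.dumps({"t_mg": trace.t_mg, "t_cccp": trace.t_cccp}))
    return sidecar


def read_trace_csv(path: str | Path, events_path: str | Path | None = None) -> Trace:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "fluorescence"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    events_path = Path(events_path) if events_path else _events_path(path)
    try:
        events = json.loads(Path(events_path).read_text())
        t_mg, t_cccp = float(events["t_mg"]), float(events["t_cccp"])
    except (OSError, KeyError, ValueError) as exc:
        raise FormatError(f"cannot read events sidecar {events_path}: {exc}") from exc
    return Trace(
        time=df.time_s.to_numpy(),
        fluorescence=df.fluorescence.to_numpy(),
        t_mg=t_mg,
        t_cccp=t_cccp,
    )


# ---------------------------------------------------------------------------
# topology


def write_topology_tsv(topology: BeadTopology, path: str | Path) -> None:
    topology.table.to_csv(path, sep="\t", index=False)


def read_topology_tsv(path: str | Path) -> BeadTopology:
    try:
        table = pd.read_csv(path, sep="\t")
    except (OSError, pd.errors.ParserError) as exc:
        raise FormatError(f"cannot parse topology {path}: {exc}") from exc
    return BeadTopology(table)


# ---------------------------------------------------------------------------
# trajectories


def _write_gro(traj: Trajectory, topology: BeadTopology, path: Path) -> None:
    t = topology.table
    resids = (t.molecule_id % 100000).to_numpy()
    resnames = [str(m)[:5] for m in t.molecule_type]
    names = [str(n)[:5] for n in t.bead_name]
    atomids = (t.bead_id % 100000).to_numpy()
    with open(path, "w") as fh:
        for f in range(traj.n_frames):
            fh.write(f"synthetic bilayer, frame {f}\n{traj.n_beads:5d}\n")
            c = traj.coords[f]
            for i in range(traj.n_beads):
                fh.write(
                    f"{resids[i]:5d}{resnames[i]:<5s}{names[i]:>5s}{atomids[i]:5d}"
                    f"{c[i, 0]:8.3f}{c[i, 1]:8.3f}{c[i, 2]:8.3f}\n"
                )
            fh.write(f"{traj.box[0]:10.5f}{traj.box[1]:10.5f}{traj.box[2]:10.5f}\n")


def _read_gro(path: Path, n_expected: int | None) -> tuple[np.ndarray, np.ndarray]:
    frames, box = [], None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i, frame_index = 0, 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i + 1])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: bad atom count at frame {frame_index}") from exc
        if n_expected is not None and natoms != n_expected:
            raise FormatError(
                f"{path}: frame {frame_index} has {natoms} beads, topology has {n_expected}"
            )
        try:
            coords = np.array(
                [
                    [float(l[20:28]), float(l[28:36]), float(l[36:44])]
                    for l in lines[i + 2 : i + 2 + natoms]
                ]
            )
            box = np.array([float(v) for v in lines[i + 2 + natoms].split()[:3]])
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}: truncated frame {frame_index}") from exc
        frames.append(coords)
        i += natoms + 3
        frame_index += 1
    if not frames:
        raise FormatError(f"{path}: no frames found")
    return np.stack(frames), box


def _mda_universe(traj: Trajectory, topology: BeadTopology):
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    t = topology.table
    mol_ids = t.molecule_id.to_numpy()
    _, resindex = np.unique(mol_ids, return_inverse=True)
    n_res = resindex.max() + 1
    u = mda.Universe.empty(
        n_atoms=len(t),
        n_residues=n_res,
        atom_resindex=resindex,
        residue_segindex=np.zeros(n_res, dtype=int),
        trajectory=False,
    )
    u.add_TopologyAttr("names", [str(n)[:4] for n in t.bead_name])
    first = np.unique(resindex, return_index=True)[1]
    u.add_TopologyAttr("resnames", [str(m)[:4] for m in t.molecule_type.iloc[first]])
    u.add_TopologyAttr("resids", np.unique(mol_ids))
    dims = np.tile(np.concatenate([traj.box * 10.0, [90.0, 90.0, 90.0]]), (traj.n_frames, 1))
    u.load_new(traj.coords * 10.0, format=MemoryReader, dimensions=dims)
    return u


def _write_pdb(traj: Trajectory, topology: BeadTopology, path: Path) -> None:
    import warnings

    import MDAnalysis as mda

    u = _mda_universe(traj, topology)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDBWriter default-attribute chatter
        with mda.Writer(str(path), n_atoms=traj.n_beads, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def _read_pdb(path: Path, n_expected: int | None) -> tuple[np.ndarray, np.ndarray]:
    import warnings

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            u = mda.Universe(str(path))
        except Exception as exc:  # MDAnalysis raises a zoo of types here
            raise FormatError(f"cannot parse {path}: {exc}") from exc
        if n_expected is not None and len(u.atoms) != n_expected:
            raise FormatError(
                f"{path}: file has {len(u.atoms)} beads, topology has {n_expected}"
            )
        coords = np.stack([u.atoms.positions / 10.0 for _ in u.trajectory])
    # the multi-MODEL reader only picks up CRYST1 records inside MODEL blocks;
    # read the header record directly
    box = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("CRYST1"):
                box = np.array([float(line[6:15]), float(line[15:24]), float(line[24:33])])
                break
    if box is None:
        raise FormatError(f"{path}: no CRYST1 box record")
    return coords, box / 10.0


def write_trajectory(traj: Trajectory, topology: BeadTopology, path: str | Path) -> None:
    """Write a trajectory as multi-frame GRO (.gro) or multi-MODEL PDB (.pdb)."""
    path = Path(path)
    if path.suffix == ".gro":
        _write_gro(traj, topology, path)
    elif path.suffix == ".pdb":
        _write_pdb(traj, topology, path)
    else:
        raise FormatError(f"unsupported trajectory format {path.suffix!r}")


def read_trajectory(
    paths: str | Path | Sequence[str | Path], topology_path: str | Path
) -> tuple[Trajectory, BeadTopology]:
    """Read one or more replica files (concatenated in order) plus topology."""
    if isinstance(paths, (str, Path)):
        paths = [paths]
    topology = read_topology_tsv(topology_path)
    parts = []
    for p in paths:
        p = Path(p)
        if p.suffix == ".gro":
            coords, box = _read_gro(p, topology.n_beads)
        elif p.suffix == ".pdb":
            coords, box = _read_pdb(p, topology.n_beads)
        else:
            raise FormatError(f"unsupported trajectory format {p.suffix!r}")
        parts.append(Trajectory(coords, box))
    return concatenate(parts), topology


# ---------------------------------------------------------------------------
# densities and ground truth


def write_density2d(map2d: DensityMap2D, path: str | Path) -> Path:
    """Sparse TSV (i, j, value) of nonzero cells plus a JSON header sidecar."""
    path = Path(path)
    xi, yi = np.nonzero(map2d.values)
    pd.DataFrame({"i": xi, "j": yi, "value": map2d.values[xi, yi]}).to_csv(
        path, sep="\t", index=False
    )
    header = {
        "origin": list(map2d.origin),
        "spacing": map2d.spacing,
        "shape": list(map2d.values.shape),
        "leaflet": map2d.leaflet,
        "species": map2d.species,
        "kind": map2d.kind,
        "n_frames": map2d.n_frames,
        "box": map2d.box.tolist(),
    }
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(header, indent=1))
    return sidecar


def write_dx(grid: DensityGrid3D, path: str | Path) -> None:
    """OpenDX-style text export of a 3-D density grid (values in nm^-3)."""
    nx, ny, nz = grid.values.shape
    h = grid.spacing
    with open(path, "w") as fh:
        fh.write(f"# {grid.species} {grid.beads}-bead density, nm^-3; ")
        fh.write(f"suggested isovalue {grid.default_isovalue} nm^-3\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6f} {:.6f} {:.6f}\n".format(*grid.origin))
        fh.write(f"delta {h:.6f} 0 0\ndelta 0 {h:.6f} 0\ndelta 0 0 {h:.6f}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {grid.values.size} data follows\n"
        )
        flat = grid.values.ravel(order="C")
        for i in range(0, flat.size, 3):
            fh.write(" ".join(f"{v:.6g}" for v in flat[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')


def write_ground_truth(truth, path: str | Path) -> None:
    Path(path).write_text(json.dumps(truth.to_json_dict(), indent=1))
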