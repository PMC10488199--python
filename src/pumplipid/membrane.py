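"""Lipid-protein contact and density analysis for coarse-grained bilayers.

The central statistic is the per-residue, per-species lipid contact
probability under a nearest-lipid exclusivity rule: in each frame a protein
residue is in contact with at most one lipid - the lipid whose headgroup
bead comes closest to any bead of the residue - and only if that minimal
distance is within the cutoff (default 0.55 nm). No other lipid being
closer means a nearer neutral lipid blocks a contact with an anionic one.
Probabilities are contact frames divided by total frames, computed after
concatenating replicas.

Distances use the minimum-image convention in x and y only (the membrane
plane is periodic; z is not). Contacts are evaluated in the raw frames;
densities are computed after rigid-body superposition of the protein onto
the first frame, so that time-averaged lipid densities are resolved in the
protein-fixed frame:

* 2-D leaflet- and species-resolved headgroup number densities (nm^-2) on a
  regular grid, and their enrichment relative to the uniform expectation
  given the leaflet composition (1 = no preference),
* 3-D bead number densities (nm^-3) on a voxel grid, exportable as OpenDX
  text with the conventional isovalues (3 nm^-3 for headgroup-only grids,
  4 nm^-3 for all-bead grids),
* site calling: smoothed local maxima of the enrichment map above a
  threshold, merged within a radius, labelled A, B, C, ... by descending
  peak enrichment, with the contact residues (probability >= 5%) captured
  within a radius of each centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, maximum_filter

from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateDataError,
    FormatError,
    SelectionError,
)

__all__ = [
    "BeadTopology",
    "Trajectory",
    "ContactProfile",
    "DensityMap2D",
    "DensityGrid3D",
    "LipidSite",
    "kabsch",
    "align_frames",
    "assign_leaflets",
    "detect_contacts",
    "contact_probabilities",
    "density_map_2d",
    "enrichment_map",
    "density_grid_3d",
    "find_sites",
    "residue_positions",
    "concatenate",
    "CONTACT_CUTOFF_NM",
    "LABEL_THRESHOLD",
    "HIGHLIGHT_THRESHOLD",
    "ISOVALUE_HEADGROUP",
    "ISOVALUE_ALL_BEADS",
]

CONTACT_CUTOFF_NM = 0.55
#: residues above this contact probability are labelled in reports
LABEL_THRESHOLD = 0.15
#: residues at or above this probability are highlighted / attached to sites
HIGHLIGHT_THRESHOLD = 0.05
ISOVALUE_HEADGROUP = 3.0  # nm^-3, headgroup-bead density isosurface
ISOVALUE_ALL_BEADS = 4.0  # nm^-3, all-bead density isosurface

ROLES = ("protein", "headgroup", "tail")


class BeadTopology:
    """Per-bead metadata: molecule, species, residue and role.

    Wraps a DataFrame with columns bead_id, molecule_id, molecule_type
    (``protein`` or a lipid species name), residue_id (1-based for protein
    beads, 0 otherwise), bead_name and role in {protein, headgroup, tail}.
    Index arrays used by the contact/density engines are precomputed once.
    """

    COLUMNS = ["bead_id", "molecule_id", "molecule_type", "residue_id", "bead_name", "role"]

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"topology missing columns {missing}")
        table = table.reset_index(drop=True)
        bad_roles = set(table.role) - set(ROLES)
        if bad_roles:
            raise FormatError(f"unknown bead roles {sorted(bad_roles)}")
        lipid_rows = table[table.molecule_type != "protein"]
        heads = lipid_rows[lipid_rows.role == "headgroup"]
        headless = set(lipid_rows.molecule_id) - set(heads.molecule_id)
        if headless:
            raise FormatError(
                f"lipid molecules without a headgroup bead: {sorted(headless)[:5]}"
            )
        prot = table[table.molecule_type == "protein"]
        if len(prot):
            resids = np.sort(prot.residue_id.unique())
            if resids[0] != 1 or not np.array_equal(resids, np.arange(1, len(resids) + 1)):
                raise FormatError("protein residue_ids must be contiguous and 1-based")
        self.table = table
        self._build_indices()

    def _build_indices(self):
        t = self.table
        self.n_beads = len(t)
        prot = t.role == "protein"
        self.protein_idx = np.flatnonzero(prot.to_numpy())
        self.residue_ids = np.sort(t.residue_id[prot].unique()).astype(int)
        rid_of_bead = t.residue_id.to_numpy()[self.protein_idx]
        res_index = np.searchsorted(self.residue_ids, rid_of_bead)
        # group same-residue beads contiguously so the distance matrix can be
        # segment-reduced with np.minimum.reduceat
        order = np.argsort(res_index, kind="stable")
        self.protein_idx = self.protein_idx[order]
        self._res_index_of_protein_bead = res_index[order]
        self._res_starts = np.searchsorted(
            self._res_index_of_protein_bead, np.arange(len(self.residue_ids))
        )

        head = (t.role == "headgroup").to_numpy()
        self.head_idx = np.flatnonzero(head)
        # lipids ordered by ascending molecule_id so argmin tie-breaks to the
        # lowest id deterministically
        lip = t[t.molecule_type != "protein"]
        self.lipid_ids = np.sort(lip.molecule_id.unique()).astype(int)
        mol_of_head = t.molecule_id.to_numpy()[self.head_idx]
        order = np.argsort(mol_of_head, kind="stable")
        self.head_idx = self.head_idx[order]
        self._lip_index_of_head_bead = np.searchsorted(self.lipid_ids, mol_of_head[order])
        self._lip_starts = np.searchsorted(
            self._lip_index_of_head_bead, np.arange(len(self.lipid_ids))
        )
        species_map = dict(zip(lip.molecule_id, lip.molecule_type))
        self.lipid_species = np.array([species_map[m] for m in self.lipid_ids])
        self.species = tuple(sorted(set(self.lipid_species)))

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def n_lipids(self) -> int:
        return len(self.lipid_ids)

    def lipid_bead_indices(self, species: str, beads: str = "all") -> np.ndarray:
        t = self.table
        sel = (t.molecule_type == species).to_numpy()
        if beads == "headgroup":
            sel &= (t.role == "headgroup").to_numpy()
        elif beads != "all":
            raise SelectionError(f"beads must be 'all' or 'headgroup', got {beads!r}")
        idx = np.flatnonzero(sel)
        if idx.size == 0:
            raise SelectionError(f"no beads match species={species!r}, beads={beads!r}")
        return idx


@dataclass
class Trajectory:
    """Frames of bead coordinates (nm) in a constant orthorhombic box."""

    coords: np.ndarray  # (T, N, 3)
    box: np.ndarray  # (3,)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise FormatError("coords must have shape (T, N, 3)")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise FormatError("box must be three positive lengths")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]


def concatenate(trajs: Sequence[Trajectory]) -> Trajectory:
    """Concatenate replica trajectories (shared topology and box) in time."""
    if not trajs:
        raise ConfigurationError("nothing to concatenate")
    box = trajs[0].box
    for tr in trajs[1:]:
        if tr.coords.shape[1] != trajs[0].coords.shape[1] or not np.allclose(tr.box, box):
            raise FormatError("replicas must share bead count and box")
    return Trajectory(np.concatenate([t.coords for t in trajs], axis=0), box.copy())


@dataclass(frozen=True)
class ContactProfile:
    """Per-(residue, species) contact counts and probabilities."""

    residue_ids: np.ndarray
    species: tuple[str, ...]
    counts: np.ndarray  # (n_residues, n_species) frames-with-contact
    n_frames: int

    @property
    def probabilities(self) -> np.ndarray:
        return self.counts / self.n_frames

    def probability(self, residue_id: int, species: str) -> float:
        i = int(np.searchsorted(self.residue_ids, residue_id))
        if i >= len(self.residue_ids) or self.residue_ids[i] != residue_id:
            raise KeyError(f"residue {residue_id} not in profile")
        return float(self.probabilities[i, self.species.index(species)])

    def to_frame(self) -> pd.DataFrame:
        probs = self.probabilities
        rows = []
        for i, rid in enumerate(self.residue_ids):
            for j, sp in enumerate(self.species):
                rows.append(
                    {
                        "residue_id": int(rid),
                        "species": sp,
                        "count": int(self.counts[i, j]),
                        "probability": probs[i, j],
                        "labelled": probs[i, j] > LABEL_THRESHOLD,
                        "highlighted": probs[i, j] >= HIGHLIGHT_THRESHOLD,
                    }
                )
        return pd.DataFrame(rows)


@dataclass
class DensityMap2D:
    """Leaflet- and species-resolved 2-D map on a regular xy grid.

    ``values`` are time-averaged headgroup number densities (nm^-2), or
    dimensionless enrichment when ``kind == 'enrichment'``.
    """

    values: np.ndarray
    spacing: float
    origin: tuple[float, float]
    leaflet: str
    species: str
    n_frames: int
    box: np.ndarray
    kind: str = "density"

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nx, ny = self.values.shape
        x = self.origin[0] + (np.arange(nx) + 0.5) * self.spacing
        y = self.origin[1] + (np.arange(ny) + 0.5) * self.spacing
        return x, y

    @property
    def mean_count(self) -> float:
        """Sum(values) * cell_area: the mean per-frame molecule count."""
        return float(self.values.sum() * self.spacing**2)


@dataclass
class DensityGrid3D:
    """Bead number density (nm^-3) on a voxel grid; ``beads`` records the
    selection ('all' or 'headgroup')."""

    values: np.ndarray
    spacing: float
    origin: tuple[float, float, float]
    species: str
    beads: str
    n_frames: int
    box: np.ndarray

    @property
    def mean_count(self) -> float:
        return float(self.values.sum() * self.spacing**3)

    @property
    def default_isovalue(self) -> float:
        return ISOVALUE_HEADGROUP if self.beads == "headgroup" else ISOVALUE_ALL_BEADS


@dataclass(frozen=True)
class LipidSite:
    """A labelled local maximum of the enrichment map with its residues."""

    label: str
    leaflet: str
    species: str
    centroid: tuple[float, float]
    peak_enrichment: float
    residues: tuple[int, ...]
    residue_probabilities: tuple[float, ...]


# ---------------------------------------------------------------------------
# geometry


def _min_image_xy(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention in x and y only (z unwrapped)."""
    d = d.copy()
    for ax in (0, 1):
        L = box[ax]
        d[..., ax] -= L * np.round(d[..., ax] / L)
    return d


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rotation R and translation t mapping mobile onto target.

    Returns (R, t) with target ~ mobile @ R.T + t. Proper rotation enforced.
    """
    if len(mobile) < 3:
        raise AlignmentError(f"need >= 3 beads for superposition, got {len(mobile)}")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    P, Q = mobile - cm, target - ct
    if np.linalg.matrix_rank(P, tol=1e-12) < 2:
        raise AlignmentError("superposition beads are collinear")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, ct - cm @ R.T


def align_frames(traj: Trajectory, topology: BeadTopology) -> Trajectory:
    """Superpose every frame's protein beads onto frame 0 (rigid body);
    the same transform is applied to all beads of the frame."""
    pidx = topology.protein_idx
    if pidx.size == 0:
        raise AlignmentError("no protein beads to align on")
    ref = traj.coords[0, pidx]
    out = traj.coords.copy()
    for t in range(traj.n_frames):
        R, tvec = kabsch(traj.coords[t, pidx], ref)
        out[t] = traj.coords[t] @ R.T + tvec
    return Trajectory(out, traj.box.copy())


def assign_leaflets(
    frame_coords: np.ndarray, topology: BeadTopology
) -> dict[int, str]:
    """Assign each lipid to the upper or lower leaflet.

    The midplane is the mean z of all lipid headgroup beads in the frame;
    a lipid is upper iff the mean z of its headgroup beads exceeds it
    (ties go to lower).
    """
    z_heads = frame_coords[topology.head_idx, 2]
    lip_of_head = topology._lip_index_of_head_bead
    sums = np.zeros(topology.n_lipids)
    counts = np.zeros(topology.n_lipids)
    np.add.at(sums, lip_of_head, z_heads)
    np.add.at(counts, lip_of_head, 1)
    mean_z = sums / counts
    midplane = z_heads.mean()
    return {
        int(mid): ("upper" if mz > midplane else "lower")
        for mid, mz in zip(topology.lipid_ids, mean_z)
    }


def _residue_lipid_min_d2(
    frame_coords: np.ndarray, box: np.ndarray, topology: BeadTopology
) -> np.ndarray:
    """(n_residues, n_lipids) matrix of squared minimal residue-bead to
    headgroup-bead distances (minimum image in xy)."""
    p = frame_coords[topology.protein_idx]
    h = frame_coords[topology.head_idx]
    d = p[:, None, :] - h[None, :, :]
    d = _min_image_xy(d, box)
    d2 = np.einsum("ijk,ijk->ij", d, d)
    # beads are pre-sorted so residues / lipids occupy contiguous row / column
    # segments; reduce each segment to its minimum
    d2 = np.minimum.reduceat(d2, topology._res_starts, axis=0)
    return np.minimum.reduceat(d2, topology._lip_starts, axis=1)


def detect_contacts(
    frame_coords: np.ndarray,
    box: np.ndarray,
    topology: BeadTopology,
    cutoff: float = CONTACT_CUTOFF_NM,
) -> dict[int, int]:
    """Contacts of one frame as {residue_id: lipid molecule_id}.

    For each residue the candidate is the lipid with the smallest
    headgroup-to-residue bead distance; it is a contact only if that
    distance is within ``cutoff``. At most one lipid per residue (the
    exclusivity rule); equal distances tie-break to the lowest lipid id.
    """
    d2 = _residue_lipid_min_d2(frame_coords, box, topology)
    best = np.argmin(d2, axis=1)  # first minimum = lowest lipid id
    best_d2 = d2[np.arange(len(best)), best]
    hit = best_d2 <= cutoff**2
    return {
        int(topology.residue_ids[r]): int(topology.lipid_ids[best[r]])
        for r in np.flatnonzero(hit)
    }


def contact_probabilities(
    traj: Trajectory,
    topology: BeadTopology,
    cutoff: float = CONTACT_CUTOFF_NM,
) -> ContactProfile:
    """Fraction of frames in which each residue contacts each lipid species.

    Replicas should be concatenated (``concatenate``) before calling so the
    normalization runs once over all frames.
    """
    species = topology.species
    sp_index = {sp: j for j, sp in enumerate(species)}
    sp_of_lipid = np.array([sp_index[s] for s in topology.lipid_species])
    counts = np.zeros((topology.n_residues, len(species)), dtype=int)
    cutoff2 = cutoff**2
    for t in range(traj.n_frames):
        d2 = _residue_lipid_min_d2(traj.coords[t], traj.box, topology)
        best = np.argmin(d2, axis=1)
        hit = d2[np.arange(len(best)), best] <= cutoff2
        np.add.at(counts, (np.flatnonzero(hit), sp_of_lipid[best[hit]]), 1)
    return ContactProfile(
        residue_ids=topology.residue_ids.copy(),
        species=species,
        counts=counts,
        n_frames=traj.n_frames,
    )


# ---------------------------------------------------------------------------
# densities


def _grid_edges(L: float, spacing: float) -> np.ndarray:
    n = int(np.ceil(L / spacing - 1e-9))
    return np.arange(n + 1) * spacing


def density_map_2d(
    traj: Trajectory,
    topology: BeadTopology,
    species: str,
    leaflet: str,
    spacing: float = 0.02,
) -> DensityMap2D:
    """Time-averaged 2-D headgroup number density (nm^-2) of one species in
    one leaflet, on cells [i*h, (i+1)*h) anchored at the box corner.

    Each lipid contributes the xy centroid of its headgroup beads, wrapped
    into the box; leaflets are reassigned per frame.
    """
    if spacing <= 0:
        raise ConfigurationError("grid spacing must be positive")
    if leaflet not in ("upper", "lower"):
        raise ConfigurationError(f"leaflet must be 'upper' or 'lower', got {leaflet!r}")
    if species not in topology.species:
        raise SelectionError(f"species {species!r} not in topology")
    xedges = _grid_edges(traj.box[0], spacing)
    yedges = _grid_edges(traj.box[1], spacing)
    hist = np.zeros((len(xedges) - 1, len(yedges) - 1))

    lip_of_head = topology._lip_index_of_head_bead
    sp_mask_lipid = topology.lipid_species == species
    n_lip = topology.n_lipids
    for t in range(traj.n_frames):
        coords = traj.coords[t]
        leaflets = assign_leaflets(coords, topology)
        in_leaflet = np.array([leaflets[int(m)] == leaflet for m in topology.lipid_ids])
        wanted = sp_mask_lipid & in_leaflet
        heads = coords[topology.head_idx]
        sums = np.zeros((n_lip, 2))
        cnts = np.zeros(n_lip)
        np.add.at(sums, lip_of_head, heads[:, :2])
        np.add.at(cnts, lip_of_head, 1)
        centroids = sums[wanted] / cnts[wanted, None]
        centroids = np.mod(centroids, traj.box[:2])
        h, _, _ = np.histogram2d(centroids[:, 0], centroids[:, 1], bins=(xedges, yedges))
        hist += h
    values = hist / (traj.n_frames * spacing**2)
    return DensityMap2D(
        values=values,
        spacing=spacing,
        origin=(0.0, 0.0),
        leaflet=leaflet,
        species=species,
        n_frames=traj.n_frames,
        box=traj.box.copy(),
    )


def enrichment_map(
    map2d: DensityMap2D,
    leaflet_counts: Mapping[str, Mapping[str, int]] | Mapping[str, int],
    composition: Mapping[str, float] | None = None,
) -> DensityMap2D:
    """Divide a density map by the uniform expectation N_species/(Lx*Ly).

    ``leaflet_counts`` is either {leaflet: {species: count}} or directly
    {species: count} for the map's leaflet; ``composition`` is an optional
    fallback (molar fractions applied to half the total lipid count is not
    attempted - counts are required to be explicit).
    """
    counts = leaflet_counts
    if map2d.leaflet in counts:  # nested form
        counts = counts[map2d.leaflet]
    n = counts.get(map2d.species, 0)
    if n <= 0:
        raise DegenerateDataError(
            f"no {map2d.species} lipids expected in the {map2d.leaflet} leaflet"
        )
    expected = n / (map2d.box[0] * map2d.box[1])
    return replace(map2d, values=map2d.values / expected, kind="enrichment")


def density_grid_3d(
    traj: Trajectory,
    topology: BeadTopology,
    species: str,
    beads: str = "headgroup",
    spacing: float = 0.1,
) -> DensityGrid3D:
    """Time-averaged 3-D bead number density (nm^-3) for one lipid species,
    counting either all its beads or only headgroup beads."""
    if spacing <= 0:
        raise ConfigurationError("voxel spacing must be positive")
    idx = topology.lipid_bead_indices(species, beads)
    edges = [_grid_edges(traj.box[ax], spacing) for ax in range(3)]
    shape = tuple(len(e) - 1 for e in edges)
    hist = np.zeros(shape)
    for t in range(traj.n_frames):
        pts = np.mod(traj.coords[t, idx], traj.box)
        h, _ = np.histogramdd(pts, bins=edges)
        hist += h
    return DensityGrid3D(
        values=hist / (traj.n_frames * spacing**3),
        spacing=spacing,
        origin=(0.0, 0.0, 0.0),
        species=species,
        beads=beads,
        n_frames=traj.n_frames,
        box=traj.box.copy(),
    )


# ---------------------------------------------------------------------------
# site calling


def residue_positions(traj: Trajectory, topology: BeadTopology) -> dict[int, np.ndarray]:
    """Time-mean bead position per protein residue (use an aligned trajectory)."""
    mean_coords = traj.coords[:, topology.protein_idx, :].mean(axis=0)
    out: dict[int, np.ndarray] = {}
    for i, rid in enumerate(topology.residue_ids):
        out[int(rid)] = mean_coords[topology._res_index_of_protein_bead == i].mean(axis=0)
    return out


def _periodic_dist_xy(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> float:
    d = np.asarray(a[:2]) - np.asarray(b[:2])
    d -= box[:2] * np.round(d / box[:2])
    return float(np.hypot(*d))


def find_sites(
    enrichment: DensityMap2D,
    profile: ContactProfile,
    residue_xy: Mapping[int, np.ndarray],
    min_enrichment: float = 2.0,
    merge_radius: float = 1.0,
    capture_radius: float = 1.0,
    prob_threshold: float = HIGHLIGHT_THRESHOLD,
    smooth_sigma_cells: float = 2.0,
) -> list[LipidSite]:
    """Call lipid interaction sites from an enrichment map.

    The map is smoothed with a periodic Gaussian (sigma in cells), local
    maxima above ``min_enrichment`` are found, maxima within
    ``merge_radius`` of a stronger one are merged into it, and residues of
    the matching species with contact probability >= ``prob_threshold``
    whose mean position lies within ``capture_radius`` of the centroid are
    attached. Sites are labelled A, B, ... by descending peak enrichment.
    """
    if enrichment.kind != "enrichment":
        raise ConfigurationError("find_sites expects an enrichment map")
    smooth = gaussian_filter(enrichment.values, sigma=smooth_sigma_cells, mode="wrap")
    local_max = (smooth == maximum_filter(smooth, size=3, mode="wrap")) & (
        smooth > min_enrichment
    )
    xi, yi = np.nonzero(local_max)
    if xi.size == 0:
        return []
    h = enrichment.spacing
    peaks = np.column_stack(
        [enrichment.origin[0] + (xi + 0.5) * h, enrichment.origin[1] + (yi + 0.5) * h]
    )
    vals = smooth[xi, yi]
    order = np.argsort(-vals)
    kept: list[tuple[np.ndarray, float]] = []
    for i in order:
        if all(
            _periodic_dist_xy(peaks[i], c, enrichment.box) > merge_radius for c, _ in kept
        ):
            kept.append((peaks[i], float(vals[i])))

    sp_col = profile.species.index(enrichment.species)
    probs = profile.probabilities[:, sp_col]
    sites = []
    for label_idx, (center, peak) in enumerate(kept):
        members = [
            (int(rid), float(probs[i]))
            for i, rid in enumerate(profile.residue_ids)
            if probs[i] >= prob_threshold
            and int(rid) in residue_xy
            and _periodic_dist_xy(residue_xy[int(rid)], center, enrichment.box)
            <= capture_radius
        ]
        members.sort(key=lambda rp: -rp[1])
        sites.append(
            LipidSite(
                label=chr(ord("A") + label_idx),
                leaflet=enrichment.leaflet,
                species=enrichment.species,
                centroid=(float(center[0]), float(center[1])),
                peak_enrichment=peak,
                residues=tuple(r for r, _ in members),
                residue_probabilities=tuple(p for _, p in members),
            )
        )
    return sites
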