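"""Synthetic data with known ground truth for every downstream stage.

Three generators emulate the three experimental inputs of the analysis:

* ACMA quench/recovery fluorescence traces with a configurable true initial
  pumping rate: F(t) = plateau + (1-plateau)*exp(-k (t - t_mg)) with
  k = rate/(1-plateau), so the instantaneous slope at Mg2+ addition is
  exactly -rate; after CCCP the signal relaxes exponentially back to a
  recovery level.
* Boltzmann-shaped detergent-solubilization scattering series.
* Coarse-grained bilayer trajectories around a static helix-circle protein
  scaffold: lipids perform per-leaflet 2-D Brownian steps with periodic
  wrapping in x and y, headgroups sit at the leaflet z-levels (+-2 nm from
  the midplane) with three tail beads evenly spaced toward the midplane.
  Optional "hotspots" plant high-affinity loci: lipids of the hotspot
  species that are inside the hotspot radius accept distance-increasing
  steps only with probability 1/(1+strength) (Metropolis-style rejection),
  so strength 0 is exactly unbiased and retention grows with strength.

All generators are bitwise deterministic for a fixed config and seed; the
random streams are per-molecule columns of arrays drawn once from the root
generator, so changing a hotspot strength re-uses the identical proposal
and acceptance streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .kinetics import SolubilizationSeries, Trace, boltzmann
from .membrane import BeadTopology, Trajectory

__all__ = [
    "TraceGenConfig",
    "ProteinLayout",
    "HotspotSpec",
    "MembraneGenConfig",
    "GroundTruth",
    "gen_acma_trace",
    "gen_solubilization_series",
    "gen_membrane_trajectory",
    "largest_remainder",
    "helix_interface_residues",
    "HEAD_OFFSET_NM",
    "TAIL_OFFSETS_NM",
]

#: headgroup z-level relative to the bilayer midplane
HEAD_OFFSET_NM = 2.0
#: three tail beads evenly spaced toward the midplane
TAIL_OFFSETS_NM = (1.5, 1.0, 0.5)


# ---------------------------------------------------------------------------
# fluorescence traces


@dataclass(frozen=True)
class TraceGenConfig:
    """Conditions of one simulated ACMA proton-pumping assay.

    ``rate`` is the true initial quench rate of the normalized fluorescence
    (fraction/s); ``plateau`` the quench floor; ``recovery`` the level the
    signal returns to after CCCP. Defaults mimic a slow reference (pure-PC)
    proteoliposome recorded for ~1000 s at 0.1 s resolution, with the 30 s
    rate window well inside the near-linear regime.
    """

    t_mg: float = 60.0
    t_cccp: float = 900.0
    t_end: float = 1000.0
    dt: float = 0.1
    rate: float = 5.0e-4
    plateau: float = 0.25
    recovery: float = 0.95
    noise_sd: float = 0.004
    seed: int = 0
    k_recovery: float = 0.05  # s^-1, post-CCCP relaxation rate

    def validate(self) -> None:
        if not (0 < self.t_mg < self.t_cccp < self.t_end):
            raise ConfigurationError(
                "event times must satisfy 0 < t_mg < t_cccp < t_end "
                f"(got {self.t_mg}, {self.t_cccp}, {self.t_end})"
            )
        if self.dt <= 0:
            raise ConfigurationError("dt must be positive")
        if not (0 <= self.plateau <= 1):
            raise ConfigurationError("plateau must be in [0, 1]")
        if self.rate < 0:
            raise ConfigurationError("rate must be >= 0")
        if self.rate > 0 and self.plateau >= 1:
            raise ConfigurationError("plateau must be < 1 when rate > 0")


def quench_curve(t: np.ndarray, cfg: TraceGenConfig) -> np.ndarray:
    """Noiseless closed-form trace for the given config."""
    f = np.ones_like(t)
    k = cfg.rate / (1.0 - cfg.plateau) if cfg.rate > 0 else 0.0
    pumping = (t >= cfg.t_mg) & (t < cfg.t_cccp)
    f[pumping] = cfg.plateau + (1.0 - cfg.plateau) * np.exp(-k * (t[pumping] - cfg.t_mg))
    f_cccp = cfg.plateau + (1.0 - cfg.plateau) * math.exp(-k * (cfg.t_cccp - cfg.t_mg))
    after = t >= cfg.t_cccp
    f[after] = cfg.recovery + (f_cccp - cfg.recovery) * np.exp(
        -cfg.k_recovery * (t[after] - cfg.t_cccp)
    )
    return f


def gen_acma_trace(cfg: TraceGenConfig) -> Trace:
    """Simulate one ACMA trace (normalized units, Gaussian noise added)."""
    cfg.validate()
    t = np.arange(0.0, cfg.t_end + cfg.dt / 2, cfg.dt)
    f = quench_curve(t, cfg)
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        f = f + rng.normal(0.0, cfg.noise_sd, size=f.shape)
    return Trace(time=t, fluorescence=f, t_mg=cfg.t_mg, t_cccp=cfg.t_cccp)


# ---------------------------------------------------------------------------
# solubilization series


def gen_solubilization_series(
    top: float,
    bottom: float,
    v50: float,
    slope: float,
    x_grid: Sequence[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SolubilizationSeries:
    """Scattering-vs-detergent series on the Boltzmann sigmoid plus noise."""
    if slope == 0:
        raise ConfigurationError("slope must be nonzero")
    x = np.asarray(x_grid, dtype=float)
    if x.ndim != 1 or len(x) < 5 or np.any(np.diff(x) <= 0):
        raise ConfigurationError("x_grid must be strictly increasing with >= 5 points")
    y = boltzmann(x, top, bottom, v50, slope)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return SolubilizationSeries(x=x, y=y)


# ---------------------------------------------------------------------------
# membrane trajectories


@dataclass(frozen=True)
class ProteinLayout:
    """Static scaffold: ``n_helices`` vertical bead columns on a circle of
    ``radius`` nm around the box centre, spanning the bilayer."""

    n_helices: int = 10
    n_res_per_helix: int = 15
    beads_per_residue: int = 1
    radius: float = 2.3
    z_span: float = 2.1  # residues from -z_span to +z_span about the midplane

    @property
    def n_residues(self) -> int:
        return self.n_helices * self.n_res_per_helix


@dataclass(frozen=True)
class HotspotSpec:
    """A planted high-affinity locus for one lipid species.

    ``residue_ids`` define the locus (their mean xy is the centre, the sign
    of their mean z picks the leaflet); ``strength`` >= 0 sets the rejection
    bias (0 = no bias); ``radius`` is the capture radius in nm.
    """

    residue_ids: tuple[int, ...]
    species: str
    strength: float
    radius: float = 0.7

    def validate(self, layout: ProteinLayout) -> None:
        if self.strength < 0:
            raise ConfigurationError("hotspot strength must be >= 0")
        if self.radius <= 0:
            raise ConfigurationError("hotspot radius must be positive")
        bad = [r for r in self.residue_ids if not (1 <= r <= layout.n_residues)]
        if bad:
            raise ConfigurationError(f"hotspot residues not in the protein: {bad}")


@dataclass(frozen=True)
class MembraneGenConfig:
    """Bilayer geometry, composition and dynamics of the generator.

    Defaults follow the simulated study systems: 524 lipids distributed
    symmetrically in both leaflets, PS:PC at a 10:90 molar ratio.
    ``diffusion_step`` is the per-frame, per-axis Gaussian step s.d. (nm).
    """

    box: tuple[float, float, float] = (13.0, 13.0, 10.0)
    n_lipids_total: int = 524
    composition: Mapping[str, float] = field(
        default_factory=lambda: {"PS": 0.10, "PC": 0.90}
    )
    hotspots: tuple[HotspotSpec, ...] = ()
    n_frames: int = 1000
    diffusion_step: float = 0.4
    seed: int = 0
    protein: ProteinLayout = field(default_factory=ProteinLayout)

    def validate(self) -> None:
        if any(b <= 0 for b in self.box):
            raise ConfigurationError("box lengths must be positive")
        if self.n_lipids_total <= 0 or self.n_lipids_total % 2:
            raise ConfigurationError("n_lipids_total must be positive and even")
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ConfigurationError("composition fractions must sum to 1")
        if any(f < 0 for f in self.composition.values()):
            raise ConfigurationError("composition fractions must be >= 0")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        if self.diffusion_step < 0:
            raise ConfigurationError("diffusion_step must be >= 0")
        for h in self.hotspots:
            h.validate(self.protein)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually emitted, for recovery tests."""

    hotspot_residues: dict[str, tuple[int, ...]]
    leaflet_counts: dict[str, dict[str, int]]
    lipid_leaflets: dict[int, str]

    def to_json_dict(self) -> dict:
        return {
            "hotspot_residues": {k: list(v) for k, v in self.hotspot_residues.items()},
            "leaflet_counts": self.leaflet_counts,
            "lipid_leaflets": {str(k): v for k, v in self.lipid_leaflets.items()},
        }


def largest_remainder(fractions: Mapping[str, float], total: int) -> dict[str, int]:
    """Integer apportionment by the largest-remainder method.

    Remainder ties are absorbed by the majority species, keeping totals
    exact and deterministic.
    """
    quotas = {sp: f * total for sp, f in fractions.items()}
    counts = {sp: int(math.floor(q)) for sp, q in quotas.items()}
    deficit = total - sum(counts.values())
    order = sorted(
        fractions,
        key=lambda sp: (-(quotas[sp] - counts[sp]), -fractions[sp], sp),
    )
    for sp in order[:deficit]:
        counts[sp] += 1
    return counts


def _protein_residue_coords(cfg: MembraneGenConfig) -> tuple[np.ndarray, np.ndarray]:
    """(n_residues, 3) residue centres and their residue ids (1-based).

    Residue ids run bottom-to-top within each helix, helices in circle order.
    """
    lay = cfg.protein
    cx, cy, cz = cfg.box[0] / 2, cfg.box[1] / 2, cfg.box[2] / 2
    zs = np.linspace(-lay.z_span, lay.z_span, lay.n_res_per_helix)
    coords = []
    for h in range(lay.n_helices):
        theta = 2 * math.pi * h / lay.n_helices
        x = cx + lay.radius * math.cos(theta)
        y = cy + lay.radius * math.sin(theta)
        for z in zs:
            coords.append((x, y, cz + z))
    rids = np.arange(1, lay.n_residues + 1)
    return np.array(coords), rids


def helix_interface_residues(
    cfg: MembraneGenConfig, helix: int, leaflet: str, reach: float = 0.55
) -> tuple[int, ...]:
    """Residues of one helix whose beads can reach headgroups of a leaflet,
    i.e. |z - leaflet headgroup level| <= ``reach``. Useful for planting
    hotspots whose ground truth equals the contact-capable residue set."""
    lay = cfg.protein
    zs = np.linspace(-lay.z_span, lay.z_span, lay.n_res_per_helix)
    z_head = HEAD_OFFSET_NM if leaflet == "upper" else -HEAD_OFFSET_NM
    local = np.flatnonzero(np.abs(zs - z_head) <= reach)
    return tuple(int(helix * lay.n_res_per_helix + j + 1) for j in local)


def gen_membrane_trajectory(
    cfg: MembraneGenConfig,
) -> tuple[Trajectory, BeadTopology, GroundTruth]:
    """Generate a bilayer trajectory, its bead topology and the ground truth."""
    cfg.validate()
    # independent child streams: initial placement and dynamics draw a fixed
    # number of variates regardless of hotspot settings, so configurations
    # differing only in strength share identical proposal/acceptance streams
    # and a zero-strength hotspot is bitwise identical to no hotspot at all
    init_ss, dyn_ss = np.random.SeedSequence(cfg.seed).spawn(2)
    rng_init = np.random.default_rng(init_ss)
    rng_dyn = np.random.default_rng(dyn_ss)
    lay = cfg.protein
    box = np.asarray(cfg.box, dtype=float)
    cz = box[2] / 2

    # --- protein scaffold ---------------------------------------------------
    res_coords, rids = _protein_residue_coords(cfg)
    prot_rows, prot_coords = [], []
    bead_id = 1
    for (x, y, z), rid in zip(res_coords, rids):
        for b in range(lay.beads_per_residue):
            # extra beads fan outward radially so residues are not points
            dx, dy = 0.0, 0.0
            if b > 0:
                ux, uy = x - box[0] / 2, y - box[1] / 2
                norm = math.hypot(ux, uy) or 1.0
                dx, dy = 0.08 * b * ux / norm, 0.08 * b * uy / norm
            name = "BB" if b == 0 else f"SC{b}"
            prot_rows.append((bead_id, 1, "protein", int(rid), name, "protein"))
            prot_coords.append((x + dx, y + dy, z))
            bead_id += 1

    # --- lipid bookkeeping ---------------------------------------------------
    n_per_leaflet = cfg.n_lipids_total // 2
    per_leaflet_counts = largest_remainder(dict(cfg.composition), n_per_leaflet)
    lipid_rows = []
    lip_species: list[str] = []
    lip_leaflet: list[str] = []
    lip_mol_ids: list[int] = []
    mol_id = 2
    for leaflet in ("upper", "lower"):
        for sp in cfg.composition:
            for _ in range(per_leaflet_counts[sp]):
                lip_species.append(sp)
                lip_leaflet.append(leaflet)
                lip_mol_ids.append(mol_id)
                zsign = 1.0 if leaflet == "upper" else -1.0
                names_z = [("HEAD", zsign * HEAD_OFFSET_NM, "headgroup")] + [
                    (f"T{i+1}", zsign * off, "tail")
                    for i, off in enumerate(TAIL_OFFSETS_NM)
                ]
                for name, zoff, role in names_z:
                    lipid_rows.append((bead_id, mol_id, sp, 0, name, role))
                    bead_id += 1
                mol_id += 1
    n_lip = len(lip_mol_ids)
    lip_species_arr = np.array(lip_species)
    lip_leaflet_arr = np.array(lip_leaflet)

    # --- hotspot preprocessing ----------------------------------------------
    hotspots = []
    for h in cfg.hotspots:
        centre = res_coords[[r - 1 for r in h.residue_ids]]
        leaflet = "upper" if centre[:, 2].mean() > cz else "lower"
        hotspots.append(
            {
                "spec": h,
                "centre": centre[:, :2].mean(axis=0),
                "leaflet": leaflet,
                "mask": (lip_species_arr == h.species) & (lip_leaflet_arr == leaflet),
                "p_reject": h.strength / (1.0 + h.strength),
            }
        )

    # --- initial positions ---------------------------------------------------
    pos = rng_init.uniform(0.0, 1.0, size=(n_lip, 2)) * box[:2]
    area = box[0] * box[1]
    u_init = rng_init.uniform(size=n_lip)
    r_init = rng_init.uniform(size=n_lip)
    phi_init = rng_init.uniform(0, 2 * math.pi, size=n_lip)
    for h in hotspots:
        if h["spec"].strength == 0:
            continue
        idx = np.flatnonzero(h["mask"])
        if idx.size == 0:
            continue
        # near-stationary start: occupancy matching the (1+strength)-fold
        # equilibrium enrichment inside the capture disk
        a_h = math.pi * h["spec"].radius ** 2
        enr = 1.0 + h["spec"].strength
        p_inside = enr * a_h / (area - a_h + enr * a_h)
        r = h["spec"].radius * np.sqrt(r_init[idx])
        pts = h["centre"] + np.column_stack(
            [r * np.cos(phi_init[idx]), r * np.sin(phi_init[idx])]
        )
        inside = u_init[idx] < p_inside
        pos[idx[inside]] = np.mod(pts[inside], box[:2])

    # --- dynamics -------------------------------------------------------------
    T = cfg.n_frames
    steps = rng_dyn.normal(0.0, cfg.diffusion_step, size=(max(T - 1, 0), n_lip, 2))
    accept_u = rng_dyn.uniform(size=(max(T - 1, 0), n_lip))
    xy = np.empty((T, n_lip, 2))
    xy[0] = pos

    def _dist_to(centre, p):
        d = p - centre
        d -= box[:2] * np.round(d / box[:2])
        return np.hypot(d[:, 0], d[:, 1])

    for t in range(1, T):
        prev = xy[t - 1]
        prop = prev + steps[t - 1]
        for h in hotspots:
            if h["p_reject"] == 0.0:
                continue
            m = h["mask"]
            d0 = _dist_to(h["centre"], prev[m])
            d1 = _dist_to(h["centre"], prop[m])
            reject = (d0 < h["spec"].radius) & (d1 > d0) & (
                accept_u[t - 1, m] < h["p_reject"]
            )
            rows = np.flatnonzero(m)[reject]
            prop[rows] = prev[rows]
        xy[t] = np.mod(prop, box[:2])

    # --- assemble coordinates -------------------------------------------------
    prot_xyz = np.array(prot_coords)
    n_prot = len(prot_xyz)
    beads_per_lipid = 1 + len(TAIL_OFFSETS_NM)
    n_beads = n_prot + n_lip * beads_per_lipid
    coords = np.empty((T, n_beads, 3))
    coords[:, :n_prot, :] = prot_xyz[None, :, :]
    z_offsets = np.array([HEAD_OFFSET_NM, *TAIL_OFFSETS_NM])
    zsigns = np.where(lip_leaflet_arr == "upper", 1.0, -1.0)
    lip_z = cz + zsigns[:, None] * z_offsets[None, :]  # (n_lip, 4)
    lip_block = coords[:, n_prot:, :].reshape(T, n_lip, beads_per_lipid, 3)
    lip_block[..., 0] = xy[:, :, None, 0]
    lip_block[..., 1] = xy[:, :, None, 1]
    lip_block[..., 2] = lip_z[None, :, :]

    topology = BeadTopology(
        pd.DataFrame(
            prot_rows + lipid_rows,
            columns=BeadTopology.COLUMNS,
        )
    )
    truth = GroundTruth(
        hotspot_residues={
            h.species: tuple(
                sorted({r for hh in cfg.hotspots if hh.species == h.species for r in hh.residue_ids})
            )
            for h in cfg.hotspots
        },
        leaflet_counts={lf: dict(per_leaflet_counts) for lf in ("upper", "lower")},
        lipid_leaflets={int(m): lf for m, lf in zip(lip_mol_ids, lip_leaflet)},
    )
    return Trajectory(coords, box), topology, truth
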