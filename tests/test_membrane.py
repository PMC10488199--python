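"""Contact engine, superposition, leaflet assignment, densities, enrichment
and site calling, each against an independent oracle where one exists."""

import numpy as np
import pandas as pd
import pytest

from pumplipid import io as plio
from pumplipid import membrane as mem
from pumplipid import synthetic as syn
from pumplipid.errors import AlignmentError, ConfigurationError, FormatError

from _oracles import best_rotation_by_grid, brute_force_contacts
from conftest import make_random_system


def minimal_system(residue_beads, lipid_heads, box=(10.0, 10.0, 8.0)):
    """One-residue protein plus one-headgroup-bead lipids at given positions."""
    rows, coords = [], []
    bead = 1
    for i, pos in enumerate(residue_beads):
        rows.append((bead, 1, "protein", 1, f"B{i}", "protein"))
        coords.append(pos)
        bead += 1
    for mol, pos in enumerate(lipid_heads, start=2):
        rows.append((bead, mol, "PC", 0, "HEAD", "headgroup"))
        coords.append(pos)
        bead += 1
    top = mem.BeadTopology(pd.DataFrame(rows, columns=mem.BeadTopology.COLUMNS))
    return np.asarray(coords, float), np.asarray(box, float), top


class TestDetectContacts:
    def test_single_pair_within_cutoff(self):
        coords, box, top = minimal_system([(0.3, 0, 0)], [(0.4, 0, 0)])
        assert mem.detect_contacts(coords, box, top) == {1: 2}

    def test_closer_lipid_blocks_farther_one(self):
        coords, box, top = minimal_system([(0.3, 0, 0)], [(0.4, 0, 0), (0.8, 0, 0)])
        # lipid 3 is within cutoff (0.5 nm) but lipid 2 is closer: exclusivity
        assert mem.detect_contacts(coords, box, top) == {1: 2}

    def test_periodic_wrap_in_x(self):
        coords, box, top = minimal_system([(0.1, 0, 0)], [(9.8, 0, 0)])
        # minimum-image distance is 0.3 nm across the boundary
        assert mem.detect_contacts(coords, box, top) == {1: 2}

    def test_no_contact_beyond_cutoff(self):
        coords, box, top = minimal_system([(0.3, 0, 0)], [(1.0, 0, 0)])
        assert mem.detect_contacts(coords, box, top) == {}

    def test_tie_breaks_to_lowest_lipid_id(self):
        coords, box, top = minimal_system([(5.0, 5, 0)], [(5.4, 5, 0), (4.6, 5, 0)])
        assert mem.detect_contacts(coords, box, top) == {1: 2}

    def test_translation_invariance(self):
        rng = np.random.default_rng(1)
        coords, box, _, top = make_random_system(rng)
        ref = mem.detect_contacts(coords, box, top)
        shifted = coords + np.array([3.7, -12.2, 0.0])
        assert mem.detect_contacts(shifted, box, top) == ref

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(99)
        for _ in range(25):
            coords, box, table, top = make_random_system(rng)
            assert mem.detect_contacts(coords, box, top) == brute_force_contacts(
                coords, box, table
            )


class TestContactProbabilities:
    def test_half_frames_probability(self):
        coords_in, box, top = minimal_system([(0.3, 0, 0)], [(0.4, 0, 0)])
        coords_out = coords_in.copy()
        coords_out[1] = (5.0, 5.0, 0.0)
        traj = mem.Trajectory(
            np.stack([coords_in] * 50 + [coords_out] * 50), box
        )
        prof = mem.contact_probabilities(traj, top)
        assert prof.probability(1, "PC") == pytest.approx(0.5)

    def test_never_within_cutoff_is_zero(self):
        coords, box, top = minimal_system([(0.3, 0, 0)], [(5.0, 5.0, 0)])
        prof = mem.contact_probabilities(mem.Trajectory(coords[None], box), top)
        assert prof.probabilities.max() == 0.0

    def test_report_thresholds(self):
        coords, box, top = minimal_system([(0.3, 0, 0)], [(0.4, 0, 0)])
        traj = mem.Trajectory(np.stack([coords] * 10), box)
        df = mem.contact_probabilities(traj, top).to_frame()
        row = df[(df.residue_id == 1) & (df.species == "PC")].iloc[0]
        assert row.probability == 1.0 and row.labelled and row.highlighted

    def test_concatenation_before_normalization(self):
        coords, box, top = minimal_system([(0.3, 0, 0)], [(0.4, 0, 0)])
        far = coords.copy()
        far[1] = (5, 5, 0)
        a = mem.Trajectory(np.stack([coords] * 10), box)
        b = mem.Trajectory(np.stack([far] * 30), box)
        prof = mem.contact_probabilities(mem.concatenate([a, b]), top)
        assert prof.probability(1, "PC") == pytest.approx(0.25)


class TestAlignment:
    def test_static_protein_is_identity(self):
        cfg = syn.MembraneGenConfig(box=(8, 8, 8), n_lipids_total=40, n_frames=5, seed=0)
        traj, top, _ = syn.gen_membrane_trajectory(cfg)
        aligned = mem.align_frames(traj, top)
        assert np.allclose(aligned.coords, traj.coords, atol=1e-12)

    def test_rigid_motion_removed(self):
        rng = np.random.default_rng(3)
        coords, box, _, top = make_random_system(rng)
        ang = np.deg2rad(30)
        R = np.array(
            [[np.cos(ang), -np.sin(ang), 0], [np.sin(ang), np.cos(ang), 0], [0, 0, 1]]
        )
        moved = coords @ R.T + np.array([1.0, -2.0, 0.5])
        traj = mem.Trajectory(np.stack([coords, moved]), box)
        aligned = mem.align_frames(traj, top)
        rmsd = np.sqrt(
            np.mean(
                np.sum(
                    (aligned.coords[1, top.protein_idx] - coords[top.protein_idx]) ** 2,
                    axis=1,
                )
            )
        )
        assert rmsd < 1e-9

    def test_least_squares_beats_rotation_grid(self):
        """Kabsch RMSD never exceeds the best brute-force in-plane rotation."""
        rng = np.random.default_rng(8)
        for _ in range(5):
            coords, box, _, top = make_random_system(rng)
            noisy = coords + rng.normal(0, 0.3, coords.shape)
            traj = mem.Trajectory(np.stack([coords, noisy]), box)
            aligned = mem.align_frames(traj, top)
            p = top.protein_idx
            rmsd = np.sqrt(np.mean(np.sum((aligned.coords[1, p] - coords[p]) ** 2, 1)))
            assert rmsd <= best_rotation_by_grid(noisy[p], coords[p]) + 1e-12

    def test_collinear_beads_rejected(self):
        rows = [(i + 1, 1, "protein", 1, f"B{i}", "protein") for i in range(3)]
        rows.append((4, 2, "PC", 0, "HEAD", "headgroup"))
        top = mem.BeadTopology(pd.DataFrame(rows, columns=mem.BeadTopology.COLUMNS))
        coords = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2], [3, 3, 3.0]])
        traj = mem.Trajectory(np.stack([coords, coords]), (8.0, 8.0, 8.0))
        with pytest.raises(AlignmentError):
            mem.align_frames(traj, top)


class TestDensity:
    def test_single_static_lipid_density(self):
        # second lipid below the midplane keeps the first in the upper leaflet
        coords, box, top = minimal_system(
            [(5, 5, 7.0)], [(3.001, 3.001, 6.0), (8.0, 8.0, 2.0)]
        )
        traj = mem.Trajectory(coords[None], box)
        dmap = mem.density_map_2d(traj, top, "PC", "upper", spacing=0.02)
        assert dmap.values.max() == pytest.approx(1 / 0.02**2)
        assert np.count_nonzero(dmap.values) == 1

    def test_2d_conservation_identity(self, null_membrane):
        _, traj, top, truth = null_membrane
        sub = mem.Trajectory(traj.coords[:100], traj.box)
        for sp, lf in (("PS", "upper"), ("PC", "lower")):
            dmap = mem.density_map_2d(sub, top, sp, lf, spacing=0.05)
            assert dmap.mean_count == pytest.approx(
                truth.leaflet_counts[lf][sp], rel=1e-9
            )

    def test_uniform_positions_match_expectation(self, null_membrane):
        """Without bias the regional mean density matches N/(Lx*Ly) within
        sampling error (3 SE, inflated 6x for frame-to-frame correlation)."""
        cfg, traj, top, truth = null_membrane
        dmap = mem.density_map_2d(traj, top, "PC", "upper", spacing=0.5)
        expected = truth.leaflet_counts["upper"]["PC"] / (cfg.box[0] * cfg.box[1])
        x, y = dmap.cell_centers()
        region = (x[:, None] < 3.0) & (y[None, :] < 3.0)  # off-protein corner
        share = 9.0 / (cfg.box[0] * cfg.box[1])
        n_eff = truth.leaflet_counts["upper"]["PC"] * traj.n_frames * share / 6
        se = expected / np.sqrt(n_eff)
        assert abs(dmap.values[region].mean() - expected) <= 3 * se

    def test_enrichment_doubling(self):
        coords, box, top = minimal_system([(5, 5, 7.0)], [(3, 3, 6.0), (8, 8, 2.0)])
        dmap = mem.density_map_2d(
            mem.Trajectory(coords[None], box), top, "PC", "upper", spacing=1.0
        )
        enr = mem.enrichment_map(dmap, {"upper": {"PC": 2}})
        # one lipid in one cell of a 10x10 box with 2 expected -> 100/2 = 50
        expected_cell = 1.0 / (2 / 100.0)
        assert enr.values.max() == pytest.approx(expected_cell)

    def test_3d_single_bead_voxel_density(self):
        coords, box, top = minimal_system([(5, 5, 7.0)], [(3.05, 3.05, 6.05)])
        grid = mem.density_grid_3d(
            mem.Trajectory(coords[None], box), top, "PC", beads="headgroup", spacing=0.1
        )
        assert grid.values.max() == pytest.approx(1 / 0.1**3)

    def test_3d_conservation_identity(self, null_membrane):
        _, traj, top, _ = null_membrane
        sub = mem.Trajectory(traj.coords[:50], traj.box)
        for beads, count in (("headgroup", 52), ("all", 208)):
            grid = mem.density_grid_3d(sub, top, "PS", beads=beads, spacing=0.2)
            assert grid.mean_count == pytest.approx(count, rel=1e-9)

    def test_isovalue_conventions(self):
        coords, box, top = minimal_system([(5, 5, 7.0)], [(3, 3, 6.0)])
        traj = mem.Trajectory(coords[None], box)
        g_head = mem.density_grid_3d(traj, top, "PC", beads="headgroup", spacing=0.5)
        g_all = mem.density_grid_3d(traj, top, "PC", beads="all", spacing=0.5)
        assert g_head.default_isovalue == 3.0
        assert g_all.default_isovalue == 4.0

    def test_bad_spacing_rejected(self):
        coords, box, top = minimal_system([(5, 5, 7.0)], [(3, 3, 6.0)])
        with pytest.raises(ConfigurationError):
            mem.density_map_2d(mem.Trajectory(coords[None], box), top, "PC", "upper", 0)


class TestFindSites:
    @staticmethod
    def flat_profile():
        return mem.ContactProfile(
            residue_ids=np.array([1]), species=("PS",),
            counts=np.array([[0]]), n_frames=10,
        )

    def bump_map(self, centers, amplitude=8.0, shape=(100, 100), spacing=0.1):
        x = (np.arange(shape[0]) + 0.5) * spacing
        y = (np.arange(shape[1]) + 0.5) * spacing
        vals = np.ones(shape)
        for cx, cy in centers:
            vals += amplitude * np.exp(
                -((x[:, None] - cx) ** 2 + (y[None, :] - cy) ** 2) / (2 * 0.3**2)
            )
        return mem.DensityMap2D(
            values=vals, spacing=spacing, origin=(0.0, 0.0), leaflet="upper",
            species="PS", n_frames=10, box=np.array([10.0, 10.0, 8.0]),
            kind="enrichment",
        )

    def test_flat_map_has_no_sites(self):
        sites = mem.find_sites(self.bump_map([], amplitude=0), self.flat_profile(), {})
        assert sites == []

    def test_single_bump_centroid(self):
        sites = mem.find_sites(self.bump_map([(5.0, 5.0)]), self.flat_profile(), {})
        assert len(sites) == 1
        assert sites[0].label == "A"
        assert abs(sites[0].centroid[0] - 5.0) <= 0.1
        assert abs(sites[0].centroid[1] - 5.0) <= 0.1

    def test_merge_rule(self):
        far = mem.find_sites(
            self.bump_map([(3.0, 5.0), (6.0, 5.0)]), self.flat_profile(), {}
        )
        near = mem.find_sites(
            self.bump_map([(5.0, 5.0), (5.5, 5.0)]), self.flat_profile(), {}
        )
        assert len(far) == 2
        assert len(near) == 1

    def test_residue_capture(self):
        prof = mem.ContactProfile(
            residue_ids=np.array([1, 2, 3]), species=("PS",),
            counts=np.array([[8], [0], [9]]), n_frames=10,
        )
        pos = {1: np.array([5.2, 5.0, 7.0]), 2: np.array([5.0, 5.3, 7.0]),
               3: np.array([9.0, 9.0, 7.0])}
        sites = mem.find_sites(self.bump_map([(5.0, 5.0)]), prof, pos)
        # residue 2 is close but below the 5% probability threshold;
        # residue 3 is probable but 5+ nm away
        assert sites[0].residues == (1,)


class TestTrajectoryIO:
    @pytest.fixture()
    def small(self):
        cfg = syn.MembraneGenConfig(box=(8, 8, 9), n_lipids_total=40, n_frames=4, seed=6)
        return syn.gen_membrane_trajectory(cfg)

    @pytest.mark.parametrize("suffix,tol", [(".gro", 5.1e-4), (".pdb", 5.1e-5)])
    def test_round_trip(self, small, tmp_path, suffix, tol):
        traj, top, _ = small
        plio.write_topology_tsv(top, tmp_path / "top.tsv")
        path = tmp_path / f"traj{suffix}"
        plio.write_trajectory(traj, top, path)
        back, top2 = plio.read_trajectory(path, tmp_path / "top.tsv")
        assert back.n_frames == traj.n_frames
        assert np.abs(back.coords - traj.coords).max() <= tol
        assert np.allclose(back.box, traj.box, atol=1e-3)
        pd.testing.assert_frame_equal(top2.table, top.table)

    def test_replica_concatenation_counts(self, small, tmp_path):
        traj, top, _ = small
        plio.write_topology_tsv(top, tmp_path / "top.tsv")
        p = tmp_path / "r.gro"
        plio.write_trajectory(traj, top, p)
        cat, _ = plio.read_trajectory([p, p, p], tmp_path / "top.tsv")
        assert cat.n_frames == 3 * traj.n_frames

    def test_headless_lipid_rejected(self):
        rows = [
            (1, 1, "protein", 1, "B0", "protein"),
            (2, 2, "PC", 0, "T1", "tail"),
        ]
        with pytest.raises(FormatError):
            mem.BeadTopology(pd.DataFrame(rows, columns=mem.BeadTopology.COLUMNS))

    def test_frame_topology_mismatch_names_frame(self, small, tmp_path):
        traj, top, _ = small
        plio.write_topology_tsv(top, tmp_path / "top.tsv")
        p = tmp_path / "t.gro"
        plio.write_trajectory(mem.Trajectory(traj.coords[:, :-1], traj.box),
                              _drop_last_bead(top), p)
        with pytest.raises(FormatError, match="frame 0"):
            plio.read_trajectory(p, tmp_path / "top.tsv")


def _drop_last_bead(top):
    t = top.table.iloc[:-1].copy()
    return mem.BeadTopology(t)
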