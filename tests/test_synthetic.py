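"""Generator contracts: determinism, closed-form traces, lipid apportionment,
bilayer geometry and the hotspot bias."""

import numpy as np
import pytest

from pumplipid import kinetics as kin
from pumplipid import membrane as mem
from pumplipid import synthetic as syn
from pumplipid.errors import ConfigurationError

from _oracles import ols_slope


class TestTraceGenerator:
    def test_zero_rate_trace_is_flat_and_inactive(self):
        cfg = syn.TraceGenConfig(rate=0.0, recovery=1.0, noise_sd=0.0)
        tr = syn.gen_acma_trace(cfg)
        assert np.allclose(tr.fluorescence, 1.0)
        assert kin.analyze_trace(tr).active is False

    def test_unit_fluorescence_before_mg(self):
        tr = syn.gen_acma_trace(syn.TraceGenConfig(noise_sd=0.0, rate=3e-3))
        assert np.all(tr.fluorescence[tr.time < tr.t_mg] == 1.0)

    def test_30s_slope_matches_closed_form_ols_oracle(self):
        """The 30 s OLS slope of the noiseless quench equals the value of an
        independent covariance-formula oracle on the analytic curve. At
        rate=0.004/plateau=0.5 the window shows a sizeable curvature bias
        (the OLS estimate is ~11% below the true instantaneous rate), so the
        assertion is against the oracle, not against -rate."""
        cfg = syn.TraceGenConfig(rate=0.004, plateau=0.5, noise_sd=0.0)
        tr = syn.gen_acma_trace(cfg)
        pr = kin.initial_rate(kin.normalize_trace(tr))
        t = np.arange(cfg.t_mg, cfg.t_mg + 30 + cfg.dt / 2, cfg.dt)
        k = cfg.rate / (1 - cfg.plateau)
        analytic = cfg.plateau + (1 - cfg.plateau) * np.exp(-k * (t - cfg.t_mg))
        expected = ols_slope(t, analytic)
        assert pr.slope == pytest.approx(expected, abs=1e-9)
        # the instantaneous initial slope is exactly -rate by construction
        d0 = (tr.fluorescence[int(cfg.t_mg / cfg.dt) + 1]
              - tr.fluorescence[int(cfg.t_mg / cfg.dt)]) / cfg.dt
        assert d0 == pytest.approx(-cfg.rate, rel=5e-3)

    def test_low_curvature_slope_near_true_rate(self):
        cfg = syn.TraceGenConfig(rate=5e-4, plateau=0.25, noise_sd=0.0)
        pr = kin.analyze_trace(syn.gen_acma_trace(cfg))
        assert pr.rate == pytest.approx(5e-4, rel=0.02)

    def test_deterministic_bitwise(self):
        cfg = syn.TraceGenConfig(noise_sd=0.01, seed=42)
        a, b = syn.gen_acma_trace(cfg), syn.gen_acma_trace(cfg)
        assert np.array_equal(a.fluorescence, b.fluorescence)
        c = syn.gen_acma_trace(syn.TraceGenConfig(noise_sd=0.01, seed=43))
        assert not np.array_equal(a.fluorescence, c.fluorescence)

    def test_invalid_event_order_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.gen_acma_trace(syn.TraceGenConfig(t_mg=500.0, t_cccp=100.0))


class TestApportionment:
    def test_largest_remainder_10_90(self):
        counts = syn.largest_remainder({"PS": 0.10, "PC": 0.90}, 262)
        assert counts == {"PS": 26, "PC": 236}

    def test_largest_remainder_ternary(self):
        counts = syn.largest_remainder({"PS": 0.10, "PE": 0.45, "PC": 0.45}, 262)
        assert sum(counts.values()) == 262
        assert counts["PS"] == 26
        assert counts["PE"] + counts["PC"] == 236

    def test_exact_totals_random_fractions(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            f = rng.dirichlet([1, 1, 1])
            fracs = {"A": f[0], "B": f[1], "C": f[2]}
            counts = syn.largest_remainder(fracs, 262)
            assert sum(counts.values()) == 262
            for sp in fracs:
                assert abs(counts[sp] - fracs[sp] * 262) < 1.0


@pytest.fixture(scope="module")
def small():
    cfg = syn.MembraneGenConfig(
        box=(9.0, 9.0, 9.0), n_lipids_total=100, n_frames=40, seed=2
    )
    return (cfg,) + syn.gen_membrane_trajectory(cfg)


class TestMembraneGenerator:

    def test_symmetric_leaflet_counts(self, small):
        cfg, traj, top, truth = small
        per_leaflet = [
            sum(1 for v in truth.lipid_leaflets.values() if v == lf)
            for lf in ("upper", "lower")
        ]
        assert per_leaflet == [50, 50]

    def test_study_system_has_262_per_leaflet(self, null_membrane):
        _, _, top, truth = null_membrane
        assert truth.leaflet_counts["upper"] == {"PS": 26, "PC": 236}
        assert top.n_lipids == 524

    def test_topology_counts_match_emission(self, small):
        cfg, traj, top, truth = small
        n_prot = len(top.protein_idx)
        assert traj.n_beads == n_prot + 4 * top.n_lipids
        assert top.n_lipids == len(truth.lipid_leaflets)

    def test_wrapped_coordinates_inside_box(self, small):
        cfg, traj, top, _ = small
        lip = np.setdiff1d(np.arange(traj.n_beads), top.protein_idx)
        xy = traj.coords[:, lip, :2]
        assert xy.min() >= 0.0
        assert xy.max() < cfg.box[0]

    def test_deterministic_bitwise(self):
        cfg = syn.MembraneGenConfig(box=(8, 8, 8), n_lipids_total=60, n_frames=10, seed=9)
        a = syn.gen_membrane_trajectory(cfg)[0]
        b = syn.gen_membrane_trajectory(cfg)[0]
        assert np.array_equal(a.coords, b.coords)

    def test_leaflet_assignment_matches_truth(self, small):
        _, traj, top, truth = small
        got = mem.assign_leaflets(traj.coords[0], top)
        assert got == truth.lipid_leaflets

    def test_composition_must_sum_to_one(self):
        with pytest.raises(ConfigurationError):
            syn.gen_membrane_trajectory(
                syn.MembraneGenConfig(composition={"PS": 0.5, "PC": 0.4}, n_frames=1)
            )

    def test_odd_lipid_count_rejected(self):
        with pytest.raises(ConfigurationError):
            syn.MembraneGenConfig(n_lipids_total=523).validate()


class TestNullUniformity:
    def test_contact_probability_uniform_across_same_depth_residues(
        self, null_membrane, null_profile
    ):
        """With no hotspot, all residues at the same membrane depth are
        exchangeable: each PS contact probability must lie within 3 sampling
        standard deviations of its depth-group mean (sampling SD from the
        binomial with an autocorrelation-inflated effective frame count)."""
        cfg, traj, top, _ = null_membrane
        probs = null_profile.probabilities[:, null_profile.species.index("PS")]
        n_per_helix = cfg.protein.n_res_per_helix
        depth = (top.residue_ids - 1) % n_per_helix
        # ~6 frames to diffuse one cutoff length at step 0.4 nm/axis
        n_eff = null_profile.n_frames / 6
        for d in range(n_per_helix):
            grp = probs[depth == d]
            mean = grp.mean()
            if mean == 0:
                assert np.all(grp == 0)
                continue
            sd = np.sqrt(mean * (1 - mean) / n_eff)
            assert np.all(np.abs(grp - mean) <= 3 * sd + 1e-12)


class TestHotspotBias:
    def test_monotone_in_strength(self):
        """Mean contact probability of the planted residues is non-decreasing
        over increasing hotspot strength (same seed, shared random streams)."""
        base = syn.MembraneGenConfig(n_frames=300, seed=21)
        planted = syn.helix_interface_residues(base, 0, "upper")
        means = []
        for strength in (0.0, 1.0, 3.0, 8.0, 25.0):
            hs = syn.HotspotSpec(residue_ids=planted, species="PS", strength=strength)
            cfg = syn.MembraneGenConfig(n_frames=300, seed=21, hotspots=(hs,))
            traj, top, _ = syn.gen_membrane_trajectory(cfg)
            prof = mem.contact_probabilities(traj, top)
            ps = prof.probabilities[:, prof.species.index("PS")]
            means.append(np.mean([ps[r - 1] for r in planted]))
        assert all(b >= a - 1e-12 for a, b in zip(means, means[1:]))
        assert means[-1] > means[0]

    def test_zero_strength_equals_no_hotspot(self):
        base = syn.MembraneGenConfig(n_frames=20, seed=4)
        planted = syn.helix_interface_residues(base, 0, "upper")
        hs = syn.HotspotSpec(residue_ids=planted, species="PS", strength=0.0)
        with_h = syn.MembraneGenConfig(n_frames=20, seed=4, hotspots=(hs,))
        a = syn.gen_membrane_trajectory(base)[0]
        b = syn.gen_membrane_trajectory(with_h)[0]
        assert np.array_equal(a.coords, b.coords)
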