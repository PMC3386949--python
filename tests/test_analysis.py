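import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cutoffmd.analysis import (
    FOLDED,
    TRANSIT,
    UNFOLDED,
    UnfoldedFeatureTable,
    ZeroPopulationError,
    assign_helicity,
    backbone_dihedrals,
    blocking_error,
    folding_free_energy,
    helical_turns,
    helix_formation_order,
    kabsch_rmsd,
    kl_divergence_4d,
    kl_divergence_histogram,
    molten_globule_filter,
    radius_of_gyration,
    transition_assign,
    unfolded_features,
)
from cutoffmd.core import K_B
from cutoffmd.dynamics import Trajectory
from cutoffmd.synthetic import TwoStateSpec, build_toy_chain, generate_two_state_trajectory


def rotation_matrix(axis, angle_deg):
    axis = np.asarray(axis, float) / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


class TestKabschRmsd:
    def test_identical_sets_zero(self):
        pts = np.random.default_rng(0).normal(size=(10, 3))
        assert kabsch_rmsd(pts, pts) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_motion_invariance(self):
        pts = np.random.default_rng(1).normal(size=(12, 3))
        moved = pts @ rotation_matrix([1, 2, 3], 37.0).T + np.array([4.0, -2.0, 9.0])
        assert kabsch_rmsd(pts, moved) < 1e-10

    def test_matches_rotation_grid_search(self):
        """4-point sets: Kabsch equals brute-force minimization over a fine
        grid of rotations (z-y-z Euler angles)."""
        rng = np.random.default_rng(2)
        a = rng.normal(size=(4, 3))
        b = rng.normal(size=(4, 3))
        got = kabsch_rmsd(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        best = np.inf
        grid = np.linspace(0, 360, 73)[:-1]
        half = np.linspace(0, 180, 37)
        for alpha in grid:
            for beta in half:
                for gamma in grid:
                    r = (
                        rotation_matrix([0, 0, 1], alpha)
                        @ rotation_matrix([0, 1, 0], beta)
                        @ rotation_matrix([0, 0, 1], gamma)
                    )
                    rmsd = np.sqrt(np.mean(np.sum((ac @ r.T - bc) ** 2, axis=1)))
                    best = min(best, rmsd)
        assert got == pytest.approx(best, abs=1e-3)

    def test_symmetry_and_triangle_inequality(self):
        rng = np.random.default_rng(3)
        x, y, z = (rng.normal(size=(6, 3)) for _ in range(3))
        assert kabsch_rmsd(x, y) == pytest.approx(kabsch_rmsd(y, x), abs=1e-8)
        assert kabsch_rmsd(x, z) <= kabsch_rmsd(x, y) + kabsch_rmsd(y, z) + 1e-8

    def test_rejects_mismatched_or_tiny_inputs(self):
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((3, 3)), np.zeros((4, 3)))
        with pytest.raises(ValueError):
            kabsch_rmsd(np.zeros((2, 3)), np.zeros((2, 3)))


class TestRadiusOfGyration:
    def test_single_point_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_unit_masses_two_angstroms_apart(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(4)
        coords = rng.normal(size=(20, 3))
        masses = rng.uniform(1, 20, 20)
        com = (masses @ coords) / masses.sum()
        expected = np.sqrt(
            np.sum(masses * np.sum((coords - com) ** 2, axis=1)) / masses.sum()
        )
        assert radius_of_gyration(coords, masses) == pytest.approx(expected)


class TestHelicity:
    def test_ideal_helix_all_flagged(self):
        pp = np.tile([-57.0, -47.0], (10, 1))
        assert assign_helicity(pp).all()

    def test_extended_chain_none_flagged(self):
        pp = np.tile([-120.0, 120.0], (10, 1))
        assert not assign_helicity(pp).any()

    def test_short_run_rejected(self):
        pp = np.tile([-120.0, 120.0], (9, 1))
        pp[3:6] = [-57.0, -47.0]  # only 3 consecutive in-window residues
        assert not assign_helicity(pp).any()

    def test_turns_examples_and_additivity(self):
        flags = np.zeros(20, dtype=bool)
        assert helical_turns(flags, (0, 20)) == 0.0
        flags[5:14] = True  # 9 helical residues
        assert helical_turns(flags, (0, 20)) == pytest.approx(2.5)
        whole = helical_turns(flags, (0, 20)) * 3.6
        parts = sum(
            helical_turns(flags, r) * 3.6 for r in [(0, 7), (7, 13), (13, 20)]
        )
        assert whole == pytest.approx(parts)

    def test_toy_chain_geometries_detected(self):
        helix = build_toy_chain(10, "helix")
        ext = build_toy_chain(10, "extended")
        fh = assign_helicity(backbone_dihedrals(helix.positions, 10))
        fe = assign_helicity(backbone_dihedrals(ext.positions, 10))
        assert fh[1:-1].all()  # termini have undefined phi or psi
        assert not fe.any()


class TestTransitionAssign:
    def test_monotone_descent_single_folding_event(self):
        series = np.linspace(10.0, 1.0, 50)
        seg = transition_assign(series, 2.5, 6.0)
        assert [e.type for e in seg.events] == ["folding"]
        after = np.flatnonzero(series < 2.5)[0]
        assert np.all(seg.labels[after:] == FOLDED)
        assert seg.labels[0] == UNFOLDED  # first frame is above 6.0

    def test_band_excursion_produces_no_event(self):
        series = np.concatenate(
            [np.full(10, 1.0), np.full(10, 4.0), np.full(10, 1.0)]
        )
        seg = transition_assign(series, 2.5, 6.0)
        assert seg.events == []
        assert np.all(seg.labels == FOLDED)

    def test_telegraph_signal_events_recovered(self):
        """12 constructed crossings with band-limited noise recover exactly
        12 events."""
        rng = np.random.default_rng(5)
        pieces = []
        for k in range(13):
            level = 1.0 if k % 2 else 8.0
            pieces.append(np.full(200, level))
        series = np.concatenate(pieces) + rng.uniform(-1.0, 1.0, 13 * 200)
        seg = transition_assign(series, 2.5, 6.0)
        assert len(seg.events) == 12
        types = [e.type for e in seg.events]
        assert types == ["folding", "unfolding"] * 6

    def test_pre_crossing_frames_are_transit(self):
        series = np.concatenate([np.full(5, 4.0), np.full(5, 1.0)])
        seg = transition_assign(series, 2.5, 6.0)
        assert np.all(seg.labels[:5] == TRANSIT)
        assert np.all(seg.labels[5:] == FOLDED)

    def test_rejects_out_of_order_thresholds(self):
        with pytest.raises(ValueError):
            transition_assign(np.zeros(10), 6.0, 2.5)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, derandomize=True, deadline=None)
    def test_interthreshold_noise_never_changes_events(self, seed):
        rng = np.random.default_rng(seed)
        base = np.concatenate([np.full(50, 8.0), np.full(50, 1.0), np.full(50, 8.0)])
        seg0 = transition_assign(base, 2.5, 6.0)
        # noise that never pushes a frame across either threshold
        noisy = base.copy()
        room_up = 0.9 * np.where(base < 2.5, 2.5 - base, np.inf)
        room_dn = 0.9 * np.where(base > 6.0, base - 6.0, np.inf)
        noise = rng.uniform(-1.0, 1.0, base.size)
        noisy = base + np.where(noise > 0, np.minimum(noise, room_up), np.maximum(noise, -room_dn))
        seg1 = transition_assign(noisy, 2.5, 6.0)
        assert [(e.type, e.start, e.end) for e in seg0.events] == [
            (e.type, e.start, e.end) for e in seg1.events
        ]


class TestFoldingFreeEnergy:
    @staticmethod
    def seg_from_labels(labels):
        from cutoffmd.analysis import StateSegmentation

        return StateSegmentation(
            labels=np.asarray(labels), events=[], thresholds=(2.5, 6.0)
        )

    def test_equal_populations_zero(self):
        seg = self.seg_from_labels([FOLDED, UNFOLDED] * 50)
        assert folding_free_energy(seg, 360.0).delta_g == pytest.approx(0.0)

    def test_closed_form_arithmetic(self):
        labels = [FOLDED] * 20 + [UNFOLDED] * 80
        seg = self.seg_from_labels(labels)
        thermo = folding_free_energy(seg, 360.0)
        assert thermo.delta_g == pytest.approx(-0.0019872041 * 360 * np.log(0.25))
        assert thermo.delta_g == pytest.approx(0.9917, abs=1e-3)

    def test_zero_population_raises(self):
        seg = self.seg_from_labels([FOLDED] * 100)
        with pytest.raises(ZeroPopulationError):
            folding_free_energy(seg, 360.0)

    def test_monotone_in_folded_population(self):
        gs = []
        for nf in (20, 40, 60, 80):
            labels = [FOLDED] * nf + [UNFOLDED] * (100 - nf)
            gs.append(folding_free_energy(self.seg_from_labels(labels), 360.0).delta_g)
        assert all(a > b for a, b in zip(gs, gs[1:]))

    def test_markov_chain_recovery(self):
        """Two-state Markov chain at stationary folded probability 0.3:
        recovered dG within 2 blocking standard errors of the closed form."""
        from cutoffmd.analysis import StateSegmentation

        rng = np.random.default_rng(12)
        n = 100_000
        kf, ku = 0.003, 0.007
        states = np.empty(n, dtype=int)
        states[0] = UNFOLDED
        u = rng.random(n)
        for t in range(1, n):
            if states[t - 1] == FOLDED:
                states[t] = UNFOLDED if u[t] < ku else FOLDED
            else:
                states[t] = FOLDED if u[t] < kf else UNFOLDED
        seg = StateSegmentation(labels=states, events=[], thresholds=(2.5, 6.0))
        thermo = folding_free_energy(seg, 360.0)
        truth = -K_B * 360.0 * np.log(0.3 / 0.7)
        assert abs(thermo.delta_g - truth) < 2 * thermo.delta_g_stderr


class TestBlocking:
    def test_constant_series_zero(self):
        assert blocking_error(np.full(256, 3.7)) == pytest.approx(0.0, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            blocking_error(np.zeros(8))

    def test_iid_normal_closed_form(self):
        ests = [
            blocking_error(np.random.default_rng(100 + s).normal(size=4096))
            for s in range(20)
        ]
        assert np.mean(ests) == pytest.approx(1.0 / 64.0, rel=0.25)

    def test_ar1_correlated_closed_form(self):
        rho, n = 0.9, 2**16
        truth = np.sqrt((1 + rho) / (1 - rho)) / np.sqrt(n)
        ests = []
        for s in range(8):
            rng = np.random.default_rng(200 + s)
            eps = rng.normal(size=n) * np.sqrt(1 - rho**2)
            x = np.empty(n)
            x[0] = rng.normal()
            for t in range(1, n):
                x[t] = rho * x[t - 1] + eps[t]
            ests.append(blocking_error(x))
        assert np.mean(ests) == pytest.approx(truth, rel=0.30)


def feature_trajectory(n=100, seed=0):
    rng = np.random.default_rng(seed)
    feats = {
        "rmsd": rng.uniform(0, 10, n),
        "rg": rng.uniform(8, 14, n),
        "turns_h1": rng.uniform(0, 2.5, n),
        "turns_h2": rng.uniform(0, 2.0, n),
        "turns_h3": rng.uniform(0, 2.2, n),
    }
    return Trajectory(times=np.arange(n, dtype=float), features=feats)


class TestUnfoldedFeatures:
    def test_all_folded_raises(self):
        traj = feature_trajectory()
        from cutoffmd.analysis import StateSegmentation

        seg = StateSegmentation(
            labels=np.full(traj.n_frames, FOLDED), events=[], thresholds=(2.5, 6.0)
        )
        with pytest.raises(ZeroPopulationError):
            unfolded_features(traj, seg)

    def test_row_count_and_values_match_channels(self):
        traj = feature_trajectory(seed=1)
        seg = transition_assign(traj.features["rmsd"], 2.5, 6.0)
        table = unfolded_features(traj, seg)
        mask = seg.labels == UNFOLDED
        assert len(table) == mask.sum()
        assert np.allclose(table.data["rg"].to_numpy(), traj.features["rg"][mask])

    def test_coordinate_path_matches_composition_oracle(self):
        """Feature table computed from coordinates equals per-frame
        recomputation via radius_of_gyration + helical_turns."""
        from cutoffmd.analysis import StateSegmentation

        chain = build_toy_chain(12, "helix")
        frames = np.stack([chain.positions, chain.positions + 0.01])
        traj = Trajectory(times=np.array([0.0, 1.0]), positions=frames)
        seg = StateSegmentation(
            labels=np.array([UNFOLDED, UNFOLDED]), events=[], thresholds=(2.5, 6.0)
        )
        ranges = [(0, 4), (4, 8), (8, 12)]
        table = unfolded_features(traj, seg, helix_ranges=ranges, system=chain)
        flags = assign_helicity(backbone_dihedrals(chain.positions, 12))
        assert table.data.iloc[0]["rg"] == pytest.approx(
            radius_of_gyration(chain.positions, chain.masses)
        )
        assert table.data.iloc[0]["turns_h2"] == pytest.approx(
            helical_turns(flags, (4, 8))
        )


class TestMoltenGlobuleFilter:
    def test_counting_oracle(self):
        traj = feature_trajectory(seed=2)
        seg = transition_assign(traj.features["rmsd"], 2.5, 6.0)
        table = unfolded_features(traj, seg)
        rng = np.random.default_rng(3)
        flags = rng.random((traj.n_frames, 15)) < 0.1
        filtered = molten_globule_filter(table, flags)
        expected = sum(
            not flags[f].any() for f in table.data.index.to_numpy()
        )
        assert len(filtered) == expected

    def test_frame_with_any_helical_residue_excluded(self):
        traj = feature_trajectory(seed=4)
        seg = transition_assign(traj.features["rmsd"], 2.5, 6.0)
        table = unfolded_features(traj, seg)
        flags = np.zeros((traj.n_frames, 10), dtype=bool)
        first = table.data.index[0]
        flags[first, 3] = True
        filtered = molten_globule_filter(table, flags)
        assert first not in filtered.data.index
        assert len(filtered) == len(table) - 1

    def test_fully_coil_ensemble_retained(self):
        traj = feature_trajectory(seed=5)
        seg = transition_assign(traj.features["rmsd"], 2.5, 6.0)
        table = unfolded_features(traj, seg)
        flags = np.zeros((traj.n_frames, 10), dtype=bool)
        assert len(molten_globule_filter(table, flags)) == len(table)


class TestKlDivergence:
    def test_two_bin_closed_form(self):
        got = kl_divergence_histogram([0.5, 0.5], [0.9, 0.1])
        assert got == pytest.approx(0.5108, abs=1e-4)

    def test_identity_near_zero(self):
        traj = feature_trajectory(seed=6)
        seg = transition_assign(traj.features["rmsd"], 2.5, 6.0)
        table = unfolded_features(traj, seg)
        assert kl_divergence_4d(table, table) == pytest.approx(0.0, abs=1e-6)

    def test_nonnegative_over_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            p = rng.random(8)
            q = rng.random(8) + 0.05
            assert kl_divergence_histogram(p, q, pseudocount=1e-3) >= -1e-12

    def test_same_generator_divergence_decreases_with_sample_size(self):
        def table(n, seed):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "rg": rng.normal(11, 1, n),
                    "turns_h1": np.abs(rng.normal(0.4, 0.3, n)),
                    "turns_h2": np.abs(rng.normal(0.3, 0.2, n)),
                    "turns_h3": np.abs(rng.normal(0.5, 0.3, n)),
                }
            )
            return UnfoldedFeatureTable(data=df)

        medians = []
        for n in (100, 1000, 10000):
            vals = [
                kl_divergence_4d(table(n, 2 * s), table(n, 2 * s + 1))
                for s in range(5)
            ]
            medians.append(np.median(vals))
        assert medians[0] > medians[1] > medians[2]

    def test_empty_input_rejected(self):
        df = pd.DataFrame(columns=["rg", "turns_h1", "turns_h2", "turns_h3"])
        empty = UnfoldedFeatureTable(data=df)
        full = feature_trajectory(seed=8)
        seg = transition_assign(full.features["rmsd"], 2.5, 6.0)
        table = unfolded_features(full, seg)
        with pytest.raises(ValueError):
            kl_divergence_4d(empty, table)


class TestHelixFormationOrder:
    @staticmethod
    def constructed_trajectory():
        """One folding event; helix 1 forms at frame 10, helix 3 at 20,
        helix 2 at 30 (within a 0..40 event window)."""
        n = 60
        rmsd = np.concatenate([np.full(5, 8.0), np.linspace(8, 1, 40), np.full(15, 1.0)])
        turns = {f"turns_h{h}": np.zeros(n) for h in (1, 2, 3)}
        for h, t_form in ((1, 10), (3, 20), (2, 30)):
            turns[f"turns_h{h}"][t_form:] = 2.0
        feats = {"rmsd": rmsd, "rg": np.full(n, 10.0), **turns}
        return Trajectory(times=np.arange(n, dtype=float), features=feats)

    def test_constructed_event_labeled_132(self):
        traj = self.constructed_trajectory()
        seg = transition_assign(traj.features["rmsd"], 2.5, 6.0)
        result = helix_formation_order(traj, seg)
        assert result.labels == ["132"]
        assert result.frequencies == {"132": 1.0}

    def test_simultaneous_formation_tie_breaks_to_123(self):
        traj = self.constructed_trajectory()
        for h in (1, 2, 3):
            ch = np.zeros(traj.n_frames)
            ch[15:] = 2.0
            traj.features[f"turns_h{h}"] = ch
        seg = transition_assign(traj.features["rmsd"], 2.5, 6.0)
        result = helix_formation_order(traj, seg)
        assert result.labels == ["123"]

    def test_incomplete_event_excluded_and_counted(self):
        traj = self.constructed_trajectory()
        late = np.zeros(traj.n_frames)
        late[50:] = 2.0  # helix 2 forms only after the event has ended
        traj.features["turns_h2"] = late
        seg = transition_assign(traj.features["rmsd"], 2.5, 6.0)
        result = helix_formation_order(traj, seg)
        assert result.n_incomplete == 1
        assert result.labels == []

    def test_frequencies_sum_to_one(self):
        traj, _ = generate_two_state_trajectory(TwoStateSpec(n_frames=30_000, seed=9))
        seg = transition_assign(traj.features["rmsd"])
        result = helix_formation_order(traj, seg)
        assert sum(result.frequencies.values()) == pytest.approx(1.0)
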