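import numpy as np
import pytest

from poregate import ChannelSpec, Trajectory, generate_trajectory, select
from poregate.dynamics import superpose
from poregate.permeation import (
    REGIONS,
    build_compartments,
    detect_permeation_events,
    dwell_profile,
    occupancy_distribution,
)
from poregate.synthetic import (
    abort_script,
    complete_crossing_script,
    parked_script,
    retrograde_script,
)
from poregate.traj_io import FrameWindow


def make_model(traj, **kwargs):
    topo = traj.topology
    return build_compartments(
        traj,
        select(topo, "resid 3:5 and name CA"),
        select(topo, "resid 8 and name CA"),
        select(topo, "resid 12 and name CA"),
        **kwargs,
    )


def oracle_events(traj, ions_sel, model, direction="ext_to_int"):
    """Independent segment-based enumeration of completed crossings.

    Splits each ion's z-series at frames where it sits above the entry
    boundary (+hysteresis); within each segment, looks for the boundaries
    being passed in order. Structured differently from the state machine.
    """
    bounds = model.boundaries()
    h = model.hysteresis
    count = 0
    for ion in ions_sel.atom_indices:
        xyz = traj.coordinates[:, int(ion), :]
        r = np.hypot(xyz[:, 0] - model.axis_xy[:, 0], xyz[:, 1] - model.axis_xy[:, 1])
        if direction == "ext_to_int":
            z = xyz[:, 2]
            b = bounds
        else:
            z = -xyz[:, 2]
            b = -bounds[::-1]
        resets = np.nonzero(z > b[0] + h)[0]
        starts = [0] + [int(t) + 1 for t in resets]
        seg_bounds = sorted(set(starts)) + [len(z)]
        for s, e in zip(seg_bounds, seg_bounds[1:]):
            if s >= e:
                continue
            if s == 0 and z[0] < b[0, 0] - h:
                continue  # started already inside: SF entry not observed
            t = s
            ok = True
            for k in range(4):
                hits = np.nonzero((z[t:e] < b[k, t:e] - h) & (r[t:e] <= model.radial_cutoff))[0]
                if len(hits) == 0:
                    ok = False
                    break
                t = t + int(hits[0])
            if ok:
                count += 1
    return count


class TestBuildCompartments:
    def test_boundaries_match_layout(self, spec):
        traj, _ = generate_trajectory(spec, n_frames=3)
        model = make_model(traj)
        # SF residues 3..5 span z 20..15; gates at 0 and -15
        assert np.allclose(model.z_ext_gate, 20.0, atol=1e-6)
        assert np.allclose(model.z_sf_bottom, 15.0, atol=1e-6)
        assert np.allclose(model.z_hbc, 0.0, atol=1e-6)
        assert np.allclose(model.z_gloop, -15.0, atol=1e-6)

    def test_swapped_selections_raise_ordering_error(self, spec):
        traj, _ = generate_trajectory(spec, n_frames=2)
        topo = traj.topology
        with pytest.raises(ValueError, match="frame 0"):
            build_compartments(
                traj,
                select(topo, "resid 12 and name CA"),  # G-loop passed as SF
                select(topo, "resid 8 and name CA"),
                select(topo, "resid 3:5 and name CA"),
            )

    def test_empty_selection_raises(self, spec):
        traj, _ = generate_trajectory(spec, n_frames=2)
        topo = traj.topology
        with pytest.warns(UserWarning):
            empty = select(topo, "resid 99")
        with pytest.raises(ValueError, match="sf"):
            build_compartments(
                traj, empty, select(topo, "resid 8"), select(topo, "resid 12")
            )

    def test_tilted_then_realigned_reproduces_boundaries(self, spec):
        traj, _ = generate_trajectory(spec, n_frames=4)
        ref = make_model(traj)
        theta = 0.5
        rot = np.array(
            [
                [1, 0, 0],
                [0, np.cos(theta), -np.sin(theta)],
                [0, np.sin(theta), np.cos(theta)],
            ]
        )
        tilted = traj.coordinates @ rot.T + np.array([3.0, -2.0, 7.0])
        realigned = np.empty_like(tilted)
        for f in range(len(tilted)):
            res = superpose(tilted[f], traj.coordinates[f])
            realigned[f] = res.apply(tilted[f])
        model = make_model(Trajectory(traj.topology, realigned))
        for attr in ("z_ext_gate", "z_sf_bottom", "z_hbc", "z_gloop"):
            assert np.allclose(getattr(model, attr), getattr(ref, attr), atol=1e-3)


class TestDetectEvents:
    @pytest.fixture
    def scripted(self):
        spec = ChannelSpec(n_ions=6)
        ions = [
            complete_crossing_script(spec, 0, 5, 60),
            complete_crossing_script(spec, 1, 40, 100),
            complete_crossing_script(spec, 2, 80, 140),
            abort_script(spec, 3, 5, 60, 120),
            abort_script(spec, 4, 30, 80, 130),
            retrograde_script(spec, 5, 10, 70, 130),
        ]
        traj, manifest = generate_trajectory(spec, ions=ions, n_frames=150, seed=2)
        return traj, manifest

    def test_counts_match_manifest(self, scripted):
        traj, manifest = scripted
        model = make_model(traj)
        events = detect_permeation_events(traj, select(traj.topology, "resname K"), model)
        assert len(events) == manifest["event_counts"]["ext_to_int"] == 3
        for ev in events:
            assert ev.frame_enter_sf <= ev.frame_cross_hbc <= ev.frame_exit_gloop

    def test_frame_reversed_gives_zero(self, scripted):
        traj, _ = scripted
        rev = Trajectory(traj.topology, traj.coordinates[::-1].copy())
        model = make_model(rev)
        events = detect_permeation_events(rev, select(rev.topology, "resname K"), model)
        assert events == []

    def test_reversal_duality(self, scripted):
        # events(ext_to_int, reversed) == events(int_to_ext, original)
        traj, _ = scripted
        ions = select(traj.topology, "resname K")
        rev = Trajectory(traj.topology, traj.coordinates[::-1].copy())
        n_rev = len(detect_permeation_events(rev, ions, make_model(rev), "ext_to_int"))
        n_fwd = len(detect_permeation_events(traj, ions, make_model(traj), "int_to_ext"))
        assert n_rev == n_fwd

    def test_zero_ions_empty(self, scripted):
        traj, _ = scripted
        model = make_model(traj)
        with pytest.warns(UserWarning):
            none = select(traj.topology, "resname XYZ")
        assert detect_permeation_events(traj, none, model) == []

    def test_multiple_events_per_ion(self):
        spec = ChannelSpec(n_ions=1)
        z_int, z_ext = spec.z_extents
        from poregate.synthetic import IonScript

        script = IonScript(
            0,
            [
                (0, z_ext + 8),
                (40, z_int - 8),
                (80, z_ext + 8),
                (120, z_int - 8),
            ],
            lateral_noise_sd=0.3,
            outcome="parked",
        )
        traj, _ = generate_trajectory(spec, ions=[script], n_frames=130, seed=4)
        model = make_model(traj)
        events = detect_permeation_events(traj, select(traj.topology, "resname K"), model)
        assert len(events) == 2
        assert len({e.ion for e in events}) == 1

    def test_radial_cutoff_excludes_outside_path(self):
        spec = ChannelSpec(n_ions=1)
        script = complete_crossing_script(spec, 0, 5, 60, lateral_noise_sd=0.0)
        script.radial_offset = 25.0  # far outside the pore
        traj, _ = generate_trajectory(spec, ions=[script], n_frames=80, seed=0)
        model = make_model(traj)
        assert detect_permeation_events(traj, select(traj.topology, "resname K"), model) == []

    def test_stride_invariance(self, scripted):
        traj, _ = scripted
        ions = select(traj.topology, "resname K")
        model = make_model(traj)
        n1 = len(detect_permeation_events(traj, ions, model, window=FrameWindow(0, 150, 1)))
        n2 = len(detect_permeation_events(traj, ions, model, window=FrameWindow(0, 150, 2)))
        assert n1 == n2 == 3

    def test_matches_brute_force_oracle(self):
        # randomized scripts, compared against the segment-enumeration oracle
        rng = np.random.default_rng(9)
        spec = ChannelSpec(n_ions=10)
        from poregate.synthetic import IonScript

        z_int, z_ext = spec.z_extents
        scripts = []
        for i in range(10):
            n_way = rng.integers(2, 5)
            frames = np.sort(rng.choice(np.arange(1, 199), size=n_way, replace=False))
            zs = rng.uniform(z_int - 10, z_ext + 10, size=n_way)
            scripts.append(
                IonScript(i, list(zip(frames.tolist(), zs.tolist())), lateral_noise_sd=0.4)
            )
        traj, _ = generate_trajectory(spec, ions=scripts, n_frames=200, seed=13)
        model = make_model(traj)
        ions = select(traj.topology, "resname K")
        for direction in ("ext_to_int", "int_to_ext"):
            fsm = len(detect_permeation_events(traj, ions, model, direction))
            assert fsm == oracle_events(traj, ions, model, direction)


class TestOccupancy:
    def test_two_parked_ions_in_sf(self):
        spec = ChannelSpec(n_ions=2)
        ions = [parked_script(0, 17.0), parked_script(1, 18.5)]
        traj, _ = generate_trajectory(spec, ions=ions, n_frames=50)
        model = make_model(traj)
        occ = occupancy_distribution(traj, select(traj.topology, "resname K"), model, "sf")
        assert occ.percent_of_frames == {2: 100.0}

    def test_radial_gating(self):
        spec = ChannelSpec(n_ions=1)
        ions = [parked_script(0, 17.0, radial_offset=15.0)]
        traj, _ = generate_trajectory(spec, ions=ions, n_frames=20)
        model = make_model(traj)
        occ = occupancy_distribution(traj, select(traj.topology, "resname K"), model, "sf")
        assert occ.percent_of_frames == {0: 100.0}

    def test_alternating_three_four(self):
        spec = ChannelSpec(n_ions=4)
        # three ions always in the cavity, a fourth alternating in/out
        from poregate.synthetic import IonScript

        ions = [parked_script(i, 8.0 - i) for i in range(3)]
        way = []
        for t in range(0, 100, 2):
            way.append((t, 8.0))
            way.append((t + 1, 40.0))
        ions.append(IonScript(3, way, lateral_noise_sd=0.0))
        traj, _ = generate_trajectory(spec, ions=ions, n_frames=100)
        model = make_model(traj)
        occ = occupancy_distribution(traj, select(traj.topology, "resname K"), model, "cavity")
        assert occ.percent_of_frames == {3: 50.0, 4: 50.0}

    def test_percentages_sum_to_100(self, scripted_random=None):
        spec = ChannelSpec(n_ions=5)
        ions = [
            complete_crossing_script(spec, i, 5 * i, 60 + 10 * i) for i in range(5)
        ]
        traj, _ = generate_trajectory(spec, ions=ions, n_frames=120, seed=3)
        model = make_model(traj)
        sel = select(traj.topology, "resname K")
        for region in REGIONS:
            occ = occupancy_distribution(traj, sel, model, region)
            assert sum(occ.percent_of_frames.values()) == pytest.approx(100.0, abs=1e-6)

    def test_empty_window_error(self, spec):
        traj, _ = generate_trajectory(ChannelSpec(n_ions=1), n_frames=5)
        model = make_model(traj)
        with pytest.raises(ValueError, match="empty"):
            occupancy_distribution(
                traj, select(traj.topology, "resname K"), model, "sf", FrameWindow(2, 2)
            )


class TestDwell:
    def test_parked_ion_assigned_to_nearest_residue(self):
        spec = ChannelSpec(n_ions=1)
        # park at SF-residue 4 z-level close to chain A's ring
        traj, _ = generate_trajectory(
            spec, ions=[parked_script(0, 17.5, radial_offset=7.0)], n_frames=100
        )
        model = make_model(traj)
        prof = dwell_profile(
            traj,
            select(traj.topology, "resname K"),
            model,
            select(traj.topology, "protein", "residue"),
        )
        assert prof.total_ion_frames == 100
        (top_res, pct) = max(prof.per_residue_percent.items(), key=lambda kv: kv[1])
        assert pct == 100.0
        assert top_res[0] == "A"

    def test_region_split_60_30_10(self):
        spec = ChannelSpec(n_ions=1)
        from poregate.synthetic import IonScript

        script = IonScript(
            0,
            [(0, 17.0), (59, 17.0), (60, 8.0), (89, 8.0), (90, -5.0), (99, -5.0)],
            lateral_noise_sd=0.0,
        )
        traj, _ = generate_trajectory(spec, ions=[script], n_frames=100)
        model = make_model(traj)
        prof = dwell_profile(
            traj,
            select(traj.topology, "resname K"),
            model,
            select(traj.topology, "protein", "residue"),
        )
        assert prof.per_region_percent["sf"] == pytest.approx(60.0)
        assert prof.per_region_percent["cavity"] == pytest.approx(30.0)
        assert prof.per_region_percent["gloop"] == pytest.approx(10.0)

    def test_region_percentages_sum_to_100(self):
        spec = ChannelSpec(n_ions=3)
        ions = [complete_crossing_script(spec, i, 10 * i, 80) for i in range(3)]
        traj, _ = generate_trajectory(spec, ions=ions, n_frames=100, seed=5)
        model = make_model(traj)
        prof = dwell_profile(
            traj,
            select(traj.topology, "resname K"),
            model,
            select(traj.topology, "protein", "residue"),
        )
        assert sum(prof.per_region_percent.values()) == pytest.approx(100.0, abs=1e-6)
        assert sum(prof.per_residue_percent.values()) == pytest.approx(100.0, abs=1e-6)

    def test_permeating_scope_restricts_to_event_ions(self):
        spec = ChannelSpec(n_ions=2)
        ions = [
            complete_crossing_script(spec, 0, 5, 60),
            parked_script(1, 17.0),  # never permeates
        ]
        traj, _ = generate_trajectory(spec, ions=ions, n_frames=100, seed=6)
        model = make_model(traj)
        sel = select(traj.topology, "resname K")
        residues = select(traj.topology, "protein", "residue")
        all_prof = dwell_profile(traj, sel, model, residues)
        perm_prof = dwell_profile(traj, sel, model, residues, scope="permeating_ions_only")
        assert perm_prof.total_ion_frames < all_prof.total_ion_frames

    def test_bad_cutoff(self, spec):
        traj, _ = generate_trajectory(ChannelSpec(n_ions=1), n_frames=5)
        model = make_model(traj)
        with pytest.raises(ValueError, match="assign_cutoff"):
            dwell_profile(
                traj,
                select(traj.topology, "resname K"),
                model,
                select(traj.topology, "protein", "residue"),
                assign_cutoff=0.0,
            )
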