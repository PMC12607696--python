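"""Binding classification: gap-surface crossing, contacts, events, diagnostics."""

import numpy as np
import pytest

from memwire.binding import (
    BindingConfig,
    InterhelicalSite,
    LipidProbe,
    cardiolipin_excursions,
    classify_trajectory,
    contact_frequencies,
    default_sites,
    extract_events,
    in_contact,
    probes_from_system,
    replicate_divergence,
    segment_intersects_triangle,
    tail_intersects_surface,
)
from memwire.model import AtomRecord, Frame, MolecularSystem, SpeciesTag, Trajectory
from memwire.synthetic import PlantedBindingEvent, SyntheticSpec, generate_system, plant_binding_event

TRI = np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 1.0, 0]])


class TestSegmentTriangle:
    def test_orthogonal_crossing_through_centroid(self):
        c = TRI.mean(axis=0)
        assert segment_intersects_triangle(c + [0, 0, 0.5], c - [0, 0, 0.5], TRI)

    def test_parallel_segment_above_plane(self):
        assert not segment_intersects_triangle(
            np.array([0.1, 0.1, 0.2]), np.array([0.5, 0.3, 0.2]), TRI
        )

    def test_segment_ending_short_of_plane(self):
        c = TRI.mean(axis=0)
        assert not segment_intersects_triangle(c + [0, 0, 1.0], c + [0, 0, 0.1], TRI)

    def test_agrees_with_plane_barycentric_oracle(self, rng):
        """Random segment/triangle pairs vs an independent plane-intersection +
        barycentric-coordinates test, away from 1e-6 boundaries."""
        n_checked = 0
        for _ in range(1000):
            tri = rng.uniform(-1, 1, size=(3, 3))
            if 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0])) < 1e-3:
                continue
            p0, p1 = rng.uniform(-1.5, 1.5, size=(2, 3))
            normal = np.cross(tri[1] - tri[0], tri[2] - tri[0])
            denom = normal @ (p1 - p0)
            if abs(denom) < 1e-6:
                continue
            t = (normal @ (tri[0] - p0)) / denom
            inside = False
            if 0 <= t <= 1:
                x = p0 + t * (p1 - p0)
                m = np.column_stack([tri[1] - tri[0], tri[2] - tri[0]])
                uv, *_ = np.linalg.lstsq(m, x - tri[0], rcond=None)
                inside = uv[0] >= 0 and uv[1] >= 0 and uv.sum() <= 1
                # skip near-boundary cases where the tolerance conventions differ
                margin = min(abs(t), abs(1 - t), abs(uv[0]), abs(uv[1]), abs(1 - uv.sum()))
                if margin < 1e-6:
                    continue
            n_checked += 1
            assert segment_intersects_triangle(p0, p1, tri) == inside
        assert n_checked > 500


def _two_bead_system(d):
    """Probe bead and one single-residue 'protein' bead a distance d apart."""
    records = [
        AtomRecord(0, "C1", "C", 0, "ARAN", 0, SpeciesTag.AA, 0.0, 12.0),
        AtomRecord(1, "CA", "C", 1, "HEL", 1, SpeciesTag.PROTEIN, 0.0, 100.0),
    ]
    system = MolecularSystem(records)
    frame = Frame(np.array([[1.0, 1, 1], [1.0 + d, 1, 1]]), np.diag([20.0, 20, 20]))
    probe = LipidProbe(0, SpeciesTag.AA, 0, ((0,),), (0,))
    return system, frame, probe


@pytest.mark.parametrize("d,expected", [(0.49, True), (0.51, False)])
def test_contact_cutoff_is_strict(d, expected):
    system, frame, probe = _two_bead_system(d)
    assert in_contact(probe, {1}, frame, system, cutoff=0.5) is expected


def test_in_contact_agrees_with_all_pairs_brute_force(base_system, rng):
    from memwire.geometry import minimum_image_distance

    system = base_system.system
    frame = base_system.trajectory.frames[0]
    probes = probes_from_system(system, (SpeciesTag.AA,))
    helix_res = set(system.helices[0].residues)
    res_atoms = system.residue_atoms(helix_res)
    res_atoms = res_atoms[system.heavy_mask[res_atoms]]
    for probe in probes[:6]:
        expected = False
        for a in probe.heavy_atoms:
            for b in res_atoms:
                if minimum_image_distance(frame.coordinates[a], frame.coordinates[b], frame.box) < 0.5:
                    expected = True
        assert in_contact(probe, helix_res, frame, system, 0.5) == expected


class TestPlantedEventRecovery:
    @pytest.fixture(scope="class")
    @staticmethod
    def planted():
        sysd = generate_system(SyntheticSpec(seed=2, n_frames=70))
        layouts = [
            PlantedBindingEvent(0, "TM4/TM5", 5, 14, 1.2),   # 10 frames
            PlantedBindingEvent(1, "TM1/TM2", 20, 39, 1.2),  # 20 frames
            PlantedBindingEvent(2, "TM2/TM3", 35, 64, 1.25), # 30 frames
            PlantedBindingEvent(3, "TM5/TM6", 10, 19, 1.4),  # bound but not deep
            PlantedBindingEvent(4, "cavity", 50, 69, 0.8),   # open-ended cavity event
        ]
        for ev in layouts:
            plant_binding_event(sysd, ev)
        traj = sysd.trajectory
        sites = default_sites(traj.system, traj.frames[0])
        probes = probes_from_system(traj.system, (SpeciesTag.AA,))
        states = classify_trajectory(traj, sites, probes)
        events = extract_events(states, traj.frame_interval, n_frames=traj.n_frames)
        return sysd, traj, sites, probes, states, events, layouts

    def test_event_counts_sites_and_durations_match_planting(self, planted):
        sysd, traj, _, _, _, events, layouts = planted
        deep_layouts = [ev for ev in layouts if ev.planted_depth <= 1.3]
        assert len(events) == len(deep_layouts)
        by_site = {ev.site: ev for ev in events}
        for pl in deep_layouts:
            got = by_site[pl.site]
            assert (got.start_frame, got.end_frame) == (pl.start_frame, pl.end_frame)
            expected_ns = (pl.end_frame - pl.start_frame + 1) * 200.0 / 1000.0
            assert got.residence_ns == pytest.approx(expected_ns)
            assert got.min_head_depth == pytest.approx(pl.planted_depth, abs=1e-9)

    def test_shallow_event_is_bound_but_not_deep(self, planted):
        sysd, traj, _, _, states, _, _ = planted
        mol = traj.system.molecule_ids[sysd.layout.aa_atoms[3][0]]
        frames_states = [
            s for s in states if s.probe_id == mol and s.site == "TM5/TM6" and 10 <= s.frame_index <= 19
        ]
        assert all(s.bound for s in frames_states)
        assert not any(s.deep for s in frames_states)

    def test_open_ended_flag(self, planted):
        *_, events, _ = planted
        cavity = [ev for ev in events if ev.site == "cavity"]
        assert len(cavity) == 1 and cavity[0].open_ended
        assert all(not ev.open_ended for ev in events if ev.site != "cavity")

    def test_deep_cavity_hierarchy_on_all_states(self, planted):
        *_, states, _, _ = planted
        for st in states:
            if st.cavity_bound:
                assert st.deep
            if st.deep:
                assert st.head_depth <= 1.3 + 1e-9

    def test_classification_invariant_under_lattice_translation(self, planted):
        sysd, traj, sites, probes, states, _, _ = planted
        frame = traj.frames[7].copy()
        frame.coordinates = frame.coordinates + np.diag(frame.box)
        shifted = Trajectory(traj.system, [frame], traj.frame_interval)
        states1 = classify_trajectory(shifted, sites, probes)
        orig = [s for s in states if s.frame_index == 7]
        assert len(orig) == len(states1)
        for s0, s1 in zip(orig, states1):
            assert (s0.bound, s0.deep, s0.cavity_bound) == (s1.bound, s1.deep, s1.cavity_bound)
            assert s0.head_depth == pytest.approx(s1.head_depth, abs=1e-9)


def test_empty_state_series_gives_no_events():
    assert extract_events([], frame_interval=200.0) == []


def test_gap_tolerance_merges_interrupted_runs():
    from memwire.binding import BindingState

    def st(fi, deep):
        return BindingState(fi, 0, "TM1/TM2", deep, deep, False, 1.0)

    series = [st(i, i not in (3,)) for i in range(7)]
    assert len(extract_events(series, 200.0, gap_tolerance_frames=0, n_frames=7)) == 2
    assert len(extract_events(series, 200.0, gap_tolerance_frames=1, n_frames=7)) == 1


class TestContactFrequencies:
    def test_scripted_contacts_seven_of_ten(self):
        sysd = generate_system(SyntheticSpec(seed=3, n_frames=10))
        plant_binding_event(sysd, PlantedBindingEvent(0, "TM4/TM5", 0, 9, 1.2))
        traj = sysd.trajectory
        system = traj.system
        sites = default_sites(system, traj.frames[0])
        site = next(s for s in sites if s.site_id == "TM4/TM5")
        probes = probes_from_system(system, (SpeciesTag.AA,))
        probe = next(p for p in probes if p.molecule_id == system.molecule_ids[sysd.layout.aa_atoms[0][0]])
        # script a contact with a residue on a non-flanking helix (TM1) in 7 frames
        tm1_res = system.helices[0].residue_range[0]
        witness = system.residue_atoms([tm1_res])[0]
        head = probe.head_atom
        for fi in range(10):
            c = traj.frames[fi].coordinates
            if fi < 7:
                c[witness] = c[head] + np.array([0.0, 0.0, 0.3])
            else:
                c[witness] = c[head] + np.array([0.0, 0.0, 3.0])
        states = classify_trajectory(traj, [site], [probe])
        table = contact_frequencies(traj, states, probe, site)
        assert table.n_bound_frames == 10
        assert table.frequencies[tm1_res] == pytest.approx(0.7)

    def test_always_and_never_contacted_residues(self):
        sysd = generate_system(SyntheticSpec(seed=3, n_frames=6))
        plant_binding_event(sysd, PlantedBindingEvent(0, "TM4/TM5", 0, 5, 1.2))
        traj = sysd.trajectory
        system = traj.system
        site = next(s for s in default_sites(system, traj.frames[0]) if s.site_id == "TM4/TM5")
        probes = probes_from_system(system, (SpeciesTag.AA,))
        probe = next(p for p in probes if p.molecule_id == system.molecule_ids[sysd.layout.aa_atoms[0][0]])
        states = classify_trajectory(traj, [site], [probe])
        table = contact_frequencies(traj, states, probe, site)
        # the z=0 beads of TM4 and TM5 touch the planted gap-center bead every frame
        mid4 = (system.helices[3].residue_range[0] + system.helices[3].residue_range[1]) // 2
        assert table.frequencies[mid4] == 1.0
        far = system.helices[0].residue_range[0]  # TM1 end, far from the site
        assert table.frequencies[far] == 0.0
        assert all(0.0 <= f <= 1.0 for f in table.frequencies.values())

    def test_frequencies_monotone_in_cutoff(self):
        sysd = generate_system(SyntheticSpec(seed=3, n_frames=4))
        plant_binding_event(sysd, PlantedBindingEvent(0, "TM4/TM5", 0, 3, 1.2))
        traj = sysd.trajectory
        system = traj.system
        site = next(s for s in default_sites(system, traj.frames[0]) if s.site_id == "TM4/TM5")
        probes = probes_from_system(system, (SpeciesTag.AA,))
        probe = next(p for p in probes if p.molecule_id == system.molecule_ids[sysd.layout.aa_atoms[0][0]])
        states = classify_trajectory(traj, [site], [probe])
        t_small = contact_frequencies(traj, states, probe, site, BindingConfig(contact_cutoff=0.45))
        t_big = contact_frequencies(traj, states, probe, site, BindingConfig(contact_cutoff=0.5))
        for r in t_big.frequencies:
            assert t_small.frequencies[r] <= t_big.frequencies[r] + 1e-12

    def test_zero_bound_frames_is_an_error(self, base_system):
        traj = base_system.trajectory
        system = traj.system
        sites = default_sites(system, traj.frames[0])
        probes = probes_from_system(system, (SpeciesTag.AA,))
        states = classify_trajectory(traj, sites[:1], probes[:1])
        assert not any(s.bound for s in states)
        with pytest.raises(ValueError, match="no bound frames"):
            contact_frequencies(traj, states, probes[0], sites[0])


class TestReplicateDivergence:
    def test_identical_trajectories_zero(self, base_system):
        traj = base_system.trajectory
        head = probes_from_system(traj.system, (SpeciesTag.AA,))[0].head_atom
        d, fp = replicate_divergence(traj, traj, head)
        assert np.allclose(d, 0.0)
        assert fp is None

    def test_linear_separation_first_passage(self):
        a = generate_system(SyntheticSpec(seed=6, n_frames=20))
        b = generate_system(SyntheticSpec(seed=6, n_frames=20))
        head = probes_from_system(a.system, (SpeciesTag.AA,))[0].head_atom
        for fi in range(20):
            b.trajectory.frames[fi].coordinates[head, 2] += 0.1 * fi  # 0.1 nm per frame
        d, fp = replicate_divergence(a.trajectory, b.trajectory, head, threshold=0.75)
        assert fp == 8  # 0.8 nm at frame 8 is the first distance > 0.75
        assert d[7] == pytest.approx(0.7, abs=1e-9)

    def test_mismatched_lengths_warn_and_use_prefix(self):
        a = generate_system(SyntheticSpec(seed=6, n_frames=5))
        b = generate_system(SyntheticSpec(seed=6, n_frames=3))
        head = probes_from_system(a.system, (SpeciesTag.AA,))[0].head_atom
        with pytest.warns(UserWarning, match="differ in length"):
            d, fp = replicate_divergence(a.trajectory, b.trajectory, head)
        assert len(d) == 3 and fp is None


class TestCardiolipinExcursions:
    def test_static_lipid_below_threshold_no_excursion(self):
        sysd = generate_system(SyntheticSpec(seed=8, n_frames=10, n_cardiolipin=2))
        intervals, furthest = cardiolipin_excursions(sysd.trajectory, lateral_threshold=3.0)
        assert all(runs == [] for runs in intervals.values())
        assert np.all(furthest < 3.0)

    def test_scripted_excursion_recovered(self):
        sysd = generate_system(SyntheticSpec(seed=8, n_frames=80, n_cardiolipin=1))
        traj = sysd.trajectory
        cl = traj.system.species_indices(SpeciesTag.CARDIOLIPIN)
        com = sysd.layout.com
        # push the lipid out to ~3.56 nm laterally for 50 frames, staying under
        # half the box length along each axis so the distance is expressible
        d = np.hypot(2.8, 2.2)
        for fi in range(20, 70):
            c = traj.frames[fi].coordinates
            c[cl, 0] = com[0] + 2.8
            c[cl, 1] = com[1] + 2.2
        intervals, furthest = cardiolipin_excursions(traj, lateral_threshold=3.0)
        (runs,) = intervals.values()
        assert runs == [(20, 69)]
        assert furthest[25] == pytest.approx(d, abs=0.05)
        assert furthest.max() == pytest.approx(d, abs=0.05)


def test_degenerate_triangle_raises(base_system):
    system = base_system.system
    frame = base_system.trajectory.frames[0].copy()
    site = default_sites(system, frame)[0]
    a = site.triangle_anchors[0]
    frame.coordinates[list(a)] = frame.coordinates[a[0]]  # collapse the triangle
    with pytest.raises(ValueError, match="degenerate"):
        tail_intersects_surface(np.zeros((2, 3)), site, frame)
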