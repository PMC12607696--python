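"""Water-wire detection: minimax-path optimality, selection, recovery."""

import math

import networkx as nx
import numpy as np
import pytest

from memwire.model import AtomRecord, Frame, MolecularSystem, SpeciesTag
from memwire.synthetic import PlantedWireSchedule, SyntheticSpec, generate_system, plant_wire_schedule
from memwire.wires import (
    GapGraph,
    WaterWire,
    WireSearchConfig,
    analyze_frame,
    assign_unit,
    build_gap_graph,
    classify_and_summarize,
    minimax_path,
    select_bulk_endpoints,
    select_cylinder_oxygens,
)

BIGBOX = np.diag([50.0, 50.0, 50.0])


def water_system(n, protein_at=None):
    records = []
    i = 0
    if protein_at is not None:
        records.append(AtomRecord(0, "CA", "C", 0, "HEL", 0, SpeciesTag.PROTEIN, 0.0, 100.0))
        i = 1
    for k in range(n):
        records.append(AtomRecord(i, "O", "O", i, "HOH", i, SpeciesTag.WATER, 0.0, 18.0))
        i += 1
    return MolecularSystem(records)


def graph_from_points(points, box, cutoff=1.0):
    frame = Frame(np.asarray(points, dtype=float), box)
    return build_gap_graph(np.arange(len(points)), frame, WireSearchConfig(graph_cutoff=cutoff)), frame


def brute_minimax(graph: GapGraph, source: int, sink: int) -> float:
    g = nx.Graph()
    g.add_nodes_from(range(graph.n_nodes))
    pos = {int(a): i for i, a in enumerate(graph.nodes)}
    for (i, j), w in zip(graph.edges, graph.weights):
        g.add_edge(int(i), int(j), weight=float(w))
    s, t = pos[source], pos[sink]
    best = math.inf
    if nx.has_path(g, s, t):
        for path in nx.all_simple_paths(g, s, t):
            best = min(best, max(g[u][v]["weight"] for u, v in zip(path, path[1:])))
    return best


class TestMinimaxPath:
    def test_collinear_four_waters(self):
        pts = [[25, 25, 25.0], [25, 25, 25.30], [25, 25, 25.62], [25, 25, 25.90]]
        graph, _ = graph_from_points(pts, BIGBOX)
        wire = minimax_path(graph, 0, 3)
        assert wire.max_gap == pytest.approx(0.32, abs=1e-12)
        assert wire.max_gap <= 0.33  # wire formed at the default threshold
        assert wire.path == [0, 1, 2, 3]
        assert wire.constriction_edge == (1, 2)

    def test_single_midpoint_gap_half_nm(self):
        pts = [[25, 25, 25.0], [25, 25, 25.5], [25, 25, 26.0]]
        graph, _ = graph_from_points(pts, BIGBOX)
        wire = minimax_path(graph, 0, 2)
        assert wire.max_gap == pytest.approx(0.5, abs=1e-12)
        assert wire.max_gap > 0.33

    def test_source_equals_sink(self):
        graph, _ = graph_from_points([[1, 1, 1.0], [1, 1, 1.4]], BIGBOX)
        wire = minimax_path(graph, 0, 0)
        assert wire.max_gap == 0.0 and wire.path == [0]

    def test_disconnected_gives_infinity(self):
        pts = [[1, 1, 1.0], [1, 1, 1.3], [1, 1, 5.0], [1, 1, 5.3]]
        graph, _ = graph_from_points(pts, BIGBOX)
        wire = minimax_path(graph, 0, 3)
        assert math.isinf(wire.max_gap) and wire.path == []

    def test_mst_path_equals_brute_force_on_random_graphs(self, rng):
        """MST-path max edge == exhaustive all-simple-paths minimax, exactly."""
        for trial in range(120):
            n = int(rng.integers(2, 13))
            nodes = np.arange(n)
            edges, weights = [], []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.45:
                        edges.append((i, j))
                        # quantized weights make ties common
                        weights.append(round(float(rng.uniform(0.1, 1.0)), 1))
            graph = GapGraph(nodes, np.array(edges).reshape(-1, 2), np.array(weights))
            s, t = rng.choice(n, size=2, replace=False)
            wire = minimax_path(graph, int(s), int(t))
            assert wire.max_gap == brute_minimax(graph, int(s), int(t))

    def test_tie_invariance_under_node_relabeling(self, rng):
        for _ in range(20):
            n = 8
            edges, weights = [], []
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.5:
                        edges.append((i, j))
                        weights.append(float(rng.choice([0.2, 0.3, 0.3, 0.3, 0.5])))
            if not edges:
                continue
            graph = GapGraph(np.arange(n), np.array(edges), np.array(weights))
            w0 = minimax_path(graph, 0, n - 1).max_gap
            perm = rng.permutation(n)
            inv = np.argsort(perm)
            pedges = np.sort(perm[np.array(edges)], axis=1)
            order = rng.permutation(len(pedges))
            graph2 = GapGraph(np.arange(n), pedges[order], np.array(weights)[order])
            w1 = minimax_path(graph2, int(perm[0]), int(perm[n - 1])).max_gap
            assert w0 == w1

    def test_adding_a_node_never_increases_max_gap(self, rng):
        pts = rng.uniform(20, 24, size=(15, 3))
        graph, _ = graph_from_points(pts, BIGBOX)
        base = minimax_path(graph, 0, 1).max_gap
        for _ in range(10):
            extra = np.vstack([pts, rng.uniform(20, 24, size=(1, 3))])
            g2, _ = graph_from_points(extra, BIGBOX)
            assert minimax_path(g2, 0, 1).max_gap <= base + 1e-12

    def test_deleting_constriction_water_increases_gap_on_single_file(self):
        z = np.arange(0, 2.01, 0.25)
        pts = np.column_stack([np.full_like(z, 25.0), np.full_like(z, 25.0), 25 + z])
        graph, _ = graph_from_points(pts, BIGBOX)
        wire = minimax_path(graph, 0, len(z) - 1)
        assert wire.max_gap == pytest.approx(0.25)
        mid = len(z) // 2
        pts2 = np.delete(pts, mid, axis=0)
        g2, _ = graph_from_points(pts2, BIGBOX)
        wire2 = minimax_path(g2, 0, len(z) - 2)
        assert wire2.max_gap > wire.max_gap


class TestSelection:
    def test_cylinder_boundary(self):
        system = water_system(3, protein_at=True)
        coords = np.array([
            [25.0, 25.0, 25.0],  # protein bead -> COM
            [25.0, 25.0, 25.0],  # water on the axis at COM z
            [25.0 + 1.51, 25.0, 25.0],  # just outside the radius
            [25.0, 25.0, 25.0 + 3.5],  # beyond the z half-length
        ])
        frame = Frame(coords, BIGBOX)
        cfg = WireSearchConfig(cylinder_radius=1.5, cylinder_z_halflength=3.4)
        sel = select_cylinder_oxygens(frame, system, cfg)
        assert list(sel) == [1]

    def test_cylinder_equals_brute_force_filter(self, base_system):
        from memwire.geometry import center_of_mass, lateral_distance

        traj, system = base_system.trajectory, base_system.system
        frame = traj.frames[0]
        cfg = WireSearchConfig()
        sel = set(select_cylinder_oxygens(frame, system, cfg))
        com = center_of_mass(system.protein_atom_set, frame.coordinates, system.masses)
        expected = set()
        cands = list(system.water_oxygen_indices())
        aa = system.species_indices(SpeciesTag.AA)
        cands += [int(a) for a in aa if system.names[a].upper().startswith("O")]
        for a in cands:
            p = frame.coordinates[a]
            if (
                lateral_distance(p, com, frame.box) <= cfg.cylinder_radius
                and abs(p[2] - com[2]) <= cfg.cylinder_z_halflength
            ):
                expected.add(int(a))
        assert sel == expected

    def test_bulk_endpoints_axis_nearest(self):
        system = water_system(5, protein_at=True)
        coords = np.array([
            [25.0, 25.0, 25.0],  # protein
            [25.2, 25.0, 27.8],  # top bulk, lateral 0.2  <- expected source
            [25.5, 25.0, 27.9],  # top bulk, lateral 0.5
            [25.1, 25.0, 22.2],  # bottom bulk, lateral 0.1 <- expected sink
            [24.0, 25.0, 22.1],  # bottom bulk, lateral 1.0
            [25.0, 25.0, 25.5],  # inside the membrane span
        ])
        frame = Frame(coords, BIGBOX)
        cfg = WireSearchConfig()
        nodes = np.arange(1, 6)
        src, snk = select_bulk_endpoints(frame, nodes, system, cfg)
        assert (src, snk) == (1, 3)

    def test_no_bulk_water_flags_unconnectable(self):
        system = water_system(2, protein_at=True)
        coords = np.array([[25.0, 25, 25], [25.0, 25, 25.5], [25.0, 25, 24.5]])
        frame = Frame(coords, BIGBOX)
        assert select_bulk_endpoints(frame, np.arange(1, 3), system, WireSearchConfig()) is None
        wire = analyze_frame(frame, system, WireSearchConfig())
        assert math.isinf(wire.max_gap)


class TestRecovery:
    def test_bernoulli_schedule_recovered_exactly(self):
        sysd = generate_system(SyntheticSpec(seed=9, n_frames=60))
        sched = PlantedWireSchedule.bernoulli(60, 0.4, seed=13)
        traj, record = plant_wire_schedule(sysd, sched)
        stats = classify_and_summarize(traj)
        assert stats.formation_frequency == record["realized_fraction"]
        assert np.array_equal(stats.formed, np.array(record["present"]))
        expected_lifetimes = np.array(record["run_lengths"], dtype=float) * 200.0 / 1000.0
        assert np.array_equal(stats.lifetimes_ns, expected_lifetimes)

    def test_all_present_respects_planted_spacing(self):
        sysd = generate_system(SyntheticSpec(seed=9, n_frames=5))
        traj, record = plant_wire_schedule(sysd, PlantedWireSchedule([True] * 5, 0.30))
        stats = classify_and_summarize(traj)
        assert np.all(stats.max_gaps <= 0.30 + 1e-12)
        assert stats.formation_frequency == 1.0

    def test_all_absent_frequency_zero(self):
        sysd = generate_system(SyntheticSpec(seed=9, n_frames=5))
        plant_wire_schedule(sysd, PlantedWireSchedule([False] * 5, 0.30, 0.50))
        stats = classify_and_summarize(sysd.trajectory)
        assert stats.formation_frequency == 0.0
        assert len(stats.lifetimes_ns) == 0
        assert np.all(stats.max_gaps >= 0.50 - 1e-12)

    def test_three_consecutive_frames_one_lifetime(self):
        sysd = generate_system(SyntheticSpec(seed=9, n_frames=5))
        plant_wire_schedule(sysd, PlantedWireSchedule([False, True, True, True, False]))
        stats = classify_and_summarize(sysd.trajectory)
        assert np.array_equal(stats.lifetimes_ns, [0.6])  # 3 x 200 ps

    def test_pbc_translation_leaves_statistics_unchanged(self):
        sysd = generate_system(SyntheticSpec(seed=9, n_frames=6))
        sched = PlantedWireSchedule.bernoulli(6, 0.5, seed=1)
        plant_wire_schedule(sysd, sched)
        stats0 = classify_and_summarize(sysd.trajectory)
        for f in sysd.trajectory.frames:
            f.coordinates += np.diag(f.box)  # one full lattice vector in each direction
        stats1 = classify_and_summarize(sysd.trajectory)
        assert np.allclose(stats0.max_gaps, stats1.max_gaps)
        assert np.array_equal(stats0.formed, stats1.formed)


class TestUnitAssignment:
    def test_planted_channel_assigned_to_its_helix_pair(self):
        sysd = generate_system(SyntheticSpec(seed=9, n_frames=3))
        plant_wire_schedule(sysd, PlantedWireSchedule([True] * 3), helix_pair=("TM4", "TM5"))
        stats = classify_and_summarize(sysd.trajectory)
        assert all(u == "TM4/TM5" for u in stats.units)

    def test_two_concurrent_channels_counts_sum(self):
        sysd = generate_system(SyntheticSpec(seed=9, n_frames=10))
        plant_wire_schedule(
            sysd, PlantedWireSchedule([True] * 5 + [False] * 5), helix_pair=("TM2", "TM3")
        )
        plant_wire_schedule(
            sysd, PlantedWireSchedule([False] * 5 + [True] * 5), helix_pair=("TM6", "TM1")
        )
        stats = classify_and_summarize(sysd.trajectory)
        assert stats.unit_counts == {"TM2/TM3": 5, "TM6/TM1": 5}
        assert stats.formation_frequency == 1.0

    def test_constriction_on_axis_labeled_cavity(self, base_system):
        traj, system = base_system.trajectory, base_system.system
        frame = traj.frames[0].copy()
        w = system.water_oxygen_indices()[:2]
        com = np.array([3.0, 3.0, 3.5])
        frame.coordinates[w[0]] = com + [0.0, 0.0, 0.15]
        frame.coordinates[w[1]] = com - [0.0, 0.0, 0.15]
        wire = WaterWire(0, [int(w[0]), int(w[1])], np.array([0.3]), 0.3,
                         constriction_edge=(int(w[0]), int(w[1])))
        assert assign_unit(wire, system, frame) == "cavity-axis"


def test_kinked_channel_still_detected():
    sysd = generate_system(SyntheticSpec(seed=9, n_frames=2))
    traj, rec = plant_wire_schedule(sysd, PlantedWireSchedule([True, True]), kink_lateral=0.4)
    stats = classify_and_summarize(traj)
    assert stats.formation_frequency == 1.0


def test_config_validation():
    with pytest.raises(ValueError):
        WireSearchConfig(gap_threshold=1.5, graph_cutoff=1.0)
    with pytest.raises(ValueError):
        WireSearchConfig(cylinder_z_halflength=1.0)
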