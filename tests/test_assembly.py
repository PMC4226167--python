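import numpy as np
import pytest
from scipy.stats import chisquare

from densecon.assembly import (
    AssemblyError,
    CellTypeSpec,
    MorphologyLibrary,
    MorphologyRecord,
    assign_cell_type,
    build_network,
    expected_soma_count,
    sample_somata,
    select_axon,
    select_dendrite,
    upscale_long_range,
)
from densecon.fixtures import make_morphology
from densecon.morphology import apply_transform
from densecon.reference_frame import VoxelGrid


def _one_voxel_grid():
    return VoxelGrid(origin=np.zeros(3), spacing=50.0, dims=(1, 1, 1))


class TestSampleSomata:
    @pytest.mark.parametrize("density,expected", [
        (8.0, 1),    # 8000 / mm^3 * 1.25e-4 mm^3 = 1
        (19.2, 2),   # 2.4 rounds half-up to 2
        (0.0, 0),
    ])
    def test_per_voxel_rounding(self, density, expected):
        grid = _one_voxel_grid()
        pts = sample_somata(np.full((1, 1, 1), density), grid,
                            np.random.default_rng(0))
        assert len(pts) == expected

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            sample_somata(np.full((1, 1, 1), -1.0), _one_voxel_grid(),
                          np.random.default_rng(0))

    def test_positions_inside_their_voxel(self):
        grid = VoxelGrid(origin=np.array([10.0, 20.0, 30.0]), spacing=50.0,
                         dims=(2, 2, 2))
        density = np.full((2, 2, 2), 80.0)  # 10 somata per voxel
        pts = sample_somata(density, grid, np.random.default_rng(1))
        assert len(pts) == 80
        for p in pts:
            assert grid.contains(p)

    def test_reproducible_under_fixed_seed(self):
        grid = _one_voxel_grid()
        d = np.full((1, 1, 1), 160.0)
        a = sample_somata(d, grid, np.random.default_rng(5))
        b = sample_somata(d, grid, np.random.default_rng(5))
        np.testing.assert_array_equal(a, b)

    def test_total_count_matches_rounded_density_sum(self):
        rng = np.random.default_rng(2)
        grid = VoxelGrid(origin=np.zeros(3), spacing=50.0, dims=(4, 4, 4))
        density = rng.random((4, 4, 4)) * 40.0
        pts = sample_somata(density, grid, rng)
        assert len(pts) == expected_soma_count(density, grid)

    def test_within_voxel_uniformity_by_octant(self):
        """Chi-square on the 8 octants of a single voxel at alpha = 0.01."""
        grid = _one_voxel_grid()
        pts = sample_somata(np.full((1, 1, 1), 32768.0), grid,
                            np.random.default_rng(3))  # 4096 somata
        octant = ((pts >= 25.0).astype(int) * [1, 2, 4]).sum(axis=1)
        counts = np.bincount(octant, minlength=8)
        assert chisquare(counts).pvalue > 0.01


class TestAssignCellType:
    def test_single_eligible_type_is_certain(self, toy_bundle):
        frame = toy_bundle.frame
        # inhibitory class has a single type everywhere
        name = assign_cell_type([30.0, 30.0, 100.0], frame,
                                toy_bundle.frequencies, toy_bundle.cell_types,
                                np.random.default_rng(0), excitatory=False)
        assert name == "INH"

    def test_column_only_type_never_in_septum(self, toy_bundle):
        frame = toy_bundle.frame
        p = np.array([10.0, 10.0, 100.0])  # far from both column axes
        _, inside = __import__("densecon").reference_frame.nearest_column(
            p, frame)
        assert not inside
        rng = np.random.default_rng(0)
        for _ in range(50):
            name = assign_cell_type(p, frame, toy_bundle.frequencies,
                                    toy_bundle.cell_types, rng,
                                    excitatory=True)
            assert name == "EXC"  # L4SS is column-only

    def test_frequencies_respected_within_binomial_bounds(self, toy_bundle):
        frame = toy_bundle.frame
        p = frame.columns[0].center  # inside: EXC/L4SS at 0.5/0.5
        rng = np.random.default_rng(4)
        n = 20000
        draws = sum(
            assign_cell_type(p, frame, toy_bundle.frequencies,
                             toy_bundle.cell_types, rng,
                             excitatory=True) == "EXC"
            for _ in range(n)
        )
        sigma = np.sqrt(0.5 * 0.5 / n)
        assert abs(draws / n - 0.5) < 3 * sigma


def _library_at_depths(frame, cell_type, depths, rng, polar=False):
    col = frame.columns[0]
    records = []
    for k, depth in enumerate(depths):
        s = col.top_depth + depth
        soma = col.center + s * col.axis + np.array([30.0, 0.0, 0.0])
        kind = "polar_dendrite" if polar else "dendrite"
        bearing = col.center - soma if polar else None
        m = make_morphology(rng, kind, soma, polar_bearing=bearing)
        records.append(MorphologyRecord(
            morphology_id=f"{cell_type}_{k}", morphology=m,
            cell_type=cell_type, column_id=col.id, soma_depth=depth))
    return MorphologyLibrary(records)


class TestSelectDendrite:
    def test_single_candidate_at_same_depth_selected(self, simple_frame):
        rng = np.random.default_rng(0)
        lib = _library_at_depths(simple_frame, "T", [100.0], rng)
        spec = CellTypeSpec(name="T", excitatory=True)
        p = simple_frame.columns[0].center + np.array([10.0, 0.0, -100.0])
        # p depth = 100 um (center sits at depth 200)
        mid, transform = select_dendrite(p, "T", lib, simple_frame,
                                         np.random.default_rng(1), spec)
        assert mid == "T_0"
        placed = apply_transform(lib[mid].morphology, transform)
        np.testing.assert_allclose(placed.soma_position, p, atol=1e-6)

    def test_candidate_beyond_one_voxel_depth_excluded(self, simple_frame):
        rng = np.random.default_rng(0)
        lib = _library_at_depths(simple_frame, "T", [100.0], rng)
        spec = CellTypeSpec(name="T", excitatory=True)
        p = simple_frame.columns[0].center + np.array([10.0, 0.0, -25.0])
        # new depth 175, candidate at 100: |dz| = 75 > spacing 50
        with pytest.raises(AssemblyError, match="depth"):
            select_dendrite(p, "T", lib, simple_frame,
                            np.random.default_rng(1), spec)

    def test_polar_rotation_preserves_center_bearing(self, simple_frame):
        rng = np.random.default_rng(2)
        lib = _library_at_depths(simple_frame, "P", [150.0], rng, polar=True)
        spec = CellTypeSpec(name="P", excitatory=True, rotate_polar=True)
        col = simple_frame.columns[0]
        p = col.center + np.array([0.0, 60.0, -50.0])  # depth 150, new azimuth
        mid, transform = select_dendrite(p, "P", lib, simple_frame,
                                         np.random.default_rng(3), spec)
        orig = lib[mid].morphology
        placed = apply_transform(orig, transform)

        def rel_azimuth(m, soma):
            com = m.positions[m.labels == "basal"].mean(axis=0)
            b_com = (com - soma)[:2]
            b_ctr = (col.center - soma)[:2]
            ang = np.arctan2(b_com[1], b_com[0]) - np.arctan2(b_ctr[1],
                                                              b_ctr[0])
            return (ang + np.pi) % (2 * np.pi) - np.pi

        assert rel_azimuth(placed, p) == pytest.approx(
            rel_azimuth(orig, orig.soma_position), abs=1e-6)


class TestSelectAxon:
    def test_single_candidate_geometry_untouched(self, simple_frame):
        rng = np.random.default_rng(0)
        lib = _library_at_depths(simple_frame, "T", [100.0], rng)
        p = simple_frame.columns[0].center
        mid = select_axon(p, "T", lib, simple_frame, np.random.default_rng(1))
        assert mid == "T_0"
        # selection returns the library id; geometry is shared, not copied
        assert lib[mid].morphology is lib["T_0"].morphology

    def test_no_depth_criterion_for_axons(self, simple_frame):
        """An axon registered far from the soma depth is still eligible."""
        rng = np.random.default_rng(0)
        lib = _library_at_depths(simple_frame, "T", [350.0], rng)
        p = simple_frame.columns[0].center + np.array([0.0, 0.0, -190.0])
        assert select_axon(p, "T", lib, simple_frame,
                           np.random.default_rng(1)) == "T_0"

    def test_other_column_candidates_excluded(self, simple_frame):
        rng = np.random.default_rng(0)
        lib = _library_at_depths(simple_frame, "T", [100.0], rng)  # col A
        p = simple_frame.columns[1].center  # nearest column is B
        with pytest.raises(AssemblyError):
            select_axon(p, "T", lib, simple_frame, np.random.default_rng(1))

    def test_deterministic_under_seed(self, simple_frame):
        rng = np.random.default_rng(0)
        lib = _library_at_depths(simple_frame, "T", [100.0, 100.0], rng)
        p = simple_frame.columns[0].center
        picks = {select_axon(p, "T", lib, simple_frame,
                             np.random.default_rng(9)) for _ in range(5)}
        assert len(picks) == 1


class TestUpscaleLongRange:
    def test_round_robin_multiplicities_differ_by_at_most_one(
            self, simple_frame):
        rng = np.random.default_rng(0)
        lib = _library_at_depths(simple_frame, "LR", [100.0] * 14, rng)
        ids = upscale_long_range("LR", lib, 311, np.random.default_rng(1))
        assert len(ids) == 311
        counts = {i: ids.count(i) for i in set(ids)}
        assert set(counts.values()) == {22, 23}  # 311 = 14*22 + 3

    def test_count_equal_to_library_uses_each_once(self, simple_frame):
        rng = np.random.default_rng(0)
        lib = _library_at_depths(simple_frame, "LR", [100.0] * 5, rng)
        ids = upscale_long_range("LR", lib, 5, np.random.default_rng(1))
        assert sorted(ids) == sorted(r.morphology_id for r in lib.records)

    def test_single_member_library_duplicates(self, simple_frame):
        rng = np.random.default_rng(0)
        lib = _library_at_depths(simple_frame, "LR", [100.0], rng)
        ids = upscale_long_range("LR", lib, 5, np.random.default_rng(1))
        assert ids == ["LR_0"] * 5


class TestBuildNetwork:
    def test_soma_count_conservation(self, toy_bundle, toy_network):
        expected = (
            expected_soma_count(toy_bundle.excitatory_density,
                                toy_bundle.frame.grid)
            + expected_soma_count(toy_bundle.inhibitory_density,
                                  toy_bundle.frame.grid)
        )
        local = [n for n in toy_network.neurons if n.cell_type != "TC"]
        assert len(local) == expected

    def test_long_range_count_per_column(self, toy_bundle, toy_network):
        tc = [n for n in toy_network.neurons if n.cell_type == "TC"]
        per_col = {}
        for n in tc:
            per_col[n.column_id] = per_col.get(n.column_id, 0) + 1
        count = toy_bundle.cell_types["TC"].long_range_count
        assert all(v == count for v in per_col.values())

    def test_same_seed_reproduces_network(self, toy_bundle):
        a = build_network(toy_bundle, seed=11)
        b = build_network(toy_bundle, seed=11)
        assert len(a.neurons) == len(b.neurons)
        for na, nb in zip(a.neurons, b.neurons):
            np.testing.assert_array_equal(na.soma_position, nb.soma_position)
            assert (na.cell_type, na.dendrite_morphology,
                    na.axon_morphology) == \
                   (nb.cell_type, nb.dendrite_morphology, nb.axon_morphology)

    def test_depth_criterion_audit(self, toy_bundle, toy_network):
        """Every placed dendrite's registered depth is within one voxel of
        its new soma depth."""
        spacing = toy_bundle.frame.grid.spacing
        for n in toy_network.neurons:
            if n.dendrite_morphology is None:
                continue
            rec = toy_bundle.library[n.dendrite_morphology]
            col = toy_bundle.frame.column(n.column_id)
            new_depth = col.depth_from_pia(n.soma_position)
            assert abs(rec.soma_depth - new_depth) <= spacing + 1e-9

    def test_dendrite_measurements_invariant_under_assembly(
            self, toy_bundle, toy_network):
        from densecon.morphology import branch_length_by_label
        for n in toy_network.neurons[:25]:
            if n.dendrite_morphology is None:
                continue
            placed = toy_network.dendrite_geometry(n.id)
            original = toy_bundle.library[n.dendrite_morphology].morphology
            for label in ("basal", "apical"):
                assert branch_length_by_label(placed, label) == pytest.approx(
                    branch_length_by_label(original, label), rel=1e-6)

    def test_missing_morphologies_fail_with_stage_context(self, toy_bundle):
        from densecon.assembly import NetworkSpecification
        # drop every EXC reconstruction: selection must fail loudly
        lib = MorphologyLibrary(
            [r for r in toy_bundle.library.records if r.cell_type != "EXC"])
        spec = NetworkSpecification(
            frame=toy_bundle.frame,
            excitatory_density=toy_bundle.excitatory_density,
            inhibitory_density=toy_bundle.inhibitory_density,
            cell_types=toy_bundle.cell_types,
            frequencies=toy_bundle.frequencies, library=lib)
        with pytest.raises(AssemblyError, match="neuron"):
            build_network(spec, seed=0)
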