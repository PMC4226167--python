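import numpy as np
import pytest

from densecon.assembly import CellTypeSpec
from densecon.density_fields import (
    ConfigurationError,
    DensityField,
    FitError,
    MetaConnectivity,
    bouton_field,
    clip_to_voxels,
    fit_alpha_profiles,
    fit_surface_pst,
    pst_field,
)
from densecon.fixtures import FixtureConfig, make_morphology
from densecon.morphology import Morphology, branch_length_by_label, \
    surface_area_by_label
from densecon.reference_frame import VoxelGrid


def _grid(dims=(4, 4, 4), spacing=50.0):
    return VoxelGrid(origin=np.zeros(3), spacing=spacing, dims=dims)


def _segment(p0, p1, r0=0.5, r1=0.5, label="axon"):
    return Morphology(
        positions=np.array([p0, p1], dtype=float),
        radii=np.array([r0, r1]),
        labels=np.array([label, label], dtype=object),
        parents=np.array([-1, 0]),
    )


class TestClipping:
    def test_straight_axon_split_evenly_across_two_voxels(self):
        m = _segment([0.0, 10.0, 10.0], [100.0, 10.0, 10.0])
        length, _ = clip_to_voxels(m, "axon", _grid())
        assert length.get((0, 0, 0)) == pytest.approx(50.0)
        assert length.get((1, 0, 0)) == pytest.approx(50.0)
        assert length.total() == pytest.approx(100.0)

    def test_oblique_segment_conserves_length_and_area(self):
        m = _segment([10.0, 20.0, 30.0], [180.0, 160.0, 140.0], 1.0, 0.2)
        length, area = clip_to_voxels(m, "axon", _grid())
        assert length.total() == pytest.approx(
            branch_length_by_label(m, "axon"), rel=1e-9)
        assert area.total() == pytest.approx(
            surface_area_by_label(m, "axon"), rel=1e-9)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_morphology_conservation(self, seed):
        rng = np.random.default_rng(seed)
        cfg = FixtureConfig()
        m = make_morphology(rng, "dendrite", [200.0, 200.0, 200.0], cfg=cfg)
        grid = _grid((8, 8, 8))
        for label in ("basal", "apical"):
            length, area = clip_to_voxels(m, label, grid)
            assert length.total() == pytest.approx(
                branch_length_by_label(m, label), rel=1e-6)
            assert area.total() == pytest.approx(
                surface_area_by_label(m, label), rel=1e-6)

    def test_per_voxel_agreement_with_resampling_oracle(self):
        """Densely resampled segments binned by midpoint must reproduce the
        exact clipped per-voxel lengths within 0.1%."""
        rng = np.random.default_rng(21)
        m = make_morphology(rng, "axon", [200.0, 200.0, 200.0],
                            total_length=300.0)
        grid = _grid((8, 8, 8))
        length, _ = clip_to_voxels(m, "axon", grid)
        oracle = np.zeros(grid.dims)
        step = 0.01
        for child in m.edges:
            if m.labels[child] != "axon":
                continue
            p0 = m.positions[m.parents[child]]
            p1 = m.positions[child]
            seglen = np.linalg.norm(p1 - p0)
            n = max(1, int(np.ceil(seglen / step)))
            ts = (np.arange(n) + 0.5) / n
            mids = p0[None, :] + ts[:, None] * (p1 - p0)[None, :]
            for mid in mids:
                if grid.contains(mid):
                    oracle[grid.point_to_voxel(mid)] += seglen / n
        for idx, v in length.items():
            assert v == pytest.approx(oracle[idx], rel=1e-3, abs=1e-3)

    def test_single_node_soma_contributes_sphere_to_its_voxel(self):
        m = Morphology(
            positions=np.array([[30.0, 30.0, 30.0]]), radii=np.array([5.0]),
            labels=np.array(["soma"], dtype=object), parents=np.array([-1]),
        )
        length, area = clip_to_voxels(m, "soma", _grid())
        assert length.total() == 0.0
        assert area.get((0, 0, 0)) == pytest.approx(4 * np.pi * 25.0)


class TestBoutonField:
    def _spec(self, densities):
        return CellTypeSpec(name="T", excitatory=True,
                            bouton_density_per_zone=densities)

    def test_length_times_zone_density(self, simple_frame):
        f = DensityField(simple_frame.grid, {(2, 4, 2): 30.0})  # z=125, granular
        spec = self._spec({"supragranular": 0.1, "granular": 0.2,
                           "infragranular": 0.3})
        out = bouton_field(f, spec, simple_frame)
        assert out.get((2, 4, 2)) == pytest.approx(6.0)

    def test_zero_length_gives_zero_boutons(self, simple_frame):
        out = bouton_field(DensityField(simple_frame.grid),
                           self._spec({"granular": 0.2}), simple_frame)
        assert out.total() == 0.0

    def test_axon_spanning_two_zones_uses_both_densities(self, simple_frame):
        f = DensityField(simple_frame.grid,
                         {(2, 4, 1): 40.0,    # z=75, supragranular
                          (2, 4, 2): 30.0})   # z=125, granular
        spec = self._spec({"supragranular": 0.1, "granular": 0.3,
                           "infragranular": 0.0})
        out = bouton_field(f, spec, simple_frame)
        assert out.get((2, 4, 1)) == pytest.approx(4.0)
        assert out.get((2, 4, 2)) == pytest.approx(9.0)

    def test_missing_zone_density_is_configuration_error(self, simple_frame):
        f = DensityField(simple_frame.grid, {(2, 4, 2): 30.0})
        with pytest.raises(ConfigurationError, match="granular"):
            bouton_field(f, self._spec({"supragranular": 0.1}), simple_frame)


class TestPSTField:
    def test_length_psts(self):
        grid = _grid()
        meta = MetaConnectivity({("A", "B", "basal"): (1.0, 0.0)})
        fields = {"basal": (DensityField(grid, {(0, 0, 0): 523.0}),
                            DensityField(grid))}
        out = pst_field(fields, "A", "B", meta)
        assert out.get((0, 0, 0)) == pytest.approx(523.0)

    def test_surface_psts(self):
        grid = _grid()
        meta = MetaConnectivity({("A", "B", "soma"): (0.0, 0.4)})
        fields = {"soma": (DensityField(grid),
                           DensityField(grid, {(1, 1, 1): 100.0}))}
        out = pst_field(fields, "A", "B", meta)
        assert out.get((1, 1, 1)) == pytest.approx(40.0)

    def test_mixed_labels_match_per_label_sum(self):
        grid = _grid()
        rng = np.random.default_rng(5)
        meta = MetaConnectivity({
            ("A", "B", "basal"): (1.1, 0.2),
            ("A", "B", "apical"): (0.7, 0.0),
            ("A", "B", "soma"): (0.0, 0.4),
        })
        fields = {}
        for label in ("basal", "apical", "soma"):
            lf = DensityField(grid, {(0, 0, 0): rng.random() * 100,
                                     (1, 0, 0): rng.random() * 100})
            af = DensityField(grid, {(0, 0, 0): rng.random() * 100})
            fields[label] = (lf, af)
        out = pst_field(fields, "A", "B", meta)
        for idx in [(0, 0, 0), (1, 0, 0)]:
            expected = 0.0
            for label, (lf, af) in fields.items():
                lam, alpha = meta.entries[("A", "B", label)]
                expected += lam * lf.get(idx) + alpha * af.get(idx)
            assert out.get(idx) == pytest.approx(expected, rel=1e-12)

    def test_absent_meta_entry_contributes_nothing(self):
        grid = _grid()
        fields = {"apical": (DensityField(grid, {(0, 0, 0): 100.0}),
                             DensityField(grid))}
        out = pst_field(fields, "A", "B", MetaConnectivity({}))
        assert out.total() == 0.0

    def test_bilinearity_in_lambda(self):
        grid = _grid()
        fields = {"basal": (DensityField(grid, {(0, 0, 0): 57.0}),
                            DensityField(grid))}
        one = pst_field(fields, "A", "B",
                        MetaConnectivity({("A", "B", "basal"): (1.0, 0.0)}))
        two = pst_field(fields, "A", "B",
                        MetaConnectivity({("A", "B", "basal"): (2.0, 0.0)}))
        assert two.total() == 2.0 * one.total()


class TestSurfacePSTFit:
    def test_single_unknown_closed_form(self):
        rng = np.random.default_rng(8)
        A = rng.random(10) * 50.0
        target = 0.37 * A
        result = fit_alpha_profiles(target, {("exc", "B", "soma"): A})
        assert result.alpha_by_group[("exc", "B", "soma")] == pytest.approx(
            target.sum() / A.sum(), rel=1e-12)

    def test_balanced_boutons_yield_zero_alpha(self):
        A = np.linspace(1.0, 5.0, 8)
        result = fit_alpha_profiles(np.zeros(8), {("exc", "B", "soma"): A})
        assert result.alpha_by_group[("exc", "B", "soma")] == 0.0

    def test_collinear_profiles_rejected(self):
        A = np.linspace(1.0, 5.0, 8)
        with pytest.raises(FitError, match="collinear"):
            fit_alpha_profiles(A, {"g1": A, "g2": 2.0 * A})

    def test_nonnegativity_constraint(self):
        A = np.ones(6)
        result = fit_alpha_profiles(-3.0 * A, {"g": A})
        assert result.alpha_by_group["g"] == 0.0

    def test_recovers_known_alpha_on_ground_truth(self, ground_truth):
        fitted, result = fit_surface_pst(
            ground_truth.network, ground_truth.meta_unknown,
            bouton_profiles=ground_truth.balanced_bouton_z)
        for group, true_alpha in ground_truth.alpha_star.items():
            assert result.alpha_by_group[group] == pytest.approx(
                true_alpha, rel=0.01)
        assert np.abs(result.residual_profile).max() < 1e-9
        # fitted meta carries the recovered values on the original keys
        assert fitted.densities("EXC", "INH", "soma")[1] == pytest.approx(
            ground_truth.alpha_star[("exc", "INH", "soma")], rel=0.01)
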