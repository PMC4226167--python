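import numpy as np
import pytest

from densecon.density_fields import DensityField
from densecon.innervation import (
    InnervationError,
    binomial_synapse_count_distribution,
    connection_probability,
    innervation_field,
    pairwise_innervation,
    synapse_count_distribution,
    synapse_count_percentile,
    target_probability,
    total_pst_field,
)
from densecon.fixtures import oracle_innervation_matrix
from densecon.reference_frame import VoxelGrid


def _grid():
    return VoxelGrid(origin=np.zeros(3), spacing=50.0, dims=(4, 4, 4))


class TestTargetProbability:
    def test_simple_ratio(self):
        grid = _grid()
        p = target_probability(DensityField(grid, {(0, 0, 0): 100.0}),
                               DensityField(grid, {(0, 0, 0): 10000.0}))
        assert p.get((0, 0, 0)) == pytest.approx(0.01)

    def test_lone_neuron_has_probability_one(self):
        grid = _grid()
        f = DensityField(grid, {(1, 1, 1): 523.0})
        p = target_probability(f, f)
        assert p.get((1, 1, 1)) == 1.0

    def test_exceeding_total_is_inconsistent(self):
        grid = _grid()
        with pytest.raises(InnervationError):
            target_probability(DensityField(grid, {(0, 0, 0): 2.0}),
                               DensityField(grid, {(0, 0, 0): 1.0}))

    def test_probabilities_sum_to_one_per_voxel(self, ground_truth):
        """Sum of p_j over all neurons is 1 wherever PST_all > 0."""
        net, meta = ground_truth.network, ground_truth.meta
        for pre_type in ("EXC", "INH"):
            pst_all = total_pst_field(net, pre_type, meta)
            acc = {}
            from densecon.innervation import _neuron_pst
            for n in net.neurons:
                pst_j = _neuron_pst(net, n.id, pre_type, meta, None)
                p = target_probability(pst_j, pst_all)
                for idx, v in p.items():
                    acc[idx] = acc.get(idx, 0.0) + v
            for idx, total in pst_all.items():
                if total > 0:
                    assert acc[idx] == pytest.approx(1.0, abs=1e-9)


class TestInnervationField:
    def test_single_voxel_product(self):
        grid = _grid()
        fld = innervation_field(DensityField(grid, {(0, 0, 0): 10.0}),
                                DensityField(grid, {(0, 0, 0): 0.01}))
        assert fld.values[(0, 0, 0)] == pytest.approx(0.1)
        assert fld.total == pytest.approx(0.1)

    def test_disjoint_supports_give_zero(self):
        grid = _grid()
        fld = innervation_field(DensityField(grid, {(0, 0, 0): 10.0}),
                                DensityField(grid, {(1, 0, 0): 0.5}))
        assert fld.total == 0.0

    def test_multi_voxel_matches_dense_product_sum(self):
        grid = _grid()
        rng = np.random.default_rng(3)
        b = DensityField(grid, {tuple(rng.integers(0, 4, 3)): rng.random() * 20
                                for _ in range(10)})
        p = DensityField(grid, {tuple(rng.integers(0, 4, 3)): rng.random()
                                for _ in range(10)})
        fld = innervation_field(b, p)
        assert fld.total == pytest.approx(
            float((b.to_dense() * p.to_dense()).sum()), rel=1e-12)

    def test_bouton_conservation_across_targets(self, ground_truth):
        """Sum over j of I~_ij(x) equals B_i(x) per voxel: boutons are
        distributed exhaustively over the available targets."""
        from densecon.density_fields import neuron_bouton_field
        from densecon.innervation import _neuron_pst
        net, meta = ground_truth.network, ground_truth.meta
        i = net.neurons[-1]  # an excitatory neuron
        b_i = neuron_bouton_field(net, i.id)
        pst_all = total_pst_field(net, i.cell_type, meta)
        acc = {}
        for n in net.neurons:
            pst_j = _neuron_pst(net, n.id, i.cell_type, meta, None)
            p_j = target_probability(pst_j, pst_all)
            fld = innervation_field(b_i, p_j)
            for idx, v in fld.values.items():
                acc[idx] = acc.get(idx, 0.0) + v
        for idx, boutons in b_i.items():
            if pst_all.get(idx) > 0:
                assert acc.get(idx, 0.0) == pytest.approx(boutons, rel=1e-9)


class TestConnectionProbability:
    @pytest.mark.parametrize("I,expected", [(0.66, 0.48), (0.68, 0.49)])
    def test_worked_examples_to_two_decimals(self, I, expected):
        assert round(connection_probability(I), 2) == expected

    def test_zero_innervation_means_no_connection(self):
        assert connection_probability(0.0) == 0.0

    def test_negative_innervation_rejected(self):
        with pytest.raises(InnervationError):
            connection_probability(-0.1)

    def test_strictly_increasing(self):
        I = np.linspace(0.0, 5.0, 200)
        p = connection_probability(I)
        assert np.all(np.diff(p) > 0)

    def test_product_form_equals_exponential_form(self):
        """1 - prod_x P(n=0; I~(x)) vs 1 - exp(-sum I~) to 1e-12."""
        rng = np.random.default_rng(9)
        vals = rng.random(50) * 0.05
        product_form = 1.0 - np.prod(np.exp(-vals))
        exp_form = 1.0 - np.exp(-vals.sum())
        assert product_form == pytest.approx(exp_form, abs=1e-12)


class TestSynapseCounts:
    def test_poisson_mass_at_worked_example(self):
        d = synapse_count_distribution(0.66)
        assert round(100 * d[0]) == 52
        assert round(100 * d[1]) == 34

    def test_zero_rate_is_point_mass(self):
        np.testing.assert_array_equal(synapse_count_distribution(0.0), [1.0])

    def test_default_truncation_captures_nearly_all_mass(self):
        d = synapse_count_distribution(2.5)
        assert d.sum() > 1.0 - 1e-8

    def test_poisson_approximates_exact_binomial(self):
        """Total-variation distance between Binomial(1e4, 6.6e-5) and
        Poisson(0.66) below 1e-4."""
        n_max = 30
        pois = synapse_count_distribution(0.66, n_max=n_max)
        bino = binomial_synapse_count_distribution(10**4, 6.6e-5, n_max=n_max)
        assert 0.5 * np.abs(pois - bino).sum() < 1e-4

    def test_percentile_of_zero_rate(self):
        assert synapse_count_percentile(0.0, 0.95) == 0

    def test_percentile_matches_cumulative_mass(self):
        d = synapse_count_distribution(0.66, n_max=20)
        n95 = synapse_count_percentile(0.66, 0.95)
        assert d[:n95 + 1].sum() >= 0.95
        assert d[:n95].sum() < 0.95


class TestPairwiseInnervation:
    def test_three_neuron_network_matches_per_pair_oracle(self):
        from densecon.fixtures import make_ground_truth_network
        gt = make_ground_truth_network(n_neurons=3, seed=4)
        ids = [n.id for n in gt.network.neurons]
        matrix = pairwise_innervation(gt.network, ids, ids, gt.meta)
        oracle = oracle_innervation_matrix(gt.network, gt.meta)
        np.testing.assert_allclose(matrix.dense(), oracle, rtol=1e-9,
                                   atol=1e-12)

    def test_permuting_neurons_permutes_matrix(self, ground_truth):
        net, meta = ground_truth.network, ground_truth.meta
        ids = [n.id for n in net.neurons]
        m1 = pairwise_innervation(net, ids, ids, meta)
        perm = ids[::-1]
        m2 = pairwise_innervation(net, perm, perm, meta)
        np.testing.assert_allclose(m2.dense(), m1.dense()[::-1, ::-1],
                                   rtol=1e-12)

    def test_non_overlapping_pre_gives_zero_row(self, ground_truth):
        """A presynaptic neuron whose axon shares no voxel with a target's
        dendrites contributes I = 0 for that pair."""
        net, meta = ground_truth.network, ground_truth.meta
        ids = [n.id for n in net.neurons]
        matrix = pairwise_innervation(net, ids, ids, meta)
        from densecon.density_fields import neuron_bouton_field
        from densecon.innervation import _neuron_pst
        for i in ids[:2]:
            b = neuron_bouton_field(net, i)
            for j in ids[:2]:
                pst = _neuron_pst(net, j, net.neuron(i).cell_type, meta, None)
                if not set(b.support()) & set(pst.support()):
                    assert matrix.value(i, j) == 0.0

    def test_matrix_annotations_carry_cell_types(self, ground_truth):
        net, meta = ground_truth.network, ground_truth.meta
        ids = [n.id for n in net.neurons]
        matrix = pairwise_innervation(net, ids, ids, meta)
        assert set(matrix.pre_info["cell_type"]) == {"EXC", "INH"}
        assert list(matrix.pre_info["id"]) == ids
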