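import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from overlapnet.modules import EdgePartition, InstanceEnsemble
from overlapnet.netio import WeightedNetwork
from overlapnet.overlap import (
    ModuleMap,
    entropy_map,
    involved_number,
    match_modules,
    module_maps,
    nodal_entropy,
    node_distribution,
    summarize_instances,
    system_composition,
    system_entropy,
)
from overlapnet.synthdata import gen_parcellation


def make_net(n, edges):
    adj = np.zeros((n, n))
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1.0
    return WeightedNetwork(adjacency=adj, density=len(edges) / (n * (n - 1) / 2),
                           node_ids=[str(i) for i in range(n)])


@pytest.fixture
def star_net():
    """Node 0 connected to 1, 2, 3; edges (0,1),(0,2),(0,3) in order."""
    return make_net(5, [(0, 1), (0, 2), (0, 3)])


class TestNodalEntropy:
    def test_single_module_is_zero(self):
        assert nodal_entropy({1: 1.0}) == 0.0

    def test_uniform_two_modules_is_one(self):
        assert nodal_entropy({1: 0.5, 2: 0.5}) == pytest.approx(1.0, abs=1e-12)

    def test_three_quarters_split_hand_value(self):
        # -(0.75 log2 0.75 + 0.25 log2 0.25) / log2 2 = 0.8112781...
        assert nodal_entropy({1: 0.75, 2: 0.25}) == pytest.approx(0.811278124459, abs=1e-10)

    def test_rejects_unnormalized_or_negative(self):
        with pytest.raises(ValueError):
            nodal_entropy({1: 0.4, 2: 0.4})
        with pytest.raises(ValueError):
            nodal_entropy(np.array([1.2, -0.2]))

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6))
    def test_bounded_and_zero_iff_single_module(self, raw):
        p = np.array(raw) / np.sum(raw)
        h = nodal_entropy(p)
        assert 0.0 <= h <= 1.0 + 1e-12
        if involved_number(p) == 1:
            assert h == 0.0

    def test_equalization_increases_entropy(self):
        """Moving mass from the larger share to the smaller raises H."""
        skewed = nodal_entropy({1: 0.8, 2: 0.15, 3: 0.05})
        evener = nodal_entropy({1: 0.6, 2: 0.25, 3: 0.15})
        uniform = nodal_entropy({1: 1 / 3, 2: 1 / 3, 3: 1 / 3})
        assert skewed < evener < uniform == pytest.approx(1.0, abs=1e-12)


class TestNodeDistribution:
    def test_mixed_membership_counts(self):
        net = make_net(4, [(0, 1), (0, 2), (0, 3)])
        part = EdgePartition(labels=np.array([2, 2, 3]), n_modules=2, modularity=0.0)
        prof = node_distribution(part, net)[0]
        assert prof.proportions == {2: pytest.approx(2 / 3), 3: pytest.approx(1 / 3)}
        assert prof.n_involved == 2

    def test_single_module_node(self, star_net):
        part = EdgePartition(labels=np.array([1, 1, 1]), n_modules=1, modularity=0.0)
        prof = node_distribution(part, star_net)[0]
        assert prof.proportions == {1: 1.0}
        assert prof.entropy == 0.0

    def test_proportions_sum_to_one_and_missing_flagged(self, star_net):
        part = EdgePartition(labels=np.array([1, 2, 1]), n_modules=2, modularity=0.0)
        profs = node_distribution(part, star_net)
        for p in profs:
            if p.missing:
                continue
            assert sum(p.proportions.values()) == pytest.approx(1.0)
        assert profs[4].missing  # node 4 has no edges

    def test_partition_network_mismatch(self, star_net):
        part = EdgePartition(labels=np.array([1, 2]), n_modules=2, modularity=0.0)
        with pytest.raises(ValueError, match="edge count"):
            node_distribution(part, star_net)

    def test_involved_number_support_size(self):
        assert involved_number(np.array([0.5, 0.3, 0.2])) == 3
        assert involved_number({1: 1.0}) == 1


class TestSummarizeInstances:
    def test_identical_instances_equal_single(self, star_net):
        part = EdgePartition(labels=np.array([1, 2, 1]), n_modules=2, modularity=0.3)
        ens = InstanceEnsemble(partitions=[part, part, part])
        out = summarize_instances(ens, star_net)
        single = entropy_map(part, star_net)
        assert np.allclose(out["node_entropy"], single, equal_nan=True)

    def test_mean_of_two_instances(self, star_net):
        a = EdgePartition(labels=np.array([1, 1, 1]), n_modules=1, modularity=0.0)
        b = EdgePartition(labels=np.array([1, 2, 1]), n_modules=2, modularity=0.0)
        out = summarize_instances(InstanceEnsemble(partitions=[a, b]), star_net)
        ha = entropy_map(a, star_net)
        hb = entropy_map(b, star_net)
        assert np.allclose(out["node_entropy"], (ha + hb) / 2, equal_nan=True)

    def test_missing_nodes_excluded_from_global(self, star_net):
        part = EdgePartition(labels=np.array([1, 2, 1]), n_modules=2, modularity=0.0)
        out = summarize_instances(InstanceEnsemble(partitions=[part]), star_net)
        valid = out["node_entropy"][~np.isnan(out["node_entropy"])]
        assert out["global_entropy"] == pytest.approx(valid.mean())
        assert np.isnan(out["node_entropy"][4])


class TestModuleMaps:
    def test_maps_stack_to_distribution(self, star_net):
        part = EdgePartition(labels=np.array([1, 2, 1]), n_modules=2, modularity=0.0)
        maps = module_maps(part, star_net)
        profs = node_distribution(part, star_net)
        for m in maps:
            for prof in profs:
                if not prof.missing:
                    assert m.values[prof.node] == pytest.approx(prof.proportions.get(m.module, 0.0))
        stacked = np.nansum([m.values for m in maps], axis=0)
        assert np.allclose(stacked[:4], 1.0)

    def test_hand_computed_two_module_example(self):
        net = make_net(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        part = EdgePartition(labels=np.array([1, 1, 2, 2]), n_modules=2, modularity=0.0)
        maps = module_maps(part, net)
        # node 2 has one edge in each module
        assert maps[0].values[2] == pytest.approx(0.5)
        assert maps[1].values[2] == pytest.approx(0.5)
        assert maps[0].values[0] == pytest.approx(1.0)
        assert maps[1].values[4] == pytest.approx(1.0)


class TestMatchModules:
    def _maps(self, arrays):
        return [ModuleMap(module=i + 1, values=np.asarray(v, dtype=float))
                for i, v in enumerate(arrays)]

    def test_self_match_is_identity_with_r_one(self):
        rng = np.random.default_rng(0)
        maps = self._maps(rng.uniform(0, 1, (3, 10)))
        res = match_modules(maps, maps)
        assert [m["module_b"] for m in res] == [1, 2, 3]
        assert all(m["r"] == pytest.approx(1.0) for m in res)

    def test_recovers_label_shuffle(self):
        rng = np.random.default_rng(1)
        arrays = rng.uniform(0, 1, (4, 12))
        maps_a = self._maps(arrays)
        perm = [2, 0, 3, 1]
        maps_b = [ModuleMap(module=i + 1, values=arrays[perm[i]]) for i in range(4)]
        res = match_modules(maps_a, maps_b)
        assert [m["module_b"] for m in res] == [perm.index(i) + 1 for i in range(4)]
        assert all(m["r"] == pytest.approx(1.0) for m in res)

    def test_noisy_copy_keeps_matching_with_lower_r(self):
        rng = np.random.default_rng(2)
        arrays = rng.uniform(0, 1, (3, 30))
        maps_a = self._maps(arrays)
        maps_b = self._maps(arrays + rng.normal(0, 0.05, arrays.shape))
        res = match_modules(maps_a, maps_b)
        assert [m["module_b"] for m in res] == [1, 2, 3]
        assert all(0.8 < m["r"] < 1.0 for m in res)

    def test_constant_map_reported_missing(self):
        maps_a = self._maps([np.ones(5)])
        maps_b = self._maps([np.arange(5.0)])
        res = match_modules(maps_a, maps_b)
        assert np.isnan(res[0]["r"])


class TestSystemSummaries:
    def test_composition_single_system_module(self):
        parc = gen_parcellation(16, seed=0)
        vals = np.zeros(16)
        vals[:2] = 0.8  # first block is VIS
        comp = system_composition(ModuleMap(module=1, values=vals), parc)
        assert comp["VIS"] == pytest.approx(100.0)

    def test_composition_percentages_sum_to_100(self):
        parc = gen_parcellation(16, seed=0)
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 1, 16)
        comp = system_composition(ModuleMap(module=1, values=vals), parc)
        assert sum(comp.values()) == pytest.approx(100.0)

    def test_system_entropy_means_and_global_identity(self):
        parc = gen_parcellation(16, seed=0)
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 1, 16)
        out = system_entropy(vals, parc)
        sizes = {s: parc.systems.count(s) for s in set(parc.systems)}
        weighted = sum(out[s] * sizes[s] for s in sizes) / 16
        assert out["GLOBAL"] == pytest.approx(weighted)
        assert out["VIS"] == pytest.approx(vals[:2].mean())

    def test_constant_map_gives_constant_system_means(self):
        parc = gen_parcellation(16, seed=0)
        out = system_entropy(np.full(16, 0.5), parc)
        assert all(v == pytest.approx(0.5) for v in out.values())
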