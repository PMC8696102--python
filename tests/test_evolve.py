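import numpy as np
import pytest

from mstalign import (
    FamilySpec,
    Params,
    crossover,
    fitness,
    make_family,
    mutate,
    progressive,
    qc,
    specimen_identity,
    steady_state,
    stochastic_nj,
    tension,
    two_stage,
)
from mstalign.evolve import (
    PairPool,
    SearchSpace,
    Specimen,
    TreeNode,
    _structure_contribution,
    gradual_extension,
    leaf_distances,
)
from mstalign.multialign import MultipleAlignment

from conftest import ARCH


@pytest.fixture(scope="module")
def identical_setup():
    structures, truth = make_family(FamilySpec(architecture=ARCH, n_copies=3, noise_sigma=0.0, seed=2))
    params = Params()
    pool = PairPool(structures, params)
    space = SearchSpace(pool, pool.eligible_ids(1))
    for s in range(3):
        space.free(s)
    return structures, truth, params, space


@pytest.fixture(scope="module")
def noisy_setup(family3, family3_pool):
    structures, truth = family3
    params = Params()
    space = SearchSpace(family3_pool, family3_pool.eligible_ids(1))
    for s in range(3):
        space.free(s)
    return structures, truth, params, space


class TestStochasticNJ:
    def test_two_structures_single_join(self):
        tree = stochastic_nj(np.ones((2, 2)), np.random.default_rng(0))
        assert sorted(tree.leaves()) == [0, 1]
        assert tree.left.is_leaf and tree.right.is_leaf

    def test_join_probability_proportional_to_similarity(self):
        sim = np.array([[0, 2, 1], [2, 0, 1], [1, 1, 0]], dtype=float)
        rng = np.random.default_rng(123)
        ab = 0
        n = 10_000
        for _ in range(n):
            tree = stochastic_nj(sim, rng)
            first = min(
                (node for node in tree.postorder() if not node.is_leaf),
                key=lambda nd: len(nd.leaves()),
            )
            if sorted(first.leaves()) == [0, 1]:
                ab += 1
        assert ab / n == pytest.approx(0.5, abs=0.02)  # exact expectation 2/4

    def test_dominant_pair_joined_first(self):
        sim = np.ones((4, 4)) - np.eye(4)
        sim[0, 1] = sim[1, 0] = 1e6
        rng = np.random.default_rng(7)
        hits = 0
        for _ in range(200):
            tree = stochastic_nj(sim, rng)
            smallest = min(
                (nd for nd in tree.postorder() if not nd.is_leaf),
                key=lambda nd: len(nd.leaves()),
            )
            hits += sorted(smallest.leaves())[:2] == [0, 1] and len(smallest.leaves()) == 2
        assert hits == 200

    def test_all_zero_similarity_uniform(self):
        tree = stochastic_nj(np.zeros((3, 3)), np.random.default_rng(1))
        assert sorted(tree.leaves()) == [0, 1, 2]

    def test_single_structure_rejected(self):
        with pytest.raises(ValueError):
            stochastic_nj(np.zeros((1, 1)), np.random.default_rng(0))


class TestProgressive:
    def test_identical_copies_reach_ground_truth(self, identical_setup):
        structures, truth, params, space = identical_setup
        tree = TreeNode(left=TreeNode(left=TreeNode(leaf=0), right=TreeNode(leaf=1)), right=TreeNode(leaf=2))
        sp = progressive(tree, space, params, np.random.default_rng(0))
        assert qc(sp.alignment, truth.reference) == 100.0
        assert tension(sp.alignment).total < 1e-12

    def test_single_leaf_tree(self, identical_setup):
        structures, _, params, space = identical_setup
        sp = progressive(TreeNode(leaf=1), space, params, np.random.default_rng(0))
        assert len(sp.alignment.columns) == len(structures[1])
        assert all(len(c) == 1 for c in sp.alignment.columns)

    def test_different_trees_similar_fitness(self, noisy_setup):
        structures, _, params, space = noisy_setup
        t1 = TreeNode(left=TreeNode(left=TreeNode(leaf=0), right=TreeNode(leaf=1)), right=TreeNode(leaf=2))
        t2 = TreeNode(left=TreeNode(left=TreeNode(leaf=1), right=TreeNode(leaf=2)), right=TreeNode(leaf=0))
        f1 = progressive(t1, space, params, np.random.default_rng(0)).fitness
        f2 = progressive(t2, space, params, np.random.default_rng(1)).fitness
        assert abs(f1 - f2) <= 0.05 * max(abs(f1), abs(f2))


class TestMutateCrossover:
    def test_mutation_preserves_fitness_at_fixed_point(self, identical_setup):
        structures, truth, params, space = identical_setup
        tree = TreeNode(left=TreeNode(left=TreeNode(leaf=0), right=TreeNode(leaf=1)), right=TreeNode(leaf=2))
        sp = progressive(tree, space, params, np.random.default_rng(0))
        rng = np.random.default_rng(5)
        for _ in range(3):
            child = mutate(sp, space, params, rng)
            child.alignment.validate()
            assert child.fitness == pytest.approx(sp.fitness, rel=1e-9)
        # input unchanged
        assert sp.alignment.columns == sp.tree.ma.columns

    def test_mutation_output_valid_on_noisy_family(self, noisy_setup):
        structures, _, params, space = noisy_setup
        tree = TreeNode(left=TreeNode(left=TreeNode(leaf=0), right=TreeNode(leaf=1)), right=TreeNode(leaf=2))
        sp = progressive(tree, space, params, np.random.default_rng(2))
        child = mutate(sp, space, params, np.random.default_rng(3))
        child.alignment.validate()

    def test_crossover_fixed_point(self, identical_setup):
        structures, truth, params, space = identical_setup
        tree = TreeNode(left=TreeNode(left=TreeNode(leaf=0), right=TreeNode(leaf=1)), right=TreeNode(leaf=2))
        sp = progressive(tree, space, params, np.random.default_rng(0))
        child = crossover(sp, sp, space, params, np.random.default_rng(4))
        assert child.fitness == pytest.approx(sp.fitness, rel=1e-9)

    def test_crossover_partitions_structures(self, noisy_setup):
        structures, _, params, space = noisy_setup
        t1 = TreeNode(left=TreeNode(left=TreeNode(leaf=0), right=TreeNode(leaf=1)), right=TreeNode(leaf=2))
        t2 = TreeNode(left=TreeNode(left=TreeNode(leaf=2), right=TreeNode(leaf=0)), right=TreeNode(leaf=1))
        s1 = progressive(t1, space, params, np.random.default_rng(0))
        s2 = progressive(t2, space, params, np.random.default_rng(1))
        child = crossover(s1, s2, space, params, np.random.default_rng(2))
        left, right = child.tree.left.leaves(), child.tree.right.leaves()
        assert left and right
        assert sorted(left + right) == [0, 1, 2]
        child.alignment.validate()

    def test_leaf_distances(self):
        tree = TreeNode(left=TreeNode(left=TreeNode(leaf=0), right=TreeNode(leaf=1)), right=TreeNode(leaf=2))
        d = leaf_distances(tree)
        assert d[(0, 1)] == 2 and d[(0, 2)] == 3 and d[(1, 2)] == 3


class TestSpecimenIdentity:
    def _specimen(self, structures, columns):
        ma = MultipleAlignment(structures, columns)
        return Specimen(TreeNode(leaf=0), ma, 0.0)

    def test_identical_is_one(self, family3):
        structures, truth = family3
        s = self._specimen(structures, truth.reference.columns)
        assert specimen_identity(s, s) == 1.0

    def test_disjoint_is_zero(self, family3):
        structures, truth = family3
        s1 = self._specimen(structures, truth.reference.columns[:20])
        s2 = self._specimen(structures, truth.reference.columns[30:50])
        assert specimen_identity(s1, s2) == 0.0

    def test_half_deleted_is_half(self, family3):
        structures, truth = family3
        s1 = self._specimen(structures, truth.reference.columns[:20])
        s2 = self._specimen(structures, truth.reference.columns[:10])
        assert specimen_identity(s1, s2) == pytest.approx(0.5)


class TestSteadyState:
    def test_perfect_specimen_survives(self, identical_setup):
        structures, truth, params, space = identical_setup
        tree = TreeNode(left=TreeNode(left=TreeNode(leaf=0), right=TreeNode(leaf=1)), right=TreeNode(leaf=2))
        sp = progressive(tree, space, params, np.random.default_rng(0))
        import dataclasses

        small = dataclasses.replace(params, ea=dataclasses.replace(params.ea, max_evals=6, stall=3))
        best, pop = steady_state([sp], space, small, np.random.default_rng(1))
        assert best.fitness >= sp.fitness

    def test_insertion_rule_rejects_identical_worse_child(self, identical_setup):
        """At capacity, a child identical (identity 1 > 0.8) to its most
        similar individual and not fitter is rejected."""
        structures, truth, params, space = identical_setup
        import dataclasses

        tree = TreeNode(left=TreeNode(left=TreeNode(leaf=0), right=TreeNode(leaf=1)), right=TreeNode(leaf=2))
        sp = progressive(tree, space, params, np.random.default_rng(0))
        tiny = dataclasses.replace(
            params, ea=dataclasses.replace(params.ea, population_max=1, max_evals=5, stall=5, p_mutation=1.0)
        )
        best, pop = steady_state([sp], space, tiny, np.random.default_rng(2))
        # at a fitness fixed point every child ties, none exceeds -> population unchanged
        assert len(pop) == 1
        assert pop[0] is sp

    def test_best_fitness_never_decreases(self, noisy_setup):
        structures, truth, params, space = noisy_setup
        import dataclasses

        small = dataclasses.replace(params, ea=dataclasses.replace(params.ea, max_evals=8, stall=8))
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            tree = stochastic_nj(np.ones((3, 3)) - np.eye(3), rng)
            sp = progressive(tree, space, params, rng)
            best, _ = steady_state([sp], space, small, rng)
            assert best.fitness >= sp.fitness
            assert qc(best.alignment, truth.reference) >= 0  # valid alignment


class TestGradualExtension:
    def test_identical_copies_reach_ground_truth(self, identical_setup):
        structures, truth, params, _ = identical_setup
        best, space = gradual_extension(structures, params, np.random.default_rng(0))
        assert space.all_freed()
        assert qc(best.alignment, truth.reference) == 100.0

    def test_underperformance_signal(self, family3):
        """Removing one structure's rows from the best alignment lowers its
        leave-one-out contribution, which drives the freeing order."""
        structures, truth = family3
        params = Params()
        full = truth.reference
        damaged_cols = [
            {s: r for s, r in c.items() if s != 2} if i % 2 else dict(c)
            for i, c in enumerate(full.columns)
        ]
        damaged = MultipleAlignment(structures, [c for c in damaged_cols if c])
        sp_full = Specimen(TreeNode(leaf=0), full, fitness(full))
        sp_damaged = Specimen(TreeNode(leaf=0), damaged, fitness(damaged))
        c_full = _structure_contribution(sp_full, 2, params)
        c_damaged = _structure_contribution(sp_damaged, 2, params)
        assert c_damaged < c_full

    def test_needs_three_structures(self, noisy_pair):
        (sa, sb), _ = noisy_pair
        with pytest.raises(ValueError):
            gradual_extension([sa, sb], Params(), np.random.default_rng(0))


class TestTwoStage:
    def test_two_structures_pairwise_path(self, noisy_pair):
        (sa, sb), truth = noisy_pair
        ma = two_stage([sa, sb], Params(), np.random.default_rng(0))
        gt = {(c[0], c[1]) for c in truth.reference.columns}
        got = {(c[0], c[1]) for c in ma.columns if len(c) == 2}
        assert len(got & gt) >= 0.95 * len(gt)

    def test_extension_is_monotone_over_core(self, family3, family3_pool):
        structures, truth = family3
        params = Params()
        rng = np.random.default_rng(3)
        best, _ = gradual_extension(structures, params, rng, family3_pool, min_segments=3)
        core_pairs = best.alignment.aligned_pairs()
        final = two_stage(structures, params, np.random.default_rng(3), family3_pool)
        final_pairs = final.aligned_pairs()
        # stage 2 only adds: residues aligned by the core stay aligned
        core_residues = {t for p in core_pairs for t in p}
        final_residues = {t for p in final_pairs for t in p}
        assert core_residues <= final_residues
        assert len(final_pairs) >= len(core_pairs)

    def test_deterministic_given_seed(self, family3, family3_pool):
        structures, _ = family3
        params = Params()
        ma1 = two_stage(structures, params, np.random.default_rng(42), family3_pool)
        ma2 = two_stage(structures, params, np.random.default_rng(42), family3_pool)
        assert ma1.columns == ma2.columns
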