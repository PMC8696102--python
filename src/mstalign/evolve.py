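"""Guide-tree seeding, steady-state evolutionary refinement and the
two-stage core/refine protocol.

The search works over *specimens*: a binary guide tree whose internal
nodes carry the multiple alignment of their leaf set (built by profile
alignment), plus the fitness of the root alignment.  Initial specimens
come from a stochastic neighbor-joining procedure that samples each join
with probability proportional to average inter-cluster similarity.  A
steady-state evolutionary algorithm with elitist insertion and 80%
identity niching refines the population, while the search space of
allowed descriptor pairs is extended gradually, one freed structure at a
time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .descriptors import (
    ContactCriterion,
    DescriptorPair,
    SimilarityParams,
    all_descriptor_pairs,
    build_all_descriptors,
)
from .multialign import MultipleAlignment, align_profiles, from_pairwise, singleton_alignment
from .pairwise import CliqueParams, PairwiseAlignment, align_pair
from .scoring import FitnessParams, fitness
from .structure import Structure

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EAParams:
    """Evolutionary-search knobs (desk-scale defaults, all configurable)."""

    population_max: int = 8
    p_mutation: float = 0.7
    stall: int = 8
    max_evals: int = 24
    n_init_trees: int = 4
    identity_threshold: float = 0.8
    min_segments_core: int = 3


@dataclass(frozen=True)
class Params:
    """Aggregate configuration for a full alignment run."""

    criterion: ContactCriterion = ContactCriterion()
    similarity: SimilarityParams = SimilarityParams()
    clique: CliqueParams = CliqueParams()
    fitness: FitnessParams = FitnessParams()
    ea: EAParams = EAParams()


# ---------------------------------------------------------------------------
# descriptor-pair pool and search space


class PairPool:
    """All similar descriptor pairs for a structure set, computed once.

    ``pairs[(i, j)]`` (i < j) lists pairs whose correspondence maps
    residues of structure i to structure j.
    """

    def __init__(self, structures: list[Structure], params: Params = Params()):
        self.structures = structures
        self.params = params
        descs = [build_all_descriptors(s, params.criterion) for s in structures]
        self.descriptors = descs
        self.pairs: dict[tuple[int, int], list[DescriptorPair]] = {}
        for i in range(len(structures)):
            for j in range(i + 1, len(structures)):
                self.pairs[(i, j)] = all_descriptor_pairs(
                    structures[i], structures[j], params.similarity, params.criterion,
                    descs[i], descs[j],
                )

    def eligible_ids(self, min_segments: int = 1) -> dict[tuple[int, int], list[int]]:
        return {
            key: [k for k, dp in enumerate(dps) if dp.n_segments >= min_segments]
            for key, dps in self.pairs.items()
        }


@dataclass
class SearchSpace:
    """Currently allowed descriptor pairs, per structure pair.

    ``eligible`` is the stage-level restriction (e.g. core stage: pairs
    with ≥3 segments); ``allowed`` ⊆ eligible is what the search may use
    right now.  Freeing a structure allows all its eligible pairs.
    """

    pool: PairPool
    eligible: dict[tuple[int, int], list[int]]
    allowed: dict[tuple[int, int], set[int]] = field(default_factory=dict)
    freed: set[int] = field(default_factory=set)

    def __post_init__(self) -> None:
        for key in self.pool.pairs:
            self.allowed.setdefault(key, set())
        self._check_freed_invariant()

    def _check_freed_invariant(self) -> None:
        for (i, j), ids in self.eligible.items():
            if i in self.freed or j in self.freed:
                assert self.allowed[(i, j)] >= set(ids)

    def free(self, s: int) -> None:
        self.freed.add(s)
        for (i, j), ids in self.eligible.items():
            if s in (i, j):
                self.allowed[(i, j)] |= set(ids)

    def allowed_list(self) -> list[tuple[int, int, DescriptorPair]]:
        out = []
        for (i, j), ids in sorted(self.allowed.items()):
            dps = self.pool.pairs[(i, j)]
            for k in sorted(ids):
                out.append((i, j, dps[k]))
        return out

    def all_freed(self) -> bool:
        return self.freed >= set(range(len(self.pool.structures)))


# ---------------------------------------------------------------------------
# guide trees and specimens


class TreeNode:
    __slots__ = ("left", "right", "leaf", "ma")

    def __init__(self, leaf: int | None = None, left: "TreeNode|None" = None,
                 right: "TreeNode|None" = None, ma: MultipleAlignment | None = None):
        self.leaf = leaf
        self.left = left
        self.right = right
        self.ma = ma

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None

    def leaves(self) -> list[int]:
        if self.is_leaf:
            return [self.leaf]
        return self.left.leaves() + self.right.leaves()

    def postorder(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.postorder() + self.right.postorder() + [self]

    def internal_nodes(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if not n.is_leaf]

    def clone(self) -> "TreeNode":
        if self.is_leaf:
            return TreeNode(leaf=self.leaf, ma=self.ma)
        return TreeNode(left=self.left.clone(), right=self.right.clone(), ma=self.ma)

    def path_to(self, target: "TreeNode") -> list["TreeNode"] | None:
        if self is target:
            return [self]
        if self.is_leaf:
            return None
        for child in (self.left, self.right):
            sub = child.path_to(target)
            if sub is not None:
                return [self] + sub
        return None


def leaf_distances(root: TreeNode) -> dict[tuple[int, int], int]:
    """Number of tree edges between every pair of leaves."""
    paths: dict[int, list[TreeNode]] = {}

    def walk(node: TreeNode, path: list[TreeNode]) -> None:
        if node.is_leaf:
            paths[node.leaf] = path + [node]
        else:
            walk(node.left, path + [node])
            walk(node.right, path + [node])

    walk(root, [])
    out: dict[tuple[int, int], int] = {}
    leaves = sorted(paths)
    for a in leaves:
        for b in leaves:
            if a >= b:
                continue
            pa, pb = paths[a], paths[b]
            common = 0
            for x, y in zip(pa, pb):
                if x is y:
                    common += 1
                else:
                    break
            d = (len(pa) - common) + (len(pb) - common)
            out[(a, b)] = out[(b, a)] = d
    return out


@dataclass
class Specimen:
    tree: TreeNode
    alignment: MultipleAlignment
    fitness: float
    _pair_cache: frozenset = field(default=None, repr=False, compare=False)

    def aligned_pairs(self) -> frozenset:
        if self._pair_cache is None:
            self._pair_cache = frozenset(self.alignment.aligned_pairs())
        return self._pair_cache


def specimen_identity(s1: Specimen, s2: Specimen) -> float:
    """Jaccard similarity of the induced aligned-residue-pair sets."""
    p1, p2 = s1.aligned_pairs(), s2.aligned_pairs()
    union = p1 | p2
    if not union:
        return 1.0
    return len(p1 & p2) / len(union)


# ---------------------------------------------------------------------------
# stochastic NJ and progressive alignment


def stochastic_nj(similarity: np.ndarray, rng: np.random.Generator) -> TreeNode:
    """Randomized neighbor joining: each step joins a cluster pair sampled
    with probability proportional to the average similarity of their
    members (uniform when all similarities vanish)."""
    sim = np.asarray(similarity, dtype=float)
    n = sim.shape[0]
    if n < 2:
        raise ValueError("need at least 2 structures")
    if sim.shape != (n, n) or not np.allclose(sim, sim.T) or (sim < 0).any():
        raise ValueError("similarity must be symmetric and nonnegative")
    clusters: list[tuple[TreeNode, list[int]]] = [(TreeNode(leaf=i), [i]) for i in range(n)]
    while len(clusters) > 1:
        k = len(clusters)
        pairs = [(a, b) for a in range(k) for b in range(a + 1, k)]
        weights = np.array(
            [np.mean(sim[np.ix_(clusters[a][1], clusters[b][1])]) for a, b in pairs]
        )
        if weights.sum() <= 0:
            probs = np.full(len(pairs), 1.0 / len(pairs))
        else:
            probs = weights / weights.sum()
        a, b = pairs[rng.choice(len(pairs), p=probs)]
        node = TreeNode(left=clusters[a][0], right=clusters[b][0])
        members = clusters[a][1] + clusters[b][1]
        clusters = [c for idx, c in enumerate(clusters) if idx not in (a, b)] + [(node, members)]
    return clusters[0][0]


def progressive(
    tree: TreeNode, space: SearchSpace, params: Params, rng: np.random.Generator,
    structures: list[Structure] | None = None,
) -> Specimen:
    """Post-order profile alignment along a guide tree."""
    structures = structures if structures is not None else space.pool.structures
    allowed = space.allowed_list()
    for node in tree.postorder():
        if node.is_leaf:
            node.ma = singleton_alignment(structures, node.leaf)
        else:
            node.ma = align_profiles(node.left.ma, node.right.ma, allowed, params.clique, rng)
    f = fitness(tree.ma, params.fitness, params.criterion)
    return Specimen(tree, tree.ma, f)


# ---------------------------------------------------------------------------
# variation operators


def mutate(s: Specimen, space: SearchSpace, params: Params, rng: np.random.Generator) -> Specimen:
    """Recompute a random internal node's alignment (fresh clique-search
    randomization) and every node on its path to the root; input unchanged."""
    tree = s.tree.clone()
    internals = tree.internal_nodes()
    target = internals[int(rng.integers(len(internals)))]
    path = tree.path_to(target)
    allowed = space.allowed_list()
    for node in reversed(path):  # target first, then ancestors up to root
        if node.is_leaf:
            continue
        node.ma = align_profiles(node.left.ma, node.right.ma, allowed, params.clique, rng)
    f = fitness(tree.ma, params.fitness, params.criterion)
    return Specimen(tree, tree.ma, f)


def _prune(node: TreeNode, keep: set[int]) -> TreeNode | None:
    """Restrict a tree (and its cached alignments) to a leaf subset."""
    if node.is_leaf:
        if node.leaf in keep:
            return TreeNode(leaf=node.leaf, ma=node.ma.restrict(keep) if node.ma else None)
        return None
    left = _prune(node.left, keep)
    right = _prune(node.right, keep)
    if left is not None and right is not None:
        return TreeNode(left=left, right=right, ma=node.ma.restrict(keep) if node.ma else None)
    return left if left is not None else right


def crossover(
    s1: Specimen, s2: Specimen, space: SearchSpace, params: Params, rng: np.random.Generator
) -> Specimen:
    """Recombine two specimens.

    A centroid pair (u, v) is sampled with probability proportional to
    guide-tree distance; the structure set is partitioned by growing
    subsets around u (proximity in s1's tree) and around v (s2's tree).
    The two subalignments are extracted and profile-aligned; the child's
    tree joins the two pruned subtrees at a new root.
    """
    leaves = sorted(set(s1.tree.leaves()))
    if leaves != sorted(set(s2.tree.leaves())):
        raise ValueError("specimens must cover the same structure set")
    if len(leaves) < 2:
        raise ValueError("need at least 2 structures")
    d1 = leaf_distances(s1.tree)
    d2 = leaf_distances(s2.tree)
    cand = [(u, v) for u in leaves for v in leaves if u != v]
    w = np.array([d1[(u, v)] + d2[(u, v)] for u, v in cand], dtype=float)
    probs = w / w.sum() if w.sum() > 0 else np.full(len(cand), 1.0 / len(cand))
    u, v = cand[rng.choice(len(cand), p=probs)]
    set1, set2 = {u}, {v}
    rest = [x for x in leaves if x not in (u, v)]
    # alternately grow each subset with the unassigned structure closest to
    # its centroid in the respective specimen's tree
    turn = 0
    while rest:
        if turn == 0:
            rest.sort(key=lambda x: (d1[(min(u, x), max(u, x))], x))
        else:
            rest.sort(key=lambda x: (d2[(min(v, x), max(v, x))], x))
        pick = rest.pop(0)
        (set1 if turn == 0 else set2).add(pick)
        turn = 1 - turn
    t1 = _prune(s1.tree.clone(), set1)
    t2 = _prune(s2.tree.clone(), set2)
    allowed = space.allowed_list()
    ma = align_profiles(t1.ma, t2.ma, allowed, params.clique, rng)
    tree = TreeNode(left=t1, right=t2, ma=ma)
    f = fitness(ma, params.fitness, params.criterion)
    return Specimen(tree, ma, f)


# ---------------------------------------------------------------------------
# steady-state EA


def steady_state(
    population: list[Specimen], space: SearchSpace, params: Params, rng: np.random.Generator
) -> tuple[Specimen, list[Specimen]]:
    """Steady-state loop with elitist insertion and identity niching.

    Children are produced by mutation (probability ``p_mutation``) or
    crossover, parents chosen fitness-proportionally.  A child is inserted
    if the population is below capacity or its fitness exceeds that of the
    most similar individual; on insertion, all individuals more than 80%
    identical to the child (the child excepted) are removed.  Stops after
    ``stall`` consecutive non-improving insertions or ``max_evals``
    children.  Returns (best specimen ever, final population).
    """
    if not population:
        raise ValueError("population must be nonempty")
    ea = params.ea
    pop = list(population)
    best = max(pop, key=lambda s: s.fitness)
    no_improve = 0
    for _ in range(ea.max_evals):
        if no_improve >= ea.stall:
            break
        f = np.array([p.fitness for p in pop])
        w = f - f.min() + 1e-9
        probs = w / w.sum()
        if len(pop) >= 2 and rng.random() >= ea.p_mutation:
            i = int(rng.choice(len(pop), p=probs))
            j = int(rng.choice(len(pop), p=probs))
            while j == i:
                j = int(rng.choice(len(pop), p=probs))
            child = crossover(pop[i], pop[j], space, params, rng)
        else:
            i = int(rng.choice(len(pop), p=probs))
            child = mutate(pop[i], space, params, rng)
        if len(pop) < ea.population_max:
            insert = True
        else:
            sims = [specimen_identity(p, child) for p in pop]
            most_similar = int(np.lexsort((np.arange(len(pop)), -np.asarray(sims)))[0])
            insert = child.fitness > pop[most_similar].fitness
        if insert:
            pop = [p for p in pop if specimen_identity(p, child) <= ea.identity_threshold]
            pop.append(child)
        if child.fitness > best.fitness:
            best = child
            no_improve = 0
        else:
            no_improve += 1
    return best, pop


# ---------------------------------------------------------------------------
# gradual extension and the two-stage protocol


def _pairwise_layer(
    structures: list[Structure], pool: PairPool, eligible: dict, params: Params,
    rng: np.random.Generator,
) -> tuple[dict[tuple[int, int], PairwiseAlignment], dict[tuple[int, int], set[int]], np.ndarray,
           dict[tuple[int, int], float]]:
    """All-vs-all pairwise alignments restricted to eligible descriptor
    pairs; returns alignments, used descriptor-pair ids, the similarity
    table (alignment sizes) and pairwise fitness scores."""
    n = len(structures)
    alignments: dict[tuple[int, int], PairwiseAlignment] = {}
    used: dict[tuple[int, int], set[int]] = {}
    sim = np.zeros((n, n))
    pw_fit: dict[tuple[int, int], float] = {}
    for (i, j), dps in sorted(pool.pairs.items()):
        elig = [dps[k] for k in eligible[(i, j)]]
        pa = align_pair(
            structures[i], structures[j], params.similarity, params.criterion,
            params.clique, rng, pairs=elig,
        )
        alignments[(i, j)] = pa
        id_of = {id(dp): k for k, dp in enumerate(dps)}
        used[(i, j)] = {id_of[id(dp)] for dp in pa.descriptor_pairs}
        sim[i, j] = sim[j, i] = pa.size
        ma2 = from_pairwise(pa, structures) if pa.pairs else None
        pw_fit[(i, j)] = fitness(ma2, params.fitness, params.criterion) if ma2 else 0.0
    return alignments, used, sim, pw_fit


def _structure_contribution(best: Specimen, s: int, params: Params) -> float:
    """Leave-one-out contribution of structure ``s`` to the best fitness."""
    others = best.alignment.structure_indices - {s}
    if not others:
        return best.fitness
    reduced = best.alignment.restrict(others)
    return best.fitness - fitness(reduced, params.fitness, params.criterion)


def gradual_extension(
    structures: list[Structure],
    params: Params = Params(),
    rng: np.random.Generator | int = 0,
    pool: PairPool | None = None,
    min_segments: int = 1,
) -> tuple[Specimen, SearchSpace]:
    """Evolutionary search with gradually extended descriptor-pair space.

    Starts from the consensus of all-vs-all pairwise alignments (only the
    descriptor pairs they used are allowed), refines with the steady-state
    EA, then repeatedly frees the most under-performing structure — the
    one whose summed pairwise scores most exceed its contribution to the
    best multiple alignment — until every structure is unconstrained.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if len(structures) < 3:
        raise ValueError("gradual extension needs at least 3 structures")
    pool = pool if pool is not None else PairPool(structures, params)
    eligible = pool.eligible_ids(min_segments)
    _, used, sim, pw_fit = _pairwise_layer(structures, pool, eligible, params, rng)
    space = SearchSpace(pool, eligible, allowed={k: set(v) for k, v in used.items()})
    for s in range(len(structures)):
        if all(space.allowed[key] >= set(eligible[key]) for key in eligible if s in key):
            space.freed.add(s)
    population = []
    for _ in range(params.ea.n_init_trees):
        tree = stochastic_nj(sim, rng)
        population.append(progressive(tree, space, params, rng, structures))
    best, pop = steady_state(population, space, params, rng)
    overall_best = best
    while not space.all_freed():
        candidates = [s for s in range(len(structures)) if s not in space.freed]
        deficits = []
        for s in candidates:
            pw_sum = sum(v for (i, j), v in pw_fit.items() if s in (i, j))
            deficits.append((pw_sum - _structure_contribution(best, s, params), -s))
        worst = candidates[int(np.argmax([d[0] for d in deficits]))]
        log.info("freeing structure %d (%s)", worst, structures[worst].name)
        space.free(worst)
        best, pop = steady_state(pop, space, params, rng)
        if best.fitness > overall_best.fitness:
            overall_best = best
    return overall_best, space


def _extend_alignment(
    ma: MultipleAlignment,
    extra: list[tuple[int, int, DescriptorPair]],
    structures: list[Structure],
) -> MultipleAlignment:
    """Extension pass: admit descriptor pairs that are consistent with the
    accumulated alignment and overlap the stage-1 alignment (touch at
    least one residue it aligned), merging columns greedily (largest
    descriptor pair first, then lowest RMSD)."""
    core_residues = {
        (s, r) for col in ma.columns if len(col) > 1 for s, r in col.items()
    }
    # every residue sits in exactly one column (singletons included)
    col_of: dict[tuple[int, int], int] = {}
    columns = [dict(c) for c in ma.columns]
    for s in range(len(structures)):
        present = {c[s] for c in columns if s in c}
        for r in range(len(structures[s])):
            if r not in present:
                columns.append({s: r})
    for idx, col in enumerate(columns):
        for s, r in col.items():
            col_of[(s, r)] = idx
    parent = list(range(len(columns)))
    groups: dict[int, dict[int, int]] = {i: dict(c) for i, c in enumerate(columns)}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    order = sorted(
        range(len(extra)),
        key=lambda k: (-extra[k][2].size, extra[k][2].rmsd, extra[k][0], extra[k][1],
                       extra[k][2].desc_a.central, extra[k][2].desc_b.central),
    )
    for k in order:
        u, v, dp = extra[k]
        corr = sorted(dp.correspondence.items())
        overlap = any(
            (u, ru) in core_residues or (v, rv) in core_residues for ru, rv in corr
        )
        if not overlap:
            continue
        # simulate the unions on a scratch union-find to test consistency
        local: dict[int, int] = {}

        def lfind(x: int) -> int:
            while x in local:
                x = local[x]
            return x

        scratch: dict[int, dict[int, int]] = {}
        need: list[tuple[int, int]] = []
        ok = True
        for ru, rv in corr:
            cu = lfind(find(col_of[(u, ru)]))
            cv = lfind(find(col_of[(v, rv)]))
            if cu == cv:
                continue
            gu = scratch.get(cu, groups[cu])
            gv = scratch.get(cv, groups[cv])
            if set(gu) & set(gv):  # would force two residues of one structure together
                ok = False
                break
            local[cv] = cu
            scratch[cu] = {**gu, **gv}
            scratch.pop(cv, None)
            need.append((cu, cv))
        if ok and need:
            for cu, cv in need:
                a, b = find(cu), find(cv)
                if a == b:
                    continue
                parent[b] = a
                groups[a] = {**groups[a], **groups.pop(b)}
    roots = sorted({find(i) for i in range(len(columns))})
    return MultipleAlignment(ma.structures, [groups[r] for r in roots if groups[r]])


def two_stage(
    structures: list[Structure],
    params: Params = Params(),
    rng: np.random.Generator | int = 0,
    pool: PairPool | None = None,
) -> MultipleAlignment:
    """Core-then-refine alignment.

    Stage 1 builds the core using only descriptor pairs with at least
    ``min_segments_core`` segments (these capture protein cores but may
    miss loops and linkers); stage 2 extends the result with every
    remaining descriptor pair that is consistent with and overlaps the
    core alignment.  If stage 1 produces no aligned columns, the search is
    rerun on the unrestricted pool.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if len(structures) < 2:
        raise ValueError("need at least 2 structures")
    pool = pool if pool is not None else PairPool(structures, params)
    core_min = params.ea.min_segments_core

    def _best_alignment(min_segments: int) -> MultipleAlignment:
        if len(structures) == 2:
            elig = pool.eligible_ids(min_segments)[(0, 1)]
            dps = [pool.pairs[(0, 1)][k] for k in elig]
            pa = align_pair(structures[0], structures[1], params.similarity,
                            params.criterion, params.clique, rng, pairs=dps)
            return from_pairwise(pa, structures) if pa.pairs else MultipleAlignment(structures, [])
        best, _ = gradual_extension(structures, params, rng, pool, min_segments)
        return best.alignment

    try:
        core = _best_alignment(core_min)
    except ValueError:
        core = MultipleAlignment(structures, [])
    if not any(len(c) > 1 for c in core.columns):
        core = _best_alignment(1)
    if not any(len(c) > 1 for c in core.columns):
        return core
    extra = [
        (i, j, dp) for (i, j), dps in sorted(pool.pairs.items()) for dp in dps
    ]
    return _extend_alignment(core, extra, structures)
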