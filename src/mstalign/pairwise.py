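"""Pairwise structure alignment as a maximal consistent ensemble of
descriptor pairs.

Descriptor pairs become nodes of a consistency graph; two nodes are linked
when the union of their residue correspondences is still injective both
ways.  The largest alignment corresponds to a maximum-weight clique, found
either exactly (branch and bound, small graphs) or with a multistart
replicator-dynamics heuristic motivated by the Motzkin–Straus theorem.
No geometric agreement is required at the edge level: flexibility and
sequence permutations are scored later, not forbidden here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .descriptors import ContactCriterion, DescriptorPair, SimilarityParams, all_descriptor_pairs
from .structure import Structure


@dataclass(frozen=True)
class CliqueParams:
    exact_limit: int = 25
    restarts: int = 8
    tol: float = 1e-7
    max_iter: int = 300


@dataclass
class SimilarityGraph:
    """Consistency graph over descriptor pairs (or any payload).

    ``adjacency`` is a symmetric boolean matrix with a False diagonal;
    ``node_weight`` is each node's alignment-size contribution.
    """

    nodes: list
    adjacency: np.ndarray
    node_weight: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.nodes)
        assert self.adjacency.shape == (n, n)
        assert not self.adjacency.diagonal().any(), "no self-edges"
        assert (self.adjacency == self.adjacency.T).all(), "adjacency must be symmetric"


@dataclass
class PairwiseAlignment:
    structure_a: Structure
    structure_b: Structure
    pairs: set[tuple[int, int]]
    support: dict[tuple[int, int], int] = field(default_factory=dict)
    descriptor_pairs: list[DescriptorPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        a_seen = [a for a, _ in self.pairs]
        b_seen = [b for _, b in self.pairs]
        if len(set(a_seen)) != len(a_seen) or len(set(b_seen)) != len(b_seen):
            raise ValueError("pairwise alignment is not injective")

    @property
    def size(self) -> int:
        return len(self.pairs)

    def inverted(self) -> "PairwiseAlignment":
        return PairwiseAlignment(
            self.structure_b,
            self.structure_a,
            {(b, a) for a, b in self.pairs},
            {(b, a): c for (a, b), c in self.support.items()},
            [dp.inverted() for dp in self.descriptor_pairs],
        )


def _corr_arrays(nodes: Sequence[DescriptorPair], na: int, nb: int) -> tuple[np.ndarray, np.ndarray]:
    ma = np.full((len(nodes), na), -1, dtype=np.int32)
    mb = np.full((len(nodes), nb), -1, dtype=np.int32)
    for k, dp in enumerate(nodes):
        for x, y in dp.correspondence.items():
            ma[k, x] = y
            mb[k, y] = x
    return ma, mb


def consistent(p: DescriptorPair, q: DescriptorPair) -> bool:
    """True iff the union of the two correspondences is injective both ways."""
    if p.desc_a.structure is not q.desc_a.structure or p.desc_b.structure is not q.desc_b.structure:
        raise ValueError("descriptor pairs must be over the same structure pair")
    for x, y in p.correspondence.items():
        if q.correspondence.get(x, y) != y:
            return False
    qrev = {v: k for k, v in q.correspondence.items()}
    for x, y in p.correspondence.items():
        if qrev.get(y, x) != x:
            return False
    return True


def build_similarity_graph(nodes: list[DescriptorPair], na: int, nb: int) -> SimilarityGraph:
    """Consistency graph with vectorized mutual-injectivity edges."""
    n = len(nodes)
    ma, mb = _corr_arrays(nodes, na, nb)
    adj = np.ones((n, n), dtype=bool)
    chunk = max(1, int(4e6 // max(na + nb, 1)))
    for s in range(0, n, chunk):
        e = min(n, s + chunk)
        da = (ma[s:e, None, :] >= 0) & (ma[None, :, :] >= 0)
        conflict = (da & (ma[s:e, None, :] != ma[None, :, :])).any(axis=2)
        db = (mb[s:e, None, :] >= 0) & (mb[None, :, :] >= 0)
        conflict |= (db & (mb[s:e, None, :] != mb[None, :, :])).any(axis=2)
        adj[s:e] = ~conflict
    np.fill_diagonal(adj, False)
    weights = np.array([dp.size for dp in nodes], dtype=float)
    return SimilarityGraph(list(nodes), adj, weights)


def max_clique_exact(g: SimilarityGraph, limit: int = 25) -> set[int]:
    """Maximum-weight clique by exhaustive branch and bound.

    Deterministic: among maximum-weight cliques the lexicographically
    smallest node set is returned.  Refuses graphs above ``limit`` nodes.
    """
    n = len(g.nodes)
    if n > limit:
        raise ValueError(f"graph has {n} nodes, exact limit is {limit}")
    if n == 0:
        return set()
    w = g.node_weight
    neigh = [int(sum(1 << j for j in np.nonzero(g.adjacency[i])[0])) for i in range(n)]
    best: list[tuple[float, tuple[int, ...]]] = [(-1.0, ())]

    def expand(current: tuple[int, ...], cur_w: float, cand: int) -> None:
        if cand == 0:
            key = (cur_w, tuple(current))
            if cur_w > best[0][0] or (cur_w == best[0][0] and tuple(current) < best[0][1]):
                best[0] = (cur_w, tuple(current))
            return
        rest = sum(w[i] for i in _bits(cand))
        if cur_w + rest < best[0][0]:
            return
        # also record the current clique itself
        if cur_w > best[0][0] or (cur_w == best[0][0] and tuple(current) < best[0][1]):
            best[0] = (cur_w, tuple(current))
        c = cand
        while c:
            i = (c & -c).bit_length() - 1
            c &= c - 1
            # prune: remaining candidates (i and onward) cannot beat best
            rem = sum(w[j] for j in _bits(cand & ~((1 << i) - 1)))
            if cur_w + rem < best[0][0]:
                return
            expand(current + (i,), cur_w + w[i], cand & neigh[i] & ~((1 << (i + 1)) - 1))
        return

    expand((), 0.0, (1 << n) - 1)
    return set(best[0][1])


def _bits(mask: int):
    while mask:
        i = (mask & -mask).bit_length() - 1
        yield i
        mask &= mask - 1


def _greedy_clique(adj: np.ndarray, order: np.ndarray) -> list[int]:
    chosen: list[int] = []
    ok = np.ones(adj.shape[0], dtype=bool)
    for i in order:
        if ok[i]:
            chosen.append(int(i))
            ok &= adj[i]
            ok[i] = False
    return chosen


def max_clique_heuristic(
    g: SimilarityGraph, restarts: int = 8, seed: int | np.random.Generator = 0,
    tol: float = 1e-7, max_iter: int = 300,
) -> set[int]:
    """Multistart replicator dynamics on the clique quadratic form.

    Iterates x ← x∘(Ax)/(xᵀAx) over the probability simplex (A the 0/1
    adjacency), whose strict local maxima characterize maximal cliques;
    the converged support is refined greedily into a clique and completed
    by weight.  The best clique over all restarts (plus one deterministic
    weight-greedy start) is returned; the result is always a clique.
    """
    n = len(g.nodes)
    if n == 0:
        return set()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    adj = g.adjacency
    a = adj.astype(float)
    w = g.node_weight
    base_order = np.lexsort((np.arange(n), -w))
    candidates: list[list[int]] = [_greedy_clique(adj, base_order)]
    # greedy growth seeded at each of the heaviest nodes: cheap insurance on
    # small sparse graphs where the replicator support can be misleading
    for i in base_order[: min(n, 32)]:
        order = np.concatenate(([i], base_order[base_order != i]))
        candidates.append(_greedy_clique(adj, order))
    starts = [np.full(n, 1.0 / n)]
    for _ in range(max(restarts - 1, 0)):
        starts.append(rng.dirichlet(np.ones(n)))
    for x in starts:
        x = x.copy()
        for _ in range(max_iter):
            ax = a @ x
            denom = x @ ax
            if denom <= 1e-12:
                break
            x_new = x * ax / denom
            if np.max(np.abs(x_new - x)) < tol:
                x = x_new
                break
            x = x_new
        support = np.nonzero(x > max(1e-9, x.max() * 1e-4))[0]
        order = support[np.lexsort((support, -x[support]))]
        clique = _greedy_clique(adj, order)
        # complete with any compatible nodes, heaviest first
        mask = np.ones(n, dtype=bool)
        for i in clique:
            mask &= adj[i]
        for i in base_order:
            if mask[i]:
                clique.append(int(i))
                mask &= adj[i]
        candidates.append(clique)
    best = max(candidates, key=lambda c: (sum(w[i] for i in c), tuple(sorted(c))))
    assert _is_clique(adj, best)
    return set(best)


def _is_clique(adj: np.ndarray, nodes: Sequence[int]) -> bool:
    nodes = list(nodes)
    return all(adj[i, j] for k, i in enumerate(nodes) for j in nodes[k + 1 :])


def resolve_conflicts(
    nodes: Sequence, weights: Sequence[float], conflicts: Sequence[tuple[int, int]]
) -> list[int]:
    """Indices to KEEP after minimum-loss conflict removal.

    Finds, by branch and bound, a removal set covering every conflict edge
    with the smallest total weight (ties: fewer nodes removed, then
    lexicographically smallest removal set).  With an empty conflict list
    the input is kept unchanged.
    """
    n = len(nodes)
    w = np.asarray(weights, dtype=float)
    edges = [tuple(e) for e in conflicts]
    if not edges:
        return list(range(n))
    best: list[tuple[float, int, tuple[int, ...]]] = [(float("inf"), n + 1, ())]

    def search(removed: frozenset[int], loss: float) -> None:
        key = (loss, len(removed), tuple(sorted(removed)))
        if key >= best[0]:
            return
        for u, v in edges:
            if u not in removed and v not in removed:
                for cand in sorted((u, v)):
                    search(removed | {cand}, loss + w[cand])
                return
        best[0] = key

    search(frozenset(), 0.0)
    removed = set(best[0][2])
    return [i for i in range(n) if i not in removed]


def align_pair(
    sa: Structure,
    sb: Structure,
    params: SimilarityParams = SimilarityParams(),
    criterion: ContactCriterion = ContactCriterion(),
    clique: CliqueParams = CliqueParams(),
    seed: int | np.random.Generator = 0,
    pairs: list[DescriptorPair] | None = None,
) -> PairwiseAlignment:
    """Full pairwise alignment of two structures.

    Pipeline: similar descriptor pairs → consistency graph → clique search
    (exact when small, heuristic otherwise) → union of correspondences.
    An empty descriptor-pair list yields an empty alignment, not an error.
    """
    dps = pairs if pairs is not None else all_descriptor_pairs(sa, sb, params, criterion)
    if not dps:
        return PairwiseAlignment(sa, sb, set())
    g = build_similarity_graph(dps, len(sa), len(sb))
    if len(dps) <= clique.exact_limit:
        sel = max_clique_exact(g, clique.exact_limit)
    else:
        sel = max_clique_heuristic(g, clique.restarts, seed, clique.tol, clique.max_iter)
    chosen = [dps[i] for i in sorted(sel)]
    pair_set: set[tuple[int, int]] = set()
    support: dict[tuple[int, int], int] = {}
    for dp in chosen:
        for x, y in dp.correspondence.items():
            pair_set.add((x, y))
            support[(x, y)] = support.get((x, y), 0) + 1
    return PairwiseAlignment(sa, sb, pair_set, support, chosen)
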