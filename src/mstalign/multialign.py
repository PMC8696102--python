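"""Multiple alignments as column sets, and profile–profile alignment.

A multiple alignment is a list of columns, each mapping structure indices
(into one shared structure list) to exactly one residue ordinal.  Two
different residues of one structure may never share a column, and a
(structure, residue) may appear in at most one column.

Profile alignment merges the columns of two sub-alignments over disjoint
structure subsets.  Candidate merges are supported by descriptor pairs; a
maximal consistent merge set is found with the same clique machinery used
for pairwise alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .descriptors import DescriptorPair
from .pairwise import (
    CliqueParams,
    PairwiseAlignment,
    SimilarityGraph,
    max_clique_exact,
    max_clique_heuristic,
    resolve_conflicts,
)
from .structure import Structure


class MultipleAlignment:
    """Columns of equivalent residues over a shared structure list.

    ``columns`` maps structure index -> residue ordinal; all alignments in
    one run share the same ``structures`` list, so sub-alignments simply
    use a subset of the indices.
    """

    def __init__(self, structures: list[Structure], columns: list[dict[int, int]]):
        self.structures = structures
        self.columns = [dict(c) for c in columns]
        self.validate()

    def validate(self) -> None:
        seen: set[tuple[int, int]] = set()
        for col in self.columns:
            if not col:
                raise ValueError("empty column")
            for s, r in col.items():
                if not 0 <= s < len(self.structures):
                    raise ValueError(f"bad structure index {s}")
                if not 0 <= r < len(self.structures[s]):
                    raise ValueError(f"bad residue ordinal {r} for structure {s}")
                if (s, r) in seen:
                    raise ValueError(f"residue ({s},{r}) in two columns")
                seen.add((s, r))

    def __len__(self) -> int:
        return len(self.columns)

    @property
    def structure_indices(self) -> set[int]:
        return {s for col in self.columns for s in col}

    def residue_to_column(self) -> dict[tuple[int, int], int]:
        return {(s, r): i for i, col in enumerate(self.columns) for s, r in col.items()}

    def aligned_pairs(self) -> set[tuple[tuple[int, int], tuple[int, int]]]:
        """Induced residue pairs ((si, ri), (sj, rj)) with si < sj."""
        out = set()
        for col in self.columns:
            items = sorted(col.items())
            for i in range(len(items)):
                for j in range(i + 1, len(items)):
                    out.add((items[i], items[j]))
        return out

    def pairs_for(self, si: int, sj: int) -> list[tuple[int, int]]:
        """Aligned residue pairs (ordinal in si, ordinal in sj)."""
        return [(c[si], c[sj]) for c in self.columns if si in c and sj in c]

    def restrict(self, subset: set[int]) -> "MultipleAlignment":
        """Sub-alignment over a structure subset (same global indexing)."""
        cols = []
        for col in self.columns:
            kept = {s: r for s, r in col.items() if s in subset}
            if kept:
                cols.append(kept)
        return MultipleAlignment(self.structures, cols)

    def n_aligned_pairs(self) -> int:
        return sum(len(c) * (len(c) - 1) // 2 for c in self.columns)

    def copy(self) -> "MultipleAlignment":
        return MultipleAlignment(self.structures, [dict(c) for c in self.columns])


def singleton_alignment(structures: list[Structure], index: int) -> MultipleAlignment:
    """Trivial alignment of one structure: one singleton column per residue."""
    return MultipleAlignment(structures, [{index: r} for r in range(len(structures[index]))])


def from_pairwise(pa: PairwiseAlignment, structures: list[Structure] | None = None) -> MultipleAlignment:
    """Two-structure alignment with one column per aligned pair."""
    if structures is None:
        structures = [pa.structure_a, pa.structure_b]
        ia, ib = 0, 1
    else:
        ia = structures.index(pa.structure_a)
        ib = structures.index(pa.structure_b)
    cols = [{ia: a, ib: b} for a, b in sorted(pa.pairs)]
    return MultipleAlignment(structures, cols)


@dataclass
class ConflictReport:
    """Transitive conflicts found when merging pairwise alignments.

    Each conflict lists ≥2 residues of one structure that the union of the
    alignments would place in a single column, with a witnessing chain of
    residue equivalences.
    """

    conflicts: list[dict]

    def __bool__(self) -> bool:
        return bool(self.conflicts)


def detect_conflicts(pairwise: list[PairwiseAlignment], structures: list[Structure]) -> ConflictReport:
    """Find residues transitively forced together by a set of pairwise
    alignments over a common structure list.
    """
    g = nx.Graph()
    for pa in pairwise:
        ia = structures.index(pa.structure_a)
        ib = structures.index(pa.structure_b)
        for a, b in pa.pairs:
            g.add_edge((ia, a), (ib, b))
    conflicts = []
    for comp in nx.connected_components(g):
        by_structure: dict[int, list[tuple[int, int]]] = {}
        for node in comp:
            by_structure.setdefault(node[0], []).append(node)
        for s, nodes in sorted(by_structure.items()):
            if len(nodes) > 1:
                nodes = sorted(nodes)
                chain = nx.shortest_path(g, nodes[0], nodes[1])
                conflicts.append({"structure": s, "residues": [n[1] for n in nodes], "chain": chain})
    return ConflictReport(conflicts)


def align_profiles(
    ma1: MultipleAlignment,
    ma2: MultipleAlignment,
    allowed: list[tuple[int, int, DescriptorPair]],
    clique: CliqueParams = CliqueParams(),
    seed: int | np.random.Generator = 0,
    candidate_cap: int = 800,
) -> MultipleAlignment:
    """Align two multiple alignments over disjoint structure subsets.

    ``allowed`` lists descriptor pairs as (structure index u, structure
    index v, pair) with the pair's correspondence mapping residues of u to
    residues of v; orientation is fixed up internally.  Candidate column
    merges are scored by supporting descriptor pairs times newly created
    residue pairs; a maximal consistent merge set is selected by clique
    search, residual conflicts are resolved by minimum-loss removal, and
    unmerged columns pass through unchanged.
    """
    side1, side2 = ma1.structure_indices, ma2.structure_indices
    if side1 & side2:
        raise ValueError("structure sets of the two profiles must be disjoint")
    r2c1 = ma1.residue_to_column()
    r2c2 = ma2.residue_to_column()
    support: dict[tuple[int, int], set[int]] = {}
    for dp_id, (u, v, dp) in enumerate(allowed):
        if u in side1 and v in side2:
            corr = dp.correspondence.items()
        elif v in side1 and u in side2:
            u, v = v, u
            corr = [(y, x) for x, y in dp.correspondence.items()]
        else:
            continue
        for ru, rv in corr:
            c1 = r2c1.get((u, ru))
            c2 = r2c2.get((v, rv))
            if c1 is not None and c2 is not None:
                support.setdefault((c1, c2), set()).add(dp_id)
    if not support:
        return MultipleAlignment(ma1.structures, ma1.columns + ma2.columns)
    cands = sorted(support)
    weights = np.array(
        [len(support[c]) * len(ma1.columns[c[0]]) * len(ma2.columns[c[1]]) for c in cands],
        dtype=float,
    )
    if len(cands) > candidate_cap:
        keep = np.sort(np.argsort(-weights, kind="stable")[:candidate_cap])
        cands = [cands[i] for i in keep]
        weights = weights[keep]
    c1s = np.array([c[0] for c in cands])
    c2s = np.array([c[1] for c in cands])
    conflict = (c1s[:, None] == c1s[None, :]) | (c2s[:, None] == c2s[None, :])
    adj = ~conflict
    np.fill_diagonal(adj, False)
    g = SimilarityGraph(list(cands), adj, weights)
    if len(cands) <= clique.exact_limit:
        sel = max_clique_exact(g, clique.exact_limit)
    else:
        sel = max_clique_heuristic(g, clique.restarts, seed, clique.tol, clique.max_iter)
    sel_sorted = sorted(sel)
    # residual conflicts cannot survive clique edges, but resolve anyway to
    # keep the generic guarantee machine-checked
    edges = [
        (i, j)
        for i in range(len(sel_sorted))
        for j in range(i + 1, len(sel_sorted))
        if conflict[sel_sorted[i], sel_sorted[j]]
    ]
    kept = resolve_conflicts(sel_sorted, [weights[i] for i in sel_sorted], edges)
    merged = {cands[sel_sorted[i]][0]: cands[sel_sorted[i]][1] for i in kept}
    used2 = set(merged.values())
    columns: list[dict[int, int]] = []
    for i, col in enumerate(ma1.columns):
        if i in merged:
            columns.append({**col, **ma2.columns[merged[i]]})
        else:
            columns.append(dict(col))
    for j, col in enumerate(ma2.columns):
        if j not in used2:
            columns.append(dict(col))
    out = MultipleAlignment(ma1.structures, columns)
    return out


# ---------------------------------------------------------------------------
# writers

def _column_order(ma: MultipleAlignment, master: int | None = None) -> list[int]:
    """Deterministic column layout: topological sort of residue order with
    blocks emitted in master-structure order (first structure by default);
    columns not containing the master follow in the order of the lowest
    structure index and residue they contain.
    """
    if master is None:
        master = min(ma.structure_indices) if ma.columns else 0

    def key(i: int) -> tuple:
        col = ma.columns[i]
        if master in col:
            return (0, col[master])
        s = min(col)
        return (1, s, col[s])

    return sorted(range(len(ma.columns)), key=key)


def to_fasta(ma: MultipleAlignment, master: int | None = None) -> str:
    """FASTA alignment: one record per structure, aligned residues as
    upper-case letters, gaps '-'.  Column order is the deterministic layout
    of :func:`_column_order`; sequentially incompatible (permuted) blocks
    appear in master-structure order.
    """
    order = _column_order(ma, master)
    indices = sorted(ma.structure_indices) if ma.columns else []
    lines = []
    for s in indices:
        st = ma.structures[s]
        seq = []
        for i in order:
            col = ma.columns[i]
            seq.append(st.residues[col[s]].aa.upper() if s in col else "-")
        lines.append(f">{st.name}")
        lines.append("".join(seq))
    return "\n".join(lines) + "\n"


def to_residue_ranges(ma: MultipleAlignment) -> str:
    """Per structure: contiguous aligned blocks as 'chain:start-end' lists.

    Only residues in multi-structure columns count as aligned.
    """
    lines = []
    for s in sorted(ma.structure_indices):
        st = ma.structures[s]
        aligned = sorted(c[s] for c in ma.columns if s in c and len(c) > 1)
        blocks: list[list[int]] = []
        for r in aligned:
            if blocks and r == blocks[-1][1] + 1 and st.same_chain(r, blocks[-1][0]):
                blocks[-1][1] = r
            else:
                blocks.append([r, r])
        span = []
        for b0, b1 in blocks:
            c0, n0, i0 = st.residues[b0].id
            _, n1, i1 = st.residues[b1].id
            span.append(f"{c0}:{n0}{i0}-{n1}{i1}")
        lines.append(f"{st.name}\t" + (" ".join(span) if span else "-"))
    return "\n".join(lines) + "\n"
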