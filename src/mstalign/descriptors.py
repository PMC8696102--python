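"""Local descriptors of protein structure.

A descriptor captures the spatial neighborhood of one central residue: the
residues it contacts, expanded into 5-residue backbone windows (*elements*,
two sequential neighbors on each side), which are merged into maximal
continuous *segments*.  Pairs of similar descriptors from two structures
are the elementary building blocks of every alignment computed here.

Contact criterion: residues i, j are in contact when dα ≤ 6.5 Å, or
dC ≤ 8 Å and dα − dC ≥ 0.75 Å, where dα is the Cα–Cα distance and dC the
distance between side-chain geometric centers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

from .structure import Structure, batch_rmsd, superpose

HALF_WINDOW = 2  # element = center ± 2


@dataclass(frozen=True)
class ContactCriterion:
    """Thresholds of the residue–residue contact definition (Å)."""

    d_alpha_max: float = 6.5
    d_c_max: float = 8.0
    d_diff_min: float = 0.75

    def __post_init__(self) -> None:
        if min(self.d_alpha_max, self.d_c_max, self.d_diff_min) <= 0:
            raise ValueError("contact thresholds must be positive")


@dataclass(frozen=True)
class SimilarityParams:
    """Descriptor-pair similarity thresholds.

    ``min_elements`` counts the central element; ``rmsd_max`` applies to the
    optimal superposition of all corresponded Cα; ``element_rmsd_max``
    gates individual element matches under the running transform.
    """

    min_elements: int = 3
    rmsd_max: float = 2.5
    element_rmsd_max: float = 1.5
    central_rmsd_max: float = 1.5


@dataclass(frozen=True)
class Element:
    """5-residue backbone window centered on a contact (or central) residue."""

    center: int
    members: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.members) != 2 * HALF_WINDOW + 1:
            raise ValueError("element must have 5 members")
        if self.members[HALF_WINDOW] != self.center:
            raise ValueError("center must be the middle member")
        if list(self.members) != list(range(self.members[0], self.members[-1] + 1)):
            raise ValueError("members must be consecutive")


@dataclass
class Descriptor:
    structure: Structure
    central: int
    contacts: frozenset[int]
    elements: list[Element]
    segments: list[tuple[int, int]]  # inclusive (start, end) ordinal runs

    @property
    def residue_set(self) -> frozenset[int]:
        return frozenset(o for s, e in self.segments for o in range(s, e + 1))

    def __repr__(self) -> str:
        return (
            f"Descriptor({self.structure.name}:{self.central}, "
            f"{len(self.contacts)} contacts, {len(self.segments)} segments)"
        )


@dataclass
class DescriptorPair:
    """Residue-level correspondence between two similar descriptors."""

    desc_a: Descriptor
    desc_b: Descriptor
    correspondence: dict[int, int]  # ordinal in a's structure -> ordinal in b's
    rmsd: float
    n_aligned_elements: int
    n_segments: int

    @property
    def size(self) -> int:
        return len(self.correspondence)

    def inverted(self) -> "DescriptorPair":
        inv = {v: k for k, v in self.correspondence.items()}
        n_seg = _covered_segments(self.desc_b, inv.keys())
        return DescriptorPair(self.desc_b, self.desc_a, inv, self.rmsd, self.n_aligned_elements, n_seg)


def contact_matrix(structure: Structure, criterion: ContactCriterion = ContactCriterion()) -> np.ndarray:
    """Boolean n×n matrix of the symmetric contact relation (diagonal False)."""
    d_alpha = cdist(structure.ca, structure.ca)
    d_c = cdist(structure.sc, structure.sc)
    contacts = (d_alpha <= criterion.d_alpha_max) | (
        (d_c <= criterion.d_c_max) & (d_alpha - d_c >= criterion.d_diff_min)
    )
    np.fill_diagonal(contacts, False)
    return contacts


def find_contacts(structure: Structure, center: int, criterion: ContactCriterion = ContactCriterion()) -> set[int]:
    """Residues in contact with ``center`` (the center itself excluded)."""
    if not 0 <= center < len(structure):
        raise IndexError(f"center {center} out of range")
    d_alpha = np.linalg.norm(structure.ca - structure.ca[center], axis=1)
    d_c = np.linalg.norm(structure.sc - structure.sc[center], axis=1)
    mask = (d_alpha <= criterion.d_alpha_max) | (
        (d_c <= criterion.d_c_max) & (d_alpha - d_c >= criterion.d_diff_min)
    )
    mask[center] = False
    return set(np.nonzero(mask)[0].tolist())


def merge_elements(elements: list[Element]) -> list[tuple[int, int]]:
    """Merge overlapping element windows into maximal consecutive runs.

    Windows merge only when they share a residue; runs that are merely
    adjacent stay separate.
    """
    if not elements:
        return []
    ivs = sorted((e.members[0], e.members[-1]) for e in elements)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:  # shared residue
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def build_descriptor(
    structure: Structure, center: int, criterion: ContactCriterion = ContactCriterion()
) -> Descriptor | None:
    """Build the descriptor of ``center``, or None if its own ±2 window does
    not fit inside the chain.

    Contact residues whose window would cross a terminus or chain boundary
    are dropped (they center no valid element).
    """
    if not structure.window_valid(center):
        return None
    raw = find_contacts(structure, center, criterion)
    kept = sorted(c for c in raw if structure.window_valid(c))
    centers = [center] + kept
    elements = [Element(c, tuple(range(c - HALF_WINDOW, c + HALF_WINDOW + 1))) for c in sorted(centers)]
    segments = merge_elements(elements)
    return Descriptor(structure, center, frozenset(kept), elements, segments)


def build_all_descriptors(
    structure: Structure, criterion: ContactCriterion = ContactCriterion()
) -> dict[int, Descriptor]:
    """Descriptors for every residue with a valid central window."""
    cm = contact_matrix(structure, criterion)
    valid = np.array([structure.window_valid(i) for i in range(len(structure))])
    out: dict[int, Descriptor] = {}
    for center in np.nonzero(valid)[0]:
        kept = sorted(int(j) for j in np.nonzero(cm[center])[0] if valid[j])
        centers = sorted([int(center)] + kept)
        elements = [Element(c, tuple(range(c - HALF_WINDOW, c + HALF_WINDOW + 1))) for c in centers]
        out[int(center)] = Descriptor(
            structure, int(center), frozenset(kept), elements, merge_elements(elements)
        )
    return out


def _covered_segments(desc: Descriptor, residues) -> int:
    rs = set(residues)
    return sum(1 for s, e in desc.segments if any(o in rs for o in range(s, e + 1)))


def _window(structure: Structure, center: int) -> np.ndarray:
    return structure.ca[center - HALF_WINDOW : center + HALF_WINDOW + 1]


def align_descriptors(
    a: Descriptor, b: Descriptor, params: SimilarityParams = SimilarityParams()
) -> DescriptorPair | None:
    """Align two descriptors element-by-element.

    The central elements are corresponded position-by-position and define a
    rigid transform; remaining elements are matched (whole 5-residue
    windows, in order, no reversal) by minimal RMSD under that transform
    via an assignment problem.  The pair is accepted when at least
    ``min_elements`` elements align and the optimal superposition of all
    corresponded Cα has RMSD ≤ ``rmsd_max``.  Elements may match out of
    sequence order (permutations allowed across segments).
    """
    if a.structure is b.structure:
        raise ValueError("descriptors must come from different structures")
    wa, wb = _window(a.structure, a.central), _window(b.structure, b.central)
    sup = superpose(wa, wb)
    if sup.rmsd > params.central_rmsd_max:
        return None
    ea = [e for e in a.elements if e.center != a.central]
    eb = [e for e in b.elements if e.center != b.central]
    awin = np.stack([_window(a.structure, e.center) for e in ea]) if ea else None
    central_map = list(
        zip(
            range(a.central - HALF_WINDOW, a.central + HALF_WINDOW + 1),
            range(b.central - HALF_WINDOW, b.central + HALF_WINDOW + 1),
        )
    )

    def _match(transform) -> tuple[dict[int, int], int]:
        matches: list[tuple[float, Element, Element]] = []
        if ea and eb:
            bwin = np.stack([transform(_window(b.structure, e.center)) for e in eb])
            # positional rmsd under the shared transform: elements must agree
            # in one common frame, not merely be locally similar
            diff = awin[:, None, :, :] - bwin[None, :, :, :]
            cost = np.sqrt(np.mean(np.sum(diff * diff, axis=-1), axis=-1))
            big = cost > params.element_rmsd_max
            cost_masked = np.where(big, 1e6, cost)
            rows, cols = linear_sum_assignment(cost_masked)
            for r, c in zip(rows, cols):
                if not big[r, c]:
                    matches.append((float(cost[r, c]), ea[r], eb[c]))
        matches.sort(key=lambda t: (t[0], t[1].center, t[2].center))
        fwd: dict[int, int] = {}
        rev: dict[int, int] = {}
        for x, y in central_map:
            fwd[x] = y
            rev[y] = x
        n_elem = 1
        for _, e_a, e_b in matches:
            add = list(zip(e_a.members, e_b.members))
            if not all(fwd.get(x, y) == y and rev.get(y, x) == x for x, y in add):
                continue
            for x, y in add:
                fwd[x] = y
                rev[y] = x
            n_elem += 1
        return fwd, n_elem

    # round 1: frame from the central elements; round 2: frame refit on the
    # whole round-1 correspondence (stabilizes distant elements)
    fwd, n_elements = _match(sup.apply)
    if n_elements > 1:
        keys = sorted(fwd)
        refit = superpose(a.structure.ca[keys], b.structure.ca[[fwd[k] for k in keys]])
        fwd2, n2 = _match(refit.apply)
        if n2 >= n_elements:
            fwd, n_elements = fwd2, n2
    if n_elements < params.min_elements:
        return None
    keys = sorted(fwd)
    pa = a.structure.ca[keys]
    pb = b.structure.ca[[fwd[k] for k in keys]]
    total = superpose(pa, pb)
    if total.rmsd > params.rmsd_max:
        return None
    return DescriptorPair(
        desc_a=a,
        desc_b=b,
        correspondence=dict(fwd),
        rmsd=total.rmsd,
        n_aligned_elements=n_elements,
        n_segments=_covered_segments(a, fwd.keys()),
    )


def all_descriptor_pairs(
    sa: Structure,
    sb: Structure,
    params: SimilarityParams = SimilarityParams(),
    criterion: ContactCriterion = ContactCriterion(),
    descs_a: dict[int, Descriptor] | None = None,
    descs_b: dict[int, Descriptor] | None = None,
) -> list[DescriptorPair]:
    """All similar descriptor pairs between two structures, ordered by the
    central ordinals.  A batched central-window RMSD screen keeps the
    quadratic scan cheap.
    """
    da = descs_a if descs_a is not None else build_all_descriptors(sa, criterion)
    db = descs_b if descs_b is not None else build_all_descriptors(sb, criterion)
    if not da or not db:
        return []
    ca_list = sorted(da)
    cb_list = sorted(db)
    wa = np.stack([_window(sa, c) for c in ca_list])
    wb = np.stack([_window(sb, c) for c in cb_list])
    na, nb = len(ca_list), len(cb_list)
    rep_a = np.repeat(np.arange(na), nb)
    rep_b = np.tile(np.arange(nb), na)
    rms = batch_rmsd(wa[rep_a], wb[rep_b]).reshape(na, nb)
    out: list[DescriptorPair] = []
    for i, ca_ in enumerate(ca_list):
        for j, cb_ in enumerate(cb_list):
            if rms[i, j] > params.central_rmsd_max:
                continue
            dp = align_descriptors(da[ca_], db[cb_], params)
            if dp is not None:
                out.append(dp)
    return out


def describe(descriptor: Descriptor) -> str:
    """Stable diagnostic listing: center id, contact ids, segment ranges."""
    st = descriptor.structure
    fmt = lambda i: "{}{}{}".format(*st.residues[i].id)
    lines = [
        f"structure: {st.name}",
        f"center: {fmt(descriptor.central)} ({st.residues[descriptor.central].aa})",
        f"contacts ({len(descriptor.contacts)}): "
        + " ".join(fmt(c) for c in sorted(descriptor.contacts)),
        f"segments ({len(descriptor.segments)}): "
        + " ".join(f"{fmt(s)}-{fmt(e)}" for s, e in descriptor.segments),
    ]
    return "\n".join(lines)
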