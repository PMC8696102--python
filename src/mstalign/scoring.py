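"""Tension-based alignment quality and the combined fitness.

The tension of a multiple alignment treats superimposed structures as
elastic objects: for every pair of aligned residues that are in contact in
at least one of the aligned structures, the RMSD of the corresponding
5-residue backbone elements is computed, averaged per residue over its
contacts, squared, averaged over the residues of each structure pair, and
finally averaged over structure pairs.

A pairwise alignment may split into regions with no contacts between them
(e.g. two domains about a hinge).  Since internal distortions between such
regions exert no tension, the size score of every region except the
largest is discounted by (1 + cos α)/2, where α is the angle between the
rotations superposing the largest and the discounted region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .descriptors import HALF_WINDOW, ContactCriterion, contact_matrix
from .multialign import MultipleAlignment
from .structure import Structure, batch_rmsd, rotation_angle, superpose


@dataclass(frozen=True)
class FitnessParams:
    """Weights combining alignment size and tension.

    ``lambda_tension`` (Å⁻²) scales the tension penalty; the augmentation
    constant multiplies the (1 + cos α)/2 discount of non-largest regions.
    """

    lambda_tension: float = 0.05
    augmentation_constant: float = 1.0

    def __post_init__(self) -> None:
        if self.lambda_tension < 0 or self.augmentation_constant < 0:
            raise ValueError("fitness weights must be nonnegative")


@dataclass
class TensionResult:
    per_residue: dict[tuple[tuple[int, int], tuple[int, int]], float]
    per_pair: dict[tuple[int, int], float]
    total: float


@dataclass
class Region:
    pairs: list[tuple[int, int]]
    rotation: np.ndarray
    size: int
    rotation_borrowed: bool = False  # too few pairs for a rotation of its own


def _contacts_of(structure: Structure, criterion: ContactCriterion) -> np.ndarray:
    cache = getattr(structure, "_contact_cache", None)
    if cache is None:
        cache = {}
        structure._contact_cache = cache  # type: ignore[attr-defined]
    if criterion not in cache:
        cache[criterion] = contact_matrix(structure, criterion)
    return cache[criterion]


Contact = tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
# ((structure i, structure j), (ri1, rj1), (ri2, rj2))


def contact_pairs(ma: MultipleAlignment, criterion: ContactCriterion = ContactCriterion()) -> list[Contact]:
    """All pairs of aligned residue pairs in contact in at least one of the
    two structures, per structure pair."""
    out: list[Contact] = []
    indices = sorted(ma.structure_indices)
    for ii, si in enumerate(indices):
        for sj in indices[ii + 1 :]:
            pairs = ma.pairs_for(si, sj)
            if len(pairs) < 2:
                continue
            arr = np.asarray(pairs)
            cm_i = _contacts_of(ma.structures[si], criterion)
            cm_j = _contacts_of(ma.structures[sj], criterion)
            contact = cm_i[arr[:, 0][:, None], arr[:, 0][None, :]] | cm_j[
                arr[:, 1][:, None], arr[:, 1][None, :]
            ]
            ks, ls = np.nonzero(np.triu(contact, k=1))
            for k, l in zip(ks, ls):
                out.append(((si, sj), tuple(arr[k]), tuple(arr[l])))
    return out


def _element_points(contact: Contact, structures: list[Structure]) -> tuple[np.ndarray, np.ndarray] | None:
    (si, sj), (ri1, rj1), (ri2, rj2) = contact
    sti, stj = structures[si], structures[sj]
    for st, r in ((sti, ri1), (sti, ri2), (stj, rj1), (stj, rj2)):
        if not st.window_valid(r):
            return None
    offs = range(-HALF_WINDOW, HALF_WINDOW + 1)
    mapping = []
    for k in offs:
        mapping.append((ri1 + k, rj1 + k))
    for k in offs:
        if (ri2 + k, rj2 + k) not in mapping:
            mapping.append((ri2 + k, rj2 + k))
    pi = sti.ca[[m[0] for m in mapping]]
    pj = stj.ca[[m[1] for m in mapping]]
    return pi, pj


def contact_tension(contact: Contact, structures: list[Structure]) -> float | None:
    """RMSD of the two contact elements' backbones after optimal
    superposition; None when a window is invalid (contact skipped)."""
    pts = _element_points(contact, structures)
    if pts is None:
        return None
    return superpose(pts[0], pts[1]).rmsd


def tension(ma: MultipleAlignment, criterion: ContactCriterion = ContactCriterion()) -> TensionResult:
    """Alignment tension, averaged contacts → residue → (squared) → pair →
    alignment, in exactly that order."""
    contacts = contact_pairs(ma, criterion)
    # batch rmsd by point count for speed
    valid: list[tuple[Contact, np.ndarray, np.ndarray]] = []
    for c in contacts:
        pts = _element_points(c, ma.structures)
        if pts is not None:
            valid.append((c, pts[0], pts[1]))
    rmsds: dict[int, float] = {}
    by_size: dict[int, list[int]] = {}
    for idx, (_, pi, _) in enumerate(valid):
        by_size.setdefault(len(pi), []).append(idx)
    for size, idxs in by_size.items():
        a = np.stack([valid[i][1] for i in idxs])
        b = np.stack([valid[i][2] for i in idxs])
        for i, r in zip(idxs, batch_rmsd(a, b)):
            rmsds[i] = float(r)
    sums: dict[tuple[tuple[int, int], tuple[int, int]], list[float]] = {}
    for idx, (c, _, _) in enumerate(valid):
        (si, sj), (ri1, rj1), (ri2, rj2) = c
        r = rmsds[idx]
        for key in ((si, ri1), (si, ri2), (sj, rj1), (sj, rj2)):
            sums.setdefault(((si, sj), key), []).append(r)
    per_residue = {k: float(np.mean(v)) for k, v in sums.items()}
    pair_vals: dict[tuple[int, int], list[float]] = {}
    for (pair, _), v in per_residue.items():
        pair_vals.setdefault(pair, []).append(v**2)
    per_pair = {p: float(np.mean(v)) for p, v in pair_vals.items()}
    total = float(np.mean(list(per_pair.values()))) if per_pair else 0.0
    return TensionResult(per_residue, per_pair, total)


def region_decomposition(
    pairs: list[tuple[int, int]],
    structure_i: Structure,
    structure_j: Structure,
    criterion: ContactCriterion = ContactCriterion(),
) -> list[Region]:
    """Split one structure pair's aligned residue pairs into contact-free
    regions (connected components of the contact relation), each with its
    own least-squares rotation.  Regions with fewer than 3 pairs borrow the
    largest region's rotation and are flagged."""
    if not pairs:
        raise ValueError("empty pair set")
    arr = np.asarray(sorted(pairs))
    cm_i = _contacts_of(structure_i, criterion)
    cm_j = _contacts_of(structure_j, criterion)
    contact = cm_i[arr[:, 0][:, None], arr[:, 0][None, :]] | cm_j[arr[:, 1][:, None], arr[:, 1][None, :]]
    n = len(arr)
    graph = coo_matrix(contact)
    _, labels = connected_components(graph, directed=False)
    regions: list[Region] = []
    for lab in range(labels.max() + 1):
        members = [tuple(p) for p in arr[labels == lab]]
        regions.append(Region(members, np.eye(3), len(members)))
    regions.sort(key=lambda r: (-r.size, -_span(r), r.pairs))
    for reg in regions:
        if reg.size >= 3:
            sub = np.asarray(reg.pairs)
            sup = superpose(structure_i.ca[sub[:, 0]], structure_j.ca[sub[:, 1]])
            reg.rotation = sup.rotation
    largest = regions[0]
    for reg in regions:
        if reg.size < 3:
            reg.rotation = largest.rotation
            reg.rotation_borrowed = True
    return regions


def _span(region: Region) -> int:
    a = [p[0] for p in region.pairs]
    return max(a) - min(a)


def augmented_size(regions: list[Region], constant: float = 1.0) -> float:
    """Size score with rotation-angle discount of non-largest regions.

    score = |largest| + Σ |region| · constant · (1 + cos α)/2 where α is
    the angle between the largest region's rotation and the region's own.
    """
    if not regions:
        raise ValueError("need at least one region")
    ordered = sorted(regions, key=lambda r: (-r.size, -_span(r), r.pairs))
    largest = ordered[0]
    score = float(largest.size)
    for reg in ordered[1:]:
        alpha = rotation_angle(largest.rotation, reg.rotation)
        score += reg.size * constant * (1.0 + np.cos(alpha)) / 2.0
    return score


def fitness(
    ma: MultipleAlignment,
    params: FitnessParams = FitnessParams(),
    criterion: ContactCriterion = ContactCriterion(),
) -> float:
    """Combined alignment score: augmented size summed over structure
    pairs, minus the tension penalty scaled by alignment size.  Higher is
    better; an empty alignment scores 0."""
    indices = sorted(ma.structure_indices)
    size_score = 0.0
    for ii, si in enumerate(indices):
        for sj in indices[ii + 1 :]:
            pairs = ma.pairs_for(si, sj)
            if not pairs:
                continue
            regions = region_decomposition(pairs, ma.structures[si], ma.structures[sj], criterion)
            size_score += augmented_size(regions, params.augmentation_constant)
    t = tension(ma, criterion)
    return size_score - params.lambda_tension * t.total * ma.n_aligned_pairs()


def score_report(ma: MultipleAlignment, params: FitnessParams = FitnessParams(),
                 criterion: ContactCriterion = ContactCriterion()) -> str:
    """TSV report: per-pair tension, region table, total fitness."""
    t = tension(ma, criterion)
    lines = ["pair\ttension_A2"]
    for (si, sj), v in sorted(t.per_pair.items()):
        lines.append(f"{ma.structures[si].name}-{ma.structures[sj].name}\t{v:.4f}")
    lines.append("")
    lines.append("pair\tregion\tsize\talpha_deg\tfactor")
    indices = sorted(ma.structure_indices)
    for ii, si in enumerate(indices):
        for sj in indices[ii + 1 :]:
            pairs = ma.pairs_for(si, sj)
            if not pairs:
                continue
            regions = region_decomposition(pairs, ma.structures[si], ma.structures[sj], criterion)
            ordered = sorted(regions, key=lambda r: (-r.size, -_span(r), r.pairs))
            for k, reg in enumerate(ordered):
                alpha = rotation_angle(ordered[0].rotation, reg.rotation)
                factor = 1.0 if k == 0 else (1.0 + np.cos(alpha)) / 2.0
                lines.append(
                    f"{ma.structures[si].name}-{ma.structures[sj].name}\t{k}\t{reg.size}"
                    f"\t{np.degrees(alpha):.2f}\t{factor:.4f}"
                )
    lines.append("")
    lines.append(f"total_tension_A2\t{t.total:.6f}")
    lines.append(f"fitness\t{fitness(ma, params, criterion):.4f}")
    return "\n".join(lines) + "\n"
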