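"""Pairwise alignment as the largest consistent ensemble of descriptor pairs.

Aligns a noisy copy of a two-domain chain, then a circular permutant: the
clique-based search has no global-superposition or sequence-order
constraint, so the permuted structure aligns in full.
"""

import numpy as np

from mstalign import FamilySpec, align_pair, all_descriptor_pairs, make_family

ARCH = (
    ("helix", 10), ("strand", 6), ("loop", 4),
    ("helix", 10), ("loop", 4), ("strand", 6),
    ("helix", 10), ("loop", 4), ("strand", 6),
)

(sa, sb), truth = make_family(
    FamilySpec(architecture=ARCH, n_copies=2, noise_sigma=0.3, seed=1)
)
pairs = all_descriptor_pairs(sa, sb)
pa = align_pair(sa, sb, pairs=pairs, seed=0)
correct = sum(1 for a, b in pa.pairs if a == b)
print(f"noisy copy: {len(pairs)} descriptor pairs -> alignment of {pa.size} residues "
      f"({correct} correct)")

(sa, sb), truth = make_family(
    FamilySpec(architecture=ARCH, n_copies=2, noise_sigma=0.2,
               permuted_copies={1: 30}, seed=5)
)
pa = align_pair(sa, sb, seed=0)
gt = {(c[0], c[1]) for c in truth.reference.columns}
print(f"circular permutant: {pa.size} residues aligned, "
      f"{len(pa.pairs & gt)} match the ground-truth mapping")
print("-> the permuted chain aligns across the cut because descriptor pairs "
      "are sequence-independent")
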