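"""Full multiple alignment of a hard synthetic family.

Five noisy copies of a 60-residue two-domain fold; one copy is circularly
permuted, another has its second domain rotated 45° about the linker.  The
two-stage search (core descriptors with ≥3 segments, then extension)
recovers the ground truth.
"""

import numpy as np

from mstalign import FamilySpec, Params, make_family, qc, qp, to_fasta, two_stage

ARCH = (
    ("helix", 10), ("strand", 6), ("loop", 4),
    ("helix", 10), ("loop", 4), ("strand", 6),
    ("helix", 10), ("loop", 4), ("strand", 6),
)

spec = FamilySpec(
    architecture=ARCH, n_copies=5, noise_sigma=0.3,
    permuted_copies={1: 30}, hinges={2: (30, 45.0)}, seed=0,
)
structures, truth = make_family(spec)
ma = two_stage(structures, Params(), np.random.default_rng(0))

print(f"aligned {len(structures)} structures into {len(ma.columns)} columns")
print(f"Q_C = {qc(ma, truth.reference):.1f}%   Q_P = {qp(ma, truth.reference):.1f}%")
print()
print(to_fasta(ma)[:400] + "...")
print("-> Q_C is the fraction of reference columns reproduced whole; "
      "Q_P the fraction of aligned residue pairs")
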