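# Methods

This note documents the models, parameters and numerical choices behind
mstalign, and what the synthetic test families do and do not demonstrate.

## Local descriptors

Every residue with a valid ±2 backbone window centers a descriptor. Its
contacts are the residues satisfying dα ≤ 6.5 Å, or dC ≤ 8.0 Å and
dα − dC ≥ 0.75 Å, with dα the Cα–Cα distance and dC the distance between
the side-chain geometric centers (unweighted mean of side-chain heavy
atoms; glycine and residues without resolved side chains fall back to the
Cα position so every residue stays contact-evaluable). Both clauses are
symmetric under this reading of dC, which follows the descriptor
literature; an asymmetric mixed Cα-to-side-chain reading was considered
and rejected. Elements are the contacts' 5-residue windows; contacts whose
window would cross a terminus or chain boundary are dropped. Windows merge
into segments only when they share a residue — adjacent but disjoint
windows stay separate. Multi-chain structures form one ordered residue
list, but windows never span a chain boundary.

## Descriptor-pair similarity

The similarity thresholds are not part of the alignment model proper and
are package choices, calibrated once on the synthetic fixtures:

| parameter          | default | meaning                                          |
|--------------------|---------|--------------------------------------------------|
| `central_rmsd_max` | 1.5 Å   | gate on the two central 5-residue windows        |
| `element_rmsd_max` | 1.5 Å   | per-element positional RMSD in the common frame  |
| `min_elements`     | 3       | aligned elements required (central one included) |
| `rmsd_max`         | 2.5 Å   | optimal superposition of all corresponded Cα     |

Matching is center-to-center with whole windows corresponded in order
(no window reversal); elements may match out of sequence order, which is
what lets one segment align to two smaller ones and permutations survive.
Elements are matched by solving an assignment problem on positional RMSD
under a shared rigid frame — first the frame of the central elements, then
once more under the frame refit on the full first-round correspondence,
which stabilizes elements far from the center. The refined match is kept
when it aligns at least as many elements.

## Pairwise alignment and clique search

Descriptor pairs are nodes of a consistency graph; an edge means the union
of two correspondences is injective in both directions. Geometric
agreement is deliberately *not* an edge requirement: flexibility and
permutations are legal, and geometry is charged later by the tension
score. Node weight is the correspondence size.

The exact maximum-weight clique (branch and bound over bitsets, ≤ 25 nodes
by default, deterministic lexicographic tie-break) doubles as the test
oracle. Larger graphs use replicator dynamics x ← x∘(Ax)/(xᵀAx) on the
0/1 adjacency — the Motzkin–Straus characterization of maximum cliques —
with support extraction, greedy completion by weight, 8 seeded restarts
(uniform + Dirichlet), convergence at max-component change < 1e-7 or 300
iterations, plus deterministic weight-greedy seeds grown from each of the
32 heaviest nodes. The best candidate by total weight wins; ties go to the
lexicographically smallest node set. On seeded random graphs (n ≤ 18) this
matches the exact oracle in ≥ 95% of instances and stays above 85% of its
weight in the worst case; both bounds are asserted in the test suite.

Conflict resolution is a minimum-loss removal: branch and bound on the
conflict edges, minimizing removed weight, then removed node count, then
lexicographic order. For two structures pairwise edge consistency already
implies global consistency, so the resolver is a no-op there; it matters
for the generalized merge conflicts of profile alignment and is kept
generic (and verified against exhaustive subset search).

## Multiple alignment

A multiple alignment is a list of columns over one shared structure list;
a column maps each participating structure to exactly one residue, no
residue appears twice, partial columns are allowed. Profile–profile
alignment proposes column merges supported by at least one descriptor
pair, scores a merge by (number of supporting descriptor pairs) × (number
of residue pairs the merged column creates), and selects a maximal
consistent merge set with the same clique machinery (merges conflict when
they share a column on either side). Candidates are capped at the 800
heaviest for tractability. Unmerged columns pass through unchanged, so
profile alignment never destroys the inputs — the output restricted to one
side's structures reproduces that side exactly.

## Guide trees and the evolutionary search

Initial specimens come from stochastic neighbor joining on the pairwise
alignment-size table: at each step a cluster pair is sampled with
probability proportional to the average similarity of its members
(uniform when all similarities vanish). Progressive profile alignment
along the tree yields the specimen; its fitness is the score of the root
alignment.

Mutation re-aligns a uniformly chosen internal node and every node on its
path to the root (fresh clique-search randomization). Crossover samples a
centroid pair with probability proportional to the sum of their guide-tree
distances, grows one subset around each centroid by proximity in the
respective parent's tree (alternating picks), extracts the two
subalignments and profile-aligns them; the child's tree joins the pruned
subtrees at a new root.

The steady-state loop inserts a child if the population is below capacity
or the child's fitness exceeds that of its most similar individual
(Jaccard identity on induced residue-pair sets); on insertion every
individual more than 80% identical to the child is removed. Search stops
after 8 consecutive non-improving children or 24 evaluations per round.
Defaults (population 8, mutation probability 0.7, 4 initial trees) are
deliberately small: on the 60-residue families used throughout, the
progressive seeds are already near-optimal and the EA's role is repair,
so a full five-structure run takes on the order of seconds. All knobs
are exposed via `EAParams` / the YAML config and logged with the run.

Gradual extension starts from the consensus of all-vs-all pairwise
alignments (only their descriptor pairs allowed), then repeatedly frees
the most under-performing structure — the one whose summed pairwise
fitness most exceeds its leave-one-out contribution to the best multiple
alignment — until every structure is unconstrained. The leave-one-out
reading of "contribution" is a package choice.

The two-stage protocol restricts stage 1 to descriptor pairs covering ≥ 3
segments of their first descriptor (the structural core), then extends
with every remaining pair that (a) touches at least one residue the core
aligned and (b) merges columns without ever placing two residues of one
structure together. Admission is greedy: larger correspondences first,
ties by lower RMSD, then deterministic ordinals. Overlap is defined at the
residue level rather than the residue-pair level: pair-level overlap can
never recruit a structure whose core coverage missed an entire domain
(observed on the hinge fixture), while residue-level overlap extends it
correctly and the consistency requirement still blocks contradictions. If
stage 1 aligns nothing (possible for tiny all-helical inputs), the search
reruns on the unrestricted pool.

## Scoring

Tension: for every pair of aligned residue pairs in contact in at least
one of the two structures, the RMSD of the corresponding element backbones
(union of the two 5-residue Cα windows, up to 10 points, optimally
superposed) is computed; these are averaged per residue over its contacts,
squared, averaged over the residues of each structure pair, then averaged
over structure pairs. The order — contacts → residue mean → square → pair
mean → alignment mean — is pinned by an independent step-by-step
recomputation in the tests, because other associations of the same words
give different numbers. Element RMSD uses Cα only, matching the rest of
the geometry model.

Regions are connected components of aligned pairs under the contact
relation (either structure); each region of ≥ 3 pairs carries its own
least-squares rotation, smaller regions borrow the largest region's
rotation and are flagged. The size score of a structure pair is
|largest| + Σ |region| · (1 + cos α)/2 with α the angle between the
largest region's rotation and the region's own; the proportionality
constant is 1 (configurable), chosen so a co-rotating region counts in
full and an anti-rotated one not at all.

Fitness = Σ over structure pairs of augmented size − λ · tension ·
(number of aligned residue pairs), λ = 0.05 Å⁻². The linear combination
and λ are package choices: λ is small enough that size dominates at
realistic noise (the ground-truth alignment outscores equally sized random
ones on every fixture tested) and large enough that fitness decreases
monotonically with coordinate noise σ ∈ {0.1, 0.5, 1.0} Å.

## Evaluation

Q_C counts a reference column as correct only when its complete
structure→residue mapping lands inside a single test column; Q_P counts
reproduced induced residue pairs. Both are percentages of the reference,
invariant to column and structure order; Q_C ≤ Q_P holds on full-column
references. Accuracy ratios divide by the per-case best across methods;
failed cases score 0 and all-zero cases get ratio 0 with a warning.
Profiles ρ_m(α) are evaluated on an α grid of 0 to 1 step 0.01; failures
never count, so ρ_m(0) is the fraction of solved cases; the trapezoidal
AUC summarizes each curve.

## Synthetic families

`make_chain` packs ideal secondary-structure blocks — helix (rise 1.5 Å,
100°/residue, radius 2.3 Å), strand (rise 3.4 Å, alternating ±0.85 Å
lateral offset), loop (shallow arc, step ≈ 3.8 Å) — as a serpentine
meander: each block on its own lane, the second half of the blocks on a
second layer (`layer_gap`, default 8 Å, giving inter-domain contacts;
25 Å isolates the domains for region tests). Side-chain pseudo-centers sit
1.5 Å outward along the local bisector, so descriptors get both point sets
and all geometry is rigid-equivariant by construction. Sequence letters
are arbitrary (alanine, glycine where the pseudo-center degenerates).

`make_family` applies, in order: hinge rotation (rigid, about a seeded
axis through the pivot Cα), independent per-atom Gaussian noise, circular
renumbering for permuted copies; the ground truth maps template ordinal t
to (t − cut) mod n in a permutant. Within-block Cα spacing is realistic
(3.8 ± 0.1 Å) but block joints are not chemically bonded geometry, there
are no rotamers, no sequence signal, and noise is isotropic — so passing
tests demonstrate the *geometric* machinery (contacts, elements, cliques,
permutation and hinge handling, scoring identities) and say nothing about
crystallographic artifacts, alternate conformations in real lattices, or
sequence-dependent packing. The worked example on a real lysozyme
structure (PDB 1lg7) covers that gap when the file is supplied.

## Degenerate inputs and tie-breaks

Empty descriptor-pair lists yield empty alignments, not errors. Columns
are merged deterministically; every stochastic routine takes one seeded
`numpy` generator threaded through the whole run, making full runs
bit-reproducible (asserted over three repeated CLI runs). FASTA output
orders columns by the master structure (the first one), with columns
absent from it following in (structure, residue) order — a convention for
sequentially incompatible permuted blocks that keeps output stable.
Superposed PDB output transforms each structure onto the first using its
largest region's rotation, since the model has no global superposition.

## Known limitations

- Descriptor similarity thresholds are calibrated on synthetic geometry;
  real-structure work may need looser element gates (all configurable).
- The replicator heuristic is not exact; its quality envelope is asserted
  statistically, not per-instance.
- Tension uses Cα-only elements; no full-backbone mode is provided because
  the structure model keeps only Cα and side-chain centers.
- The EA defaults favor desk-scale runs; large families (tens of
  structures) would need bigger populations and budgets, and the candidate
  cap in profile alignment may then bind.
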