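import numpy as np
import pytest

from mstalign import (
    ContactCriterion,
    FamilySpec,
    FitnessParams,
    MultipleAlignment,
    Residue,
    Structure,
    augmented_size,
    contact_pairs,
    contact_tension,
    fitness,
    make_family,
    region_decomposition,
    tension,
)
from mstalign.scoring import Region, score_report
from mstalign.descriptors import contact_matrix

from conftest import ARCH, random_rotation


def _identical_family(n_copies=3, seed=2):
    return make_family(FamilySpec(architecture=ARCH, n_copies=n_copies, noise_sigma=0.0, seed=seed))


class TestContactPairs:
    def test_identical_copies_reproduce_template_contacts(self):
        structures, truth = _identical_family(2)
        cm = contact_matrix(structures[0])
        contacts = contact_pairs(truth.reference)
        got = {(c1[0], c2[0]) for _, c1, c2 in contacts}
        expected = {(i, j) for i in range(len(structures[0])) for j in range(i + 1, len(structures[0])) if cm[i, j]}
        assert got == expected

    def test_no_shared_columns_gives_empty(self, family3):
        structures, _ = family3
        ma = MultipleAlignment(structures, [{0: 1, 1: 1}, {0: 5, 2: 5}])
        # columns share no structure pair twice -> no contact can be emitted
        assert contact_pairs(ma) == []

    def test_hand_built_single_contact(self):
        # 4 residues: 0 and 1 in contact (3.8 Å), 2 and 3 far from both
        def mk(name):
            pos = [0.0, 3.8, 50.0, 80.0]
            res = [
                Residue(("A", i + 1, ""), "A", np.array([p, 0, 0]), np.array([p, 1, 0]))
                for i, p in enumerate(pos)
            ]
            return Structure(name, res)

        sa, sb = mk("a"), mk("b")
        ma = MultipleAlignment([sa, sb], [{0: i, 1: i} for i in range(4)])
        contacts = contact_pairs(ma)
        assert len(contacts) == 1
        assert contacts[0][1] == (0, 0) and contacts[0][2] == (1, 1)


class TestContactTension:
    def test_identical_structures_zero(self):
        structures, truth = _identical_family(2)
        contacts = contact_pairs(truth.reference)
        inner = [c for c in contacts if all(2 <= r < 58 for r in (c[1][0], c[2][0]))]
        assert inner
        for c in inner[:10]:
            assert contact_tension(c, structures) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_zero(self):
        structures, truth = _identical_family(2)
        rng = np.random.default_rng(4)
        structures[1] = structures[1].transformed(random_rotation(rng), rng.normal(size=3) * 10)
        ma = MultipleAlignment(structures, truth.reference.columns)
        contacts = contact_pairs(ma)
        c = next(c for c in contacts if all(2 <= r < 58 for r in (c[1][0], c[2][0])))
        assert contact_tension(c, structures) < 1e-9

    def test_displaced_element_matches_superposition_oracle(self):
        structures, truth = _identical_family(2)
        from scipy.optimize import minimize
        from scipy.spatial.transform import Rotation

        contacts = contact_pairs(truth.reference)
        c = next(c for c in contacts if all(4 <= r < 56 for r in (c[1][0], c[2][0]))
                 and abs(c[1][0] - c[2][0]) > 4)
        (si, sj), (ri1, rj1), (ri2, rj2) = c
        # displace the second element of structure j by 1 Å along x
        stj = structures[sj]
        ca = stj.ca.copy()
        ca[rj2 - 2 : rj2 + 3] += np.array([1.0, 0, 0])
        moved = Structure("moved", [
            Residue(r.id, r.aa, ca[i], r.sc_center) for i, r in enumerate(stj.residues)
        ])
        got = contact_tension(c, [structures[si], moved])
        pi = structures[si].ca[np.r_[ri1 - 2 : ri1 + 3, ri2 - 2 : ri2 + 3]]
        pj = moved.ca[np.r_[rj1 - 2 : rj1 + 3, rj2 - 2 : rj2 + 3]]

        a0 = pi - pi.mean(axis=0)
        b0 = pj - pj.mean(axis=0)

        def cost(angles):
            r = Rotation.from_euler("xyz", angles).as_matrix()
            d = b0 @ r.T - a0
            return np.sqrt((d * d).sum(axis=1).mean())

        best = min(
            minimize(cost, x0, method="Nelder-Mead").fun
            for x0 in ([0, 0, 0], [0.5, -0.5, 0.3], [1.5, 1.0, -1.0])
        )
        assert got == pytest.approx(best, abs=1e-3)


class TestTension:
    def test_identical_copies_total_zero(self):
        _, truth = _identical_family(3)
        assert tension(truth.reference).total == pytest.approx(0.0, abs=1e-12)

    def test_rigid_invariance(self):
        structures, truth = _identical_family(3)
        base = tension(truth.reference).total
        rng = np.random.default_rng(6)
        structures[2] = structures[2].transformed(random_rotation(rng), rng.normal(size=3) * 8)
        moved = MultipleAlignment(structures, truth.reference.columns)
        assert abs(tension(moved).total - base) < 1e-9

    def test_single_contact_total_is_r_squared(self):
        def mk(name, stretch):
            pos = np.array([0.0, 3.8, 40.0, 43.8])
            res = []
            for i, p in enumerate(pos):
                x = np.array([p, 0, 0], dtype=float)
                res.append(Residue(("A", i + 1, ""), "A", x, x + np.array([0, 1, 0])))
            return Structure(name, res)

        # need valid +-2 windows: use 6-residue chains with the contact mid-chain
        def mk6(name, shift):
            pos = [0.0, 3.8, 7.6, 11.4, 15.2, 19.0]
            res = []
            for i, p in enumerate(pos):
                x = np.array([p, 0, 0], dtype=float)
                if name == "b" and i == 3:
                    x = x + np.array([0, shift, 0])
                res.append(Residue(("A", i + 1, ""), "A", x, x + np.array([0, 1, 0])))
            return Structure(name, res)

        sa, sb = mk6("a", 0.0), mk6("b", 0.7)
        ma = MultipleAlignment([sa, sb], [{0: i, 1: i} for i in range(6)])
        t = tension(ma)
        contacts = contact_pairs(ma)
        rs = [contact_tension(c, [sa, sb]) for c in contacts]
        rs = [r for r in rs if r is not None]
        # independent step-by-step recomputation of the averaging cascade
        per_res = {}
        valid = [(c, r) for c, r in zip([c for c in contacts], [contact_tension(c, [sa, sb]) for c in contacts]) if r is not None]
        for c, r in valid:
            (si, sj), (a1, b1), (a2, b2) = c
            for key in ((si, a1), (si, a2), (sj, b1), (sj, b2)):
                per_res.setdefault(key, []).append(r)
        means = {k: np.mean(v) for k, v in per_res.items()}
        expected = np.mean([m**2 for m in means.values()])
        assert t.total == pytest.approx(expected, rel=1e-12)

    def test_matches_stepwise_recomputation_on_noisy_family(self, family3):
        structures, truth = family3
        t = tension(truth.reference)
        contacts = contact_pairs(truth.reference)
        per_res = {}
        for c in contacts:
            r = contact_tension(c, structures)
            if r is None:
                continue
            (si, sj), (a1, b1), (a2, b2) = c
            for key in ((si, a1), (si, a2), (sj, b1), (sj, b2)):
                per_res.setdefault(((si, sj), key), []).append(r)
        means = {}
        for (pair, key), v in per_res.items():
            means.setdefault(pair, []).append(np.mean(v) ** 2)
        per_pair = {p: np.mean(v) for p, v in means.items()}
        assert t.total == pytest.approx(np.mean(list(per_pair.values())), rel=1e-9)
        for p, v in per_pair.items():
            assert t.per_pair[p] == pytest.approx(v, rel=1e-9)


class TestRegions:
    def test_connected_alignment_is_one_region(self):
        structures, truth = _identical_family(2)
        pairs = truth.reference.pairs_for(0, 1)
        regions = region_decomposition(pairs, structures[0], structures[1])
        assert len(regions) == 1
        assert regions[0].size == len(pairs)

    def test_hinge_splits_into_regions_and_sizes_sum(self):
        # domains far enough apart that neither structure has cross contacts
        spec = FamilySpec(architecture=ARCH, n_copies=2, noise_sigma=0.0,
                          hinges={1: (30, 45.0)}, seed=3, layer_gap=25.0)
        (sa, sb), truth = make_family(spec)
        pairs = truth.reference.pairs_for(0, 1)
        regions = region_decomposition(pairs, sa, sb)
        assert len(regions) == 2
        assert sum(r.size for r in regions) == len(pairs)
        # the two regions' rotations differ by roughly the hinge angle
        from mstalign import rotation_angle

        alpha = rotation_angle(regions[0].rotation, regions[1].rotation)
        assert alpha == pytest.approx(np.deg2rad(45.0), abs=0.05)

    def test_empty_pairs_rejected(self, family3):
        structures, _ = family3
        with pytest.raises(ValueError):
            region_decomposition([], structures[0], structures[1])


class TestAugmentedSize:
    def _region(self, size, angle_deg):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("z", angle_deg, degrees=True).as_matrix()
        return Region([(i, i) for i in range(size)], rot, size)

    def test_single_region(self):
        assert augmented_size([self._region(17, 0)]) == 17

    @pytest.mark.parametrize("angle, factor", [(0, 1.0), (90, 0.5), (180, 0.0)])
    def test_discount_factor(self, angle, factor):
        big = self._region(20, 0)
        small = Region([(100 + i, 100 + i) for i in range(8)],
                       self._region(8, angle).rotation, 8)
        assert augmented_size([big, small]) == pytest.approx(20 + 8 * factor, abs=1e-9)

    def test_never_exceeds_pair_count(self, hinged_pair):
        (sa, sb), truth = hinged_pair
        pairs = truth.reference.pairs_for(0, 1)
        regions = region_decomposition(pairs, sa, sb)
        assert augmented_size(regions) <= len(pairs)


class TestFitness:
    def test_monotone_in_size_at_zero_tension(self):
        structures, truth = _identical_family(2)
        full = fitness(truth.reference)
        partial = MultipleAlignment(structures, truth.reference.columns[:-10])
        assert full > fitness(partial)

    def test_empty_alignment_scores_zero(self, family3):
        structures, _ = family3
        assert fitness(MultipleAlignment(structures, [])) == 0.0

    def test_decreases_with_growing_noise(self):
        scores = []
        for sigma in (0.1, 0.5, 1.0):
            structures, truth = make_family(
                FamilySpec(architecture=ARCH, n_copies=3, noise_sigma=sigma, seed=9)
            )
            scores.append(fitness(truth.reference))
        assert scores[0] > scores[1] > scores[2]

    def test_ground_truth_beats_random_alignments_of_same_size(self, family3):
        structures, truth = family3
        gt_fit = fitness(truth.reference)
        rng = np.random.default_rng(21)
        n = len(structures[0])
        for _ in range(10):
            perms = [np.arange(n), rng.permutation(n), rng.permutation(n)]
            cols = [{s: int(perms[s][t]) for s in range(3)} for t in range(n)]
            rand = MultipleAlignment(structures, cols)
            assert gt_fit > fitness(rand)

    def test_score_report_contains_sections(self, family3):
        _, truth = family3
        text = score_report(truth.reference)
        assert "tension_A2" in text and "fitness" in text and "alpha_deg" in text
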