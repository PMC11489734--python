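"""Contact definition, significance filtering, reciprocal features, blocks."""

import numpy as np
import pytest

from symgate.features import (
    BlockFeatureSet,
    TrajectoryFeatures,
    arrange_and_augment,
    compute_distances,
    define_contacts,
    featurize_reciprocal,
    filter_contact_spec,
    roll_blocks,
    select_significant_contacts,
)

from conftest import pentamer_ring_coords


def brute_force_contact_pairs(coords_list, subunit_ids, n_fold, cutoff):
    """Oracle: O(n²) scan over all atom pairs + explicit orbit closure."""
    n_atoms = len(subunit_ids)
    m = n_atoms // n_fold
    order = np.argsort(subunit_ids, kind="stable")
    atom_idx = order.reshape(n_fold, m)
    pos = {int(atom_idx[s, a]): (s, a) for s in range(n_fold) for a in range(m)}

    qualifying = set()
    for c in coords_list:
        for i in range(n_atoms):
            for j in range(i + 1, n_atoms):
                if np.linalg.norm(c[i] - c[j]) <= cutoff:
                    qualifying.add(frozenset((i, j)))
    closed = set()
    for pair in qualifying:
        i, j = tuple(pair)
        (si, ai), (sj, aj) = pos[i], pos[j]
        if abs(si - sj) in (0, 1, 2, n_fold - 1, n_fold - 2):
            for k in range(n_fold):
                gi = atom_idx[(si + k) % n_fold, ai]
                gj = atom_idx[(sj + k) % n_fold, aj]
                closed.add(frozenset((int(gi), int(gj))))
    return closed


class TestDefineContacts:
    def test_matches_brute_force_enumeration(self):
        coords, subunit_ids = pentamer_ring_coords()
        rng = np.random.default_rng(0)
        seeds = [coords, coords + rng.normal(0, 0.02, coords.shape)]
        spec = define_contacts(seeds, subunit_ids, n_fold=5, cutoff=1.0)
        spec.validate()

        m = spec.atoms_per_subunit
        order = np.argsort(subunit_ids, kind="stable")
        atom_idx = order.reshape(5, m)
        got = set()
        for (a, a2, si, sj) in spec.pairs:
            got.add(frozenset((int(atom_idx[si, a]), int(atom_idx[sj, a2]))))
        expected = brute_force_contact_pairs(seeds, subunit_ids, 5, 1.0)
        assert got == expected

    def test_cutoff_inclusion_boundaries(self):
        # two subunits of one atom each at controlled separation
        for dist, included in [(0.9, True), (1.1, False)]:
            coords = np.array([[0.0, 0.0, 0.0], [dist, 0.0, 0.0],
                               [0.0, 5.0, 0.0], [dist, 5.0, 0.0],
                               [0.0, 10.0, 0.0]])
            # pentamer with 1 atom per subunit, ring-distance artificial:
            # place atoms so only the (s, s+1) image at index 0 is near
            subunit_ids = np.arange(5)
            if included:
                spec = define_contacts(coords, subunit_ids, n_fold=5, cutoff=1.0)
                offs = (spec.pairs[:, 3] - spec.pairs[:, 2]) % 5
                assert np.all((offs == 1) | (offs == 2))
            else:
                with pytest.raises(ValueError, match="empty selection"):
                    define_contacts(coords, subunit_ids, n_fold=5, cutoff=0.5)

    def test_unequal_subunits_rejected(self):
        coords = np.zeros((7, 3))
        subunit_ids = np.array([0, 0, 1, 1, 2, 2, 2])
        with pytest.raises(ValueError, match="subunit 2"):
            define_contacts(coords, subunit_ids, n_fold=3, cutoff=1.0)

    def test_block_roll_equivariance_of_featurization(self):
        """Relabeling subunits s -> s+1 rolls the distance blocks exactly."""
        coords, subunit_ids = pentamer_ring_coords()
        spec = define_contacts(coords, subunit_ids, n_fold=5, cutoff=1.0)
        rng = np.random.default_rng(1)
        traj = coords[None] + rng.normal(0, 0.01, size=(10, *coords.shape))
        d = compute_distances(traj, spec, subunit_ids)
        relabeled = (subunit_ids + 1) % 5
        d_relabeled = compute_distances(traj, spec, relabeled)
        assert np.allclose(d_relabeled, roll_blocks(d, 5, 1), atol=1e-12)


class TestSignificanceFilter:
    def test_constant_removed_variable_kept(self):
        n_fold, b = 5, 2
        frames = 6
        d = np.ones((frames, n_fold * b))
        # slot 1 of every block alternates 1.0 / 2.0: ratio 1.0/1.5 = 0.667
        d[::2, 1::b] = 1.0
        d[1::2, 1::b] = 2.0
        mask = select_significant_contacts(d, n_fold, ratio_threshold=0.2)
        assert mask.tolist() == [False, True] * n_fold

    def test_mask_is_roll_invariant(self, rng):
        n_fold, b = 5, 4
        d = 1.0 + rng.random((50, n_fold * b))
        for mode in ("pooled", "all"):
            mask = select_significant_contacts(d, n_fold, mode=mode)
            rolled = roll_blocks(mask[None].astype(float), n_fold, 1)[0] > 0.5
            assert np.array_equal(mask, rolled)

    def test_per_contact_mode_ignores_symmetry(self, rng):
        n_fold, b = 5, 3
        d = np.ones((40, n_fold * b))
        d[:, 0] += np.linspace(0, 1, 40)[:, None].squeeze()  # only block 0 varies
        mask = select_significant_contacts(d, n_fold, mode="per_contact")
        assert mask[0] and not mask[b]

    def test_rejects_nonpositive_distances(self):
        d = np.ones((3, 5))
        d[1, 2] = -0.1
        with pytest.raises(ValueError, match="positive"):
            select_significant_contacts(d, 5)

    def test_filter_spec_keeps_block_structure(self):
        coords, subunit_ids = pentamer_ring_coords()
        spec = define_contacts(coords, subunit_ids, n_fold=5, cutoff=1.2)
        d = compute_distances(
            coords[None] + np.random.default_rng(2).normal(
                0, 0.03, size=(30, *coords.shape)
            ),
            spec, subunit_ids,
        )
        mask = select_significant_contacts(d, 5, ratio_threshold=0.05)
        if mask.any() and not mask.all():
            sub = filter_contact_spec(spec, mask)
            sub.validate()
            assert sub.n_pairs == mask.sum()


class TestReciprocal:
    def test_values_and_monotonicity(self, rng):
        d = rng.uniform(0.5, 3.0, size=(20, 8))
        f = featurize_reciprocal(d)
        assert np.allclose(f.values, 1.0 / d)
        assert np.allclose(featurize_reciprocal(np.array([[2.0]])).values, 0.5)
        assert np.allclose(featurize_reciprocal(np.array([[1.0]])).values, 1.0)
        # monotone reversal
        a, b = np.sort(rng.uniform(0.1, 5.0, size=(2, 50)), axis=0)
        assert np.all(1.0 / a >= 1.0 / b)

    def test_error_reports_location(self):
        d = np.ones((4, 3))
        d[2, 1] = 0.0
        with pytest.raises(ValueError, match="frame 2, pair 1"):
            featurize_reciprocal(d)


class TestAugmentation:
    def test_fivefold_expansion(self, rng):
        traj = TrajectoryFeatures(values=rng.random((100, 15)))
        fs = arrange_and_augment([traj], n_fold=5)
        assert len(fs.trajectories) == 5
        assert fs.n_frames_total == 500
        assert fs.augmented

    def test_roll_group_law_and_identity(self, rng):
        x = rng.random((7, 20))
        assert np.array_equal(roll_blocks(x, 5, 0), x)
        assert np.array_equal(
            roll_blocks(x, 5, 2), roll_blocks(roll_blocks(x, 5, 1), 5, 1)
        )

    def test_closed_under_block_roll(self, rng):
        traj = TrajectoryFeatures(values=rng.random((9, 10)))
        fs = arrange_and_augment([traj], n_fold=5)
        members = [t.values for t in fs.trajectories]
        for t in fs.trajectories:
            rolled = roll_blocks(t.values, 5, 1)
            assert any(np.array_equal(rolled, m) for m in members)

    def test_indivisible_feature_count_rejected(self, rng):
        traj = TrajectoryFeatures(values=rng.random((5, 7)))
        with pytest.raises(ValueError, match="divisible"):
            arrange_and_augment([traj], n_fold=5)

    def test_augment_is_idempotent(self, rng):
        traj = TrajectoryFeatures(values=rng.random((10, 10)))
        fs = arrange_and_augment([traj], n_fold=5)
        assert fs.augment() is fs


try:
    from hypothesis import given, settings
    from hypothesis import strategies as st

    @given(
        shift_a=st.integers(min_value=0, max_value=9),
        shift_b=st.integers(min_value=0, max_value=9),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_block_rolls_form_a_cyclic_group(shift_a, shift_b, seed):
        """roll(a) ∘ roll(b) = roll(a + b mod n) and roll(n) = identity."""
        x = np.random.default_rng(seed).random((4, 15))
        lhs = roll_blocks(roll_blocks(x, 5, shift_b), 5, shift_a)
        rhs = roll_blocks(x, 5, (shift_a + shift_b) % 5)
        assert np.array_equal(lhs, rhs)
        assert np.array_equal(roll_blocks(x, 5, 5), x)

except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass
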