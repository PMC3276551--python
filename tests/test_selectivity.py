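from collections import Counter

import numpy as np
import pytest
from scipy import linalg

from pdznet.features import AMINO_ACIDS, PocketFeatureVector
from pdznet.selectivity import (
    SCATTER_SHRINKAGE,
    InteractionRecord,
    SelectivityError,
    build_selectivity_space,
    build_training_sets,
    nearest_neighbors,
    project_pocket,
    train_fld_axis,
)


def _vec(values, pocket=0):
    v = np.zeros(10 * ((len(values) + 9) // 10))
    v[: len(values)] = values
    return PocketFeatureVector(pocket, v)


def _fld_oracle(pos, neg):
    """Independent FLD route: generalized eigenproblem eigh(S_B, S_W_reg)."""
    mu_p, mu_n = pos.mean(axis=0), neg.mean(axis=0)
    delta = (mu_p - mu_n)[:, None]
    sb = delta @ delta.T
    sw = np.zeros_like(sb)
    for cls, mu in ((pos, mu_p), (neg, mu_n)):
        c = cls - mu
        sw += c.T @ c
    d = sw.shape[0]
    lam = SCATTER_SHRINKAGE * (np.trace(sw) / d if np.trace(sw) > 0 else 1.0)
    vals, vecs = linalg.eigh(sb, sw + lam * np.eye(d))
    w = vecs[:, np.argmax(vals)]
    return w / np.linalg.norm(w)


class TestTrainingSets:
    def test_single_positive_rule(self):
        inter = [
            InteractionRecord("X_1", "AAAAAAAAAV", True),
            InteractionRecord("Y_1", "AAAAAAAAAL", True),
            InteractionRecord("Z_1", "AAAAAAAAAL", True),
        ]
        pockets = {d: _vec([i]) for i, d in enumerate(["X_1", "Y_1", "Z_1"])}
        sets = build_training_sets(inter, pockets, 0)
        assert sets["V"] == (["X_1"], ["Y_1", "Z_1"])

    def test_multi_membership(self):
        inter = [
            InteractionRecord("X_1", "AAAAAAAAAV", True),
            InteractionRecord("X_1", "AAAAAAAAAL", True),
            InteractionRecord("Y_1", "AAAAAAAAAG", True),
        ]
        pockets = {"X_1": _vec([0]), "Y_1": _vec([1])}
        sets = build_training_sets(inter, pockets, 0)
        assert "X_1" in sets["V"][0] and "X_1" in sets["L"][0]

    def test_no_binders_is_an_error(self):
        inter = [InteractionRecord("X_1", "AAAAAAAAAV", False)]
        with pytest.raises(SelectivityError, match="no binder"):
            build_training_sets(inter, {"X_1": _vec([0])}, 0)

    def test_membership_matches_planted_table(self, world, world_vectors):
        """Noise-free positives contain every domain of the preferring class."""
        sets = build_training_sets(world.interactions, world_vectors[0], 0)
        for cls in range(world.config.n_classes):
            for aa in world.preferred[(cls, 0)]:
                members = {
                    d for d, c in world.class_of_domain.items() if c == cls
                }
                positives = set(sets[aa][0])
                # label noise can add members, but most of the class must be there
                assert len(members & positives) / len(members) > 0.8


class TestFldAxis:
    def test_separable_toy_axis_direction(self):
        pos = np.array([[2, 0.1], [3, -0.1]])
        neg = np.array([[-2, 0.1], [-3, -0.1]])
        w, fs = train_fld_axis(pos, neg)
        assert abs(abs(w[0]) - 1.0) < 1e-6 and abs(w[1]) < 1e-6
        assert fs > 0

    def test_label_swap_flips_sign_keeps_score(self):
        rng = np.random.default_rng(2)
        pos, neg = rng.normal(size=(5, 3)) + 1, rng.normal(size=(6, 3))
        w1, f1 = train_fld_axis(pos, neg)
        w2, f2 = train_fld_axis(neg, pos)
        assert np.allclose(w1, -w2, atol=1e-9)
        assert f1 == pytest.approx(f2, rel=1e-9)

    def test_shuffled_labels_score_lower(self):
        """Random label shuffles never beat the separable labelling."""
        rng = np.random.default_rng(3)
        pos = rng.normal(size=(15, 4)) + 3.0
        neg = rng.normal(size=(15, 4))
        _, f_true = train_fld_axis(pos, neg)
        data = np.vstack([pos, neg])
        worse = 0
        for _ in range(100):
            perm = rng.permutation(30)
            _, f_shuf = train_fld_axis(data[perm[:15]], data[perm[15:]])
            worse += f_shuf < f_true
        assert worse == 100

    def test_identical_means_degenerate(self):
        x = np.array([[1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(SelectivityError, match="degenerate"):
            train_fld_axis(x, x)

    def test_matches_generalized_eigen_oracle(self):
        """Closed-form axis agrees with the eigh(S_B, S_W) route (200 draws)."""
        rng = np.random.default_rng(4)
        for _ in range(200):
            d = int(rng.integers(2, 7))
            n_p, n_n = int(rng.integers(2, 16)), int(rng.integers(2, 16))
            pos = rng.normal(size=(n_p, d)) + rng.normal(size=d)
            neg = rng.normal(size=(n_n, d))
            w, _ = train_fld_axis(pos, neg)
            w_oracle = _fld_oracle(pos, neg)
            assert abs(abs(w @ w_oracle) - 1.0) < 1e-6


class TestSpace:
    def test_world_space_axes_unit_or_zero(self, spaces):
        for space in spaces.values():
            norms = np.linalg.norm(space.projection, axis=0)
            for j, aa in enumerate(AMINO_ACIDS):
                if aa in space.untrainable:
                    assert norms[j] == 0.0
                else:
                    assert norms[j] == pytest.approx(1.0, abs=1e-9)

    def test_missing_class_axis_flagged_zero(self):
        rng = np.random.default_rng(5)
        inter, pockets = [], {}
        # only two amino acids ever bound -> 18 untrainable would be fatal,
        # so allow it explicitly via max_untrainable
        for i in range(6):
            d = f"D{i}_1"
            aa = "V" if i % 2 else "L"
            inter.append(InteractionRecord(d, "AAAAAAAAA" + aa, True))
            pockets[d] = _vec(rng.normal(size=10))
        space = build_selectivity_space(inter, pockets, 0, max_untrainable=20)
        assert "W" in space.untrainable
        assert np.all(space.projection[:, AMINO_ACIDS.index("W")] == 0.0)

    def test_too_many_untrainable_axes_fatal(self):
        inter = [InteractionRecord("D0_1", "AAAAAAAAAV", True),
                 InteractionRecord("D1_1", "AAAAAAAAAL", True)]
        pockets = {"D0_1": _vec([1.0]), "D1_1": _vec([2.0])}
        with pytest.raises(SelectivityError, match="untrainable"):
            build_selectivity_space(inter, pockets, 0)

    def test_planted_clusters_separate_on_preferred_axis(self, world, spaces, world_vectors):
        """Coordinates on a planted amino acid's axis split its class from the rest."""
        space = spaces[0]
        aa = world.preferred[(0, 0)][0]
        j = AMINO_ACIDS.index(aa)
        if aa in space.untrainable:
            pytest.skip("axis untrainable in this world draw")
        coords = {d: space.training_coords[i, j] for i, d in enumerate(space.training_ids)}
        in_class = [v for d, v in coords.items() if world.class_of_domain[d] == 0]
        out_class = [v for d, v in coords.items() if world.class_of_domain[d] != 0]
        assert np.mean(in_class) > np.mean(out_class)


class TestProjection:
    def test_training_pocket_reprojects_to_stored_coords(self, spaces, world_vectors):
        space = spaces[0]
        d = space.training_ids[0]
        coords = project_pocket(world_vectors[0][d], space)
        assert np.allclose(coords, space.training_coords[0], atol=1e-12)

    def test_linearity(self, spaces):
        rng = np.random.default_rng(6)
        space = spaces[0]
        dim = space.projection.shape[0]
        u, v = rng.normal(size=dim), rng.normal(size=dim)
        lhs = project_pocket(2.5 * u - 0.5 * v, space)
        rhs = 2.5 * project_pocket(u, space) - 0.5 * project_pocket(v, space)
        assert np.allclose(lhs, rhs, atol=1e-9)

    def test_zero_vector_zero_coords(self, spaces):
        dim = spaces[0].projection.shape[0]
        assert np.allclose(project_pocket(np.zeros(dim), spaces[0]), 0.0)

    def test_per_axis_dot_products(self, spaces):
        rng = np.random.default_rng(7)
        space = spaces[0]
        v = rng.normal(size=space.projection.shape[0])
        coords = project_pocket(v, space)
        brute = np.array([v @ space.projection[:, j] for j in range(20)])
        assert np.allclose(coords, brute, atol=1e-12)

    def test_dimension_mismatch(self, spaces):
        with pytest.raises(SelectivityError, match="mismatch"):
            project_pocket(np.zeros(7), spaces[0])


class TestNeighbors:
    def test_query_equal_training_pocket_is_first(self, spaces):
        space = spaces[0]
        nbs = nearest_neighbors(space.training_coords[3], space, 5)
        assert nbs[0].domain_id == space.training_ids[3]
        assert nbs[0].distance == 0.0

    def test_k_equals_training_size_exhaustive(self, spaces):
        space = spaces[0]
        nbs = nearest_neighbors(np.zeros(20), space, space.n_training)
        assert len(nbs) == space.n_training
        assert all(a.distance <= b.distance for a, b in zip(nbs, nbs[1:]))

    def test_matches_brute_force_sort(self, spaces):
        rng = np.random.default_rng(8)
        space = spaces[0]
        q = rng.normal(size=20)
        nbs = nearest_neighbors(q, space, 5)
        dists = {
            d: float(np.linalg.norm(space.training_coords[i] - q))
            for i, d in enumerate(space.training_ids)
        }
        brute = sorted(dists, key=lambda d: (dists[d], d))[:5]
        assert [n.domain_id for n in nbs] == brute

    def test_k_too_large_suggests_reduction(self, spaces):
        with pytest.raises(SelectivityError, match="reduce k"):
            nearest_neighbors(np.zeros(20), spaces[0], spaces[0].n_training + 1)

    def test_permutation_invariance(self, world, world_vectors):
        """Neighbor sets do not depend on interaction-record input order."""
        rng = np.random.default_rng(9)
        shuffled = list(world.interactions)
        rng.shuffle(shuffled)
        s1 = build_selectivity_space(world.interactions, world_vectors[0], 0)
        s2 = build_selectivity_space(shuffled, world_vectors[0], 0)
        q = rng.normal(size=20)
        n1 = [n.domain_id for n in nearest_neighbors(q, s1, 10)]
        n2 = [n.domain_id for n in nearest_neighbors(q, s2, 10)]
        assert n1 == n2


def test_preference_pool_recovers_planted_amino_acids(world, world_vectors):
    """Held-out pockets gather neighbor pools containing the planted preferences."""
    hits = total = 0
    for dom in list(world.class_of_domain)[:6]:
        cls = world.class_of_domain[dom]
        held_in = [r for r in world.interactions if r.domain_id != dom]
        for pocket in (0, -1):
            space = build_selectivity_space(held_in, {
                d: v for d, v in world_vectors[pocket].items() if d != dom
            }, pocket)
            coords = project_pocket(world_vectors[pocket][dom], space)
            pool = Counter()
            for nb in nearest_neighbors(coords, space, min(40, space.n_training)):
                pool.update(nb.prefs)
            for aa in world.preferred[(cls, pocket)]:
                total += 1
                hits += aa in pool
    assert hits / total >= 0.8
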