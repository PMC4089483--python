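"""Normalization, weight initialization/training, ranking."""

import numpy as np
import pytest

from blobid.config import TrainConfig
from blobid.errors import FitError, ParameterError
from blobid.features import N_FEATURES
from blobid.ligands import LigandGroup
from blobid.matching import (
    FeatureDatabase,
    FeatureStats,
    WeightVector,
    candidate_score,
    cross_entropy_train,
    discriminatory_power,
    fit_normalization,
    initial_weights,
    rank_database,
)


def _toy_db(rng, n_ligands=5, n_conf=3, planted_feature=None):
    """Synthetic database with optional single separating feature."""
    codes, conf_ids, vectors = [], [], []
    for li in range(n_ligands):
        for k in range(n_conf):
            v = rng.normal(0, 1, N_FEATURES)
            if planted_feature is not None:
                v[planted_feature] = 10.0 * li + rng.normal(0, 0.01)
            codes.append(f"L{li:02d}")
            conf_ids.append(k)
            vectors.append(v)
    vectors = np.array(vectors)
    return FeatureDatabase(
        codes=codes,
        conformer_ids=np.array(conf_ids),
        vectors=vectors,
        groups=[LigandGroup(members=[c], representative=c)
                for c in sorted(set(codes))],
        stats=fit_normalization(vectors),
    )


class TestNormalization:
    def test_z_scored_columns_standardized(self, rng):
        x = rng.normal(3, 5, size=(200, N_FEATURES))
        stats = fit_normalization(x)
        z = stats.z(x)
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_correlation_matrix_structure(self, rng):
        x = rng.normal(size=(300, N_FEATURES))
        z = fit_normalization(x).z(x)
        corr = np.cov(z, rowvar=False, ddof=0)
        np.testing.assert_allclose(np.diag(corr), 1.0, atol=1e-9)
        off = corr[~np.eye(N_FEATURES, dtype=bool)]
        assert np.all(np.abs(off) < 1.0)

    def test_zero_variance_feature_rejected(self, rng):
        x = rng.normal(size=(50, N_FEATURES))
        x[:, 7] = 4.2
        with pytest.raises(FitError, match="8"):
            fit_normalization(x)


class TestInitialWeights:
    def test_identity_correlation_gives_equal_weights(self):
        # columns are exactly uncorrelated: corr = identity, all
        # eigenvalues degenerate, so every feature shares equally
        x = np.vstack([np.eye(N_FEATURES), -np.eye(N_FEATURES)])
        w = initial_weights(x)
        np.testing.assert_allclose(w.w, 1.0 / N_FEATURES, atol=1e-9)

    def test_simplex_constraints(self, rng):
        x = rng.normal(size=(100, N_FEATURES)) @ rng.normal(
            size=(N_FEATURES, N_FEATURES)
        )
        w = initial_weights(x)
        assert np.all(w.w >= 0)
        assert w.w.sum() == pytest.approx(1.0, abs=1e-9)

    def test_correlated_pair_closed_form(self):
        """One correlated feature pair: eigenvalues 1+r, 1-r and a
        20-fold degenerate 1; the symbolic solution gives
        raw = ((1+r)/2, (1+r)/2, 0.2, ..., 0.2) for m = 5."""
        r = 0.6
        e = np.vstack([np.eye(N_FEATURES), -np.eye(N_FEATURES)])
        x = e.copy()
        x[:, 1] = r * e[:, 0] + np.sqrt(1 - r * r) * e[:, 1]
        w = initial_weights(x)
        raw = np.full(N_FEATURES, 0.2)
        raw[0] = raw[1] = (1 + r) / 2
        np.testing.assert_allclose(w.w, raw / raw.sum(), atol=1e-8)


class TestCandidateScore:
    def test_identical_vectors_zero(self, rng):
        db = _toy_db(rng)
        v = db.vectors[0]
        w = WeightVector(np.full(N_FEATURES, 1 / N_FEATURES))
        assert candidate_score(v, v, db.stats, w) == 0.0

    def test_symmetry(self, rng):
        db = _toy_db(rng)
        w = WeightVector(np.full(N_FEATURES, 1 / N_FEATURES))
        a, b = db.vectors[0], db.vectors[5]
        assert candidate_score(a, b, db.stats, w) == pytest.approx(
            candidate_score(b, a, db.stats, w)
        )

    def test_hand_computed_weighted_l1(self):
        stats = FeatureStats(mean=np.zeros(N_FEATURES), sd=np.ones(N_FEATURES))
        w = np.zeros(N_FEATURES)
        w[:3] = [0.5, 0.3, 0.2]
        a = np.zeros(N_FEATURES)
        b = np.zeros(N_FEATURES)
        b[:3] = [2.0, -1.0, 4.0]
        got = candidate_score(a, b, stats, WeightVector(w))
        assert got == pytest.approx(0.5 * 2 + 0.3 * 1 + 0.2 * 4)


class TestRankDatabase:
    def test_self_vector_ranks_first_with_zero_score(self, rng):
        db = _toy_db(rng)
        grid = db.vectors[7]  # some conformer of L02
        ranked = rank_database(grid, db)
        assert ranked[0].code == db.codes[7]
        assert ranked[0].score == 0.0

    def test_extra_grid_never_raises_composite(self, rng):
        db = _toy_db(rng)
        g1 = rng.normal(size=N_FEATURES)
        g2 = rng.normal(size=N_FEATURES)
        one = {r.code: r.score for r in rank_database(g1, db)}
        two = {r.code: r.score for r in rank_database(np.vstack([g1, g2]), db)}
        for code in one:
            assert two[code] <= one[code] + 1e-12

    def test_matches_exhaustive_enumeration(self, rng):
        db = _toy_db(rng, n_ligands=5, n_conf=3)
        grids = rng.normal(size=(2, N_FEATURES))
        w = WeightVector(rng.dirichlet(np.ones(N_FEATURES)))
        ranked = rank_database(grids, db, db.stats, w)
        expected = {}
        for code in db.unique_codes:
            scores = [
                candidate_score(g, v, db.stats, w)
                for g in grids
                for v, c in zip(db.vectors, db.codes)
                if c == code
            ]
            expected[code] = min(scores)
        order = sorted(expected, key=lambda c: (expected[c], c))
        assert [r.code for r in ranked] == order
        for r in ranked:
            assert r.score == pytest.approx(expected[r.code], abs=1e-12)

    def test_single_feature_weights_sort_by_that_feature(self, rng):
        db = _toy_db(rng)
        w = np.zeros(N_FEATURES)
        w[4] = 1.0
        grid = rng.normal(size=N_FEATURES)
        ranked = rank_database(grid, db, db.stats, WeightVector(w))
        zg = db.stats.z(grid)[4]
        zdb = db.stats.z(db.vectors)[:, 4]
        expected = {}
        for code in db.unique_codes:
            mask = [c == code for c in db.codes]
            expected[code] = np.min(np.abs(zdb[mask] - zg))
        order = sorted(expected, key=lambda c: (expected[c], c))
        assert [r.code for r in ranked] == order

    def test_ranks_are_permutation_and_sorted(self, rng):
        db = _toy_db(rng)
        ranked = rank_database(rng.normal(size=N_FEATURES), db)
        assert sorted(r.rank for r in ranked) == list(range(1, 6))
        scores = [r.score for r in ranked]
        assert scores == sorted(scores)


class TestCrossEntropy:
    def test_never_worse_than_initialization_and_deterministic(self, rng):
        db = _toy_db(rng, n_ligands=6, n_conf=2)
        cases = []
        for li in range(6):
            base = db.vectors[li * 2]
            cases.append((base[None, :] + rng.normal(0, 0.05, (1, N_FEATURES)),
                          f"L{li:02d}"))
        cfg = TrainConfig(population=20, elite=5, iterations=8, seed=3)

        def objective(wv):
            total = 0.0
            for grids, code in cases:
                ranked = rank_database(grids, db, db.stats, wv)
                rank = next(r.rank for r in ranked if r.code == code)
                total += 1.0 / rank
            return total / len(cases)

        w_init = initial_weights(db.vectors, db.stats)
        w = cross_entropy_train(cases, db, cfg)
        assert objective(w) >= objective(w_init) - 1e-12
        w2 = cross_entropy_train(cases, db, cfg)
        np.testing.assert_array_equal(w.w, w2.w)

    def test_planted_separating_feature_dominates(self, rng):
        """Only one feature identifies the truth; the other 21 point at a
        decoy ligand.  Exhaustive one-hot comparison confirms the planted
        feature is the unique perfect single-feature ranker, and training
        concentrates the most weight on it."""
        planted = 9
        n_lig = 8
        db = _toy_db(rng, n_ligands=n_lig, n_conf=2, planted_feature=planted)
        cases = []
        for li in range(n_lig):
            decoy = (li + 1) % n_lig
            v = db.vectors[decoy * 2].copy()  # misleading shape features
            v[planted] = 10.0 * li  # only this feature names the truth
            cases.append((v[None, :], f"L{li:02d}"))

        def objective(wv):
            total = 0.0
            for grids, code in cases:
                ranked = rank_database(grids, db, db.stats, wv)
                total += 1.0 / next(r.rank for r in ranked if r.code == code)
            return total / len(cases)

        onehot_scores = []
        for f in range(N_FEATURES):
            w1 = np.zeros(N_FEATURES)
            w1[f] = 1.0
            onehot_scores.append(objective(WeightVector(w1)))
        assert np.argmax(onehot_scores) == planted
        assert onehot_scores[planted] == pytest.approx(1.0)

        cfg = TrainConfig(population=40, elite=8, iterations=20, seed=0)
        w = cross_entropy_train(cases, db, cfg)
        assert np.argmax(w.w) == planted

    def test_too_few_cases_rejected(self, rng):
        db = _toy_db(rng)
        with pytest.raises(ParameterError):
            cross_entropy_train([(db.vectors[:1], "L00")] * 3, db)


class TestDiscriminatoryPower:
    def test_equal_weights_half_category(self):
        w = WeightVector(np.full(N_FEATURES, 1 / N_FEATURES))
        assert discriminatory_power(w, range(11)) == pytest.approx(0.5)

    def test_categories_partition_to_one(self, rng):
        w = WeightVector(rng.dirichlet(np.ones(N_FEATURES)))
        total = sum(
            discriminatory_power(w, name)
            for name in (
                "moment_invariants", "chirality", "distances",
                "connectivity", "centroid_distance_moments", "atom_count",
            )
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_full_and_empty_categories(self, rng):
        w = WeightVector(rng.dirichlet(np.ones(N_FEATURES)))
        assert discriminatory_power(w, range(N_FEATURES)) == pytest.approx(1.0)
        assert discriminatory_power(w, []) == 0.0


class TestSerialization:
    def test_database_json_round_trip(self, rng, tmp_path):
        db = _toy_db(rng)
        path = tmp_path / "db.json"
        db.save(path)
        back = FeatureDatabase.load(path)
        assert back.codes == db.codes
        np.testing.assert_allclose(back.vectors, db.vectors)
        np.testing.assert_allclose(back.stats.mean, db.stats.mean)
        assert [g.members for g in back.groups] == [g.members for g in db.groups]
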