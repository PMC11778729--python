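"""Normalization, concatenation, alignment training and cross-validated scoring."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sonar import (
    TaskEmbeddings,
    TrainingConfig,
    ValidationError,
    apply_alignment,
    build_task_embeddings,
    concatenate,
    cosine_matrix,
    crossval_scores,
    maxabs_normalize,
    train_alignment,
)
from sonar import SimulationConfig, make_hard_concepts, simulate
from sonar import pipeline
from sonar.fusion import _loss_and_grad

finite_vectors = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False),
    min_size=1,
    max_size=20,
).map(np.asarray)


class TestMaxabsNormalize:
    @pytest.mark.parametrize(
        "vec, expected",
        [
            ([2, -4, 1], [0.5, -1.0, 0.25]),
            ([0, 0], [0, 0]),
            ([-3], [-1.0]),
        ],
    )
    def test_examples(self, vec, expected):
        np.testing.assert_allclose(maxabs_normalize(np.array(vec, float)), expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            maxabs_normalize(np.array([1.0, np.nan]))

    @given(finite_vectors)
    def test_idempotent_and_bounded(self, v):
        once = maxabs_normalize(v)
        assert np.all(np.abs(once) <= 1.0 + 1e-15)
        np.testing.assert_allclose(maxabs_normalize(once), once, atol=1e-15)
        if np.any(v != 0):
            assert np.abs(once).max() == pytest.approx(1.0)

    @given(finite_vectors, st.floats(min_value=1e-3, max_value=1e3))
    def test_positive_scale_invariant(self, v, c):
        np.testing.assert_allclose(
            maxabs_normalize(c * v), maxabs_normalize(v), rtol=1e-9, atol=1e-12
        )


class TestConcatenate:
    def test_segment_arithmetic(self):
        out = concatenate(np.zeros(768), np.zeros(768), np.zeros(48))
        assert out.dimension == 1584
        assert out.boundaries == {
            "coder": (0, 768),
            "sapbert": (768, 1536),
            "dist": (1536, 1584),
        }

    def test_semantic_only_ablation(self):
        out = concatenate(np.zeros(10), np.zeros(12), None)
        assert out.dimension == 22
        assert "dist" not in out.boundaries

    def test_components_stay_bounded(self):
        emb = build_task_embeddings(
            ["a", "b"],
            [
                ("coder", {"a": np.array([3.0, -6.0]), "b": np.array([1.0, 1.0])}),
                ("dist", {"a": np.array([5.0]), "b": np.array([-2.0])}),
            ],
        )
        assert np.all(np.abs(emb.X) <= 1.0)
        assert emb.boundaries == {"coder": (0, 2), "dist": (2, 3)}

    def test_inconsistent_segment_dimension_rejected(self):
        with pytest.raises(ValidationError):
            build_task_embeddings(
                ["a", "b"],
                [("coder", {"a": np.zeros(3), "b": np.zeros(4)})],
            )


class TestApplyAlignment:
    def test_identity_and_scale(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(4, 6))
        np.testing.assert_array_equal(apply_alignment(X, np.eye(6)), X)
        S1 = cosine_matrix(apply_alignment(X, np.eye(6)), apply_alignment(X, np.eye(6)))
        S2 = cosine_matrix(apply_alignment(X, 2 * np.eye(6)), apply_alignment(X, 2 * np.eye(6)))
        np.testing.assert_allclose(S1, S2, rtol=1e-12)

    def test_matches_double_loop_product(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=7)
        M = rng.normal(size=(7, 7))
        expected = np.array(
            [sum(x[i] * M[i, j] for i in range(7)) for j in range(7)]
        )
        np.testing.assert_allclose(apply_alignment(x, M), expected, rtol=1e-12)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            apply_alignment(np.zeros(3), np.eye(4))


class TestTrainAlignment:
    def _task(self, seed=0, n_concepts=10, d=12):
        rng = np.random.default_rng(seed)
        centers = rng.normal(size=(n_concepts, d))
        X = np.repeat(centers, 3, axis=0) + 0.3 * rng.normal(size=(3 * n_concepts, d))
        accs = tuple(f"v{i}" for i in range(len(X)))
        emb = TaskEmbeddings(accs, X, {"x": (0, d)})
        pairs = [(f"v{3 * c}", f"v{3 * c + 1}") for c in range(n_concepts)]
        return emb, pairs

    def test_gradient_matches_finite_differences(self):
        rng = np.random.default_rng(2)
        n, d = 8, 5
        X = rng.normal(size=(n, d))
        M = np.eye(d) + 0.05 * rng.normal(size=(d, d))
        I = np.array([0, 2, 4])
        J = np.array([1, 3, 5])
        K = np.array([[6, 7], [7, 6], [6, 7]])
        _, grad = _loss_and_grad(M, X, I, J, K, margin=0.5, ortho_penalty=0.01)
        eps = 1e-6
        for a, b in [(0, 0), (1, 3), (4, 2), (2, 4)]:
            Mp, Mm = M.copy(), M.copy()
            Mp[a, b] += eps
            Mm[a, b] -= eps
            lp, _ = _loss_and_grad(Mp, X, I, J, K, 0.5, 0.01)
            lm, _ = _loss_and_grad(Mm, X, I, J, K, 0.5, 0.01)
            assert grad[a, b] == pytest.approx((lp - lm) / (2 * eps), abs=1e-6)

    def test_zero_epochs_returns_identity(self):
        emb, pairs = self._task()
        matrix = train_alignment(emb, pairs, TrainingConfig(epochs=0, seed=1))
        np.testing.assert_array_equal(matrix.M, np.eye(emb.dimension))

    def test_seeded_runs_bit_identical(self):
        emb, pairs = self._task()
        config = TrainingConfig(epochs=40, seed=9)
        m1 = train_alignment(emb, pairs, config)
        m2 = train_alignment(emb, pairs, config)
        np.testing.assert_array_equal(m1.M, m2.M)

    def test_loss_trace_non_increasing_within_tolerance(self):
        emb, pairs = self._task()
        matrix = train_alignment(emb, pairs, TrainingConfig(epochs=80, seed=4))
        trace = np.asarray(matrix.meta["loss_trace"])
        assert trace[-1] <= trace[0]
        assert np.diff(trace).max() <= 1e-3 * (abs(trace[0]) + 1)

    def test_no_positives_rejected(self):
        emb, _ = self._task()
        with pytest.raises(ValidationError):
            train_alignment(emb, [], TrainingConfig())

    def test_heldout_positive_cosine_improves_on_generator_task(self):
        """Training on half the concepts of a 20-concept synthetic task does
        not degrade (and typically tightens) held-out positive-pair cosine."""
        cfg = make_hard_concepts(
            dataclasses.replace(SimulationConfig(seed=7), n_concepts=20), 0.3
        )
        dataset = simulate(cfg)
        cohorts = {
            cid: pipeline.prepare_cohort(
                dataset.records(cid), dataset.patient_table(cid), cfg.schema
            )
            for cid in dataset.cohort_ids[:1]
        }
        gold = pipeline.remap_gold(dataset.gold, cohorts)
        emb_sets = pipeline.compute_semantic_embeddings(cohorts)
        coh = cohorts["STUDY1"]
        emb, _ = pipeline.comparison_embeddings(coh, coh, emb_sets, "concat")
        pairs = gold.positive_pairs(emb.accessions, emb.accessions, True)
        concepts = sorted(pairs)
        train_pairs = [p for c in concepts[::2] for p in pairs[c]]
        held_pairs = [p for c in concepts[1::2] for p in pairs[c]]
        matrix = train_alignment(emb, train_pairs, TrainingConfig(epochs=100, seed=3))

        def mean_cos(M):
            U = emb.X @ M
            U = U / np.linalg.norm(U, axis=1, keepdims=True)
            return float(
                np.mean([U[emb.row(a)] @ U[emb.row(b)] for a, b in held_pairs])
            )

        assert mean_cos(matrix.M) >= mean_cos(np.eye(emb.dimension))


class TestCrossvalScores:
    def _task(self):
        rng = np.random.default_rng(3)
        d = 10
        centers = rng.normal(size=(4, d))
        X = np.repeat(centers, 2, axis=0) + 0.2 * rng.normal(size=(8, d))
        accs = tuple(f"v{i}" for i in range(8))
        emb = TaskEmbeddings(accs, X, {"x": (0, d)})
        pairs = {f"c{c}": [(f"v{2 * c}", f"v{2 * c + 1}")] for c in range(4)}
        return emb, pairs

    def test_fold_partition_and_positive_scored_once(self):
        emb, pairs = self._task()
        result = crossval_scores(emb, emb, pairs, TrainingConfig(epochs=5, seed=0), True)
        folds = list(result.fold_of_concept.values())
        assert sorted(result.fold_of_concept) == sorted(pairs)
        assert folds.count(0) == folds.count(1) == 2
        for concept, fold in result.fold_of_concept.items():
            (a, b) = pairs[concept][0]
            ia, ib = emb.row(a), emb.row(b)
            held = cosine_matrix(
                emb.X @ result.matrices[1 - fold].M, emb.X @ result.matrices[1 - fold].M
            )
            assert result.scores[ia, ib] == held[ia, ib]

    def test_non_gold_scores_average_both_matrices(self):
        emb, pairs = self._task()
        result = crossval_scores(emb, emb, pairs, TrainingConfig(epochs=5, seed=0), True)
        s0 = cosine_matrix(emb.X @ result.matrices[0].M, emb.X @ result.matrices[0].M)
        s1 = cosine_matrix(emb.X @ result.matrices[1].M, emb.X @ result.matrices[1].M)
        # v0 and v2 belong to different concepts: a non-gold pair
        i, j = emb.row("v0"), emb.row("v2")
        assert result.scores[i, j] == pytest.approx((s0[i, j] + s1[i, j]) / 2)

    def test_identity_matrices_reduce_to_unsupervised(self):
        emb, pairs = self._task()
        result = crossval_scores(emb, emb, pairs, TrainingConfig(epochs=0, seed=0), True)
        np.testing.assert_array_equal(result.scores, cosine_matrix(emb.X, emb.X))

    def test_single_concept_rejected(self):
        emb, pairs = self._task()
        only = {"c0": pairs["c0"]}
        with pytest.raises(ValidationError, match="seed|concept"):
            crossval_scores(emb, emb, only, TrainingConfig(epochs=1, seed=0), True)
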