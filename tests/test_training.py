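"""Link loss, negative sampling, search/retrain loop and pair scoring."""

import numpy as np
import pytest

from metadti.evaluation import make_splits
from metadti.hetnet import normalized_relations
from metadti.metagraph import IDENTITY, NULL, MetaGraph
from metadti.training import (
    InteractionSets,
    TrainConfig,
    dti_loss,
    dti_loss_grad,
    predict_ranked,
    sample_negatives,
    score_pair,
    search_metagraph,
    train_final,
)


def sets_from(pos, neg, ratio=1):
    return InteractionSets(
        positives=frozenset(pos), negatives=frozenset(neg), ratio=ratio
    )


class TestSampleNegatives:
    def test_ratio_one_counts_and_disjointness(self):
        rng = np.random.default_rng(0)
        drugs, prots = range(20), range(100, 120)
        pos = {(d, p) for d, p in zip(range(10), range(100, 110))}
        sets = sample_negatives(pos, drugs, prots, 1, rng)
        assert sets.n_neg == 10
        assert not (sets.positives & sets.negatives)

    @pytest.mark.parametrize("ratio,expected", [(5, 50), (10, 100)])
    def test_higher_ratios(self, ratio, expected):
        rng = np.random.default_rng(1)
        pos = {(d, 100 + d) for d in range(10)}
        sets = sample_negatives(pos, range(20), range(100, 120), ratio, rng)
        assert sets.n_neg == expected

    def test_infeasible_request_names_counts(self):
        pos = {(d, p) for d in range(3) for p in (10, 11, 12)} - {(2, 12)}
        with pytest.raises(ValueError, match="16.*1|1.*16"):
            sample_negatives(pos, range(3), (10, 11, 12), 2,
                             np.random.default_rng(0))

    def test_seeded_reproducibility(self):
        pos = {(d, 50 + d) for d in range(8)}
        a = sample_negatives(pos, range(30), range(50, 70), 3,
                             np.random.default_rng(7))
        b = sample_negatives(pos, range(30), range(50, 70), 3,
                             np.random.default_rng(7))
        assert a.negatives == b.negatives

    def test_negatives_only_from_unknown_pairs(self):
        drugs, prots = range(4), range(10, 13)
        pos = {(0, 10), (1, 11)}
        sets = sample_negatives(pos, drugs, prots, 4, np.random.default_rng(2))
        assert sets.n_neg == 8
        all_pairs = {(d, p) for d in drugs for p in prots}
        assert sets.negatives <= all_pairs - pos


class TestScorePair:
    def test_orthogonal_vectors_score_half(self):
        assert score_pair([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.5)

    def test_log_three_closed_form(self):
        h = np.array([np.sqrt(np.log(3.0)), 0.0])
        assert score_pair(h, h) == pytest.approx(0.75)

    def test_saturation_is_stable(self):
        s = score_pair([-50.0, 0.0], [1.0, 0.0])
        assert 0.0 < s < 1e-20

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_pair([1.0], [1.0, 2.0])


class TestLoss:
    def test_all_zero_logits_give_n_log_two(self):
        d = np.zeros((30, 4))
        p = np.zeros((30, 4))
        sets = sets_from({(i, i) for i in range(10)},
                         {(i, i + 10) for i in range(10)})
        assert dti_loss(d, p, sets) == pytest.approx(20 * np.log(2.0))
        assert abs(dti_loss(d, p, sets) - 13.8629) < 1e-3

    def test_single_aligned_positive(self):
        F = np.zeros((2, 5))
        F[0, 0] = 1.0
        F[1, 0] = 1.0
        sets = sets_from({(0, 1)}, set())
        want = float(np.logaddexp(0.0, -1.0))  # -log sigma(1)
        assert dti_loss(F, F, sets) == pytest.approx(want)
        assert abs(want - 0.31326) < 1e-5

    def test_scaling_shared_direction_decreases_positive_term(self):
        losses = []
        for scale in (1.0, 2.0, 4.0):
            F = np.zeros((2, 3))
            F[0, 0] = scale
            F[1, 0] = scale
            losses.append(dti_loss(F, F, sets_from({(0, 1)}, set())))
        assert losses[0] > losses[1] > losses[2] > 0

    def test_decomposes_as_sum_of_per_pair_terms(self):
        rng = np.random.default_rng(0)
        F_d = rng.normal(size=(12, 6))
        F_p = rng.normal(size=(12, 6))
        pos = {(0, 5), (1, 6), (2, 7)}
        neg = {(3, 8), (4, 9)}
        total = dti_loss(F_d, F_p, sets_from(pos, neg))
        parts = sum(
            dti_loss(F_d, F_p, sets_from({pr}, set())) for pr in pos
        )
        for pr in neg:
            # a lone negative needs a dummy positive; subtract it back out
            dummy = (11, 11)
            parts += dti_loss(F_d, F_p, sets_from({dummy}, {pr})) - dti_loss(
                F_d, F_p, sets_from({dummy}, set())
            )
        assert total == pytest.approx(parts, rel=1e-10)

    def test_empty_positives_rejected(self):
        with pytest.raises(ValueError):
            dti_loss(np.ones((2, 2)), np.ones((2, 2)), sets_from(set(), {(0, 1)}))

    def test_gradient_matches_central_finite_differences(self):
        rng = np.random.default_rng(3)
        F_d = rng.normal(size=(6, 5))
        F_p = rng.normal(size=(6, 5))
        sets = sets_from({(0, 3), (1, 4)}, {(2, 5), (0, 4)})
        _, grad_d, grad_p = dti_loss_grad(F_d, F_p, sets)
        eps = 1e-6
        for F, G in ((F_d, grad_d), (F_p, grad_p)):
            for i in range(F.shape[0]):
                for j in range(F.shape[1]):
                    x0 = F[i, j]
                    F[i, j] = x0 + eps
                    lp = dti_loss(F_d, F_p, sets)
                    F[i, j] = x0 - eps
                    lm = dti_loss(F_d, F_p, sets)
                    F[i, j] = x0
                    fd = (lp - lm) / (2 * eps)
                    assert abs(G[i, j] - fd) < 1e-4 * max(1.0, abs(fd))


@pytest.fixture(scope="module")
def small_setup(request):
    """Small planted net, one-hot-free quick embedding, pools and split."""
    small = request.getfixturevalue("small_planted")
    from metadti.embedding import node2vec_embeddings

    H0 = node2vec_embeddings(small.net, d=16, ws=20, nw=5, seed=0).H
    rng = np.random.default_rng(0)
    drugs = [int(i) for i in small.net.catalog.indices_of_type("drug")]
    prots = [int(i) for i in small.net.catalog.indices_of_type("protein")]
    pools = sample_negatives(small.positives, drugs, prots, 1, rng)
    (split,) = make_splits(
        set(pools.positives), set(pools.negatives), repeats=1, seed=1
    )
    relations = normalized_relations(small.net)
    cfg = TrainConfig(hidden_size=16, epochs=30, T=2, seed=5)
    return small, H0, split, relations, cfg


class TestSearch:
    def test_same_seed_gives_identical_metagraph(self, small_setup):
        small, H0, split, relations, cfg = small_setup
        runs = [
            search_metagraph(
                small.net, H0, split.train, split.validation, "protein", cfg,
                relations=relations,
            )[0]
            for _ in range(2)
        ]
        assert runs[0] == runs[1]

    def test_final_metagraph_obeys_candidate_rules(self, small_setup):
        small, H0, split, relations, cfg = small_setup
        mg, sig = search_metagraph(
            small.net, H0, split.train, split.validation, "drug", cfg,
            relations=relations,
        )
        assert mg.T == cfg.T and mg.role == "drug"
        for slot, mode in mg.selected.items():
            assert mode in sig.candidates[slot].members
        # top chain slot must target the role
        top_mode = mg.selected[(cfg.T - 1, cfg.T)]
        assert top_mode not in (IDENTITY, NULL)
        assert small.net.relation_typing[top_mode][1] == "drug"

    def test_invalid_role_rejected(self, small_setup):
        small, H0, split, relations, cfg = small_setup
        with pytest.raises(ValueError):
            search_metagraph(
                small.net, H0, split.train, split.validation, "gene", cfg,
                relations=relations,
            )


class TestTrainFinal:
    def make_metagraphs(self, T=2):
        mg_d = MetaGraph(
            T=T, role="drug",
            selected={(0, 1): IDENTITY, (0, 2): NULL, (1, 2): "disease_drug"},
        )
        mg_p = MetaGraph(
            T=T, role="protein",
            selected={(0, 1): IDENTITY, (0, 2): NULL, (1, 2): "disease_protein"},
        )
        return mg_d, mg_p

    def test_loss_decreases_and_refreeze_reproduces_final_loss(self, small_setup):
        small, H0, split, relations, cfg = small_setup
        mg_d, mg_p = self.make_metagraphs()
        model = train_final(
            small.net, H0, mg_d, mg_p, split.train, cfg, relations=relations
        )
        hist = model.loss_history
        assert hist[-1] < hist[0]
        F_d, F_p = model.features(relations)
        assert dti_loss(F_d, F_p, split.train) == pytest.approx(hist[-1], abs=1e-6)

    def test_weights_cover_selected_real_slots_only(self, small_setup):
        small, H0, split, relations, cfg = small_setup
        mg_d, mg_p = self.make_metagraphs()
        model = train_final(
            small.net, H0, mg_d, mg_p, split.train, cfg, relations=relations
        )
        assert set(model.weights_drug.W) == set(mg_d.real_slots())
        assert set(model.weights_protein.W) == set(mg_p.real_slots())

    def test_validation_selection_returns_finite_model(self, small_setup):
        small, H0, split, relations, cfg = small_setup
        mg_d, mg_p = self.make_metagraphs()
        model = train_final(
            small.net, H0, mg_d, mg_p, split.train, cfg,
            relations=relations, val_sets=split.validation,
        )
        F_d, F_p = model.features(relations)
        assert np.all(np.isfinite(F_d)) and np.all(np.isfinite(F_p))


class TestPredictRanked:
    def trained(self, small_setup):
        small, H0, split, relations, cfg = small_setup
        mg_d = MetaGraph(
            T=2, role="drug",
            selected={(0, 1): IDENTITY, (0, 2): NULL, (1, 2): "disease_drug"},
        )
        mg_p = MetaGraph(
            T=2, role="protein",
            selected={(0, 1): IDENTITY, (0, 2): NULL, (1, 2): "disease_protein"},
        )
        model = train_final(
            small.net, H0, mg_d, mg_p, split.train, cfg, relations=relations
        )
        return small, model, relations

    def test_scores_sorted_and_consistent_with_score_pair(self, small_setup):
        small, model, relations = self.trained(small_setup)
        pairs = {
            (int(d), int(p))
            for d in small.drug_indices[:6]
            for p in small.protein_indices[:5]
        }
        ranked = predict_ranked(model, relations, pairs, top_k=10)
        assert len(ranked) == 10
        scores = [r.score for r in ranked]
        assert scores == sorted(scores, reverse=True)
        F_d, F_p = model.features(relations)
        for r in ranked[:3]:
            assert r.score == pytest.approx(
                float(1 / (1 + np.exp(-F_d[r.drug] @ F_p[r.protein])))
            )

    def test_empty_candidates_give_empty_list(self, small_setup):
        _, model, relations = self.trained(small_setup)
        assert predict_ranked(model, relations, set(), top_k=5) == []

    def test_identical_large_norm_pair_outranks_orthogonal(self):
        # scoring is monotone in the inner product, checked via score_pair
        big = np.array([3.0, 0.0])
        other = np.array([0.0, 3.0])
        assert score_pair(big, big) > score_pair(big, other)
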