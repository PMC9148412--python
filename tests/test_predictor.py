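import itertools

import numpy as np
import pytest
from scipy.sparse.csgraph import connected_components

from ppbn.errors import ConflictError
from ppbn.predictor import (
    CORE_POSTURES,
    Posture,
    PostureSequence,
    default_allowed_mask,
    estimate_occupancy,
    fit_transition_model,
    posture_order,
    predict_next,
    shifts_per_hour,
)

S, P, L, R = CORE_POSTURES


class TestDefaultAllowedMask:
    def test_prone_not_reachable_from_supine(self):
        mask = default_allowed_mask()
        assert not mask[0, 1]                 # SUPINE -> PRONE forbidden

    def test_lateral_entered_from_supine(self):
        mask = default_allowed_mask()
        assert mask[0, 2] and mask[0, 3]      # SUPINE -> LLR / RLR

    def test_self_transitions_allowed(self):
        assert np.all(np.diag(default_allowed_mask()))
        assert np.all(np.diag(default_allowed_mask(include_offbed=True)))

    def test_lateral_to_lateral_forbidden(self):
        mask = default_allowed_mask()
        assert not mask[2, 3] and not mask[3, 2]

    @pytest.mark.parametrize("include_offbed", [False, True])
    def test_strongly_connected(self, include_offbed):
        adj = default_allowed_mask(include_offbed).astype(int)
        n, _ = connected_components(adj, directed=True, connection="strong")
        assert n == 1

    def test_offbed_touches_only_supine(self):
        mask = default_allowed_mask(include_offbed=True)
        assert mask[0, 4] and mask[4, 0]
        assert not mask[1:4, 4].any() and not mask[4, 1:4].any()


class TestFitTransitionModel:
    def test_pure_prior_is_uniform_over_allowed(self):
        model = fit_transition_model([], order=1, alpha=1.0,
                                     labels=CORE_POSTURES)
        mask = default_allowed_mask()
        for i in range(4):
            expected = mask[i] / mask[i].sum()
            np.testing.assert_allclose(model.probs[i], expected)

    def test_count_normalisation_with_structural_zero(self):
        seq = PostureSequence([S, L, S, S, L, S, L])
        # SUPINE history: 3 x SUPINE->LLR, 1 x SUPINE->SUPINE
        model = fit_transition_model([seq], order=1, alpha=0.0)
        row = model.row([S])
        assert row[model.index[L]] == pytest.approx(0.75)
        assert row[model.index[S]] == pytest.approx(0.25)
        assert row[model.index[P]] == 0.0

    def test_rows_are_distributions(self):
        seq = PostureSequence([S, L, P, S, R, P, S, S, L, S])
        for order in (1, 2):
            model = fit_transition_model([seq], order=order, alpha=0.7)
            sums = model.probs.sum(axis=-1)
            np.testing.assert_allclose(sums, 1.0, atol=1e-9)

    def test_forbidden_observed_transition_skipped_with_warning(self):
        seq = PostureSequence([S, P, S])       # SUPINE->PRONE violates the mask
        with pytest.warns(UserWarning, match="forbidden"):
            model = fit_transition_model([seq], order=1, alpha=0.0)
        assert model.probs[0, 1] == 0.0

    def test_structural_zeros_survive_any_alpha(self):
        seq = PostureSequence([S, L, P, S, R, S])
        for alpha in (0.0, 1.0, 100.0):
            model = fit_transition_model([seq], order=2, alpha=alpha)
            mask = model.mask
            for hist in np.ndindex(*model.probs.shape[:-1]):
                assert np.all(model.probs[hist][~mask[hist[-1]]] == 0.0)

    def test_no_data_no_alpha_rejected(self):
        with pytest.raises(ValueError):
            fit_transition_model([], order=1, alpha=0.0)


class TestPredictNext:
    @pytest.fixture()
    def model(self):
        seq = PostureSequence([S, L, P, S, S, R, P, S, L, S, S])
        return fit_transition_model([seq], order=1, alpha=1.0)

    def test_uniform_likelihood_returns_transition_row(self, model):
        res = predict_next(model, [S])
        row = model.row([S])
        np.testing.assert_allclose([res.posterior[l] for l in model.labels], row)

    def test_hand_bayes_example(self, model):
        prior = np.array([0.5, 0.0, 0.5, 0.0])
        model.probs[0] = prior                 # overwrite the SUPINE row
        lik = dict(zip(CORE_POSTURES, [0.2, 0.3, 0.8, 0.7]))
        res = predict_next(model, [S], obs_likelihood=lik)
        np.testing.assert_allclose(
            [res.posterior[l] for l in CORE_POSTURES], [0.2, 0.0, 0.8, 0.0])
        assert res.predicted == L

    def test_disjoint_support_conflict(self, model):
        model.probs[0] = np.array([0.0, 1.0, 0.0, 0.0])
        with pytest.raises(ConflictError):
            predict_next(model, [S], obs_likelihood={
                S: 1.0, P: 0.0, L: 0.0, R: 0.0})

    def test_short_history_rejected(self):
        seq = PostureSequence([S, L, P, S, S])
        model = fit_transition_model([seq], order=2, alpha=1.0)
        with pytest.raises(ValueError):
            predict_next(model, [S])

    def test_posterior_normalised_on_randomised_pairs(self, model):
        rng = np.random.default_rng(0)
        for _ in range(10_000):
            model.probs[0] = rng.dirichlet(np.ones(4)) * np.array([1, 0, 1, 1])
            model.probs[0] /= model.probs[0].sum()
            lik = dict(zip(CORE_POSTURES, rng.random(4) + 1e-6))
            res = predict_next(model, [S], obs_likelihood=lik)
            assert sum(res.posterior.values()) == pytest.approx(1.0, abs=1e-9)


class TestSequenceStatistics:
    def test_occupancy_direct_count(self):
        occ = estimate_occupancy(PostureSequence([S, S, P, L]))
        assert [occ[l] for l in CORE_POSTURES] == [0.5, 0.25, 0.25, 0.0]

    def test_single_label_occupancy(self):
        occ = estimate_occupancy(PostureSequence([P, P]))
        assert occ[P] == 1.0

    def test_occupancy_sums_to_one(self):
        seq = PostureSequence([S, L, P, R, Posture.OFFBED, S])
        assert sum(estimate_occupancy(seq).values()) == pytest.approx(1.0, abs=1e-12)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            estimate_occupancy(PostureSequence([]))

    def test_constant_sequence_no_shifts(self):
        assert shifts_per_hour(PostureSequence([S] * 10)) == 0.0

    def test_hand_computed_shift_rate(self):
        seq = PostureSequence([S, S, L, L, P], epoch_seconds=30.0)
        assert shifts_per_hour(seq) == pytest.approx(48.0)

    def test_epoch_duration_scaling(self):
        labels = [S, L, S, L, S]
        fast = shifts_per_hour(PostureSequence(labels, epoch_seconds=30.0))
        slow = shifts_per_hour(PostureSequence(labels, epoch_seconds=60.0))
        assert fast == pytest.approx(2 * slow)

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError):
            shifts_per_hour(PostureSequence([S]))


class TestParameterRecovery:
    def test_order1_fit_recovers_calibrated_matrix(self, medium_simulation,
                                                   calibrated_matrix):
        model = fit_transition_model([medium_simulation], order=1, alpha=0.0,
                                     labels=posture_order(include_offbed=True))
        err = np.abs(model.probs - calibrated_matrix)
        mask = model.mask
        assert err[mask].max() <= 0.02
        assert np.all(model.probs[~mask] == 0.0)


class TestGreedyPathMatchesEnumeration:
    def test_argmax_iteration_is_most_probable_path(self, calibrated_matrix):
        """With a flat likelihood, iterating the argmax from supine traces the
        same path as exhaustive maximisation over all allowed paths."""
        labels = posture_order(include_offbed=True)
        model = fit_transition_model([], order=1, alpha=1.0, labels=labels)
        model.probs = calibrated_matrix.copy()

        for length in range(1, 9):
            # greedy: repeated predict_next with uniform likelihood
            greedy, hist = [], [Posture.SUPINE]
            for _ in range(length):
                nxt = predict_next(model, hist).predicted
                greedy.append(nxt)
                hist.append(nxt)
            # oracle: exhaustive enumeration of all paths of this length
            best_p, best_path = -1.0, None
            idx = {l: i for i, l in enumerate(labels)}
            for path in itertools.product(labels, repeat=length):
                p, cur = 1.0, idx[Posture.SUPINE]
                for step in path:
                    p *= calibrated_matrix[cur, idx[step]]
                    cur = idx[step]
                if p > best_p:
                    best_p, best_path = p, list(path)
            assert greedy == best_path
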