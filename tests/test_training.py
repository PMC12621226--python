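"""Folds, samplers, budgets, and the two training entry points."""

import math

import numpy as np
import pytest

from preictal.architecture import TrainHyperparams
from preictal.coxstuart import EarlyStopConfig
from preictal.training import (
    SearchSpace,
    TrialRecord,
    hyperband_smax,
    make_folds,
    sample_trial,
    successive_halving_budgets,
    train_multi_patient,
    tune_independent_patient,
)

from conftest import make_tiny_store, tiny_spec


# -- folds ------------------------------------------------------------------

def test_stratified_folds_balanced_exactly():
    labels = np.tile([0, 1], 50)
    plan = make_folds(labels, k=5, seed=42)
    for fold in range(5):
        _, val = plan.fold_indices(fold)
        assert len(val) == 20
        assert (labels[val] == 0).sum() == 10


def test_folds_deterministic_and_partitioning():
    labels = np.tile([0, 1], 30)
    a = make_folds(labels, k=5, seed=42)
    b = make_folds(labels, k=5, seed=42)
    np.testing.assert_array_equal(a.assignments, b.assignments)
    # folds partition the index set
    assert sorted(np.concatenate([a.fold_indices(f)[1] for f in range(5)]).tolist()) \
        == list(range(60))


def test_folds_reject_too_few_minority_windows():
    with pytest.raises(ValueError):
        make_folds([0, 0, 0, 1, 1, 1, 1, 1, 1, 1], k=5)


# -- sampler ----------------------------------------------------------------

def test_random_sampling_respects_bounds():
    space = SearchSpace()
    for t in range(1000):
        p = sample_trial(space, "random", [], seed=t)
        assert 1e-5 <= p["learning_rate"] <= 1e-2
        assert p["batch_size"] in (64, 128)
        assert 50 <= p["epochs"] <= 200
        assert 0.5 <= p["weight_decay"] <= 1.0


def test_random_sampling_is_seed_deterministic():
    space = SearchSpace()
    assert sample_trial(space, "random", [], seed=5) == \
        sample_trial(space, "random", [], seed=5)


def test_tpe_prefers_neighbourhood_of_good_observations():
    """With one good (low-loss) and one bad observation, the candidate pool
    member closest to the good point wins the density-ratio ranking."""
    space = SearchSpace()
    base = {"batch_size": 64, "epochs": 100, "weight_decay": 0.7}
    history = [
        ({"learning_rate": 0.001, **base}, 0.1),
        ({"learning_rate": 0.009, **base}, 0.9),
    ]
    picks = [
        sample_trial(space, "tpe", history, seed=s, gamma=0.5, n_candidates=64)
        for s in range(10)
    ]
    near_good = [abs(p["learning_rate"] - 0.001) < abs(p["learning_rate"] - 0.009)
                 for p in picks]
    assert all(near_good)


def test_tpe_falls_back_to_random_with_sparse_history():
    space = SearchSpace()
    p = sample_trial(space, "tpe", [({"learning_rate": 1e-3, "batch_size": 64,
                                      "epochs": 60, "weight_decay": 0.6}, 0.5)], seed=0)
    assert 1e-5 <= p["learning_rate"] <= 1e-2


def test_tpe_assignments_respect_bounds():
    space = SearchSpace()
    rng = np.random.default_rng(0)
    history = []
    for i in range(12):
        params = sample_trial(space, "tpe", history, seed=i)
        history.append((params, float(rng.uniform())))
        assert 1e-5 <= params["learning_rate"] <= 1e-2
        assert params["batch_size"] in (64, 128)
        assert 50 <= params["epochs"] <= 200
        assert 0.5 <= params["weight_decay"] <= 1.0


# -- budgets ----------------------------------------------------------------

@pytest.mark.parametrize("R,r_min,eta,expected", [
    (81, 1, 3, 4),
    (1, 1, 3, 0),
    (16, 1, 2, 4),
    (200, 50, 2, 2),
])
def test_hyperband_bracket_count(R, r_min, eta, expected):
    assert hyperband_smax(R, r_min, eta) == expected


def test_hyperband_validates_inputs():
    with pytest.raises(ValueError):
        hyperband_smax(1, 2, 3)
    with pytest.raises(ValueError):
        hyperband_smax(8, 1, 1.0)


def test_successive_halving_budget_schedule():
    assert successive_halving_budgets(8, 1, 2) == [1, 2, 4, 8]
    assert successive_halving_budgets(81, 1, 3) == [1, 3, 9, 27, 81]


# -- multi-patient training -------------------------------------------------

@pytest.fixture(scope="module")
def quick_result():
    store = make_tiny_store(n=80, seed=3)
    hp = TrainHyperparams(learning_rate=2e-3, batch_size=16, weight_decay=1e-4,
                          seed=42, epochs=6)
    return train_multi_patient(store, tiny_spec(), hp,
                               EarlyStopConfig(window_wp=3), k_folds=2,
                               max_epochs=6)


def test_training_result_bookkeeping(quick_result):
    res = quick_result
    assert len(res.fold_histories) == 2
    assert res.best_fold == int(np.argmin(res.fold_best_losses))
    for h in res.fold_histories:
        assert list(h.columns[:3]) == ["epoch", "train_loss", "val_loss"]
        assert h["epoch"].iloc[0] == 1
    assert res.test_metrics.accuracy is not None
    assert "test:" in res.summary()


def test_checkpoint_equals_minimum_validation_loss(quick_result):
    res = quick_result
    for f, h in enumerate(res.fold_histories):
        assert res.fold_best_losses[f] == pytest.approx(h["val_loss"].min())


def test_learnable_store_beats_chance(quick_result):
    assert quick_result.test_metrics.accuracy >= 0.75


# -- independent-patient tuning ---------------------------------------------

def test_tuning_with_injected_objective_bookkeeping():
    """Pluggable objective: quadratic loss in learning rate, no training."""
    space = SearchSpace(n_trials=5)
    store = make_tiny_store(n=40, seed=5)

    def objective(params):
        loss = (params["learning_rate"] - 0.005) ** 2
        return TrialRecord(-1, params, loss)

    res = tune_independent_patient(
        store, tiny_spec(), space, n_trials=5, strategy="tpe", seed=7,
        objective=objective, evaluate_test=False)
    assert len(res.trials) == 5
    assert [t.trial_id for t in res.trials] == list(range(5))
    assert res.best_trial.best_val_loss == min(t.best_val_loss for t in res.trials)
    assert "best trial" in res.summary()


def test_tuning_trains_and_is_seed_deterministic():
    store = make_tiny_store(n=40, seed=6)
    kwargs = dict(space=SearchSpace(), n_trials=2, strategy="random", seed=11,
                  base_hyperparams=TrainHyperparams(batch_size=16, seed=11),
                  max_epochs_cap=2)
    a = tune_independent_patient(store, tiny_spec(), **kwargs)
    b = tune_independent_patient(store, tiny_spec(), **kwargs)
    assert a.best_trial.trial_id == b.best_trial.trial_id
    assert a.best_trial.best_val_loss == pytest.approx(b.best_trial.best_val_loss)
    assert a.test_metrics.accuracy is not None


def test_successive_halving_prunes_and_tracks_budgets():
    store = make_tiny_store(n=40, seed=8)
    res = tune_independent_patient(
        store, tiny_spec(), SearchSpace(), n_trials=4, strategy="random",
        pruner="successive_halving", seed=13, R=8, r_min=1, eta=2,
        base_hyperparams=TrainHyperparams(batch_size=16, seed=13),
        evaluate_test=False)
    lengths = sorted(len(t.history) for t in res.trials)
    # eliminated trials stop at rung budgets; the survivor reaches R = 8
    assert lengths[-1] == 8
    assert set(lengths) <= {1, 2, 4, 8}
    pruned = [t for t in res.trials if t.status == "pruned"]
    assert pruned and all(len(t.history) < 8 for t in pruned)
    assert res.best_trial.status == "completed"
    # the minimum loss recorded matches the best over the trial's history
    hist_min = min(row["val_loss"] for row in res.best_trial.history)
    assert res.best_trial.best_val_loss == pytest.approx(hist_min)


def test_math_of_objective_selection():
    records = [TrialRecord(i, {}, loss) for i, loss in enumerate([0.5, 0.2, 0.9])]
    assert min(records, key=lambda t: t.best_val_loss).trial_id == 1


def test_search_space_validation():
    with pytest.raises(ValueError):
        SearchSpace(learning_rate=(1e-2, 1e-5))
    with pytest.raises(ValueError):
        SearchSpace(batch_size=())
    with pytest.raises(ValueError):
        SearchSpace(weight_decay=(-0.5, 1.0))


def test_nonfinite_loss_aborts_training():
    store = make_tiny_store(n=20, seed=9)
    store.data[:] = np.nan
    hp = TrainHyperparams(learning_rate=1e-3, batch_size=8, seed=0)
    with pytest.raises(FloatingPointError):
        train_multi_patient(store, tiny_spec(), hp, EarlyStopConfig(window_wp=3),
                            k_folds=2, max_epochs=2)
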