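"""Metrics, effect sizes and summary-table arithmetic."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from preictal.benchmarks import (
    CV_FOLDS,
    MULTI_PATIENT_CV,
    best_hyperparameters,
    subject_runs,
)
from preictal.evaluation import (
    ConfusionMatrix,
    cohens_d,
    compare_models,
    confusion_from_labels,
    interpret_d,
    metrics,
    summarize_trials,
    welch_t,
)

# |d| values published for the Cox-Stuart model against each baseline,
# recomputable from the fold summary statistics with the pooled-SD form.
REFERENCE_EFFECT_SIZES = {
    ("cnn", "val_acc"): 4.2314,
    ("cnn", "val_sen"): 3.7561,
    ("cnn", "val_spe"): 4.3797,
    ("cnn_bilstm", "val_acc"): 0.7918,
    ("cnn_bilstm", "val_sen"): 0.8485,
    ("cnn_bilstm", "val_spe"): 0.5019,
    ("threshold_stop_cnn_bilstm", "val_acc"): 1.0290,
    ("threshold_stop_cnn_bilstm", "val_sen"): 1.0895,
    ("threshold_stop_cnn_bilstm", "val_spe"): 0.7495,
}


@pytest.mark.parametrize("cm,acc,sen,spe", [
    (ConfusionMatrix(tp=1, fn=0, tn=1, fp=0), 1.0, 1.0, 1.0),
    (ConfusionMatrix(tp=0, fn=1, tn=1, fp=0), 0.5, 0.0, 1.0),
    (ConfusionMatrix(tp=9996, fn=4, tn=9988, fp=12), 0.9992, 0.9996, 0.9988),
])
def test_metric_formulas(cm, acc, sen, spe):
    m = metrics(cm)
    assert m.accuracy == pytest.approx(acc, abs=1e-12)
    assert m.sensitivity == pytest.approx(sen, abs=1e-12)
    assert m.specificity == pytest.approx(spe, abs=1e-12)


def test_undefined_ratio_is_flagged_not_zeroed():
    m = metrics(ConfusionMatrix(tp=0, fn=0, tn=3, fp=1))
    assert m.sensitivity is None
    assert m.specificity == pytest.approx(0.75)


@given(st.integers(1, 50), st.integers(0, 50), st.integers(1, 50), st.integers(0, 50),
       st.integers(2, 9))
def test_metrics_scale_invariant(tp, fn, tn, fp, scale):
    base = metrics(ConfusionMatrix(tp, fn, tn, fp))
    scaled = metrics(ConfusionMatrix(tp * scale, fn * scale, tn * scale, fp * scale))
    assert scaled.accuracy == pytest.approx(base.accuracy)
    assert scaled.sensitivity == pytest.approx(base.sensitivity)
    assert scaled.specificity == pytest.approx(base.specificity)


def test_confusion_from_labels_counts_preictal_as_positive():
    cm = confusion_from_labels([0, 0, 1, 1, 0], [0, 1, 1, 0, 0])
    assert (cm.tp, cm.fn, cm.tn, cm.fp) == (2, 1, 1, 1)


@pytest.mark.parametrize("model,metric", sorted(REFERENCE_EFFECT_SIZES))
def test_pooled_sd_effect_sizes_reproduce_reference(model, metric):
    """All nine published |d| values follow from the fold summaries to 4 dp."""
    mean_b, sd_b = MULTI_PATIENT_CV[model][metric]
    mean_a, sd_a = MULTI_PATIENT_CV["coxstuart_cnn_bilstm"][metric]
    d = cohens_d(mean_a, sd_a, mean_b, sd_b)
    assert d == pytest.approx(REFERENCE_EFFECT_SIZES[(model, metric)], abs=5e-5)


def test_cohens_d_degenerate_cases():
    assert cohens_d(1.0, 0.0, 1.0, 0.0) == 0.0
    assert math.isinf(cohens_d(1.0, 0.0, 0.9, 0.0))
    assert cohens_d(0.5, 0.1, 0.5, 0.3) == 0.0


def test_welch_t_on_fold_summaries():
    t, df, p = welch_t(0.9983, 0.0005, 5, 0.9892, 0.0030, 5)
    assert t == pytest.approx(6.69, abs=0.01)
    assert df == pytest.approx(4.22, abs=0.05)
    # two-sided p rounds to the published 0.0021
    assert p == pytest.approx(0.0021, abs=2e-4)


def test_welch_t_symmetries():
    t, _, p = welch_t(0.5, 0.1, 5, 0.7, 0.2, 5)
    t2, _, p2 = welch_t(0.7, 0.2, 5, 0.5, 0.1, 5)
    assert t2 == pytest.approx(-t)
    assert p2 == pytest.approx(p)
    t0, _, p0 = welch_t(0.5, 0.1, 5, 0.5, 0.1, 5)
    assert t0 == 0.0 and p0 == pytest.approx(1.0)
    with pytest.raises(ValueError):
        welch_t(0.5, 0.1, 1, 0.5, 0.1, 5)


@pytest.mark.parametrize("d,band", [
    (0.1, "negligible"), (0.2, "small"), (0.49, "small"),
    (0.5, "medium"), (0.79, "medium"), (0.8, "large"), (4.2314, "large"),
])
def test_effect_size_bands(d, band):
    assert interpret_d(d) == band


@given(st.floats(0, 10), st.floats(0, 10))
def test_band_ordering_is_monotone(d1, d2):
    order = ["negligible", "small", "medium", "large"]
    lo, hi = sorted([d1, d2])
    assert order.index(interpret_d(lo)) <= order.index(interpret_d(hi))


def test_compare_models_bundles_t_and_d():
    a = MULTI_PATIENT_CV["coxstuart_cnn_bilstm"]["val_acc"]
    b = MULTI_PATIENT_CV["cnn"]["val_acc"]
    res = compare_models(*a, CV_FOLDS, *b, CV_FOLDS)
    assert res.band == "large"
    assert res.cohens_d == pytest.approx(4.2314, abs=5e-5)
    assert res.p_value < 0.05


def test_subject_table_mean_row():
    """Column means of the tuned-hyperparameter table at printed precision."""
    means = summarize_trials(
        best_hyperparameters(),
        precision={"learning_rate": 4, "batch_size": 0, "epoch": 0, "weight_decay": 4},
    )
    assert means["learning_rate"] == pytest.approx(0.0061, abs=0)
    assert means["batch_size"] == 109
    assert means["epoch"] == 134
    assert means["weight_decay"] == pytest.approx(0.7007, abs=0)


def test_mean_data_volume():
    runs = summarize_trials(subject_runs(), precision={"data_volume": 0,
                                                       "train_time_s": 0})
    assert runs["data_volume"] == 1060
    assert runs["train_time_s"] == 1346


def test_single_row_summary_is_identity():
    table = best_hyperparameters().iloc[[0]]
    means = summarize_trials(table, precision={"learning_rate": 4})
    assert means["learning_rate"] == pytest.approx(0.0073)
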