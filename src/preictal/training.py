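"""Training loops and the hyperparameter-search layer.

Two entry points mirror the two data-partitioning modes:

* :func:`train_multi_patient` — pooled data, stratified K-fold
  cross-validation, Adam with reduce-on-plateau scheduling, Cox-Stuart
  early stopping, checkpoint on validation-loss improvement, and a single
  held-out test evaluation of the best fold state.
* :func:`tune_independent_patient` — per-subject search over the
  hyperparameter space (learning rate, batch size, epochs, weight decay)
  with a random or TPE-style sampler and optional successive-halving
  pruning across geometric epoch budgets.

The TPE-style sampler splits observed trials at the gamma-quantile of
their losses, fits separate per-dimension densities l(x) (good) and g(x)
(bad), and returns the candidate maximizing the density ratio l/g — the
quantity the expected-improvement criterion is proportional to. Both
results objects expose ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np
import pandas as pd

from . import nn
from .architecture import LayerSpec, TrainHyperparams, build_model
from .coxstuart import CoxStuartStopper, EarlyStopConfig
from .data_io import WindowStore
from .evaluation import MetricSet, confusion_from_labels, metrics
from .preprocessing import SplitSpec, partition

__all__ = [
    "FoldPlan",
    "SearchSpace",
    "TrialRecord",
    "TrainingResult",
    "TuningResult",
    "make_folds",
    "train_multi_patient",
    "sample_trial",
    "hyperband_smax",
    "successive_halving_budgets",
    "tune_independent_patient",
]


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    k: int
    seed: int
    assignments: np.ndarray  # window index -> fold id

    def fold_indices(self, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_idx, val_idx) for one fold."""
        val = np.where(self.assignments == fold)[0]
        train = np.where(self.assignments != fold)[0]
        return train, val


def make_folds(labels: Sequence[int], k: int = 5, seed: int = 42) -> FoldPlan:
    """Stratified, shuffled K-fold assignment of window indices."""
    from sklearn.model_selection import StratifiedKFold

    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the minority class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.empty(len(labels), dtype=np.int64)
    for fold, (_, val_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        assignments[val_idx] = fold
    return FoldPlan(k=k, seed=seed, assignments=assignments)


# ---------------------------------------------------------------------------
# Single fit
# ---------------------------------------------------------------------------

def _evaluate(model: nn.DualBranchNet, X: np.ndarray, y: np.ndarray,
              batch_size: int = 256) -> tuple[float, MetricSet]:
    losses = []
    preds = []
    for a in range(0, len(X), batch_size):
        xb, yb = X[a:a + batch_size], y[a:a + batch_size]
        logits = model.forward(xb, training=False)
        loss, _ = nn.cross_entropy(logits, yb)
        losses.append(loss * len(xb))
        preds.append(logits.argmax(axis=1))
    pred = np.concatenate(preds)
    cm = confusion_from_labels(y, pred)
    return float(np.sum(losses) / len(X)), metrics(cm)


def fit_model(
    model: nn.DualBranchNet,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_val: np.ndarray,
    y_val: np.ndarray,
    hp: TrainHyperparams,
    max_epochs: int,
    stopper: CoxStuartStopper | None = None,
    rng: np.random.Generator | None = None,
    scheduler_kwargs: dict | None = None,
    start_epoch: int = 0,
    optimizer: nn.Adam | None = None,
) -> dict:
    """Train for up to ``max_epochs`` epochs; checkpoint on val-loss improvement.

    Returns a dict with the best state, best validation loss, per-epoch
    history rows, and the number of epochs executed. ``start_epoch`` and
    ``optimizer`` allow budgeted resumption (successive halving).
    """
    rng = rng or np.random.default_rng(hp.seed)
    opt = optimizer or nn.Adam(model, lr=hp.learning_rate,
                               weight_decay=hp.weight_decay)
    sched = nn.ReduceLROnPlateau(opt, **(scheduler_kwargs or {}))
    best_loss = math.inf
    best_state = None
    best_epoch = None
    history: list[dict] = []

    epoch = start_epoch
    for epoch in range(start_epoch + 1, max_epochs + 1):
        order = rng.permutation(len(X_train))
        train_losses = []
        for a in range(0, len(order), hp.batch_size):
            idx = order[a:a + hp.batch_size]
            logits = model.forward(X_train[idx], training=True)
            loss, dlogits = nn.cross_entropy(logits, y_train[idx])
            if not math.isfinite(loss):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            train_losses.append(loss * len(idx))
        train_loss = float(np.sum(train_losses) / len(X_train))
        val_loss, val_metrics = _evaluate(model, X_val, y_val)
        sched.step(val_loss)
        history.append({
            "epoch": epoch,
            "train_loss": train_loss,
            "val_loss": val_loss,
            "val_acc": val_metrics.accuracy,
            "val_sen": val_metrics.sensitivity,
            "val_spe": val_metrics.specificity,
            "lr": opt.lr,
        })
        if val_loss < best_loss:
            best_loss = val_loss
            best_state = model.state_dict()
            best_epoch = epoch
        if stopper is not None and stopper.on_epoch_end(epoch, val_loss) == "stop":
            break

    return {
        "best_state": best_state,
        "best_val_loss": best_loss,
        "best_epoch": best_epoch,
        "history": history,
        "epochs_run": epoch,
        "optimizer": opt,
    }


# ---------------------------------------------------------------------------
# Multi-patient training
# ---------------------------------------------------------------------------

@dataclass
class TrainingResult:
    """Cross-validated multi-patient training outcome."""

    fold_histories: list[pd.DataFrame]
    fold_best_losses: list[float]
    best_fold: int
    best_state: list[np.ndarray]
    test_metrics: MetricSet
    test_confusion: object
    stopped_epochs: list[int]

    @property
    def cv_table(self) -> pd.DataFrame:
        """Best-epoch validation metrics per fold."""
        rows = []
        for f, h in enumerate(self.fold_histories):
            best = h.loc[h["val_loss"].idxmin()]
            rows.append({
                "fold": f,
                "best_epoch": int(best["epoch"]),
                "val_loss": best["val_loss"],
                "val_acc": best["val_acc"],
                "val_sen": best["val_sen"],
                "val_spe": best["val_spe"],
                "epochs_run": int(h["epoch"].max()),
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        cv = self.cv_table
        lines = ["Multi-patient training summary", "=" * 34]
        lines.append(cv.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
        lines.append("")
        for m in ("val_acc", "val_sen", "val_spe"):
            lines.append(f"mean {m}: {cv[m].mean():.4f} +/- {cv[m].std(ddof=1):.4f}")
        t = self.test_metrics
        lines.append(
            f"test: accuracy {t.accuracy:.4f}, sensitivity {t.sensitivity:.4f}, "
            f"specificity {t.specificity:.4f}"
        )
        lines.append(f"best fold: {self.best_fold}  "
                     f"(val_loss {self.fold_best_losses[self.best_fold]:.4f})")
        return "\n".join(lines)


def train_multi_patient(
    store: WindowStore,
    spec: Sequence[LayerSpec],
    hyperparams: TrainHyperparams | None = None,
    early_stop_config: EarlyStopConfig | None = None,
    k_folds: int = 5,
    max_epochs: int | None = None,
    split_spec: SplitSpec | None = None,
    dtype=np.float32,
) -> TrainingResult:
    """Pooled-data training: 6:2:2 split, K-fold CV over the non-test 80%,
    Cox-Stuart early stopping per fold, best fold state evaluated on test."""
    hp = hyperparams or TrainHyperparams()
    es_cfg = early_stop_config or EarlyStopConfig()
    max_epochs = max_epochs or hp.epochs
    split = split_spec or SplitSpec(mode="multi_patient", seed=hp.seed)

    train_store, val_store, test_store = partition(store, split)
    # CV pool = train + validation windows (the test partition stays held out)
    X = np.concatenate([train_store.data, val_store.data]).astype(dtype)
    y = np.concatenate([train_store.labels, val_store.labels]).astype(np.int64)
    X_test = test_store.data.astype(dtype)
    y_test = test_store.labels.astype(np.int64)

    plan = make_folds(y, k=k_folds, seed=hp.seed)
    input_shape = (hp.batch_size,) + X.shape[1:]

    fold_histories: list[pd.DataFrame] = []
    fold_best: list[float] = []
    fold_states: list[list[np.ndarray]] = []
    stopped: list[int] = []
    for fold in range(plan.k):
        tr_idx, val_idx = plan.fold_indices(fold)
        model = build_model(spec, TrainHyperparams(**{**hp.__dict__, "seed": hp.seed + fold}),
                            input_shape=input_shape, dtype=dtype)
        res = fit_model(
            model, X[tr_idx], y[tr_idx], X[val_idx], y[val_idx], hp,
            max_epochs=max_epochs,
            stopper=CoxStuartStopper(es_cfg),
            rng=np.random.default_rng(hp.seed + 1000 + fold),
        )
        fold_histories.append(pd.DataFrame(res["history"]))
        fold_best.append(res["best_val_loss"])
        fold_states.append(res["best_state"])
        stopped.append(res["epochs_run"])

    best_fold = int(np.argmin(fold_best))
    model = build_model(spec, TrainHyperparams(**{**hp.__dict__, "seed": hp.seed + best_fold}),
                        input_shape=input_shape, dtype=dtype)
    model.load_state_dict(fold_states[best_fold])
    _, test_metrics_ = _evaluate(model, X_test, y_test)
    preds = []
    for a in range(0, len(X_test), 256):
        preds.append(model.forward(X_test[a:a + 256], training=False).argmax(axis=1))
    cm = confusion_from_labels(y_test, np.concatenate(preds))

    return TrainingResult(
        fold_histories=fold_histories,
        fold_best_losses=fold_best,
        best_fold=best_fold,
        best_state=fold_states[best_fold],
        test_metrics=test_metrics_,
        test_confusion=cm,
        stopped_epochs=stopped,
    )


# ---------------------------------------------------------------------------
# Hyperparameter search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SearchSpace:
    """Search bounds for the independent-patient tuner."""

    learning_rate: tuple[float, float] = (1e-5, 1e-2)
    batch_size: tuple[int, ...] = (64, 128)
    epochs: tuple[int, int] = (50, 200)
    weight_decay: tuple[float, float] = (0.5, 1.0)  # sampled log-uniformly
    n_trials: int = 5

    def __post_init__(self) -> None:
        if self.learning_rate[0] >= self.learning_rate[1]:
            raise ValueError("learning_rate bounds must be increasing")
        if not self.batch_size:
            raise ValueError("batch_size choices must be non-empty")
        if self.epochs[0] > self.epochs[1]:
            raise ValueError("epochs bounds must be non-decreasing")
        if not 0 < self.weight_decay[0] <= self.weight_decay[1]:
            raise ValueError("weight_decay bounds must be positive and increasing")


@dataclass
class TrialRecord:
    trial_id: int
    params: dict
    best_val_loss: float
    history: list[dict] = field(default_factory=list)
    status: Literal["completed", "pruned"] = "completed"
    state: list[np.ndarray] | None = None


def _kde_logpdf(obs: np.ndarray, x: float, span: float) -> float:
    """Log density of a Gaussian mixture centred on the observations.

    Bandwidth by the normal-reference rule, floored at span/10 so that a
    single observation (or ties) still defines a proper density.
    """
    n = len(obs)
    sd = obs.std(ddof=1) if n > 1 else 0.0
    bw = 1.06 * sd * n ** (-0.2) if sd > 0 else 0.0
    bw = max(bw, span / 10.0, 1e-12)
    z = (x - obs) / bw
    dens = np.exp(-0.5 * z**2).sum() / (n * bw * math.sqrt(2 * math.pi))
    return math.log(dens + 1e-300)


def _cat_logpmf(obs: list, value, choices: tuple) -> float:
    counts = {c: 1.0 for c in choices}  # add-one smoothing
    for o in obs:
        counts[o] += 1.0
    total = sum(counts.values())
    return math.log(counts[value] / total)


def _draw(space: SearchSpace, rng: np.random.Generator) -> dict:
    lo, hi = space.learning_rate
    wd_lo, wd_hi = space.weight_decay
    return {
        "learning_rate": float(rng.uniform(lo, hi)),
        "batch_size": int(rng.choice(space.batch_size)),
        "epochs": int(rng.integers(space.epochs[0], space.epochs[1] + 1)),
        "weight_decay": float(np.exp(rng.uniform(np.log(wd_lo), np.log(wd_hi)))),
    }


def sample_trial(
    space: SearchSpace,
    strategy: Literal["random", "tpe"],
    history: Sequence[tuple[dict, float]],
    seed: int,
    gamma: float = 0.25,
    n_candidates: int = 24,
) -> dict:
    """Sample one hyperparameter assignment.

    ``random`` draws uniformly (log-uniformly for weight decay). ``tpe``
    splits the observed (params, loss) history at the gamma-quantile of
    losses, fits good/bad densities per dimension, and returns the
    candidate (from a seeded pool) with the highest aggregate l/g density
    ratio; with fewer than two observations it falls back to random.
    """
    rng = np.random.default_rng(seed)
    if strategy == "random" or len(history) < 2:
        return _draw(space, rng)
    if strategy != "tpe":
        raise ValueError(f"unknown strategy {strategy!r}")

    losses = np.array([h[1] for h in history])
    n_good = max(1, math.ceil(gamma * len(history)))
    order = np.argsort(losses, kind="stable")
    good = [history[i][0] for i in order[:n_good]]
    bad = [history[i][0] for i in order[n_good:]]
    if not bad:
        return _draw(space, rng)

    spans = {
        "learning_rate": space.learning_rate[1] - space.learning_rate[0],
        "epochs": float(space.epochs[1] - space.epochs[0]) or 1.0,
        "weight_decay": math.log(space.weight_decay[1]) - math.log(space.weight_decay[0]),
    }

    def score(cand: dict) -> float:
        s = 0.0
        for dim, span in spans.items():
            tf = math.log if dim == "weight_decay" else float
            g_obs = np.array([tf(p[dim]) for p in good], dtype=float)
            b_obs = np.array([tf(p[dim]) for p in bad], dtype=float)
            x = tf(cand[dim])
            s += _kde_logpdf(g_obs, x, span) - _kde_logpdf(b_obs, x, span)
        s += _cat_logpmf([p["batch_size"] for p in good], cand["batch_size"],
                         space.batch_size)
        s -= _cat_logpmf([p["batch_size"] for p in bad], cand["batch_size"],
                         space.batch_size)
        return s

    candidates = [_draw(space, rng) for _ in range(n_candidates)]
    return max(candidates, key=score)


def hyperband_smax(R: float, r_min: float, eta: float) -> int:
    """Bracket count s_max = floor(log_eta(R / r_min))."""
    if r_min <= 0 or R < r_min:
        raise ValueError("need R >= r_min > 0")
    if eta <= 1:
        raise ValueError("eta must exceed 1")
    return int(math.floor(math.log(R / r_min) / math.log(eta) + 1e-12))


def successive_halving_budgets(R: float, r_min: float, eta: float) -> list[int]:
    """Geometric epoch budgets r_min * eta^s for s = 0..s_max."""
    s_max = hyperband_smax(R, r_min, eta)
    return [int(round(r_min * eta**s)) for s in range(s_max + 1)]


@dataclass
class TuningResult:
    """Independent-patient search outcome."""

    trials: list[TrialRecord]
    best_trial: TrialRecord
    test_metrics: MetricSet | None = None

    def trial_table(self) -> pd.DataFrame:
        rows = []
        for t in self.trials:
            rows.append({
                "trial": t.trial_id,
                **t.params,
                "best_val_loss": t.best_val_loss,
                "epochs_run": len(t.history),
                "status": t.status,
            })
        return pd.DataFrame(rows)

    def summary(self) -> str:
        table = self.trial_table()
        lines = ["Independent-patient tuning summary", "=" * 34]
        lines.append(table.to_string(index=False, float_format=lambda v: f"{v:.5f}"))
        completed = table[table["status"] == "completed"]
        if len(completed) > 1:
            lines.append(
                f"best_val_loss over completed trials: "
                f"{completed['best_val_loss'].mean():.5f} +/- "
                f"{completed['best_val_loss'].std(ddof=1):.5f}"
            )
        lines.append(f"best trial: {self.best_trial.trial_id} "
                     f"(params {self.best_trial.params})")
        if self.test_metrics is not None:
            t = self.test_metrics
            lines.append(
                f"test: accuracy {t.accuracy:.4f}, sensitivity {t.sensitivity:.4f}, "
                f"specificity {t.specificity:.4f}"
            )
        return "\n".join(lines)


def tune_independent_patient(
    store: WindowStore,
    spec: Sequence[LayerSpec],
    space: SearchSpace | None = None,
    n_trials: int | None = None,
    strategy: Literal["random", "tpe"] = "tpe",
    pruner: Literal["none", "successive_halving"] = "none",
    seed: int = 42,
    base_hyperparams: TrainHyperparams | None = None,
    max_epochs_cap: int | None = None,
    eta: float = 2.0,
    r_min: int = 1,
    R: int | None = None,
    evaluate_test: bool = True,
    objective: Callable[[dict], TrialRecord] | None = None,
    dtype=np.float32,
) -> TuningResult:
    """Per-subject hyperparameter search.

    Each trial trains the network with sampled hyperparameters on the
    subject's 6:2:2 split and scores it by its best validation loss.
    ``pruner='successive_halving'`` advances all trials through the
    geometric budgets of :func:`successive_halving_budgets` (total resource
    R = the trial's epoch budget), eliminating the worst 1 - 1/eta at each
    rung. An external optimizer can be plugged in by passing ``objective``,
    which must map a sampled-params dict to a completed TrialRecord.
    """
    space = space or SearchSpace()
    n_trials = n_trials or space.n_trials
    hp0 = base_hyperparams or TrainHyperparams()

    train_store, val_store, test_store = partition(
        store, SplitSpec(mode="independent_patient", seed=seed))
    X_tr = train_store.data.astype(dtype)
    y_tr = train_store.labels.astype(np.int64)
    X_va = val_store.data.astype(dtype)
    y_va = val_store.labels.astype(np.int64)

    def default_objective(params: dict, trial_id: int) -> TrialRecord:
        hp = TrainHyperparams(**{
            **hp0.__dict__,
            "learning_rate": params["learning_rate"],
            "batch_size": params["batch_size"],
            "weight_decay": params["weight_decay"],
            "seed": seed + trial_id,
        })
        budget = params["epochs"]
        if max_epochs_cap is not None:
            budget = min(budget, max_epochs_cap)
        model = build_model(spec, hp, input_shape=(hp.batch_size,) + X_tr.shape[1:],
                            dtype=dtype)
        res = fit_model(model, X_tr, y_tr, X_va, y_va, hp, max_epochs=budget,
                        rng=np.random.default_rng(seed + 500 + trial_id))
        return TrialRecord(trial_id, params, res["best_val_loss"],
                           history=res["history"], state=res["best_state"])

    history: list[tuple[dict, float]] = []
    trials: list[TrialRecord] = []

    if pruner == "none":
        for t in range(n_trials):
            params = sample_trial(space, strategy, history, seed=seed + 100 + t)
            rec = objective(params) if objective else default_objective(params, t)
            rec.trial_id = t
            history.append((params, rec.best_val_loss))
            trials.append(rec)
    elif pruner == "successive_halving":
        params_list = [
            sample_trial(space, strategy, history, seed=seed + 100 + t)
            for t in range(n_trials)
        ]
        total_R = R if R is not None else max(
            1, (max_epochs_cap or min(p["epochs"] for p in params_list)))
        budgets = successive_halving_budgets(R=total_R, r_min=r_min, eta=eta)
        # live state per trial: (model, optimizer, record)
        live: dict[int, dict] = {}
        for t, params in enumerate(params_list):
            hp = TrainHyperparams(**{
                **hp0.__dict__,
                "learning_rate": params["learning_rate"],
                "batch_size": params["batch_size"],
                "weight_decay": params["weight_decay"],
                "seed": seed + t,
            })
            model = build_model(spec, hp, input_shape=(hp.batch_size,) + X_tr.shape[1:],
                                dtype=dtype)
            rec = TrialRecord(t, params, math.inf)
            live[t] = {"model": model, "hp": hp, "rec": rec, "opt": None, "epoch": 0}
            trials.append(rec)
        active = list(live)
        for rung, budget in enumerate(budgets):
            for t in active:
                st = live[t]
                res = fit_model(
                    st["model"], X_tr, y_tr, X_va, y_va, st["hp"],
                    max_epochs=budget, start_epoch=st["epoch"],
                    optimizer=st["opt"],
                    rng=np.random.default_rng(seed + 500 + t + 1000 * rung),
                )
                st["epoch"] = budget
                st["opt"] = res["optimizer"]
                rec = st["rec"]
                rec.history.extend(res["history"])
                if res["best_val_loss"] < rec.best_val_loss:
                    rec.best_val_loss = res["best_val_loss"]
                    rec.state = res["best_state"]
            if rung < len(budgets) - 1:
                active.sort(key=lambda t: live[t]["rec"].best_val_loss)
                keep = max(1, int(len(active) / eta))
                for t in active[keep:]:
                    live[t]["rec"].status = "pruned"
                active = active[:keep]
        for t, rec in enumerate(trials):
            history.append((rec.params, rec.best_val_loss))
    else:
        raise ValueError(f"unknown pruner {pruner!r}")

    completed = [t for t in trials if t.status == "completed"]
    best = min(completed, key=lambda t: t.best_val_loss)

    test_metrics_ = None
    if evaluate_test and best.state is not None:
        hp = TrainHyperparams(**{
            **hp0.__dict__,
            "learning_rate": best.params["learning_rate"],
            "batch_size": best.params["batch_size"],
            "weight_decay": best.params["weight_decay"],
            "seed": seed + best.trial_id,
        })
        model = build_model(spec, hp, input_shape=(hp.batch_size,) + X_tr.shape[1:],
                            dtype=dtype)
        model.load_state_dict(best.state)
        _, test_metrics_ = _evaluate(
            model, test_store.data.astype(dtype),
            test_store.labels.astype(np.int64))

    return TuningResult(trials=trials, best_trial=best, test_metrics=test_metrics_)
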