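"""Bundled reference tables from a published CHB-MIT seizure-prediction benchmark.

These small summary tables back the worked examples and the reproduction
script: per-model 5-fold cross-validation statistics for the multi-patient
pipeline, per-subject tuned hyperparameters for the independent-patient
pipeline, and per-subject balanced data volumes. Values are summary
statistics only (means and standard deviations over folds/trials), not raw
EEG data.
"""

from __future__ import annotations

import pandas as pd

# 5-fold cross-validation summaries (mean, std) per model and validation
# metric, n = 5 folds. Models: a plain CNN, the CNN-BiLSTM hybrid, the
# hybrid with a loss-threshold early stop, and the hybrid with the
# Cox-Stuart early stop.
CV_FOLDS = 5

MULTI_PATIENT_CV: dict[str, dict[str, tuple[float, float]]] = {
    "cnn": {
        "val_acc": (0.9892, 0.0030),
        "val_sen": (0.9900, 0.0032),
        "val_spe": (0.9884, 0.0029),
    },
    "cnn_bilstm": {
        "val_acc": (0.9972, 0.0019),
        "val_sen": (0.9972, 0.0024),
        "val_spe": (0.9972, 0.0017),
    },
    "threshold_stop_cnn_bilstm": {
        "val_acc": (0.9968, 0.0020),
        "val_sen": (0.9967, 0.0025),
        "val_spe": (0.9969, 0.0016),
    },
    "coxstuart_cnn_bilstm": {
        "val_acc": (0.9983, 0.0005),
        "val_sen": (0.9987, 0.0007),
        "val_spe": (0.9979, 0.0010),
    },
}

# Best hyperparameters found by the 5-trial independent-patient search for
# each of the 23 CHB-MIT subjects.
_BEST_HYPERPARAMS_ROWS = [
    # subject, learning_rate, batch_size, epoch, weight_decay
    ("chb01", 0.0073, 128, 184, 0.5467),
    ("chb02", 0.0027, 64, 171, 0.6191),
    ("chb03", 0.0015, 64, 130, 0.5986),
    ("chb04", 0.0100, 128, 133, 0.8397),
    ("chb05", 0.0053, 128, 127, 0.7894),
    ("chb06", 0.0037, 64, 115, 0.5150),
    ("chb07", 0.0085, 128, 159, 0.8994),
    ("chb08", 0.0070, 128, 168, 0.7281),
    ("chb09", 0.0091, 64, 104, 0.5555),
    ("chb10", 0.0011, 128, 126, 0.5095),
    ("chb11", 0.0074, 128, 137, 0.6919),
    ("chb12", 0.0055, 128, 187, 0.6217),
    ("chb13", 0.0033, 128, 105, 0.7723),
    ("chb14", 0.0057, 64, 61, 0.8377),
    ("chb15", 0.0002, 128, 111, 0.9027),
    ("chb16", 0.0097, 128, 165, 0.7252),
    ("chb17", 0.0097, 128, 110, 0.8361),
    ("chb18", 0.0036, 128, 104, 0.6273),
    ("chb19", 0.0092, 64, 144, 0.5959),
    ("chb20", 0.0088, 128, 136, 0.9236),
    ("chb21", 0.0079, 64, 153, 0.6968),
    ("chb22", 0.0060, 128, 119, 0.6222),
    ("chb23", 0.0077, 128, 122, 0.6613),
]

# Per-subject balanced window counts (data volume) and wall-clock training
# time in seconds for the 5-trial independent-patient runs.
_SUBJECT_RUN_ROWS = [
    # subject, train_time_s, data_volume
    ("chb01", 1509, 1328),
    ("chb02", 1319, 476),
    ("chb03", 1498, 1194),
    ("chb04", 1365, 714),
    ("chb05", 1246, 1184),
    ("chb06", 1286, 1650),
    ("chb07", 1377, 714),
    ("chb08", 1480, 1190),
    ("chb09", 1232, 714),
    ("chb10", 1377, 1666),
    ("chb11", 1038, 476),
    ("chb12", 1072, 880),
    ("chb13", 1041, 1230),
    ("chb14", 1291, 1428),
    ("chb15", 1641, 2982),
    ("chb16", 1556, 842),
    ("chb17", 1171, 714),
    ("chb18", 1161, 1014),
    ("chb19", 1438, 476),
    ("chb20", 1625, 1190),
    ("chb21", 1553, 952),
    ("chb22", 1564, 714),
    ("chb23", 1111, 660),
]


def best_hyperparameters() -> pd.DataFrame:
    """Per-subject tuned hyperparameters as a DataFrame indexed by subject."""
    df = pd.DataFrame(
        _BEST_HYPERPARAMS_ROWS,
        columns=["subject", "learning_rate", "batch_size", "epoch", "weight_decay"],
    )
    return df.set_index("subject")


def subject_runs() -> pd.DataFrame:
    """Per-subject training time and balanced data volume."""
    df = pd.DataFrame(
        _SUBJECT_RUN_ROWS, columns=["subject", "train_time_s", "data_volume"]
    )
    return df.set_index("subject")
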