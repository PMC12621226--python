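import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from preictal.architecture import LayerSpec
from preictal.data_io import WindowStore

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_tiny_store(
    n: int = 60,
    n_channels: int = 4,
    separable: bool = True,
    seed: int = 0,
) -> WindowStore:
    """Small labeled window store with an easily learnable mean shift."""
    rng = np.random.default_rng(seed)
    data = rng.standard_normal((n, n_channels, 10, 256)).astype(np.float32)
    labels = np.tile([0, 1], n // 2 + 1)[:n].astype(np.int64)
    if separable:
        data[labels == 1] += 0.8
    prov = [("tiny", 256 * i) for i in range(n)]
    return WindowStore(data=data, labels=labels, provenance=prov)


def tiny_spec(n_channels: int = 4) -> list[LayerSpec]:
    """Minimal dual-branch spec over a [n_channels x 10 x 256] grid."""
    cnn_flat = 2 * 2 * 15  # 2 maps of 2 x 15 after the conv/pool chain
    lstm_flat = n_channels * 2 * 2
    return [
        LayerSpec("conv2d", "cnn", n_channels, 2, kernel=(3, 3)),
        LayerSpec("maxpool", "cnn", 2, 2, pool=(2, 4)),
        LayerSpec("activation", "cnn"),
        LayerSpec("conv2d", "cnn", 2, 2, kernel=(3, 3)),
        LayerSpec("maxpool", "cnn", 2, 2, pool=(1, 4)),
        LayerSpec("activation", "cnn"),
        LayerSpec("bilstm", "bilstm", 10 * 256, 4, hidden=2),
        LayerSpec("activation", "bilstm"),
        LayerSpec("fully_connected", "fusion", None, cnn_flat + lstm_flat),
        LayerSpec("fully_connected", "fusion", cnn_flat + lstm_flat, 2),
    ]


@pytest.fixture(scope="session")
def tiny_store() -> WindowStore:
    return make_tiny_store()
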