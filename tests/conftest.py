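import numpy as np
import pytest

from plantfuse.dataset import build_dataset
from plantfuse.synthetic import SyntheticSpec, generate_dataset


class FakeBackbone:
    """Feature-dim-only backbone stand-in (synthetic) for fusion-layer tests."""

    def __init__(self, dims):
        self.dims = dims

    @property
    def fusible_layers(self):
        return [(f"layer{i + 1}", d) for i, d in enumerate(self.dims)]

    @property
    def n_fusible(self):
        return len(self.dims)


def toy_bitwise_data(n: int, seed: int):
    """Two modalities whose informative layers each carry one bit of a 4-class
    label; the other fusible layers are pure noise.  The unique good fusion
    taps modality A's layer 2 and modality B's layer 1."""
    r = np.random.default_rng(seed)
    y = r.integers(0, 4, size=n)
    b0, b1 = y // 2, y % 2
    feats = {
        "A": [r.normal(size=(n, 4)), np.eye(2)[b0] + 0.05 * r.normal(size=(n, 2))],
        "B": [np.eye(2)[b1] + 0.05 * r.normal(size=(n, 2)), r.normal(size=(n, 4))],
    }
    return feats, y


@pytest.fixture(scope="session")
def toy_backbones():
    return {"A": FakeBackbone([4, 2]), "B": FakeBackbone([2, 4])}


@pytest.fixture(scope="session")
def small_raw_dataset(tmp_path_factory):
    """5-class synthetic dataset, seed 7 (shared across tests)."""
    out = tmp_path_factory.mktemp("raw5")
    spec = SyntheticSpec(n_classes=5, seed=7, max_observations=25)
    meta = generate_dataset(spec, out)
    return {"dir": str(out), "meta": meta, "spec": spec}


@pytest.fixture(scope="session")
def small_built_dataset(small_raw_dataset, tmp_path_factory):
    out = tmp_path_factory.mktemp("built5")
    manifest = build_dataset(f"{small_raw_dataset['dir']}/metadata.csv",
                             str(out), seed=42, image_size=32)
    return {"dir": str(out), "manifest": manifest}
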