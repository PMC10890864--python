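import numpy as np
import pytest

from octsr.phantom import PhantomSpec, build_dataset
from octsr.training import PhantomDataset


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory) -> PhantomDataset:
    """Small 32x32 dataset shared by training/CLI tests (cheap to fit on)."""
    root = tmp_path_factory.mktemp("tiny_ds")
    spec = PhantomSpec(height_px=32, width_px=32, frames_per_sequence=5)
    build_dataset(spec, 8, 8, root, seed=11)
    return PhantomDataset(root)


@pytest.fixture(scope="session")
def tiny_dataset_dir(tiny_dataset) -> str:
    return str(tiny_dataset.root)
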