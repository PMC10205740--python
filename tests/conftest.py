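import numpy as np
import pytest

from epiderm.synthetic_histology import (DEFAULT_STRATA, GeneratorConfig,
                                         generate_dataset)


def make_dataset(tmp_root, n, size_px, seed, seg_share=1.0, annotator=None):
    strata = dict(DEFAULT_STRATA)
    strata["segmentation_share"] = seg_share
    template = GeneratorConfig(height_px=size_px, width_px=size_px)
    return generate_dataset(n, tmp_root, strata=strata, config_template=template,
                            seed=seed, annotator=annotator)


@pytest.fixture(scope="session")
def ds_small(tmp_path_factory):
    """12 fully annotated 64x64 samples: fast I/O and pipeline checks."""
    root = tmp_path_factory.mktemp("ds_small")
    return make_dataset(root, 12, 64, seed=101)


@pytest.fixture(scope="session")
def ds_medium(tmp_path_factory):
    """26 fully annotated 128x128 samples: small training runs."""
    root = tmp_path_factory.mktemp("ds_medium")
    return make_dataset(root, 26, 128, seed=5)


@pytest.fixture(scope="session")
def ds_reg_small(tmp_path_factory):
    """40 samples at 128x128 for quick regression-training checks."""
    root = tmp_path_factory.mktemp("ds_reg_small")
    return make_dataset(root, 40, 128, seed=13)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
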