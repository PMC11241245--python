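import numpy as np
import pytest

from histonet.synthetic import FixtureSpec, generate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_tree(tmp_path_factory):
    """A tiny 3-class BreakHis-layout tree (8 images per class, side 32)."""
    root = tmp_path_factory.mktemp("tree")
    spec = FixtureSpec(classes=("A", "F", "DC"), counts=(8, 8, 8), side=32,
                       seed=11)
    generate_dataset(spec, root, force=True)
    return root, spec


@pytest.fixture(scope="session")
def imbalanced_tree(tmp_path_factory):
    """An imbalanced 3-class tree (4/6/10 images, side 32)."""
    root = tmp_path_factory.mktemp("imtree")
    spec = FixtureSpec(classes=("A", "F", "DC"), counts=(4, 6, 10), side=32,
                       seed=13)
    generate_dataset(spec, root, force=True)
    return root, spec


@pytest.fixture(scope="session")
def he_image(rng):
    """One synthetic H&E-like image."""
    spec = FixtureSpec(classes=("DC",), counts=(1,), side=48, seed=3)
    from histonet.synthetic import generate_image

    return generate_image(spec, "DC", np.random.default_rng(3))
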