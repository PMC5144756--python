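import numpy as np
import pytest

from tractatlas.synthdata import BundleSpec, make_bundle
from tractatlas.tract_io import Fiber, Tractogram


@pytest.fixture
def straight_fiber():
    return Fiber(np.array([[0.0, 0.0, 0.0], [5.0, 0.0, 0.0],
                           [10.0, 0.0, 0.0]]))


@pytest.fixture
def small_tractogram():
    rng = np.random.default_rng(0)
    fibers = [Fiber(np.cumsum(rng.normal(scale=2.0, size=(8, 3)), axis=0))
              for _ in range(5)]
    return Tractogram(subject_id="toy", fibers=fibers)


@pytest.fixture
def two_bundles():
    """Two well-separated straight bundles with ground-truth labels."""
    t1, l1 = make_bundle(BundleSpec("straight", 80.0, (0.0, 0.0, 0.0),
                                    n_fibers=30, dispersion=2.0),
                         seed=1, label=0)
    t2, l2 = make_bundle(BundleSpec("straight", 80.0, (60.0, 0.0, 0.0),
                                    n_fibers=30, dispersion=2.0),
                         seed=2, label=1)
    fibers = t1.fibers + t2.fibers
    labels = np.concatenate([l1, l2])
    return Tractogram(subject_id="pair", fibers=fibers, frame="atlas"), labels
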