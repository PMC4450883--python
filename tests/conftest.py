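import dataclasses

import numpy as np
import pytest

import mahinge as mh


@pytest.fixture(scope="session")
def pattern():
    return mh.SamplingPattern()


@pytest.fixture(scope="session")
def small_train_frames():
    """Six moderately noisy annotated phantoms for quick training."""
    return mh.generate_dataset(6, mh.PhantomParams(), seed=41)


@pytest.fixture(scope="session")
def small_detector(small_train_frames):
    """A quickly trained detector shared across scan/refine/pipeline tests."""
    spec = mh.TrainingSpec(negatives_per_frame=80, seed=7)
    return mh.HingePointDetector(training=spec).fit(small_train_frames)


@pytest.fixture(scope="session")
def test_frames():
    return mh.generate_dataset(4, mh.PhantomParams(), seed=91)


def random_iksvm_model(rng, m: int, n: int, with_duplicates: bool = False):
    """Random SVM expansion for oracle tests (nonnegative support vectors)."""
    X = rng.uniform(0, 255, size=(m, n))
    if with_duplicates and m > 1:
        X[m // 2] = X[0]  # exercise tied support values
    coef = rng.normal(scale=1.0, size=m)
    bias = float(rng.normal())
    return mh.IKSVMModel(
        support_vectors=X, coefficients=coef, bias=bias, C=1.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def noiseless_params():
    return dataclasses.replace(mh.PhantomParams(), speckle_shape=np.inf)
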