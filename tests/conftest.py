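import numpy as np
import pandas as pd
import pytest

from editsig import default_panel, spec_from_table1


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def table1_spec():
    return spec_from_table1(seed=0)


@pytest.fixture(scope="session")
def small_spec():
    """Reduced cohort (20/class, 500 reads) for fast generator tests."""
    from dataclasses import replace

    spec = spec_from_table1(seed=0)
    return replace(
        spec, class_sizes={d: 20 for d in spec.class_sizes}, reads_per_sample=500
    )


def planted_two_class(
    n_per_class=200, n_informative=5, n_noise=20, shift=1.5, seed=0
):
    """Gaussian two-class design with the first features mean-shifted."""
    rng = np.random.default_rng(seed)
    p = n_informative + n_noise
    X = pd.DataFrame(
        rng.normal(size=(2 * n_per_class, p)),
        columns=[f"f{i}" for i in range(p)],
    )
    y = pd.Series(np.repeat(["A", "B"], n_per_class), index=X.index)
    X.iloc[:n_per_class, :n_informative] += shift
    return X, y


def planted_four_class(n_per_class=60, n_noise=10, shift=2.5, seed=0):
    """Strong-signal 4-class design: one shifted feature per class."""
    rng = np.random.default_rng(seed)
    classes = ["CTRL", "BD", "SZ", "SA"]
    p = len(classes) + n_noise
    X = pd.DataFrame(
        rng.normal(size=(len(classes) * n_per_class, p)),
        columns=[f"f{i}" for i in range(p)],
    )
    y = pd.Series(np.repeat(classes, n_per_class), index=X.index)
    for i, cls in enumerate(classes):
        X.loc[y == cls, f"f{i}"] += shift
    return X, y
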