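import numpy as np
import pytest

from epom.io import GenomicWindow, GroupDesign
from epom.prep import SignalMatrix


def make_matrix(values, groups_of_samples, windows=None, mark="H3K4me1",
                region_class="enhancer"):
    """SignalMatrix from a raw array and a list of group labels per column."""
    values = np.asarray(values, dtype=float)
    samples = [f"s{i:03d}" for i in range(values.shape[1])]
    design = GroupDesign(dict(zip(samples, groups_of_samples)))
    if windows is None:
        windows = [GenomicWindow("chr1", 200 * k, 200 * (k + 1))
                   for k in range(values.shape[0])]
    return SignalMatrix(mark=mark, region_class=region_class,
                        windows=windows, samples=samples, values=values,
                        design=design)


@pytest.fixture
def rng():
    return np.random.default_rng(20160111)


@pytest.fixture
def small_dataset():
    """A small planted dataset shared across downstream tests."""
    from epom.synthetic import SimulationConfig, simulate_dataset

    cfg = SimulationConfig(
        n_groups=4, samples_per_group=4, n_windows=600,
        planted_fraction_per_group=0.05, effect_size=10.0, noise_sd=1.0,
        marks=("H3K4me1",), seed=11,
    )
    return simulate_dataset(cfg)
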