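import numpy as np
import pytest

import zeitzeiger as zz


@pytest.fixture(scope="session")
def benchmark():
    """Canonical synthetic multi-group oscillatory dataset (72 x 500)."""
    return zz.default_benchmark(seed=0)


@pytest.fixture(scope="session")
def benchmark_model(benchmark):
    model = zz.ZeitZeiger(sumabsv=3.0, n_spc=2, m=12, n_knots=3)
    model.fit(
        benchmark.data.values,
        benchmark.data.times,
        feature_ids=benchmark.data.feature_ids,
    )
    return model


@pytest.fixture(scope="session")
def two_sinusoid_data():
    """48 observations: two clean sinusoids (phases 0 and 0.25) among 48
    noise features — the smallest instance where a one-feature-per-component
    predictor should isolate exactly the two oscillating features."""
    ds = zz.simulate(
        zz.SimulationConfig(
            n_signal_features=2,
            n_noise_features=48,
            n_timepoints_per_cycle=12,
            n_replicates=4,
            n_groups=1,
            amplitudes=2.0,
            phases=np.array([0.0, 0.25]),
            noise_sd=0.2,
            seed=11,
        )
    )
    return ds
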