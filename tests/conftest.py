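import numpy as np
import pytest

from nitratrace import MCMCConfig, SampleRecord, SourceProfile


@pytest.fixture
def tiny_samples():
    return [
        SampleRecord("S1", "surface", d15N_NO3=4.5, d18O_NO3=3.2, region="ZXHs",
                     no3=2.1, tn=2.3, nh4=0.15, cond=310.0, d18O_H2O=-6.2),
        SampleRecord("S2", "surface", d15N_NO3=5.1, d18O_NO3=2.8, region="ZXHs",
                     no3=1.8, tn=2.0),
        SampleRecord("G1", "ground", d15N_NO3=14.0, d18O_NO3=8.0, region="DDKd",
                     no3=7.5, tn=7.7, cond=650.0),
    ]


@pytest.fixture
def two_sources():
    return [
        SourceProfile("low", mean={"d15N_NO3": 0.0, "d18O_NO3": 0.0},
                      sd={"d15N_NO3": 1.0, "d18O_NO3": 1.0}),
        SourceProfile("high", mean={"d15N_NO3": 20.0, "d18O_NO3": 20.0},
                      sd={"d15N_NO3": 1.0, "d18O_NO3": 1.0}),
    ]


@pytest.fixture
def fast_mcmc():
    return MCMCConfig(n_chains=2, n_iter=4000, n_burn=2000, thin=2, rng_seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
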