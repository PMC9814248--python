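import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from napxps import peakmodel, synth  # noqa: E402


@pytest.fixture(scope="session")
def region_models():
    return peakmodel.default_region_models()


@pytest.fixture(scope="session")
def noiseless_series():
    """Noise-free N2-condition series shared across fitting tests."""
    sc = synth.preset_scenarios(snr=None)["N2"]
    return synth.generate_series(sc, seed=11)


@pytest.fixture(scope="session")
def c1s_only_scenario():
    """A C1s-only scenario for fast replicate studies (SNR 100)."""
    base = synth.preset_scenarios(snr=100.0)["N2"]
    return synth.DamageScenario(
        condition="N2",
        models={"C1s": peakmodel.default_region_models()["C1s"]},
        initial_areas={k: v for k, v in base.initial_areas.items()
                       if k.startswith("C1s")},
        rates={k: v for k, v in base.rates.items() if k.startswith("C1s")},
        timepoints=(0.0, 7200.0),
        snr=100.0,
        windows={"C1s": base.windows["C1s"]},
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
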