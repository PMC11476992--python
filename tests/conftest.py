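import pandas as pd
import pytest

from vitreoquant import synthdata, quantio


@pytest.fixture(scope="session")
def small_config():
    """Compact but fully featured study simulation."""
    return synthdata.SynthConfig(
        n_proteins=60, peptides_per_protein=(2, 6), days=(7, 14, 21),
        de_fraction=0.2, decoy_fraction=0.1, seed=42)


@pytest.fixture(scope="session")
def small_swath(small_config):
    return synthdata.generate_swath(small_config)


@pytest.fixture(scope="session")
def noise_free_config():
    """All stochastic terms off: areas are an exact closed form."""
    return synthdata.SynthConfig(
        n_proteins=20, peptides_per_protein=(2, 4), days=(7, 14),
        tech_replicates=2, replicate_cv=0.0, eye_jitter_sd_log2=0.0,
        bias_log2_range=(0.0, 0.0), de_fraction=0.0, decoy_fraction=0.0,
        dropout_midpoint_log2=None, low_confidence_fraction=0.0, seed=3)


@pytest.fixture(scope="session")
def noise_free_swath(noise_free_config):
    return synthdata.generate_swath(noise_free_config)


@pytest.fixture()
def tiny_matrix():
    """3 proteins x 6 injections (2 days x OD/OS + replicates), complete."""
    samples = pd.DataFrame({
        "sample_id": ["d7_od", "d7_os", "d14_od_1", "d14_od_2",
                      "d14_os_1", "d14_os_2"],
        "eye": ["OD", "OS", "OD", "OD", "OS", "OS"],
        "day": [7, 7, 14, 14, 14, 14],
        "replicate": [1, 1, 1, 2, 1, 2],
        "cohort": ["SWATH"] * 6,
    }).set_index("sample_id")
    data = pd.DataFrame(
        [[10.0, 10.0, 20.0, 20.0, 20.0, 20.0],
         [100.0, 100.0, 100.0, 100.0, 100.0, 100.0],
         [8.0, 8.0, 2.0, 2.0, 2.0, 2.0]],
        index=["A", "B", "C"], columns=samples.index)
    counts = pd.Series([3, 2, 2], index=data.index)
    return quantio.QuantMatrix(data, samples, counts)
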