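import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pvcircuit import morphometry as mm
from pvcircuit import synthetic as syn

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def quiet_cell():
    """Noise-free cell spec for exact-oracle tests."""
    return syn.CellSpec(phenotype="TF", noise_sd=0.0)


@pytest.fixture(scope="session")
def step_protocol():
    return syn.StepProtocol()


@pytest.fixture(scope="session")
def photostim_protocol():
    return syn.PhotostimProtocol(n_trials=10)


@pytest.fixture(scope="session")
def morph_cohort():
    """34 excitatory-class + 30 inhibitory-class synthetic morphologies with
    their feature matrix and true labels (matches the study's cohort sizes)."""
    morphs, labels = {}, {}
    for k in range(34):
        cid = f"e{k:02d}"
        morphs[cid] = syn.generate_morphology(syn.epvin_morphology_spec(), seed=200 + k)
        labels[cid] = "excitatory"
    for k in range(30):
        cid = f"i{k:02d}"
        morphs[cid] = syn.generate_morphology(syn.ipvin_morphology_spec(), seed=500 + k)
        labels[cid] = "inhibitory"
    return mm.feature_table(morphs), pd.Series(labels)
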