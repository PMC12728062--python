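import numpy as np
import pytest

from aanrehab.synth import TrialSpec, VirtualPatient


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def clean_patient():
    """Noise-free, tremor-free patient for exact-construction checks."""
    return VirtualPatient(capability=1.0, rom_base=60.0, tremor_amp=0.0,
                          cocontraction=0.0, noise_sd=0.0)


@pytest.fixture
def one_reach():
    """A single 3 s reach trial starting at t=0."""
    return [TrialSpec(trial_id=0, distance_D=30.0, width_W=5.0,
                      duration_T=3.0, t_start=0.0, t_end=3.0)]


@pytest.fixture(scope="session")
def reference_study():
    """The standard synthetic study: trained bundle + training tables.

    Session-scoped because training the stacked model on the 20-subject
    cohort is the expensive step shared by the pipeline-level tests.
    """
    from aanrehab.pipeline import train_reference_bundle

    bundle, features, labels, cohort = train_reference_bundle(seed=0)
    return {"bundle": bundle, "features": features, "labels": labels,
            "cohort": cohort}
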