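import numpy as np
import pytest

from bmpkit.datasets import reference_levels
from bmpkit.simulate import (
    DesignSpec,
    KineticTruth,
    apply_inhibition,
    default_vial,
    encode_headspace,
    simulate_design,
    true_curve,
)


@pytest.fixture(scope="session")
def vial():
    return default_vial("v1")


@pytest.fixture(scope="session")
def quiet_truth():
    """Ground truth with measurement noise switched off."""
    return KineticTruth(noise_pressure=0.0, noise_fraction=0.0)


@pytest.fixture(scope="session")
def independent_levels():
    return tuple(reference_levels("independent"))


@pytest.fixture(scope="session")
def successive_levels():
    return tuple(reference_levels("successive"))


@pytest.fixture(scope="session")
def clean_encoding(vial, quiet_truth):
    """One noise-free encoded control vial plus its true curve."""
    design = DesignSpec("independent", (1.7,), sampling_interval=0.5)
    v_eff, r_eff, lag_eff = apply_inhibition(quiet_truth, 1.7, "independent")
    times, cum = true_curve(design, v_eff, r_eff, lag_eff)
    observations = encode_headspace(times, cum, vial, seed=0)
    return {
        "times": times,
        "true_cumulative": cum,
        "observations": observations,
        "effective": (v_eff, r_eff, lag_eff),
    }


@pytest.fixture(scope="session")
def noisy_independent_bundle(independent_levels):
    return simulate_design(
        DesignSpec("independent", independent_levels, vials_per_level=3),
        KineticTruth(seed=7),
        seed=7,
    )
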