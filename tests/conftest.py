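import hypothesis
import numpy as np
import pytest

from snplie import LigandPose

hypothesis.settings.register_profile(
    "snplie", derandomize=True, deadline=None, max_examples=50
)
hypothesis.settings.load_profile("snplie")


@pytest.fixture
def reference_pose():
    """A rigid 30-heavy-atom ligand pose with reproducible coordinates."""
    rng = np.random.default_rng(20240)
    return LigandPose(
        ligand="testlig",
        atom_names=tuple(f"C{i}" for i in range(30)),
        coords=rng.normal(scale=3.0, size=(30, 3)),
    )


@pytest.fixture
def table5_matrix():
    from snplie import datasets

    return datasets.load_variant_affinity_matrix()
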