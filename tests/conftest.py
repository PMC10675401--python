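import numpy as np
import pytest

from locfuse import SyntheticConfig, simulate_dataset


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240131)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A 2-per-class paired benchmark shared by io/feature tests."""
    cfg = SyntheticConfig(n_per_class=2, seed=11, separation=1.0)
    records, pssms, images, labels = simulate_dataset(cfg)
    return {"records": records, "pssms": pssms, "images": images, "labels": labels}


@pytest.fixture(scope="session")
def one_patch(tiny_dataset):
    """One unmixed 512x512 protein-channel patch from the tiny benchmark."""
    from locfuse import extract_patches, unmix_stains

    image = next(iter(tiny_dataset["images"].values()))
    patches, _ = extract_patches(unmix_stains(image))
    return patches[0].pixels
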