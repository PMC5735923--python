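"""Shared fixtures: phantoms rendered once per session."""

import numpy as np
import pytest

import blastoquant as bq
from blastoquant.synthetic_phantom import Inclusion, random_spec


@pytest.fixture(scope="session")
def inclusion_phantom():
    """One 1,280x1,024 phantom with known inclusions, plus pipeline products."""
    inclusions = (
        Inclusion(270, 200, 6.0, "dark", 100.0),
        Inclusion(380, 300, 6.0, "dark", 100.0),
        Inclusion(300, 300, 12.0, "light", 240.0),
        Inclusion(360, 180, 6.0, "light", 240.0),
    )
    spec = bq.PhantomSpec(seed=7, inclusions=inclusions)
    image, truth = bq.generate_phantom(spec)
    std = bq.standardize_image(image)
    masks = bq.segment_image(std)
    return {"spec": spec, "image": image, "truth": truth, "std": std, "masks": masks}


@pytest.fixture(scope="session")
def featureless_phantom():
    """A phantom with no inclusions (ICM and texture present)."""
    spec = bq.PhantomSpec(seed=3)
    image, truth = bq.generate_phantom(spec)
    std = bq.standardize_image(image)
    masks = bq.segment_image(std)
    return {"spec": spec, "image": image, "truth": truth, "std": std, "masks": masks}


@pytest.fixture(scope="session")
def recovery_suite():
    """20 random phantoms with ground truth, standardized and segmented."""
    out = []
    for seed in range(20):
        spec = random_spec(seed)
        image, truth = bq.generate_phantom(spec)
        std = bq.standardize_image(image)
        masks = bq.segment_image(std)
        out.append({"spec": spec, "truth": truth, "std": std, "masks": masks})
    return out


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
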