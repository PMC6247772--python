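import numpy as np
import pytest

import wingmorph as wm


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180611)


@pytest.fixture(scope="session")
def wing_template():
    """Common landmark + contour template pair."""
    return wm.make_wing_template(seed=0)


@pytest.fixture(scope="session")
def small_collection():
    """Three well-separated species, 15 specimens each, with replicates."""
    base_lm, base_ct = wm.make_wing_template(seed=0)
    specs = []
    for i, lab in enumerate(["alpha", "beta", "gamma"]):
        lm = wm.perturb_template(base_lm, 0.15, mode_seed=100 + i)
        ct = base_ct + 0.15 * wm.synthetic.deformation_field(100 + i)(base_ct)
        specs.append(
            wm.SpeciesSpec(
                label=lab, n=15, mean_landmarks=lm, mean_contour=ct,
                size_mean=3.0 - 0.4 * i, size_sd=0.1, shape_sd=0.01,
                contour_noise_sd=0.004,
            )
        )
    return wm.generate_collection(
        specs, seed=5, with_replicates=True, digitization_sd=2.0
    )


@pytest.fixture(scope="session")
def default_collection():
    """The standard 7-species preset (273 specimens)."""
    return wm.generate_collection(wm.default_species_specs(0), seed=1)


def random_similarity(rng, reflect: bool = False) -> tuple:
    """A random rotation matrix, scale and translation."""
    th = rng.uniform(0, 2 * np.pi)
    c, s = np.cos(th), np.sin(th)
    rot = np.array([[c, -s], [s, c]])
    if reflect:
        rot = rot @ np.diag([1.0, -1.0])
    return rot, rng.uniform(0.3, 3.0), rng.uniform(-10, 10, 2)
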