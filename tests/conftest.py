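import warnings

import numpy as np
import pytest

from scaffold_regen.designs import DESIGNS, Material


@pytest.fixture(scope="session")
def test_material():
    return Material("test solid", elastic_modulus=2000.0, poisson_ratio=0.3)


@pytest.fixture(scope="session")
def cohort():
    """One full synthetic-cohort run (phantoms -> quantification -> scoring
    -> statistics) shared across the suite."""
    from scaffold_regen.pipeline import cohort_run

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return cohort_run(seed=7)


@pytest.fixture(scope="session")
def pb_phantom():
    """Strong-responder compliant-leg polyamide phantom."""
    from scaffold_regen.phantom import build_phantom

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_phantom(DESIGNS["PB"], 20.8, 6.8, seed=11)


@pytest.fixture(scope="session")
def tb_phantom():
    """Weak-responder compliant-leg titanium phantom (halo present)."""
    from scaffold_regen.phantom import build_phantom

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_phantom(DESIGNS["TB"], 10.6, 6.8, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
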