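"""Shared fixtures: phantoms and their full-pipeline analyses.

The phantom generation and the pipeline runs are the expensive pieces, so
they are session-scoped and shared across test modules.
"""

import numpy as np
import pytest

from vertperf import PhantomSpec, generate_phantom
from vertperf.pipeline import analyze


@pytest.fixture(scope="session")
def protocol():
    from vertperf import SPGRProtocol

    return SPGRProtocol()


@pytest.fixture(scope="session")
def noiseless_bundle():
    return generate_phantom(PhantomSpec(seed=1).noiseless())


@pytest.fixture(scope="session")
def noiseless_analysis(noiseless_bundle):
    b = noiseless_bundle
    return analyze(b.vfa, b.dynamic, b.masks, b.spec.protocol,
                   methods=("rbm",))


@pytest.fixture(scope="session")
def noisy_bundle():
    return generate_phantom(PhantomSpec(seed=0))


@pytest.fixture(scope="session")
def noisy_analysis(noisy_bundle):
    b = noisy_bundle
    return analyze(b.vfa, b.dynamic, b.masks, b.spec.protocol,
                   methods=("pwm", "rbm"),
                   aif_kinds=("aortic", "segmental"))


@pytest.fixture(scope="session")
def template_aif(noiseless_analysis):
    """Fitted aortic AIF of the noiseless phantom: the simulation template."""
    return noiseless_analysis.aifs["aortic"]


@pytest.fixture(scope="session")
def times(noiseless_bundle):
    return noiseless_bundle.dynamic.times
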