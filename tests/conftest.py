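import numpy as np
import pytest

from breastcomp import (
    ImageVolume,
    PhantomSpec,
    StructureMask,
    generate_breast_phantom,
    generate_dose,
)


@pytest.fixture(scope="session")
def fatty_patient():
    """One fatty-archetype phantom with a boost in fibroglandular tissue."""
    patient = generate_breast_phantom(PhantomSpec(archetype="fatty"), seed=11)
    generate_dose(patient, base_gy=40.05, n_fractions=15, gradient_gy=2.0,
                  boost_gy=8.0, boost_tissue="fibroglandular")
    return patient


@pytest.fixture(scope="session")
def dense_patient():
    patient = generate_breast_phantom(
        PhantomSpec(archetype="extremely_dense"), seed=12
    )
    generate_dose(patient, base_gy=40.05, n_fractions=15)
    return patient


@pytest.fixture
def slab_geometry():
    """Flat-surfaced body slab on a 1 mm isotropic grid with a breast box."""
    shape = (20, 30, 20)
    ct = ImageVolume(np.zeros(shape), spacing=(1.0, 1.0, 1.0))
    body = np.zeros(shape, dtype=bool)
    body[:, 8:, :] = True  # air above row 8, body below
    breast = np.zeros(shape, dtype=bool)
    breast[5:15, 8:25, 5:15] = True
    return (
        ct,
        StructureMask.from_reference("body", body, ct),
        StructureMask.from_reference("breast", breast, ct),
    )
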