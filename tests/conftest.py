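import numpy as np
import pytest

from dermoct import AScan, PhantomSpec, noiseless_template


@pytest.fixture
def default_spec() -> PhantomSpec:
    return PhantomSpec()


@pytest.fixture
def small_spec() -> PhantomSpec:
    """Short-profile spec for cheap tests (covers ~690 um of depth)."""
    return PhantomSpec(n_samples=300)


@pytest.fixture
def surface_template(small_spec) -> AScan:
    """Noiseless surface-origin template of the small spec."""
    spec = small_spec.replace(air_gap_um=0.0)
    return AScan(noiseless_template(spec), spec.axial_pitch_um, origin="surface")


def random_spec(rng: np.random.Generator, speckle_cv: float = 0.0,
                n_samples: int = 600) -> PhantomSpec:
    """Random but physically plausible phantom parameters."""
    return PhantomSpec(
        air_gap_um=float(rng.uniform(40, 150)),
        sc_thickness_um=float(rng.uniform(12, 35)),
        epi_thickness_um=float(rng.uniform(30, 70)),
        dermis_mu_per_cm=float(rng.uniform(40, 120)),
        valley_rel=float(rng.uniform(0.4, 0.7)),
        sc_peak_rel=float(rng.uniform(0.75, 1.0)),
        speckle_cv=speckle_cv,
        axial_pitch_um=float(rng.uniform(1.5, 3.0)),
        n_samples=n_samples,
    )
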