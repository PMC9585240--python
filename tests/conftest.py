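import numpy as np
import pytest

from microvns.coil_geometry import CurrentPath


@pytest.fixture(scope="session")
def circular_loop():
    """Unit-current circular loop, radius 0.1 mm, finely discretized."""
    R = 1e-4
    th = np.linspace(0.0, 2 * np.pi, 721)
    pts = np.c_[R * np.cos(th), R * np.sin(th), np.zeros_like(th)]
    return R, CurrentPath(pts, closed=True)


@pytest.fixture(scope="session")
def small_synthetic():
    """A small synthetic nerve (fast to generate and segment)."""
    import warnings

    from microvns.synthetic_tem import (
        SyntheticNerveSpec, render_image, sample_population,
    )

    spec = SyntheticNerveSpec(
        nerve_semi_axes=(80.0, 80.0), target_fiber_count=500, seed=11
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        recs = sample_population(spec)
        img, boundary, origin = render_image(recs, spec)
    return spec, recs, img, boundary, origin
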