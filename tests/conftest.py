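import numpy as np
import pytest

from renoterra import PhantomSpec, generate_phantom


def random_spec(seed: int) -> PhantomSpec:
    """Small random anisotropic phantom spec (<=32^3 grid, <=9 endpoints)."""
    rng = np.random.default_rng(seed)
    dims = tuple(int(x) for x in rng.integers(16, 33, size=3))
    spacing = tuple(float(x) for x in rng.uniform(0.5, 3.0, size=3))
    return PhantomSpec(
        dims=dims,
        spacing=spacing,
        n_arteries=int(rng.integers(1, 4)),
        endpoints_per_artery=(1, 3),
        isthmus_fraction=float(rng.uniform(0.0, 0.08)),
        seed=seed,
    )


@pytest.fixture(scope="session")
def bundle():
    """One mid-sized anisotropic phantom shared across read-only tests."""
    return generate_phantom(
        PhantomSpec(dims=(32, 32, 24), spacing=(0.9, 0.9, 1.3), seed=11)
    )
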