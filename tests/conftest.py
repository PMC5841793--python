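import numpy as np
import pytest

from carapace.schemes import LandmarkScheme, get_scheme
from carapace.synthgen import SimulationParams, build_shape_model, simulate_dataset


@pytest.fixture(scope="session")
def schemes():
    return {v: get_scheme(v) for v in ("dorsal", "lateral", "posterior")}


@pytest.fixture
def toy_scheme():
    """Minimal 3-point scheme for TPS plumbing tests."""
    return LandmarkScheme(
        view="toy", n_points=3, semilandmark_indices=frozenset(),
        symmetric=False, midline_indices=frozenset(), pair_map={},
        sliding_neighbors={}, repeatable_pc_count=2,
    )


@pytest.fixture
def symmetric_toy_scheme():
    """Six points: two on the midline, two bilateral pairs."""
    return LandmarkScheme(
        view="symtoy", n_points=6, semilandmark_indices=frozenset(),
        symmetric=True, midline_indices=frozenset({0, 1}),
        pair_map={2: 3, 3: 2, 4: 5, 5: 4},
        sliding_neighbors={}, repeatable_pc_count=2,
    )


@pytest.fixture(scope="session")
def small_study():
    """One modest synthetic modern dataset shared across tests."""
    params = SimulationParams(n_modern=60, seed=42)
    model = build_shape_model(params)
    configs, meta = simulate_dataset(params, model)
    return params, model, configs, meta


def random_configs(rng: np.random.Generator, n: int, k: int,
                   scale: float = 1.0) -> np.ndarray:
    """Random well-conditioned k-point configurations."""
    return rng.standard_normal((n, k, 2)) * scale
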