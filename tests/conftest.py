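import numpy as np
import pytest

from avidex.fd_model_io import FDGrid, ForceDistanceCurve
from avidex.fd_sim import builtin_presets, canonical_s0, canonical_s1, canonical_s2


@pytest.fixture
def s0():
    return canonical_s0()


@pytest.fixture
def s1():
    return canonical_s1()


@pytest.fixture
def s2():
    return canonical_s2()


@pytest.fixture(scope="session")
def presets():
    return builtin_presets()


def flat_curve(n=100, spacing=0.5, force=0.0, grid_index=(0, 0)):
    z = np.arange(n) * spacing
    return ForceDistanceCurve(
        separation=z,
        force=np.full(n, float(force)),
        segment=np.full(n, "retract", dtype=object),
        grid_index=grid_index,
    )


@pytest.fixture
def small_grid():
    """A 3-curve grid with distinct constant force levels."""
    curves = [
        flat_curve(force=0.0, grid_index=(0, 0)),
        flat_curve(force=1.25, grid_index=(0, 1)),
        flat_curve(force=-2.5, grid_index=(1, 0)),
    ]
    return FDGrid(curves=curves, n_rows=2, n_cols=2, surface_label="demo")
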