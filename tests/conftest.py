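import numpy as np
import pytest

from arctraj import (PhantomConfig, Sphere, Structure, StructureSet, Grid,
                     build_phantom, make_case_suite, merge_oars)


def make_grid(extent_mm: float, spacing_mm: float, center=(0.0, 0.0, 0.0)) -> Grid:
    """Cubic grid spanning [-extent, +extent] mm around ``center``."""
    n = int(round(2 * extent_mm / spacing_mm)) + 1
    origin = tuple(c - extent_mm for c in center)
    return Grid(shape=(n, n, n), spacing=(spacing_mm,) * 3, origin=origin)


def sphere_structure(grid: Grid, center, diameter, name="s", role="oar") -> Structure:
    return Structure(name=name, role=role, grid=grid,
                     primitive=Sphere(center=tuple(center), diameter=diameter))


@pytest.fixture(scope="session")
def phantom():
    return build_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def suite(phantom):
    return make_case_suite(phantom, seed=7)


@pytest.fixture(scope="session")
def avoidance(phantom):
    return merge_oars(phantom, phantom.names("oar"))
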