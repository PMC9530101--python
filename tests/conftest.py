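"""Shared fixtures: small grids, compact phantoms, a tiny simulated cohort."""

import numpy as np
import pytest

from meniscusmotion.grids import Grid, LabelMask
from meniscusmotion.phantom import (
    CohortSpec,
    MeniscusGeometry,
    PhantomSpec,
    make_phantom,
    simulate_cohort,
)


def identity_grid(shape, spacing=(1.0, 1.0, 1.0), centered=True) -> Grid:
    if centered:
        return Grid.centered(shape, spacing)
    return Grid(shape=tuple(shape), spacing=tuple(spacing), origin=(0.0, 0.0, 0.0),
                direction=tuple(np.eye(3).ravel()))


def crescent_mask(grid: Grid, center=(0.0, 0.0), inner=6.0, outer=11.0,
                  span_deg=200.0, opening_deg=0.0, z_lo=-2.0, z_hi=2.0) -> np.ndarray:
    """Annulus-sector predicate evaluated on a grid (test-local oracle shape)."""
    X = grid.world_grid()
    dx, dy = X[0] - center[0], X[1] - center[1]
    r = np.hypot(dx, dy)
    theta = np.degrees(np.arctan2(dy, dx))
    gap = (theta - opening_deg + 180.0) % 360.0 - 180.0
    in_arc = np.abs(gap) >= (360.0 - span_deg) / 2.0
    return (r >= inner) & (r <= outer) & in_arc & (X[2] >= z_lo) & (X[2] <= z_hi)


@pytest.fixture(scope="session")
def compact_spec() -> PhantomSpec:
    """The compact cohort-scale phantom at clinical resolution."""
    return CohortSpec(n_subjects=2).phantom


@pytest.fixture(scope="session")
def compact_phantom(compact_spec):
    return make_phantom(compact_spec, seed=11)


@pytest.fixture(scope="session")
def tiny_cohort_spec() -> CohortSpec:
    """A miniature cohort for pipeline tests (small grid, fast registrations)."""
    phantom = PhantomSpec(
        shape=(56, 56, 28),
        spacing=(0.8, 0.8, 0.7),
        tibia_radius=11.0,
        tibia_height=5.0,
        tibia_cut_y=7.0,
        tibia_top_z=-1.5,
        mm=MeniscusGeometry(center=(-7.0, 0.0), inner_radius=4.0, outer_radius=8.0,
                            span_deg=200.0, opening_deg=0.0, thickness=3.0),
        lm=MeniscusGeometry(center=(7.0, 0.0), inner_radius=3.5, outer_radius=7.0,
                            span_deg=160.0, opening_deg=180.0, thickness=3.0),
    )
    return CohortSpec(n_subjects=2, seed=5, phantom=phantom)


@pytest.fixture(scope="session")
def tiny_cohort_dir(tiny_cohort_spec, tmp_path_factory):
    root = tmp_path_factory.mktemp("tiny_cohort")
    truth = simulate_cohort(tiny_cohort_spec, root)
    return root, truth


def joint_mask(mm: LabelMask, lm: LabelMask) -> LabelMask:
    return LabelMask(mm.data | lm.data, mm.grid, "meniscus_joint")
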