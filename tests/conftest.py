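import numpy as np
import pytest

from fibremap.compare import OrientationDifferenceMap
from fibremap.containers import FibreOrientationMap
from fibremap.phantom import (
    FibreGroundTruth,
    FibrePopulation,
    PhantomSpec,
    SusceptibilityParams,
    generate_phantom,
)


def single_pixel_gt(delta_deg, alpha_deg=0.0, susceptibility=None, amplitude=1.0):
    """1×1 ground truth with one fibre population."""
    pop = FibrePopulation(delta_deg, alpha_deg, amplitude)
    return FibreGroundTruth([[(pop,)]], susceptibility or SusceptibilityParams())


def multi_pop_gt(deltas, alphas=None, susceptibility=None):
    """1×1 ground truth with several equal-amplitude populations."""
    alphas = alphas or [0.0] * len(deltas)
    pops = tuple(FibrePopulation(d, a) for d, a in zip(deltas, alphas))
    return FibreGroundTruth([[pops]], susceptibility or SusceptibilityParams())


def fold_phantom(width=24, height=24, delta_a=0.0, delta_b=90.0, seed=0):
    """Two overlapping bands: unidirectional margins, two-layer overlap."""
    spec = PhantomSpec(width, height)
    spec.add_band((2, height - 2, 2, width // 2 + 4), delta_a)
    spec.add_band((2, height - 2, width // 2 - 4, width - 2), delta_b)
    return generate_phantom(spec, seed=seed)


def fom_from_lists(grid):
    """Build a FibreOrientationMap from nested lists of orientation lists."""
    h, w = len(grid), len(grid[0])
    ori = np.full((h, w, FibreOrientationMap.MAX_ORIENTATIONS), np.nan)
    for r in range(h):
        for c in range(w):
            vals = grid[r][c]
            ori[r, c, : len(vals)] = sorted(vals)
    return FibreOrientationMap(ori)


def diff_map_from_values(values):
    """Wrap a flat array of Δφ values as a one-row difference map."""
    values = np.asarray(values, dtype=float)
    diffs = np.full((1, values.size, 3), np.nan)
    diffs[0, :, 0] = values
    return OrientationDifferenceMap(diffs, np.zeros((1, values.size), dtype=int))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
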