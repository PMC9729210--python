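import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from powerseg import PhantomSpec, make_phantom, realize, three_object_spec


def brute_force_location(values, p, step=1e-4):
    """Independent argmin of the robust location objective.

    Dense grid search over [min(values), max(values)] refined by bounded
    golden-section/Brent search around the best grid point.  Deliberately
    avoids the reweighting fixed point it is used to check.
    """
    values = np.asarray(values, dtype=float)
    lo, hi = values.min(), values.max()
    if hi == lo:
        return float(lo)
    grid = np.arange(lo, hi + step, step)
    obj = (np.abs(values[:, None] - grid[None, :]) ** (2 * p)).sum(axis=0)
    best = grid[np.argmin(obj)]
    a, b = max(lo, best - 2 * step), min(hi, best + 2 * step)
    res = minimize_scalar(
        lambda a_: float(np.sum(np.abs(values - a_) ** (2 * p))),
        bounds=(a, b), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x) if res.fun <= obj.min() else float(best)


@pytest.fixture(scope="session")
def noiseless_disk():
    """Two-value phantom: one 0.8 disk (r=20) on a 0.2 background."""
    spec = PhantomSpec(shape=(128, 128),
                       objects=(("disk", (64, 64, 20), 0.8),),
                       background=0.2)
    return make_phantom(spec)


@pytest.fixture(scope="session")
def speckled_scene():
    """The standard three-object phantom under variance-0.2 speckle."""
    return realize(three_object_spec(seed=0))
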