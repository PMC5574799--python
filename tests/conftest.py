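from fractions import Fraction

import numpy as np
import pytest

import rrbm

#: Caption parameter sets for the four reference dynamics: asexual-only
#: equilibrium, 3-year mixed cycle, constant annual sexual reproduction,
#: and the unstable (variable) regime.
SCENARIO_PARAMS = {
    name: rrbm.ModelParams(**rrbm.SCENARIOS[name].values)
    for name in ("fig1a", "fig1b", "fig1c", "fig1d")
}


@pytest.fixture(params=sorted(SCENARIO_PARAMS))
def scenario_params(request):
    return SCENARIO_PARAMS[request.param]


def draw_params(rng: np.random.Generator) -> rrbm.ModelParams:
    """One uniform draw from the valid parameter ranges used by the
    property suites: thresholds and surplus on the scale of the bundled
    scenarios, coefficients well inside (0, 1)."""
    L1 = rng.uniform(1.0, 5.0)
    return rrbm.ModelParams(
        L1=L1,
        L2=L1 + rng.uniform(0.5, 5.0),
        Ps=rng.uniform(0.5, 5.0),
        p=rng.uniform(0.05, 0.95),
        q=rng.uniform(0.05, 0.95),
        d=rng.uniform(0.05, 0.95),
        R=rng.uniform(0.2, 8.0),
    )


def exact_orbit(params: rrbm.ModelParams, y0, years: int):
    """Independent oracle: iterate the annual map in exact rational
    arithmetic.  Returns (reserves, branches) with branches in
    {'RA', 'AR', 'SAR'}; immune to floating-point rounding, so cycle
    structure read off it is exact."""
    L1, L2, Ps = (Fraction(params.L1), Fraction(params.L2),
                  Fraction(params.Ps))
    p, q, d, R = (Fraction(params.p), Fraction(params.q),
                  Fraction(params.d), Fraction(params.R))
    y = Fraction(y0)
    ys, branches = [], []
    for _ in range(years):
        ys.append(y)
        pool = y + Ps
        if pool < L1:
            branches.append("RA")
            y = pool
        elif pool <= L2:
            branches.append("AR")
            y = pool - d * (pool - L1)
        else:
            branches.append("SAR")
            y = pool - (p + q + R * p) * (pool - L1)
    return ys, branches
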