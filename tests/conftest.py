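import numpy as np
import pytest

from frontostriatal import CircuitParams, model_1, model_2


@pytest.fixture
def m1():
    return model_1()


@pytest.fixture
def m2():
    return model_2()


@pytest.fixture
def default_params():
    return CircuitParams()


def bisect_equilibrium_y(a, b, x_p, j_d=1.0, tol=1e-12):
    """Independent brute-force oracle: dense sign-scan of the scalar
    fixed-point residual in Y followed by plain bisection.

    Deliberately shares no code with the package's solver.
    """

    def g(y):
        p = y / (1.0 + y)
        x_s = x_p * max(0.0, 1.0 - b * p)
        x_d = j_d - x_s
        return x_d * max(0.0, 1.0 - a * p) - y

    grid = np.linspace(0.0, j_d, 4001)
    vals = [g(v) for v in grid]
    for i in range(len(grid) - 1):
        if vals[i] == 0.0:
            return grid[i]
        if vals[i] * vals[i + 1] < 0:
            lo, hi = grid[i], grid[i + 1]
            for _ in range(200):
                mid = 0.5 * (lo + hi)
                if g(lo) * g(mid) <= 0:
                    hi = mid
                else:
                    lo = mid
                if hi - lo < tol:
                    break
            return 0.5 * (lo + hi)
    raise AssertionError(f"oracle found no root for a={a}, b={b}, x_p={x_p}, j_d={j_d}")
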