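import numpy as np
import pytest

from stemgrowth.richards import RichardsParams


@pytest.fixture
def logistic_params() -> RichardsParams:
    """The reference curve used throughout: a=300, b=100, c=0.08, d=1."""
    return RichardsParams(300.0, 100.0, 0.08, 1.0)


def random_params(n: int, seed: int) -> list[RichardsParams]:
    """Random valid parameter sets spanning realistic growth curves."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        a = float(np.exp(rng.uniform(np.log(50), np.log(400))))
        b = float(np.exp(rng.uniform(np.log(2), np.log(1e4))))
        c = float(np.exp(rng.uniform(np.log(0.02), np.log(0.3))))
        d = float(np.exp(rng.uniform(np.log(0.3), np.log(3.0))))
        out.append(RichardsParams(a, b, c, d))
    return out


# ---------------------------------------------------------------------------
# independent numeric oracles (use only curve evaluation, never the closed
# forms they are meant to check)


def numeric_growth_extrema(params: RichardsParams) -> dict:
    """Locate max growth rate and curvature extrema numerically.

    Uses only curve evaluation: the first derivative comes from a complex
    step (exact to machine precision), the second from a central difference
    of it; extrema are located by a dense grid followed by bounded scalar
    minimization.  Never touches the closed-form derivatives it checks.
    """
    from scipy.optimize import minimize_scalar

    a, b, c, d = params.a, params.b, params.c, params.d

    def value(x):
        # complex-capable evaluation of the growth curve
        return a * (1.0 + b * np.exp(-c * x)) ** (-1.0 / d)

    scale = 1.0 / c
    x0 = np.log(b) / c
    hc = 1e-20  # complex step
    h2 = 1e-3 * scale  # real step for the second derivative

    def f1(x):
        return np.imag(value(x + 1j * hc)) / hc

    def f3(x):
        # 5-point stencil second difference of the (exact) first derivative
        return (-f1(x + 2 * h2) + 16 * f1(x + h2) - 30 * f1(x)
                + 16 * f1(x - h2) - f1(x - 2 * h2)) / (12 * h2**2)

    def f2(x):
        return (f1(x + h2) - f1(x - h2)) / (2 * h2)

    grid = np.linspace(x0 - 20 * scale, x0 + 20 * scale, 4001)
    g1 = f1(grid)
    g2 = f2(grid)

    def refine_peak(i):
        lo, hi = grid[max(i - 2, 0)], grid[min(i + 2, len(grid) - 1)]
        res = minimize_scalar(lambda x: -f1(x), bounds=(lo, hi), method="bounded",
                              options={"xatol": 1e-10 * scale})
        return float(res.x)

    def root_of_f3_near(i):
        # curvature extrema are roots of the third derivative; root-finding is
        # far better conditioned than locating a flat extremum of f2
        from scipy.optimize import brentq

        lo, hi = grid[max(i - 3, 0)], grid[min(i + 3, len(grid) - 1)]
        if f3(lo) * f3(hi) > 0:  # widen until bracketed
            lo, hi = lo - scale, hi + scale
        return float(brentq(f3, lo, hi, xtol=1e-12 * scale))

    x_peak = refine_peak(int(np.argmax(g1)))
    x_start = root_of_f3_near(int(np.argmax(g2)))
    x_end = root_of_f3_near(int(np.argmin(g2)))
    return {
        "day_max_gr": x_peak,
        "max_gr": float(f1(x_peak)),
        "start_logg": x_start,
        "end_logg": x_end,
    }


def gauss_legendre_auc(params: RichardsParams, window: tuple[float, float],
                       panels: int = 16, order: int = 30) -> float:
    """Piecewise fixed-order Gauss-Legendre integral of the curve."""
    from stemgrowth.richards import richards_value

    nodes, weights = np.polynomial.legendre.leggauss(order)
    edges = np.linspace(window[0], window[1], panels + 1)
    total = 0.0
    for lo, hi in zip(edges[:-1], edges[1:]):
        mid, half = (lo + hi) / 2, (hi - lo) / 2
        total += half * float(np.sum(weights * richards_value(params, mid + half * nodes)))
    return total
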