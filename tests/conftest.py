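"""Shared fixtures and independent oracles.

The dense oracle solves the master equation by Gaussian elimination in
exact rational arithmetic (fractions.Fraction over the float rate
constants, which are exact rationals), so its stationary distribution
and fluxes carry no roundoff at all.  It shares no code with the
package's King--Altman solver.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from cycledissip import Binding, CycleScheme


def _frac_solve(a: list[list[Fraction]], b: list[Fraction]) -> list[Fraction]:
    """Gaussian elimination with partial pivoting over the rationals."""
    n = len(b)
    m = [row[:] + [rhs] for row, rhs in zip(a, b)]
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(m[r][col]))
        if m[piv][col] == 0:
            raise ZeroDivisionError("singular system")
        m[col], m[piv] = m[piv], m[col]
        for r in range(n):
            if r != col and m[r][col] != 0:
                factor = m[r][col] / m[col][col]
                m[r] = [x - factor * y for x, y in zip(m[r], m[col])]
    return [m[i][n] / m[i][i] for i in range(n)]


def dense_steady_state(scheme: CycleScheme):
    """Exact stationary distribution and net flux from the master equation.

    Returns (p, J) as Fractions: p solves A p = 0 with sum(p) = 1, and
    J is the net flux through edge 0, k1 p_1 - k2 p_2.
    """
    n = scheme.n_states
    kf = [Fraction(k) for k in scheme.forward_rates]
    kr = [Fraction(k) for k in scheme.reverse_rates]
    a = [[Fraction(0)] * n for _ in range(n)]
    for i in range(n):
        j = (i + 1) % n
        a[j][i] += kf[i]
        a[i][i] -= kf[i]
        a[i][j] += kr[i]
        a[j][j] -= kr[i]
    a[0] = [Fraction(1)] * n  # replace one balance row with normalisation
    rhs = [Fraction(1)] + [Fraction(0)] * (n - 1)
    p = _frac_solve(a, rhs)
    flux = kf[0] * p[0] - kr[0] * p[1]
    return p, flux


def random_scheme(
    rng: np.random.Generator,
    n_states: int,
    *,
    log10_range: tuple[float, float] = (-2.0, 8.0),
    force_rt: float | tuple[float, float] = (1.0, 40.0),
    with_bindings: bool = False,
) -> CycleScheme:
    """Log-uniform random scheme with the force imposed on the last reverse rate."""
    import math

    kf = 10.0 ** rng.uniform(*log10_range, n_states)
    kr = 10.0 ** rng.uniform(*log10_range, n_states)
    x = force_rt if isinstance(force_rt, (int, float)) else rng.uniform(*force_rt)
    kr[-1] = math.exp(math.fsum(np.log(kf)) - math.fsum(np.log(kr[:-1])) - x)
    bindings = ()
    conc = {}
    if with_bindings:
        conc = {"S": 1e-3, "P": 1e-6}
        bindings = (
            Binding(0, "forward", kf[0] / conc["S"], "S"),
            Binding(n_states - 1, "reverse", kr[-1] / conc["P"], "P"),
        )
    return CycleScheme(tuple(kf), tuple(kr), bindings=bindings, concentrations=conc)


def equilibrium_scheme(rng: np.random.Generator, n_states: int) -> CycleScheme:
    """Random scheme rebalanced so prod(k_fwd) = prod(k_rev)."""
    return random_scheme(rng, n_states, force_rt=0.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)


@pytest.fixture
def toy3() -> CycleScheme:
    """3-state reference scheme: k1=100, k2=1, k3=50, k4=2, k5=10, k6=0.001."""
    return CycleScheme((100.0, 50.0, 10.0), (1.0, 2.0, 0.001))
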