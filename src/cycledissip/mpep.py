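"""Maximum partial entropy production (MPEP) over a forward rate constant.

The partial entropy production of one edge, sigma_ij(k), has a maximum
as the forward rate constant k of that edge is varied with everything
else held fixed: small k throttles the edge flux, large k exhausts the
edge force (the edge approaches local balance), and the product of the
two peaks in between.  The optimizer does not assume unimodality: it
scans a log-spaced grid across the search bounds first, then refines
the best bracket by golden-section search on log10(k).

A two-edge variant alternates single-edge maximizations until both
optimal constants are self-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .scheme import CycleScheme, SchemeError
from .thermo import solve_steady_state

__all__ = ["MPEPResult", "MPEPPairResult", "mpep_optimize_edge", "mpep_optimize_pair"]

#: Default search bounds for an elementary-step rate constant, s^-1.
DEFAULT_BOUNDS = (1e-6, 1e12)

_INVPHI = (math.sqrt(5.0) - 1.0) / 2.0  # 1/phi
_INVPHI2 = (3.0 - math.sqrt(5.0)) / 2.0  # 1/phi^2


@dataclass(frozen=True)
class MPEPResult:
    """Optimum of one edge's partial entropy production.

    ``boundary`` is True when the best value sits at a search bound, in
    which case no interior maximum was found within the bounds.
    """

    edge: int
    k_optimal: float  # s^-1
    sigma_at_optimum_rt: float  # s^-1
    total_dissipation_rt: float  # s^-1
    n_evaluations: int
    converged: bool
    boundary: bool
    search_bounds: tuple[float, float]


@dataclass(frozen=True)
class MPEPPairResult:
    """Self-consistent two-edge optimum from alternating maximization."""

    first: MPEPResult
    second: MPEPResult
    n_outer_iterations: int
    converged: bool


def _objective(scheme: CycleScheme, edge: int, hold_step_equilibrium: bool):
    """sigma_edge/RT and total dissipation/RT as functions of the forward k.

    By default only the forward constant varies (the step equilibrium
    constant changes as a consequence).  With ``hold_step_equilibrium``
    the reverse constant co-varies to keep K_step = k_fwd/k_rev fixed.
    """
    k_ratio = scheme.forward_rates[edge] / scheme.reverse_rates[edge]

    def sigma_of(k: float) -> tuple[float, float]:
        if hold_step_equilibrium:
            trial = scheme.replace_rate(edge, forward=k, reverse=k / k_ratio)
        else:
            trial = scheme.replace_rate(edge, forward=k)
        st = solve_steady_state(trial)
        return float(st.edge_sigma_rt[edge]), st.dissipation_rt

    return sigma_of


def mpep_optimize_edge(
    scheme: CycleScheme,
    edge: int,
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    *,
    n_grid: int = 1000,
    sigma_rtol: float = 1e-8,
    hold_step_equilibrium: bool = False,
) -> MPEPResult:
    """Maximize sigma_edge/RT over the edge's forward rate constant.

    Deterministic: a ``n_grid``-point multiplicative grid across
    ``bounds`` locates the global bracket, then golden-section search on
    the log axis refines it until the objective changes by less than
    ``sigma_rtol`` relative (and the bracket is tighter than 1e-6 in
    log10 k).  A maximum on a search bound is flagged, not hidden.
    """
    if not 0 <= edge < scheme.n_edges:
        raise SchemeError(f"edge {edge} out of range for {scheme.n_states}-state cycle")
    lo, hi = bounds
    if not (0 < lo < hi) or not (math.isfinite(lo) and math.isfinite(hi)):
        raise SchemeError(f"invalid search bounds {bounds}")
    sigma_of = _objective(scheme, edge, hold_step_equilibrium)
    ratio = hi / lo

    def k_at(t: float) -> float:
        # multiplicative parametrisation keeps the search exactly
        # covariant under a common rescaling of rates and bounds
        return lo * ratio**t

    n_eval = 0

    def f(t: float) -> tuple[float, float]:
        nonlocal n_eval
        n_eval += 1
        return sigma_of(k_at(t))

    # coarse global scan
    ts = [i / (n_grid - 1) for i in range(n_grid)]
    vals = [f(t) for t in ts]
    best = max(range(n_grid), key=lambda i: vals[i][0])
    boundary = best in (0, n_grid - 1)

    # golden-section refinement inside the bracketing neighbours
    a = ts[max(best - 1, 0)]
    b = ts[min(best + 1, n_grid - 1)]
    h = b - a
    c, d = a + _INVPHI2 * h, a + _INVPHI * h
    fc, fd = f(c), f(d)
    t_best, v_best = (c, fc) if fc[0] >= fd[0] else (d, fd)
    log_tol = 1e-6 / math.log10(ratio)  # bracket width of 1e-6 in log10 k
    converged = False
    for _ in range(200):
        if fc[0] >= fd[0]:
            b, d, fd = d, c, fc
            h = b - a
            c = a + _INVPHI2 * h
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            h = b - a
            d = a + _INVPHI * h
            fd = f(d)
        cand = (c, fc) if fc[0] >= fd[0] else (d, fd)
        if cand[1][0] > v_best[0]:
            prev = v_best[0]
            t_best, v_best = cand
            if prev > 0 and abs(v_best[0] - prev) <= sigma_rtol * v_best[0] and h <= log_tol:
                converged = True
                break
        if h <= log_tol:
            converged = True
            break
    if boundary and vals[best][0] >= v_best[0]:
        t_best, v_best = ts[best], vals[best]
    sigma_opt, diss_opt = v_best
    return MPEPResult(
        edge=edge,
        k_optimal=k_at(t_best),
        sigma_at_optimum_rt=sigma_opt,
        total_dissipation_rt=diss_opt,
        n_evaluations=n_eval,
        converged=converged,
        boundary=boundary,
        search_bounds=(lo, hi),
    )


def mpep_optimize_pair(
    scheme: CycleScheme,
    edges: tuple[int, int],
    bounds: tuple[float, float] = DEFAULT_BOUNDS,
    *,
    max_outer: int = 100,
    k_rtol: float = 1e-6,
    n_grid: int = 1000,
    hold_step_equilibrium: bool = False,
) -> MPEPPairResult:
    """Self-consistent MPEP in two transitions by alternating maximization.

    Each outer iteration re-maximizes each edge in turn with the other
    edge's current optimum frozen into the scheme; convergence is
    declared when both optimal constants move by less than ``k_rtol``
    relative between outer iterations.  Non-convergence after
    ``max_outer`` iterations is reported via ``converged=False``, never
    raised.
    """
    e1, e2 = edges
    if e1 == e2:
        raise SchemeError("the two MPEP edges must be distinct")
    current = scheme
    res1 = res2 = None
    k_prev = (current.forward_rates[e1], current.forward_rates[e2])
    converged = False
    n_outer = 0
    for n_outer in range(1, max_outer + 1):
        res1 = mpep_optimize_edge(
            current, e1, bounds, n_grid=n_grid, hold_step_equilibrium=hold_step_equilibrium
        )
        current = current.replace_rate(e1, forward=res1.k_optimal)
        res2 = mpep_optimize_edge(
            current, e2, bounds, n_grid=n_grid, hold_step_equilibrium=hold_step_equilibrium
        )
        current = current.replace_rate(e2, forward=res2.k_optimal)
        k_now = (res1.k_optimal, res2.k_optimal)
        if all(abs(a - b) <= k_rtol * abs(b) for a, b in zip(k_prev, k_now)):
            converged = True
            break
        k_prev = k_now
    # re-evaluate edge 1 at the final scheme so both records are consistent
    final1 = mpep_optimize_edge(current, e1, bounds, n_grid=n_grid, hold_step_equilibrium=hold_step_equilibrium)
    return MPEPPairResult(first=final1, second=res2, n_outer_iterations=n_outer, converged=converged)
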