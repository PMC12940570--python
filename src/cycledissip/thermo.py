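"""Steady-state fluxes, force, and entropy production for unicyclic schemes.

The stationary distribution of the master equation dp/dt = A p is
computed by the King--Altman / Hill diagram method: the weight of state
j is the sum over directed spanning trees rooted at j of the product of
their rate constants.  For a single cycle the trees are simply the
cycle with one edge removed and all remaining edges directed toward the
root, so every weight is a sum of positive products -- there is no
cancellation, and the stationary solution is accurate to a few ulps
even when rate constants span many orders of magnitude.  (A dense
linear solve of the master equation gives the same answer and serves as
the brute-force oracle in the test suite.)

With Sigma the sum of all tree weights, the one-way cycle fluxes are

    J+ = prod(k_fwd) / Sigma,    J- = prod(k_rev) / Sigma,

the net flux is J = J+ - J-, the thermodynamic force is
X/RT = ln(prod k_fwd / prod k_rev) = ln(J+/J-), and the total
dissipation per enzyme is J * X/RT (s^-1 in RT units).  The total
decomposes exactly into nonnegative per-edge partial entropy
productions

    sigma_ij / RT = (k_ij p_i - k_ji p_j) ln(k_ij p_i / (k_ji p_j)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .scheme import CycleScheme, SchemeError

__all__ = [
    "SteadyState",
    "solve_steady_state",
    "one_way_fluxes",
    "edge_entropy_production",
    "thermodynamic_force",
    "force_from_mass_action",
    "closed_form_flux",
    "king_altman_denominator",
]

#: Relative scale below which a cycle force X/RT is treated as exact
#: equilibrium (detailed balance), so that J, X, and all sigma are
#: returned as exactly zero rather than as solver noise.
EQUILIBRIUM_RTOL = 1e-12

#: Relative tolerance under which forward and backward one-way edge
#: fluxes are considered equal, returning sigma = 0 (the x ln x limit).
EDGE_BALANCE_RTOL = 1e-14


@dataclass(frozen=True)
class SteadyState:
    """Stationary solution of a unicyclic scheme.

    Attributes
    ----------
    probabilities:
        State occupancies p_i, summing to 1.
    net_flux:
        J = J+ - J-, cycle completions per enzyme per second.
    forward_flux, backward_flux:
        One-way cycle fluxes J+ and J-, s^-1.
    force_rt:
        X/RT = ln(prod k_fwd / prod k_rev), dimensionless.
    dissipation_rt:
        J * X/RT, s^-1 per enzyme.
    edge_sigma_rt:
        Per-edge partial entropy production over RT, s^-1, one per edge;
        nonnegative and summing to ``dissipation_rt``.
    """

    probabilities: np.ndarray
    net_flux: float
    forward_flux: float
    backward_flux: float
    force_rt: float
    dissipation_rt: float
    edge_sigma_rt: np.ndarray

    @property
    def at_equilibrium(self) -> bool:
        return self.force_rt == 0.0


def _tree_weights(kf, kr) -> np.ndarray:
    """Directed-spanning-tree weight of each state (matrix-tree theorem).

    Removing edge e from the cycle leaves a path; directing it toward
    root j uses the forward constants of the edges before j and the
    reverse constants of the edges after j.  Sums of positive products
    only; tolerates exact zeros in the rate arrays.
    """
    n = len(kf)
    if n != len(kr) or n < 2:
        raise SchemeError("need matching forward/reverse rate arrays of length >= 2")
    q = np.empty(n)
    for j in range(n):
        total = 0.0
        for e in range(n):
            w = 1.0
            m = (e + 1) % n
            while m != j:
                w *= kf[m]
                m = (m + 1) % n
            m = j
            while m != e:
                w *= kr[m]
                m = (m + 1) % n
            total += w
        q[j] = total
    return q


def _denominator_raw(kf, kr) -> float:
    return float(math.fsum(_tree_weights(kf, kr)))


def _net_flux_raw(kf, kr) -> float:
    """(prod kf - prod kr) / Sigma on raw rate arrays; tolerates zeros.

    Used by the numeric kinetic-limit oracles, where an exactly zero
    product-rebinding rate avoids cancellation that a merely tiny one
    would cause.
    """
    return (math.prod(kf) - math.prod(kr)) / _denominator_raw(kf, kr)


def king_altman_denominator(scheme: CycleScheme) -> float:
    """The King--Altman denominator Sigma (units s^(N-1)).

    Sum over all directed spanning trees of the rate graph; the one-way
    cycle fluxes are J+- = prod(k_fwd|k_rev) / Sigma.
    """
    return _denominator_raw(scheme.forward_rates, scheme.reverse_rates)


def thermodynamic_force(scheme: CycleScheme, *, per_rt: bool = True) -> float:
    """Cycle force X = RT ln(prod k_fwd / prod k_rev).

    Returns X/RT (dimensionless) by default, or X in J mol^-1 with
    ``per_rt=False``.  Values within ``EQUILIBRIUM_RTOL`` of detailed
    balance (relative to the summed log-rate magnitude) snap to exactly
    zero.
    """
    logs_f = [math.log(k) for k in scheme.forward_rates]
    logs_r = [math.log(k) for k in scheme.reverse_rates]
    x = math.fsum(logs_f) - math.fsum(logs_r)
    scale = math.fsum(abs(v) for v in logs_f + logs_r)
    if abs(x) <= EQUILIBRIUM_RTOL * max(1.0, scale):
        x = 0.0
    return x if per_rt else x * scheme.rt


def force_from_mass_action(gamma: float, k_eq: float, *, temperature: float = 298.15, per_rt: bool = True) -> float:
    """Force from the mass-action ratio: X = RT ln(K_eq / Gamma).

    Sign convention: X >= 0 means net forward (substrate-consuming)
    drive, so Gamma = c_p/c_s below K_eq gives X > 0 and J+ >= J-.
    """
    if gamma <= 0 or k_eq <= 0:
        raise ValueError("mass-action ratio and equilibrium constant must be positive")
    x = math.log(k_eq / gamma)
    if per_rt:
        return x
    from .scheme import R_GAS

    return x * R_GAS * temperature


def _edge_sigma(j: float, kr: float, p_j: float) -> float:
    """sigma/RT of one edge: (a - b) ln(a/b) with a = k_ij p_i, b = k_ji p_j.

    At steady state the difference a - b equals the cycle flux J on
    every edge of a unicycle, so it is taken from the (cancellation-
    free) product form rather than recomputed by subtraction, and the
    log factor becomes log1p(J/b).  Both factors share J's sign, making
    nonnegativity exact.
    """
    b = kr * p_j
    if abs(j) <= EDGE_BALANCE_RTOL * b:
        return 0.0
    return j * math.log1p(j / b)


def solve_steady_state(scheme: CycleScheme) -> SteadyState:
    """Solve for the stationary state and assemble all derived quantities.

    At exact detailed balance (prod k_fwd = prod k_rev, up to the
    equilibrium snap tolerance) the net flux, force, dissipation, and
    every per-edge sigma are returned as exactly zero.
    """
    q = _tree_weights(scheme.forward_rates, scheme.reverse_rates)
    if not np.all(np.isfinite(q)) or np.any(q <= 0.0):
        raise SchemeError("degenerate rate graph: a state has no finite positive tree weight")
    sigma_denom = float(math.fsum(q))
    p = q / sigma_denom
    x_rt = thermodynamic_force(scheme)
    j_plus = math.prod(scheme.forward_rates) / sigma_denom
    j_minus = math.prod(scheme.reverse_rates) / sigma_denom
    if x_rt == 0.0:
        j_mean = 0.5 * (j_plus + j_minus)
        return SteadyState(
            probabilities=p,
            net_flux=0.0,
            forward_flux=j_mean,
            backward_flux=j_mean,
            force_rt=0.0,
            dissipation_rt=0.0,
            edge_sigma_rt=np.zeros(scheme.n_edges),
        )
    j = j_plus - j_minus
    sigma = np.array(
        [
            _edge_sigma(j, scheme.reverse_rates[i], p[(i + 1) % scheme.n_states])
            for i in range(scheme.n_edges)
        ]
    )
    return SteadyState(
        probabilities=p,
        net_flux=j,
        forward_flux=j_plus,
        backward_flux=j_minus,
        force_rt=x_rt,
        dissipation_rt=j * x_rt,
        edge_sigma_rt=sigma,
    )


def one_way_fluxes(scheme: CycleScheme, state: SteadyState | None = None) -> tuple[float, float]:
    """One-way cycle fluxes (J+, J-); J+ - J- equals the net flux."""
    if state is not None:
        return state.forward_flux, state.backward_flux
    st = solve_steady_state(scheme)
    return st.forward_flux, st.backward_flux


def edge_entropy_production(scheme: CycleScheme, state: SteadyState, edge: int) -> float:
    """Partial entropy production sigma_ij/RT (s^-1) of one edge.

    sigma_ij/RT = (k_ij p_i - k_ji p_j) ln(k_ij p_i / (k_ji p_j)),
    nonnegative by construction; exactly 0 when the edge is balanced.
    """
    if not 0 <= edge < scheme.n_edges:
        raise SchemeError(f"edge {edge} out of range for {scheme.n_states}-state cycle")
    return float(state.edge_sigma_rt[edge])


def closed_form_flux(scheme: CycleScheme) -> float:
    """Net flux from the King--Altman closed forms for 2-4 state cycles.

    J = (prod k_fwd - prod k_rev) / Sigma with the denominators written
    out term by term; an independent hand-written cross-check of the
    solver.  (In the four-state denominator, the last state's tree sum
    is k2k4k8 + k1k3k5 + k3k5k8 + k2k5k8 by spanning-tree enumeration.)
    """
    kf, kr = scheme.forward_rates, scheme.reverse_rates
    num = math.prod(kf) - math.prod(kr)
    n = scheme.n_states
    if n == 2:
        k1, k3 = kf
        k2, k4 = kr
        den = k1 + k2 + k3 + k4
    elif n == 3:
        k1, k3, k5 = kf
        k2, k4, k6 = kr
        den = k1 * (k3 + k4 + k5) + (k2 * k4 + k2 * k5 + k3 * k5) + k6 * (k2 + k3 + k4)
    elif n == 4:
        k1, k3, k5, k7 = kf
        k2, k4, k6, k8 = kr
        s1 = k2 * k4 * k6 + k2 * k4 * k7 + k2 * k5 * k7 + k3 * k5 * k7
        s2 = k1 * k5 * k7 + k4 * k6 * k8 + k1 * k4 * k6 + k1 * k4 * k7
        s3 = k1 * k3 * k7 + k2 * k6 * k8 + k3 * k6 * k8 + k1 * k3 * k6
        s4 = k2 * k4 * k8 + k1 * k3 * k5 + k3 * k5 * k8 + k2 * k5 * k8
        den = s1 + s2 + s3 + s4
    else:
        raise SchemeError(f"closed-form flux is written out for 2-4 states, not {n}; use solve_steady_state")
    return num / den
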