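"""Unicyclic reversible kinetic schemes.

A scheme is a single closed loop of N enzyme conformational states
(E, ES, EZ, EP, ...) connected by reversible first-order transitions.
States are numbered 1..N counterclockwise; edge ``i`` (0-based) connects
state ``i+1`` to state ``i+2`` (mod N).  The forward rate constant of
edge ``i`` is the odd-indexed k_{2i+1} of the conventional numbering
(k1, k3, k5, k7) and the reverse rate constant is the even-indexed
k_{2i+2} (k2, k4, k6, k8).

Ligand-binding transitions (substrate binding E + S -> ES, product
rebinding E + P -> EP) are pseudo-first-order: the stored first-order
rate is the second-order constant (M^-1 s^-1) times the ligand
concentration (M).  The second-order constant and concentration are
retained so that saturating- and vanishing-ligand limits are well
defined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

__all__ = ["Binding", "CycleScheme", "SchemeError"]

#: Gas constant, J mol^-1 K^-1.
R_GAS = 8.314

#: Default temperature, K.
DEFAULT_TEMPERATURE = 298.15

_FORWARD = "forward"
_REVERSE = "reverse"


class SchemeError(ValueError):
    """Raised when a kinetic scheme violates its invariants."""


@dataclass(frozen=True)
class Binding:
    """A ligand-binding transition on one edge of the cycle.

    Parameters
    ----------
    edge:
        0-based edge index.
    direction:
        ``"forward"`` (e.g. substrate binding E + S -> ES on edge 0) or
        ``"reverse"`` (e.g. product rebinding E + P -> EP on the last
        edge).
    second_order:
        Second-order rate constant, M^-1 s^-1.
    ligand:
        Label keying into :attr:`CycleScheme.concentrations` ("S", "P").
    """

    edge: int
    direction: str
    second_order: float
    ligand: str

    def __post_init__(self) -> None:
        if self.direction not in (_FORWARD, _REVERSE):
            raise SchemeError(f"binding direction must be 'forward' or 'reverse', got {self.direction!r}")
        if not (math.isfinite(self.second_order) and self.second_order > 0):
            raise SchemeError(f"second-order constant must be positive and finite, got {self.second_order}")


def _check_rates(rates: tuple[float, ...], label: str) -> None:
    for i, k in enumerate(rates):
        if not (math.isfinite(k) and k > 0):
            raise SchemeError(f"nonpositive rate constant: {label}[{i}] = {k}")


@dataclass(frozen=True)
class CycleScheme:
    """A unicyclic reversible kinetic scheme with N >= 2 states.

    Parameters
    ----------
    forward_rates:
        First-order forward rate constants (k1, k3, k5, k7, ...), s^-1,
        one per edge, in cycle order.
    reverse_rates:
        First-order reverse rate constants (k2, k4, k6, k8, ...), s^-1.
    bindings:
        Ligand-binding declarations.  For every binding the stored
        first-order rate must equal ``second_order * concentration``
        (relative tolerance 1e-9); enforced on construction.
    concentrations:
        Molar ligand concentrations keyed by label.
    temperature:
        Kelvin.
    name:
        Optional identifier carried through pipelines.
    """

    forward_rates: tuple[float, ...]
    reverse_rates: tuple[float, ...]
    bindings: tuple[Binding, ...] = ()
    concentrations: Mapping[str, float] = field(default_factory=dict)
    temperature: float = DEFAULT_TEMPERATURE
    name: str = ""

    def __post_init__(self) -> None:
        fwd = tuple(float(k) for k in self.forward_rates)
        rev = tuple(float(k) for k in self.reverse_rates)
        object.__setattr__(self, "forward_rates", fwd)
        object.__setattr__(self, "reverse_rates", rev)
        object.__setattr__(self, "concentrations", dict(self.concentrations))
        object.__setattr__(self, "bindings", tuple(self.bindings))
        n = len(fwd)
        if n < 2:
            raise SchemeError(f"a cycle needs at least 2 states, got {n} edges")
        if len(rev) != n:
            raise SchemeError(f"{n} forward but {len(rev)} reverse rate constants")
        _check_rates(fwd, "forward")
        _check_rates(rev, "reverse")
        if not (math.isfinite(self.temperature) and self.temperature > 0):
            raise SchemeError(f"temperature must be positive, got {self.temperature}")
        seen: set[tuple[int, str]] = set()
        for b in self.bindings:
            if not 0 <= b.edge < n:
                raise SchemeError(f"binding edge {b.edge} out of range for {n}-state cycle")
            if (b.edge, b.direction) in seen:
                raise SchemeError(f"duplicate binding on edge {b.edge} ({b.direction})")
            seen.add((b.edge, b.direction))
            if b.ligand not in self.concentrations:
                raise SchemeError(f"no concentration declared for ligand {b.ligand!r}")
            conc = self.concentrations[b.ligand]
            if not (math.isfinite(conc) and conc > 0):
                raise SchemeError(f"ligand concentration [{b.ligand}] must be positive, got {conc}")
            stored = fwd[b.edge] if b.direction == _FORWARD else rev[b.edge]
            expected = b.second_order * conc
            if not math.isclose(stored, expected, rel_tol=1e-9):
                raise SchemeError(
                    f"edge {b.edge} {b.direction} rate {stored} inconsistent with "
                    f"{b.second_order} M^-1 s^-1 x [{b.ligand}] = {expected} s^-1"
                )

    # -- topology -----------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.forward_rates)

    @property
    def n_edges(self) -> int:
        return len(self.forward_rates)

    # -- thermodynamic bookkeeping ------------------------------------

    @property
    def step_equilibrium_constants(self) -> tuple[float, ...]:
        """K_i = k_(2i-1) / k_(2i) for each step around the cycle."""
        return tuple(f / r for f, r in zip(self.forward_rates, self.reverse_rates))

    @property
    def cycle_equilibrium_constant(self) -> float:
        """K = prod_i K_i; unity at detailed balance."""
        return math.exp(
            math.fsum(math.log(f) for f in self.forward_rates)
            - math.fsum(math.log(r) for r in self.reverse_rates)
        )

    @property
    def rt(self) -> float:
        """R*T in J mol^-1."""
        return R_GAS * self.temperature

    # -- binding lookups ----------------------------------------------

    def binding_for(self, edge: int, direction: str) -> Binding | None:
        for b in self.bindings:
            if b.edge == edge and b.direction == direction:
                return b
        return None

    @property
    def substrate_binding(self) -> Binding | None:
        """The forward binding step on edge 0, if declared."""
        return self.binding_for(0, _FORWARD)

    @property
    def product_binding(self) -> Binding | None:
        """The reverse (product-rebinding) step on the last edge, if declared."""
        return self.binding_for(self.n_edges - 1, _REVERSE)

    @property
    def mass_action_ratio(self) -> float | None:
        """Gamma = [P]/[S] when both binding steps are declared."""
        s, p = self.substrate_binding, self.product_binding
        if s is None or p is None:
            return None
        return self.concentrations[p.ligand] / self.concentrations[s.ligand]

    @property
    def chemical_equilibrium_constant(self) -> float | None:
        """K_eq = c_p(eq)/c_s(eq), from second-order binding constants.

        Substituting k1 = k1*[S] and k_last_rev = k*[P] into
        prod(k_fwd)/prod(k_rev) = 1 at equilibrium gives
        K_eq = (k1*/k*) x prod of the interior step constants.
        """
        s, p = self.substrate_binding, self.product_binding
        if s is None or p is None:
            return None
        k = self.cycle_equilibrium_constant  # = K_eq * [S]/[P] at working conc
        return k * self.mass_action_ratio

    # -- derived schemes ----------------------------------------------

    def replace_rate(self, edge: int, *, forward: float | None = None, reverse: float | None = None) -> "CycleScheme":
        """Return a scheme with one edge's rate constant(s) replaced.

        If the replaced rate belongs to a declared binding step, the
        second-order constant is recomputed from the unchanged ligand
        concentration so the binding invariant still holds.
        """
        if not 0 <= edge < self.n_edges:
            raise SchemeError(f"edge {edge} out of range")
        fwd = list(self.forward_rates)
        rev = list(self.reverse_rates)
        if forward is not None:
            fwd[edge] = forward
        if reverse is not None:
            rev[edge] = reverse
        bindings = []
        for b in self.bindings:
            if b.edge == edge and b.direction == _FORWARD and forward is not None:
                b = replace(b, second_order=forward / self.concentrations[b.ligand])
            elif b.edge == edge and b.direction == _REVERSE and reverse is not None:
                b = replace(b, second_order=reverse / self.concentrations[b.ligand])
            bindings.append(b)
        return replace(self, forward_rates=tuple(fwd), reverse_rates=tuple(rev), bindings=tuple(bindings))

    def with_concentration(self, ligand: str, concentration: float) -> "CycleScheme":
        """Return a scheme re-evaluated at a new ligand concentration.

        Every binding step involving ``ligand`` has its stored
        first-order rate rescaled to ``second_order * concentration``.
        """
        if ligand not in self.concentrations:
            raise SchemeError(f"unknown ligand {ligand!r}")
        fwd = list(self.forward_rates)
        rev = list(self.reverse_rates)
        for b in self.bindings:
            if b.ligand != ligand:
                continue
            rate = b.second_order * concentration
            if b.direction == _FORWARD:
                fwd[b.edge] = rate
            else:
                rev[b.edge] = rate
        conc = dict(self.concentrations)
        conc[ligand] = concentration
        return replace(self, forward_rates=tuple(fwd), reverse_rates=tuple(rev), concentrations=conc)

    def scaled(self, factor: float) -> "CycleScheme":
        """Rescale every rate constant by ``factor`` (time rescaling)."""
        return replace(
            self,
            forward_rates=tuple(k * factor for k in self.forward_rates),
            reverse_rates=tuple(k * factor for k in self.reverse_rates),
            bindings=tuple(replace(b, second_order=b.second_order * factor) for b in self.bindings),
        )
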