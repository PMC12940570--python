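"""Seeded generators for thermodynamically consistent random ensembles.

Real curated rate-constant collections for single-cycle enzymes share a
few statistical features that these generators emulate: microscopic
rate constants spread over many orders of magnitude (sampled
log-uniformly), a strictly positive net thermodynamic drive for every
enzyme (imposed by rescaling a single reverse constant), scheme sizes
of 2-4 states, and -- for ensemble statistics -- an approximate
power-law coupling between total dissipation and catalytic efficiency
with log-normal scatter.

All randomness flows through one integer seed via
``numpy.random.default_rng``, so ensembles are reproducible
byte-for-byte across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kinetics import KineticSummary
from .scheme import Binding, CycleScheme

__all__ = ["ImposedScaling", "EnsembleSpec", "generate_scheme", "generate_ensemble", "generate_scaling_ensemble"]

#: Default working concentrations for generated schemes, M.  Millimolar
#: substrate and micromolar product are typical forward-driven assay
#: conditions; together with the imposed force they fix the binding
#: second-order constants.
DEFAULT_S_CONC = 1e-3
DEFAULT_P_CONC = 1e-6


@dataclass(frozen=True)
class ImposedScaling:
    """A power law dissipation/RT = 10^intercept * (kcat/KM)^slope with
    log-normal scatter (SD in log10 units)."""

    slope: float = 0.72
    intercept: float = -1.0
    scatter_sd: float = 0.5
    log10_efficiency_range: tuple[float, float] = (2.0, 9.0)
    log10_kcat_range: tuple[float, float] = (-1.0, 6.0)


@dataclass(frozen=True)
class EnsembleSpec:
    """Study conditions for a synthetic enzyme ensemble.

    ``seed`` is mandatory: unseeded generation is an error, not a
    silent default.
    """

    seed: int
    n_enzymes: int = 75
    size_weights: dict[int, float] = field(default_factory=lambda: {2: 0.25, 3: 0.5, 4: 0.25})
    log10_rate_range: tuple[float, float] = (-2.0, 8.0)
    force_rt_range: tuple[float, float] = (1.0, 40.0)
    scaling: ImposedScaling | None = None
    s_conc: float = DEFAULT_S_CONC
    p_conc: float = DEFAULT_P_CONC
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("EnsembleSpec.seed must be an integer")
        if self.n_enzymes < 1:
            raise ValueError("n_enzymes must be positive")
        if not self.size_weights or any(s < 2 or s > 4 for s in self.size_weights):
            raise ValueError("scheme sizes must lie in {2, 3, 4}")
        lo, hi = self.log10_rate_range
        if not lo < hi:
            raise ValueError("empty rate range")
        flo, fhi = self.force_rt_range
        if flo > fhi:
            raise ValueError("empty force range")


def generate_scheme(
    spec: EnsembleSpec,
    size: int,
    rng: np.random.Generator,
    *,
    name: str = "",
) -> CycleScheme:
    """Draw one thermodynamically consistent scheme.

    Rate constants are log-uniform over ``spec.log10_rate_range``; the
    last reverse constant is then rescaled so that X/RT equals a value
    drawn uniformly from ``spec.force_rt_range`` (this touches a single
    marginal and is rejection-free).  Substrate binding is declared on
    edge 0 and product rebinding on the last edge, with second-order
    constants back-computed from the working concentrations.
    """
    lo, hi = spec.log10_rate_range
    kf = 10.0 ** rng.uniform(lo, hi, size)
    kr = 10.0 ** rng.uniform(lo, hi, size)
    x_target = rng.uniform(*spec.force_rt_range)
    log_kr_last = (
        math.fsum(math.log(k) for k in kf) - math.fsum(math.log(k) for k in kr[:-1]) - x_target
    )
    kr[-1] = math.exp(log_kr_last)
    bindings = (
        Binding(0, "forward", kf[0] / spec.s_conc, "S"),
        Binding(size - 1, "reverse", kr[-1] / spec.p_conc, "P"),
    )
    return CycleScheme(
        forward_rates=tuple(kf),
        reverse_rates=tuple(kr),
        bindings=bindings,
        concentrations={"S": spec.s_conc, "P": spec.p_conc},
        temperature=spec.temperature,
        name=name,
    )


def generate_ensemble(spec: EnsembleSpec) -> list[CycleScheme]:
    """Generate ``spec.n_enzymes`` schemes with sizes drawn per the weights."""
    rng = np.random.default_rng(spec.seed)
    sizes = sorted(spec.size_weights)
    probs = np.array([spec.size_weights[s] for s in sizes], float)
    probs /= probs.sum()
    drawn = rng.choice(sizes, size=spec.n_enzymes, p=probs)
    return [
        generate_scheme(spec, int(size), rng, name=f"synthetic_{i + 1:03d}")
        for i, size in enumerate(drawn)
    ]


_CLASS_LABELS = ("specialist", "generalist", "mutant", "wild-type")


def generate_scaling_ensemble(spec: EnsembleSpec) -> list[KineticSummary]:
    """Generate kinetic summaries with an imposed dissipation power law.

    log10(diss/RT) = intercept + slope * log10(kcat/KM) + eps with
    eps ~ Normal(0, scatter_sd); kcat/KM is log-uniform over the stated
    range, kcat log-uniform independently, and KM their ratio.  Class
    labels are assigned uniformly at random (no family structure).
    """
    if spec.scaling is None:
        raise ValueError("generate_scaling_ensemble needs spec.scaling set")
    law = spec.scaling
    rng = np.random.default_rng(spec.seed)
    log_eff = rng.uniform(*law.log10_efficiency_range, spec.n_enzymes)
    log_kcat = rng.uniform(*law.log10_kcat_range, spec.n_enzymes)
    eps = rng.normal(0.0, law.scatter_sd, spec.n_enzymes) if law.scatter_sd > 0 else np.zeros(spec.n_enzymes)
    log_diss = law.intercept + law.slope * log_eff + eps
    labels = rng.choice(_CLASS_LABELS, spec.n_enzymes)
    out = []
    for i in range(spec.n_enzymes):
        eff = 10.0 ** log_eff[i]
        kcat = 10.0 ** log_kcat[i]
        out.append(
            KineticSummary(
                name=f"scaling_{i + 1:03d}",
                kcat=kcat,
                km=kcat / eff,
                kcat_over_km=eff,
                dissipation_rt=10.0 ** log_diss[i],
                kcat_over_j=1.0,
                forward_driven=True,
                class_label=str(labels[i]),
            )
        )
    return out
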