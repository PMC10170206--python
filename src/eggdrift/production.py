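"""Annual egg production of the spawning population.

Total egg production is the number of mature females (mature count times
the female sex ratio, 1:1 by default) multiplied by mean fecundity over
the population length distribution.  The 95% CI on the mature count is
propagated by linear scaling; fecundity uncertainty is not modelled.
Annual production is then split across spawning nights — by default two
peak nights at 40% each and two minor nights at 10% each, matching diver
observations of aggregation spawning.

The fecundity-at-length relation is site/species-specific and must be
supplied; the built-in default is a placeholder power law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SpawningPopulation",
    "ProductionEstimate",
    "total_egg_production",
    "allocate_to_nights",
    "power_law_fecundity",
]

DEFAULT_NIGHT_WEIGHTS = (0.4, 0.4, 0.1, 0.1)


def power_law_fecundity(a: float = 2.0, b: float = 3.0) -> Callable[[float], float]:
    """Placeholder fecundity-at-length: eggs = a * L^b, L in cm.

    Coefficients are synthetic defaults, not a published relation; supply
    the species' estimated relation for scientific use.  (Which length
    metric — total vs standard length — the real relation expects is
    likewise a property of that relation.)
    """

    def fecundity(length_cm: float) -> float:
        return a * float(length_cm) ** b

    return fecundity


@dataclass
class SpawningPopulation:
    """Mature-population summary driving the egg-production estimate."""

    n_mature: float
    n_ci: tuple[float, float]  # 95% CI on n_mature
    length_dist: Sequence[tuple[float, float]]  # (length bin midpoint, proportion)
    fecundity_fn: Callable[[float], float] = field(default_factory=power_law_fecundity)
    sex_ratio_female: float = 0.5

    def __post_init__(self) -> None:
        if len(self.length_dist) == 0:
            raise ValueError("length distribution is empty")
        props = np.array([p for _, p in self.length_dist], dtype=float)
        if abs(props.sum() - 1.0) > 1e-6:
            raise ValueError("length-distribution proportions must sum to 1")
        if not 0.0 < self.sex_ratio_female < 1.0:
            raise ValueError("sex_ratio_female must be in (0, 1)")
        fec = np.array([self.fecundity_fn(L) for L, _ in self.length_dist])
        if (fec < 0).any():
            raise ValueError("fecundity must be non-negative")

    def mean_fecundity(self) -> float:
        """Expected eggs per female across the length distribution."""
        return float(
            sum(p * self.fecundity_fn(L) for L, p in self.length_dist)
        )


@dataclass
class ProductionEstimate:
    """Total annual egg production and its allocation across nights."""

    total_eggs: float
    ci: tuple[float, float]
    night_weights: tuple[float, ...] = DEFAULT_NIGHT_WEIGHTS
    per_night: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        w = np.asarray(self.night_weights, dtype=float)
        if (w <= 0).any() or abs(w.sum() - 1.0) > 1e-6:
            raise ValueError("night weights must be positive and sum to 1")
        if not self.per_night:
            self.per_night = tuple(float(wi) * self.total_eggs for wi in w)


def total_egg_production(
    pop: SpawningPopulation,
    night_weights: tuple[float, ...] = DEFAULT_NIGHT_WEIGHTS,
) -> ProductionEstimate:
    """Total eggs = n_mature * female ratio * mean fecundity-at-length.

    The CI scales the total by the relative abundance CI (females are the
    only uncertain factor).  Fractional eggs are retained internally.
    """
    total = pop.n_mature * pop.sex_ratio_female * pop.mean_fecundity()
    lo = total * pop.n_ci[0] / pop.n_mature
    hi = total * pop.n_ci[1] / pop.n_mature
    return ProductionEstimate(total_eggs=total, ci=(lo, hi), night_weights=night_weights)


def allocate_to_nights(
    est: ProductionEstimate, weights: Sequence[float] | None = None
) -> ProductionEstimate:
    """Reallocate a production estimate across spawning nights.

    ``per_night[i] = weights[i] * total``; conserves the total exactly.
    """
    w = tuple(float(v) for v in (weights if weights is not None else est.night_weights))
    arr = np.asarray(w)
    if (arr <= 0).any() or abs(arr.sum() - 1.0) > 1e-6:
        raise ValueError("night weights must be positive and sum to 1")
    return ProductionEstimate(
        total_eggs=est.total_eggs,
        ci=est.ci,
        night_weights=w,
        per_night=tuple(wi * est.total_eggs for wi in w),
    )
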