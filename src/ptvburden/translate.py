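"""Translate log-hazard coefficients into years, and the somatic-accumulation model.

Under a Gompertz proportional-hazards model the log-hazard is
``ln h(t) = ln h0 + Gamma * t + x @ beta``.  A covariate coefficient ``beta``
(log-hazard per unit) can therefore be equated with the Gompertz age term:
one unit of the covariate shifts the hazard curve by ``beta / Gamma`` years.
This module performs that translation for the ultra-rare PTV burden, derives
the mortality-rate doubling time, and evaluates whether the linear somatic
accumulation of protein-truncating variants could contribute appreciably to
the exponential (Gompertz) growth of mortality with age.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "SomaticModelParams",
    "years_per_unit",
    "doubling_time",
    "burden_sd_effect",
    "somatic_burden_at_age",
    "somatic_hazard_slope",
]


def _require_positive_gamma(gamma: float) -> None:
    if gamma <= 0:
        raise ValueError(f"Gompertz slope must be positive, got {gamma}")


def years_per_unit(beta: float, gamma: float) -> float:
    """Years of life/healthspan shift per unit of a log-hazard covariate.

    Equates the covariate contribution ``beta`` with the Gompertz age term
    ``Gamma * t``: one unit of the covariate is worth ``beta / Gamma`` years.
    """
    _require_positive_gamma(gamma)
    return beta / gamma


def doubling_time(gamma: float) -> float:
    """Mortality-rate doubling time ``ln(2) / Gamma`` in years."""
    _require_positive_gamma(gamma)
    return math.log(2.0) / gamma


def burden_sd_effect(sd: float, beta: float, gamma: float) -> float:
    """Years of lifespan variability induced by burden variability ``sd``."""
    if sd < 0:
        raise ValueError("standard deviation must be non-negative")
    _require_positive_gamma(gamma)
    return sd * beta / gamma


@dataclass(frozen=True)
class SomaticModelParams:
    """Parameters of the linear somatic PTV-accumulation model.

    Attributes
    ----------
    beta : log-hazard per mutation (per-PTV proportional-hazards coefficient).
    lam : fraction of the genome at which a mutation would create an
        ultra-rare PTV (dimensionless).
    genome_size : diploid-relevant genome size L in base pairs.
    mutation_rate : somatic mutation rate R per base pair per year.
    gamma : Gompertz log-hazard slope per year, for comparison.
    """

    beta: float = 0.046
    lam: float = 0.33e-5
    genome_size: float = 3.0e9
    mutation_rate: float = 1.0e-8
    gamma: float = 0.09

    def __post_init__(self) -> None:
        for name in ("beta", "lam", "genome_size", "mutation_rate", "gamma"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.lam > 1:
            raise ValueError("lam is a genome fraction and cannot exceed 1")


def somatic_burden_at_age(params: SomaticModelParams, age: float) -> float:
    """Expected somatic ultra-rare PTV count accumulated by ``age`` years.

    The somatic burden grows linearly as ``lam * L * R * t``.
    """
    if age < 0:
        raise ValueError("age must be non-negative")
    return params.lam * params.genome_size * params.mutation_rate * age


def somatic_hazard_slope(
    params: SomaticModelParams, negligible_ratio: float = 1e-2
) -> tuple[float, float, str]:
    """Linear-in-age log-hazard slope contributed by somatic PTV accumulation.

    Returns ``(slope, ratio, verdict)`` where ``slope = beta * lam * L * R``
    per year, ``ratio = slope / Gamma``, and the verdict is ``"negligible"``
    when the ratio falls below ``negligible_ratio`` (default 1%), else
    ``"appreciable"``.
    """
    slope = params.beta * params.lam * params.genome_size * params.mutation_rate
    ratio = slope / params.gamma
    verdict = "negligible" if ratio < negligible_ratio else "appreciable"
    return slope, ratio, verdict
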