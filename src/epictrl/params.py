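"""Parameter containers for the epidemic, individual, and government layers.

Units: time in mean infectious periods; utilities and costs in units where the
individual social-distancing cost coefficient β = 1 (the model's natural unit
choice). Discount rates f, f_g ≥ 1 are per-unit-time bases, i.e. utility at
time t is weighted by f^(−t); f = 1 disables discounting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

__all__ = [
    "EpidemicParams",
    "InfectionCostParams",
    "UtilityParams",
    "GovernmentParams",
    "ModelParams",
]


@dataclass(frozen=True)
class EpidemicParams:
    """Baseline infectiousness and initial conditions of the rescaled SIR model.

    ``kappa_star`` is the behaviour adopted in the absence of any epidemic and
    equals the basic reproduction number R0 (> 1 for an epidemic to occur).
    """

    kappa_star: float = 4.0
    i0: float = 3e-8

    def __post_init__(self) -> None:
        if not self.kappa_star > 1.0:
            raise ValueError(f"kappa_star must exceed 1, got {self.kappa_star}")
        if not 0.0 < self.i0 < 1.0:
            raise ValueError(f"i0 must lie in (0, 1), got {self.i0}")

    @property
    def s0(self) -> float:
        return 1.0 - self.i0


@dataclass(frozen=True)
class InfectionCostParams:
    """Per-infection cost α(i), optionally rising at a healthcare threshold.

    In the threshold variant

        α(i) = α0 + (α1 − α0)/2 · (tanh[(i − i_hc)·σ] + 1),

    the cost climbs from α0 towards α1 as the infected fraction approaches the
    healthcare capacity i_hc, with steepness σ (per unit infected fraction).
    With ``constant=True`` the cost is α0 for every i (α1, i_hc, σ are ignored).
    """

    alpha0: float
    alpha1: float | None = None
    i_hc: float = 0.1
    sigma: float = 300.0
    constant: bool = False

    def __post_init__(self) -> None:
        if self.alpha0 < 0:
            raise ValueError(f"alpha0 must be >= 0, got {self.alpha0}")
        if self.constant:
            if self.alpha1 is None:
                object.__setattr__(self, "alpha1", self.alpha0)
            return
        if self.alpha1 is None:
            raise ValueError("alpha1 required for the threshold cost variant")
        if self.alpha1 < self.alpha0:
            raise ValueError(
                f"alpha1={self.alpha1} must be >= alpha0={self.alpha0}"
            )
        if not self.i_hc > 0:
            raise ValueError(f"i_hc must be > 0, got {self.i_hc}")
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @classmethod
    def const(cls, alpha: float) -> "InfectionCostParams":
        """Constant cost α(i) ≡ alpha."""
        return cls(alpha0=alpha, alpha1=alpha, constant=True)

    def alpha_at_zero(self) -> float:
        """α(0): the per-infection cost in the disease-free limit.

        For the threshold variant this exceeds α0 by
        (α1 − α0)·(1 − tanh(i_hc·σ))/2, which is negligible for i_hc·σ ≳ 5
        but appreciable for low thresholds.
        """
        if self.constant:
            return self.alpha0
        return self.alpha0 + 0.5 * (self.alpha1 - self.alpha0) * (
            1.0 - math.tanh(self.i_hc * self.sigma)
        )


@dataclass(frozen=True)
class UtilityParams:
    """Individual utility parameters: discount base f ≥ 1, distancing cost β,
    and the infection-cost function."""

    cost: InfectionCostParams
    f: float = 1.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.f < 1.0:
            raise ValueError(f"f must be >= 1, got {self.f}")
        if not self.beta > 0:
            raise ValueError(f"beta must be > 0, got {self.beta}")

    @property
    def log_f(self) -> float:
        return math.log(self.f)


@dataclass(frozen=True)
class GovernmentParams:
    """Government objective parameters.

    ``gamma_g`` is the shadow cost of public funds: γ_g = 0 means the
    tax/subsidy process is free to the government; γ_g > 0 makes intervening
    intrinsically costly.
    """

    cost_g: InfectionCostParams
    f_g: float = 1.0
    beta_g: float = 1.0
    gamma_g: float = 0.0

    def __post_init__(self) -> None:
        if self.f_g < 1.0:
            raise ValueError(f"f_g must be >= 1, got {self.f_g}")
        if not self.beta_g > 0:
            raise ValueError(f"beta_g must be > 0, got {self.beta_g}")
        if self.gamma_g < 0:
            raise ValueError(f"gamma_g must be >= 0, got {self.gamma_g}")

    @property
    def log_f_g(self) -> float:
        return math.log(self.f_g)


@dataclass(frozen=True)
class ModelParams:
    """Full scenario parameter set (government block optional)."""

    epidemic: EpidemicParams
    utility: UtilityParams
    government: GovernmentParams | None = None

    def with_government(self, gov: GovernmentParams) -> "ModelParams":
        return replace(self, government=gov)
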