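"""Four-process organelle abundance model: rate constants, propensities, regimes.

The copy number ``n`` of an organelle evolves by four elementary processes:

* de novo synthesis   n -> n+1   at rate ``k_denovo``            (zeroth order)
* fission             n -> n+1   at rate ``k_fission * n``       (first order)
* homotypic fusion    n -> n-1   at rate ``k_fusion * n*(n-1)``  (second order)
* decay               n -> n-1   at rate ``gamma * n``           (first order)

Rates carry arbitrary reciprocal-time units; stationary distributions depend
only on rate ratios, so by convention the time unit is 1/gamma where gamma > 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "RateConstants",
    "Propensities",
    "Regime",
    "propensities_at",
    "classify_regime",
    "mean_field_steady_state",
    "gamma_for_target_mean",
]


@dataclass(frozen=True)
class RateConstants:
    """The four rate parameters defining one model instance.

    Parameters
    ----------
    k_denovo : float
        De novo synthesis rate, organelles per unit time.
    k_fission : float
        Fission rate, per organelle per unit time.
    k_fusion : float
        Homotypic fusion rate, per organelle pair (n*(n-1) counting) per unit
        time.
    gamma : float
        First-order decay rate (aggregating maturation, dilution by division,
        autophagy, heterotypic fusion), per organelle per unit time.
    """

    k_denovo: float
    k_fission: float
    k_fusion: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("k_denovo", "k_fission", "k_fusion", "gamma"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")

    def validate_stationary(self) -> None:
        """Raise if no non-degenerate stationary state can exist."""
        if self.k_denovo == 0 and self.k_fission == 0:
            raise ValueError(
                "no production process: k_denovo = k_fission = 0 gives a "
                "degenerate stationary state absorbed at the initial floor"
            )
        if self.gamma == 0 and self.k_fusion == 0:
            raise ValueError(
                "no loss process: gamma = k_fusion = 0 means abundance diverges"
            )

    def to_dict(self) -> dict[str, float]:
        return {
            "k_denovo": self.k_denovo,
            "k_fission": self.k_fission,
            "k_fusion": self.k_fusion,
            "gamma": self.gamma,
        }

    @classmethod
    def from_dict(cls, mapping: Mapping[str, float]) -> "RateConstants":
        return cls(
            k_denovo=float(mapping["k_denovo"]),
            k_fission=float(mapping["k_fission"]),
            k_fusion=float(mapping["k_fusion"]),
            gamma=float(mapping["gamma"]),
        )


@dataclass(frozen=True)
class Propensities:
    """The four reaction propensities evaluated at one copy number."""

    birth_denovo: float
    birth_fission: float
    death_fusion: float
    death_decay: float

    @property
    def birth_flux(self) -> float:
        """Total birth flux R+ = k_denovo + k_fission * n."""
        return self.birth_denovo + self.birth_fission

    @property
    def death_flux(self) -> float:
        """Total death flux R- = gamma * n + k_fusion * n * (n-1)."""
        return self.death_fusion + self.death_decay

    @property
    def total(self) -> float:
        return self.birth_flux + self.death_flux


@dataclass(frozen=True)
class Regime:
    """Which elementary processes are active.

    ``denovo_decay`` is the Golgi-like limit (fission = fusion = 0),
    ``fission_fusion`` the vacuole-like limit (de novo = decay = 0), and
    ``denovo_fission_decay`` the peroxisome-like limit (fusion = 0).
    """

    label: str
    zeroed_rates: frozenset[str] = field(default_factory=frozenset)


def propensities_at(n: int, rates: RateConstants) -> Propensities:
    """Evaluate the four propensities at copy number ``n``.

    Fusion needs at least two organelles (n*(n-1) = 0 at n <= 1) and decay at
    least one, so the death propensities vanish near the origin.
    """
    if n < 0 or int(n) != n:
        raise ValueError(f"copy number must be a non-negative integer, got {n!r}")
    n = int(n)
    return Propensities(
        birth_denovo=rates.k_denovo,
        birth_fission=rates.k_fission * n,
        death_fusion=rates.k_fusion * n * (n - 1),
        death_decay=rates.gamma * n,
    )


def classify_regime(rates: RateConstants) -> Regime:
    """Return the most specific named regime whose zero-rate pattern holds.

    Precedence follows specificity: two zeroed rates (denovo_decay,
    fission_fusion) beat one (denovo_fission_decay) beat none (general).
    """
    if rates.k_fission == 0 and rates.k_fusion == 0:
        return Regime("denovo_decay", frozenset({"k_fission", "k_fusion"}))
    if rates.k_denovo == 0 and rates.gamma == 0:
        return Regime("fission_fusion", frozenset({"k_denovo", "gamma"}))
    if rates.k_fusion == 0:
        return Regime("denovo_fission_decay", frozenset({"k_fusion"}))
    return Regime("general", frozenset())


def mean_field_steady_state(rates: RateConstants) -> float:
    """Deterministic stationary mean from balancing birth and death fluxes.

    Solves ``k_denovo + k_fission*m = gamma*m + k_fusion*m*(m-1)`` for the
    unique positive root, using the moment closure <n(n-1)> ~ <n>(<n>-1).
    The exact stationary mean (``analytics.cme_stationary``) is authoritative
    when they disagree; the closure error is largest at small means.
    """
    rates.validate_stationary()
    a = rates.k_fusion
    b = rates.gamma - rates.k_fission - rates.k_fusion
    c = -rates.k_denovo
    if a == 0:
        # linear: (gamma - k_fission) m = k_denovo
        if b <= 0:
            raise ValueError(
                "no stationary mean: k_fission >= gamma with no fusion "
                "(supercritical branching)"
            )
        return -c / b
    disc = b * b - 4 * a * c
    m = (-b + math.sqrt(disc)) / (2 * a)
    if m <= 0:
        raise ValueError("no positive stationary mean for these rates")
    return m


def gamma_for_target_mean(
    k_denovo: float, k_fission: float, k_fusion: float, target_mean: float
) -> float:
    """Decay rate that pins the mean-field stationary mean at ``target_mean``.

    Used for parameter sweeps where the mean organelle abundance is held
    constant while fission/fusion rates vary.
    """
    if target_mean <= 0:
        raise ValueError("target_mean must be > 0")
    m = target_mean
    gamma = (k_denovo + k_fission * m - k_fusion * m * (m - 1)) / m
    if gamma < 0:
        raise ValueError(
            f"infeasible target mean {m}: fusion alone over-dissipates "
            f"(required gamma = {gamma:.4g} < 0)"
        )
    return gamma
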