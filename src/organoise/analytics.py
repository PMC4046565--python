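"""Analytical and numerically exact predictions for organelle abundance noise.

The central quantity is the Fano factor sigma^2/<n> of the stationary copy
number distribution.  A fluctuation-dissipation argument (Paulsson-style)
gives the closed-form approximation

    sigma^2/<n> = <|delta|> / C,   <|delta|> = 1,
    C = dln(R-)/dln(n) - dln(R+)/dln(n)  evaluated at the mean,

which for the four-process model reduces to

    sigma^2/<n> = 1 / [ (k_fusion(2<n>-1) + gamma) / (k_fusion(<n>-1) + gamma)
                        - k_fission <n> / (k_denovo + k_fission <n>) ].

Because the model is a one-dimensional birth-death chain, its exact stationary
law is also available in product form (``cme_stationary``); that solver is the
oracle against which the closed form and the Gillespie sampler are validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .rates import RateConstants, gamma_for_target_mean, mean_field_steady_state

__all__ = [
    "AbundanceDistribution",
    "FDTComponents",
    "fano_fdt",
    "fdt_components",
    "fano_shifted_poisson",
    "fano_denovo_fission",
    "fano_fusion_decay_balanced",
    "poisson_distribution",
    "shifted_poisson_distribution",
    "cme_stationary",
    "percent_error",
    "fano_sweep",
    "percent_error_curve",
]

#: Default bound on probability mass beyond the truncation point.
TAIL_TOLERANCE = 1e-8


@dataclass(frozen=True)
class AbundanceDistribution:
    """Probability distribution over copy numbers 0..n_max.

    ``probabilities[n]`` is P(N = n); ``tail_mass`` bounds the probability
    beyond ``n_max`` that the truncation discarded.
    """

    probabilities: np.ndarray
    tail_mass: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 1 or p.size == 0:
            raise ValueError("probabilities must be a non-empty 1-d array")
        if np.any(p < -1e-12):
            raise ValueError("negative probability entry")
        object.__setattr__(self, "probabilities", p)

    @property
    def support(self) -> np.ndarray:
        return np.arange(self.probabilities.size)

    @property
    def mean(self) -> float:
        return float(np.dot(self.support, self.probabilities))

    @property
    def variance(self) -> float:
        m = self.mean
        return float(np.dot((self.support - m) ** 2, self.probabilities))

    @property
    def fano(self) -> float:
        m = self.mean
        if m == 0:
            raise ZeroDivisionError("Fano factor undefined for zero mean")
        return self.variance / m

    def pmf(self, n: int) -> float:
        if 0 <= n < self.probabilities.size:
            return float(self.probabilities[n])
        return 0.0


@dataclass(frozen=True)
class FDTComponents:
    """Pieces of the fluctuation-dissipation Fano estimate at the mean."""

    step_size: float
    dissipation: float
    birth_flux: float
    death_flux: float

    @property
    def fano(self) -> float:
        return self.step_size / self.dissipation


def fdt_components(
    rates: RateConstants, mean: float, *, discrete: bool = False
) -> FDTComponents:
    """Dissipation C and fluxes at ``mean``.

    ``discrete=True`` uses the symmetric unit-step difference quotient for the
    logarithmic derivatives instead of the continuous form; both coincide with
    the printed closed form for this reaction scheme's default contract.
    """
    if mean <= 0:
        raise ValueError("mean must be > 0")
    m = mean
    r = rates
    birth = r.k_denovo + r.k_fission * m
    death = r.gamma * m + r.k_fusion * m * (m - 1)
    if r.gamma == 0 and r.k_fusion == 0:
        raise ValueError("no death process: stationary state does not exist")
    if birth <= 0:
        raise ValueError("no birth flux at this mean")
    if discrete:
        # (Delta R / R) / (Delta n / n) with Delta n = 1 centred at m
        def logslope(flux):
            return (flux(m + 0.5) - flux(m - 0.5)) / flux(m) * m

        c = logslope(lambda x: r.gamma * x + r.k_fusion * x * (x - 1)) - logslope(
            lambda x: r.k_denovo + r.k_fission * x
        )
    else:
        # d ln R- / d ln n - d ln R+ / d ln n at n = m
        denom_death = r.k_fusion * (m - 1) + r.gamma
        if denom_death <= 0:
            raise ValueError("death flux vanishes at this mean")
        c = (r.k_fusion * (2 * m - 1) + r.gamma) / denom_death - (
            r.k_fission * m
        ) / (r.k_denovo + r.k_fission * m)
    if c <= 0:
        raise ValueError(
            f"non-positive dissipation C = {c:.4g}: infeasible (rates, mean) pair"
        )
    return FDTComponents(step_size=1.0, dissipation=c, birth_flux=birth, death_flux=death)


def fano_fdt(rates: RateConstants, mean: float) -> float:
    """Fluctuation-dissipation Fano factor at the given stationary mean.

    Exact in the pure de novo + decay (Poisson) and pure fission + fusion
    (shifted Poisson) limits; an O(1/<n>) approximation elsewhere, accurate
    for means above ~2.
    """
    return fdt_components(rates, mean).fano


def fano_shifted_poisson(mean: float) -> float:
    """Fano factor 1 - 1/<n> of a shifted Poisson (fission-fusion balance).

    The support starts at one organelle, which is what pushes the Fano factor
    below the Poisson value at low means.
    """
    if mean < 1:
        raise ValueError("shifted-Poisson mean must be >= 1 (support starts at 1)")
    return 1.0 - 1.0 / mean


def fano_denovo_fission(k_denovo: float, k_fission: float, mean: float) -> float:
    """Fano factor 1 + k_fission*<n>/k_denovo (no fusion, peroxisome case)."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if k_denovo <= 0:
        raise ValueError(
            "k_denovo = 0 with fission gives unbounded Fano (pure branching)"
        )
    return 1.0 + k_fission * mean / k_denovo


def fano_fusion_decay_balanced(k_denovo: float, k_fission: float, mean: float) -> float:
    """Fano factor when fusion and first-order decay remove organelles at
    similar rates: (2 k_denovo + 3 k_fission <n>) / (3 k_denovo + k_fission <n>).

    Grows much larger than 1 only when k_fission*<n> >> k_denovo; saturates
    at 3.
    """
    num = 2.0 * k_denovo + 3.0 * k_fission * mean
    den = 3.0 * k_denovo + k_fission * mean
    if den <= 0:
        raise ValueError("k_denovo and k_fission*mean cannot both be zero")
    return num / den


def _check_tail(tail: float, tolerance: float) -> None:
    if tail > tolerance:
        raise ValueError(
            f"tail mass {tail:.3g} beyond n_max exceeds tolerance {tolerance:.3g}; "
            "raise n_max"
        )


def poisson_distribution(
    mean: float, n_max: int | None = None, *, tail_tolerance: float = TAIL_TOLERANCE
) -> AbundanceDistribution:
    """Poisson reference distribution (de novo + decay regime)."""
    if mean <= 0:
        raise ValueError("mean must be > 0")
    if n_max is None:
        n_max = default_n_max(mean, 1.0)
    n = np.arange(n_max + 1)
    p = sps.poisson.pmf(n, mean)
    tail = float(sps.poisson.sf(n_max, mean))
    _check_tail(tail, tail_tolerance)
    return AbundanceDistribution(p, tail)


def shifted_poisson_distribution(
    mean: float, n_max: int | None = None, *, tail_tolerance: float = TAIL_TOLERANCE
) -> AbundanceDistribution:
    """Shifted Poisson: 1 + Poisson(mean - 1); P(0) = 0.

    The stationary picture of a fission-fusion balance: a cell can only fuse
    down to a single organelle, never to zero.
    """
    if mean < 1:
        raise ValueError("shifted-Poisson mean must be >= 1")
    lam = mean - 1.0
    if n_max is None:
        n_max = default_n_max(mean, 1.0) + 1
    n = np.arange(n_max + 1)
    p = np.zeros(n_max + 1)
    p[1:] = sps.poisson.pmf(n[1:] - 1, lam)
    tail = float(sps.poisson.sf(n_max - 1, lam))
    _check_tail(tail, tail_tolerance)
    return AbundanceDistribution(p, tail)


def default_n_max(mean: float, fano: float) -> int:
    """Truncation heuristic: mean + 12 standard deviations (at least 20)."""
    return max(20, math.ceil(mean + 12.0 * math.sqrt(mean * max(fano, 1.0))))


def cme_stationary(
    rates: RateConstants,
    n_max: int | None = None,
    *,
    tail_tolerance: float = TAIL_TOLERANCE,
) -> AbundanceDistribution:
    """Exact stationary distribution of the chemical master equation.

    The four-process scheme is a one-dimensional birth-death chain with birth
    rate ``b(n) = k_denovo + k_fission n`` and death rate
    ``d(n) = gamma n + k_fusion n (n-1)``, so the stationary law satisfies
    detailed balance and is the product form

        p(n) ∝ prod_{i=1..n} b(i-1)/d(i),

    computed in log space on 0..n_max with the truncation's discarded mass
    reported as ``tail_mass``.  For the pure fission-fusion regime the support
    starts at n = 1 (state 0 is unreachable) and the product form is a
    zero-truncated Poisson with lambda = k_fission/k_fusion.
    """
    rates.validate_stationary()
    if rates.k_denovo == 0 and rates.gamma > 0:
        raise ValueError(
            "degenerate stationary state: with k_denovo = 0 and gamma > 0 the "
            "chain is absorbed at 0"
        )
    if rates.k_fusion == 0 and rates.k_fission >= rates.gamma:
        raise ValueError(
            "no stationary state: k_fission >= gamma with no fusion "
            "(supercritical branching)"
        )
    # with gamma = 0 the death rate at n = 1 vanishes (fusion needs a pair),
    # so state 0 is transient and the stationary support starts at 1
    n_start = 0 if rates.gamma > 0 else 1

    # initial truncation guess from the mean-field mean
    if n_max is None:
        try:
            m = mean_field_steady_state(rates)
        except ValueError:
            m = 1.0
        n_max = default_n_max(m, 2.0)

    for _ in range(40):
        n = np.arange(n_start, n_max + 1)
        birth = rates.k_denovo + rates.k_fission * n[:-1]
        death = rates.gamma * n[1:] + rates.k_fusion * n[1:] * (n[1:] - 1)
        if np.any(death <= 0):
            raise ValueError("death rate vanishes on the interior of the support")
        logw = np.concatenate([[0.0], np.cumsum(np.log(birth) - np.log(death))])
        logw -= logw.max()
        w = np.exp(logw)
        total = w.sum()
        # geometric bound on the discarded tail
        b_top = rates.k_denovo + rates.k_fission * n_max
        d_top = rates.gamma * (n_max + 1) + rates.k_fusion * (n_max + 1) * n_max
        r = b_top / d_top
        tail = w[-1] * r / (1.0 - r) / total if r < 1 else math.inf
        if tail <= tail_tolerance:
            p = np.zeros(n_max + 1)
            p[n_start:] = w / total * (1.0 - tail)
            return AbundanceDistribution(p, float(tail))
        n_max *= 2
        if n_max > 10_000_000:
            raise ValueError(
                "truncation exceeded 1e7 states; rates may not be stationary"
            )
    raise ValueError("truncation did not converge; rates may not be stationary")


def percent_error(calculated_fano: float, simulated_fano: float) -> float:
    """Signed percent error of the closed-form Fano against simulation."""
    if simulated_fano <= 0:
        raise ValueError("simulated Fano must be > 0")
    return 100.0 * (calculated_fano - simulated_fano) / simulated_fano


def fano_sweep(
    k_fission_over_k_denovo,
    k_fusion_values,
    target_mean: float,
    *,
    k_denovo: float = 1.0,
) -> pd.DataFrame:
    """Closed-form Fano across a (fission/de novo ratio, fusion rate) grid.

    The decay rate is chosen at each grid point so the mean-field mean stays
    at ``target_mean``; fusion rates are in units of ``k_denovo``.  Grid
    points where no non-negative decay rate exists are flagged infeasible
    rather than dropped.
    """
    ratios = np.atleast_1d(np.asarray(k_fission_over_k_denovo, dtype=float))
    fusions = np.atleast_1d(np.asarray(k_fusion_values, dtype=float))
    if ratios.size == 0 or fusions.size == 0:
        raise ValueError("empty sweep grid")
    rows = []
    for kfus in fusions:
        for ratio in ratios:
            kfis = ratio * k_denovo
            row = {
                "ratio": ratio,
                "k_fusion": kfus,
                "mean": target_mean,
                "feasible": True,
                "gamma": np.nan,
                "fano": np.nan,
            }
            try:
                g = gamma_for_target_mean(k_denovo, kfis, kfus, target_mean)
                rc = RateConstants(k_denovo, kfis, kfus, g)
                row["gamma"] = g
                row["fano"] = fano_fdt(rc, target_mean)
            except ValueError:
                row["feasible"] = False
            rows.append(row)
    return pd.DataFrame(rows)


def percent_error_curve(
    rate_to_vary: str,
    grid,
    base_rates: RateConstants,
    sim_config,
    partition=None,
) -> pd.DataFrame:
    """Closed form vs simulation across a grid of one rate constant.

    For each grid value, runs endpoint Gillespie sampling, computes the
    simulated mean and Fano, evaluates the fluctuation-dissipation prediction
    at the *simulated* mean and reports the signed percent error.  Emulates
    the validation sweep in which de novo, fission or fusion rates tune the
    mean from ~1 to ~4.
    """
    from .simulate import sample_stationary  # local import avoids cycle

    valid = {"k_denovo", "k_fission", "k_fusion", "gamma"}
    if rate_to_vary not in valid:
        raise ValueError(f"rate_to_vary must be one of {sorted(valid)}")
    rows = []
    for value in np.atleast_1d(np.asarray(grid, dtype=float)):
        d = base_rates.to_dict()
        d[rate_to_vary] = float(value)
        rc = RateConstants.from_dict(d)
        sample = sample_stationary(rc, sim_config, partition)
        counts = np.asarray(sample.counts, dtype=float)
        mean = counts.mean()
        fano_sim = counts.var(ddof=1) / mean
        fano_calc = fano_fdt(rc, mean)
        rows.append(
            {
                "rate": rate_to_vary,
                "value": float(value),
                "mean": mean,
                "fano_simulated": fano_sim,
                "fano_calculated": fano_calc,
                "percent_error": percent_error(fano_calc, fano_sim),
            }
        )
    return pd.DataFrame(rows)
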