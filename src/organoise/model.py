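"""Model/Results front end.

Two objects organise the package the way statistical-modelling libraries do:

* :class:`OrganelleAbundanceModel` — the mechanistic four-process model,
  built from rate constants; simulation, stationary distributions and the
  fluctuation-dissipation Fano prediction hang off it.
* :class:`FanoModel` — built from single-cell count data; ``fit()`` returns a
  :class:`FanoResults` carrying the mean/Fano estimates, their bootstrap
  standard errors, percentile intervals, the regime call, and a ``summary()``
  table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import analytics, inference, simulate
from .inference import CountSample, RegimeCall, SummaryStats
from .rates import RateConstants, classify_regime, mean_field_steady_state

__all__ = ["OrganelleAbundanceModel", "FanoModel", "FanoResults"]


class OrganelleAbundanceModel:
    """Four-process stochastic model of organelle copy number.

    Parameters
    ----------
    rates : RateConstants or mapping
        The four rate constants (k_denovo, k_fission, k_fusion, gamma).
    """

    def __init__(self, rates):
        if not isinstance(rates, RateConstants):
            rates = RateConstants.from_dict(rates)
        self.rates = rates

    @property
    def regime(self):
        return classify_regime(self.rates)

    def mean_field_mean(self) -> float:
        return mean_field_steady_state(self.rates)

    def predicted_fano(self, mean: float | None = None) -> float:
        """Fluctuation-dissipation Fano factor at the stationary mean."""
        if mean is None:
            mean = self.stationary_distribution().mean
        return analytics.fano_fdt(self.rates, mean)

    def stationary_distribution(self, n_max: int | None = None):
        """Exact master-equation stationary law (product form)."""
        return analytics.cme_stationary(self.rates, n_max)

    def simulate(self, config: simulate.SimulationConfig, partition=None):
        """One event-resolved Gillespie trajectory."""
        return simulate.simulate_trajectory(self.rates, config, partition)

    def sample(self, config: simulate.SimulationConfig, partition=None) -> CountSample:
        """Endpoint stationary sample across independent replicates."""
        return simulate.sample_stationary(self.rates, config, partition)

    def __repr__(self) -> str:
        r = self.rates
        return (
            f"OrganelleAbundanceModel(k_denovo={r.k_denovo:g}, "
            f"k_fission={r.k_fission:g}, k_fusion={r.k_fusion:g}, "
            f"gamma={r.gamma:g}; regime={self.regime.label})"
        )


class FanoModel:
    """Fano-factor analysis of a single-cell organelle count sample."""

    def __init__(self, data, condition: str = "", marker: str = ""):
        if isinstance(data, CountSample):
            self.sample = data
        else:
            self.sample = CountSample(
                counts=np.asarray(data), condition=condition, marker=marker
            )

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        count_col: str = "count",
        condition: str = "",
        marker: str = "",
    ) -> "FanoModel":
        if count_col not in df.columns:
            raise ValueError(f"dataframe has no column {count_col!r}")
        condition = condition or (
            str(df["condition"].iloc[0]) if "condition" in df.columns else ""
        )
        marker = marker or (str(df["marker"].iloc[0]) if "marker" in df.columns else "")
        return cls(df[count_col].to_numpy(), condition=condition, marker=marker)

    def fit(self, bootstrap_reps: int = 1000, seed: int = 0) -> "FanoResults":
        stats = inference.bootstrap_uncertainty(self.sample, bootstrap_reps, seed)
        call = inference.classify_regime_from_counts(stats)
        return FanoResults(self, stats, call)


class FanoResults:
    """Fitted summary of a count sample: estimates, uncertainty, regime."""

    def __init__(self, model: FanoModel, stats: SummaryStats, regime: RegimeCall):
        self.model = model
        self.stats = stats
        self.regime = regime

    @property
    def mean(self) -> float:
        return self.stats.mean

    @property
    def fano(self) -> float:
        return self.stats.fano

    @property
    def se_mean(self) -> float:
        return self.stats.se_mean

    @property
    def se_fano(self) -> float:
        return self.stats.se_fano

    @property
    def conf_int_fano(self) -> tuple[float, float]:
        return self.stats.ci_fano

    def solve_k_denovo_ratio(self) -> float:
        """k_denovo/(k_fission <n>) under the decay-free (vacuole) model."""
        return inference.solve_k_denovo_ratio(self.stats.mean, self.stats.fano)

    def compare_to_reference(self, kind: str = "poisson", **kwargs):
        """Overlay the sample on a reference built from its own mean."""
        if kind == "poisson":
            ref = analytics.poisson_distribution(self.stats.mean)
        elif kind == "shifted_poisson":
            ref = analytics.shifted_poisson_distribution(max(self.stats.mean, 1.0))
        else:
            raise ValueError("kind must be 'poisson' or 'shifted_poisson'")
        return inference.compare_to_reference(self.model.sample, ref, **kwargs)

    def summary(self) -> str:
        s = self.stats
        sample = self.model.sample
        lines = [
            "Organelle abundance Fano analysis",
            "=" * 46,
            f"condition: {sample.condition or '-'}    marker: {sample.marker or '-'}",
            f"n_cells: {s.n_cells}    bootstrap reps: {s.bootstrap_reps} (seed {s.seed})",
            "-" * 46,
            f"mean abundance   {s.mean:8.3f}   SE {s.se_mean:7.3f}",
            f"variance         {s.variance:8.3f}",
            f"Fano factor      {s.fano:8.3f}   SE {s.se_fano:7.3f}",
            f"95% CI (Fano)    [{s.ci_fano[0]:.3f}, {s.ci_fano[1]:.3f}]",
            "-" * 46,
            f"regime call: {self.regime.call}",
            f"  {self.regime.rationale}",
        ]
        if s.n_degenerate_resamples:
            lines.append(
                f"note: {s.n_degenerate_resamples} degenerate (mean-0) resamples excluded"
            )
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (
            f"<FanoResults mean={self.mean:.3g} fano={self.fano:.3g} "
            f"regime={self.regime.call}>"
        )


def fano_report(samples: Sequence[CountSample], **kwargs) -> pd.DataFrame:
    """Convenience wrapper over :func:`inference.fano_vs_mean_report`."""
    return inference.fano_vs_mean_report(samples, **kwargs)
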