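"""Genetic trends, selection intensity and threshold-model interpretation.

The annual genetic improvement (AGI) of a breed is the OLS slope of its
yearly mean EBV on birth year.  Improvement totals are expressed as a
percentage of the phenotypic standard deviation.  The breeder's equation
R = i * sigma_p * h^2 / L back-calculates the realized selection intensity
i from an observed response per year; and a liability-threshold view maps
an observed dysplasia incidence onto a normal-distribution cutoff so that
a shift in the population mean translates into a new incidence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class TrendSummary:
    """AGI and total change for one breed (or pooled) and one trait."""

    breed: str
    trait: str
    agi: float
    agi_se: float
    intercept: float
    years: np.ndarray
    mean_ebv: np.ndarray

    @property
    def year_span(self) -> float:
        return float(self.years.max() - self.years.min())

    @property
    def total_change(self) -> float:
        """Total EBV change over the observed span implied by the slope."""
        return float(self.agi * self.year_span)


def genetic_trend(ebv, birth_years, breeds=None, trait: str = "",
                  year_range: tuple[int, int] | None = None,
                  per_dog: bool = False) -> dict[str, TrendSummary]:
    """Per-breed (plus pooled) regression of EBV on birth year.

    The default regresses the yearly mean EBV on year, matching how trend
    lines are plotted; ``per_dog`` weights each dog instead.  A breed with
    fewer than two distinct years is signalled.
    """
    ebv = np.asarray(ebv, dtype=float)
    years = np.asarray(birth_years, dtype=float)
    breeds = (np.asarray(breeds) if breeds is not None
              else np.repeat("all", len(ebv)))
    ok = np.isfinite(years) & np.isfinite(ebv)
    if year_range is not None:
        ok &= (years >= year_range[0]) & (years <= year_range[1])

    out: dict[str, TrendSummary] = {}
    labels = list(pd.unique(breeds[ok]))
    groups = [(str(b), ok & (breeds == b)) for b in labels]
    if len(labels) > 1:
        groups.append(("pooled", ok))
    for label, mask in groups:
        frame = pd.DataFrame({"year": years[mask], "ebv": ebv[mask]})
        if frame["year"].nunique() < 2:
            raise ValueError(f"breed {label!r} has fewer than 2 distinct "
                             "birth years; trend undefined")
        if per_dog:
            fit = stats.linregress(frame["year"], frame["ebv"])
            means = frame.groupby("year")["ebv"].mean()
        else:
            means = frame.groupby("year")["ebv"].mean()
            fit = stats.linregress(means.index.to_numpy(), means.to_numpy())
        out[label] = TrendSummary(
            breed=label, trait=trait, agi=float(fit.slope),
            agi_se=float(fit.stderr) if np.isfinite(fit.stderr) else 0.0,
            intercept=float(fit.intercept),
            years=means.index.to_numpy(), mean_ebv=means.to_numpy())
    return out


def trends_to_frame(trends: dict[str, TrendSummary]) -> pd.DataFrame:
    rows = [(t.breed, t.trait, t.agi, t.agi_se, t.year_span, t.total_change)
            for t in trends.values()]
    return pd.DataFrame(rows, columns=["breed", "trait", "agi", "agi_se",
                                       "year_span", "total_change"])


def improvement_as_sd_fraction(total_change: float,
                               phenotypic_variance: float) -> float:
    """|total EBV change| as a percentage of the phenotypic SD."""
    if phenotypic_variance <= 0:
        raise ValueError("phenotypic variance must be positive")
    return 100.0 * abs(total_change) / np.sqrt(phenotypic_variance)


@dataclass
class SelectionResponseInputs:
    """Inputs to the breeder's equation R = i sigma_p h2 / L."""

    response_per_year: float
    heritability: float
    phenotypic_sd: float
    generation_interval_years: float

    def __post_init__(self) -> None:
        if self.heritability <= 0 or self.phenotypic_sd <= 0 \
                or self.generation_interval_years <= 0:
            raise ValueError("heritability, sigma_p and L must be positive")


def selection_intensity(inputs: SelectionResponseInputs) -> float:
    """Realized selection intensity i = R L / (sigma_p h2)."""
    return (abs(inputs.response_per_year) * inputs.generation_interval_years
            / (inputs.phenotypic_sd * inputs.heritability))


def retained_proportion(intensity: float) -> float:
    """Proportion p retained under normal truncation with intensity i.

    Inverts i(p) = phi(z_p) / p with z_p the upper-tail cutoff of mass p.
    i = 0 maps to p = 1 (no selection).
    """
    if intensity < 0:
        raise ValueError("intensity must be nonnegative")
    if intensity == 0:
        return 1.0

    def gap(p):
        z = stats.norm.isf(p)
        return stats.norm.pdf(z) / p - intensity

    return float(optimize.brentq(gap, 1e-12, 1 - 1e-12))


def threshold_cutoff(mean: float, sd: float, incidence: float) -> float:
    """Liability cutoff whose upper-tail mass equals the incidence.

    cutoff = mean + sd * Phi^-1(1 - incidence).
    """
    if not 0 < incidence < 1:
        raise ValueError("incidence must lie in (0, 1)")
    if sd <= 0:
        raise ValueError("sd must be positive")
    return float(mean + sd * stats.norm.isf(incidence))


def shifted_incidence(cutoff: float, new_mean: float, sd: float) -> float:
    """Upper-tail mass above a fixed cutoff after the mean moves."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    return float(stats.norm.sf((cutoff - new_mean) / sd))


def plot_trend(trend: TrendSummary, phenotype_by_year: pd.Series | None = None,
               ax=None):
    """Yearly mean EBV (and optionally phenotype, on a twin axis) vs year."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(trend.years, trend.mean_ebv, "o-", color="tab:blue",
            label=f"EBV ({trend.trait})")
    ax.plot(trend.years, trend.intercept + trend.agi * trend.years, "--",
            color="tab:blue", alpha=0.6)
    ax.set_xlabel("birth year")
    ax.set_ylabel("mean EBV")
    if phenotype_by_year is not None:
        twin = ax.twinx()
        twin.plot(phenotype_by_year.index, phenotype_by_year.to_numpy(),
                  "s-", color="tab:red", alpha=0.7, label="phenotype")
        twin.set_ylabel("mean phenotype deviation")
    ax.set_title(f"{trend.breed}: AGI = {trend.agi:+.4f} / year")
    return ax
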