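"""Four-parameter logistic dose-response fitting and IC50 comparison.

The model is the standard 4PL

    f(d) = bottom + (top - bottom) / (1 + (d / ic50)^hill)

with ``ic50`` the inflection (relative EC50) concentration. Because cell
counts grow exponentially between treatment start and fixation, the package
fits drug plates on the *doublings* scale — log2 of the fold change over the
day-0 baseline — where the response is affine in the fractional
growth-rate inhibition; fitting raw counts instead confounds apparent
potency with the number of divisions during the assay (the rationale behind
growth-rate-corrected GR metrics). :func:`fit_4pl` itself is scale-agnostic
and fits whatever responses the series carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit


def four_pl(d, bottom, top, ic50, hill):
    """4PL response at dose ``d`` (d = 0 maps to ``top``)."""
    d = np.asarray(d, dtype=float)
    with np.errstate(divide="ignore"):
        ratio = np.where(d > 0, d / ic50, 0.0)
    return bottom + (top - bottom) / (1.0 + ratio**hill)


@dataclass
class DoseSeries:
    """One drug's dose-response data for one population.

    ``responses`` has shape (n_conditions, n_replicates); NaN marks missing
    replicates. Dose 0 rows are allowed and anchor the top plateau.
    """

    drug: str
    doses: np.ndarray
    responses: np.ndarray
    population: str = "positive"
    response_scale: str = "count"

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.atleast_2d(np.asarray(self.responses, dtype=float))
        if self.responses.shape[0] != self.doses.shape[0]:
            raise ValueError("responses must have one row per dose condition")
        if np.any(self.doses < 0):
            raise ValueError("doses must be >= 0")

    @property
    def means(self) -> np.ndarray:
        return np.nanmean(self.responses, axis=1)

    @property
    def sds(self) -> np.ndarray:
        if self.responses.shape[1] < 2:
            return np.full(self.responses.shape[0], np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanstd(self.responses, axis=1, ddof=1)

    def n_distinct_positive_doses(self) -> int:
        return len(np.unique(self.doses[self.doses > 0]))


@dataclass
class DRFit:
    """Result of a 4PL fit."""

    bottom: float = np.nan
    top: float = np.nan
    ic50: float = np.nan
    hill: float = np.nan
    converged: bool = False
    reason: str = ""
    rss: float = np.nan
    n: int = 0
    ci95: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    response_scale: str = "count"

    @property
    def span(self) -> float:
        """Fitted dynamic range top - bottom (response units)."""
        return self.top - self.bottom


def fit_4pl(series: DoseSeries, weights: str = "none") -> DRFit:
    """Least-squares 4PL fit of condition means.

    Initialisation: top = max mean, bottom = min mean, ic50 = geometric
    mid-dose, hill = 1. IC50 is bounded within [min dose / 10, max dose x
    10]. Failure to converge or a flat response returns ``converged=False``
    with a reason, never an exception.

    ``weights='sd'`` weights condition means by their replicate SD (used
    only when every SD is finite and nonzero). The default is unweighted:
    on the doublings scale the replicate variance is nearly constant across
    doses, and with quadruplicates the per-condition SD estimates are so
    noisy (3 degrees of freedom) that occasional near-zero values would
    dominate a weighted loss and distort the fit.
    """
    if series.n_distinct_positive_doses() < 4:
        return DRFit(
            converged=False,
            reason="fewer than 4 distinct positive doses",
            response_scale=series.response_scale,
        )
    doses = series.doses
    means = series.means
    ok = np.isfinite(means)
    doses, means = doses[ok], means[ok]
    if np.ptp(means) == 0:
        return DRFit(
            converged=False, reason="no dose effect",
            response_scale=series.response_scale,
        )

    if weights not in ("none", "sd"):
        raise ValueError(f"unknown weighting scheme {weights!r}")
    sds = series.sds[ok]
    use_weights = (
        weights == "sd" and np.all(np.isfinite(sds)) and np.all(sds > 0)
    )
    sigma = sds if use_weights else None

    pos = doses[doses > 0]
    log_mid = np.exp(np.mean(np.log(pos)))
    p0 = [float(means.min()), float(means.max()), float(log_mid), 1.0]
    lo = [-np.inf, -np.inf, pos.min() / 10.0, 0.05]
    hi = [np.inf, np.inf, pos.max() * 10.0, 20.0]
    try:
        popt, pcov = curve_fit(
            four_pl, doses, means, p0=p0, sigma=sigma, bounds=(lo, hi),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        return DRFit(
            converged=False, reason=f"optimizer failed: {exc}",
            response_scale=series.response_scale,
        )

    bottom, top, ic50, hill = (float(v) for v in popt)
    resid = means - four_pl(doses, *popt)
    rss = float(np.sum(resid**2))

    reason = ""
    converged = True
    if ic50 <= lo[2] * 1.01 or ic50 >= hi[2] * 0.99:
        converged = False
        reason = "ic50 pinned at dose-range boundary"
    if abs(top - bottom) < 1e-12:
        converged = False
        reason = "no dose effect"

    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    names = ("bottom", "top", "ic50", "hill")
    ci = {
        nm: (float(v - 1.96 * s), float(v + 1.96 * s))
        for nm, v, s in zip(names, popt, se)
    }
    return DRFit(
        bottom=bottom, top=top, ic50=ic50, hill=hill, converged=converged,
        reason=reason, rss=rss, n=int(len(means)), ci95=ci,
        response_scale=series.response_scale,
    )


def to_doublings(series: DoseSeries, baseline: float) -> DoseSeries:
    """Transform counts to log2 fold of the day-0 baseline (doublings)."""
    if not baseline > 0:
        raise ValueError("baseline must be > 0")
    resp = np.log2(np.clip(series.responses, 0.5, None) / baseline)
    return DoseSeries(
        drug=series.drug, doses=series.doses, responses=resp,
        population=series.population, response_scale="doublings",
    )


def fit_dose_response(series: DoseSeries, baseline: float | None = None) -> DRFit:
    """Fit the 4PL on the doublings scale (IC50 free of division-number bias).

    ``baseline`` is the day-0 count of the same population; when the series
    already carries a non-count scale it is fitted as-is.
    """
    if series.response_scale == "count":
        if baseline is None:
            raise ValueError("day-0 baseline required to fit a count series")
        series = to_doublings(series, baseline)
    return fit_4pl(series)


def ic50_fold_ratio(fit_a: DRFit, fit_b: DRFit) -> float:
    """IC50 fold difference ic50_a / ic50_b between two converged fits."""
    if not (fit_a.converged and fit_b.converged):
        raise ValueError("fold ratio requires two converged fits")
    return fit_a.ic50 / fit_b.ic50


def series_from_counts(
    df: pd.DataFrame, drug: str, population: str = "positive"
) -> DoseSeries:
    """Build a DoseSeries from a screen table (plate map joined with counts).

    ``population`` selects the response column: ``positive`` -> n_positive,
    ``negative`` -> n_negative, ``bulk`` -> n_total.
    """
    col = {
        "positive": "n_positive",
        "negative": "n_negative",
        "bulk": "n_total",
    }[population]
    sub = df[(df["drug"] == drug) & (df["plate_role"] == "drug")]
    if sub.empty:
        raise ValueError(f"no drug-plate wells for drug {drug!r}")
    wide = sub.pivot_table(
        index="dose_nM", columns="replicate", values=col, aggfunc="mean"
    ).sort_index()
    return DoseSeries(
        drug=drug,
        doses=wide.index.to_numpy(),
        responses=wide.to_numpy(),
        population=population,
    )


def bulk_surrogate(
    df: pd.DataFrame, drug: str, weights: Mapping[str, float] | None = None
) -> DoseSeries:
    """Bulk-viability surrogate series: weighted sum over all cells.

    Emulates an ATP-luminescence readout that cannot distinguish
    subpopulations: per-well signal = w_pos * n_positive + w_neg *
    n_negative. ``weights`` must contain positive entries for ``positive``
    and ``negative``.
    """
    weights = dict(weights) if weights is not None else {"positive": 1.0, "negative": 1.0}
    for key in ("positive", "negative"):
        if key not in weights:
            raise ValueError(f"missing per-population weight {key!r}")
        if weights[key] <= 0:
            raise ValueError(f"weight {key!r} must be > 0")
    sub = df[(df["drug"] == drug) & (df["plate_role"] == "drug")].copy()
    if sub.empty:
        raise ValueError(f"no drug-plate wells for drug {drug!r}")
    sub["signal"] = (
        weights["positive"] * sub["n_positive"]
        + weights["negative"] * sub["n_negative"]
    )
    wide = sub.pivot_table(
        index="dose_nM", columns="replicate", values="signal", aggfunc="mean"
    ).sort_index()
    return DoseSeries(
        drug=drug, doses=wide.index.to_numpy(), responses=wide.to_numpy(),
        population="bulk",
    )


@dataclass(frozen=True)
class FlatnessCheck:
    """Linear trend of response vs log10 dose with its 95% CI."""

    slope: float
    ci_low: float
    ci_high: float

    @property
    def flat(self) -> bool:
        return self.ci_low <= 0.0 <= self.ci_high


def flatness_check(series: DoseSeries, baseline: float | None = None) -> FlatnessCheck:
    """Test whether a dose series is flat (slope CI covers zero).

    Used on the marker-negative population: a drug-insensitive stromal
    compartment should show no dose trend. Counts are transformed to the
    doublings scale first when a baseline is given.
    """
    if series.response_scale == "count" and baseline is not None:
        series = to_doublings(series, baseline)
    keep = series.doses > 0
    x = np.log10(series.doses[keep])
    y = series.means[keep]
    res = stats.linregress(x, y)
    # 95% CI via t quantile on the slope standard error
    tq = stats.t.ppf(0.975, len(x) - 2)
    return FlatnessCheck(
        slope=float(res.slope),
        ci_low=float(res.slope - tq * res.stderr),
        ci_high=float(res.slope + tq * res.stderr),
    )


def plot_fit(series: DoseSeries, fit: DRFit, ax=None):
    """Plot condition means +/- SD with the fitted curve (matplotlib)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pos = series.doses > 0
    ax.errorbar(
        series.doses[pos], series.means[pos], yerr=series.sds[pos],
        fmt="o", capsize=3, label=f"{series.drug} ({series.population})",
    )
    if fit.converged:
        grid = np.geomspace(series.doses[pos].min(), series.doses[pos].max(), 200)
        ax.plot(grid, four_pl(grid, fit.bottom, fit.top, fit.ic50, fit.hill))
        ax.axvline(fit.ic50, ls="--", lw=0.8, color="gray")
    ax.set_xscale("log")
    ax.set_xlabel("dose (nM)")
    ax.set_ylabel(series.response_scale)
    ax.legend()
    return ax
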