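"""Plate-level assay logic: layouts, baselines, growth endpoint, normalization.

The screen runs three plate roles fixed at different times: a day-0 plate
(fixed when treatment starts), growth plates (fixed serially to monitor the
untreated culture) and the drug plate (fixed once the cancer population has
at least quadrupled, i.e. roughly two doublings). Functions here operate on
the "screen table": the plate map joined 1:1 with per-well counts, columns
``well, plate_role, drug, dose_nM, replicate, media, t_hours, n_total,
n_positive, n_negative``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PLATE_MAP_COLUMNS = ["well", "plate_role", "drug", "dose_nM", "replicate", "media"]
PLATE_ROLES = {"day0", "growth", "drug"}
DEFAULT_FOLD_THRESHOLD = 4.0


def validate_plate_map(df: pd.DataFrame) -> pd.DataFrame:
    """Check a plate map for required columns and per-row consistency.

    Raises ValueError listing the missing columns or offending rows.
    """
    missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plate map missing required columns: {missing}")
    bad_role = df.index[~df["plate_role"].isin(PLATE_ROLES)].tolist()
    bad_dose = df.index[
        pd.to_numeric(df["dose_nM"], errors="coerce").isna()
        | (pd.to_numeric(df["dose_nM"], errors="coerce") < 0)
    ].tolist()
    problems = []
    if bad_role:
        problems.append(f"rows with unknown plate_role: {bad_role[:10]}")
    if bad_dose:
        problems.append(f"rows with missing/negative dose_nM: {bad_dose[:10]}")
    if (df["plate_role"] == "drug").any() and not (df["plate_role"] == "day0").any():
        problems.append("drug wells present but no matching day-0 wells")
    if problems:
        raise ValueError("malformed plate map: " + "; ".join(problems))
    out = df.copy()
    out["dose_nM"] = pd.to_numeric(out["dose_nM"])
    return out


@dataclass(frozen=True)
class Baseline:
    """Day-0 per-population counts: mean and dispersion across replicates."""

    n_positive: float
    n_negative: float
    sd_positive: float
    sd_negative: float
    n_wells: int

    @property
    def dispersion_defined(self) -> bool:
        return self.n_wells > 1


def baseline_counts(screen_df: pd.DataFrame) -> Baseline:
    """Mean day-0 counts across replicate wells (the day-0 'circles')."""
    day0 = screen_df[screen_df["plate_role"] == "day0"]
    if day0.empty:
        raise ValueError("no day-0 wells in screen table")
    n = len(day0)
    return Baseline(
        n_positive=float(day0["n_positive"].mean()),
        n_negative=float(day0["n_negative"].mean()),
        sd_positive=float(day0["n_positive"].std(ddof=1)) if n > 1 else float("nan"),
        sd_negative=float(day0["n_negative"].std(ddof=1)) if n > 1 else float("nan"),
        n_wells=n,
    )


@dataclass
class GrowthSeries:
    """Untreated-well cancer counts over time, with the day-0 baseline."""

    timepoints_h: np.ndarray
    n_positive: list[np.ndarray]  # replicate counts per timepoint
    baseline_positive: float

    def __post_init__(self) -> None:
        self.timepoints_h = np.asarray(self.timepoints_h, dtype=float)
        if len(self.timepoints_h) != len(self.n_positive):
            raise ValueError("one replicate array per timepoint required")
        if np.any(np.diff(self.timepoints_h) <= 0):
            raise ValueError("timepoints must be strictly increasing")


def growth_series(screen_df: pd.DataFrame, baseline: Baseline) -> GrowthSeries:
    """Assemble the untreated growth series from growth-plate wells."""
    growth = screen_df[
        (screen_df["plate_role"] == "growth") & (screen_df["dose_nM"] == 0)
    ]
    if growth.empty:
        raise ValueError("no untreated growth-plate wells in screen table")
    tps = np.sort(growth["t_hours"].unique())
    counts = [
        growth.loc[growth["t_hours"] == t, "n_positive"].to_numpy(dtype=float)
        for t in tps
    ]
    return GrowthSeries(tps, counts, baseline.n_positive)


@dataclass(frozen=True)
class EndpointDecision:
    reached: bool
    time_h: float  # NaN when not reached
    index: int  # -1 when not reached
    fold: float  # fold over baseline at the decision timepoint (or last)


def check_endpoint(
    series: GrowthSeries, fold_threshold: float = DEFAULT_FOLD_THRESHOLD
) -> EndpointDecision:
    """First timepoint at which the untreated cancer count has quadrupled.

    Compares the replicate-mean marker-positive count at each timepoint to
    ``fold_threshold`` x the day-0 baseline (default 4x, about two
    doublings). Returns "not reached" when no timepoint qualifies.
    """
    if not series.baseline_positive > 0:
        raise ValueError("baseline must be > 0 for the endpoint rule")
    means = np.array([np.mean(c) for c in series.n_positive])
    folds = means / series.baseline_positive
    hit = np.nonzero(folds >= fold_threshold)[0]
    if hit.size == 0:
        return EndpointDecision(False, float("nan"), -1, float(folds[-1]))
    i = int(hit[0])
    return EndpointDecision(True, float(series.timepoints_h[i]), i, float(folds[i]))


NORMALIZATION_MODES = {"percent_highest", "fold_of_day0"}


def normalize_response(
    screen_df: pd.DataFrame,
    mode: str = "percent_highest",
    baseline: Baseline | None = None,
) -> pd.DataFrame:
    """Normalize per-condition mean counts, separately per population.

    ``percent_highest`` divides each (drug, dose) condition mean by the
    maximum condition mean of the same drug and population, x100.
    ``fold_of_day0`` divides by the day-0 baseline of that population.
    Returns a tidy frame: drug, dose_nM, population, mean, sd, norm.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(f"unknown normalization mode {mode!r}")
    drug_df = screen_df[screen_df["plate_role"] == "drug"]
    if drug_df.empty:
        raise ValueError("no drug-plate wells to normalize")
    rows = []
    for pop, col in (("positive", "n_positive"), ("negative", "n_negative")):
        grouped = (
            drug_df.groupby(["drug", "dose_nM"])[col]
            .agg(["mean", "std"])
            .reset_index()
        )
        for drug, sub in grouped.groupby("drug"):
            if mode == "percent_highest":
                ref = sub["mean"].max()
                if not ref > 0:
                    raise ValueError(
                        f"all-zero counts for drug {drug!r} population {pop!r} "
                        "under percent_highest"
                    )
                norm = 100.0 * sub["mean"] / ref
            else:
                if baseline is None:
                    raise ValueError("fold_of_day0 requires a day-0 baseline")
                ref = baseline.n_positive if pop == "positive" else baseline.n_negative
                if not ref > 0:
                    raise ValueError(f"zero day-0 baseline for population {pop!r}")
                norm = sub["mean"] / ref
            out = sub.copy()
            out["population"] = pop
            out["norm"] = norm
            rows.append(out)
    res = pd.concat(rows, ignore_index=True)
    res = res.rename(columns={"std": "sd"})
    return res[["drug", "dose_nM", "population", "mean", "sd", "norm"]]
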