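"""End-to-end steps tying imaging, assay and dose-response together.

``quantify_plate`` walks a plate directory and produces the per-cell and
per-well tables; ``analyze_screen`` turns a screen table (plate map joined
with counts) into per-drug, per-population dose-response fits, IC50 fold
ratios, the growth endpoint report and the stromal-flatness check.
"""

from __future__ import annotations

import tempfile
from pathlib import Path

import pandas as pd

from . import io as pio
from .assay import (
    DEFAULT_FOLD_THRESHOLD,
    baseline_counts,
    check_endpoint,
    growth_series,
    normalize_response,
)
from .dose_response import (
    DRFit,
    bulk_surrogate,
    fit_dose_response,
    flatness_check,
    ic50_fold_ratio,
    series_from_counts,
)
from .imaging import SegmentationParams, quantify_well


def quantify_plate(
    plate_dir: str | Path, params: SegmentationParams | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify every well of a plate directory.

    Returns (well table, cell table); wells appear in plate-map order.
    """
    params = params or SegmentationParams()
    plate_map = pio.read_plate_map(plate_dir)
    counts = []
    cell_frames = []
    for well in plate_map["well"]:
        sites = pio.list_sites(plate_dir, well)
        if not sites:
            raise FileNotFoundError(f"no site images found for well {well}")
        fields = [pio.load_field(plate_dir, well, s) for s in sites]
        wc, cells = quantify_well(fields, params)
        counts.append(wc)
        cell_frames.append(cells)
    wells_df = pd.DataFrame(
        [
            {
                "well": c.well, "n_total": c.n_total, "n_positive": c.n_positive,
                "n_negative": c.n_negative, "n_sites": c.n_sites,
            }
            for c in counts
        ]
    )
    cells_df = (
        pd.concat(cell_frames, ignore_index=True)
        if cell_frames
        else pd.DataFrame()
    )
    return wells_df, cells_df


def _fit_payload(fit: DRFit) -> dict:
    return {
        "converged": bool(fit.converged),
        "reason": fit.reason,
        "bottom": float(fit.bottom),
        "top": float(fit.top),
        "ic50_nM": float(fit.ic50),
        "hill": float(fit.hill),
        "rss": float(fit.rss),
        "response_scale": fit.response_scale,
        "ci95": {k: list(v) for k, v in fit.ci95.items()},
    }


def analyze_screen(
    screen_df: pd.DataFrame,
    fold_threshold: float = DEFAULT_FOLD_THRESHOLD,
    normalization: str = "percent_highest",
    bulk_weights: dict[str, float] | None = None,
) -> dict:
    """Full downstream analysis of one quantified screen.

    For every drug with enough doses: 4PL fits (doublings scale) of the
    marker-positive population and the bulk surrogate, the flatness check of
    the marker-negative series, and normalized dose series. Adds pairwise
    IC50 fold ratios between converged positive-population fits and, when
    growth wells exist, the quadrupling-endpoint report. Drugs that cannot
    be fitted get a "not fittable" entry rather than an error.
    """
    base = baseline_counts(screen_df)
    results: dict = {
        "baseline": {
            "n_positive": base.n_positive,
            "n_negative": base.n_negative,
            "sd_positive": base.sd_positive,
            "sd_negative": base.sd_negative,
            "n_wells": base.n_wells,
        },
        "drugs": {},
        "fold_ratios": {},
    }

    drug_rows = screen_df[screen_df["plate_role"] == "drug"]
    drugs = [d for d in drug_rows["drug"].unique() if d != "none"]
    fits: dict[str, DRFit] = {}
    for drug in drugs:
        entry: dict = {}
        pos = series_from_counts(screen_df, drug, "positive")
        if pos.n_distinct_positive_doses() < 4:
            entry["status"] = "not fittable: fewer than 4 distinct doses"
            results["drugs"][drug] = entry
            continue
        entry["status"] = "fitted"
        fit_pos = fit_dose_response(pos, baseline=base.n_positive)
        entry["positive"] = _fit_payload(fit_pos)
        if fit_pos.converged:
            fits[drug] = fit_pos

        bulk = bulk_surrogate(screen_df, drug, bulk_weights)
        fit_bulk = fit_dose_response(
            bulk, baseline=base.n_positive + base.n_negative
        )
        entry["bulk"] = _fit_payload(fit_bulk)

        neg = series_from_counts(screen_df, drug, "negative")
        if base.n_negative > 0:
            flat = flatness_check(neg, baseline=base.n_negative)
            entry["negative_flatness"] = {
                "slope": flat.slope,
                "ci95": [flat.ci_low, flat.ci_high],
                "flat": bool(flat.flat),
            }
        results["drugs"][drug] = entry

    for a in fits:
        for b in fits:
            if a != b:
                results["fold_ratios"][f"{a}/{b}"] = ic50_fold_ratio(fits[a], fits[b])

    try:
        series = growth_series(screen_df, base)
        dec = check_endpoint(series, fold_threshold)
        results["endpoint"] = {
            "reached": dec.reached,
            "time_h": dec.time_h,
            "fold": dec.fold,
            "fold_threshold": fold_threshold,
        }
    except ValueError:
        results["endpoint"] = None

    norm = normalize_response(
        screen_df, normalization,
        baseline=base if normalization == "fold_of_day0" else None,
    )
    results["normalized"] = norm.to_dict(orient="records")
    return results


def simulate_and_fit(
    config,
    seg_params: SegmentationParams | None = None,
    workdir: str | Path | None = None,
    **analyze_kwargs,
) -> dict:
    """Render a synthetic plate, quantify the images and analyze the screen.

    The full in-silico experiment in one call: images are written to
    ``workdir`` (a throwaway temporary directory by default), pushed through
    segmentation and scoring, joined with the plate map and fitted.
    """
    from .synthetic import generate_plate

    if workdir is not None:
        result = generate_plate(config, workdir)
        wells, _ = quantify_plate(workdir, seg_params)
    else:
        with tempfile.TemporaryDirectory() as td:
            result = generate_plate(config, td)
            wells, _ = quantify_plate(td, seg_params)
    screen = pio.screen_table(result.plate_map, wells)
    return analyze_screen(screen, **analyze_kwargs)
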