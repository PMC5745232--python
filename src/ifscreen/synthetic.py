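"""Ground-truthed synthetic 384-well plates for the co-culture drug assay.

The generator stands in for the microscope: it simulates per-well population
dynamics under drug (exponential growth with multiplicative Hill inhibition
of the growth rate), places cells in the imaged area with population-specific
morphology, renders two co-registered fluorescence channels (pan-nuclear dye
and a cytoplasmic epithelial marker present only in marker-positive cells),
and emits TIFFs together with a plate map and per-cell / per-well ground
truth so every downstream stage can be checked against known truth.

Expected count model, per population::

    n(t) = n0 * 2**((t / Td) * g * (1 - E(dose)))            Td finite
    E(dose) = emax * dose**h / (dose**h + (ic50 * shift)**h)  if drug-sensitive
    E = 0                                                     otherwise

where ``g`` is the media growth multiplier and ``shift`` the media IC50
shift. Irradiated feeders (infinite doubling time) stay at ``n0`` regardless
of dose, time or media. An optional death-rate term lets curves fall below
the day-0 level (cytotoxic rather than cytostatic response). Observed counts
are Poisson-sampled around the expectation.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi

from .imaging import FieldImage

WELL_ROWS = "ABCDEFGHIJKLMNOP"
WELL_COLS = 24


def well_name(index: int) -> str:
    """Row-major well id on a 384-well plate (0 -> A1, 383 -> P24)."""
    if not 0 <= index < len(WELL_ROWS) * WELL_COLS:
        raise ValueError(f"well index {index} outside a 384-well plate")
    return f"{WELL_ROWS[index // WELL_COLS]}{index % WELL_COLS + 1}"


class PackingError(ValueError):
    """Requested cell density exceeds the placement packing limit."""


@dataclass
class Morphology:
    """Rendered cell geometry (pixel units).

    Nuclei are 2-D Gaussians; ``elongation`` is the major/minor axis ratio
    (area-preserving). ``cytoplasm_scale`` sets the cytoplasm radius as a
    multiple of the nucleus radius. ``size_effect_scale`` lets the nucleus
    diameter grow with the drug effect level (drugged epithelial cells swell).
    """

    nucleus_diameter_px: float = 10.0
    nucleus_diameter_sd: float = 1.0
    cytoplasm_scale: float = 1.6
    elongation: float = 1.0
    size_effect_scale: float = 0.0

    def __post_init__(self) -> None:
        if self.nucleus_diameter_px <= 0 or self.nucleus_diameter_sd < 0:
            raise ValueError("nucleus diameter must be positive, sd >= 0")
        if self.cytoplasm_scale <= 0 or self.elongation < 1.0:
            raise ValueError("cytoplasm_scale > 0 and elongation >= 1 required")


@dataclass
class PopulationParams:
    """One cell population in a well (cancer, tumor stroma, or feeders)."""

    name: str
    n0: float
    doubling_time_h: float = 48.0
    drug_sensitive: bool = False
    ic50_true: float = 100.0
    hill_true: float = 1.0
    emax_true: float = 1.0
    marker_positive: bool = False
    morphology: Morphology = field(default_factory=Morphology)
    death_rate_per_h: float = 0.0

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")
        if not (self.doubling_time_h > 0 or math.isinf(self.doubling_time_h)):
            raise ValueError("doubling_time_h must be positive or infinite")
        if not 0.0 <= self.emax_true <= 1.0:
            raise ValueError("emax_true must lie in [0, 1]")
        if self.ic50_true <= 0 or self.hill_true <= 0:
            raise ValueError("ic50_true and hill_true must be positive")
        if self.death_rate_per_h < 0:
            raise ValueError("death_rate_per_h must be >= 0")


@dataclass
class MediaScenario:
    """Growth-media condition: growth multipliers and a potency shift.

    ``growth_multiplier`` may be a scalar or a per-population mapping.
    ``ic50_shift`` multiplies every drug-sensitive population's IC50
    (growth-factor-rich media right-shift the dose-response; removing EGF and
    insulin restores it, i.e. shift 1).
    """

    name: str
    growth_multiplier: float | Mapping[str, float] = 1.0
    ic50_shift: float = 1.0

    def __post_init__(self) -> None:
        if self.ic50_shift <= 0:
            raise ValueError("ic50_shift must be > 0")
        gms = (
            self.growth_multiplier.values()
            if isinstance(self.growth_multiplier, Mapping)
            else [self.growth_multiplier]
        )
        if any(g <= 0 for g in gms):
            raise ValueError("growth multipliers must be > 0")

    def g(self, population: str) -> float:
        if isinstance(self.growth_multiplier, Mapping):
            return float(self.growth_multiplier.get(population, 1.0))
        return float(self.growth_multiplier)


R10 = MediaScenario("R10")
TCM = MediaScenario("TCM", growth_multiplier={"cancer": 1.25}, ic50_shift=3.0)
TCM_MINUS_E_I = MediaScenario(
    "TCM_minus_E_I", growth_multiplier={"cancer": 1.25}, ic50_shift=1.0
)
MEDIA = {m.name: m for m in (R10, TCM, TCM_MINUS_E_I)}


@dataclass
class OpticsParams:
    """Rendering model of the high-content imager."""

    image_size: tuple[int, int] = (512, 512)
    psf_sigma: float = 1.2
    background_level: float = 100.0
    noise_sd: float = 8.0
    marker_intensity: float = 600.0
    nuclear_intensity: float = 1200.0
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")
        if min(
            self.background_level,
            self.noise_sd,
            self.marker_intensity,
            self.nuclear_intensity,
        ) < 0:
            raise ValueError("intensities must be >= 0")

    @property
    def max_value(self) -> int:
        return 2**self.bit_depth - 1


def hill_effect(dose: float, ic50: float, hill: float, emax: float) -> float:
    """Fractional growth inhibition E(dose) of the Hill model."""
    if dose < 0:
        raise ValueError("dose must be >= 0")
    if dose == 0:
        return 0.0
    dh = dose**hill
    return emax * dh / (dh + ic50**hill)


def expected_count(
    pop: PopulationParams, dose: float, t: float, media: MediaScenario = R10
) -> float:
    """Deterministic expected cell count of one population at time ``t``."""
    if dose < 0:
        raise ValueError(f"dose must be >= 0, got {dose}")
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if pop.drug_sensitive:
        e = hill_effect(
            dose, pop.ic50_true * media.ic50_shift, pop.hill_true, pop.emax_true
        )
    else:
        e = 0.0
    if math.isinf(pop.doubling_time_h):
        return float(pop.n0)
    n = pop.n0 * 2.0 ** ((t / pop.doubling_time_h) * media.g(pop.name) * (1.0 - e))
    if pop.death_rate_per_h > 0:
        n *= math.exp(-pop.death_rate_per_h * e * t)
    return float(n)


def drug_effect(
    pop: PopulationParams, dose: float, media: MediaScenario = R10
) -> float:
    """Effect level E(dose) actually applied to a population (0 if insensitive)."""
    if not pop.drug_sensitive:
        return 0.0
    return hill_effect(
        dose, pop.ic50_true * media.ic50_shift, pop.hill_true, pop.emax_true
    )


@dataclass(frozen=True)
class PopulationCount:
    expected: float
    sampled: int


def simulate_well_counts(
    pops: Sequence[PopulationParams],
    dose: float,
    t: float,
    media: MediaScenario = R10,
    rng: np.random.Generator | int | None = None,
) -> dict[str, PopulationCount]:
    """Expected and Poisson-sampled counts per population for one well."""
    rng = np.random.default_rng(rng)
    out: dict[str, PopulationCount] = {}
    for pop in pops:
        mu = expected_count(pop, dose, t, media)
        out[pop.name] = PopulationCount(expected=mu, sampled=int(rng.poisson(mu)))
    return out


@dataclass(frozen=True)
class CellPlacement:
    """One cell dropped into the imaged area."""

    x: float
    y: float
    population: str
    marker_positive: bool
    sigma_major: float
    sigma_minor: float
    angle: float
    cytoplasm_radius: float

    @property
    def nucleus_radius(self) -> float:
        # radius of the circle with the same area as the 2-sigma ellipse
        return 2.0 * math.sqrt(self.sigma_major * self.sigma_minor)


MAX_AREA_FRACTION = 0.40  # nucleus-area packing limit of the placement model
MIN_SEP_FACTOR = 0.75  # minimum centre separation as fraction of r_i + r_j


def place_cells(
    counts: Mapping[str, int],
    pops: Mapping[str, PopulationParams],
    image_size: tuple[int, int],
    rng: np.random.Generator | int | None = None,
    effects: Mapping[str, float] | None = None,
    max_area_fraction: float = MAX_AREA_FRACTION,
    min_sep_factor: float = MIN_SEP_FACTOR,
) -> list[CellPlacement]:
    """Place the requested number of cells of each population in the field.

    Hard-core dart throwing: centres keep a minimum separation of
    ``min_sep_factor * (r_i + r_j)`` so nuclei may touch but never coincide,
    and every nucleus lies fully inside the frame. ``effects`` optionally maps
    population name to the drug-effect level E, scaling the nucleus diameter
    by ``1 + size_effect_scale * E``.

    Raises :class:`PackingError` when the requested nucleus area exceeds
    ``max_area_fraction`` of the frame or dart throwing saturates.
    """
    rng = np.random.default_rng(rng)
    effects = effects or {}
    h, w = image_size
    cells: list[tuple[str, bool, float, float, float, float]] = []
    for name, n in counts.items():
        if n < 0:
            raise ValueError(f"negative count for population {name!r}")
        if n == 0:
            continue
        pop = pops[name]
        m = pop.morphology
        scale = 1.0 + m.size_effect_scale * float(effects.get(name, 0.0))
        diam = rng.normal(m.nucleus_diameter_px * scale, m.nucleus_diameter_sd, n)
        diam = np.clip(diam, 0.3 * m.nucleus_diameter_px, None)
        sigma = diam / 4.0
        s_major = sigma * math.sqrt(m.elongation)
        s_minor = sigma / math.sqrt(m.elongation)
        angles = rng.uniform(0, np.pi, n)
        cyto_r = m.cytoplasm_scale * diam / 2.0
        for i in range(n):
            cells.append(
                (name, pop.marker_positive, s_major[i], s_minor[i], angles[i], cyto_r[i])
            )

    if not cells:
        return []

    # hard-core separation uses the major-axis extent so elongated nuclei
    # do not merge along their long axis; the area check uses the true area
    radii = np.array([2.0 * c[2] for c in cells])
    area_radii = np.array([2.0 * math.sqrt(c[2] * c[3]) for c in cells])
    area_fraction = float(np.sum(np.pi * area_radii**2) / (h * w))
    if area_fraction > max_area_fraction:
        raise PackingError(
            f"requested nucleus area fraction {area_fraction:.2f} exceeds the "
            f"packing limit {max_area_fraction:.2f} for a {h}x{w} field"
        )

    # grid-accelerated hard-core placement
    cell_px = max(4.0, 2.0 * radii.max())
    gx = int(np.ceil(w / cell_px))
    gy = int(np.ceil(h / cell_px))
    grid: dict[tuple[int, int], list[int]] = {}
    xs = np.empty(len(cells))
    ys = np.empty(len(cells))
    order = rng.permutation(len(cells))
    placed: list[int] = []
    for idx in order:
        r = radii[idx]
        margin = 2.0 * r + 1.0  # keep the rendered nucleus inside the frame
        if 2 * margin >= min(h, w):
            raise PackingError("cell larger than the imaged area")
        ok = False
        for _ in range(200):
            x = rng.uniform(margin, w - margin)
            y = rng.uniform(margin, h - margin)
            cx, cy = int(x / cell_px), int(y / cell_px)
            good = True
            for nx in range(max(0, cx - 1), min(gx, cx + 2)):
                for ny in range(max(0, cy - 1), min(gy, cy + 2)):
                    for j in grid.get((nx, ny), ()):
                        sep = min_sep_factor * (r + radii[j])
                        if (x - xs[j]) ** 2 + (y - ys[j]) ** 2 < sep**2:
                            good = False
                            break
                    if not good:
                        break
                if not good:
                    break
            if good:
                ok = True
                break
        if not ok:
            raise PackingError(
                f"dart throwing saturated after placing {len(placed)} of "
                f"{len(cells)} cells (packing limit {max_area_fraction:.2f})"
            )
        xs[idx], ys[idx] = x, y
        grid.setdefault((int(x / cell_px), int(y / cell_px)), []).append(idx)
        placed.append(idx)

    return [
        CellPlacement(
            x=float(xs[i]),
            y=float(ys[i]),
            population=cells[i][0],
            marker_positive=cells[i][1],
            sigma_major=float(cells[i][2]),
            sigma_minor=float(cells[i][3]),
            angle=float(cells[i][4]),
            cytoplasm_radius=float(cells[i][5]),
        )
        for i in sorted(placed)
    ]


def _paint_gaussian(
    img: np.ndarray, x: float, y: float, s_major: float, s_minor: float,
    angle: float, amplitude: float
) -> None:
    ext = int(np.ceil(3.5 * s_major)) + 1
    h, w = img.shape
    x0, x1 = max(0, int(x) - ext), min(w, int(x) + ext + 1)
    y0, y1 = max(0, int(y) - ext), min(h, int(y) + ext + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - x, yy - y
    ca, sa = math.cos(angle), math.sin(angle)
    u = ca * dx + sa * dy
    v = -sa * dx + ca * dy
    img[y0:y1, x0:x1] += amplitude * np.exp(
        -0.5 * ((u / s_major) ** 2 + (v / s_minor) ** 2)
    )


def _paint_cytoplasm(
    img: np.ndarray, x: float, y: float, radius: float, amplitude: float
) -> None:
    # flat-topped super-Gaussian disc: soft-edged whole-cell footprint
    ext = int(np.ceil(1.6 * radius)) + 1
    h, w = img.shape
    x0, x1 = max(0, int(x) - ext), min(w, int(x) + ext + 1)
    y0, y1 = max(0, int(y) - ext), min(h, int(y) + ext + 1)
    if x0 >= x1 or y0 >= y1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r2 = ((xx - x) ** 2 + (yy - y) ** 2) / radius**2
    img[y0:y1, x0:x1] += amplitude * np.exp(-(r2**2))


def render_field(
    placements: Sequence[CellPlacement],
    optics: OpticsParams,
    rng: np.random.Generator | int | None = None,
    well: str = "A1",
    site: int = 0,
    noiseless: bool = False,
) -> FieldImage:
    """Render the two-channel fluorescence image of one field.

    Channel 1 (nuclear): one blurred Gaussian spot per cell. Channel 2
    (marker): a soft-edged cytoplasmic disc around marker-positive cells
    only. Both channels share the point-spread blur, additive background and
    Gaussian read noise, and are clipped to the configured bit depth.
    """
    rng = np.random.default_rng(rng)
    h, w = optics.image_size
    nuc = np.zeros((h, w), dtype=np.float64)
    mark = np.zeros((h, w), dtype=np.float64)
    for p in placements:
        if not (0 <= p.x < w and 0 <= p.y < h):
            raise ValueError(f"placement at ({p.x:.1f}, {p.y:.1f}) outside bounds")
        brightness = float(rng.lognormal(mean=0.0, sigma=0.15))
        _paint_gaussian(
            nuc, p.x, p.y, p.sigma_major, p.sigma_minor, p.angle,
            optics.nuclear_intensity * brightness,
        )
        if p.marker_positive:
            _paint_cytoplasm(
                mark, p.x, p.y, p.cytoplasm_radius,
                optics.marker_intensity * float(rng.lognormal(0.0, 0.15)),
            )
    if optics.psf_sigma > 0:
        nuc = ndi.gaussian_filter(nuc, optics.psf_sigma)
        mark = ndi.gaussian_filter(mark, optics.psf_sigma)
    nuc += optics.background_level
    mark += optics.background_level
    if not noiseless and optics.noise_sd > 0:
        nuc += rng.normal(0.0, optics.noise_sd, nuc.shape)
        mark += rng.normal(0.0, optics.noise_sd, mark.shape)
    dtype = np.uint8 if optics.bit_depth == 8 else np.uint16
    nuc = np.clip(np.rint(nuc), 0, optics.max_value).astype(dtype)
    mark = np.clip(np.rint(mark), 0, optics.max_value).astype(dtype)
    return FieldImage(
        well=well, site=site, channel_nuclear=nuc, channel_marker=mark,
        bit_depth=optics.bit_depth,
    )


@dataclass(frozen=True)
class HillParams:
    """Per-drug ground-truth potency for a population."""

    ic50: float
    hill: float = 1.0
    emax: float = 1.0


def dilution_series(top: float, factor: float = 3.0, n: int = 12) -> tuple[float, ...]:
    """Descending n-point serial dilution from ``top`` (nM)."""
    return tuple(top / factor**i for i in range(n))


@dataclass
class DrugLayout:
    """One drug's dose block on the drug plate."""

    name: str
    doses: tuple[float, ...] = field(default_factory=lambda: dilution_series(10000.0))
    n_replicates: int = 4
    n_controls: int = 4
    sensitivity: Mapping[str, HillParams] | None = None

    def __post_init__(self) -> None:
        if not self.doses:
            raise ValueError(f"drug {self.name!r}: dose list is empty")
        if any(d <= 0 for d in self.doses):
            raise ValueError(f"drug {self.name!r}: treated doses must be > 0")

    def populations_for(
        self, pops: Sequence[PopulationParams]
    ) -> list[PopulationParams]:
        """Populations with this drug's ground truth substituted in."""
        if self.sensitivity is None:
            return list(pops)
        out = []
        for p in pops:
            hp = self.sensitivity.get(p.name)
            if hp is None:
                out.append(dataclasses.replace(p, drug_sensitive=False))
            else:
                out.append(
                    dataclasses.replace(
                        p,
                        drug_sensitive=True,
                        ic50_true=hp.ic50,
                        hill_true=hp.hill,
                        emax_true=hp.emax,
                    )
                )
        return out


@dataclass
class PlateConfig:
    """Full recipe for one synthetic plate set (day-0 / growth / drug wells)."""

    populations: list[PopulationParams]
    drugs: list[DrugLayout]
    media: MediaScenario = field(default_factory=lambda: R10)
    optics: OpticsParams = field(default_factory=OpticsParams)
    t_end_h: float = 96.0
    n_day0_wells: int = 4
    growth_timepoints_h: tuple[float, ...] = ()
    n_growth_replicates: int = 2
    sites_per_well: int = 1
    seed: int = 0

    def layout(self) -> pd.DataFrame:
        """Plate map: one row per well with role, drug, dose and timepoint."""
        rows = []
        idx = 0

        def add(role, drug, dose, rep, t):
            nonlocal idx
            rows.append(
                {
                    "well": well_name(idx),
                    "plate_role": role,
                    "drug": drug,
                    "dose_nM": dose,
                    "replicate": rep,
                    "media": self.media.name,
                    "t_hours": t,
                }
            )
            idx += 1

        for r in range(self.n_day0_wells):
            add("day0", "none", 0.0, r, 0.0)
        for t in self.growth_timepoints_h:
            for r in range(self.n_growth_replicates):
                add("growth", "none", 0.0, r, float(t))
        for drug in self.drugs:
            for r in range(drug.n_controls):
                add("drug", drug.name, 0.0, r, self.t_end_h)
            for dose in drug.doses:
                for r in range(drug.n_replicates):
                    add("drug", drug.name, float(dose), r, self.t_end_h)
        return pd.DataFrame(rows)


@dataclass
class PlateResult:
    """Paths and in-memory tables produced by :func:`generate_plate`."""

    directory: Path
    plate_map: pd.DataFrame
    ground_truth_wells: pd.DataFrame
    ground_truth_cells: pd.DataFrame


def generate_plate(config: PlateConfig, out_dir: str | Path) -> PlateResult:
    """Simulate, render and write a full plate to ``out_dir``.

    Writes ``images/{well}_{site}_{channel}.tif`` for both channels,
    ``plate_map.csv``, ``ground_truth_wells.csv`` (per-well expected and
    sampled counts per population) and ``ground_truth_cells.csv`` (per-cell
    placements). Identical config + seed reproduce identical outputs.
    """
    import tifffile

    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    layout = config.layout()
    drug_by_name = {d.name: d for d in config.drugs}
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(layout))

    gt_wells = []
    gt_cells = []
    pops_by_name = {p.name: p for p in config.populations}
    for (_, row), child in zip(layout.iterrows(), children):
        rng = np.random.default_rng(child)
        if row.drug != "none" and row.drug in drug_by_name:
            pops = drug_by_name[row.drug].populations_for(config.populations)
        else:
            pops = config.populations
        sim = simulate_well_counts(
            pops, row.dose_nM, row.t_hours, config.media, rng
        )
        for pop in pops:
            gt_wells.append(
                {
                    "well": row.well,
                    "t_hours": row.t_hours,
                    "population": pop.name,
                    "expected": sim[pop.name].expected,
                    "sampled": sim[pop.name].sampled,
                }
            )
        effects = {
            p.name: drug_effect(p, row.dose_nM, config.media) for p in pops
        }
        counts = {p.name: sim[p.name].sampled for p in pops}
        # split cells across imaging sites
        site_counts = _split_sites(counts, config.sites_per_well, rng)
        for site in range(config.sites_per_well):
            placements = place_cells(
                site_counts[site],
                {p.name: p for p in pops},
                config.optics.image_size,
                rng,
                effects=effects,
            )
            fimg = render_field(
                placements, config.optics, rng, well=row.well, site=site
            )
            tifffile.imwrite(
                img_dir / f"{row.well}_{site}_nuclear.tif", fimg.channel_nuclear
            )
            tifffile.imwrite(
                img_dir / f"{row.well}_{site}_marker.tif", fimg.channel_marker
            )
            for p in placements:
                gt_cells.append(
                    {
                        "well": row.well,
                        "site": site,
                        "population": p.population,
                        "x": p.x,
                        "y": p.y,
                        "marker_positive": p.marker_positive,
                    }
                )

    gt_wells_df = pd.DataFrame(gt_wells)
    gt_cells_df = pd.DataFrame(
        gt_cells, columns=["well", "site", "population", "x", "y", "marker_positive"]
    )
    layout.to_csv(out_dir / "plate_map.csv", index=False)
    gt_wells_df.to_csv(out_dir / "ground_truth_wells.csv", index=False)
    gt_cells_df.to_csv(out_dir / "ground_truth_cells.csv", index=False)
    return PlateResult(out_dir, layout, gt_wells_df, gt_cells_df)


def _split_sites(
    counts: Mapping[str, int], n_sites: int, rng: np.random.Generator
) -> list[dict[str, int]]:
    if n_sites == 1:
        return [dict(counts)]
    out: list[dict[str, int]] = [dict() for _ in range(n_sites)]
    for name, n in counts.items():
        split = rng.multinomial(n, np.full(n_sites, 1.0 / n_sites))
        for s in range(n_sites):
            out[s][name] = int(split[s])
    return out


# --- canned scenarios ------------------------------------------------------

SCENARIO_OPTICS = OpticsParams(image_size=(768, 768))


def cancer_population(
    n0: float = 250.0,
    doubling_time_h: float = 48.0,
    ic50: float = 100.0,
    hill: float = 1.0,
    emax: float = 1.0,
) -> PopulationParams:
    """Marker-positive epithelial cancer population (default conditions)."""
    return PopulationParams(
        name="cancer",
        n0=n0,
        doubling_time_h=doubling_time_h,
        drug_sensitive=True,
        ic50_true=ic50,
        hill_true=hill,
        emax_true=emax,
        marker_positive=True,
        morphology=Morphology(size_effect_scale=0.3),
    )


def feeder_population(n0: float = 500.0) -> PopulationParams:
    """Irradiated (non-dividing) feeder fibroblasts: marker-negative."""
    return PopulationParams(
        name="feeder",
        n0=n0,
        doubling_time_h=math.inf,
        drug_sensitive=False,
        marker_positive=False,
        morphology=Morphology(nucleus_diameter_px=10.0, elongation=3.0),
    )


def fibroblast_population(
    n0: float = 250.0, doubling_time_h: float = 60.0
) -> PopulationParams:
    """Proliferating tumor-derived stromal fibroblasts: drug-insensitive."""
    return PopulationParams(
        name="fibroblast",
        n0=n0,
        doubling_time_h=doubling_time_h,
        drug_sensitive=False,
        marker_positive=False,
        morphology=Morphology(nucleus_diameter_px=10.0, elongation=3.0),
    )


def _alk_scenario(drug_truths: dict[str, float], seed: int) -> PlateConfig:
    drugs = [
        DrugLayout(name=d, sensitivity={"cancer": HillParams(ic50=ic)})
        for d, ic in drug_truths.items()
    ]
    return PlateConfig(
        populations=[cancer_population(), feeder_population()],
        drugs=drugs,
        media=TCM_MINUS_E_I,
        optics=SCENARIO_OPTICS,
        t_end_h=96.0,
        seed=seed,
    )


def scenario(name: str, seed: int = 0) -> PlateConfig:
    """Canned plate configurations.

    ``alk_mut``: crizotinib-resistant culture with secondary kinase-domain
    mutations — sensitive to the second-generation inhibitor (ceritinib IC50
    90 nM) but not the first (crizotinib 1300 nM). ``alk_wt``: no kinase
    mutation — both inhibitors potent (53 / 60 nM). ``alk_g1202del``: only
    the third-generation inhibitor retains potency (lorlatinib 2 nM vs
    crizotinib 166 and ceritinib 268 nM). ``pure`` / ``mixed``: a single
    drugged epithelial culture without / with proliferating insensitive
    fibroblasts, for bulk-readout comparisons. ``default``: small
    single-drug co-culture plate.
    """
    scenarios = {
        "alk_mut": {"ceritinib": 90.0, "crizotinib": 1300.0},
        "alk_wt": {"ceritinib": 53.0, "crizotinib": 60.0},
        "alk_g1202del": {
            "lorlatinib": 2.0,
            "crizotinib": 166.0,
            "ceritinib": 268.0,
        },
    }
    if name in scenarios:
        return _alk_scenario(scenarios[name], seed)
    if name == "pure":
        return PlateConfig(
            populations=[cancer_population(ic50=100.0)],
            drugs=[DrugLayout(name="drugA")],
            optics=SCENARIO_OPTICS,
            seed=seed,
        )
    if name == "mixed":
        return PlateConfig(
            populations=[cancer_population(ic50=100.0), fibroblast_population(250.0)],
            drugs=[DrugLayout(name="drugA")],
            optics=SCENARIO_OPTICS,
            seed=seed,
        )
    if name == "tiny":
        # desk-scale smoke plate: small wells, few doses, small images
        return PlateConfig(
            populations=[
                cancer_population(n0=40.0, ic50=50.0),
                feeder_population(n0=30.0),
            ],
            drugs=[
                DrugLayout(
                    name="drugA",
                    doses=dilution_series(1000.0, factor=4.0, n=6),
                    n_replicates=2,
                    n_controls=2,
                    sensitivity={"cancer": HillParams(50.0)},
                )
            ],
            optics=OpticsParams(image_size=(256, 256)),
            n_day0_wells=2,
            growth_timepoints_h=(48.0, 96.0),
            n_growth_replicates=1,
            seed=seed,
        )
    if name == "default":
        return PlateConfig(
            populations=[cancer_population(), feeder_population()],
            drugs=[DrugLayout(name="drugA", sensitivity={"cancer": HillParams(100.0)})],
            optics=SCENARIO_OPTICS,
            growth_timepoints_h=(24.0, 48.0, 72.0, 96.0, 120.0),
            seed=seed,
        )
    raise KeyError(f"unknown scenario {name!r}")
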