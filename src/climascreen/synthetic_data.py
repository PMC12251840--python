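"""Virtual landscapes and virtual species with known tolerance structure.

Every downstream stage (thinning, extraction, statistics, clustering,
thresholding) is exercised against data whose truth is known: smooth
climate surfaces with a latitudinal gradient, and species whose
occurrences are drawn from a bivariate Gaussian suitability over the
landscape's climate values.  A configurable number of "planted" species
have their niche center strictly below the landscape's lower quartile of
the matching variable — these are the candidates a correct screening must
recover.

Default surfaces emulate a subtropical monsoon domain: MTCM falls
latitudinally from ~10 °C at 18° N to −6 °C at 34° N, while PDQ rises
longitudinally from ~40 mm in the continental west (98° E) to ~170 mm in
the maritime east (122° E), each with smooth local noise (15 mm / 1.5 °C
standard deviation, 3-cell correlation length).  The two gradients are
deliberately orthogonal: were both variables driven by latitude the
landscape's climate space would collapse onto a line and a niche center
off that line (dry but mild, say) could not be realized anywhere, so
planted tolerance structure would be unrecoverable by construction.
Per-species sampling intensity is uneven by default (log-normal, clipped
to 10–120 records) to mimic collection bias.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

from .climate_raster import ClimateGrid
from .occurrence_io import OccurrenceRecord

_VAR_INDEX = {"PDQ": 0, "MTCM": 1}


@dataclass(frozen=True)
class SurfaceConfig:
    """Parameters of one synthetic climate surface.

    The deterministic part is
    value = base + gradient * latitude + lon_gradient * longitude
    (units of the variable, gradients per degree); smooth noise is white
    noise convolved with a Gaussian kernel of ``noise_corr_cells`` cells,
    rescaled to standard deviation ``noise_amp``.
    """

    lat_min: float = 18.0
    lat_max: float = 34.0
    lon_min: float = 98.0
    lon_max: float = 122.0
    cell_size: float = 0.25  # degrees
    base: float = 0.0
    gradient: float = 0.0  # per degree latitude
    lon_gradient: float = 0.0  # per degree longitude
    noise_amp: float = 0.0
    noise_corr_cells: float = 3.0
    nodata_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.lat_max > self.lat_min and self.lon_max > self.lon_min):
            raise ValueError("degenerate extent")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")
        if not 0.0 <= self.nodata_fraction <= 1.0:
            raise ValueError("nodata_fraction outside [0, 1]")


def default_surface_config(variable: str, seed: int = 0, **overrides) -> SurfaceConfig:
    """Study-condition defaults per variable (see module docstring)."""
    if variable == "PDQ":
        params = dict(base=-499.0, lon_gradient=5.5, noise_amp=15.0)
    elif variable == "MTCM":
        params = dict(base=28.0, gradient=-1.0, noise_amp=1.5)
    else:
        raise ValueError(f"unknown variable {variable!r}")
    params.update(overrides)
    return SurfaceConfig(seed=seed, **params)


@dataclass(frozen=True)
class VirtualSpecies:
    """A species with a bivariate Gaussian climatic niche."""

    name: str
    mu_pdq: float  # niche center, mm
    mu_mtcm: float  # niche center, °C
    sigma_pdq: float  # niche breadth, mm
    sigma_mtcm: float  # niche breadth, °C
    planted_drought: bool
    planted_cold: bool
    n_occurrences: int

    def __post_init__(self) -> None:
        if self.sigma_pdq <= 0 or self.sigma_mtcm <= 0:
            raise ValueError("niche breadths must be positive")
        if self.n_occurrences < 0:
            raise ValueError("n_occurrences must be >= 0")


def gen_climate_grid(config: SurfaceConfig, variable: str) -> ClimateGrid:
    """Deterministic synthetic surface: base + gradient·lat + smooth noise,
    with ``nodata_fraction`` of cells masked."""
    n_rows = int(round((config.lat_max - config.lat_min) / config.cell_size))
    n_cols = int(round((config.lon_max - config.lon_min) / config.cell_size))
    if n_rows < 1 or n_cols < 1:
        raise ValueError("extent smaller than one cell")
    lat_centers = config.lat_max - (np.arange(n_rows) + 0.5) * config.cell_size
    lon_centers = config.lon_min + (np.arange(n_cols) + 0.5) * config.cell_size
    values = (
        config.base
        + config.gradient * lat_centers[:, None]
        + config.lon_gradient * lon_centers[None, :]
    )

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, _VAR_INDEX[variable]]))
    if config.noise_amp > 0:
        white = rng.standard_normal((n_rows, n_cols))
        smooth = gaussian_filter(white, sigma=config.noise_corr_cells, mode="reflect")
        sd = smooth.std()
        if sd > 0:
            values = values + config.noise_amp * smooth / sd
    n_nodata = int(round(config.nodata_fraction * n_rows * n_cols))
    if n_nodata:
        flat = rng.choice(n_rows * n_cols, size=n_nodata, replace=False)
        values = values.copy()
        values.ravel()[flat] = np.nan
    return ClimateGrid(
        variable=variable,
        values=values,
        x_ll=config.lon_min,
        y_ll=config.lat_min,
        cell_size=config.cell_size,
    )


def _valid_cells(pdq_grid: ClimateGrid, mtcm_grid: ClimateGrid):
    """Row/col indices and values of cells valid in both grids."""
    if pdq_grid.values.shape != mtcm_grid.values.shape:
        raise ValueError("grids must share one geometry")
    mask = ~np.isnan(pdq_grid.values) & ~np.isnan(mtcm_grid.values)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        raise ValueError("no cell is valid in both grids")
    return rows, cols, pdq_grid.values[rows, cols], mtcm_grid.values[rows, cols]


def gen_species_pool(
    n_species: int,
    n_planted_drought: int,
    n_planted_cold: int,
    pdq_grid: ClimateGrid,
    mtcm_grid: ClimateGrid,
    seed: int = 0,
    sigma_pdq: float = 12.0,
    sigma_mtcm: float = 1.2,
    n_occurrences: Optional[int] = None,
) -> list[VirtualSpecies]:
    """Draw a pool with exact planted counts per variable.

    Planted-drought species get a PDQ niche center uniform on
    (landscape min, landscape Q25), strictly below the lower quartile;
    planted-cold species likewise on the MTCM axis.  All other centers
    sit in the landscape interquartile range.  The planted-drought and
    planted-cold subsets are disjoint, so the per-variable counts are
    exact by construction.  ``n_occurrences=None`` draws uneven
    per-species sampling (log-normal around ~25, clipped to [10, 120]).
    """
    if n_planted_drought + n_planted_cold > n_species:
        raise ValueError("planted counts exceed pool size")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    _, _, vp, vt = _valid_cells(pdq_grid, mtcm_grid)
    p_lo, p25, p75 = np.quantile(vp, [0.0, 0.25, 0.75])
    t_lo, t25, t75 = np.quantile(vt, [0.0, 0.25, 0.75])

    def below(lo: float, q25: float) -> float:
        mu = rng.uniform(lo, q25)
        while not mu < q25:  # guard the measure-zero boundary draw
            mu = rng.uniform(lo, q25)
        return float(mu)

    width = len(str(max(n_species, 1)))
    pool: list[VirtualSpecies] = []
    for i in range(n_species):
        drought = i < n_planted_drought
        cold = n_planted_drought <= i < n_planted_drought + n_planted_cold
        mu_p = below(p_lo, p25) if drought else float(rng.uniform(p25, p75))
        mu_t = below(t_lo, t25) if cold else float(rng.uniform(t25, t75))
        if n_occurrences is None:
            n_occ = int(np.clip(round(rng.lognormal(mean=np.log(25.0), sigma=0.45)), 10, 120))
        else:
            n_occ = n_occurrences
        pool.append(
            VirtualSpecies(
                name=f"species_{i + 1:0{width}d}",
                mu_pdq=mu_p,
                mu_mtcm=mu_t,
                sigma_pdq=sigma_pdq,
                sigma_mtcm=sigma_mtcm,
                planted_drought=drought,
                planted_cold=cold,
                n_occurrences=n_occ,
            )
        )
    return pool


def suitability_weights(
    species: VirtualSpecies, pdq_values: np.ndarray, mtcm_values: np.ndarray
) -> np.ndarray:
    """Unnormalized bivariate Gaussian suitability of each cell."""
    zp = (pdq_values - species.mu_pdq) / species.sigma_pdq
    zt = (mtcm_values - species.mu_mtcm) / species.sigma_mtcm
    return np.exp(-0.5 * (zp**2 + zt**2))


def gen_occurrences(
    species: VirtualSpecies,
    pdq_grid: ClimateGrid,
    mtcm_grid: ClimateGrid,
    seed: int = 0,
) -> list[OccurrenceRecord]:
    """Sample occurrence points cell-weighted by niche suitability.

    Cells are drawn with probability proportional to the species'
    suitability at the cell's climate values; the point is then placed
    uniformly inside the chosen cell (so it always extracts back to that
    cell).  Raises if total suitability underflows to zero — the niche
    lies outside the landscape's climate range.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    rows, cols, vp, vt = _valid_cells(pdq_grid, mtcm_grid)
    w = suitability_weights(species, vp, vt)
    total = w.sum()
    if total <= 0:
        raise ValueError(f"{species.name}: niche outside landscape climate range")
    idx = rng.choice(rows.size, size=species.n_occurrences, p=w / total)
    cs = pdq_grid.cell_size
    u_lon = rng.uniform(0.0, cs, size=species.n_occurrences)
    u_lat = rng.uniform(0.0, cs, size=species.n_occurrences)
    out = []
    for j, (i_cell, du, dv) in enumerate(zip(idx, u_lon, u_lat)):
        r, c = rows[i_cell], cols[i_cell]
        lon = pdq_grid.x_ll + c * cs + du
        lat = pdq_grid.y_ll + (pdq_grid.n_rows - 1 - r) * cs + dv
        out.append(
            OccurrenceRecord(
                species=species.name, lat=float(lat), lon=float(lon),
                record_id=f"{species.name}_{j + 1}",
            )
        )
    return out


@dataclass
class SyntheticDataset:
    pdq_grid: ClimateGrid
    mtcm_grid: ClimateGrid
    pool: list[VirtualSpecies]
    occurrences: list[OccurrenceRecord]


def gen_dataset(
    n_species: int = 35,
    n_planted_drought: int = 9,
    n_planted_cold: int = 9,
    seed: int = 0,
    n_occurrences: Optional[int] = None,
    sigma_pdq: float = 12.0,
    sigma_mtcm: float = 1.2,
    surface_overrides: Optional[dict] = None,
) -> SyntheticDataset:
    """One full virtual study: two surfaces, a species pool, occurrences."""
    ov = surface_overrides or {}
    pdq = gen_climate_grid(default_surface_config("PDQ", seed=seed, **ov), "PDQ")
    mtcm = gen_climate_grid(default_surface_config("MTCM", seed=seed, **ov), "MTCM")
    pool = gen_species_pool(
        n_species, n_planted_drought, n_planted_cold, pdq, mtcm,
        seed=seed, sigma_pdq=sigma_pdq, sigma_mtcm=sigma_mtcm,
        n_occurrences=n_occurrences,
    )
    occ: list[OccurrenceRecord] = []
    for i, sp in enumerate(pool):
        occ.extend(gen_occurrences(sp, pdq, mtcm, seed=seed * 100003 + i))
    return SyntheticDataset(pdq, mtcm, pool, occ)


def write_manifest(pool: Sequence[VirtualSpecies], path: str | Path) -> None:
    """JSON manifest of the true niche parameters, for recovery tests."""
    Path(path).write_text(json.dumps([asdict(sp) for sp in pool], indent=1))


def read_manifest(path: str | Path) -> list[VirtualSpecies]:
    return [VirtualSpecies(**d) for d in json.loads(Path(path).read_text())]
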