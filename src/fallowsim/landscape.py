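"""Synthetic raster landscapes for the enrollment simulator.

A landscape bundle holds co-registered rasters on a regular grid of square
cells (30 m by default): land-use codes, a farm-parcel partition, slope,
Euclidean distance to the nearest water and forest cell, a soil rental
rate surface (the annual payment basis, $/acre/yr) and six correlated
environmental-benefit-index (EBI) composites on the 50-350 point scale.

The generator emulates the structure of a real agricultural study region —
contiguous water and forest patches, a Voronoi parcel mosaic, smooth
spatially autocorrelated fields — without reproducing any particular
geography.  Every bundle is a deterministic function of (config, seed).

EBI composites follow a shared-component construction: each of the six
layers is a weighted sum of one of three N1 variants, one of two N2
variants and a common N3 field (3 x 2 x 1 = 6 combinations), all
standardized; sharing components gives the layers moderate-to-high
positive pairwise correlation, steerable through the component weights.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from enum import IntEnum
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

__all__ = [
    "LandUse",
    "LandscapeConfig",
    "Landscape",
    "STUDY_AREA_PROFILE",
    "generate_landscape",
    "distance_transform",
    "eligibility_mask",
    "read_grid",
    "write_grid",
    "area_in_acres",
    "SQM_PER_ACRE",
]

SQM_PER_ACRE = 4046.8564


class LandUse(IntEnum):
    CROP = 1
    PASTURE = 2
    FOREST = 3
    WATER = 4
    OTHER = 5
    FALLOW = 6


#: land uses a farmer may offer for conservation
ELIGIBLE_USES = (LandUse.CROP, LandUse.PASTURE)


@dataclass(frozen=True)
class LandscapeConfig:
    """Generator configuration.

    The default is a desk-scale landscape (200 x 200 cells at 30 m, ~300
    parcels) sized so that a full sensitivity experiment runs in minutes.
    ``ebi_weights`` are the (N1, N2, N3) component weights; with
    standardized components the correlation between two layers is the sum
    of squared shared weights over the total squared weight, so the default
    (0.75, 0.5, 1.0) targets pairwise correlations between roughly 0.35
    and 0.89.
    """

    rows: int = 200
    cols: int = 200
    cell_size: float = 30.0
    parcel_count: int = 300
    water_frac: float = 0.04
    forest_frac: float = 0.18
    pasture_share: float = 0.30  # of farmland area; remainder is crop
    other_cell_frac: float = 0.03  # farmland speckled with ineligible cells
    slope_max: float = 25.0  # percent
    field_sigma: float = 6.0  # Gaussian smoothing length, cells
    cash_rent: float = 110.0  # county cash-rent constant, $/acre/yr
    srr_relief: float = 0.4  # +/- relative spread of the productivity index
    ebi_weights: tuple = (0.75, 0.5, 1.0)
    ebi_range: tuple = (50.0, 350.0)
    ebi_corr_band: tuple = (0.35, 0.89)  # documentation target, not enforced

    def validate(self) -> None:
        n_cells = self.rows * self.cols
        land_cells = int(n_cells * (1 - self.water_frac - self.forest_frac))
        if self.parcel_count > land_cells:
            raise ValueError(
                f"parcel_count {self.parcel_count} exceeds available "
                f"farmland cells (~{land_cells})"
            )
        if not (0 < self.water_frac < 1 and 0 < self.forest_frac < 1):
            raise ValueError("water_frac and forest_frac must be in (0, 1)")


#: full-scale profile mirroring the reference region's structure:
#: ~985 km^2 at 30 m cells and 2687 farmland parcels
STUDY_AREA_PROFILE = LandscapeConfig(rows=1046, cols=1046, parcel_count=2687)


@dataclass
class Landscape:
    """Immutable environment of the simulation: co-registered rasters."""

    config: LandscapeConfig
    seed: int
    landuse: np.ndarray  # int codes, see LandUse
    parcel_id: np.ndarray  # int, 0 = no parcel
    slope: np.ndarray  # percent
    dist_water: np.ndarray  # meters
    dist_forest: np.ndarray  # meters
    srr: np.ndarray  # $/acre/yr
    ebi_layers: np.ndarray  # shape (6, rows, cols), points

    @property
    def shape(self) -> tuple:
        return self.landuse.shape

    @property
    def cell_size(self) -> float:
        return self.config.cell_size

    @property
    def cell_acres(self) -> float:
        return self.cell_size**2 / SQM_PER_ACRE

    @property
    def n_parcels(self) -> int:
        return int(self.parcel_id.max())

    def save(self, outdir) -> None:
        """Write the bundle as ESRI ASCII grids plus a JSON manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        rasters = {
            "landuse": (self.landuse, "%d"),
            "parcel_id": (self.parcel_id, "%d"),
            "slope": (self.slope, "%.8g"),
            "dist_water": (self.dist_water, "%.8g"),
            "dist_forest": (self.dist_forest, "%.8g"),
            "srr": (self.srr, "%.8g"),
        }
        for i in range(self.ebi_layers.shape[0]):
            rasters[f"ebi_{i + 1}"] = (self.ebi_layers[i], "%.8g")
        for name, (arr, fmt) in rasters.items():
            write_grid(outdir / f"{name}.asc", arr, self.cell_size, fmt=fmt)
        manifest = {
            "format": "fallowsim-landscape/1",
            "seed": self.seed,
            "config": dataclasses.asdict(self.config),
            "rasters": {name: f"{name}.asc" for name in rasters},
            "ebi_layers": [f"ebi_{i + 1}" for i in range(self.ebi_layers.shape[0])],
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, outdir) -> "Landscape":
        outdir = Path(outdir)
        manifest = json.loads((outdir / "manifest.json").read_text())
        cfg_d = manifest["config"]
        for key in ("ebi_weights", "ebi_range", "ebi_corr_band"):
            cfg_d[key] = tuple(cfg_d[key])
        config = LandscapeConfig(**cfg_d)
        grids = {}
        shape = None
        for name, fname in manifest["rasters"].items():
            arr, meta = read_grid(outdir / fname)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise ValueError(
                    f"raster {name} shape {arr.shape} differs from bundle {shape}"
                )
            grids[name] = arr
        ebi = np.stack([grids[n] for n in manifest["ebi_layers"]])
        return cls(
            config=config,
            seed=manifest["seed"],
            landuse=grids["landuse"].astype(np.int16),
            parcel_id=grids["parcel_id"].astype(np.int32),
            slope=grids["slope"],
            dist_water=grids["dist_water"],
            dist_forest=grids["dist_forest"],
            srr=grids["srr"],
            ebi_layers=ebi,
        )


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Standardized (zero mean, unit sd) smoothed Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def _rescale(arr: np.ndarray, lo: float, hi: float) -> np.ndarray:
    a, b = arr.min(), arr.max()
    return lo + (arr - a) * (hi - lo) / (b - a)


def generate_landscape(
    config: LandscapeConfig | None = None, seed: int = 0
) -> Landscape:
    """Generate a deterministic synthetic landscape bundle.

    Steps: threshold smoothed random fields into contiguous water and
    forest patches; tessellate the remaining farmland into ``parcel_count``
    Voronoi parcels seeded at random farmland cells; assign each parcel a
    primary use (crop or pasture, greedily balancing the configured area
    share) with a sparse speckle of ineligible 'other' cells; derive slope,
    soil rental rate and the six EBI composites from further smoothed
    fields; compute exact Euclidean distance transforms of the water and
    forest masks.
    """
    config = config or LandscapeConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    shape = (config.rows, config.cols)
    n_cells = config.rows * config.cols

    # water and forest patches from thresholded smooth fields
    wf = _smooth_field(rng, shape, config.field_sigma)
    water = wf >= np.quantile(wf, 1 - config.water_frac)
    ff = _smooth_field(rng, shape, config.field_sigma)
    ff_land = ff[~water]
    forest = (~water) & (ff >= np.quantile(ff_land, 1 - config.forest_frac))
    farm = ~(water | forest)

    # Voronoi parcel mosaic over farmland cells
    farm_idx = np.flatnonzero(farm.ravel())
    seeds = rng.choice(farm_idx, size=config.parcel_count, replace=False)
    seed_coords = np.column_stack(np.unravel_index(seeds, shape))
    farm_coords = np.column_stack(np.unravel_index(farm_idx, shape))
    tree = cKDTree(seed_coords)
    _, owner = tree.query(farm_coords, k=1)
    parcel_id = np.zeros(shape, dtype=np.int32)
    parcel_id.ravel()[farm_idx] = owner + 1

    # parcel primary use: greedy crop/pasture split toward the target share
    landuse = np.full(shape, int(LandUse.OTHER), dtype=np.int16)
    landuse[water] = int(LandUse.WATER)
    landuse[forest] = int(LandUse.FOREST)
    sizes = np.bincount(owner, minlength=config.parcel_count)
    order = rng.permutation(config.parcel_count)
    pasture_area = 0.0
    assigned_area = 0.0
    parcel_use = np.empty(config.parcel_count, dtype=np.int16)
    for p in order:
        if pasture_area < config.pasture_share * (assigned_area + sizes[p]):
            parcel_use[p] = int(LandUse.PASTURE)
            pasture_area += sizes[p]
        else:
            parcel_use[p] = int(LandUse.CROP)
        assigned_area += sizes[p]
    landuse.ravel()[farm_idx] = parcel_use[owner]

    # ineligible speckle inside farmland; parcel seed cells stay eligible
    sf = _smooth_field(rng, shape, config.field_sigma / 2)
    speckle = np.zeros(shape, dtype=bool)
    if config.other_cell_frac > 0:
        thr = np.quantile(sf[farm], 1 - config.other_cell_frac)
        speckle = farm & (sf >= thr)
        speckle.ravel()[seeds] = False
        landuse[speckle] = int(LandUse.OTHER)

    slope = _rescale(_smooth_field(rng, shape, config.field_sigma), 0, config.slope_max)

    dist_water = distance_transform(water, config.cell_size)
    dist_forest = distance_transform(forest, config.cell_size)

    prod = _rescale(
        _smooth_field(rng, shape, config.field_sigma),
        1 - config.srr_relief,
        1 + config.srr_relief,
    )
    srr = prod * config.cash_rent

    w1, w2, w3 = config.ebi_weights
    n1 = [_smooth_field(rng, shape, config.field_sigma) for _ in range(3)]
    n2 = [_smooth_field(rng, shape, config.field_sigma) for _ in range(2)]
    n3 = _smooth_field(rng, shape, config.field_sigma)
    raw = np.stack([w1 * a + w2 * b + w3 * n3 for a in n1 for b in n2])
    lo, hi = config.ebi_range
    gmin, gmax = raw.min(), raw.max()
    ebi = lo + (raw - gmin) * (hi - lo) / (gmax - gmin)

    return Landscape(
        config=config,
        seed=seed,
        landuse=landuse,
        parcel_id=parcel_id,
        slope=slope,
        dist_water=dist_water,
        dist_forest=dist_forest,
        srr=srr,
        ebi_layers=ebi,
    )


def distance_transform(mask: np.ndarray, cell_size: float = 30.0) -> np.ndarray:
    """Exact Euclidean distance (meters, center-to-center) to the nearest
    true cell of ``mask``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("mask has no true cells")
    return ndimage.distance_transform_edt(~mask) * float(cell_size)


def eligibility_mask(landuse: np.ndarray) -> np.ndarray:
    """True exactly where land may be offered for conservation (crop or
    pasture); converted (fallow) land is no longer eligible."""
    landuse = np.asarray(landuse)
    valid = np.isin(landuse, [int(c) for c in LandUse])
    if not valid.all():
        bad = np.unique(landuse[~valid])
        raise ValueError(f"unknown land-use codes: {bad.tolist()}")
    return np.isin(landuse, [int(c) for c in ELIGIBLE_USES])


def area_in_acres(map_units: float, cell_size: float = 30.0) -> float:
    """Convert a cell count into acres (cell_size in meters)."""
    if map_units < 0:
        raise ValueError("map_units must be non-negative")
    return map_units * cell_size**2 / SQM_PER_ACRE


def write_grid(
    path,
    raster: np.ndarray,
    cell_size: float,
    nodata: float = -9999,
    fmt: str = "%.8g",
    xllcorner: float = 0.0,
    yllcorner: float = 0.0,
) -> None:
    """Write one raster as an ESRI ASCII grid (row-major from the top row)."""
    raster = np.asarray(raster)
    rows, cols = raster.shape
    header = (
        f"ncols {cols}\n"
        f"nrows {rows}\n"
        f"xllcorner {xllcorner:.8g}\n"
        f"yllcorner {yllcorner:.8g}\n"
        f"cellsize {cell_size:.8g}\n"
        f"NODATA_value {nodata:.8g}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, raster, fmt=fmt)


def read_grid(path) -> tuple[np.ndarray, dict]:
    """Read an ESRI ASCII grid; returns (array, header metadata)."""
    keys = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}
    meta: dict = {}
    with open(path) as fh:
        pos = 0
        for _ in range(6):
            line = fh.readline()
            parts = line.split()
            if len(parts) != 2 or parts[0].lower() not in keys:
                raise ValueError(f"malformed ESRI ASCII header line: {line!r}")
            meta[parts[0].lower()] = float(parts[1])
            pos = fh.tell()
        fh.seek(pos)
        data = np.loadtxt(fh, ndmin=2)
    rows, cols = int(meta["nrows"]), int(meta["ncols"])
    if data.shape != (rows, cols):
        raise ValueError(
            f"grid body shape {data.shape} does not match header ({rows}, {cols})"
        )
    return data, meta
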