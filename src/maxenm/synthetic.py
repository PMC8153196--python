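"""Virtual-species simulation: climate-like layers, a known truth, occurrences.

The generators produce inputs with the statistical structure the niche
pipeline assumes, so every downstream stage can be exercised end to end
without external downloads:

* spatially autocorrelated, partially correlated "bioclimatic" layers on a
  0.1-degree geographic lattice (Gaussian-smoothed white noise, linearly
  mixed through the Cholesky factor of a target correlation matrix);
* a virtual species whose true suitability is an inverse-logit of linear
  and quadratic terms in the standardized layers;
* presence records sampled proportionally to that suitability, with
  coordinate jitter and a reported-uncertainty column;
* perturbed future layer stacks for several pseudo-GCMs under labelled
  emission-intensity scenarios.

Every generator is deterministic under its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .occurrences import OccurrenceSet
from .rasters import GridSpec, RasterStack

EARTH_RADIUS_KM = 6371.0088
_M_PER_DEG = EARTH_RADIUS_KM * 1000.0 * math.pi / 180.0  # metres per degree of arc


@dataclass
class ClimateSimConfig:
    """Parameters of the synthetic climate-layer generator.

    ``pairwise_corr`` is the target inter-layer correlation matrix
    (symmetric, unit diagonal, positive definite); ``autocorr_length`` is
    the Gaussian smoothing scale in cells.
    """

    grid_rows: int = 60
    grid_cols: int = 60
    n_layers: int = 8
    autocorr_length: float = 5.0
    pairwise_corr: np.ndarray | None = None
    nodata_fraction: float = 0.0
    seed: int = 0
    xllcorner: float = -100.0
    yllcorner: float = 30.0
    cellsize: float = 0.1

    def __post_init__(self) -> None:
        if self.grid_rows < 10 or self.grid_cols < 10:
            raise ValueError("grid must be at least 10 x 10")
        if self.n_layers < 2:
            raise ValueError("need at least 2 layers")
        if not 0 <= self.nodata_fraction < 1:
            raise ValueError("nodata_fraction must be in [0, 1)")
        if self.pairwise_corr is None:
            self.pairwise_corr = np.eye(self.n_layers)
        self.pairwise_corr = np.asarray(self.pairwise_corr, dtype=float)
        c = self.pairwise_corr
        if c.shape != (self.n_layers, self.n_layers):
            raise ValueError("pairwise_corr shape must be (n_layers, n_layers)")
        if not np.allclose(c, c.T) or not np.allclose(np.diag(c), 1.0):
            raise ValueError("pairwise_corr must be symmetric with unit diagonal")


@dataclass
class VirtualSpeciesConfig:
    """True response of the virtual species on standardized layers.

    ``true_coefficients`` maps layer name -> (linear, quadratic) weight;
    suitability is the inverse-logit of intercept + sum of terms.
    """

    true_coefficients: dict[str, tuple[float, float]] = field(default_factory=dict)
    intercept: float = 0.0
    n_presences: int = 100
    jitter_sd: float = 2000.0  # metres
    uncertainty_range: tuple[float, float] = (10.0, 15_000.0)
    sampling_seed: int = 0


@dataclass
class FutureSimConfig:
    """Perturbation scheme for pseudo-GCM future stacks.

    ``scenarios`` are (label, intensity) pairs; the scenario intensity
    multiplies both the systematic per-layer shift ``delta_mean`` and the
    per-GCM random shift (scale ``delta_sd``).
    """

    n_gcms: int = 4
    scenarios: tuple[tuple[str, float], ...] = (("low", 1.0), ("high", 2.0))
    delta_mean: dict[str, float] = field(default_factory=dict)
    delta_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_gcms < 1:
            raise ValueError("need at least one GCM")
        if not self.scenarios:
            raise ValueError("need at least one scenario")


def generate_climate_stack(config: ClimateSimConfig) -> RasterStack:
    """Simulate co-registered, autocorrelated, cross-correlated layers.

    White-noise fields are smoothed with a Gaussian kernel of scale
    ``autocorr_length`` (wrap mode keeps variance roughly stationary),
    standardized, then mixed through the Cholesky factor of the target
    correlation matrix. Layers are named ``BIO_1 .. BIO_n`` and given
    distinct affine offsets so they live on climate-like scales.
    """
    try:
        chol = np.linalg.cholesky(config.pairwise_corr)
    except np.linalg.LinAlgError as exc:
        raise ValueError("pairwise_corr must be positive definite") from exc
    rng = np.random.default_rng(config.seed)
    shape = (config.grid_rows, config.grid_cols)
    fields = np.empty((config.n_layers, *shape))
    for i in range(config.n_layers):
        white = rng.standard_normal(shape)
        smooth = ndimage.gaussian_filter(white, sigma=config.autocorr_length, mode="wrap")
        smooth -= smooth.mean()
        sd = smooth.std()
        fields[i] = smooth / sd if sd > 0 else smooth
    mixed = np.tensordot(chol, fields, axes=(1, 0))
    layers: dict[str, np.ndarray] = {}
    for i in range(config.n_layers):
        # arbitrary distinct climate-like scales: offsets grow with index
        layers[f"BIO_{i + 1}"] = 10.0 + 5.0 * i + (2.0 + i) * mixed[i]
    if config.nodata_fraction > 0:
        n_cells = shape[0] * shape[1]
        n_bad = int(round(config.nodata_fraction * n_cells))
        bad = rng.choice(n_cells, size=n_bad, replace=False)
        for arr in layers.values():
            arr.ravel()[bad] = np.nan
    grid = GridSpec(
        nrows=config.grid_rows,
        ncols=config.grid_cols,
        xllcorner=config.xllcorner,
        yllcorner=config.yllcorner,
        cellsize=config.cellsize,
    )
    return RasterStack(grid, layers)


def true_suitability(stack: RasterStack, vs: VirtualSpeciesConfig) -> np.ndarray:
    """Per-cell inverse-logit of the virtual species' response.

    Layers are standardized over their valid cells before the linear and
    quadratic terms are applied; nodata propagates as NaN.
    """
    if not vs.true_coefficients:
        raise ValueError("no coefficients supplied")
    missing = [k for k in vs.true_coefficients if k not in stack.layers]
    if missing:
        raise KeyError(f"coefficients reference layers not in stack: {missing}")
    eta = np.full((stack.grid.nrows, stack.grid.ncols), vs.intercept, dtype=float)
    valid = stack.valid_mask()
    for name, (b1, b2) in vs.true_coefficients.items():
        arr = stack[name]
        mu = np.nanmean(arr[valid])
        sd = np.nanstd(arr[valid])
        z = (arr - mu) / (sd if sd > 0 else 1.0)
        eta = eta + b1 * z + b2 * z * z
    suit = 1.0 / (1.0 + np.exp(-eta))
    suit[~valid] = np.nan
    return suit


def sample_occurrences(
    suit: np.ndarray, grid: GridSpec, vs: VirtualSpeciesConfig
) -> OccurrenceSet:
    """Draw presence records with probability proportional to suitability.

    Cell draws are with replacement; coordinates are the cell centre plus
    isotropic Gaussian jitter of ``jitter_sd`` metres, and each record
    carries a uniform reported uncertainty from ``uncertainty_range``.
    """
    suit = np.asarray(suit, dtype=float)
    p = np.where(np.isfinite(suit), suit, 0.0).ravel()
    if vs.n_presences == 0:
        return OccurrenceSet(
            pd.DataFrame(columns=["id", "longitude", "latitude", "uncertainty_m", "source"])
        )
    total = p.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample")
    rng = np.random.default_rng(vs.sampling_seed)
    cells = rng.choice(p.size, size=vs.n_presences, replace=True, p=p / total)
    lon_g, lat_g = grid.cell_centers()
    lon = lon_g.ravel()[cells]
    lat = lat_g.ravel()[cells]
    if vs.jitter_sd > 0:
        jitter_deg = vs.jitter_sd / _M_PER_DEG
        lat = lat + rng.normal(0.0, jitter_deg, size=lon.size)
        lon = lon + rng.normal(0.0, jitter_deg, size=lon.size) / np.cos(np.radians(lat))
    lo, hi = vs.uncertainty_range
    unc = rng.uniform(lo, hi, size=lon.size)
    df = pd.DataFrame(
        {
            "id": [f"occ_{i:05d}" for i in range(lon.size)],
            "longitude": np.clip(lon, -180.0, 180.0),
            "latitude": np.clip(lat, -90.0, 90.0),
            "uncertainty_m": unc,
            "source": "virtual-species",
        }
    )
    return OccurrenceSet(df)


def generate_future_stacks(
    stack: RasterStack, config: FutureSimConfig
) -> dict[tuple[str, str], RasterStack]:
    """One perturbed stack per (pseudo-GCM, scenario).

    future = present + intensity * (delta_mean + eps_gcm) with
    eps_gcm ~ N(0, delta_sd) drawn once per GCM and layer, so the GCMs
    disagree systematically while the higher-intensity scenario amplifies
    every shift.
    """
    rng = np.random.default_rng(config.seed)
    gcm_names = [f"GCM_{chr(ord('A') + i)}" for i in range(config.n_gcms)]
    eps = {
        g: {name: rng.normal(0.0, config.delta_sd) if config.delta_sd > 0 else 0.0
            for name in stack.layer_names}
        for g in gcm_names
    }
    out: dict[tuple[str, str], RasterStack] = {}
    for g in gcm_names:
        for label, intensity in config.scenarios:
            layers = {}
            for name in stack.layer_names:
                shift = intensity * (config.delta_mean.get(name, 0.0) + eps[g][name])
                layers[name] = stack[name] + shift
            out[(g, label)] = RasterStack(stack.grid, layers)
    return out


def default_virtual_species(
    seed: int = 0,
    grid_rows: int = 60,
    grid_cols: int = 60,
    n_presences: int = 250,
) -> tuple[RasterStack, VirtualSpeciesConfig, np.ndarray, OccurrenceSet]:
    """The default study fixture: 8 layers, 2 informative, 2 decoys, 4 noise.

    BIO_1 carries a linear effect and BIO_2 a quadratic one; BIO_3 and
    BIO_4 are decoys correlated 0.9 and 0.85 with BIO_1 (one-factor
    structure, so their mutual correlation is 0.765) — they carry the
    linear signal at second hand and exercise variable selection;
    BIO_5..BIO_8 are pure noise. Returns the stack, the species config,
    the true suitability surface, and sampled occurrences.
    """
    corr = np.eye(8)
    corr[0, 2] = corr[2, 0] = 0.9
    corr[0, 3] = corr[3, 0] = 0.85
    corr[2, 3] = corr[3, 2] = 0.9 * 0.85
    clim = ClimateSimConfig(
        grid_rows=grid_rows,
        grid_cols=grid_cols,
        n_layers=8,
        autocorr_length=4.0,
        pairwise_corr=corr,
        seed=seed,
    )
    stack = generate_climate_stack(clim)
    vs = VirtualSpeciesConfig(
        true_coefficients={"BIO_1": (2.5, 0.0), "BIO_2": (0.0, -2.0)},
        intercept=0.5,
        n_presences=n_presences,
        jitter_sd=2000.0,
        uncertainty_range=(10.0, 15_000.0),
        sampling_seed=seed + 1,
    )
    suit = true_suitability(stack, vs)
    occ = sample_occurrences(suit, stack.grid, vs)
    return stack, vs, suit, occ
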