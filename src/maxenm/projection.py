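"""Geographic transfer, extrapolation risk (MOP), and GCM agreement maps.

A selected ensemble is transferred to a target region by predicting each
replicate on the target stack with variables clamped to their calibration
range, then taking the cellwise median and max-min range. The
Mobility-oriented Parity (MOP) analysis measures, for every target cell,
the mean multivariate environmental distance to its nearest subset of
calibration cells, and flags *strict extrapolation* wherever any variable
leaves the calibration range — predictions there rest on no calibration
evidence. Multi-GCM futures are summarized by the nine-code agreement
legend: gain codes 1-4 (how many GCMs turn an unsuitable cell suitable),
loss codes 5-8 (4 + how many turn a suitable cell unsuitable), and 9 for
no change under every GCM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .rasters import RasterStack
from .selection import Ensemble

__all__ = [
    "ProjectionBundle",
    "transfer",
    "mop_tables",
    "mop",
    "binarize",
    "gcm_agreement",
    "extrapolation_agreement",
]


@dataclass
class ProjectionBundle:
    """Transferred prediction plus its extrapolation diagnostics."""

    median_suitability: np.ndarray
    uncertainty_range: np.ndarray
    mop_similarity: np.ndarray
    strict_extrapolation: np.ndarray
    scenario_label: str = ""


def transfer(
    ensemble: Ensemble, target_stack: RasterStack, clamp: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Project every replicate onto the target; median and max-min range."""
    preds = [
        m.predict_logistic(target_stack.subset(m.variable_set), clamp=clamp)
        for m in ensemble.models
    ]
    cube = np.stack(preds)
    median = np.nanmedian(cube, axis=0) if len(preds) > 1 else cube[0].copy()
    rng = np.nanmax(cube, axis=0) - np.nanmin(cube, axis=0)
    return median, rng


def mop_tables(
    cal_env: np.ndarray,
    target_env: np.ndarray,
    reference_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """MOP on environment tables: (similarity in [0,1], strict mask).

    Variables are standardized by the calibration mean/sd; each target
    row's distance is the mean Euclidean distance to its nearest
    ceil(reference_fraction * N) calibration rows, rescaled so that
    similarity = 1 - d / d_max. The strict mask is true where any raw
    variable falls outside the calibration [min, max].
    """
    cal = np.asarray(cal_env, dtype=float)
    tgt = np.asarray(target_env, dtype=float)
    if cal.size == 0 or cal.shape[0] < 1:
        raise ValueError("empty calibration table")
    if cal.shape[1] != tgt.shape[1]:
        raise ValueError("calibration and target variable sets differ")
    n_ref = max(1, int(np.ceil(reference_fraction * cal.shape[0])))
    mu = cal.mean(axis=0)
    sd = cal.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    cal_z = (cal - mu) / sd
    tgt_z = (tgt - mu) / sd
    nn = NearestNeighbors(n_neighbors=n_ref).fit(cal_z)
    dist, _ = nn.kneighbors(tgt_z)
    mean_dist = dist.mean(axis=1)
    d_max = mean_dist.max()
    similarity = 1.0 - mean_dist / d_max if d_max > 0 else np.ones_like(mean_dist)
    lo = cal.min(axis=0)
    hi = cal.max(axis=0)
    strict = np.any((tgt < lo) | (tgt > hi), axis=1)
    return similarity, strict


def mop(
    cal_stack: RasterStack,
    cal_mask: np.ndarray,
    target_stack: RasterStack,
    names: list[str],
    reference_fraction: float = 0.1,
) -> tuple[np.ndarray, np.ndarray]:
    """Raster MOP: similarity raster (NaN outside data) and strict mask."""
    cal_env, _ = cal_stack.table(names, mask=cal_mask)
    tgt_env, idx = target_stack.table(names)
    sim, strict = mop_tables(cal_env, tgt_env, reference_fraction)
    shape = (target_stack.grid.nrows, target_stack.grid.ncols)
    sim_r = np.full(shape[0] * shape[1], np.nan)
    sim_r[idx] = sim
    strict_r = np.zeros(shape[0] * shape[1], dtype=bool)
    strict_r[idx] = strict
    return sim_r.reshape(shape), strict_r.reshape(shape)


def binarize(suitability: np.ndarray, threshold: float) -> np.ndarray:
    """Presence/absence raster: true where suitability >= threshold.

    NaN (undefined) cells are false; keep the suitability raster around if
    the defined-cell mask is needed downstream.
    """
    s = np.asarray(suitability, dtype=float)
    return np.where(np.isfinite(s), s >= threshold, False)


def suitability_threshold(cal_suitability: np.ndarray, e_threshold: float = 0.05) -> float:
    """E-quantile of the calibration-point suitabilities (omission rule)."""
    return float(np.quantile(np.asarray(cal_suitability, dtype=float), e_threshold))


def gcm_agreement(
    present_binary: np.ndarray,
    future_binaries: list[np.ndarray],
    valid_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Nine-code change map across GCMs.

    For a cell unsuitable at present, codes 1..G count the GCMs that
    predict future suitability (gain); for a suitable cell, codes
    G+1..2G are G plus the number of GCMs predicting loss; cells where
    every GCM agrees with the present state are coded 9. Cells outside
    ``valid_mask`` are 0.
    """
    if not future_binaries:
        raise ValueError("need at least one future binary raster")
    present = np.asarray(present_binary, dtype=bool)
    futures = [np.asarray(f, dtype=bool) for f in future_binaries]
    for f in futures:
        if f.shape != present.shape:
            raise ValueError("future rasters must match the present grid")
    g = len(futures)
    stackf = np.stack(futures)
    gains = np.sum(stackf & ~present[None], axis=0)
    losses = np.sum(~stackf & present[None], axis=0)
    codes = np.full(present.shape, 9, dtype=int)
    codes = np.where(~present & (gains > 0), gains, codes)
    codes = np.where(present & (losses > 0), g + losses, codes)
    if valid_mask is not None:
        codes = np.where(valid_mask, codes, 0)
    return codes


AGREEMENT_LEGEND = {
    0: "no data",
    1: "gain predicted by one GCM",
    2: "gain predicted by two GCMs",
    3: "gain predicted by three GCMs",
    4: "gain predicted by four GCMs",
    5: "loss predicted by one GCM",
    6: "loss predicted by two GCMs",
    7: "loss predicted by three GCMs",
    8: "loss predicted by four GCMs",
    9: "no change from the present prediction",
}


def extrapolation_agreement(strict_masks: list[np.ndarray]) -> np.ndarray:
    """Cellwise count of GCMs whose MOP flags strict extrapolation."""
    if not strict_masks:
        raise ValueError("need at least one strict-extrapolation mask")
    shape = strict_masks[0].shape
    for m in strict_masks:
        if m.shape != shape:
            raise ValueError("masks must be co-registered")
    return np.sum(np.stack([m.astype(int) for m in strict_masks]), axis=0)
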