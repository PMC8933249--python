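"""Background-referenced thresholding and Otsu analysis.

The segmentation gates signals two ways before and after boundary
refinement:

* neuromelanin (NM) images: an intensity floor equal to the background mean
  plus four background standard deviations (the SD may be a cohort-averaged
  calibration constant); signal below the floor is zeroed.
* susceptibility maps: negatives are zeroed inside the mapped boundary, then
  an Otsu threshold is computed inside the ROI and capped at 30 ppb; if the
  threshold removes pixels, the mapped boundary shrinks to the surviving
  support.

NM "contrast" is always percent over the background mean:
``contrast% = 100 * (S - bg_mean) / bg_mean``, which is what the 5/7/8 %
volume gates refer to.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core_io import StructureSet, contour_to_mask
from .errors import CollapseError, ConfigurationError, DegenerateError


@dataclass
class ThresholdConfig:
    nm_sd_multiplier: float = 4.0
    nm_contrast_gate_pct: float = 5.0     # alternatives: 7, 8
    qsm_otsu_cap_ppb: float = 30.0
    qsm_gate_ppb: float = 50.0            # alternatives: 75, 100
    qsm_floor_ppb: float = 0.0

    def __post_init__(self):
        for name in ("nm_sd_multiplier", "nm_contrast_gate_pct",
                     "qsm_otsu_cap_ppb", "qsm_gate_ppb", "qsm_floor_ppb"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class BackgroundStats:
    mean: float
    sd: float
    n_pixels: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n_pixels < 20:
            raise ConfigurationError(
                f"background ROI too small ({self.n_pixels} px, need >= 20)")


def background_stats(image: np.ndarray, bg_rois: StructureSet) -> BackgroundStats:
    """Pooled mean/SD over all background-ROI pixels of a 3D image.

    ``bg_rois`` holds BG contours (either hemisphere); pixels are pooled
    across slices and hemispheres.
    """
    image = np.asarray(image)
    values = []
    for hemi in ("L", "R"):
        for c in bg_rois.get("BG", hemi):
            if not (0 <= c.slice_index < image.shape[2]):
                continue
            m = contour_to_mask(c, image.shape[:2])
            values.append(image[:, :, c.slice_index][m])
    if not values:
        raise ConfigurationError("no background ROIs found on any slice")
    pooled = np.concatenate(values)
    return BackgroundStats(float(pooled.mean()), float(pooled.std()), int(pooled.size))


def nm_floor(stats: BackgroundStats, config: ThresholdConfig,
             sd_ref: float | None = None) -> float:
    """NM intensity floor: background mean + multiplier x SD.

    ``sd_ref`` is the cohort-averaged background SD calibration constant when
    available; otherwise this subject's own background SD is used.
    """
    sd = stats.sd if sd_ref is None else float(sd_ref)
    return stats.mean + config.nm_sd_multiplier * sd


def otsu_threshold(values: np.ndarray, n_bins: int = 256) -> float:
    """Otsu threshold maximizing between-class variance on a uniform histogram.

    Bins span [min, max] of the input; the returned threshold is the upper
    edge of the chosen background bin. Raises :class:`DegenerateError` for
    (near-)constant input.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2 or np.ptp(values) == 0:
        raise DegenerateError("Otsu needs at least two distinct values")
    counts, edges = np.histogram(values, bins=n_bins)
    p = counts.astype(float) / counts.sum()
    w0 = np.cumsum(p)
    centers = (edges[:-1] + edges[1:]) / 2.0
    mu = np.cumsum(p * centers)
    mu_t = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    # a flat maximum (e.g. two well-separated masses) is resolved to its
    # center, the conventional Otsu tie-break
    ties = np.flatnonzero(sigma_b == sigma_b.max())
    k = int(round(ties.mean()))
    return float(edges[k + 1])


def qsm_prepare(chi: np.ndarray, roi_mask: np.ndarray,
                config: ThresholdConfig | None = None,
                min_area: int = 5) -> tuple[np.ndarray, float, np.ndarray]:
    """Pre-DPA preparation of a susceptibility map inside a mapped boundary.

    Steps: zero negative values; Otsu inside the ROI, capped at
    ``qsm_otsu_cap_ppb``; zero sub-threshold pixels; shrink the ROI to the
    largest connected component of the surviving support.

    Works on a 2D slice or a 3D block (connectivity follows the array rank).

    Returns ``(floored_map, effective_threshold, shrunk_roi_mask)``.
    Raises :class:`CollapseError` if nothing survives.
    """
    config = config or ThresholdConfig()
    chi = np.asarray(chi, dtype=float).copy()
    roi_mask = np.asarray(roi_mask, dtype=bool)
    chi[chi < config.qsm_floor_ppb] = 0.0
    inside = chi[roi_mask]
    if inside.size == 0 or not (inside > 0).any():
        raise CollapseError("ROI empty after removing negative susceptibility",
                            stage="qsm_prepare")
    try:
        thr = otsu_threshold(inside)
    except DegenerateError:
        thr = 0.0  # uniform ROI: thresholding is a no-op
    thr_eff = min(thr, config.qsm_otsu_cap_ppb)
    chi[chi < thr_eff] = 0.0
    support = roi_mask & (chi > 0)
    if support.sum() < min_area:
        raise CollapseError(
            f"structure support below {min_area} px after Otsu thresholding",
            stage="qsm_prepare")
    labels, n = ndimage.label(support)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        support = labels == (1 + int(np.argmax(sizes)))
    return chi, float(thr_eff), support


def gate_structure(values_map: np.ndarray, mask: np.ndarray,
                   gate: float) -> tuple[np.ndarray, float]:
    """Keep mask pixels whose map value exceeds ``gate``.

    Returns the gated mask and the volume loss ``1 - V_gated / V_ungated``.
    The map is in the units the gate refers to (ppb for susceptibility,
    contrast % for NM).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy(), 0.0
    gated = mask & (np.asarray(values_map) > gate) if gate > 0 else mask.copy()
    loss = 1.0 - gated.sum() / mask.sum()
    return gated, float(loss)


def nm_contrast_map(image: np.ndarray, bg_mean: float) -> np.ndarray:
    """Percent NM contrast over the background mean."""
    if bg_mean <= 0:
        raise ConfigurationError("background mean must be positive")
    return 100.0 * (np.asarray(image, dtype=float) - bg_mean) / bg_mean
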