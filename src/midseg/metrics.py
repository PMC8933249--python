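"""Evaluation and quantification of segmented midbrain nuclei.

DICE overlap, volume ratio (automated / manual), threshold volume loss,
total iron content (sum over slices of slice volume x mean susceptibility),
total NM content (slice volume x mean NM contrast %), and the SNpc
derivation ``SNpc = (NM \\ VTA) & SN_iron`` — the NM-rich region contains
SNpc plus VTA while the iron SN contains SNpc plus SNpr, so their overlap
(less the VTA) isolates the pars compacta.

All masks are compared at the original (unzoomed) resolution, where the
final boundaries live. Reports list both hemispheres and their mean, since
left/right differences are not of interest here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core_io import StructureSet, Volume3D
from .errors import ConfigurationError
from .thresholds import BackgroundStats, nm_contrast_map


def dice(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """DICE similarity 2|A&B| / (|A|+|B|). Both-empty input is undefined."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    denom = a.sum() + b.sum()
    if denom == 0:
        raise ValueError("DICE undefined for two empty masks")
    return float(2.0 * (a & b).sum() / denom)


def volume_ratio(auto_mask: np.ndarray, manual_mask: np.ndarray,
                 spacing: tuple[float, float, float]) -> float:
    """Automated volume divided by manual volume (mm^3 / mm^3)."""
    v_manual = np.asarray(manual_mask, bool).sum()
    if v_manual == 0:
        raise ValueError("manual volume is zero")
    return float(np.asarray(auto_mask, bool).sum() / v_manual)


def mask_volume_mm3(mask: np.ndarray, spacing) -> float:
    return float(np.asarray(mask, bool).sum() * np.prod(spacing))


def iron_content(chi: Volume3D, sset: StructureSet, label: str,
                 hemisphere: str) -> float:
    """Total iron content in ppb*mm^3.

    Per-slice ``area_mm2 * dz * mean(chi)`` summed over the structure's
    slices — algebraically the voxel volume times the chi sum over the mask.
    """
    mask = sset.mask(label, hemisphere, chi.shape)
    if not mask.any():
        raise ValueError(f"structure {label}/{hemisphere} absent")
    return float(chi.voxel_volume * chi.data[mask].sum())


def nm_content(nm: Volume3D, bg: BackgroundStats, sset: StructureSet,
               hemisphere: str, label: str = "NM") -> float:
    """Total NM content in %*mm^3 (slice volume x mean contrast, summed)."""
    if bg is None:
        raise ConfigurationError("background stats required for NM content")
    mask = sset.mask(label, hemisphere, nm.shape)
    if not mask.any():
        raise ValueError(f"structure {label}/{hemisphere} absent")
    contrast = nm_contrast_map(nm.data, bg.mean)
    return float(nm.voxel_volume * contrast[mask].sum())


def derive_snpc(nm_mask: np.ndarray, sn_iron_mask: np.ndarray,
                vta_mask: np.ndarray | None = None) -> np.ndarray:
    """SNpc mask: ``(NM \\ VTA) & SN_iron`` on a shared grid."""
    nm = np.asarray(nm_mask, bool)
    sn = np.asarray(sn_iron_mask, bool)
    if vta_mask is not None:
        nm = nm & ~np.asarray(vta_mask, bool)
    return nm & sn


def evaluate_structures(auto: StructureSet, manual: StructureSet,
                        nm: Volume3D, chi: Volume3D,
                        bg: BackgroundStats | None = None,
                        labels=("NM", "SN", "RN", "STN")) -> pd.DataFrame:
    """Per structure/hemisphere comparison of two segmentations.

    Returns one row per (structure, hemisphere) plus an ``LR-mean`` row per
    structure, with volume, DICE, VR and content measures.
    """
    rows = []
    for label in labels:
        per_hemi = []
        for hemi in ("L", "R"):
            if not auto.get(label, hemi) or not manual.get(label, hemi):
                continue
            a = auto.mask(label, hemi, nm.shape)
            m = manual.mask(label, hemi, nm.shape)
            rec = {
                "structure": label,
                "hemisphere": hemi,
                "volume_mm3": mask_volume_mm3(a, nm.spacing),
                "manual_volume_mm3": mask_volume_mm3(m, nm.spacing),
                "dice": dice(a, m),
                "volume_ratio": volume_ratio(a, m, nm.spacing),
            }
            if label in ("SN", "RN", "STN"):
                rec["mean_chi_ppb"] = float(chi.data[a].mean()) if a.any() else np.nan
                rec["iron_content_ppb_mm3"] = iron_content(chi, auto, label, hemi)
            if label == "NM" and bg is not None:
                contrast = nm_contrast_map(nm.data, bg.mean)
                rec["nm_contrast_pct"] = float(contrast[a].mean()) if a.any() else np.nan
                rec["nm_content_pct_mm3"] = nm_content(nm, bg, auto, hemi)
            rows.append(rec)
            per_hemi.append(rec)
        if per_hemi:
            mean_rec = {"structure": label, "hemisphere": "LR-mean"}
            for key in per_hemi[0]:
                if key in ("structure", "hemisphere"):
                    continue
                mean_rec[key] = float(np.mean([r[key] for r in per_hemi]))
            rows.append(mean_rec)
    return pd.DataFrame(rows)
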