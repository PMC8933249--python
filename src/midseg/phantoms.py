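"""Synthetic phantoms emulating the study data.

Three families:

* 2D shape phantoms (rectangle / moon / cashew / disk) with two intensity
  levels and additive noise at a specified contrast-to-noise ratio
  ``CNR = (I_in - I_out) / sigma`` — the boundary-refinement test bed. The
  rectangle is 35 x 40 px so its true area is 1,400 pixels.
* paired NM / susceptibility midbrain phantoms with per-structure ground
  truth (crescent-like SN with ~125 ppb susceptibility, RN ~100 ppb,
  STN ~110 ppb, an NM-rich region at 5-10 % contrast over a 1,000 a.u.
  background, a Y-like VTA and background boxes), warped per synthetic
  subject by a smooth random in-plane displacement plus a small rigid
  component and an integer slice shift.
* dipole-forward QSM phantoms (wrapped phase from a known chi map) for
  validating the reconstruction chain.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .core_io import Contour, StructureSet, Volume3D, mask_to_contour
from .errors import GeometryError
from .qsm_recon import PhaseVolume, field_ratio_to_phase, forward_field_ratio

# ---------------------------------------------------------------------------
# 2D shape phantoms
# ---------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    shape: str = "rectangle"          # rectangle | moon | cashew | disk
    canvas: tuple[int, int] = (72, 72)
    inside: float = 170.0
    outside: float = 100.0
    cnr: float = 7.0                  # np.inf for noise-free
    noise: str = "gaussian"           # gaussian | rician
    seed: int = 0
    rect_size: tuple[int, int] = (35, 40)
    disk_radius: float = 20.0

    def __post_init__(self):
        if self.cnr <= 0:
            raise ValueError("cnr must be positive")
        if self.inside <= self.outside:
            raise ValueError("inside intensity must exceed outside")


def _shape_mask(spec: PhantomSpec) -> np.ndarray:
    nx, ny = spec.canvas
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    if spec.shape == "rectangle":
        w, h = spec.rect_size
        x0, y0 = int(round(cx - (w - 1) / 2)), int(round(cy - (h - 1) / 2))
        if x0 < 2 or y0 < 2 or x0 + w > nx - 2 or y0 + h > ny - 2:
            raise GeometryError("rectangle does not fit the canvas")
        mask = np.zeros((nx, ny), dtype=bool)
        mask[x0:x0 + w, y0:y0 + h] = True
    elif spec.shape == "disk":
        mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= spec.disk_radius ** 2
    elif spec.shape == "moon":
        r1, r2, off = 18.0, 14.0, 7.0
        outer = (xs - cx) ** 2 + (ys - cy) ** 2 <= r1 ** 2
        inner = (xs - cx - off) ** 2 + (ys - cy) ** 2 <= r2 ** 2
        mask = outer & ~inner
    elif spec.shape == "cashew":
        r = 12.0
        d1 = (xs - cx + 7) ** 2 + (ys - cy - 3) ** 2 <= r ** 2
        d2 = (xs - cx - 7) ** 2 + (ys - cy + 3) ** 2 <= r ** 2
        blur = ndimage.gaussian_filter((d1 | d2).astype(float), 1.5)
        mask = blur > 0.5
    else:
        raise ValueError(f"unknown shape {spec.shape!r}")
    if not mask.any() or mask[:2].any() or mask[-2:].any() \
            or mask[:, :2].any() or mask[:, -2:].any():
        raise GeometryError("shape touches the canvas border")
    return mask


def make_shape_phantom(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, float]:
    """Two-intensity shape with noise at the requested CNR.

    Returns ``(image, truth_mask, noise_sigma)``.
    """
    mask = _shape_mask(spec)
    image = np.where(mask, spec.inside, spec.outside).astype(float)
    sigma = 0.0 if np.isinf(spec.cnr) else (spec.inside - spec.outside) / spec.cnr
    if sigma > 0:
        rng = np.random.default_rng(spec.seed)
        if spec.noise == "gaussian":
            image = image + rng.normal(0.0, sigma, image.shape)
        elif spec.noise == "rician":
            image = np.hypot(image + rng.normal(0.0, sigma, image.shape),
                             rng.normal(0.0, sigma, image.shape))
        else:
            raise ValueError(f"unknown noise model {spec.noise!r}")
    return image, mask, sigma


def enclosing_initial_contour(spec: PhantomSpec, seed: int | None = None,
                              margin: float = 2.0,
                              perturb: float = 2.0) -> Contour:
    """A perturbed closed region drawn around the phantom's central area.

    An ellipse around the truth bounding box, with seeded low-frequency
    radial jitter — emulating a rough operator-style enclosing region.
    """
    mask = _shape_mask(spec)
    idx = np.argwhere(mask)
    c = idx.mean(axis=0)
    hx, hy = (idx.max(axis=0) - idx.min(axis=0)) / 2.0 + margin
    theta = np.linspace(0, 2 * np.pi, 96, endpoint=False)
    with np.errstate(divide="ignore"):
        r_box = np.minimum(np.abs(hx / np.cos(theta)), np.abs(hy / np.sin(theta)))
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    jitter = np.zeros_like(theta)
    for harm in (2, 3, 5):
        jitter += rng.uniform(-1, 1) * np.cos(harm * theta + rng.uniform(0, 2 * np.pi))
    r = r_box + perturb * jitter / 3.0
    verts = np.stack([c[0] + r * np.cos(theta), c[1] + r * np.sin(theta)], axis=1)
    lim = np.array(spec.canvas) - 2.5
    verts = np.clip(verts, 2.5, lim)
    return Contour(0, verts)


# ---------------------------------------------------------------------------
# Midbrain phantom
# ---------------------------------------------------------------------------


@dataclass
class MidbrainSpec:
    """Geometry and contrast of the synthetic midbrain.

    Susceptibility means emulate healthy elderly midbrain nuclei (SN around
    125 ppb, RN 100, STN 110); the NM-rich region sits 5-10 % above a
    1,000 a.u. background with 1 % background noise. Sizes approximate
    healthy-cohort volumes (SN ~490, NM ~250, RN ~190, STN ~90 mm^3) on a
    0.67 x 0.67 x 2 mm grid.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (0.67, 0.67, 2.0)
    bg_nm: float = 1000.0
    nm_noise_sd: float = 10.0
    chi_noise_sd: float = 8.0
    chi_sn: float = 125.0
    chi_sn_sd: float = 20.0
    chi_rn: float = 100.0
    chi_rn_sd: float = 15.0
    chi_stn: float = 110.0
    chi_stn_sd: float = 12.0
    nm_contrast_range: tuple[float, float] = (0.05, 0.10)
    rn_n_slices: int = 3
    rn_anchor_slice: int = 29          # canonical RN anchor (crop slice 10)
    warp_amplitude_px: float = 1.2     # RMS of the smooth in-plane warp
    stn_jitter_px: float = 1.5         # extra independent STN displacement
    max_rotation_deg: float = 3.0
    max_translation_px: float = 2.0
    max_z_shift: int = 2
    nigrosome_gap: bool = False


STRUCT_SLICES = {          # canonical slice windows (0-based), rn_anchor 29
    "SN": (26, 30),
    "RN": (28, 30),
    "STN": (30, 31),       # abuts the SN anterosuperiorly (shares slice 30)
    "NM": (27, 30),
    "VTA": (27, 30),
    "BG": (27, 30),
}


def _ellipse(xs, ys, center, semi, angle_deg=0.0):
    t = np.deg2rad(angle_deg)
    dx, dy = xs - center[0], ys - center[1]
    u = dx * np.cos(t) + dy * np.sin(t)
    v = -dx * np.sin(t) + dy * np.cos(t)
    return (u / semi[0]) ** 2 + (v / semi[1]) ** 2 <= 1.0


def canonical_masks(spec: MidbrainSpec) -> dict[tuple[str, str], np.ndarray]:
    """Unwarped per-structure boolean masks on the phantom grid."""
    nx, ny, nz = spec.shape
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx = (nx - 1) / 2.0
    masks: dict[tuple[str, str], np.ndarray] = {}
    if spec.rn_n_slices == 2:
        rn_slices = (spec.rn_anchor_slice, spec.rn_anchor_slice + 1)
    elif spec.rn_n_slices == 3:
        rn_slices = (spec.rn_anchor_slice - 1, spec.rn_anchor_slice + 1)
    else:
        raise ValueError("rn_n_slices must be 2 or 3")

    # whole-head context for global registration: brain envelope and
    # ventricles (painted, not part of the truth structure set)
    env = np.zeros(spec.shape, bool)
    for z in range(nz):
        f = 1.0 - ((z - (nz - 1) / 2.0) / (nz / 2.0 + 2.0)) ** 2
        if f <= 0:
            continue
        env[:, :, z] = _ellipse(xs, ys, (cx, cx), (27.0 * np.sqrt(f), 28.0 * np.sqrt(f)))
    masks[("_brain", "L")] = env
    vent = np.zeros(spec.shape, bool)
    for z in range(40, 56):
        f = 1.0 - ((z - 47.5) / 9.0) ** 2
        if f <= 0:
            continue
        for sgn in (-1.0, 1.0):
            vent[:, :, z] |= _ellipse(xs, ys, (cx + sgn * 7.0, 25.0),
                                      (4.0 * np.sqrt(f), 6.5 * np.sqrt(f)))
    masks[("_vent", "L")] = vent
    # z-asymmetric landmarks: pons-like body below the midbrain and a
    # posterior bright band above it (anchor the slice direction for the
    # global registration, as real anatomy does)
    pons = np.zeros(spec.shape, bool)
    for z in range(7, 26):
        f = 1.0 - ((z - 16.0) / 10.0) ** 2
        if f <= 0:
            continue
        pons[:, :, z] = _ellipse(xs, ys, (cx, 27.0),
                                 (16.0 * np.sqrt(f), 12.0 * np.sqrt(f)))
    masks[("_pons", "L")] = pons
    band = np.zeros(spec.shape, bool)
    for z in range(34, 45):
        f = 1.0 - ((z - 39.0) / 6.0) ** 2
        if f <= 0:
            continue
        band[:, :, z] = _ellipse(xs, ys, (cx, 44.0),
                                 (14.0 * np.sqrt(f), 7.0 * np.sqrt(f)))
    masks[("_band", "L")] = band

    for hemi, s in (("L", -1.0), ("R", 1.0)):
        m = {lab: np.zeros(spec.shape, bool) for lab in
             ("SN", "RN", "STN", "NM", "VTA", "BG")}

        z0, z1 = STRUCT_SLICES["SN"]
        taper = {z: f for z, f in zip(range(z0, z1 + 1), (0.78, 0.92, 1.0, 0.92, 0.78))}
        for z, f in taper.items():
            body = _ellipse(xs, ys, (cx + s * 8.0, 31.0), (10.4 * f, 4.4 * f), -35.0 * s)
            bite = (xs - (cx + s * 8.0)) ** 2 + (ys - 25.0) ** 2 <= (4.0 * f) ** 2
            m["SN"][:, :, z] = body & ~bite
        # nigrosome gap (if requested) is painted in chi, not in geometry
        for z, f in zip(range(rn_slices[0], rn_slices[1] + 1),
                        (0.85, 1.0, 0.85) if spec.rn_n_slices == 3 else (1.0, 0.9)):
            rn = _ellipse(xs, ys, (cx + s * 4.5, 41.0), (5.7 * f, 4.9 * f))
            m["RN"][:, :, z] = rn & ~ndimage.binary_dilation(m["SN"][:, :, z])
        z0, z1 = STRUCT_SLICES["STN"]
        for z, f in zip(range(z0, z1 + 1), (1.0, 0.85)):
            stn = _ellipse(xs, ys, (cx + s * 7.0, 24.5),
                           (5.0 * f, 3.3 * f), -30.0 * s)
            # direct anterior abutment with the SN: no intensity seam, the
            # nuclei merge smoothly and only the template boundary separates
            # them (chi contrast 110 vs 125 ppb is within the noise)
            m["STN"][:, :, z] = stn & ~m["SN"][:, :, z]
        z0, z1 = STRUCT_SLICES["VTA"]
        for z in range(z0, z1 + 1):
            stem = _ellipse(xs, ys, (cx + s * 2.5, 29.0), (1.8, 2.5))
            arm1 = _ellipse(xs, ys, (cx + s * 3.8, 27.0), (1.4, 1.8), 35.0 * s)
            arm2 = _ellipse(xs, ys, (cx + s * 1.6, 26.8), (1.2, 1.7), -30.0 * s)
            m["VTA"][:, :, z] = stem | arm1 | arm2
        z0, z1 = STRUCT_SLICES["NM"]
        for z, f in zip(range(z0, z1 + 1), (0.85, 1.0, 1.0, 0.9)):
            blob = _ellipse(xs, ys, (cx + s * 7.5, 30.8), (6.6 * f, 3.4 * f), -35.0 * s)
            snpc = blob & m["SN"][:, :, z]
            union = ndimage.binary_fill_holes(snpc | m["VTA"][:, :, z])
            # enclosed gaps between SNpc and VTA go to the VTA so that
            # NM == SNpc | VTA holds exactly
            m["VTA"][:, :, z] |= union & ~(snpc | m["VTA"][:, :, z])
            m["NM"][:, :, z] = union
        z0, z1 = STRUCT_SLICES["BG"]
        bx = int(round(cx + s * 16))
        for z in range(z0, z1 + 1):
            box = np.zeros((nx, ny), bool)
            box[bx - 2:bx + 3, 16:23] = True
            m["BG"][:, :, z] = box
        for lab in ("SN", "RN", "STN", "NM", "VTA", "BG"):
            masks[(lab, hemi)] = m[lab]
    return masks


def _smooth_warp(spec: MidbrainSpec, rng: np.random.Generator):
    """Random smooth in-plane displacement field + rigid component + z shift."""
    nx, ny, nz = spec.shape
    coarse = rng.normal(size=(2, 5, 5, 3))
    disp = np.stack([ndimage.zoom(coarse[i], (nx / 5, ny / 5, nz / 3), order=3)
                     for i in range(2)])
    disp = disp[:, :nx, :ny, :nz]
    rms = np.sqrt((disp ** 2).mean())
    if rms > 0:
        disp *= spec.warp_amplitude_px / rms
    theta = np.deg2rad(rng.uniform(-spec.max_rotation_deg, spec.max_rotation_deg))
    trans = rng.uniform(-spec.max_translation_px, spec.max_translation_px, size=2)
    z_shift = int(rng.integers(-spec.max_z_shift, spec.max_z_shift + 1))
    return disp, theta, trans, z_shift


def _warp_mask(mask: np.ndarray, disp, theta, trans, z_shift,
               center) -> np.ndarray:
    """Forward-warp a boolean mask: subject = f(canonical).

    The forward map is ``f(p) = R p + t + d(p)`` (in-plane) with a slice
    shift; resampling inverts it by fixed-point iteration.
    """
    nx, ny, nz = mask.shape
    xs, ys = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float),
                         indexing="ij")
    cxy = np.asarray(center)
    out = np.zeros_like(mask)
    zsup = np.where(mask.any(axis=(0, 1)))[0]
    R_inv = np.array([[np.cos(theta), np.sin(theta)],
                      [-np.sin(theta), np.cos(theta)]])
    for z in zsup:
        zq = z + z_shift
        if not (0 <= zq < nz):
            continue
        q = np.stack([xs, ys], axis=0)
        # initial guess ignores d; three fixed-point sweeps refine it
        p = np.tensordot(R_inv, q - trans[:, None, None]
                         - cxy[:, None, None], axes=(1, 0)) + cxy[:, None, None]
        for _ in range(3):
            d = np.stack([
                ndimage.map_coordinates(disp[i][:, :, z], p, order=1, mode="nearest")
                for i in range(2)])
            p = np.tensordot(R_inv, q - trans[:, None, None] - d
                             - cxy[:, None, None], axes=(1, 0)) + cxy[:, None, None]
        vals = ndimage.map_coordinates(mask[:, :, z].astype(float), p,
                                       order=1, mode="constant")
        out[:, :, zq] = vals > 0.5
    return out


@dataclass
class MidbrainPhantom:
    nm: Volume3D
    chi: Volume3D
    truth: StructureSet
    warp_params: dict = field(default_factory=dict)


def make_midbrain_phantom(spec: MidbrainSpec | None = None, seed: int = 0,
                          warped: bool = True) -> MidbrainPhantom:
    """One synthetic subject: paired NM + chi volumes with ground truth.

    ``warped=False`` produces the canonical (template best-case) anatomy;
    otherwise a seeded smooth warp, rigid jitter and slice shift are applied.
    Intensities are painted in subject space from the warped truth masks, so
    image edges and truth contours agree exactly.
    """
    spec = spec or MidbrainSpec()
    rng = np.random.default_rng(seed)
    masks = canonical_masks(spec)
    nx, ny, nz = spec.shape
    center = ((nx - 1) / 2.0, (ny - 1) / 2.0)

    if warped:
        disp, theta, trans, z_shift = _smooth_warp(spec, rng)
        masks = {k: _warp_mask(v, disp, theta, trans, z_shift, center)
                 for k, v in masks.items()}
        # the STN's position relative to its neighborhood varies between
        # individuals more than a smooth whole-midbrain warp captures; give
        # it an extra independent in-plane displacement
        for hemi in ("L", "R"):
            jit = rng.uniform(-spec.stn_jitter_px, spec.stn_jitter_px, 2)
            stn = ndimage.shift(masks[("STN", hemi)].astype(float),
                                (jit[0], jit[1], 0.0), order=1) > 0.5
            masks[("STN", hemi)] = stn & ~(masks[("SN", "L")] | masks[("SN", "R")])
        warp_params = {"theta_rad": theta, "translation_px": trans,
                       "z_shift": z_shift, "displacement": disp}
    else:
        warp_params = {"theta_rad": 0.0, "translation_px": np.zeros(2),
                       "z_shift": 0, "displacement": np.zeros((2,) + spec.shape)}

    brain = masks[("_brain", "L")]
    vent = masks[("_vent", "L")]
    chi = rng.normal(0.0, spec.chi_noise_sd, spec.shape)
    chi[~brain] = 0.0
    chi[vent] = rng.normal(-20.0, 5.0, int(vent.sum()))
    for lab, mean, sd in (("SN", spec.chi_sn, spec.chi_sn_sd),
                          ("RN", spec.chi_rn, spec.chi_rn_sd),
                          ("STN", spec.chi_stn, spec.chi_stn_sd)):
        for hemi in ("L", "R"):
            m = masks[(lab, hemi)]
            chi[m] = rng.normal(mean, sd, int(m.sum()))
    if spec.nigrosome_gap:
        xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
        for hemi, s in (("L", -1.0), ("R", 1.0)):
            zc = sum(STRUCT_SLICES["SN"]) // 2
            gap2d = _ellipse(xs, ys, (center[0] + s * 11.0, 31.5), (2.4, 1.7),
                             -35.0 * s)
            gap = np.zeros(spec.shape, bool)
            gap[:, :, zc] = gap2d
            if warped:
                gap = _warp_mask(gap, disp, theta, trans, z_shift, center)
            gm = gap & masks[("SN", hemi)]
            chi[gm] = rng.normal(30.0, 10.0, int(gm.sum()))

    nm_scale = rng.uniform(0.98, 1.02)
    contrast = rng.uniform(*spec.nm_contrast_range)
    nm = np.full(spec.shape, spec.bg_nm * nm_scale)
    nm[~brain] = 250.0
    nm[vent] = 650.0 * nm_scale
    nm[masks[("_pons", "L")]] = 900.0 * nm_scale
    nm[masks[("_band", "L")]] = 1120.0 * nm_scale
    for hemi in ("L", "R"):
        nm[masks[("NM", hemi)]] = spec.bg_nm * nm_scale * (1.0 + contrast)
    nm = nm + rng.normal(0.0, spec.nm_noise_sd, spec.shape)

    truth = StructureSet()
    for (lab, hemi), m in masks.items():
        if lab.startswith("_"):
            continue
        for z in np.where(m.any(axis=(0, 1)))[0]:
            cs = mask_to_contour(m[:, :, z], slice_index=int(z), min_area=4)
            if cs:
                truth.add(lab, hemi, cs[0])
    truth.validate(spec.shape[:2])
    warp_params["nm_contrast"] = contrast

    meta = {"TE_ms": 7.5, "units": "a.u."}
    nm_vol = Volume3D(nm, spec.spacing, meta=dict(meta))
    chi_vol = Volume3D(chi, spec.spacing, meta={"TE_ms": 15.0, "units": "ppb"})
    return MidbrainPhantom(nm_vol, chi_vol, truth, warp_params)


def make_cohort(n: int, spec: MidbrainSpec | None = None, seed: int = 0,
                first_unwarped: bool = True) -> list[MidbrainPhantom]:
    """A cohort of synthetic subjects with distinct seeded warps."""
    spec = spec or MidbrainSpec()
    out = []
    for i in range(n):
        out.append(make_midbrain_phantom(
            spec, seed=seed + i, warped=not (first_unwarped and i == 0)))
    return out


# ---------------------------------------------------------------------------
# QSM forward phantoms
# ---------------------------------------------------------------------------


def sphere_chi(shape=(64, 64, 64), radius: float = 6.0, value_ppb: float = 100.0,
               center=None) -> np.ndarray:
    c = [(n - 1) / 2.0 for n in shape] if center is None else center
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    r2 = sum((g - ci) ** 2 for g, ci in zip(grids, c))
    return np.where(r2 <= radius ** 2, value_ppb, 0.0)


def make_qsm_phantom(chi_ppb: np.ndarray,
                     spacing=(1.0, 1.0, 1.0),
                     te_ms: float = 15.0, b0_tesla: float = 3.0,
                     b0_dir=(0, 0, 1),
                     external_chi_ppb: np.ndarray | None = None,
                     noise_sd_rad: float = 0.0,
                     seed: int = 0) -> tuple[PhaseVolume, np.ndarray]:
    """Wrapped GRE phase from a known chi map (plus optional external source).

    Returns the wrapped :class:`PhaseVolume` and the truth chi array. The
    external source (e.g. outside the brain mask) adds a background field
    for exercising SHARP.
    """
    total = np.asarray(chi_ppb, dtype=float)
    if external_chi_ppb is not None:
        total = total + external_chi_ppb
    fr = forward_field_ratio(total, spacing, b0_dir)
    phase = field_ratio_to_phase(fr, te_ms, b0_tesla)
    if noise_sd_rad > 0:
        phase = phase + np.random.default_rng(seed).normal(0, noise_sd_rad, phase.shape)
    wrapped = np.angle(np.exp(1j * phase))
    vol = Volume3D(wrapped, spacing, meta={"TE_ms": te_ms, "units": "rad"})
    return PhaseVolume(vol, te_ms, b0_tesla, tuple(b0_dir)), np.asarray(chi_ppb, float)
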