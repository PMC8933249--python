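"""Susceptibility-map reconstruction from gradient-echo phase.

Chain: 3D best-path phase unwrapping -> SHARP background-field removal
(spherical-mean-value filtering + truncated deconvolution) -> truncated
k-space division (TKD) dipole inversion with iterative cone replacement.

Unit conventions: wrapped phase in radians; the local field is carried in
radians until inversion, where it is scaled once to a dimensionless field
ratio ``dB/B0 = phi / (gamma * B0 * TE)`` and the output map to ppb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.restoration import unwrap_phase as _sk_unwrap

from .core_io import Volume3D
from .errors import GeometryError

GAMMA_RAD_S_T = 2.675e8  # proton gyromagnetic ratio, rad/s/T


@dataclass
class QSMConfig:
    """Reconstruction parameters.

    Defaults follow the processing chain this package implements: SHARP
    truncation 0.05 with a 6-voxel spherical kernel, TKD threshold 0.1, and
    4 cone-replacement iterations with image-domain threshold 0.1.
    """

    sharp_tsvd_threshold: float = 0.05
    sharp_kernel_radius_voxels: int = 6
    tkd_threshold: float = 0.1
    iter_threshold: float = 0.1
    n_iterations: int = 4
    gamma: float = GAMMA_RAD_S_T
    b0_tesla: float = 3.0
    te_ms: float = 15.0
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        for name in ("sharp_tsvd_threshold", "tkd_threshold", "iter_threshold"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if self.sharp_kernel_radius_voxels < 1:
            raise ValueError("sharp_kernel_radius_voxels must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class PhaseVolume:
    """GRE phase in radians with the acquisition context needed for scaling."""

    volume: Volume3D
    te_ms: float = 15.0
    b0_tesla: float = 3.0
    b0_dir: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self):
        if self.te_ms <= 0:
            raise ValueError("TE must be positive")


@dataclass
class SusceptibilityMap:
    """Susceptibility in ppb, zero outside the brain mask."""

    volume: Volume3D
    mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        if self.mask is None:
            self.mask = np.ones(self.volume.shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        data = self.volume.data
        if not np.isfinite(data[self.mask]).all():
            raise ValueError("non-finite susceptibility inside mask")

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


# ---------------------------------------------------------------------------
# Dipole kernel and forward model
# ---------------------------------------------------------------------------

def dipole_kernel(grid_shape: tuple[int, int, int],
                  spacing: tuple[float, float, float],
                  b0_dir: tuple[float, float, float] = (0, 0, 1)) -> np.ndarray:
    """Unit dipole response in k-space: ``D(k) = 1/3 - (k.b)^2 / |k|^2``.

    ``D(0)`` is set to 0. ``b0_dir`` need not be normalized but must be
    nonzero.
    """
    b = np.asarray(b0_dir, dtype=float)
    nb = np.linalg.norm(b)
    if nb == 0:
        raise ValueError("B0 direction must be a nonzero vector")
    b = b / nb
    if min(grid_shape) < 8:
        raise ValueError(f"grid must be >= 8 per axis, got {grid_shape}")
    ks = [np.fft.fftfreq(n, d=s) for n, s in zip(grid_shape, spacing)]
    kx, ky, kz = np.meshgrid(*ks, indexing="ij")
    k2 = kx**2 + ky**2 + kz**2
    kb = kx * b[0] + ky * b[1] + kz * b[2]
    with np.errstate(divide="ignore", invalid="ignore"):
        D = 1.0 / 3.0 - kb**2 / k2
    D[k2 == 0] = 0.0
    return D


def forward_field_ratio(chi_ppb: np.ndarray, spacing, b0_dir=(0, 0, 1)) -> np.ndarray:
    """Dimensionless field perturbation dB/B0 induced by a chi map in ppb."""
    D = dipole_kernel(chi_ppb.shape, spacing, b0_dir)
    return np.real(np.fft.ifftn(D * np.fft.fftn(chi_ppb * 1e-9)))


def field_ratio_to_phase(field_ratio: np.ndarray, te_ms: float, b0_tesla: float,
                         gamma: float = GAMMA_RAD_S_T) -> np.ndarray:
    return gamma * b0_tesla * (te_ms * 1e-3) * field_ratio


def phase_to_field_ratio(phase_rad: np.ndarray, te_ms: float, b0_tesla: float,
                         gamma: float = GAMMA_RAD_S_T) -> np.ndarray:
    return phase_rad / (gamma * b0_tesla * (te_ms * 1e-3))


# ---------------------------------------------------------------------------
# Unwrapping
# ---------------------------------------------------------------------------

def unwrap_phase(phase: PhaseVolume, mask: np.ndarray) -> PhaseVolume:
    """Best-path 3D phase unwrapping inside a mask.

    Output is congruent to the input modulo 2*pi voxelwise; voxels outside
    the mask are returned untouched.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("unwrap mask is empty")
    wrapped = np.ma.array(phase.volume.data.astype(float), mask=~mask)
    unwrapped = np.asarray(_sk_unwrap(wrapped))
    out = phase.volume.data.astype(float).copy()
    out[mask] = unwrapped[mask]
    return PhaseVolume(phase.volume.copy(data=out), phase.te_ms,
                       phase.b0_tesla, phase.b0_dir)


# ---------------------------------------------------------------------------
# SHARP
# ---------------------------------------------------------------------------

def _sphere_kernel_fft(shape, radius_voxels: int) -> np.ndarray:
    """FFT of ``delta - sphere`` with the sphere kernel in wrap-around layout."""
    grids = [(np.arange(n) + n // 2) % n - n // 2 for n in shape]
    x, y, z = np.meshgrid(*grids, indexing="ij")
    sphere = (x**2 + y**2 + z**2) <= radius_voxels**2
    rho = sphere / sphere.sum()
    delta = np.zeros(shape)
    delta[0, 0, 0] = 1.0
    return np.fft.fftn(delta - rho)


def sharp_filter(unwrapped: PhaseVolume, mask: np.ndarray,
                 config: QSMConfig | None = None) -> tuple[Volume3D, np.ndarray]:
    """SHARP background-field removal.

    Spherical-mean-value filtering removes harmonic (background-sourced)
    components, followed by truncated deconvolution of the SMV operator at
    ``sharp_tsvd_threshold``. The result is valid on the mask eroded by the
    kernel radius; it is returned zeroed outside that eroded mask, which is
    also returned.
    """
    config = config or QSMConfig()
    mask = np.asarray(mask, dtype=bool)
    r = config.sharp_kernel_radius_voxels
    shape = unwrapped.volume.shape
    c_hat = _sphere_kernel_fft(shape, r)

    grids = [np.arange(-r, r + 1)] * 3
    x, y, z = np.meshgrid(*grids, indexing="ij")
    ball = (x**2 + y**2 + z**2) <= r**2
    eroded = ndimage.binary_erosion(mask, structure=ball)
    if not eroded.any():
        raise GeometryError("mask too thin to erode by the SHARP kernel radius")

    phi = unwrapped.volume.data.astype(float) * mask
    smv = np.real(np.fft.ifftn(c_hat * np.fft.fftn(phi))) * eroded
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = np.where(np.abs(c_hat) > config.sharp_tsvd_threshold, 1.0 / c_hat, 0.0)
    local = np.real(np.fft.ifftn(inv * np.fft.fftn(smv))) * eroded
    out = unwrapped.volume.copy(data=local)
    out.meta["units"] = "rad"
    return out, eroded


# ---------------------------------------------------------------------------
# Dipole inversion
# ---------------------------------------------------------------------------

def _truncated_kernel(D: np.ndarray, threshold: float) -> np.ndarray:
    sign = np.where(D >= 0, 1.0, -1.0)
    return np.where(np.abs(D) >= threshold, D, sign * threshold)


def tkd_invert(local_field: Volume3D, mask: np.ndarray | None = None,
               config: QSMConfig | None = None) -> SusceptibilityMap:
    """Truncated k-space division of a local field map (radians) to ppb.

    The dipole kernel is divided where ``|D| >= tkd_threshold``; elsewhere it
    is replaced by ``sign(D) * tkd_threshold``.
    """
    config = config or QSMConfig()
    mask = np.ones(local_field.shape, bool) if mask is None else np.asarray(mask, bool)
    fr = phase_to_field_ratio(local_field.data.astype(float), config.te_ms,
                              config.b0_tesla, config.gamma)
    D = dipole_kernel(local_field.shape, local_field.spacing, config.b0_dir)
    Dt = _truncated_kernel(D, config.tkd_threshold)
    chi = np.real(np.fft.ifftn(np.fft.fftn(fr) / Dt)) * 1e9
    chi *= mask
    vol = local_field.copy(data=chi)
    vol.meta["units"] = "ppb"
    return SusceptibilityMap(vol, mask)


def iterative_tkd(local_field: Volume3D, mask: np.ndarray | None = None,
                  config: QSMConfig | None = None) -> SusceptibilityMap:
    """TKD with iterative refinement of the ill-conditioned k-space cone.

    Starting from the plain TKD map, each of ``n_iterations`` passes
    thresholds the image at ``iter_threshold * max|chi|``, forward-transforms
    it, and replaces k-space data inside the cone ``|D| < iter_threshold``
    with the thresholded-image model, keeping well-conditioned k-space fixed.
    This suppresses streaking sourced from the cone.
    """
    config = config or QSMConfig()
    if config.n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    mask = np.ones(local_field.shape, bool) if mask is None else np.asarray(mask, bool)
    fr = phase_to_field_ratio(local_field.data.astype(float), config.te_ms,
                              config.b0_tesla, config.gamma)
    D = dipole_kernel(local_field.shape, local_field.spacing, config.b0_dir)
    Dt = _truncated_kernel(D, config.tkd_threshold)
    F = np.fft.fftn(fr)
    well = np.abs(D) >= config.iter_threshold
    X_well = F / Dt
    chi = np.real(np.fft.ifftn(X_well)) * 1e9 * mask
    for _ in range(config.n_iterations):
        lim = config.iter_threshold * np.abs(chi).max()
        chi_t = np.where(np.abs(chi) >= lim, chi, 0.0)
        X = np.fft.fftn(chi_t * 1e-9)
        X[well] = X_well[well]
        chi = np.real(np.fft.ifftn(X)) * 1e9 * mask
    vol = local_field.copy(data=chi)
    vol.meta["units"] = "ppb"
    return SusceptibilityMap(vol, mask)


def reconstruct_qsm(phase: PhaseVolume, mask: np.ndarray,
                    config: QSMConfig | None = None) -> SusceptibilityMap:
    """Full chain: unwrap -> SHARP -> iterative TKD."""
    config = config or QSMConfig()
    config.te_ms = phase.te_ms
    config.b0_tesla = phase.b0_tesla
    config.b0_dir = phase.b0_dir
    unwrapped = unwrap_phase(phase, mask)
    local, eroded = sharp_filter(unwrapped, mask, config)
    return iterative_tkd(local, eroded, config)
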