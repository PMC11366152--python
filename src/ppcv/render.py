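"""Render a vascular network into a DART-style B-scan flow stack.

Each slice image is the cross-section of every vessel at the slice plane
x_i, rasterized with subpixel supersampling (fractional pixel coverage),
convolved with an isotropic Gaussian PSF, corrupted by multiplicative
gamma speckle, and clipped to [0, i_max].  Flow intensity is mapped as

    I = background + (foreground − background) · coverage

so a threshold at fraction f of the way from background to foreground
selects pixels with coverage above f.  Capillary cross-sections are
sub-pixel at this pixel pitch, which biases any fixed-threshold area
measurement; the segmentation default is calibrated against noise-free
phantom rasterizations (see ``SegmentationSettings.threshold``).

The renderer also attaches clean pixel-center rasterizations of the
capillary-only and large-vessel-only cross sections (``capillary_masks``,
``vessel_masks``); these are phantom ground truth for validating the
segmentation stage and are not part of the measured signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError
from .geometry import ScanGeometry
from .network import (CAPILLARY, LARGE_VESSEL, VascularNetwork,
                      _points_in_cylinder)


@dataclass(frozen=True)
class RenderParams:
    """Imaging model of the renderer.

    ``speckle_shape`` is the gamma shape parameter k of unit-mean
    multiplicative speckle (contrast = 1/√k); ``None`` disables speckle.
    ``psf_sigma_um = 0`` disables blurring.
    """

    psf_sigma_um: float = 1.5
    speckle_shape: float | None = 16.0
    background_level: float = 20.0
    foreground_level: float = 200.0
    i_max: float = 255.0
    supersample: int = 3

    def __post_init__(self):
        if self.psf_sigma_um < 0:
            raise ConfigurationError("psf_sigma_um must be >= 0")
        if self.speckle_shape is not None and self.speckle_shape <= 0:
            raise ConfigurationError("speckle_shape must be positive or None")
        if not 0 <= self.background_level < self.foreground_level <= self.i_max:
            raise ConfigurationError(
                "levels must satisfy 0 <= background < foreground <= i_max")
        if self.supersample < 1:
            raise ConfigurationError("supersample must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RenderParams":
        return cls(**d)


@dataclass
class BScanStack:
    """An ordered stack of co-registered B-scan flow images."""

    images: np.ndarray  # (n_slices, H, W) float32, intensities in [0, i_max]
    geometry: ScanGeometry
    metadata: dict = field(default_factory=dict)
    capillary_masks: np.ndarray | None = None  # (n_slices, H, W) bool
    vessel_masks: np.ndarray | None = None

    def __post_init__(self):
        self.images = np.asarray(self.images, dtype=np.float32)
        if self.images.ndim != 3:
            raise ConfigurationError("stack images must be (n_slices, H, W)")
        n, h, w = self.images.shape
        if n != self.geometry.n_slices:
            raise ConfigurationError(
                f"stack has {n} slices but geometry declares {self.geometry.n_slices}")
        if w != self.geometry.n_ascans:
            raise ConfigurationError(
                f"stack width {w} != n_ascans {self.geometry.n_ascans}")
        if not np.all(np.isfinite(self.images)) or self.images.min() < 0:
            raise ConfigurationError("intensities must be finite and >= 0")

    @property
    def n_slices(self) -> int:
        return self.images.shape[0]


def _rasterize_slice(segments, x_plane: float, geom: ScanGeometry,
                     sub: int) -> np.ndarray:
    """Boolean supersampled raster (H·sub × W·sub) of all segments' cross
    sections at plane x = x_plane.  Subpixel centers follow the pixel-center
    convention: sample j of pixel p sits at ((p·sub + j + 0.5)/sub) · pitch.
    """
    H, W = geom.n_axial_px, geom.n_ascans
    pu = geom.lateral_pixel_um / sub
    pz = geom.axial_pixel_um / sub
    out = np.zeros((H * sub, W * sub), dtype=bool)
    for seg in segments:
        for p0, p1 in zip(seg.centerline[:-1], seg.centerline[1:]):
            r = seg.radius_um
            if max(p0[0], p1[0]) < x_plane - r or min(p0[0], p1[0]) > x_plane + r:
                continue
            c0 = max(0, int(np.floor((min(p0[1], p1[1]) - r) / pu)))
            c1 = min(W * sub, int(np.ceil((max(p0[1], p1[1]) + r) / pu)) + 1)
            r0 = max(0, int(np.floor((min(p0[2], p1[2]) - r) / pz)))
            r1 = min(H * sub, int(np.ceil((max(p0[2], p1[2]) + r) / pz)) + 1)
            if c0 >= c1 or r0 >= r1:
                continue
            uu = (np.arange(c0, c1) + 0.5) * pu
            zz = (np.arange(r0, r1) + 0.5) * pz
            U, Z = np.meshgrid(uu, zz, indexing="xy")
            pts = np.stack([np.full(U.size, x_plane), U.ravel(), Z.ravel()], axis=1)
            inside = _points_in_cylinder(pts, p0, p1, r).reshape(Z.shape)
            out[r0:r1, c0:c1] |= inside
    return out


def render_stack(
    network: VascularNetwork,
    geometry: ScanGeometry | None = None,
    params: RenderParams | None = None,
    seed: int = 0,
) -> BScanStack:
    """Render the network into a noisy B-scan flow stack (deterministic
    for fixed inputs and seed)."""
    geom = geometry or network.geometry
    params = params or RenderParams()
    rng = np.random.default_rng(seed)
    sub = params.supersample
    H, W = geom.n_axial_px, geom.n_ascans

    caps = network.capillaries()
    vessels = network.large_vessels()

    images = np.empty((geom.n_slices, H, W), dtype=np.float32)
    cap_masks = np.empty((geom.n_slices, H, W), dtype=bool)
    ves_masks = np.empty((geom.n_slices, H, W), dtype=bool)

    for i, x in enumerate(geom.slice_positions_um):
        cap_sub = _rasterize_slice(caps, x, geom, sub)
        ves_sub = _rasterize_slice(vessels, x, geom, sub)
        both = cap_sub | ves_sub
        coverage = both.reshape(H, sub, W, sub).mean(axis=(1, 3))
        img = params.background_level + \
            (params.foreground_level - params.background_level) * coverage
        if params.psf_sigma_um > 0:
            img = gaussian_filter(
                img, sigma=(params.psf_sigma_um / geom.axial_pixel_um,
                            params.psf_sigma_um / geom.lateral_pixel_um))
        if params.speckle_shape is not None:
            img = img * rng.gamma(params.speckle_shape,
                                  1.0 / params.speckle_shape, size=img.shape)
        images[i] = np.clip(img, 0.0, params.i_max)
        # clean pixel-center ground-truth rasterizations (no PSF, no noise)
        half = sub // 2
        cap_masks[i] = cap_sub[half::sub, half::sub]
        ves_masks[i] = ves_sub[half::sub, half::sub]

    meta = {
        "seed": seed,
        "render_params": params.to_dict(),
        "network_seed": network.seed,
    }
    return BScanStack(images, geom, meta, cap_masks, ves_masks)
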