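"""Synthetic peak-systole valve frames for orifice planimetry.

The frame shows, on a dark background, the bright rim of the circular valve
holder (26 mm base diameter, giving the pixel calibration), the darker closed
leaflet tissue filling the holder, and a bright open-orifice region in the
middle. A tri-leaflet valve opens into a three-lobed aperture, modeled as the
polar curve r(θ) = r₀ (1 + ε cos(n_lobes·θ)); r₀ is solved so the enclosed
area matches ``target_goa``. The pre-blur rasterized mask is returned as
ground truth alongside the rendered 8-bit image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from ..errors import ParameterError
from ..planimetry import OrificeFrame

__all__ = ["OrificeImageParams", "gen_orifice_image"]

HOLDER_DIAMETER_MM = 26.0
LOBE_ECCENTRICITY = 0.18

# gray levels
BACKGROUND = 25.0
TISSUE = 80.0
RIM = 230.0


@dataclass
class OrificeImageParams:
    image_size: int = 192  # square frame, pixels
    holder_diameter_px: float = 176.0
    target_goa: float = 3.24  # cm²
    n_lobes: int = 3
    contrast: float = 0.65  # orifice brightness above tissue, fraction of headroom
    blur_sigma: float = 1.2  # px
    noise_sd: float = 4.0  # gray levels
    seed: int = 0
    timestamp: float = 0.0  # s, for peak-frame matching

    def validate(self) -> None:
        if self.image_size < 32:
            raise ParameterError("image_size must be >= 32 pixels")
        if not 0 < self.holder_diameter_px <= self.image_size:
            raise ParameterError("holder_diameter_px must fit inside image_size")
        if self.target_goa <= 0:
            raise ParameterError("target_goa must be positive")
        if self.n_lobes < 1:
            raise ParameterError("n_lobes must be >= 1")
        if not 0.0 <= self.contrast <= 1.0:
            raise ParameterError("contrast must lie in [0, 1]")
        if self.blur_sigma < 0 or self.noise_sd < 0:
            raise ParameterError("blur_sigma/noise_sd must be >= 0")
        mm_per_px = HOLDER_DIAMETER_MM / self.holder_diameter_px
        holder_area_cm2 = np.pi * (HOLDER_DIAMETER_MM / 2.0) ** 2 / 100.0
        eps = LOBE_ECCENTRICITY if self.n_lobes >= 2 else 0.0
        r0_mm = np.sqrt(self.target_goa * 100.0 / (np.pi * (1.0 + eps**2 / 2.0)))
        if self.target_goa >= 0.8 * holder_area_cm2 or r0_mm * (1.0 + eps) >= 0.92 * (
            HOLDER_DIAMETER_MM / 2.0
        ):
            raise ParameterError(
                f"target_goa={self.target_goa} cm² too large for a "
                f"{HOLDER_DIAMETER_MM} mm holder"
            )
        del mm_per_px


def gen_orifice_image(params: OrificeImageParams) -> tuple[OrificeFrame, np.ndarray]:
    """Render one calibrated grayscale frame; returns ``(frame, truth_mask)``."""
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)

    n = p.image_size
    mm_per_px = HOLDER_DIAMETER_MM / p.holder_diameter_px
    cy = cx = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy - cy, xx - cx
    rr = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)

    holder_r = p.holder_diameter_px / 2.0
    img = np.full((n, n), BACKGROUND)
    img[rr < holder_r] = TISSUE
    rim_band = np.abs(rr - holder_r) < 2.0
    img[rim_band] = RIM

    # orifice boundary r(θ) = r0 (1 + ε cos kθ); area = π r0² (1 + ε²/2)
    eps = LOBE_ECCENTRICITY if p.n_lobes >= 2 else 0.0
    target_px2 = p.target_goa * 100.0 / mm_per_px**2
    r0 = np.sqrt(target_px2 / (np.pi * (1.0 + eps**2 / 2.0)))
    mask = rr <= r0 * (1.0 + eps * np.cos(p.n_lobes * theta))
    img[mask] = TISSUE + p.contrast * (255.0 - TISSUE)

    if p.blur_sigma > 0:
        img = gaussian_filter(img, p.blur_sigma)
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, img.shape)
    pixels = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    frame = OrificeFrame(pixels=pixels, mm_per_px=mm_per_px, timestamp=p.timestamp)
    return frame, mask
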