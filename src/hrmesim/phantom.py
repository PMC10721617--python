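"""Synthetic scenes: proflavine-like nuclear phantoms rendered through a
fiber bundle.

The scene model is deliberately simple: bright circular nuclei scattered
by a homogeneous Poisson process over a dimmer cytoplasmic background.
A rendered frame samples a moving circular window of that scene,
integrates over the exposure while the probe translates, applies a
Gaussian blur standing in for the optics' lateral resolution, imposes
the hexagonal fiber-core transmission pattern and the circular field
mask, gamma-encodes, and adds clipped Gaussian sensor noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .acquisition import AcquisitionParams, Frame, FrameSequence, TrajectorySpec

__all__ = ["ScenePhantom", "generate_phantom", "render_sequence", "honeycomb_map"]


@dataclass
class ScenePhantom:
    """Ground-truth scene: nuclei as (y_um, x_um, radius_um, intensity).

    ``extent`` is the (height, width) of the scene in micrometers;
    ``cytoplasm_intensity`` the background level as a fraction of full
    scale; ``honeycomb_pitch`` the fiber core spacing in micrometers.
    """

    nuclei: np.ndarray  # (n, 4) columns: y, x, radius, intensity
    extent: tuple[float, float]
    cytoplasm_intensity: float = 0.15
    honeycomb_pitch: float = 3.0

    def __post_init__(self) -> None:
        self.nuclei = np.atleast_2d(np.asarray(self.nuclei, dtype=np.float64))
        if self.nuclei.size == 0:
            self.nuclei = np.empty((0, 4))
        if self.nuclei.shape[1] != 4:
            raise ValueError("nuclei must have columns (y, x, radius, intensity)")
        h, w = self.extent
        if h <= 0 or w <= 0:
            raise ValueError("extent must be positive")
        if self.nuclei.shape[0]:
            y, x, r, a = self.nuclei.T
            if (y < 0).any() or (y > h).any() or (x < 0).any() or (x > w).any():
                raise ValueError("nuclei must lie within extent")
            if (r <= 0).any():
                raise ValueError("nucleus radii must be positive")
            if (a <= 0).any() or (a > 1).any():
                raise ValueError("nucleus intensities must be in (0, 1]")

    @property
    def n_nuclei(self) -> int:
        return self.nuclei.shape[0]


def generate_phantom(
    extent: tuple[float, float],
    nucleus_density: float,
    nucleus_radius_range: tuple[float, float] = (3.0, 5.0),
    intensity_range: tuple[float, float] = (0.6, 0.95),
    seed: int = 0,
    cytoplasm_intensity: float = 0.15,
    honeycomb_pitch: float = 3.0,
) -> ScenePhantom:
    """Draw a nuclear phantom from a homogeneous Poisson process.

    ``nucleus_density`` is in nuclei per square millimeter; ``extent`` in
    micrometers.  Nucleus count ~ Poisson(density x area); positions
    uniform; radii and peak intensities uniform over the given ranges.
    Overlaps are permitted.  Deterministic for a given seed.
    """
    h, w = extent
    if h <= 0 or w <= 0:
        raise ValueError("extent must be positive")
    if nucleus_density < 0:
        raise ValueError("nucleus_density must be >= 0")
    r_lo, r_hi = nucleus_radius_range
    if r_lo <= 0 or r_hi < r_lo:
        raise ValueError("radius range must be positive and ordered")
    rng = np.random.default_rng(seed)
    area_mm2 = (h / 1000.0) * (w / 1000.0)
    n = rng.poisson(nucleus_density * area_mm2)
    nuclei = np.column_stack([
        rng.uniform(0, h, n),
        rng.uniform(0, w, n),
        rng.uniform(r_lo, r_hi, n),
        rng.uniform(*intensity_range, n),
    ]) if n else np.empty((0, 4))
    return ScenePhantom(
        nuclei=nuclei,
        extent=extent,
        cytoplasm_intensity=cytoplasm_intensity,
        honeycomb_pitch=honeycomb_pitch,
    )


def _rasterize_scene(phantom: ScenePhantom, pixel_pitch: float) -> np.ndarray:
    """Render the full phantom extent on the device pixel grid (linear)."""
    h_px = int(round(phantom.extent[0] / pixel_pitch))
    w_px = int(round(phantom.extent[1] / pixel_pitch))
    img = np.full((h_px, w_px), phantom.cytoplasm_intensity, dtype=np.float64)
    for y, x, r, a in phantom.nuclei:
        cy, cx, rp = y / pixel_pitch, x / pixel_pitch, r / pixel_pitch
        y0, y1 = max(0, int(cy - rp) - 1), min(h_px, int(cy + rp) + 2)
        x0, x1 = max(0, int(cx - rp) - 1), min(w_px, int(cx + rp) + 2)
        if y0 >= y1 or x0 >= x1:
            continue
        yy, xx = np.mgrid[y0:y1, x0:x1]
        inside = (yy + 0.5 - cy) ** 2 + (xx + 0.5 - cx) ** 2 <= rp**2
        # nuclei are brighter than cytoplasm; overlaps take the max
        np.maximum(img[y0:y1, x0:x1], np.where(inside, a, 0.0),
                   out=img[y0:y1, x0:x1])
    return img


def honeycomb_map(size: int, pitch_px: float, depth: float = 0.35) -> np.ndarray:
    """Hexagonal-lattice multiplicative transmission map on [1-depth, 1].

    Superposition of three plane-wave cosines at 60 degrees gives the
    classic honeycomb intensity pattern of a coherent fiber bundle.
    """
    y, x = np.mgrid[0:size, 0:size].astype(np.float64)
    k = 2 * np.pi / pitch_px
    f = (
        np.cos(k * x)
        + np.cos(k * (x / 2 + np.sqrt(3) * y / 2))
        + np.cos(k * (x / 2 - np.sqrt(3) * y / 2))
    )
    f = (f + 1.5) / 4.5  # range [0, 1]
    return 1.0 - depth * (1.0 - f)


def circular_mask(size: int) -> np.ndarray:
    """Boolean mask of the inscribed circular field of view."""
    c = (size - 1) / 2.0
    y, x = np.mgrid[0:size, 0:size]
    return (y - c) ** 2 + (x - c) ** 2 <= (size / 2.0) ** 2


def render_sequence(
    phantom: ScenePhantom,
    trajectory: TrajectorySpec,
    params: AcquisitionParams,
    n_frames: int = 5,
    seed: int = 0,
    start_offset_um: tuple[float, float] | None = None,
    honeycomb_depth: float = 0.35,
    exposure_substeps: int | None = None,
    apply_field_mask: bool = True,
) -> FrameSequence:
    """Render ``n_frames`` frames of the phantom under probe translation.

    Each frame integrates the scene over its exposure window: the
    within-exposure blur extent is speed x exposure and the inter-frame
    scene shift is speed / frame_rate.  The probe window must stay
    inside the phantom extent for the whole sequence, else a ValueError
    is raised.  Noise uses a per-frame substream derived from ``seed``.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    size = params.raster_size
    scene = _rasterize_scene(phantom, params.pixel_pitch)
    # optics: lateral resolution modeled as Gaussian PSF (FWHM = resolution)
    psf_sigma = params.lateral_resolution / params.pixel_pitch / 2.355
    if psf_sigma > 0:
        scene = ndimage.gaussian_filter(scene, psf_sigma, mode="nearest")
    hcomb = honeycomb_map(size, phantom.honeycomb_pitch / params.pixel_pitch,
                          depth=honeycomb_depth)
    mask = circular_mask(size)

    if start_offset_um is None:
        # center the window; leave room for the full trajectory
        sy = (phantom.extent[0] - size * params.pixel_pitch) / 2
        sx = (phantom.extent[1] - size * params.pixel_pitch) / 2
        start_offset_um = (sy, sx)

    blur_um = trajectory.speed * params.exposure  # mm/s * ms = um
    if exposure_substeps is None:
        exposure_substeps = max(1, int(np.ceil(2 * blur_um / params.pixel_pitch)))

    master = np.random.default_rng(seed)
    frame_seeds = master.integers(0, 2**31 - 1, size=n_frames)

    frames = []
    for i in range(n_frames):
        t0 = i * params.frame_period_ms
        acc = np.zeros((size, size))
        for s in range(exposure_substeps):
            t = t0 + (s + 0.5) / exposure_substeps * params.exposure
            dy, dx = trajectory.offset_um(t)
            oy = (start_offset_um[0] + dy) / params.pixel_pitch
            ox = (start_offset_um[1] + dx) / params.pixel_pitch
            if (oy < 0 or ox < 0 or oy + size > scene.shape[0]
                    or ox + size > scene.shape[1]):
                raise ValueError("trajectory carries the probe outside the phantom")
            acc += _bilinear_window(scene, oy, ox, size)
        img = acc / exposure_substeps
        img = img * hcomb
        if apply_field_mask:
            img[~mask] = 0.0
        if params.gamma_exponent != 1.0:
            img = np.power(np.clip(img, 0.0, 1.0), params.gamma_exponent)
        if params.noise_sigma > 0:
            rng = np.random.default_rng(frame_seeds[i])
            img = img + rng.normal(0.0, params.noise_sigma, img.shape)
        img = np.clip(img, 0.0, 1.0)
        frames.append(Frame(
            pixels=img,
            params=params,
            timestamp=t0,
            gamma_encoded=True,
        ))
    return FrameSequence(frames=frames, selected_index=n_frames - 1)


def _bilinear_window(scene: np.ndarray, oy: float, ox: float, size: int) -> np.ndarray:
    """Extract a size x size window at fractional offset (oy, ox)."""
    iy, ix = int(np.floor(oy)), int(np.floor(ox))
    fy, fx = oy - iy, ox - ix
    # need one extra row/col for interpolation
    block = scene[iy:iy + size + 1, ix:ix + size + 1]
    if block.shape[0] < size + 1 or block.shape[1] < size + 1:
        pad_y = size + 1 - block.shape[0]
        pad_x = size + 1 - block.shape[1]
        block = np.pad(block, ((0, pad_y), (0, pad_x)), mode="edge")
    return (
        (1 - fy) * (1 - fx) * block[:size, :size]
        + (1 - fy) * fx * block[:size, 1:size + 1]
        + fy * (1 - fx) * block[1:size + 1, :size]
        + fy * fx * block[1:size + 1, 1:size + 1]
    )
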