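"""Acquisition metadata and image containers for fiber-bundle microendoscopy.

Pixel intensities are stored as float64 on the normalized [0, 1] scale
throughout; ``bit_depth`` matters only when frames are written to or read
from integer image files.  Two device presets are provided: the high
frame rate system (70 fps, 1.4 ms exposure, 1.24 um/px, 790 um field of
view) and the original slower system it is compared against (15 fps,
0.78 um/px).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

__all__ = [
    "AcquisitionParams",
    "TrajectorySpec",
    "Frame",
    "FrameSequence",
    "HF_HRME_PARAMS",
    "ORIGINAL_HRME_PARAMS",
    "write_frame",
    "read_frame",
    "write_sequence",
    "read_sequence",
]


@dataclass(frozen=True)
class AcquisitionParams:
    """Camera and probe constants of a microendoscope acquisition.

    Parameters
    ----------
    frame_rate : float
        Frames per second.
    exposure : float
        Per-frame exposure in milliseconds; must fit in the frame period.
    pixel_pitch : float
        Micrometers per pixel at the tissue interface.
    fov_diameter : float
        Diameter of the circular illuminated field, micrometers.
    lateral_resolution : float
        Optical lateral resolution (FWHM-like scale), micrometers.
    bit_depth : int
        Bits per pixel of the sensor output (for file quantization).
    gamma_exponent : float
        Display gamma applied by the camera pipeline (1 = linear).
    noise_sigma : float
        Additive Gaussian sensor noise, as a fraction of full scale.
    saturation_level : float
        Intensity (fraction of full scale) at/above which a pixel is
        considered saturated.
    """

    frame_rate: float = 70.0
    exposure: float = 1.4
    pixel_pitch: float = 1.24
    fov_diameter: float = 790.0
    lateral_resolution: float = 4.0
    bit_depth: int = 8
    gamma_exponent: float = 1.0
    noise_sigma: float = 0.01
    saturation_level: float = 1.0
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")
        if self.exposure > 1000.0 / self.frame_rate + 1e-9:
            raise ValueError(
                f"exposure {self.exposure} ms exceeds frame period "
                f"{1000.0 / self.frame_rate:.3f} ms"
            )
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.fov_diameter <= 0:
            raise ValueError("fov_diameter must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not 0 < self.saturation_level <= 1:
            raise ValueError("saturation_level must be in (0, 1]")

    @property
    def raster_size(self) -> int:
        """Side length in pixels of the square raster holding the field."""
        return int(round(self.fov_diameter / self.pixel_pitch))

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.frame_rate


#: High frame rate device: 70 fps, 1.4 ms, 1.24 um/px, 790 um FOV, 4 um resolution.
HF_HRME_PARAMS = AcquisitionParams(
    frame_rate=70.0,
    exposure=1.4,
    pixel_pitch=1.24,
    fov_diameter=790.0,
    lateral_resolution=4.0,
    metadata={"dynamic_range_db": 74.35, "temporal_dark_noise_e": 3.8},
)

#: Original slower device: 15 fps, 0.78 um/px.
ORIGINAL_HRME_PARAMS = AcquisitionParams(
    frame_rate=15.0,
    exposure=10.0,
    pixel_pitch=0.78,
    fov_diameter=790.0,
    lateral_resolution=4.0,
    metadata={"dynamic_range_db": 57.85, "temporal_dark_noise_e": 7.65},
)


@dataclass(frozen=True)
class TrajectorySpec:
    """Constant-velocity probe translation over the scene.

    speed is in millimeters per second; direction is a 2-vector (dy, dx)
    normalized to unit length on construction; duration in seconds.
    """

    speed: float = 0.0
    direction: tuple[float, float] = (0.0, 1.0)
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.speed < 0:
            raise ValueError("speed must be >= 0")
        norm = float(np.hypot(*self.direction))
        if norm == 0:
            if self.speed > 0:
                raise ValueError("zero direction with nonzero speed")
            object.__setattr__(self, "direction", (0.0, 1.0))
        else:
            object.__setattr__(
                self,
                "direction",
                (self.direction[0] / norm, self.direction[1] / norm),
            )

    def offset_um(self, t_ms: float) -> tuple[float, float]:
        """Probe-center displacement (dy, dx) in micrometers at time ``t_ms``."""
        d = self.speed * t_ms  # mm/s * ms = um
        return (d * self.direction[0], d * self.direction[1])


@dataclass
class Frame:
    """A single grayscale frame with its acquisition metadata.

    ``pixels`` is a square float64 array on [0, 1]; ``timestamp`` in
    milliseconds from sequence start; ``gamma_encoded`` records whether a
    display gamma has been applied.
    """

    pixels: np.ndarray
    params: AcquisitionParams
    timestamp: float = 0.0
    gamma_encoded: bool = True

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D raster")
        if self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("raster must be square")
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def copy_with(self, pixels: np.ndarray, **kw) -> "Frame":
        return Frame(
            pixels=pixels,
            params=kw.pop("params", self.params),
            timestamp=kw.pop("timestamp", self.timestamp),
            gamma_encoded=kw.pop("gamma_encoded", self.gamma_encoded),
        )


@dataclass
class FrameSequence:
    """Ordered frames sharing acquisition parameters.

    ``selected_index`` marks the clinically selected frame that downstream
    averaging treats as the anchor (it is averaged together with the
    frames preceding it).
    """

    frames: list[Frame]
    selected_index: int = -1

    def __post_init__(self) -> None:
        if len(self.frames) < 1:
            raise ValueError("sequence needs at least one frame")
        p0 = self.frames[0].params
        if any(f.params != p0 for f in self.frames):
            raise ValueError("all frames must share acquisition params")
        if self.selected_index < 0:
            self.selected_index = len(self.frames) - 1
        if not 0 <= self.selected_index < len(self.frames):
            raise ValueError("selected_index out of range")
        ts = [f.timestamp for f in self.frames]
        period = p0.frame_period_ms
        for a, b in zip(ts, ts[1:]):
            if not np.isclose(b - a, period, rtol=1e-6, atol=1e-6):
                raise ValueError("timestamps must step by one frame period")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def params(self) -> AcquisitionParams:
        return self.frames[0].params

    @property
    def selected(self) -> Frame:
        return self.frames[self.selected_index]


def _quantize(pixels: np.ndarray, bit_depth: int) -> np.ndarray:
    full = (1 << bit_depth) - 1
    q = np.rint(np.clip(pixels, 0.0, 1.0) * full)
    return q.astype(np.uint16 if bit_depth > 8 else np.uint8)


def write_frame(frame: Frame, path: str | Path, bit_depth: int | None = None) -> None:
    """Write one frame as 16-bit TIFF or 8-bit PNG depending on extension."""
    path = Path(path)
    depth = bit_depth or (8 if path.suffix.lower() == ".png" else 16)
    data = _quantize(frame.pixels, depth)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def read_frame(path: str | Path, params: AcquisitionParams | None = None,
               gamma_encoded: bool = True) -> Frame:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    if data.ndim == 3:  # first page of a stack
        data = data[0]
    full = float(np.iinfo(data.dtype).max) if data.dtype.kind == "u" else 1.0
    return Frame(
        pixels=np.asarray(data, dtype=np.float64) / full,
        params=params or AcquisitionParams(),
        gamma_encoded=gamma_encoded,
    )


def write_sequence(seq: FrameSequence, path: str | Path,
                   bit_depth: int = 16) -> None:
    """Write a frame sequence as a multi-page TIFF."""
    stack = np.stack([_quantize(f.pixels, bit_depth) for f in seq.frames])
    tifffile.imwrite(Path(path), stack, metadata={
        "selected_index": seq.selected_index,
        "frame_rate": seq.params.frame_rate,
    })


def read_sequence(path: str | Path, params: AcquisitionParams | None = None,
                  selected_index: int = -1, gamma_encoded: bool = True) -> FrameSequence:
    stack = tifffile.imread(Path(path))
    if stack.ndim == 2:
        stack = stack[None]
    full = float(np.iinfo(stack.dtype).max) if stack.dtype.kind == "u" else 1.0
    params = params or AcquisitionParams()
    frames = [
        Frame(
            pixels=np.asarray(page, dtype=np.float64) / full,
            params=params,
            timestamp=i * params.frame_period_ms,
            gamma_encoded=gamma_encoded,
        )
        for i, page in enumerate(stack)
    ]
    return FrameSequence(frames=frames, selected_index=selected_index)
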