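"""Frame-rate and contrast degradation: simulate a slow, noisy camera
from a fast acquisition.

Blur synthesis works in linear intensity space: invert the source gamma,
average the selected frame with its preceding frames (a 5-frame average
of a 70 fps / 1.4 ms acquisition emulates a 14 fps system with a 7 ms
composite exposure), soften the fiber-core honeycomb with a small
Gaussian, re-inject sensor noise, re-impose the saturated regions of
the selected frame, and re-apply the target system's gamma.  Contrast
reduction then remaps the composite's grayscale distribution onto the
target system's luminance mean and standard deviation.

``method_config`` enumerates the ablation grid: method 1 enables every
component; methods 2-6 each disable exactly one (gamma handling, fiber
smoothing, noise injection, saturation preservation, contrast
reduction, in that order).  Frame averaging always runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .acquisition import Frame, FrameSequence

__all__ = [
    "LuminanceStats",
    "DegradationConfig",
    "method_config",
    "linearize",
    "encode_gamma",
    "average_frames",
    "smooth_fiber_pattern",
    "inject_noise",
    "preserve_saturation",
    "transfer_luminance_stats",
    "apply_method",
    "DegenerateInputError",
]


class DegenerateInputError(ValueError):
    """Input lacks the variation the operation requires (e.g. zero variance)."""


@dataclass(frozen=True)
class LuminanceStats:
    """Target grayscale mean/std on the normalized [0, 1] scale."""

    mean: float = 0.35
    std: float = 0.12

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("std must be >= 0")


@dataclass(frozen=True)
class DegradationConfig:
    n_average: int = 5
    enable_gamma_correction: bool = True
    enable_fiber_smoothing: bool = True
    enable_noise_injection: bool = True
    enable_saturation_preservation: bool = True
    enable_contrast_reduction: bool = True
    source_gamma: float = 0.7
    target_gamma: float = 0.7
    smoothing_sigma: float = 1.0
    noise_sigma: float = 0.04
    saturation_level: float = 1.0
    target_stats: LuminanceStats = field(default_factory=LuminanceStats)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_average < 1:
            raise ValueError("n_average must be >= 1")
        if self.smoothing_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("sigmas must be >= 0")
        if not 0 < self.saturation_level <= 1:
            raise ValueError("saturation_level must be in (0, 1]")
        if self.source_gamma <= 0 or self.target_gamma <= 0:
            raise ValueError("gamma exponents must be positive")


#: which single component each ablation method switches off (method 1: none)
_METHOD_OFF = {
    1: None,
    2: "enable_gamma_correction",
    3: "enable_fiber_smoothing",
    4: "enable_noise_injection",
    5: "enable_saturation_preservation",
    6: "enable_contrast_reduction",
}


def method_config(method: int, base: DegradationConfig | None = None
                  ) -> DegradationConfig:
    """Ablation config for methods 1-6 (1 = all components enabled)."""
    if method not in _METHOD_OFF:
        raise ValueError("method must be in 1..6")
    cfg = base or DegradationConfig()
    cfg = replace(
        cfg,
        enable_gamma_correction=True,
        enable_fiber_smoothing=True,
        enable_noise_injection=True,
        enable_saturation_preservation=True,
        enable_contrast_reduction=True,
    )
    off = _METHOD_OFF[method]
    return cfg if off is None else replace(cfg, **{off: False})


def linearize(frame: Frame, gamma: float) -> Frame:
    """Invert display gamma: normalized pixels raised to 1/gamma."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if not frame.gamma_encoded:
        raise ValueError("frame is already linear")
    out = np.power(np.clip(frame.pixels, 0.0, 1.0), 1.0 / gamma)
    return frame.copy_with(out, gamma_encoded=False)


def encode_gamma(frame: Frame, gamma: float) -> Frame:
    """Apply display gamma: normalized pixels raised to gamma."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    if frame.gamma_encoded:
        raise ValueError("frame is already gamma encoded")
    out = np.power(np.clip(frame.pixels, 0.0, 1.0), gamma)
    return frame.copy_with(out, gamma_encoded=True)


def average_frames(seq: FrameSequence, n: int) -> tuple[Frame, float, float]:
    """Average the selected frame with its n-1 predecessors.

    Returns (composite frame, equivalent frame rate, composite exposure
    in ms).  Averaging k frames of an f fps camera emulates an f/k fps
    camera with a k-fold exposure.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if seq.selected_index < n - 1:
        raise ValueError(
            f"selected frame has only {seq.selected_index} predecessors, "
            f"need {n - 1}")
    window = seq.frames[seq.selected_index - n + 1: seq.selected_index + 1]
    composite = np.mean([f.pixels for f in window], axis=0)
    params = seq.params
    equivalent_rate = params.frame_rate / n
    composite_exposure = n * params.exposure
    out = seq.selected.copy_with(composite)
    return out, equivalent_rate, composite_exposure


def smooth_fiber_pattern(frame: Frame, sigma: float) -> Frame:
    """Soften the fiber-core honeycomb with a normalized Gaussian kernel."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return frame.copy_with(frame.pixels.copy())
    out = ndimage.gaussian_filter(frame.pixels, sigma, mode="nearest")
    return frame.copy_with(out)


def inject_noise(frame: Frame, noise_sigma: float, seed: int = 0) -> Frame:
    """Add zero-mean Gaussian noise, clipped to [0, 1]; seed-deterministic."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0:
        return frame.copy_with(frame.pixels.copy())
    rng = np.random.default_rng(seed)
    out = np.clip(frame.pixels + rng.normal(0.0, noise_sigma, frame.shape),
                  0.0, 1.0)
    return frame.copy_with(out)


def preserve_saturation(composite: Frame, selected: Frame,
                        saturation_level: float = 1.0) -> Frame:
    """Re-impose the selected frame's saturated pixels on the composite.

    Averaging dampens saturation; pixels at or above the saturation
    level in the selected frame are forced to full scale in the output.
    """
    if composite.shape != selected.shape:
        raise ValueError("frames must share raster shape")
    sat = selected.pixels >= saturation_level
    out = composite.pixels.copy()
    out[sat] = 1.0
    return composite.copy_with(out)


def transfer_luminance_stats(frame: Frame, target: LuminanceStats) -> Frame:
    """Affine grayscale-distribution transfer to a target mean and std.

    The frame is mean-normalized, divided by its standard deviation,
    scaled by the target std and shifted to the target mean; before
    clipping the output statistics equal the targets exactly.  On a
    single-channel image this is the luminance-channel color transfer
    (a grayscale image's CIELAB L channel is a monotone function of
    intensity, so matching intensity stats keeps the contract exact).
    """
    px = frame.pixels
    s = px.std()
    if s == 0:
        raise DegenerateInputError("zero-variance input: cannot transfer stats")
    out = (px - px.mean()) / s * target.std + target.mean
    return frame.copy_with(np.clip(out, 0.0, 1.0))


def apply_method(seq: FrameSequence, config: DegradationConfig) -> Frame:
    """Run the full degradation pipeline on a frame sequence.

    Stage order: (gamma inversion) -> frame averaging -> (fiber-core
    smoothing) -> (noise injection) -> (saturation preservation) ->
    (gamma re-encoding) -> (contrast reduction); parenthesized stages
    honor their config toggles, averaging always runs.
    """
    selected = seq.selected
    work_seq = seq
    if config.enable_gamma_correction:
        lin = [linearize(f, config.source_gamma) if f.gamma_encoded else f
               for f in seq.frames]
        work_seq = FrameSequence(frames=lin, selected_index=seq.selected_index)
    composite, _, _ = average_frames(work_seq, config.n_average)
    if config.enable_fiber_smoothing:
        composite = smooth_fiber_pattern(composite, config.smoothing_sigma)
    if config.enable_noise_injection:
        composite = inject_noise(composite, config.noise_sigma, config.seed)
    if config.enable_saturation_preservation:
        composite = preserve_saturation(composite, selected,
                                        config.saturation_level)
    if config.enable_gamma_correction:
        composite = encode_gamma(composite, config.target_gamma)
    if config.enable_contrast_reduction:
        composite = transfer_luminance_stats(composite, config.target_stats)
    return composite
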