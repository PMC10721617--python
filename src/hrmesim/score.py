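"""Frame preprocessing and site scoring.

A frame is resampled to the reference pixel pitch, cropped to the
bounding square of the illuminated probe circle, split into quadrants,
and each quadrant is scored by a pluggable classifier returning the
probability of high-grade disease.  The site score is the mean quadrant
probability; the positivity call applies an inclusive cutoff
(default 0.4).  A simple automated quality check stands in for expert
review: a frame fails when more than half the field is out of contact
or out of focus.

The baseline classifier here is a fixed-weight morphometry scorer
(nuclear segmentation, count density, size, contrast) — a transparent
stand-in for a trained network, with no claim of equivalent accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol

import numpy as np
from scipy import ndimage
from skimage import filters, measure, transform

from .acquisition import Frame

__all__ = [
    "ProbeRegion",
    "QuadrantSet",
    "SiteScore",
    "QCResult",
    "ProbeNotFoundError",
    "detect_probe_region",
    "resample_to_reference",
    "split_quadrants",
    "QuadrantClassifier",
    "MorphometryClassifier",
    "baseline_quadrant_probability",
    "score_site",
    "call_site",
    "assess_quality",
    "score_frame",
]


class ProbeNotFoundError(ValueError):
    """No illuminated probe disk could be located in the frame."""


@dataclass(frozen=True)
class ProbeRegion:
    """Illuminated circular field: center (y, x), radius, bounding square.

    Coordinates are 0-based pixels; the bounding square is half-open
    (y0, x0, y1, x1) and inscribes the circle, clipped to the raster.
    """

    center: tuple[float, float]
    radius: float
    bounding_square: tuple[int, int, int, int]

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        y0, x0, y1, x1 = self.bounding_square
        if y1 <= y0 or x1 <= x0:
            raise ValueError("empty bounding square")


def detect_probe_region(frame: Frame, min_area_fraction: float = 0.05
                        ) -> ProbeRegion:
    """Locate the bright probe disk: Otsu threshold, largest component,
    centroid and equivalent radius.

    Otsu runs on a strongly smoothed copy so the threshold separates the
    illuminated field from the dark exterior rather than nuclei from
    cytoplasm; holes in the component are filled before measuring.
    """
    px = frame.pixels
    if px.max() <= px.min():
        raise ProbeNotFoundError("frame has no intensity variation")
    smooth = ndimage.gaussian_filter(px, max(2.0, px.shape[0] / 64))
    thr = filters.threshold_otsu(smooth)
    mask = ndimage.binary_fill_holes(smooth > thr)
    # a probe disk sits on a dark exterior; when the "background" is
    # nearly as bright as the "foreground" the whole frame is
    # illuminated and the field is the inscribed circle of the raster
    if (~mask).any() and mask.any():
        if smooth[~mask].mean() > 0.5 * smooth[mask].mean():
            mask = np.ones_like(mask)
    h, w = px.shape
    if mask.all():
        side = min(h, w)
        return ProbeRegion(center=((h - 1) / 2.0, (w - 1) / 2.0),
                           radius=side / 2.0, bounding_square=(0, 0, h, w))
    labeled, n = ndimage.label(mask)
    if n == 0:
        raise ProbeNotFoundError("no bright region found")
    props = measure.regionprops(labeled)
    best = max(props, key=lambda p: p.area)
    if best.area < min_area_fraction * px.size:
        raise ProbeNotFoundError(
            f"largest bright component covers {best.area / px.size:.1%} "
            f"of the raster (< {min_area_fraction:.0%})")
    cy, cx = best.centroid
    radius = float(np.sqrt(best.area / np.pi))
    h, w = px.shape
    y0 = max(0, int(round(cy - radius)))
    x0 = max(0, int(round(cx - radius)))
    y1 = min(h, int(round(cy + radius)))
    x1 = min(w, int(round(cx + radius)))
    return ProbeRegion(center=(float(cy), float(cx)), radius=radius,
                       bounding_square=(y0, x0, y1, x1))


def resample_to_reference(frame: Frame, src_pitch: float, ref_pitch: float,
                          printed_factor: bool = True) -> Frame:
    """Bilinear resample so the pixel pitch matches a reference device.

    The scale factor is src_pitch/ref_pitch, rounded to one decimal in
    the default ``printed_factor`` mode (1.24/0.78 -> 1.6), exact
    otherwise.  Output side = round(input side x factor).
    """
    if src_pitch <= 0 or ref_pitch <= 0:
        raise ValueError("pixel pitches must be positive")
    factor = src_pitch / ref_pitch
    if printed_factor:
        factor = round(factor, 1)
    if factor == 1.0:
        return frame.copy_with(frame.pixels.copy())
    n = frame.shape[0]
    out_n = int(round(n * factor))
    out = transform.resize(frame.pixels, (out_n, out_n), order=1,
                           anti_aliasing=factor < 1.0)
    return frame.copy_with(np.clip(out, 0.0, 1.0))


@dataclass
class QuadrantSet:
    """The four sub-rasters of a probe crop, in fixed order
    (top-left, top-right, bottom-left, bottom-right)."""

    quadrants: list[np.ndarray]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.quadrants) != 4:
            raise ValueError("need exactly 4 quadrants")


def split_quadrants(frame: Frame, region: ProbeRegion) -> QuadrantSet:
    """Crop the probe bounding square and split it into quadrants.

    Odd side lengths use a floor split: the first (top/left) block gets
    the extra pixel, so the four quadrants tile the crop exactly.
    """
    y0, x0, y1, x1 = region.bounding_square
    h, w = frame.shape
    if y0 < 0 or x0 < 0 or y1 > h or x1 > w:
        raise ValueError("region outside raster")
    crop = frame.pixels[y0:y1, x0:x1]
    my = (crop.shape[0] + 1) // 2
    mx = (crop.shape[1] + 1) // 2
    return QuadrantSet(
        quadrants=[
            crop[:my, :mx], crop[:my, mx:],
            crop[my:, :mx], crop[my:, mx:],
        ],
        provenance=f"bbox=({y0},{x0},{y1},{x1})",
    )


class QuadrantClassifier(Protocol):
    """Anything mapping a quadrant raster to a probability of AIN2+."""

    def __call__(self, quadrant: np.ndarray) -> float: ...


def _segment_nuclei(quadrant: np.ndarray, min_area_px: int = 4,
                    min_contrast_ratio: float = 1.3
                    ) -> tuple[np.ndarray, int]:
    """Threshold-based nuclear segmentation; returns (label image, count).

    Candidate nuclei are pixels above mean + 0.8 std, cleaned of
    specks below ``min_area_px``.  A contrast gate rejects the whole
    segmentation when the candidate foreground is barely brighter than
    the background (flat, noise-only quadrants would otherwise yield
    spurious "nuclei" from the noise itself).
    """
    q = np.asarray(quadrant, dtype=float)
    thr = q.mean() + 0.8 * q.std()
    mask = q > thr
    labeled, n = ndimage.label(mask)
    if n:
        areas = ndimage.sum_labels(mask, labeled, index=np.arange(1, n + 1))
        keep = np.flatnonzero(areas >= min_area_px) + 1
        mask = np.isin(labeled, keep)
        labeled, n = ndimage.label(mask)
    if n:
        bg = q[~mask]
        if bg.size == 0 or bg.mean() <= 0 or \
                q[mask].mean() < min_contrast_ratio * bg.mean():
            return np.zeros_like(labeled), 0
    return labeled, n


@dataclass
class MorphometryClassifier:
    """Fixed-weight logistic scorer over nuclear morphometry features.

    Features: nuclear area fraction, nucleus count density (per 1000 px),
    mean nucleus area (px), and nuclear/background intensity ratio.
    Weights are configuration constants, not trained at run time; an
    all-zero feature vector (no nuclei) maps well below 0.1.
    """

    weights: dict[str, float] = field(default_factory=lambda: {
        "bias": -3.0,
        "area_fraction": 9.0,
        "count_density": 0.35,
        "mean_area": 0.010,
        "contrast": 0.5,
    })
    min_area_px: int = 4

    def features(self, quadrant: np.ndarray) -> dict[str, float]:
        q = np.asarray(quadrant, dtype=float)
        if q.size == 0:
            raise ValueError("empty quadrant")
        if q.std() == 0:
            # low-information quadrant: all features at their floor
            return {"area_fraction": 0.0, "count_density": 0.0,
                    "mean_area": 0.0, "contrast": 0.0,
                    "low_information": 1.0}
        labeled, n = _segment_nuclei(q, self.min_area_px)
        mask = labeled > 0
        af = float(mask.mean())
        density = 1000.0 * n / q.size
        mean_area = float(mask.sum() / n) if n else 0.0
        bg = q[~mask]
        contrast = float(q[mask].mean() / bg.mean() - 1.0) if (
            n and bg.size and bg.mean() > 0) else 0.0
        return {"area_fraction": af, "count_density": density,
                "mean_area": mean_area, "contrast": max(0.0, contrast),
                "low_information": 0.0}

    def __call__(self, quadrant: np.ndarray) -> float:
        f = self.features(quadrant)
        w = self.weights
        z = (w["bias"]
             + w["area_fraction"] * f["area_fraction"]
             + w["count_density"] * f["count_density"]
             + w["mean_area"] * f["mean_area"]
             + w["contrast"] * f["contrast"])
        return float(1.0 / (1.0 + np.exp(-z)))


def baseline_quadrant_probability(quadrant: np.ndarray,
                                  classifier: MorphometryClassifier | None = None
                                  ) -> float:
    """Score one quadrant with the default morphometry classifier."""
    return (classifier or MorphometryClassifier())(quadrant)


@dataclass
class SiteScore:
    site_id: str
    quadrant_probabilities: tuple[float, float, float, float]
    score: float
    cutoff: float
    call: str  # "positive" | "negative"


def score_site(quadrants: QuadrantSet,
               classifier: QuadrantClassifier | None = None,
               site_id: str = "", cutoff: float = 0.4) -> SiteScore:
    """Mean of the four quadrant probabilities, with the positivity call."""
    clf = classifier or MorphometryClassifier()
    probs = []
    for q in quadrants.quadrants:
        p = float(clf(q))
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"classifier returned {p}, outside [0, 1]")
        probs.append(p)
    score = float(np.mean(probs))
    return SiteScore(
        site_id=site_id,
        quadrant_probabilities=tuple(probs),
        score=score,
        cutoff=cutoff,
        call=call_site(score, cutoff),
    )


def call_site(score: float, cutoff: float = 0.4) -> str:
    """Positive iff score >= cutoff (inclusive)."""
    if not 0 <= score <= 1 or not 0 <= cutoff <= 1:
        raise ValueError("score and cutoff must be in [0, 1]")
    return "positive" if score >= cutoff else "negative"


@dataclass
class QCResult:
    contact_fraction: float
    sharp_fraction: float
    criterion: float
    passed: bool


def assess_quality(frame: Frame, region: ProbeRegion, criterion: float = 0.5,
                   contact_threshold: float = 0.1,
                   focus_threshold: float = 1e-4,
                   tile: int = 16) -> QCResult:
    """Automated image-quality proxy for expert review.

    ``contact_fraction`` is the fraction of in-region pixels above the
    contact intensity threshold; ``sharp_fraction`` the fraction of
    in-region tiles whose mean squared gradient exceeds the focus
    threshold.  The frame fails when more than ``criterion`` of the
    field is degraded, i.e. 1 - min(contact, sharp) > criterion
    (strictly; exactly 50% degraded passes).
    """
    px = frame.pixels
    y0, x0, y1, x1 = region.bounding_square
    cy, cx = region.center
    yy, xx = np.mgrid[0:px.shape[0], 0:px.shape[1]]
    inside = (yy - cy) ** 2 + (xx - cx) ** 2 <= region.radius**2
    if not inside.any():
        raise ValueError("region covers no pixels")
    contact_fraction = float((px[inside] > contact_threshold).mean())

    gy, gx = np.gradient(px)
    energy = gy**2 + gx**2
    sharp_votes = []
    for ty in range(y0, y1, tile):
        for tx in range(x0, x1, tile):
            sel = inside[ty:ty + tile, tx:tx + tile]
            if sel.mean() < 0.5:
                continue  # tile mostly outside the field
            e = energy[ty:ty + tile, tx:tx + tile][sel]
            sharp_votes.append(e.mean() > focus_threshold)
    sharp_fraction = float(np.mean(sharp_votes)) if sharp_votes else 0.0
    degraded = 1.0 - min(contact_fraction, sharp_fraction)
    return QCResult(
        contact_fraction=contact_fraction,
        sharp_fraction=sharp_fraction,
        criterion=criterion,
        passed=not degraded > criterion,
    )


def score_frame(frame: Frame, classifier: QuadrantClassifier | None = None,
                cutoff: float = 0.4, ref_pitch: float = 0.78,
                site_id: str = "", resample: bool = True) -> SiteScore:
    """End-to-end single-frame scoring: resample, crop, split, score."""
    work = frame
    if resample and frame.params.pixel_pitch != ref_pitch:
        work = resample_to_reference(frame, frame.params.pixel_pitch, ref_pitch)
    region = detect_probe_region(work)
    quads = split_quadrants(work, region)
    return score_site(quads, classifier, site_id=site_id, cutoff=cutoff)
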