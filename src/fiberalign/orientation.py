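"""Local fiber-orientation estimation from grayscale actin images.

The pipeline treats every sufficiently bright, sufficiently anisotropic
pixel as one sample of local fiber direction.  Orientation is estimated
with the structure tensor: Gaussian-derivative gradients, tensor products
smoothed over a window, and eigen-analysis per pixel.  The direction of
minimal intensity variation (the eigenvector of the smaller eigenvalue) is
the fiber orientation; the normalized eigenvalue contrast is the coherence,
and the eigenvalue sum is the local gradient energy.

Angles follow the package-wide convention: degrees, axial (mod 180),
counterclockwise from the image-column axis in a y-up frame, which means
the row component of the gradient is negated before any angle is taken.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label
from skimage.morphology import disk

__all__ = [
    "Micrograph",
    "OrientationField",
    "FiberMask",
    "EmptySampleError",
    "structure_tensor_field",
    "fiber_mask",
    "extract_orientation_sample",
    "segment_cells",
]


class EmptySampleError(RuntimeError):
    """Raised when no pixels survive masking; relax the thresholds."""


@dataclass
class Micrograph:
    """A single-channel intensity image annotated with its flow axis."""

    pixels: np.ndarray
    flow_dir_deg: float = 0.0
    pixel_size_um: float | None = None
    image_id: str = "synthetic"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 16 or px.shape[1] < 16:
            raise ValueError("image must be 2D and at least 16x16 pixels")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("intensities must be finite and non-negative")
        self.pixels = px
        self.flow_dir_deg = float(self.flow_dir_deg) % 180.0


@dataclass
class OrientationField:
    """Per-pixel orientation (deg, [0,180)), coherence ([0,1]) and energy."""

    theta: np.ndarray
    coherence: np.ndarray
    energy: np.ndarray
    sigma_grad: float
    sigma_window: float

    @property
    def border_px(self) -> int:
        """Border width excluded from masks (edge-artifact suppression)."""
        return int(np.ceil(3 * self.sigma_window))


@dataclass
class FiberMask:
    mask: np.ndarray
    provenance: dict = field(default_factory=dict)


@dataclass
class OrientationSample:
    """A weighted collection of axial orientation measurements."""

    angles: np.ndarray
    weights: np.ndarray
    flow_dir_deg: float = 0.0
    source: str = "synthetic"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=np.float64) % 180.0
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.angles.shape != self.weights.shape:
            raise ValueError("angles and weights must have equal length")
        if np.any(self.weights < 0):
            raise ValueError("weights must be >= 0")
        if self.angles.size and self.weights.sum() <= 0:
            raise ValueError("non-empty sample must carry positive total weight")

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())

    @property
    def kish_ess(self) -> float:
        """Kish effective sample size of the weights."""
        w = self.weights
        s = w.sum()
        return float(s * s / np.sum(w * w)) if s > 0 else 0.0


def structure_tensor_field(
    image: Micrograph | np.ndarray,
    sigma_grad: float = 1.5,
    sigma_window: float = 6.0,
) -> OrientationField:
    """Estimate the per-pixel orientation field of an actin image.

    Gradients are Gaussian derivatives at scale ``sigma_grad``; the tensor
    products are smoothed with a Gaussian window of ``sigma_window``
    (reflective boundary handling throughout).  With eigenvalues
    l1 >= l2 of the smoothed tensor,

    * ``theta``      -- fiber direction: eigenvector of l2, i.e. the
      gradient-dominant half-angle ``0.5*atan2(2 Jxy, Jxx - Jyy)`` plus 90
      degrees, taken mod 180;
    * ``coherence``  -- (l1 - l2)/(l1 + l2), zero where the tensor vanishes;
    * ``energy``     -- l1 + l2.

    Isotropic pixels (l1 == l2) get coherence 0 and theta 0 by convention;
    any positive coherence threshold downstream removes them.
    """
    if sigma_grad <= 0 or sigma_window <= 0:
        raise ValueError("sigmas must be positive")
    if sigma_window < sigma_grad:
        raise ValueError("sigma_window must be >= sigma_grad")
    img = image.pixels if isinstance(image, Micrograph) else np.asarray(image, np.float64)
    if min(img.shape) < 6 * sigma_window:
        raise ValueError(
            f"image of shape {img.shape} is smaller than 6*sigma_window = {6 * sigma_window:g} px"
        )
    gx = ndimage.gaussian_filter(img, sigma_grad, order=(0, 1), mode="reflect")
    # row index increases downward; negate for the y-up frame
    gy = -ndimage.gaussian_filter(img, sigma_grad, order=(1, 0), mode="reflect")
    jxx = ndimage.gaussian_filter(gx * gx, sigma_window, mode="reflect")
    jxy = ndimage.gaussian_filter(gx * gy, sigma_window, mode="reflect")
    jyy = ndimage.gaussian_filter(gy * gy, sigma_window, mode="reflect")

    energy = jxx + jyy
    spread = np.hypot(jxx - jyy, 2.0 * jxy)  # = l1 - l2
    with np.errstate(invalid="ignore", divide="ignore"):
        coherence = np.where(energy > 0, spread / np.where(energy > 0, energy, 1.0), 0.0)
    coherence = np.clip(coherence, 0.0, 1.0)

    grad_angle = 0.5 * np.degrees(np.arctan2(2.0 * jxy, jxx - jyy))
    theta = (grad_angle + 90.0) % 180.0
    theta = np.where(spread > 0, theta, 0.0)
    return OrientationField(theta, coherence, energy, float(sigma_grad), float(sigma_window))


def fiber_mask(
    image: Micrograph | np.ndarray,
    fld: OrientationField,
    intensity_quantile: float = 0.75,
    coherence_min: float = 0.2,
) -> FiberMask:
    """Select fiber pixels: bright (above the intensity quantile), coherent
    (>= ``coherence_min``), with positive energy, away from the border.

    An empty mask is flagged in provenance rather than raised; downstream
    samplers decide how to react.
    """
    if not (0 < intensity_quantile < 1):
        raise ValueError("intensity_quantile must lie in (0, 1)")
    if not (0 <= coherence_min < 1):
        raise ValueError("coherence_min must lie in [0, 1)")
    img = image.pixels if isinstance(image, Micrograph) else np.asarray(image, np.float64)
    cutoff = float(np.quantile(img, intensity_quantile))
    mask = (img > cutoff) & (fld.coherence >= coherence_min) & (fld.energy > 0)
    b = fld.border_px
    if b > 0:
        border = np.zeros_like(mask)
        if mask.shape[0] > 2 * b and mask.shape[1] > 2 * b:
            border[b:-b, b:-b] = True
        mask &= border
    return FiberMask(
        mask,
        provenance={
            "intensity_quantile": intensity_quantile,
            "intensity_cutoff": cutoff,
            "coherence_min": coherence_min,
            "border_px": b,
            "n_pixels": int(mask.sum()),
            "empty": bool(mask.sum() == 0),
        },
    )


def extract_orientation_sample(
    fld: OrientationField,
    mask: FiberMask,
    weighting: str = "coherence",
    flow_dir_deg: float = 0.0,
    source: str = "synthetic",
) -> OrientationSample:
    """Collect masked pixel orientations into a weighted sample.

    Weighting schemes: ``uniform`` (1 per pixel), ``coherence`` (the pixel's
    coherence), ``coherence_energy`` (coherence * energy, normalized to
    mean 1 so total weight stays comparable across images).
    """
    m = mask.mask
    if m.sum() == 0:
        raise EmptySampleError(
            "mask selected no pixels; relax intensity_quantile or coherence_min"
        )
    angles = fld.theta[m]
    if weighting == "uniform":
        weights = np.ones(angles.size)
    elif weighting == "coherence":
        weights = fld.coherence[m]
    elif weighting == "coherence_energy":
        w = fld.coherence[m] * fld.energy[m]
        weights = w / w.mean() if w.mean() > 0 else np.ones(angles.size)
    else:
        raise ValueError(f"unknown weighting scheme {weighting!r}")
    return OrientationSample(angles, weights, flow_dir_deg=flow_dir_deg, source=source)


def segment_cells(
    image: Micrograph | np.ndarray,
    layout: str,
    min_area_px: int = 50,
    metadata_count: int | None = None,
) -> tuple[np.ndarray, int]:
    """Label cell regions and count them.

    Sparse layouts: global Otsu threshold, morphological closing, connected
    components with a minimum-area filter.  Confluent layouts are a single
    whole-field region; the count comes from metadata when supplied (cells
    in a monolayer are not separable without a junction channel).
    """
    img = image.pixels if isinstance(image, Micrograph) else np.asarray(image, np.float64)
    if layout == "confluent":
        labels = np.ones(img.shape, dtype=np.int32)
        return labels, (metadata_count if metadata_count is not None else 1)
    if layout != "sparse":
        raise ValueError(f"layout must be confluent|sparse, got {layout!r}")
    if np.ptp(img) == 0:
        return np.zeros(img.shape, dtype=np.int32), 0
    thr = threshold_otsu(img)
    fg = ndimage.binary_closing(img > thr, structure=disk(3))
    labels, n = cc_label(fg, return_num=True)
    # minimum-area filter, relabelled consecutively
    areas = np.bincount(labels.ravel())
    keep = np.flatnonzero(areas >= min_area_px)
    keep = keep[keep != 0]
    remap = np.zeros(areas.size, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)
    return remap[labels], int(keep.size)
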