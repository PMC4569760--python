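"""ROI standardization and the derivative transform stack.

Every region of interest (ROI) drawn on a combined-contrast-enhanced (CCE)
liver MR image passes through a fixed standardization chain before texture
features are computed:

1. rotate the ROI content so its rectangle has zero tilt angle,
2. resample onto an isotropic 0.5 mm/pixel grid,
3. remove the bilinear spatial trend ``a + b*x + c*y + d*x*y`` of the
   intensities (shading from coil sensitivity and slow anatomy gradients),
4. rescale intensities affinely to the unit interval.

Gradient-magnitude and Laplacian transforms of the standardized image are
then computed to expose edge-enhanced and zero-crossing texture patterns;
the three images (original / gradient / laplacian) form a
:class:`TransformStack`, the unit on which the 55-feature catalog operates.

Conventions: arrays are row-major with 0-based pixel-center coordinates;
a positive tilt is a counterclockwise rotation of the ROI rectangle.
The derivative images are deliberately *not* rescaled to [0, 1]: they are
honest derivative fields, and feature classes that need a bounded range
shift-normalize internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

__all__ = [
    "ROIImage",
    "TransformStack",
    "rotate_to_zero_tilt",
    "resample_to_resolution",
    "detrend_bilinear",
    "rescale_unit_interval",
    "standardize_roi",
    "gradient_components",
    "gradient_transform",
    "laplacian_transform",
    "build_transform_stack",
]

MIN_ROI_AREA_MM2 = 100.0


@dataclass
class ROIImage:
    """A rectangular grayscale region of interest.

    Parameters
    ----------
    pixels
        2-D float array of intensities (row-major).
    pixel_spacing_mm
        Isotropic pixel spacing in millimetres.
    tilt_deg
        Rotation of the ROI rectangle relative to the image axes,
        positive = counterclockwise.
    origin
        (row, col) of the ROI's upper-left corner in its source image.
    name
        Optional identifier used in error messages.
    """

    pixels: np.ndarray
    pixel_spacing_mm: float
    tilt_deg: float = 0.0
    origin: tuple[int, int] = (0, 0)
    name: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("ROI pixels must be a 2-D array")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def area_mm2(self) -> float:
        h, w = self.pixels.shape
        return h * w * self.pixel_spacing_mm**2


@dataclass
class TransformStack:
    """Standardized image plus its gradient-magnitude and Laplacian versions."""

    original: np.ndarray
    gradient: np.ndarray
    laplacian: np.ndarray
    pixel_spacing_mm: float = 0.5

    def __post_init__(self) -> None:
        if not (self.original.shape == self.gradient.shape == self.laplacian.shape):
            raise ValueError("stack images must share identical dimensions")

    @property
    def shape(self) -> tuple[int, int]:
        return self.original.shape


def _largest_inscribed_rectangle(w: float, h: float, angle_rad: float) -> tuple[float, float]:
    """Largest axis-aligned rectangle inside a w-by-h rectangle rotated by angle.

    Closed form, valid for |angle| <= 45 degrees.
    """
    a = abs(angle_rad) % math.pi
    if a > math.pi / 2:
        a = math.pi - a
    sin_a, cos_a = math.sin(a), math.cos(a)
    if sin_a < 1e-12:
        return w, h
    width_is_longer = w >= h
    side_long, side_short = (w, h) if width_is_longer else (h, w)
    if side_short <= 2.0 * sin_a * cos_a * side_long or abs(sin_a - cos_a) < 1e-10:
        # half-constrained case: two crop corners touch the long side
        x = 0.5 * side_short
        if width_is_longer:
            wr, hr = x / sin_a, x / cos_a
        else:
            wr, hr = x / cos_a, x / sin_a
    else:
        cos_2a = cos_a * cos_a - sin_a * sin_a
        wr = (w * cos_a - h * sin_a) / cos_2a
        hr = (h * cos_a - w * sin_a) / cos_2a
    return wr, hr


def rotate_to_zero_tilt(roi: ROIImage) -> ROIImage:
    """Rotate ROI content by ``-tilt_deg`` so the output has zero tilt.

    Bilinear interpolation; the output is cropped to the largest interior
    rectangle guaranteed free of rotation fill values.

    Raises
    ------
    ValueError
        If ``|tilt_deg| > 45`` or the fill-free crop falls below the
        100 mm² minimum ROI area.
    """
    if abs(roi.tilt_deg) > 45.0:
        raise ValueError(
            f"ROI {roi.name or '<unnamed>'}: |tilt| = {abs(roi.tilt_deg):.1f} deg exceeds 45 deg"
        )
    if roi.tilt_deg == 0.0:
        return replace(roi, pixels=roi.pixels.copy())

    rotated = ndimage.rotate(
        roi.pixels, angle=-roi.tilt_deg, reshape=True, order=1, mode="constant", cval=np.nan
    )
    h0, w0 = roi.pixels.shape
    wr, hr = _largest_inscribed_rectangle(w0, h0, math.radians(roi.tilt_deg))
    # shave one pixel on each side to stay clear of interpolated fill
    wc = max(int(math.floor(wr)) - 2, 0)
    hc = max(int(math.floor(hr)) - 2, 0)
    area = wc * hc * roi.pixel_spacing_mm**2
    if area < MIN_ROI_AREA_MM2:
        raise ValueError(
            f"ROI {roi.name or '<unnamed>'}: fill-free crop after derotation is "
            f"{area:.1f} mm^2, below the {MIN_ROI_AREA_MM2:.0f} mm^2 minimum"
        )
    hr_tot, wr_tot = rotated.shape
    r0 = (hr_tot - hc) // 2
    c0 = (wr_tot - wc) // 2
    cropped = rotated[r0 : r0 + hc, c0 : c0 + wc]
    if np.isnan(cropped).any():  # pragma: no cover - geometric guarantee
        cropped = np.nan_to_num(cropped, nan=float(np.nanmean(cropped)))
    return replace(roi, pixels=cropped, tilt_deg=0.0)


def resample_to_resolution(roi: ROIImage, target_spacing_mm: float = 0.5) -> ROIImage:
    """Bilinearly resample onto an isotropic grid of ``target_spacing_mm``.

    The physical extent is preserved to within one pixel.
    """
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    zoom = roi.pixel_spacing_mm / target_spacing_mm
    if abs(zoom - 1.0) < 1e-12:
        return replace(roi, pixels=roi.pixels.copy())
    out = ndimage.zoom(roi.pixels, zoom, order=1, mode="nearest", grid_mode=True)
    return replace(roi, pixels=out, pixel_spacing_mm=target_spacing_mm)


def _bilinear_basis(shape: tuple[int, int]) -> np.ndarray:
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(float)
    if h > 1:
        y = y / (h - 1)
    if w > 1:
        x = x / (w - 1)
    return np.column_stack(
        [np.ones(h * w), x.ravel(), y.ravel(), (x * y).ravel()]
    )


def detrend_bilinear(image: np.ndarray) -> np.ndarray:
    """Subtract the least-squares bilinear trend ``a + b*x + c*y + d*x*y``.

    The residual has zero projection onto span{1, x, y, xy}.  Degenerate
    geometries (single row or column) are handled by the rank-revealing
    least-squares solve, which simply ignores the vanishing basis terms.
    """
    image = np.asarray(image, dtype=float)
    if image.size < 4:
        raise ValueError("detrending needs at least 4 pixels")
    basis = _bilinear_basis(image.shape)
    coef, *_ = np.linalg.lstsq(basis, image.ravel(), rcond=None)
    return image - (basis @ coef).reshape(image.shape)


def rescale_unit_interval(image: np.ndarray) -> np.ndarray:
    """Affinely map intensities to [0, 1]; a constant image maps to all 0.5."""
    image = np.asarray(image, dtype=float)
    lo = image.min()
    span = image.max() - lo
    if span <= 0:
        return np.full_like(image, 0.5)
    return (image - lo) / span


def standardize_roi(roi: ROIImage, target_spacing_mm: float = 0.5) -> ROIImage:
    """Full standardization chain: rotate, resample, detrend, rescale."""
    out = rotate_to_zero_tilt(roi)
    out = resample_to_resolution(out, target_spacing_mm)
    pixels = detrend_bilinear(out.pixels)
    pixels = rescale_unit_interval(pixels)
    return replace(out, pixels=pixels)


def gradient_components(image: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference first derivatives (d/dx, d/dy), edge-replicated borders.

    These component operators are linear; the magnitude in
    :func:`gradient_transform` is only absolutely homogeneous.
    """
    p = np.pad(np.asarray(image, dtype=float), 1, mode="edge")
    gx = (p[1:-1, 2:] - p[1:-1, :-2]) / 2.0
    gy = (p[2:, 1:-1] - p[:-2, 1:-1]) / 2.0
    return gx, gy


def gradient_transform(image: np.ndarray) -> np.ndarray:
    """Gradient-magnitude image (Euclidean norm of the central differences)."""
    gx, gy = gradient_components(image)
    return np.hypot(gx, gy)


_LAPLACIAN_KERNEL = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])


def laplacian_transform(image: np.ndarray) -> np.ndarray:
    """Five-point-stencil Laplacian, edge-replicated borders."""
    return ndimage.convolve(np.asarray(image, dtype=float), _LAPLACIAN_KERNEL, mode="nearest")


def build_transform_stack(roi: ROIImage, target_spacing_mm: float = 0.5) -> TransformStack:
    """Standardize an ROI and attach its gradient and Laplacian transforms."""
    std = standardize_roi(roi, target_spacing_mm)
    return TransformStack(
        original=std.pixels,
        gradient=gradient_transform(std.pixels),
        laplacian=laplacian_transform(std.pixels),
        pixel_spacing_mm=std.pixel_spacing_mm,
    )
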