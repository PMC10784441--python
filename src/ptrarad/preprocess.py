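"""CT slice standardization and the X / XL / XH image triple.

Standardization mirrors common radiomics practice: gray-level histograms are
aligned to a landmark reference, the pixel grid is resampled to 0.5 mm with a
cubic B-spline kernel (nearest-neighbor for masks so they stay binary), and
each slice is expanded into the triple used by all feature extraction —
the standardized original X, a Gaussian-smoothed XL, and the unsharp residual
XH = X - XL which enhances boundaries, streaks and plaque-like detail.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import SimpleITK as sitk
from scipy import ndimage

DEFAULT_TARGET_SPACING = 0.5  # mm
DEFAULT_SMOOTH_SIGMA = 1.5  # px, post-resampling
MAX_RESAMPLED_PIXELS = 4096 * 4096


@dataclass(frozen=True)
class CTSlice:
    """A 2D HU image on a physical grid (row-major, 0-based, pixel-center)."""

    pixels: np.ndarray
    spacing: float = 1.0  # mm, isotropic
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("pixel spacing must be positive")
        object.__setattr__(self, "pixels", np.asarray(self.pixels, dtype=np.float64))


@dataclass(frozen=True)
class PreprocessedStudy:
    """The image triple X (standardized), XL (smoothed), XH = X - XL."""

    X: CTSlice
    XL: CTSlice
    XH: CTSlice
    params: dict

    def variant(self, name: str) -> CTSlice:
        return {"X": self.X, "XL": self.XL, "XH": self.XH}[name]


def decile_landmarks(img: np.ndarray) -> np.ndarray:
    """Intensity landmarks at the 0,10,...,100th percentiles (11 values)."""
    return np.percentile(np.asarray(img, dtype=np.float64).ravel(), np.arange(0, 101, 10))


def pooled_reference(images: list[np.ndarray]) -> np.ndarray:
    """Reference landmark set: per-decile mean over a training cohort."""
    return np.mean([decile_landmarks(im) for im in images], axis=0)


def align_histogram(img: CTSlice, reference: np.ndarray) -> CTSlice:
    """Piecewise-linear landmark mapping of deciles onto reference deciles.

    Monotone by construction, so pixel rank order is preserved.  A constant
    input has no defined mapping and is returned unchanged with a warning.
    """
    reference = np.asarray(reference, dtype=np.float64)
    if np.any(np.diff(reference) < 0):
        raise ValueError("reference landmarks must be monotone increasing")
    src = decile_landmarks(img.pixels)
    if src[0] == src[-1]:
        warnings.warn("constant image: histogram alignment undefined, returning input")
        return img
    # collapse duplicate source landmarks so np.interp stays well defined
    keep = np.concatenate([[True], np.diff(src) > 0])
    mapped = np.interp(img.pixels, src[keep], reference[keep])
    return CTSlice(mapped, img.spacing, img.origin)


def _to_sitk(arr: np.ndarray, spacing: float) -> sitk.Image:
    im = sitk.GetImageFromArray(np.asarray(arr, dtype=np.float64))
    im.SetSpacing((spacing, spacing))
    return im


def resample(
    img: CTSlice,
    target_spacing: float = DEFAULT_TARGET_SPACING,
    mask: bool = False,
) -> CTSlice:
    """Resample to an isotropic target spacing.

    Intensities use a cubic B-spline kernel; with ``mask=True`` the input is
    treated as binary and resampled nearest-neighbor.
    """
    if target_spacing <= 0:
        raise ValueError("target spacing must be positive")
    if target_spacing == img.spacing:
        return img
    h, w = img.pixels.shape
    new_h = int(round(h * img.spacing / target_spacing))
    new_w = int(round(w * img.spacing / target_spacing))
    if new_h * new_w > MAX_RESAMPLED_PIXELS:
        raise MemoryError("resampled image exceeds the configured size cap")
    src = _to_sitk(img.pixels, img.spacing)
    res = sitk.ResampleImageFilter()
    res.SetOutputSpacing((target_spacing, target_spacing))
    res.SetSize((new_w, new_h))
    res.SetOutputOrigin(src.GetOrigin())
    res.SetInterpolator(sitk.sitkNearestNeighbor if mask else sitk.sitkBSpline)
    res.SetUseNearestNeighborExtrapolator(True)  # edge pixels beyond the last center
    out = sitk.GetArrayFromImage(res.Execute(src))
    if mask:
        out = out > 0.5
    return CTSlice(out.astype(np.float64), target_spacing, img.origin)


def make_variants(img: CTSlice, sigma_smooth: float = DEFAULT_SMOOTH_SIGMA) -> PreprocessedStudy:
    """Build the X / XL / XH triple: XL = Gaussian(sigma) * X, XH = X - XL."""
    if sigma_smooth <= 0:
        raise ValueError("smoothing sigma must be positive")
    xl = ndimage.gaussian_filter(img.pixels, sigma=sigma_smooth, mode="reflect")
    xh = img.pixels - xl
    return PreprocessedStudy(
        X=img,
        XL=CTSlice(xl, img.spacing, img.origin),
        XH=CTSlice(xh, img.spacing, img.origin),
        params={"smoothing_sigma": sigma_smooth, "spacing": img.spacing},
    )


def preprocess_case(
    image: np.ndarray,
    masks: dict[str, np.ndarray],
    spacing: float = 1.0,
    reference: np.ndarray | None = None,
    target_spacing: float = DEFAULT_TARGET_SPACING,
    sigma_smooth: float = DEFAULT_SMOOTH_SIGMA,
) -> tuple[PreprocessedStudy, dict[str, np.ndarray]]:
    """Full standardization of one case: align, resample, build the triple.

    Returns the preprocessed study and the masks resampled (nearest-neighbor)
    onto the same grid.
    """
    sl = CTSlice(image, spacing)
    if reference is not None:
        sl = align_histogram(sl, reference)
    sl = resample(sl, target_spacing)
    out_masks = {
        name: resample(CTSlice(m.astype(np.float64), spacing), target_spacing, mask=True).pixels
        > 0.5
        for name, m in masks.items()
    }
    study = make_variants(sl, sigma_smooth)
    return study, out_masks


# ---------------------------------------------------------------------------
# readers for the standard on-disk formats
# ---------------------------------------------------------------------------


def read_nifti_slice(path: str) -> CTSlice:
    """Read a 2D NIfTI image (or the first slice of a 3D one) as a CTSlice."""
    import nibabel as nib

    im = nib.load(path)
    data = np.asanyarray(im.dataobj, dtype=np.float64)
    if data.ndim == 3:
        data = data[..., 0]
    spacing = float(im.header.get_zooms()[0])
    return CTSlice(data, spacing)


def read_dicom_slice(path: str) -> CTSlice:
    """Read one DICOM file, applying rescale slope/intercept to HU."""
    import pydicom

    ds = pydicom.dcmread(path)
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    spacing = float(ds.PixelSpacing[0]) if hasattr(ds, "PixelSpacing") else 1.0
    return CTSlice(arr * slope + intercept, spacing)
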