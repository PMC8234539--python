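"""Quantitative feature extraction from lesion-masked 3D volumes.

Families: first-order intensity statistics, mask shape descriptors, GLCM
texture, plus first-order/GLCM variants on Laplacian-of-Gaussian filtered
images and on the eight sub-bands of a one-level separable 3D wavelet
decomposition (coiflet-1).  Feature names follow the
``filter_class_feature`` convention, e.g. ``original_firstorder_Mean``,
``log-sigma-2-mm_glcm_Contrast``, ``wavelet-HLH_firstorder_Entropy``.

Conventions (documented, configurable where noted):
  * intensities are z-normalized over the whole volume before extraction;
  * texture discretization uses 32 equal-width bins inside the ROI;
  * GLCM: distance 1 voxel, 13 unique 3D directions, symmetric, features
    from the direction-averaged matrix;
  * LoG sigmas {1, 2, 3} mm, spacing-aware, scale-normalized (x sigma^2);
  * no resampling — anisotropic spacing affects shape and LoG only;
  * zero-variance sentinels: skewness/kurtosis/GLCM-correlation return 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

__all__ = [
    "ImageROI",
    "znormalize",
    "discretize",
    "first_order",
    "shape",
    "glcm",
    "log_filter",
    "wavelet_bank",
    "extract_all",
    "feature_names",
    "GLCM_DIRECTIONS",
    "DEFAULT_BINS",
    "DEFAULT_SIGMAS_MM",
]

DEFAULT_BINS = 32
DEFAULT_SIGMAS_MM = (1.0, 2.0, 3.0)

#: 13 unique 3D direction offsets (half of the 26-neighborhood)
GLCM_DIRECTIONS = tuple(
    (dx, dy, dz)
    for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
    if (dx, dy, dz) > (0, 0, 0)
)

# coiflet-1 decomposition taps, renormalized to exactly unit energy
_COIF1_LO = np.array([
    -0.01565572813546454, -0.0727326195128539, 0.38486484686420286,
    0.8525720202122554, 0.33789766245780922, -0.0727326195128539,
])
_COIF1_LO = _COIF1_LO / np.linalg.norm(_COIF1_LO)
_COIF1_HI = np.array(
    [(-1) ** k * _COIF1_LO[len(_COIF1_LO) - 1 - k]
     for k in range(len(_COIF1_LO))]
)


@dataclass
class ImageROI:
    """A scalar 3D volume with an aligned binary lesion mask."""

    intensities: np.ndarray
    mask: np.ndarray
    spacing: tuple  # mm per axis

    def __post_init__(self):
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.mask = np.asarray(self.mask).astype(bool)
        self.spacing = tuple(float(s) for s in self.spacing)
        if self.intensities.shape != self.mask.shape:
            raise ValueError("intensity and mask shapes differ")
        if self.intensities.ndim != 3:
            raise ValueError("expected 3D volumes")
        if self.mask.sum() < 1:
            raise ValueError("mask is empty")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def values(self) -> np.ndarray:
        """Intensities of the masked voxels, flattened."""
        return self.intensities[self.mask]


def znormalize(image: np.ndarray) -> np.ndarray:
    """Whole-volume z-score normalization (population SD)."""
    image = np.asarray(image, dtype=float)
    sd = image.std()
    if sd == 0:
        raise ValueError("zero variance: cannot z-normalize a constant volume")
    return (image - image.mean()) / sd


def discretize(roi: ImageROI, n_bins: int = DEFAULT_BINS) -> np.ndarray:
    """Masked intensities mapped to integer labels 1..n_bins.

    Equal-width bins over [min, max] within the mask; the maximum maps to
    n_bins; a constant ROI maps entirely to bin 1.  Voxels outside the
    mask are labeled 0.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    vals = roi.values
    lo, hi = vals.min(), vals.max()
    labels = np.zeros(roi.mask.shape, dtype=np.int32)
    if hi == lo:
        labels[roi.mask] = 1
        return labels
    width = (hi - lo) / n_bins
    binned = np.floor((vals - lo) / width).astype(np.int32) + 1
    labels[roi.mask] = np.clip(binned, 1, n_bins)
    return labels


# ---------------------------------------------------------------------------
# first order
# ---------------------------------------------------------------------------

FIRST_ORDER_NAMES = (
    "Mean", "Median", "Minimum", "Maximum", "Range", "Variance",
    "Skewness", "Kurtosis", "Energy", "TotalEnergy", "Entropy",
    "Uniformity", "RootMeanSquared", "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation", "Percentile10", "Percentile90",
    "InterquartileRange",
)


def first_order(roi: ImageROI, n_bins: int = DEFAULT_BINS) -> dict:
    """18 first-order intensity statistics of the masked voxels.

    Entropy (bits) and uniformity come from the equal-width discretized
    histogram; variance/skewness/kurtosis use population moments with
    zero-variance sentinel 0 for the standardized moments.
    """
    x = roi.values
    n = x.size
    mean = x.mean()
    var = x.var()
    centered = x - mean
    if var > 0:
        skew = (centered**3).mean() / var**1.5
        kurt = (centered**4).mean() / var**2
    else:
        skew = 0.0
        kurt = 0.0

    labels = discretize(roi, n_bins)[roi.mask]
    counts = np.bincount(labels, minlength=n_bins + 1)[1:]
    p = counts[counts > 0] / n
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p**2).sum())

    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = x[(x >= p10) & (x <= p90)]
    voxel_vol = float(np.prod(roi.spacing))
    energy = float((x**2).sum())

    return {
        "Mean": float(mean),
        "Median": float(p50),
        "Minimum": float(x.min()),
        "Maximum": float(x.max()),
        "Range": float(np.ptp(x)),
        "Variance": float(var),
        "Skewness": float(skew),
        "Kurtosis": float(kurt),
        "Energy": energy,
        "TotalEnergy": energy * voxel_vol,
        "Entropy": entropy,
        "Uniformity": uniformity,
        "RootMeanSquared": float(np.sqrt((x**2).mean())),
        "MeanAbsoluteDeviation": float(np.abs(centered).mean()),
        "RobustMeanAbsoluteDeviation": float(
            np.abs(robust - robust.mean()).mean() if robust.size else 0.0),
        "Percentile10": float(p10),
        "Percentile90": float(p90),
        "InterquartileRange": float(p75 - p25),
    }


# ---------------------------------------------------------------------------
# shape
# ---------------------------------------------------------------------------

SHAPE_NAMES = (
    "VoxelVolume", "SurfaceArea", "Sphericity", "SurfaceVolumeRatio",
    "Maximum3DDiameter", "Elongation", "Flatness",
)


def _surface_area(mask: np.ndarray, spacing) -> float:
    from skimage.measure import marching_cubes, mesh_surface_area

    padded = np.pad(mask.astype(float), 1)
    try:
        verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=spacing)
        return float(mesh_surface_area(verts, faces))
    except (ValueError, RuntimeError):
        # degenerate mask (e.g. single voxel on some skimage versions):
        # fall back to the voxelized surface
        sp = np.asarray(spacing)
        area = 0.0
        face_areas = [sp[1] * sp[2], sp[0] * sp[2], sp[0] * sp[1]]
        for axis, fa in enumerate(face_areas):
            shifted = np.roll(mask, 1, axis=axis)
            shifted2 = np.roll(mask, -1, axis=axis)
            area += fa * ((mask & ~shifted).sum() + (mask & ~shifted2).sum())
        return float(area)


def shape(mask: np.ndarray, spacing) -> dict:
    """Mask-only shape descriptors (intensity-independent)."""
    mask = np.asarray(mask).astype(bool)
    sp = np.asarray(spacing, dtype=float)
    n_vox = int(mask.sum())
    if n_vox < 1:
        raise ValueError("mask is empty")
    volume = n_vox * float(np.prod(sp))
    area = _surface_area(mask, sp)
    sphericity = float(np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area)

    coords = np.argwhere(mask) * sp
    if len(coords) > 256:
        try:
            coords_hull = coords[ConvexHull(coords).vertices]
        except Exception:
            coords_hull = coords
    else:
        coords_hull = coords
    diam = float(pdist(coords_hull).max()) if len(coords_hull) > 1 else 0.0

    # principal axes from the voxel-coordinate covariance
    if len(coords) > 1:
        cov = np.cov(coords.T)
        eig = np.sort(np.linalg.eigvalsh(cov))[::-1]
        eig = np.clip(eig, 0, None)
        elong = float(np.sqrt(eig[1] / eig[0])) if eig[0] > 0 else 0.0
        flat = float(np.sqrt(eig[2] / eig[0])) if eig[0] > 0 else 0.0
    else:
        elong = flat = 1.0

    return {
        "VoxelVolume": volume,
        "SurfaceArea": area,
        "Sphericity": sphericity,
        "SurfaceVolumeRatio": area / volume,
        "Maximum3DDiameter": diam,
        "Elongation": elong,
        "Flatness": flat,
    }


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

GLCM_NAMES = (
    "Contrast", "Correlation", "JointEnergy", "JointEntropy",
    "Idm", "Dissimilarity",
)


def _cooccurrence(labels: np.ndarray, offset, n_bins: int) -> np.ndarray:
    """Symmetric co-occurrence counts for one offset (labels 0 = outside)."""
    dx, dy, dz = offset
    sl_a = tuple(
        slice(max(0, -d), labels.shape[k] - max(0, d))
        for k, d in enumerate((dx, dy, dz))
    )
    sl_b = tuple(
        slice(max(0, d), labels.shape[k] - max(0, -d))
        for k, d in enumerate((dx, dy, dz))
    )
    a = labels[sl_a].ravel()
    b = labels[sl_b].ravel()
    valid = (a > 0) & (b > 0)
    a, b = a[valid] - 1, b[valid] - 1
    if a.size == 0:
        return np.zeros((n_bins, n_bins))
    m = np.bincount(a * n_bins + b, minlength=n_bins * n_bins).reshape(
        n_bins, n_bins).astype(float)
    return m + m.T  # symmetric accumulation


def glcm(labels: np.ndarray, n_bins: int = DEFAULT_BINS,
         directions=GLCM_DIRECTIONS) -> dict:
    """GLCM texture features from the direction-averaged probability matrix.

    Each directional matrix is normalized to sum 1 before averaging; empty
    directions are skipped.  Returns sentinel values (contrast 0, energy 1,
    correlation 0) with a warning when no direction yields a voxel pair.
    """
    mats = []
    for off in directions:
        m = _cooccurrence(labels, off, n_bins)
        tot = m.sum()
        if tot > 0:
            mats.append(m / tot)
    if not mats:
        warnings.warn("GLCM: no valid voxel pairs; returning sentinels")
        return {"Contrast": 0.0, "Correlation": 0.0, "JointEnergy": 1.0,
                "JointEntropy": 0.0, "Idm": 1.0, "Dissimilarity": 0.0}
    P = np.mean(mats, axis=0)
    P = P / P.sum()

    i = np.arange(1, n_bins + 1, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = ii - jj

    px = P.sum(axis=1)
    mu = (i * px).sum()
    sigma2 = ((i - mu) ** 2 * px).sum()

    contrast = float((P * diff**2).sum())
    dissim = float((P * np.abs(diff)).sum())
    energy = float((P**2).sum())
    nz = P[P > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    idm = float((P / (1.0 + diff**2)).sum())
    if sigma2 > 0:
        corr = float(((ii - mu) * (jj - mu) * P).sum() / sigma2)
    else:
        corr = 0.0
    return {"Contrast": contrast, "Correlation": corr, "JointEnergy": energy,
            "JointEntropy": entropy, "Idm": idm, "Dissimilarity": dissim}


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------


def log_filter(image: np.ndarray, sigma_mm: float, spacing) -> np.ndarray:
    """Scale-normalized Laplacian-of-Gaussian response (sigma in mm)."""
    if sigma_mm <= 0:
        raise ValueError("sigma must be positive")
    image = np.asarray(image, dtype=float)
    sp = np.asarray(spacing, dtype=float)
    extent = np.asarray(image.shape) * sp
    if sigma_mm > extent.min() / 2:
        warnings.warn(f"LoG sigma {sigma_mm} mm exceeds half the grid extent")
    sigma_vox = sigma_mm / sp
    resp = ndimage.gaussian_laplace(image, sigma=sigma_vox)
    # the truncated derivative kernel has a small DC gain; remove it so a
    # constant image maps to an identically-zero response
    dc = ndimage.gaussian_laplace(np.ones_like(image), sigma=sigma_vox)
    return sigma_mm**2 * (resp - image.mean() * dc)


def _dwt_axis(x: np.ndarray, taps: np.ndarray, axis: int) -> np.ndarray:
    """Periodized filter + downsample-by-2 along one axis."""
    n = x.shape[axis]
    out_shape = list(x.shape)
    out_shape[axis] = n // 2
    out = np.zeros(out_shape)
    xm = np.moveaxis(x, axis, 0)
    om = np.moveaxis(out, axis, 0)
    for pos in range(n // 2):
        idx = (2 * pos + np.arange(len(taps))) % n
        om[pos] = np.tensordot(taps, xm[idx], axes=(0, 0))
    return out


def wavelet_bank(image: np.ndarray) -> dict:
    """One-level separable 3D DWT (coiflet-1, periodic boundary).

    Returns the eight sub-bands keyed 'LLL'..'HHH' (letter order follows
    axis order).  Axis lengths must be even and at least the filter length.
    """
    image = np.asarray(image, dtype=float)
    L = len(_COIF1_LO)
    for ax, n in enumerate(image.shape):
        if n < L or n % 2:
            raise ValueError(
                f"axis {ax} length {n} unsupported: need even length >= {L}"
            )
    bands = {"": image}
    for axis in range(3):
        new = {}
        for key, vol in bands.items():
            new[key + "L"] = _dwt_axis(vol, _COIF1_LO, axis)
            new[key + "H"] = _dwt_axis(vol, _COIF1_HI, axis)
        bands = new
    return bands


WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")


# ---------------------------------------------------------------------------
# full registry
# ---------------------------------------------------------------------------


def _image_names(prefix: str):
    return (
        [f"{prefix}_firstorder_{n}" for n in FIRST_ORDER_NAMES]
        + [f"{prefix}_glcm_{n}" for n in GLCM_NAMES]
    )


def feature_names(sigmas_mm=DEFAULT_SIGMAS_MM) -> list[str]:
    """Stable, ordered list of every feature the extractor emits."""
    names = _image_names("original")
    names += [f"original_shape_{n}" for n in SHAPE_NAMES]
    for s in sigmas_mm:
        names += _image_names(f"log-sigma-{s:g}-mm")
    for band in WAVELET_BANDS:
        names += _image_names(f"wavelet-{band}")
    return names


def _extract_on(roi: ImageROI, prefix: str, n_bins: int) -> dict:
    out = {}
    fo = first_order(roi, n_bins)
    for k, v in fo.items():
        out[f"{prefix}_firstorder_{k}"] = v
    labels = discretize(roi, n_bins)
    tex = glcm(labels, n_bins)
    for k, v in tex.items():
        out[f"{prefix}_glcm_{k}"] = v
    return out


def _downsample_mask(mask: np.ndarray) -> np.ndarray:
    """Mask on the half-resolution wavelet grid (any covered child voxel)."""
    m = mask
    for axis in range(3):
        mm = np.moveaxis(m, axis, 0)
        m = np.moveaxis(mm[0::2] | mm[1::2], 0, axis)
    return m


def extract_all(roi: ImageROI, n_bins: int = DEFAULT_BINS,
                sigmas_mm=DEFAULT_SIGMAS_MM,
                normalize: bool = True) -> dict:
    """Extract the complete feature vector for one lesion ROI.

    The whole volume is z-normalized first (unless ``normalize=False``),
    then first-order + GLCM features are computed on the original image,
    each LoG response and each wavelet sub-band; shape features come from
    the mask alone.  Returns an ordered name -> value dict matching
    ``feature_names``.
    """
    img = znormalize(roi.intensities) if normalize else roi.intensities
    base = ImageROI(img, roi.mask, roi.spacing)

    out = _extract_on(base, "original", n_bins)
    for k, v in shape(roi.mask, roi.spacing).items():
        out[f"original_shape_{k}"] = v
    for s in sigmas_mm:
        filt = log_filter(img, s, roi.spacing)
        out.update(_extract_on(ImageROI(filt, roi.mask, roi.spacing),
                               f"log-sigma-{s:g}-mm", n_bins))
    bands = wavelet_bank(img)
    wmask = _downsample_mask(roi.mask)
    half_spacing = tuple(2 * s for s in roi.spacing)
    for band in WAVELET_BANDS:
        out.update(_extract_on(ImageROI(bands[band], wmask, half_spacing),
                               f"wavelet-{band}", n_bins))

    expected = feature_names(sigmas_mm)
    assert list(out.keys()) == expected, "feature registry drifted"
    return out
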