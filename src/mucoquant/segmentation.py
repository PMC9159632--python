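"""Feature segmentation: adaptive thresholding, morphological cleanup,
connected components and moment-based ellipse fitting.

The threshold rule is ``I(x) > mean_w(x) + s * (I_max - I_min)`` where
``mean_w`` is the mean over a square window centred at ``x`` (edge pixels use
the in-bounds part of the window) and the range is global.  The sensitivity
``s`` is therefore dimensionless and independent of the image's intensity
scale, and masks shrink monotonically as ``s`` grows — raising ``s`` can only
remove foreground pixels, which is what makes sensitivity sweeps well ordered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.morphology import closing, disk, opening

from .errors import InputError, ParameterError
from .geometry import fold_axis_angle
from .io import Micrograph

#: 8-connectivity structuring element for component labelling
EIGHT_CONNECTED = np.ones((3, 3), dtype=bool)


@dataclass
class Feature:
    """One segmented connected component with its moment-fitted ellipse.

    ``centroid`` is the intensity-unweighted pixel centroid ``(row, col)``.
    ``orientation_deg`` is the major-axis angle in ``[0, 180)`` measured from
    the +column axis toward the +row axis.  Axis lengths are full lengths:
    ``4 * sqrt(eigenvalue)`` of the pixel-coordinate covariance, so a rendered
    solid ellipse recovers its true axis lengths.
    """

    label: int
    pixels: np.ndarray  # (n, 2) int array of (row, col)
    centroid: tuple[float, float]
    area: int
    major_axis_len: float
    minor_axis_len: float
    orientation_deg: float


@dataclass
class FeatureSet:
    """All features segmented from one channel, plus the label image."""

    features: list[Feature]
    label_image: np.ndarray
    channel: str = ""
    sensitivity: float | None = None

    def __len__(self) -> int:
        return len(self.features)

    @property
    def labels(self) -> list[int]:
        return [f.label for f in self.features]

    def occupancy(self) -> np.ndarray:
        """Boolean mask of all feature pixels."""
        return self.label_image > 0


def adaptive_threshold(image: np.ndarray, sensitivity: float, window: int = 51) -> np.ndarray:
    """Adaptive (local-mean) threshold with a global-range sensitivity offset.

    A pixel is foreground iff ``I > mean_w + sensitivity * (I_max - I_min)``.
    A tiny absolute guard (1e-12 of the intensity scale) absorbs floating-
    point wobble in the windowed mean so that a constant image is always all
    background.

    Parameters
    ----------
    image
        2-D finite intensity array.
    sensitivity
        Dimensionless offset in units of the global intensity range, in [0, 1].
        Larger values are more restrictive.
    window
        Odd window edge length in pixels, >= 3.
    """
    if window < 3 or window % 2 == 0:
        raise ParameterError(f"window must be odd and >= 3, got {window}")
    if not 0.0 <= sensitivity <= 1.0:
        raise ParameterError(f"sensitivity must be in [0, 1], got {sensitivity}")
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise InputError("image must be 2-D")
    if not np.all(np.isfinite(img)):
        raise InputError("image contains non-finite pixels")
    # in-bounds windowed mean: ratio of zero-padded windowed sums cancels the
    # padding, leaving the mean over the in-bounds part of the window
    wsum = ndimage.uniform_filter(img, size=window, mode="constant", cval=0.0)
    wcnt = ndimage.uniform_filter(np.ones_like(img), size=window, mode="constant", cval=0.0)
    local_mean = wsum / wcnt
    global_range = float(img.max() - img.min()) if img.size else 0.0
    guard = 1e-12 * max(1.0, float(np.abs(img).max())) if img.size else 0.0
    return img > local_mean + sensitivity * global_range + guard


def clean_mask(mask: np.ndarray, opening_radius: int = 0, closing_radius: int = 0) -> np.ndarray:
    """Binary opening then closing with disk structuring elements.

    A radius of 0 skips that step entirely.
    """
    if opening_radius < 0 or closing_radius < 0:
        raise ParameterError("morphology radii must be >= 0")
    out = np.asarray(mask, dtype=bool)
    if opening_radius > 0:
        out = opening(out, disk(opening_radius))
    if closing_radius > 0:
        out = closing(out, disk(closing_radius))
    return out.astype(bool)


def _fit_ellipse(coords: np.ndarray) -> tuple[float, float, float]:
    """Moment ellipse of a pixel set: (major_len, minor_len, orientation_deg).

    Works in (x=col, y=row) so the orientation convention of
    :mod:`mucoquant.geometry` holds.  Degenerate sets give zero axis lengths.
    """
    x = coords[:, 1].astype(float)
    y = coords[:, 0].astype(float)
    cxx = np.mean((x - x.mean()) ** 2)
    cyy = np.mean((y - y.mean()) ** 2)
    cxy = np.mean((x - x.mean()) * (y - y.mean()))
    common = np.hypot(cxx - cyy, 2.0 * cxy)
    lam1 = 0.5 * (cxx + cyy + common)
    lam2 = 0.5 * (cxx + cyy - common)
    orientation = fold_axis_angle(np.degrees(0.5 * np.arctan2(2.0 * cxy, cxx - cyy)))
    major = 4.0 * np.sqrt(max(lam1, 0.0))
    minor = 4.0 * np.sqrt(max(lam2, 0.0))
    return major, minor, orientation


def extract_features(
    mask: np.ndarray,
    cell_mask: np.ndarray | None = None,
    min_area: int = 4,
    channel: str = "",
    sensitivity: float | None = None,
) -> FeatureSet:
    """Label 8-connected components inside the cell and fit ellipse moments.

    Components smaller than ``min_area`` pixels are dropped; surviving
    components keep their original labels in the returned label image.
    """
    mask = np.asarray(mask, dtype=bool)
    if cell_mask is not None:
        cell_mask = np.asarray(cell_mask, dtype=bool)
        if cell_mask.shape != mask.shape:
            raise InputError("mask and cell_mask must share shape")
        mask = mask & cell_mask
    label_image, n_labels = ndimage.label(mask, structure=EIGHT_CONNECTED)
    features: list[Feature] = []
    for label, sl in enumerate(ndimage.find_objects(label_image), start=1):
        if sl is None:
            continue
        local = label_image[sl] == label
        area = int(local.sum())
        if area < min_area:
            label_image[sl][local] = 0
            continue
        rr, cc = np.nonzero(local)
        coords = np.column_stack([rr + sl[0].start, cc + sl[1].start])
        major, minor, orientation = _fit_ellipse(coords)
        features.append(
            Feature(
                label=label,
                pixels=coords,
                centroid=(float(coords[:, 0].mean()), float(coords[:, 1].mean())),
                area=area,
                major_axis_len=major,
                minor_axis_len=minor,
                orientation_deg=orientation,
            )
        )
    return FeatureSet(features, label_image, channel=channel, sensitivity=sensitivity)


@dataclass
class SegmentationParams:
    """Bundle of segmentation settings for one channel."""

    sensitivity: float = 0.5
    window: int = 51
    min_area: int = 4
    opening_radius: int = 0
    closing_radius: int = 0


def segment_channel(
    micrograph: Micrograph,
    channel: str,
    params: SegmentationParams | None = None,
    **overrides,
) -> FeatureSet:
    """Threshold, clean and extract features from one channel of a micrograph.

    ``channel`` is ``"grl"`` or ``"mdl"``; keyword overrides patch individual
    fields of ``params``.
    """
    if channel not in ("grl", "mdl"):
        raise ParameterError(f"channel must be 'grl' or 'mdl', got {channel!r}")
    p = params or SegmentationParams()
    if overrides:
        p = SegmentationParams(**{**p.__dict__, **overrides})
    image = micrograph.grl_channel if channel == "grl" else micrograph.mdl_channel
    mask = adaptive_threshold(image, p.sensitivity, p.window)
    mask = clean_mask(mask, p.opening_radius, p.closing_radius)
    return extract_features(
        mask, micrograph.cell_mask, p.min_area, channel=channel, sensitivity=p.sensitivity
    )


def featureset_to_dataframe(fset: FeatureSet):
    """Flatten a FeatureSet to one row per feature (for CSV export)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "label": f.label,
                "centroid_row": f.centroid[0],
                "centroid_col": f.centroid[1],
                "area": f.area,
                "major_axis_len": f.major_axis_len,
                "minor_axis_len": f.minor_axis_len,
                "orientation_deg": f.orientation_deg,
            }
            for f in fset.features
        ]
    )
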