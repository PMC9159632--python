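import numpy as np
import pytest

import mucoquant as mq
from mucoquant.geometry import ellipse_mask
from mucoquant.segmentation import Feature, FeatureSet, extract_features


def small_cell_params(**overrides) -> mq.ImageSimParams:
    """Compact simulation settings used throughout the suite: a ~18x14 um
    cell in a 256x256 frame, a dozen mucocysts."""
    defaults = dict(
        image_shape=(256, 256),
        cell_semi_axes=(9.0, 7.0),
        n_mucocysts=12,
        tip_bias=0.9,
        seed=11,
    )
    defaults.update(overrides)
    return mq.ImageSimParams(**defaults)


@pytest.fixture(scope="session")
def docked_image():
    """One docked-mode micrograph plus ground truth (session-cached)."""
    return mq.generate_cell_image(small_cell_params())


@pytest.fixture(scope="session")
def cytoplasmic_image():
    return mq.generate_cell_image(small_cell_params(mode="cytoplasmic"))


def rendered_feature(
    semi_axes=(20.0, 10.0),
    orientation_deg=0.0,
    shape=(101, 101),
    center=None,
) -> Feature:
    """Segment a single rendered solid ellipse and return its fitted Feature."""
    if center is None:
        center = ((shape[0] - 1) / 2, (shape[1] - 1) / 2)
    mask = ellipse_mask(shape, center, semi_axes, orientation_deg)
    fset = extract_features(mask, min_area=4)
    assert len(fset) == 1
    return fset.features[0]


def point_feature(row: float, col: float, label: int = 1) -> Feature:
    """Single-point Feature with an exact (possibly subpixel) centroid."""
    return Feature(
        label=label,
        pixels=np.array([[int(round(row)), int(round(col))]]),
        centroid=(row, col),
        area=1,
        major_axis_len=0.0,
        minor_axis_len=0.0,
        orientation_deg=0.0,
    )


def featureset_from_mask(mask, min_area=1, **kw) -> FeatureSet:
    return extract_features(np.asarray(mask, bool), min_area=min_area, **kw)


def angle_distance(a: float, b: float) -> float:
    """Distance between two undirected axis angles in degrees."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)
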