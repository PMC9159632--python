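"""Tip-polarity statistics for puncta paired with elongated organelles.

For each Mdl punctum overlapping a Grl organelle two statistics describe
where the punctum sits:

* the acute **angle** (degrees, 0-90) between the organelle's fitted major
  axis and the segment connecting the two centroids — 0 means the punctum
  lies along the long axis, 90 along the short axis;
* the **normalized offset** — the centroid distance divided by half the
  organelle's major-axis length, so a punctum at the organelle tip scores 1.

The null model re-places the punctum centroid uniformly inside the fitted
ellipse of its own organelle; observed and null samples are compared with a
two-sample Kolmogorov-Smirnov test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

from .errors import InputError, MeasurementError, ParameterError, UndefinedAngleError
from .geometry import acute_angle_to_axis, sample_unit_disk
from .segmentation import Feature, FeatureSet

logger = logging.getLogger(__name__)


@dataclass
class MucocystPair:
    """One Mdl punctum assigned to the Grl organelle it overlaps most."""

    grl: Feature
    mdl: Feature
    shared_pixels: int = 1


@dataclass
class TipNull:
    """Randomization null for one pair: R uniform points in the fitted ellipse."""

    pair: MucocystPair
    n_randomizations: int
    null_angles: np.ndarray
    null_offsets: np.ndarray
    seed: int


def pair_features(grl: FeatureSet, mdl: FeatureSet) -> list[MucocystPair]:
    """Assign each overlapping Mdl feature to one Grl feature.

    An Mdl feature sharing >= 1 pixel with any Grl feature yields exactly one
    pair, with the Grl feature sharing the most pixels (ties go to the
    smaller Grl label).  Non-overlapping Mdl features yield nothing.
    """
    if grl.label_image.shape != mdl.label_image.shape:
        raise InputError("feature sets come from images of different shapes")
    by_label = {f.label: f for f in grl.features}
    pairs = []
    for m in mdl.features:
        labels = grl.label_image[m.pixels[:, 0], m.pixels[:, 1]]
        labels = labels[labels > 0]
        if labels.size == 0:
            continue
        counts = np.bincount(labels)
        best = int(np.flatnonzero(counts == counts.max())[0])  # tie -> smaller label
        pairs.append(MucocystPair(grl=by_label[best], mdl=m, shared_pixels=int(counts[best])))
    return pairs


def tip_angle(pair: MucocystPair) -> float:
    """Acute angle (degrees, [0, 90]) between the Grl major axis and the
    centroid-connecting segment.  Undefined for coincident centroids."""
    dr = pair.mdl.centroid[0] - pair.grl.centroid[0]
    dc = pair.mdl.centroid[1] - pair.grl.centroid[1]
    if dr == 0.0 and dc == 0.0:
        raise UndefinedAngleError("centroids coincide; tip angle undefined")
    return acute_angle_to_axis(dr, dc, pair.grl.orientation_deg)


def tip_offset(pair: MucocystPair) -> float:
    """Centroid distance normalized to half the Grl major-axis length.

    1 means the punctum centroid sits at the vertex (tip) of the fitted
    ellipse; 0 means it sits on the organelle centroid.
    """
    half_major = pair.grl.major_axis_len / 2.0
    if half_major <= 0:
        raise MeasurementError("degenerate Grl fit: zero major axis")
    dr = pair.mdl.centroid[0] - pair.grl.centroid[0]
    dc = pair.mdl.centroid[1] - pair.grl.centroid[1]
    return float(np.hypot(dr, dc) / half_major)


def randomize_within_mucocyst(pair: MucocystPair, n_randomizations: int, seed: int = 0) -> TipNull:
    """Null statistics from uniform points inside the pair's fitted ellipse.

    Uniformity over the ellipse comes from mapping uniform unit-disk samples
    through the ellipse's axes, which also yields the statistics directly in
    the axis frame: a disk point ``(u, v)`` maps to offset
    ``sqrt(u^2 + (b/a)^2 v^2)`` and angle ``atan2(b|v|, a|u|)``.
    """
    if n_randomizations < 1:
        raise ParameterError("need at least one randomization round")
    a = pair.grl.major_axis_len / 2.0
    b = pair.grl.minor_axis_len / 2.0
    if a <= 0 or b <= 0:
        raise MeasurementError("degenerate Grl fit: cannot sample within ellipse")
    rng = np.random.default_rng(seed)
    uv = sample_unit_disk(rng, n_randomizations)
    au = a * uv[:, 0]
    bv = b * uv[:, 1]
    offsets = np.sqrt(au**2 + bv**2) / a
    angles = np.degrees(np.arctan2(np.abs(bv), np.abs(au)))
    return TipNull(
        pair=pair,
        n_randomizations=n_randomizations,
        null_angles=angles,
        null_offsets=offsets,
        seed=seed,
    )


def ks_two_sample(observed, null) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test.

    ``D`` is the supremum over the pooled sample points of the absolute ECDF
    difference; the two-sided p-value comes from the asymptotic Kolmogorov
    distribution evaluated at ``sqrt(n1*n2/(n1+n2)) * D``.
    """
    x = np.sort(np.asarray(observed, dtype=float))
    y = np.sort(np.asarray(null, dtype=float))
    if x.size == 0 or y.size == 0:
        raise InputError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    ecdf_x = np.searchsorted(x, pooled, side="right") / x.size
    ecdf_y = np.searchsorted(y, pooled, side="right") / y.size
    d = float(np.abs(ecdf_x - ecdf_y).max())
    en = np.sqrt(x.size * y.size / (x.size + y.size))
    p = float(np.clip(special.kolmogorov(en * d), 1e-300, 1.0))
    return d, p


@dataclass
class TipSummary:
    """Pooled tip-polarity analysis over a set of pairs."""

    n_pairs: int
    n_angle_excluded: int
    observed_angles: np.ndarray
    observed_offsets: np.ndarray
    null_angles: np.ndarray
    null_offsets: np.ndarray
    angle_D: float
    angle_p: float
    offset_D: float
    offset_p: float
    n_randomizations: int = 0
    seed: int = 0


def tip_statistics(
    pairs: list[MucocystPair], n_randomizations: int = 1000, seed: int = 0
) -> TipSummary:
    """Pool angle/offset statistics over pairs and KS-test both against the null.

    Pairs with coincident centroids are excluded from the angle sample (and
    logged) but contribute offset 0 to the offset sample.  The null pools
    ``n_randomizations`` draws per pair; per-pair seeds derive from ``seed``.
    """
    if not pairs:
        raise InputError("no pairs to analyse")
    angles, offsets = [], []
    null_angles, null_offsets = [], []
    excluded = 0
    root = np.random.SeedSequence(seed)
    for pair, child in zip(pairs, root.spawn(len(pairs))):
        offsets.append(tip_offset(pair))
        try:
            angles.append(tip_angle(pair))
        except UndefinedAngleError:
            excluded += 1
            logger.info("pair on Grl label %d: coincident centroids, angle skipped",
                        pair.grl.label)
        null = randomize_within_mucocyst(
            pair, n_randomizations, seed=int(child.generate_state(1)[0] % (2**31))
        )
        null_angles.append(null.null_angles)
        null_offsets.append(null.null_offsets)
    null_angles = np.concatenate(null_angles)
    null_offsets = np.concatenate(null_offsets)
    if not angles:
        raise MeasurementError("every pair had coincident centroids; no angle sample")
    angle_d, angle_p = ks_two_sample(angles, null_angles)
    offset_d, offset_p = ks_two_sample(offsets, null_offsets)
    return TipSummary(
        n_pairs=len(pairs),
        n_angle_excluded=excluded,
        observed_angles=np.asarray(angles),
        observed_offsets=np.asarray(offsets),
        null_angles=null_angles,
        null_offsets=null_offsets,
        angle_D=angle_d,
        angle_p=angle_p,
        offset_D=offset_d,
        offset_p=offset_p,
        n_randomizations=n_randomizations,
        seed=seed,
    )


def histogram_table(values, bin_width: float, upper: float) -> "np.ndarray":
    """Counts in fixed-width bins [0, upper] (last bin right-inclusive)."""
    edges = np.arange(0.0, upper + bin_width / 2, bin_width)
    if edges[-1] < upper:
        edges = np.append(edges, upper)
    counts, _ = np.histogram(np.asarray(values, dtype=float), bins=edges)
    return counts
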