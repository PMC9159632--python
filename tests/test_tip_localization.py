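import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from mucoquant.errors import InputError, MeasurementError, UndefinedAngleError
from mucoquant.geometry import axis_unit_vector
from mucoquant.tip_localization import (
    MucocystPair,
    ks_two_sample,
    pair_features,
    randomize_within_mucocyst,
    tip_angle,
    tip_offset,
    tip_statistics,
)

from conftest import featureset_from_mask, point_feature


def make_pair(orientation_deg=0.0, major=40.0, minor=20.0, displacement=(0.0, 0.0)):
    """Pair with an idealized Grl feature and a point Mdl at a given offset."""
    grl = point_feature(50.0, 50.0, label=1)
    grl.major_axis_len = major
    grl.minor_axis_len = minor
    grl.orientation_deg = orientation_deg
    mdl = point_feature(50.0 + displacement[0], 50.0 + displacement[1], label=1)
    return MucocystPair(grl=grl, mdl=mdl, shared_pixels=1)


class TestPairing:
    def test_disjoint_sets_give_no_pairs(self):
        grl_mask = np.zeros((30, 30), bool)
        grl_mask[0:5, 0:5] = True
        mdl_mask = np.zeros((30, 30), bool)
        mdl_mask[20:22, 20:22] = True
        assert pair_features(featureset_from_mask(grl_mask), featureset_from_mask(mdl_mask)) == []

    def test_punctum_inside_ellipse_gives_one_pair(self, docked_image):
        micrograph, _ = docked_image
        from mucoquant.segmentation import segment_channel

        grl = segment_channel(micrograph, "grl", sensitivity=0.5)
        mdl = segment_channel(micrograph, "mdl", sensitivity=0.4)
        pairs = pair_features(grl, mdl)
        assert len(pairs) >= 1
        assert all(p.shared_pixels >= 1 for p in pairs)
        # one pair per Mdl feature at most
        assert len({p.mdl.label for p in pairs}) == len(pairs)

    def test_assigned_to_largest_overlap_with_tie_to_smaller_label(self):
        grl_mask = np.zeros((20, 20), bool)
        grl_mask[0:4, 0:10] = True    # becomes label 1
        grl_mask[8:12, 0:10] = True   # becomes label 2
        grl = featureset_from_mask(grl_mask)
        assert grl.labels == [1, 2]
        mdl_mask = np.zeros((20, 20), bool)
        mdl_mask[2:4, 0:3] = True     # 6 px in label 1
        mdl_mask[4:8, 0] = True       # bridge outside both
        mdl_mask[8:10, 0] = True      # 2 px in label 2
        mdl = featureset_from_mask(mdl_mask)
        assert len(mdl) == 1
        [pair] = pair_features(grl, mdl)
        assert pair.grl.label == 1 and pair.shared_pixels == 6


class TestAngleAndOffset:
    def test_displacement_along_major_axis_is_zero(self):
        u = axis_unit_vector(30.0)
        pair = make_pair(orientation_deg=30.0, displacement=(8.0 * u[0], 8.0 * u[1]))
        assert tip_angle(pair) == pytest.approx(0.0, abs=1e-9)

    def test_displacement_along_minor_axis_is_ninety(self):
        u = axis_unit_vector(30.0 + 90.0)
        pair = make_pair(orientation_deg=30.0, displacement=(5.0 * u[0], 5.0 * u[1]))
        assert tip_angle(pair) == pytest.approx(90.0, abs=1e-9)

    def test_diagonal_displacement_on_circle_is_45(self):
        pair = make_pair(orientation_deg=0.0, major=20.0, minor=20.0, displacement=(3.0, 3.0))
        assert tip_angle(pair) == pytest.approx(45.0, abs=1e-9)

    def test_coincident_centroids_raise(self):
        pair = make_pair(displacement=(0.0, 0.0))
        with pytest.raises(UndefinedAngleError):
            tip_angle(pair)
        assert tip_offset(pair) == 0.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        orientation=st.floats(0, 180, exclude_max=True),
        direction=st.floats(0, 360),
        dist=st.floats(0.5, 30),
    )
    def test_angle_invariant_to_axis_reversal_and_swap(self, orientation, direction, dist):
        d = np.deg2rad(direction)
        disp = (dist * np.sin(d), dist * np.cos(d))
        pair = make_pair(orientation_deg=orientation, displacement=disp)
        flipped = make_pair(
            orientation_deg=(orientation + 180.0) % 360.0, displacement=disp
        )
        swapped = make_pair(orientation_deg=orientation, displacement=(-disp[0], -disp[1]))
        a = tip_angle(pair)
        assert 0.0 <= a <= 90.0
        assert tip_angle(flipped) == pytest.approx(a, abs=1e-6)
        assert tip_angle(swapped) == pytest.approx(a, abs=1e-6)

    def test_offset_one_at_tip_and_linear(self):
        u = axis_unit_vector(60.0)
        tip = make_pair(orientation_deg=60.0, major=40.0, displacement=(20 * u[0], 20 * u[1]))
        assert tip_offset(tip) == pytest.approx(1.0, abs=1e-12)
        half = make_pair(orientation_deg=60.0, major=40.0, displacement=(10 * u[0], 10 * u[1]))
        assert tip_offset(half) == pytest.approx(0.5, abs=1e-12)

    def test_degenerate_major_axis_raises(self):
        pair = make_pair(major=0.0, displacement=(1.0, 0.0))
        with pytest.raises(MeasurementError):
            tip_offset(pair)


class TestWithinMucocystNull:
    def test_circular_feature_analytic_means(self):
        """Uniform disk: E[offset] = 2/3 and angles ~ Uniform(0, 90)."""
        pair = make_pair(major=30.0, minor=30.0, displacement=(5.0, 0.0))
        R = 100_000
        null = randomize_within_mucocyst(pair, R, seed=17)
        se_offset = np.sqrt(1 / 18) / np.sqrt(R)  # sd of r under density 2r
        assert abs(null.null_offsets.mean() - 2 / 3) < 3 * se_offset
        se_angle = (90 / np.sqrt(12)) / np.sqrt(R)
        assert abs(null.null_angles.mean() - 45.0) < 3 * se_angle

    def test_offsets_bounded_by_one_and_angles_in_range(self):
        pair = make_pair(major=40.0, minor=16.0, displacement=(2.0, 1.0))
        null = randomize_within_mucocyst(pair, 5000, seed=3)
        assert null.null_offsets.max() <= 1.0 + 1e-12
        assert 0.0 <= null.null_angles.min() and null.null_angles.max() <= 90.0

    def test_deterministic_under_seed(self):
        pair = make_pair(displacement=(2.0, 1.0))
        a = randomize_within_mucocyst(pair, 1000, seed=5)
        b = randomize_within_mucocyst(pair, 1000, seed=5)
        assert np.array_equal(a.null_offsets, b.null_offsets)
        assert np.array_equal(a.null_angles, b.null_angles)


class TestKolmogorovSmirnov:
    def test_identical_samples_give_zero(self):
        d, p = ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0 and p == 1.0

    def test_fully_separated_samples_give_one(self):
        d, _ = ks_two_sample([0.0, 0.1, 0.2], [5.0, 6.0, 7.0])
        assert d == 1.0

    def test_shifted_quartet_gives_quarter(self):
        d, _ = ks_two_sample([1, 2, 3, 4], [2, 3, 4, 5])
        assert d == 0.25

    def test_empty_sample_rejected(self):
        with pytest.raises(InputError):
            ks_two_sample([], [1.0])

    def test_statistic_matches_scipy(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = rng.normal(0.5, 1.2, size=55)
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(stats.ks_2samp(x, y).statistic, abs=1e-12)

    def test_matches_r_asymptotic_ks_test(self):
        """Independent oracle: R's ks.test(exact=FALSE) uses the asymptotic
        Kolmogorov distribution for its two-sided p-value."""
        import shutil
        import subprocess

        if shutil.which("Rscript") is None:
            pytest.skip("Rscript not available")
        rng = np.random.default_rng(11)
        x = rng.normal(size=40)
        y = rng.normal(0.2, 1.0, size=55)
        d, p = ks_two_sample(x, y)
        xs = ",".join(f"{float(v):.17g}" for v in x)
        ys = ",".join(f"{float(v):.17g}" for v in y)
        res = subprocess.run(
            ["Rscript", "-e",
             f"r <- ks.test(c({xs}), c({ys}), exact=FALSE); cat(r$statistic, r$p.value)"],
            capture_output=True, text=True, check=True,
        )
        r_d, r_p = (float(v) for v in res.stdout.split())
        assert d == pytest.approx(r_d, abs=1e-6)
        assert p == pytest.approx(r_p, rel=1e-5)


class TestPooledStatistics:
    def test_tip_biased_image_rejects_null(self, docked_image):
        micrograph, _ = docked_image
        from mucoquant.segmentation import segment_channel

        grl = segment_channel(micrograph, "grl", sensitivity=0.5)
        mdl = segment_channel(micrograph, "mdl", sensitivity=0.4)
        pairs = pair_features(grl, mdl)
        summary = tip_statistics(pairs, n_randomizations=300, seed=4)
        assert summary.n_pairs == len(pairs)
        assert summary.angle_p < 0.01 and summary.offset_p < 0.01
        # tip-biased puncta sit near the tip, far beyond the uniform null mean
        assert np.median(summary.observed_offsets) > np.median(summary.null_offsets)

    def test_deterministic_under_seed(self, docked_image):
        micrograph, _ = docked_image
        from mucoquant.segmentation import segment_channel

        grl = segment_channel(micrograph, "grl", sensitivity=0.5)
        mdl = segment_channel(micrograph, "mdl", sensitivity=0.4)
        pairs = pair_features(grl, mdl)
        s1 = tip_statistics(pairs, n_randomizations=100, seed=21)
        s2 = tip_statistics(pairs, n_randomizations=100, seed=21)
        assert np.array_equal(s1.null_angles, s2.null_angles)
        assert (s1.angle_D, s1.angle_p) == (s2.angle_D, s2.angle_p)

    def test_offset_recovery_monotone_in_tip_bias(self):
        """Median measured offset tracks the planted tip bias."""
        import mucoquant as mq
        from conftest import small_cell_params
        from mucoquant.segmentation import segment_channel

        medians = []
        for beta in (0.0, 0.25, 0.5, 0.75, 1.0):
            micrograph, _ = mq.generate_cell_image(
                small_cell_params(tip_bias=beta, gauss_noise_sd=0.005, seed=40)
            )
            grl = segment_channel(micrograph, "grl", sensitivity=0.5)
            mdl = segment_channel(micrograph, "mdl", sensitivity=0.4)
            pairs = pair_features(grl, mdl)
            assert len(pairs) >= 5
            medians.append(np.median([tip_offset(p) for p in pairs]))
        assert all(a < b for a, b in zip(medians, medians[1:]))
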