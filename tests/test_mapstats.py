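"""Map construction, registration, averaging and reproducibility."""

import numpy as np
import pytest

from collimap import (
    PhaseMap,
    average_registered_maps,
    circular_mean,
    detect_structure_border,
    group_from_maps,
    linear_retinotopy_truth,
    make_retinotopy_sessions,
    orientation_from_pair,
    pixelwise_reproducibility,
    register_group,
    retinotopy_from_pair,
    selective_domain_fraction,
    visual_field_coverage,
)
from collimap.circstats import circular_difference as circ_diff_deg
from collimap.mapstats import GroupMaps, RetinotopicMap, RigidTransform
from collimap.phasemap import TWO_PI

F_STIM = 0.125
F_ORI = 1.0 / 15.0


def phase_map(phase, magnitude=1.0, f=F_STIM, valid=None):
    phase = np.asarray(phase, dtype=float)
    mag = np.broadcast_to(np.asarray(magnitude, dtype=float), phase.shape).copy()
    return PhaseMap(phase, mag, f, valid)


def uniform_group(values, period, n=5, mags=None):
    """GroupMaps with identical geometry, shape (n, h, w)."""
    values = np.asarray(values, dtype=float)
    stack = np.broadcast_to(values, (n, *values.shape)).copy()
    if mags is None:
        mags = np.ones_like(stack)
    return GroupMaps(values=stack, magnitudes=mags,
                     valid=np.ones(stack.shape, dtype=bool), period_deg=period,
                     transforms=[RigidTransform(0.0, (0, 0))] * n)


class TestRetinotopyFromPair:
    def test_zero_phases(self):
        rmap = retinotopy_from_pair(phase_map(np.zeros((4, 4))),
                                    phase_map(np.zeros((4, 4))), span_deg=110)
        assert np.allclose(rmap.position_deg, 0.0)
        assert rmap.delay_estimate_s == 0.0

    def test_stated_convention(self):
        """phi_f = pi/2 + 0.6, phi_r = -pi/2 + 0.6 -> delay 0.6, 27.5 deg."""
        fwd = phase_map(np.full((3, 3), np.pi / 2 + 0.6))
        rev = phase_map(np.full((3, 3), (-np.pi / 2 + 0.6) % TWO_PI))
        rmap = retinotopy_from_pair(fwd, rev, span_deg=110)
        assert np.allclose(rmap.position_deg, 27.5, atol=1e-9)
        assert rmap.delay_estimate_s == pytest.approx(0.6 / (TWO_PI * F_STIM))

    def test_mismatched_inputs_rejected(self):
        with pytest.raises(ValueError):
            retinotopy_from_pair(phase_map(np.zeros((3, 3))),
                                 phase_map(np.zeros((4, 4))), 110)
        with pytest.raises(ValueError):
            retinotopy_from_pair(phase_map(np.zeros((3, 3)), f=F_STIM),
                                 phase_map(np.zeros((3, 3)), f=F_ORI), 110)

    def test_delay_invariance(self, sweep_protocol):
        """A shared delay up to 3.9 s moves positions by < 0.1 deg."""
        base = None
        for delay in (0.0, 3.9):
            truth = linear_retinotopy_truth(shape=(12, 12), delay_s=delay, seed=6)
            fwd, rev, _ = make_retinotopy_sessions(truth, sweep_protocol)
            from collimap import analyze_retinotopy_pair
            rmap = analyze_retinotopy_pair(fwd, rev, sweep_protocol)
            if base is None:
                base = rmap.position_deg
            else:
                assert circ_diff_deg(rmap.position_deg, base, 110.0).max() < 0.1


class TestOrientationFromPair:
    def test_pure_delay_reads_zero_orientation(self):
        d = 0.8
        omap = orientation_from_pair(phase_map(np.full((4, 4), d), f=F_ORI),
                                     phase_map(np.full((4, 4), d), f=F_ORI))
        assert np.allclose(circ_diff_deg(omap.orientation_deg, 0.0, 180.0), 0.0,
                           atol=1e-9)

    def test_doubled_angle_coding(self):
        """phi+ = d + pi/2, phi- = d - pi/2 -> 45 deg."""
        d = 1.1
        ccw = phase_map(np.full((4, 4), d + np.pi / 2), f=F_ORI)
        cw = phase_map(np.full((4, 4), (d - np.pi / 2) % TWO_PI), f=F_ORI)
        omap = orientation_from_pair(ccw, cw)
        assert np.allclose(omap.orientation_deg, 45.0, atol=1e-9)
        assert omap.delay_estimate_s == pytest.approx(d / (TWO_PI * F_ORI))


class TestRegistration:
    span_az, span_el = 110.0, 60.0

    @staticmethod
    def analytic_pair(h, w, theta_deg=0.0, dy=0, dx=0):
        """Map pair sampled on a rotated/shifted grid so that warping by
        (theta, (dy, dx)) reproduces the untransformed reference."""
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        cy, cx = (h - 1) / 2, (w - 1) / 2
        th = np.deg2rad(theta_deg)
        qx, qy = xx - cx, yy - cy
        rx = np.cos(th) * qx - np.sin(th) * qy + cx + dx
        ry = np.sin(th) * qx + np.cos(th) * qy + cy + dy
        az = 10 + 90 * (rx / (w - 1)) + 3 * np.sin(2 * np.pi * ry / h)
        el = 6 + 48 * (ry / (h - 1)) + 2 * np.cos(2 * np.pi * rx / w)
        valid = np.ones((h, w), dtype=bool)
        return (RetinotopicMap(az % 110, np.ones((h, w)), "azimuth", 110, 1.0, valid),
                RetinotopicMap(el % 60, np.ones((h, w)), "elevation", 60, 1.0, valid))

    def test_identical_pairs_identity_transform(self):
        pair = self.analytic_pair(32, 32)
        tfs, _, _ = register_group([pair, pair])
        for tf in tfs:
            assert abs(tf.rotation_deg) <= 0.5
            assert tf.shift == (0, 0)

    def test_planted_transform_recovered(self):
        """5 deg rotation + (3, -2) px shift found within 0.5 deg / 0.5 px."""
        ref = self.analytic_pair(48, 48)
        moved = self.analytic_pair(48, 48, theta_deg=5.0, dy=3, dx=-2)
        tfs, az_group, _ = register_group([ref, moved])
        tf = tfs[1]
        assert abs(abs(tf.rotation_deg) - 5.0) <= 0.5
        assert abs(abs(tf.shift[0]) - 3) <= 0.5 and abs(abs(tf.shift[1]) - 2) <= 0.5
        # registered moving map matches the reference where defined
        err = circ_diff_deg(az_group.values[1], az_group.values[0], 110.0)
        assert np.median(err[az_group.valid.all(axis=0)]) < 0.5

    def test_idempotence(self):
        """Registering already-registered maps gives identity transforms."""
        ref = self.analytic_pair(32, 32)
        moved = self.analytic_pair(32, 32, theta_deg=4.0, dy=2, dx=1)
        tfs, az_group, el_group = register_group([ref, moved])
        pairs2 = []
        for i in range(2):
            pairs2.append((
                RetinotopicMap(az_group.values[i], az_group.magnitudes[i], "azimuth",
                               110, 1.0, az_group.valid[i]),
                RetinotopicMap(el_group.values[i], el_group.magnitudes[i], "elevation",
                               60, 1.0, el_group.valid[i])))
        tfs2, _, _ = register_group(pairs2)
        for tf in tfs2:
            assert abs(tf.rotation_deg) <= 0.5
            assert abs(tf.shift[0]) <= 1 and abs(tf.shift[1]) <= 1

    def test_noise_maps_terminate(self, rng):
        maps = []
        for _ in range(2):
            az = RetinotopicMap(rng.uniform(0, 110, (24, 24)), np.ones((24, 24)),
                                "azimuth", 110, 1.0, np.ones((24, 24), bool))
            el = RetinotopicMap(rng.uniform(0, 60, (24, 24)), np.ones((24, 24)),
                                "elevation", 60, 1.0, np.ones((24, 24), bool))
            maps.append((az, el))
        tfs, _, _ = register_group(maps)  # must not raise or hang
        assert len(tfs) == 2

    def test_single_animal_rejected(self):
        with pytest.raises(ValueError, match="2 animals"):
            register_group([self.analytic_pair(16, 16)])


class TestAveraging:
    def test_identical_maps_average_to_themselves(self, rng):
        values = rng.uniform(0, 110, (6, 6))
        group = uniform_group(values, 110.0)
        avg, _, valid = average_registered_maps(group)
        assert np.allclose(circ_diff_deg(avg[valid], values[valid], 110.0), 0, atol=1e-9)
        assert valid.all()

    def test_antipodal_orientations_flagged_invalid(self):
        group = uniform_group(np.full((3, 3), 10.0), 180.0, n=2)
        group.values[1] = 100.0  # 90 deg apart on the 180-deg circle
        _, _, valid = average_registered_maps(group)
        assert not valid.any()

    def test_matches_pixelwise_circular_mean_oracle(self, rng):
        n, h, w = 4, 5, 5
        group = GroupMaps(values=rng.uniform(0, 110, (n, h, w)),
                          magnitudes=rng.uniform(0.5, 2.0, (n, h, w)),
                          valid=np.ones((n, h, w), bool), period_deg=110.0,
                          transforms=[RigidTransform(0.0, (0, 0))] * n)
        avg, _, valid = average_registered_maps(group)
        for i in range(h):
            for j in range(w):
                expected = circular_mean(group.values[:, i, j],
                                         group.magnitudes[:, i, j], period=110.0)
                assert circ_diff_deg(avg[i, j], expected, 110.0) < 1e-9

    def test_fewer_than_two_contributors_invalid(self):
        group = uniform_group(np.full((3, 3), 50.0), 110.0, n=3)
        group.valid[1:, 0, 0] = False
        _, _, valid = average_registered_maps(group)
        assert not valid[0, 0] and valid[1, 1]


class TestReproducibility:
    def test_identical_strong_maps_all_significant(self, rng):
        group = uniform_group(rng.uniform(0, 110, (8, 8)), 110.0, n=5)
        p, mask = pixelwise_reproducibility(group, n_mc=20_000, seed=0)
        assert mask.all()
        assert (p <= 0.01).all()

    def test_type_one_error_on_null_maps(self, rng):
        """Independent uniform phases: ~5% of pixels significant."""
        n, n_pix = 5, 10_000
        group = GroupMaps(values=rng.uniform(0, 110, (n, 100, 100)),
                          magnitudes=rng.uniform(0.5, 1.5, (n, 100, 100)),
                          valid=np.ones((n, 100, 100), bool), period_deg=110.0,
                          transforms=[RigidTransform(0.0, (0, 0))] * n)
        _, mask = pixelwise_reproducibility(group, alpha=0.05, n_mc=100_000, seed=1)
        assert mask.mean() == pytest.approx(0.05, abs=0.01)

    def test_concentrated_phases_high_power(self, rng):
        """kappa-concentrated phases across 5 animals: > 99% significant."""
        n, h, w = 5, 50, 50
        base = rng.uniform(0, 110, (h, w))
        jitter = rng.vonmises(0.0, 50.0, (n, h, w)) * 110 / TWO_PI
        group = GroupMaps(values=(base[None] + jitter) % 110,
                          magnitudes=rng.uniform(0.5, 1.5, (n, h, w)),
                          valid=np.ones((n, h, w), bool), period_deg=110.0,
                          transforms=[RigidTransform(0.0, (0, 0))] * n)
        _, mask = pixelwise_reproducibility(group, n_mc=100_000, seed=2)
        assert mask.mean() > 0.99

    def test_single_animal_rejected(self):
        group = uniform_group(np.zeros((3, 3)), 110.0, n=1)
        with pytest.raises(ValueError):
            pixelwise_reproducibility(group)


class TestDomainsAndCoverage:
    def make_tested_group(self, sig, border=None, values=None, period=110.0):
        h, w = sig.shape
        vals = values if values is not None else np.full((h, w), 30.0)
        group = uniform_group(vals, period, n=3)
        group.significance_mask = sig
        group.border_mask = border
        group.p_map = np.where(sig, 0.01, 0.5)
        return group

    def test_domain_fraction_cases(self):
        h = w = 8
        all_sig = self.make_tested_group(np.ones((h, w), bool))
        assert selective_domain_fraction(all_sig)[0] == 1.0
        none_sig = self.make_tested_group(np.zeros((h, w), bool))
        assert selective_domain_fraction(none_sig)[0] == 0.0
        checker = np.indices((h, w)).sum(axis=0) % 2 == 0
        half = self.make_tested_group(checker)
        assert selective_domain_fraction(half)[0] == 0.5

    def test_domain_area_uses_pixel_pitch(self):
        sig = np.ones((10, 10), bool)
        _, area = selective_domain_fraction(self.make_tested_group(sig),
                                            pixel_pitch_um=10.5)
        assert area == pytest.approx(100 * (10.5e-3) ** 2)

    def test_disjoint_masks_empty_coverage(self):
        sig_a = np.zeros((8, 8), bool)
        sig_a[:4] = True
        sig_b = ~sig_a
        az = self.make_tested_group(sig_a)
        el = self.make_tested_group(sig_b, period=60.0)
        cells, area = visual_field_coverage(az, el)
        assert cells == set() and area == 0.0

    def test_full_field_coverage_area(self):
        """Uniform full-span maps, all significant: 110 x 60 deg^2."""
        h = w = 40
        yy, xx = np.mgrid[0:h, 0:w]
        az_vals = 110.0 * xx / w + 1.0
        el_vals = 60.0 * yy / h + 0.5
        az = self.make_tested_group(np.ones((h, w), bool), values=az_vals)
        el = self.make_tested_group(np.ones((h, w), bool), values=el_vals, period=60.0)
        _, area = visual_field_coverage(az, el, cell_deg=5.0)
        assert abs(area - 110 * 60) <= 5.0 * 5.0

    def test_half_field_selective_group(self):
        """Only the left half is significant: coverage matches the
        azimuth range planted there."""
        h = w = 40
        yy, xx = np.mgrid[0:h, 0:w]
        az_vals = 110.0 * xx / w + 1.0
        el_vals = 60.0 * yy / h + 0.5
        sig = xx < w // 2
        az = self.make_tested_group(sig, values=az_vals)
        el = self.make_tested_group(sig, values=el_vals, period=60.0)
        _, area = visual_field_coverage(az, el, cell_deg=5.0)
        assert abs(area - 55 * 60) <= 2 * 5.0 * 60


class TestStructureBorder:
    def test_uniform_magnitude_full_frame(self):
        assert detect_structure_border(np.ones((9, 9))).all()

    def test_disk_recovered(self):
        yy, xx = np.mgrid[0:41, 0:41]
        disk = (yy - 20) ** 2 + (xx - 20) ** 2 <= 12**2
        mag = np.where(disk, 1.0, 0.05)
        border = detect_structure_border(mag, threshold=0.5)
        from scipy.ndimage import binary_dilation
        assert border[disk].mean() > 0.99
        assert not border[~binary_dilation(disk, iterations=1)].any()

    def test_all_zero_warns_and_empty(self):
        with pytest.warns(UserWarning, match="all zero"):
            border = detect_structure_border(np.zeros((5, 5)))
        assert not border.any()

    def test_largest_component_kept(self):
        mag = np.zeros((20, 20))
        mag[2:12, 2:12] = 1.0
        mag[16:18, 16:18] = 1.0
        border = detect_structure_border(mag, threshold=0.5, closing_radius=0)
        assert border[5, 5] and not border[16, 16]


class TestGroupFromMaps:
    def test_transforms_carry_orientation_maps(self):
        """Orientation maps inherit retinotopy-derived transforms."""
        from collimap import OrientationMap
        h = w = 24
        ori = np.full((h, w), 40.0)
        maps = [OrientationMap(ori, np.ones((h, w)), 1.0, np.ones((h, w), bool))
                for _ in range(3)]
        tfs = [RigidTransform(0.0, (0, 0)), RigidTransform(0.0, (2, -1)),
               RigidTransform(3.0, (0, 0))]
        group = group_from_maps(maps, tfs)
        assert group.period_deg == 180.0
        interior = group.valid.all(axis=0)
        assert interior.any()
        assert np.allclose(
            circ_diff_deg(group.values[:, interior], 40.0, 180.0), 0.0, atol=0.5)
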