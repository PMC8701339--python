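"""Per-degree CDR profiles: construction, averaging, OS inversion."""

import numpy as np
import pytest
from shapely.geometry import LineString, Polygon

from onh360.profiles import (
    CdrProfile,
    ProfileSource,
    average_graders,
    invert_os,
    profile_from_outlines,
)
from onh360.roi_io import Eye, Structure
from onh360.synthetic import GraderNoise, SyntheticEyeSpec, generate_eye

from conftest import circle_polygon, make_outline


def _circle_pair(cup_r, disc_r, cup_center=None, center=(100.0, 100.0), n=1440,
                 eye=Eye.OD):
    cup_center = cup_center or center
    cup = make_outline(circle_polygon(cup_center, cup_r, n), structure=Structure.CUP,
                       eye=eye)
    disc = make_outline(circle_polygon(center, disc_r, n), structure=Structure.DISC,
                        eye=eye)
    return cup, disc


class TestProfileFromOutlines:
    def test_concentric_circles_closed_form(self):
        cup, disc = _circle_pair(3.0, 6.0)
        p = profile_from_outlines(cup, disc, source=ProfileSource.GRADER_1)
        np.testing.assert_allclose(p.half_cdr, 0.5, atol=1e-3)
        assert p.vcdr == pytest.approx(0.5, abs=1e-3)
        assert p.hcdr == pytest.approx(0.5, abs=1e-3)
        assert p.area_ratio == pytest.approx(0.25, abs=1e-3)
        assert p.warnings == []

    def test_cup_equals_disc_gives_unit_cdr(self):
        cup, _ = _circle_pair(5.0, 6.0)
        disc = make_outline(cup.vertices, structure=Structure.DISC)
        p = profile_from_outlines(cup, disc, source=ProfileSource.GRADER_1)
        np.testing.assert_allclose(p.half_cdr, 1.0, atol=1e-9)
        assert p.vcdr == pytest.approx(1.0, abs=1e-9)

    def test_offset_cup_analytic_ray_oracle(self):
        # cup circle r=2 centered 1 px right of the disc centroid, disc R=4:
        # ray-circle intersections give half_cdr 3/4 at 90 deg, 1/4 at 270,
        # sqrt(3)/4 full CDR on the vertical bisector, 0.5 on the horizontal
        cup, disc = _circle_pair(2.0, 4.0, cup_center=(101.0, 100.0), n=14400)
        p = profile_from_outlines(cup, disc, source=ProfileSource.GRADER_1)
        assert p.half_cdr[90] == pytest.approx(3.0 / 4.0, abs=1e-6)
        assert p.half_cdr[270] == pytest.approx(1.0 / 4.0, abs=1e-6)
        assert p.full_cdr[90] == pytest.approx(0.5, abs=1e-6)
        # vertical ray: |(0, -t) - (1, 0)| = 2  =>  t = sqrt(3)
        assert p.half_cdr[0] == pytest.approx(np.sqrt(3.0) / 4.0, abs=1e-6)
        assert p.vcdr == pytest.approx(2 * np.sqrt(3.0) / 8.0, abs=1e-6)

    def test_full_cdr_is_180_degree_periodic_exactly(self):
        spec = SyntheticEyeSpec(seed=5, cup_offset=(8.0, -5.0))
        img, _ = generate_eye(spec)
        p = profile_from_outlines(img.get("g1", "cup"), img.get("g1", "disc"),
                                  source=ProfileSource.GRADER_1)
        np.testing.assert_array_equal(p.full_cdr, np.roll(p.full_cdr, 180))

    def test_vcdr_equals_vertical_chord_ratio_oracle(self):
        # independent route: intersect both polygons with the vertical line
        # through the disc centroid and ratio the chord lengths
        for seed in range(5):
            spec = SyntheticEyeSpec(seed=seed, cup_offset=(6.0, 4.0),
                                    grader_noise=GraderNoise(jitter_sd=0.0))
            img, _ = generate_eye(spec)
            cup_o, disc_o = img.get("g1", "cup"), img.get("g1", "disc")
            p = profile_from_outlines(cup_o, disc_o, source=ProfileSource.GRADER_1)
            disc_poly = Polygon(disc_o.vertices)
            cup_poly = Polygon(cup_o.vertices)
            centroid = disc_poly.centroid
            vline = LineString([(centroid.x, -1e4), (centroid.x, 1e4)])
            chord_disc = vline.intersection(disc_poly).length
            chord_cup = vline.intersection(cup_poly).length
            assert p.vcdr == pytest.approx(chord_cup / chord_disc, abs=1e-9)

    def test_cup_outside_disc_flagged_not_clipped(self):
        cup, disc = _circle_pair(3.0, 4.0, cup_center=(102.5, 100.0))
        p = profile_from_outlines(cup, disc, source=ProfileSource.GRADER_1)
        assert "cup_outside_disc" in p.warnings
        assert p.half_cdr.max() > 1.0

    def test_mismatched_images_raise(self):
        cup, disc = _circle_pair(3.0, 6.0)
        disc.image_id = "other"
        with pytest.raises(ValueError, match="different images"):
            profile_from_outlines(cup, disc)

    def test_centroid_outside_cup_raises(self):
        # cup far off to one side so the disc centroid misses it entirely
        cup, disc = _circle_pair(0.5, 4.0, cup_center=(103.0, 100.0))
        with pytest.raises(ValueError, match="centroid"):
            profile_from_outlines(cup, disc, source=ProfileSource.GRADER_1)


def _profile(cup_radii, disc_radii, source, eye=Eye.OD, image_id="img1"):
    return CdrProfile(
        image_id=image_id, eye=eye,
        half_cut_cup=np.asarray(cup_radii, dtype=float) * np.ones(360),
        half_cut_disc=np.asarray(disc_radii, dtype=float) * np.ones(360),
        area_ratio=float(np.mean(cup_radii) ** 2 / np.mean(disc_radii) ** 2),
        source=source,
    )


class TestAverageGraders:
    def test_identical_inputs_idempotent(self):
        p1 = _profile(3.0, 10.0, ProfileSource.GRADER_1)
        p2 = _profile(3.0, 10.0, ProfileSource.GRADER_2)
        m = average_graders(p1, p2)
        np.testing.assert_array_equal(m.half_cut_cup, p1.half_cut_cup)
        np.testing.assert_array_equal(m.half_cdr, p1.half_cdr)
        assert m.source is ProfileSource.MEAN_OF_GRADERS

    def test_constant_radii_closed_form(self):
        p1 = _profile(3.0, 10.0, ProfileSource.GRADER_1)
        p2 = _profile(5.0, 10.0, ProfileSource.GRADER_2)
        m = average_graders(p1, p2)
        np.testing.assert_allclose(m.half_cdr, 0.4)

    def test_full_cut_throughs_are_degreewise_means(self):
        img, _ = generate_eye(SyntheticEyeSpec(seed=21, cup_offset=(5.0, 2.0)))
        p1 = profile_from_outlines(img.get("g1", "cup"), img.get("g1", "disc"),
                                   source=ProfileSource.GRADER_1)
        p2 = profile_from_outlines(img.get("g2", "cup"), img.get("g2", "disc"),
                                   source=ProfileSource.GRADER_2)
        m = average_graders(p1, p2)
        np.testing.assert_allclose(
            m.full_cut_cup, (p1.full_cut_cup + p2.full_cut_cup) / 2, rtol=1e-12
        )
        np.testing.assert_allclose(
            m.full_cut_disc, (p1.full_cut_disc + p2.full_cut_disc) / 2, rtol=1e-12
        )
        assert m.area_ratio == pytest.approx((p1.area_ratio + p2.area_ratio) / 2)

    def test_cdr_after_averaging_differs_from_averaged_cdrs(self):
        # graders with different disc sizes: ratio-of-means != mean-of-ratios
        p1 = _profile(3.0, 10.0, ProfileSource.GRADER_1)
        p2 = _profile(5.0, 8.0, ProfileSource.GRADER_2)
        m_default = average_graders(p1, p2)
        m_ratio = average_graders(p1, p2, mode="average_cdrs")
        assert m_default.half_cdr[0] == pytest.approx(4.0 / 9.0)
        assert m_ratio.half_cdr[0] == pytest.approx((0.3 + 0.625) / 2)

    def test_source_validation(self):
        p1 = _profile(3.0, 10.0, ProfileSource.GRADER_1)
        with pytest.raises(ValueError, match="grader"):
            average_graders(p1, p1)


class TestInvertOs:
    def _os_profile(self):
        rng = np.random.default_rng(2)
        cup = 3 + rng.uniform(-0.5, 0.5, 360)
        disc = 10 + rng.uniform(-0.5, 0.5, 360)
        return CdrProfile(image_id="L", eye=Eye.OS, half_cut_cup=cup,
                          half_cut_disc=disc, area_ratio=0.09,
                          source=ProfileSource.MEAN_OF_GRADERS)

    def test_involution(self):
        p = self._os_profile()
        back = invert_os(invert_os(p))
        np.testing.assert_array_equal(back.half_cut_cup, p.half_cut_cup)
        assert back.inverted is False

    def test_fixed_points_and_scalars(self):
        p = self._os_profile()
        q = invert_os(p)
        assert q.half_cdr[0] == p.half_cdr[0]
        assert q.half_cdr[180] == p.half_cdr[180]
        assert q.vcdr == pytest.approx(p.vcdr, abs=1e-15)
        assert q.hcdr == pytest.approx(p.hcdr, abs=1e-15)

    def test_peak_moves_from_90_to_270(self):
        p = self._os_profile()
        p.half_cut_cup[90] = 9.0  # temporal peak in the OS frame
        q = invert_os(p)
        assert int(np.argmax(q.half_cdr)) == 270

    def test_preserves_multiset_of_values(self):
        p = self._os_profile()
        q = invert_os(p)
        np.testing.assert_allclose(np.sort(q.half_cdr), np.sort(p.half_cdr))

    def test_rejects_od(self):
        p = _profile(3.0, 10.0, ProfileSource.GRADER_1, eye=Eye.OD)
        with pytest.raises(ValueError, match="OS"):
            invert_os(p)
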