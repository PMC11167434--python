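"""Silhouette digitization: registration, pixel coding, percentages, group stats."""

import colorsys

import numpy as np
import pytest

from emomap import silhouette as sil, synthetic_data as sd
from emomap.types import EMOTIONS, SEGMENTS, BodyEmotionMatrix, round_half_away


@pytest.fixture(scope="module")
def colored(template_module):
    return sd.simulate_silhouette(
        {"face": 0.5, "hands": 0.2, "trunk": 0.3, "feet": 0.1}, {"trunk": 0.15}, template_module
    )


@pytest.fixture(scope="module")
def template_module():
    return sil.make_body_template()


class TestTemplate:
    def test_segments_tile_body(self, template_module):
        t = template_module
        assert sum(t.segment_counts().values()) == t.pixel_count_inside
        assert np.array_equal(t.segment_labels > 0, t.body_mask.astype(bool))

    def test_png_roundtrip(self, template_module, tmp_path):
        sil.write_template_png(template_module, tmp_path / "t.png")
        back = sil.read_template_png(tmp_path / "t.png")
        assert np.array_equal(back.segment_labels, template_module.segment_labels)


class TestSubtractionAndPercentages:
    def test_subtraction_definition(self, colored):
        sub = sil.subtraction_map(colored)
        assert set(np.unique(sub)) <= {-1, 0, 1}
        assert np.all(sub[colored.activation.astype(bool)] == 1)
        assert np.all(sub[colored.deactivation.astype(bool)] == -1)

    def test_identical_channels_cancel(self, template_module):
        s = sd.simulate_silhouette({"trunk": 0.3}, None, template_module)
        both = sil.Silhouette(activation=s.activation, deactivation=s.activation)
        assert np.all(sil.subtraction_map(both) == 0)

    def test_fully_colored_trunk_is_100(self, template_module):
        s = sd.simulate_silhouette({"trunk": 1.0}, None, template_module)
        pct = sil.segment_percentages(s, template_module)
        assert pct["trunk"] == 100.0 and pct["face"] == 0.0

    def test_empty_silhouette_zero(self, template_module):
        s = sd.simulate_silhouette({}, None, template_module)
        assert all(v == 0.0 for v in sil.segment_percentages(s, template_module).values())

    def test_counting_oracle(self, template_module, colored):
        """Percentages equal 100 x round(fraction x count) / count for the
        planted fractions, exactly."""
        counts = template_module.segment_counts()
        pct = sil.segment_percentages(colored, template_module, channel="activation")
        planted = {"face": 0.5, "hands": 0.2, "trunk": 0.3, "feet": 0.1}
        for seg in SEGMENTS:
            expected = 100.0 * round_half_away(planted[seg] * counts[seg]) / counts[seg]
            assert pct[seg] == pytest.approx(expected, abs=1e-12)

    def test_conservation_across_segments(self, template_module, colored):
        pct = sil.segment_percentages(colored, template_module, channel="activation")
        counts = template_module.segment_counts()
        total_from_segments = sum(pct[s] / 100.0 * counts[s] for s in SEGMENTS)
        assert total_from_segments == pytest.approx(colored.activation.sum())


class TestCodePixels:
    def test_blank_page_codes_nothing(self, template_module):
        page = np.ones((*template_module.shape, 3))
        s = sil.code_pixels(page, template_module)
        assert s.activation.sum() == 0 and s.deactivation.sum() == 0

    def test_pure_red_face_counts(self, template_module):
        page = np.ones((*template_module.shape, 3))
        face = np.argwhere(template_module.segment_mask("face"))[:500]
        page[face[:, 0], face[:, 1]] = (1.0, 0.0, 0.0)
        s = sil.code_pixels(page, template_module)
        assert s.activation.sum() == 500
        assert s.deactivation.sum() == 0

    def test_random_colors_match_per_pixel_rule_oracle(self, template_module, rng):
        """Random HSV colours: the coded channels match an independent
        per-pixel reimplementation of the hue-window rule via colorsys."""
        rules = sil.DEFAULT_COLOR_RULES
        h, w = template_module.shape
        page = rng.random((h, w, 3))
        s = sil.code_pixels(page, template_module, rules)
        body = template_module.body_mask.astype(bool)
        coords = np.argwhere(body)[rng.choice(template_module.pixel_count_inside, 300, replace=False)]
        for r, c in coords:
            hh, ss, vv = colorsys.rgb_to_hsv(*page[r, c])
            hue = hh * 360.0
            ok = ss >= rules.min_saturation and vv >= rules.min_value
            red = ok and (hue < rules.red_hue_max_deg or hue > rules.red_hue_min_deg)
            blue = ok and rules.blue_hue_range_deg[0] <= hue <= rules.blue_hue_range_deg[1]
            assert bool(s.activation[r, c]) == red
            assert bool(s.deactivation[r, c]) == blue

    def test_pixels_outside_body_discarded(self, template_module):
        page = np.zeros((*template_module.shape, 3))
        page[..., 0] = 1.0  # whole page red
        s = sil.code_pixels(page, template_module)
        assert np.array_equal(s.activation.astype(bool), template_module.body_mask.astype(bool))


class TestRegistration:
    def test_identity_scan_recovers_identity(self, template_module, colored):
        scan = sd.render_scan(colored, template_module)
        _, params = sil.register_to_template(scan, template_module)
        assert abs(params.shift_rows) < 0.5 and abs(params.shift_cols) < 0.5
        assert abs(params.angle_deg) < 0.5
        assert abs(params.scale - 1.0) < 0.01

    @pytest.mark.parametrize("shift,angle", [((-3.0, 5.0), 0.0), ((8.0, -6.0), 4.0), ((10.0, 2.0), -5.0)])
    def test_planted_transform_recovered(self, template_module, colored, shift, angle):
        scan = sd.render_scan(colored, template_module, shift=shift, angle_deg=angle)
        registered, params = sil.register_to_template(scan, template_module)
        assert abs(params.shift_rows - shift[0]) < 0.5
        assert abs(params.shift_cols - shift[1]) < 0.5
        assert abs(params.angle_deg - angle) < 0.5
        # and the registered page digitizes to the planted percentages
        coded = sil.code_pixels(registered, template_module)
        direct = sil.segment_percentages(colored, template_module)
        recovered = sil.segment_percentages(coded, template_module)
        for seg in SEGMENTS:
            assert recovered[seg] == pytest.approx(direct[seg], abs=1.0)

    def test_blank_page_fails_loudly(self, template_module):
        with pytest.raises(RuntimeError, match="blank"):
            sil.register_to_template(np.ones((*template_module.shape, 3)), template_module)


class TestGroupStats:
    def test_identical_nonzero_pixels_flagged(self):
        raster = np.zeros((10, 10), dtype=np.int8)
        raster[2, 2] = 1
        t, degenerate = sil.group_pixel_tmap([raster] * 5)
        assert t[2, 2] == 0.0 and degenerate[2, 2]
        assert not degenerate[0, 0]  # all-zero pixels are not flagged

    def test_sign_flip_negates(self, rng):
        rasters = [rng.choice([-1, 0, 1], size=(12, 12)) for _ in range(6)]
        t1, _ = sil.group_pixel_tmap(rasters)
        t2, _ = sil.group_pixel_tmap([-r for r in rasters])
        assert np.allclose(t1, -t2)

    def test_mean_t_matches_analytic_expectation(self, rng):
        """Pixels with mean 0.5 and sd 0.5 at n=26: t averages near
        0.5/(0.5/sqrt(26)) across many independent pixels."""
        from scipy.special import gammaln

        n = 26
        stack = rng.normal(0.5, 0.5, size=(n, 60, 60))
        t, _ = sil.group_pixel_tmap(list(stack))
        df = n - 1
        bias = np.sqrt(df / 2.0) * np.exp(gammaln((df - 1) / 2.0) - gammaln(df / 2.0))
        expected = 0.5 / (0.5 / np.sqrt(n)) * bias
        assert abs(np.mean(t) - expected) < 0.1


class TestPrePostReliability:
    def _mats(self, rng, n=30, noise=0.0, source="pixels"):
        base = [rng.random((5, 4)) * 60 for _ in range(n)]
        import pandas as pd

        def make(vals, sid):
            df = pd.DataFrame(vals, index=list(EMOTIONS), columns=list(SEGMENTS))
            return BodyEmotionMatrix(values=df, source=source, subject_id=sid)

        pre = [make(b, f"s{i}") for i, b in enumerate(base)]
        post = [make(np.clip(b + rng.normal(0, noise, b.shape), 0, 100), f"s{i}") for i, b in enumerate(base)]
        return pre, post

    def test_identical_gives_r_one(self, rng):
        pre, post = self._mats(rng, noise=0.0)
        r, p = sil.prepost_reliability(pre, pre)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_noise_gives_low_r(self, rng):
        lows = 0
        for _ in range(20):
            pre, _ = self._mats(rng)
            post, _ = self._mats(rng)
            r, _ = sil.prepost_reliability(pre, post)
            lows += abs(r) < 0.2
        assert lows >= 19

    def test_small_noise_attenuation(self, rng):
        pre, post = self._mats(rng, noise=0.1 * 17.3)  # sd of uniform(0,60) = 17.3
        r, _ = sil.prepost_reliability(pre, post)
        assert r > 0.95
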