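import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lysoquant.assays import (
    DilutionPlate,
    autophagic_flux,
    cfu_concentration,
    degradation_slope,
    ph_ratio_per_lysosome,
    secretion_ratio,
    surface_marker_summary,
)
from lysoquant.errors import DomainError, NoSignalError, SampleSizeError, UncountableError
from lysoquant.io import Image2D
from lysoquant.puncta import detect_puncta
from lysoquant.simulate import SceneSpec, simulate_scene

positive = st.floats(0.1, 1e6, allow_nan=False, allow_infinity=False)


class TestAutophagicFlux:
    def test_worked_examples(self):
        assert autophagic_flux(2.0, 1.0, 2.0, 1.0) == 1.0
        assert autophagic_flux(4.0, 2.0, 1.0, 1.0) == 2.0

    def test_swap_inverts(self):
        a = autophagic_flux(4.0, 2.0, 3.0, 2.0)
        b = autophagic_flux(3.0, 2.0, 4.0, 2.0)
        assert a == pytest.approx(1.0 / b)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(positive, positive, positive, positive, st.floats(0.1, 100.0))
    def test_scale_invariance_per_condition(self, a, b, c, d, s):
        assert autophagic_flux(a * s, b * s, c, d) == pytest.approx(
            autophagic_flux(a, b, c, d), rel=1e-9
        )

    def test_zero_band_rejected(self):
        with pytest.raises(DomainError):
            autophagic_flux(1.0, 0.0, 1.0, 1.0)


class TestCfu:
    def test_single_countable_plate(self):
        plate = DilutionPlate([150], [1e3], 0.1)
        assert cfu_concentration(plate) == pytest.approx(1.5e6)

    def test_uncountable_plates_skipped(self):
        # 400 colonies is above the countable range; only the 40-colony
        # plate contributes: 40 * 1e3 / 0.1 = 4e5
        plate = DilutionPlate([400, 40], [1e2, 1e3], 0.1)
        assert cfu_concentration(plate) == pytest.approx(4.0e5)

    def test_all_zero_uncountable(self):
        with pytest.raises(UncountableError):
            cfu_concentration(DilutionPlate([0, 0], [10, 100], 0.1))


class TestSecretionRatio:
    def test_worked_examples(self):
        assert secretion_ratio(1e5, 2.0, 1e5, 2.0) == 1.0
        assert secretion_ratio(2e5, 1.0, 1e6, 1.0) == pytest.approx(0.2)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(positive, positive, positive, positive, st.floats(0.1, 50.0))
    def test_volume_scale_invariance(self, cs, vs, ci, vi, s):
        assert secretion_ratio(cs, vs * s, ci, vi * s) == pytest.approx(
            secretion_ratio(cs, vs, ci, vi), rel=1e-9
        )

    def test_zero_intracellular_rejected(self):
        with pytest.raises(DomainError):
            secretion_ratio(1e5, 1.0, 0.0, 1.0)


class TestPhRatio:
    def _scene_puncta(self, fitc_scale=1.0):
        spec = SceneSpec(n_puncta={"ref": 5}, noise_sd=0.0, min_separation=20, seed=6)
        stack, geom, _ = simulate_scene(spec)
        far_red = stack[0]
        fitc = Image2D(far_red.pixels * fitc_scale)
        puncta = detect_puncta(far_red, geom)
        return fitc, far_red, puncta

    def test_equal_channels_ratio_one(self):
        fitc, far_red, puncta = self._scene_puncta(1.0)
        out = ph_ratio_per_lysosome(fitc, far_red, puncta)
        np.testing.assert_allclose(out.ratio, 1.0)

    def test_half_intensity_ratio_half(self):
        fitc, far_red, puncta = self._scene_puncta(0.5)
        out = ph_ratio_per_lysosome(fitc, far_red, puncta)
        np.testing.assert_allclose(out.ratio, 0.5)

    def test_common_scale_invariance(self):
        fitc, far_red, puncta = self._scene_puncta(0.7)
        r1 = ph_ratio_per_lysosome(fitc, far_red, puncta).ratio
        r2 = ph_ratio_per_lysosome(
            Image2D(fitc.pixels * 13.0), Image2D(far_red.pixels * 13.0), puncta
        ).ratio
        np.testing.assert_allclose(r1, r2)

    def test_independent_amplitudes_match_pixel_summation(self):
        # two puncta with different per-channel amplitude quotients,
        # verified by direct pixel summation over the label regions
        spec = SceneSpec(n_puncta={"ref": 2}, noise_sd=0.0, min_separation=40, seed=9)
        stack, geom, _ = simulate_scene(spec)
        far_red = stack[0]
        g = np.random.default_rng(1)
        scale_map = np.ones_like(far_red.pixels)
        puncta = detect_puncta(far_red, geom)
        quotients = {}
        for i, row in puncta.table.iterrows():
            q = g.uniform(0.3, 2.0)
            sel = puncta.labels == row.label
            # scale a generous neighbourhood of each punctum
            from scipy.ndimage import binary_dilation

            region = binary_dilation(sel, iterations=6)
            scale_map[region] = q
            quotients[row.label] = q
        fitc = Image2D(far_red.pixels * scale_map)
        out = ph_ratio_per_lysosome(fitc, far_red, puncta)
        for _, row in out.iterrows():
            assert row.ratio == pytest.approx(quotients[row.label], rel=1e-6)

    def test_empty_puncta_empty_result(self):
        from lysoquant.puncta import PunctaSet

        empty = PunctaSet(
            pd.DataFrame(columns=["label", "x", "y", "area_px", "intensity"]),
            labels=np.zeros((8, 8), int),
        )
        img = Image2D(np.ones((8, 8)))
        assert len(ph_ratio_per_lysosome(img, img, empty)) == 0


class TestSurfaceMarker:
    def _events(self, n, frac_pi, marker_live, marker_dead, seed=0):
        g = np.random.default_rng(seed)
        n_dead = int(n * frac_pi)
        pi = np.concatenate([np.full(n - n_dead, 10.0), np.full(n_dead, 1000.0)])
        marker = np.concatenate(
            [np.full(n - n_dead, marker_live), np.full(n_dead, marker_dead)]
        )
        idx = g.permutation(n)
        return pd.DataFrame({"pi": pi[idx], "marker": marker[idx]})

    def test_no_pi_positive_plain_mean(self):
        ev = self._events(6000, 0.0, 100.0, 0.0)
        assert surface_marker_summary(ev, 500.0)["mean_marker"] == pytest.approx(100.0)

    def test_exclusion_forced(self):
        ev = self._events(10000, 0.5, 100.0, 1e6)
        out = surface_marker_summary(ev, 500.0)
        assert out["mean_marker"] == pytest.approx(100.0)
        assert out["fraction_excluded"] == pytest.approx(0.5)

    def test_lognormal_mean_within_one_percent(self):
        g = np.random.default_rng(7)
        marker = g.lognormal(5.0, 0.5, 100_000)
        ev = pd.DataFrame({"pi": np.zeros(100_000), "marker": marker})
        out = surface_marker_summary(ev, 1.0)
        assert out["mean_marker"] == pytest.approx(marker.mean(), rel=1e-12)
        assert out["mean_marker"] == pytest.approx(np.exp(5.0 + 0.125), rel=0.01)

    def test_threshold_monotonicity(self):
        g = np.random.default_rng(3)
        ev = pd.DataFrame({"pi": g.uniform(0, 100, 8000), "marker": g.uniform(0, 10, 8000)})
        counts = [
            surface_marker_summary(ev, thr)["n_live"] for thr in (10.0, 30.0, 60.0, 90.0)
        ]
        assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_all_pi_positive_rejected(self):
        ev = self._events(6000, 1.0, 0.0, 100.0)
        with pytest.raises(NoSignalError):
            surface_marker_summary(ev, 500.0)

    def test_too_few_events_rejected(self):
        ev = self._events(100, 0.0, 1.0, 0.0)
        with pytest.raises(SampleSizeError):
            surface_marker_summary(ev, 500.0)


class TestDegradationSlope:
    def test_linear_trace(self):
        t = np.arange(0, 180, 10.0)
        assert degradation_slope(t, 3.0 * t + 50.0) == pytest.approx(3.0)

    def test_window_restriction(self):
        t = np.arange(0, 100.0)
        y = np.where(t < 50, 2.0 * t, 100.0)
        assert degradation_slope(t, y, window=(0, 49)) == pytest.approx(2.0)
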