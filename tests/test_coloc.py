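import numpy as np
import pandas as pd
import pytest

from lysoquant.coloc import coloc_pair, manders, pearson, triple_overlap
from lysoquant.errors import DomainError, NoSignalError
from lysoquant.io import Image2D
from lysoquant.puncta import PunctaSet
from lysoquant.simulate import SceneSpec, simulate_scene


def _brute_force_manders(a, b, mask, ta, tb):
    """Independent double-loop reference for the thresholded coefficients."""
    num1 = den1 = num2 = den2 = 0.0
    h, w = a.shape
    for i in range(h):
        for j in range(w):
            if not mask[i, j]:
                continue
            if a[i, j] > ta:
                den1 += a[i, j]
                if b[i, j] > tb:
                    num1 += a[i, j]
            if b[i, j] > tb:
                den2 += b[i, j]
                if a[i, j] > ta:
                    num2 += b[i, j]
    return num1 / den1, num2 / den2


def _brute_force_pearson(a, b, mask):
    va = [a[i, j] for i in range(a.shape[0]) for j in range(a.shape[1]) if mask[i, j]]
    vb = [b[i, j] for i in range(a.shape[0]) for j in range(a.shape[1]) if mask[i, j]]
    va, vb = np.array(va), np.array(vb)
    da, db = va - va.mean(), vb - vb.mean()
    return float(da @ db / np.sqrt((da @ da) * (db @ db)))


def _puncta_set(points):
    pts = np.asarray(points, float).reshape(-1, 2)
    return PunctaSet(
        pd.DataFrame(
            {"label": np.arange(1, len(pts) + 1), "x": pts[:, 0], "y": pts[:, 1],
             "area_px": 1, "intensity": 1.0}
        )
    )


class TestPearson:
    def test_affine_identity_gives_one(self, rng):
        a = Image2D(rng.uniform(0, 100, (16, 16)))
        b = Image2D(2 * a.pixels + 5)
        mask = np.ones((16, 16), bool)
        assert pearson(a, b, mask) == pytest.approx(1.0)
        c = Image2D(np.clip(-a.pixels + 200, 0, None))
        assert pearson(a, c, mask) == pytest.approx(-1.0)

    def test_four_pixel_hand_oracle(self):
        # textbook formula on a=(1,2,3,4), b=(1,2,3,5) evaluated by hand
        a = Image2D(np.array([[1.0, 2.0], [3.0, 4.0]]))
        b = Image2D(np.array([[1.0, 2.0], [3.0, 5.0]]))
        mask = np.ones((2, 2), bool)
        assert pearson(a, b, mask) == pytest.approx(0.9827076298239908, abs=1e-12)

    def test_zero_variance_rejected(self):
        a = Image2D(np.ones((4, 4)))
        b = Image2D(np.arange(16.0).reshape(4, 4))
        with pytest.raises(DomainError):
            pearson(a, b, np.ones((4, 4), bool))


class TestManders:
    def test_identical_binary_masks(self):
        img = np.zeros((10, 10))
        img[2:5, 2:5] = 50.0
        a, b = Image2D(img), Image2D(img.copy())
        m1, m2 = manders(a, b, np.ones((10, 10), bool), 0.0, 0.0)
        assert m1 == 1.0 and m2 == 1.0

    def test_disjoint_signal(self):
        a = np.zeros((10, 10))
        b = np.zeros((10, 10))
        a[1:3, 1:3] = 10.0
        b[6:8, 6:8] = 10.0
        m1, m2 = manders(Image2D(a), Image2D(b), np.ones((10, 10), bool), 0.0, 0.0)
        assert m1 == 0.0 and m2 == 0.0

    @pytest.mark.parametrize("seed", range(10))
    def test_brute_force_oracle_random_pairs(self, seed):
        g = np.random.default_rng(seed)
        a = g.uniform(0, 100, (16, 16))
        b = g.uniform(0, 100, (16, 16))
        mask = g.random((16, 16)) > 0.2
        ta, tb = g.uniform(10, 40, 2)
        m1, m2 = manders(Image2D(a), Image2D(b), mask, ta, tb)
        e1, e2 = _brute_force_manders(a, b, mask, ta, tb)
        assert m1 == pytest.approx(e1, abs=1e-12)
        assert m2 == pytest.approx(e2, abs=1e-12)
        r = pearson(Image2D(a), Image2D(b), mask)
        assert r == pytest.approx(_brute_force_pearson(a, b, mask), abs=1e-12)

    def test_symmetry(self, rng):
        a = Image2D(rng.uniform(0, 50, (12, 12)))
        b = Image2D(rng.uniform(0, 50, (12, 12)))
        mask = np.ones((12, 12), bool)
        m1, m2 = manders(a, b, mask, 5.0, 8.0)
        m2s, m1s = manders(b, a, mask, 8.0, 5.0)
        assert m1 == pytest.approx(m1s) and m2 == pytest.approx(m2s)

    def test_rescaling_channel_a_leaves_m1(self, rng):
        a = rng.uniform(0, 50, (12, 12))
        b = Image2D(rng.uniform(0, 50, (12, 12)))
        mask = np.ones((12, 12), bool)
        m1, _ = manders(Image2D(a), b, mask, 5.0, 8.0)
        m1s, _ = manders(Image2D(3 * a), b, mask, 15.0, 8.0)
        assert m1 == pytest.approx(m1s, abs=1e-12)

    def test_no_signal_error(self):
        a = Image2D(np.zeros((6, 6)))
        b = Image2D(np.ones((6, 6)))
        with pytest.raises(NoSignalError, match="channel A"):
            manders(a, b, np.ones((6, 6), bool), 0.0, 0.0)


class TestColocOnScenes:
    @pytest.mark.parametrize("rho", [0.0, 0.5, 1.0])
    def test_m1_tracks_generator_fraction(self, rho):
        spec = SceneSpec(
            shape=(512, 512), cell_radius=220, nucleus_radius=60,
            n_puncta={"A": 150, "B": 150}, coloc={("A", "B"): rho},
            background=0.0, noise_sd=0.0, min_separation=10, seed=17,
        )
        stack, geom, _ = simulate_scene(spec)
        res = coloc_pair(stack.channel("A"), stack.channel("B"), geom)
        assert res.manders_m1 == pytest.approx(rho, abs=0.05)


class TestTripleOverlap:
    def test_duplicated_partners_give_one(self):
        ref = _puncta_set([(5, 5), (10, 10), (20, 5)])
        assert triple_overlap(ref, _puncta_set(ref.centroids), _puncta_set(ref.centroids), 2.0) == 1.0

    def test_empty_partners_give_zero(self):
        ref = _puncta_set([(5, 5), (10, 10)])
        empty = _puncta_set(np.empty((0, 2)))
        assert triple_overlap(ref, empty, empty, 2.0) == 0.0

    def test_one_to_one_matching(self):
        # two reference puncta but a single shared partner: only one can match
        ref = _puncta_set([(0, 0), (1, 0)])
        partner = _puncta_set([(0.5, 0)])
        assert triple_overlap(ref, partner, _puncta_set(ref.centroids), 2.0) == 0.5

    def test_empty_reference_rejected(self):
        empty = _puncta_set(np.empty((0, 2)))
        with pytest.raises(DomainError):
            triple_overlap(empty, empty, empty, 2.0)

    def test_generator_fraction_recovered(self):
        spec = SceneSpec(
            shape=(512, 512), cell_radius=220, nucleus_radius=60,
            n_puncta={"lamp1": 200, "cx43": 200, "gal3": 200},
            triple=("lamp1", "cx43", "gal3", 0.25),
            noise_sd=0.0, min_separation=8, seed=23,
        )
        _, _, truth = simulate_scene(spec)
        sets = {
            ch: _puncta_set(truth.data.query("channel == @ch")[["x", "y"]].to_numpy())
            for ch in ("lamp1", "cx43", "gal3")
        }
        frac = triple_overlap(sets["lamp1"], sets["cx43"], sets["gal3"], 2.0)
        # 0.25 +/- 3 binomial standard errors at n = 200
        assert frac == pytest.approx(0.25, abs=3 * np.sqrt(0.25 * 0.75 / 200))
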