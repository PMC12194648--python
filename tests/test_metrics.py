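"""Contrast metrics: brute-force oracles, sampling behaviour, SSIM composite."""

import itertools

import numpy as np
import pytest
from skimage.color import rgb2lab

from occgray import (
    C2GSSIMParams,
    bt601,
    c2g_ssim,
    ccfr,
    ccpr,
    delta_e,
    e_score,
    sample_pairs,
)
from occgray.metrics import gray_lightness


def brute_force_ccpr_ccfr(image, gray, tau):
    """Independent double-loop reference over all unordered pixel pairs.

    Colour differences are CIE76 in Lab; gray differences are Lab L* of the
    achromatic gray — computed here directly from skimage, not through the
    package's sampling path.
    """
    pix = image.reshape(-1, 3)
    lab = rgb2lab(pix.reshape(-1, 1, 3)).reshape(-1, 3)
    g = gray.reshape(-1)
    glab = rgb2lab(np.stack([g, g, g], -1).reshape(-1, 1, 3)).reshape(-1, 3)[:, 0]
    n = len(pix)
    omega_total = omega_kept = theta_total = theta_bad = 0
    for i, j in itertools.combinations(range(n), 2):
        cdiff = np.sqrt(((lab[i] - lab[j]) ** 2).sum())
        gdiff = abs(glab[i] - glab[j])
        if cdiff >= tau:
            omega_total += 1
            if gdiff >= tau:
                omega_kept += 1
        if gdiff > tau:
            theta_total += 1
            if cdiff <= tau:
                theta_bad += 1
    p = omega_kept / omega_total if omega_total else 1.0
    f = 1.0 - theta_bad / theta_total if theta_total else 1.0
    return p, f


class TestDeltaE:
    def test_identical_zero(self):
        assert delta_e((0.3, 0.5, 0.7), (0.3, 0.5, 0.7)) == 0.0

    def test_black_white_spans_lightness(self):
        assert delta_e((0, 0, 0), (1, 1, 1)) == pytest.approx(100.0, abs=1e-5)

    def test_symmetric(self):
        c1, c2 = (0.2, 0.8, 0.1), (0.9, 0.1, 0.4)
        assert delta_e(c1, c2) == delta_e(c2, c1)


class TestSamplePairs:
    def test_requested_count(self, random_image):
        s = sample_pairs(random_image, n=80, tau=4, seed=1)
        assert s.n_pairs == 80
        assert not s.exhaustive
        # distinct unordered pairs
        assert len({tuple(p) for p in s.pairs}) == 80
        assert np.all(s.pairs[:, 0] < s.pairs[:, 1])

    def test_two_pixel_image_exhaustive(self):
        img = np.array([[[0.0, 0, 0], [1.0, 1, 1]]])
        s = sample_pairs(img, n=80, tau=4, seed=0)
        assert s.exhaustive and s.n_pairs == 1

    def test_seed_reproducibility(self, random_image):
        a = sample_pairs(random_image, n=40, tau=4, seed=9)
        b = sample_pairs(random_image, n=40, tau=4, seed=9)
        assert np.array_equal(a.pairs, b.pairs)
        c = sample_pairs(random_image, n=40, tau=4, seed=10)
        assert not np.array_equal(a.pairs, c.pairs)

    def test_omega_subset(self, random_image):
        s = sample_pairs(random_image, n=50, tau=10, seed=3)
        assert s.omega.shape == (50,)
        assert np.all(s.color_diff[s.omega] >= 10)


class TestOracleEquivalence:
    @pytest.mark.parametrize("tau", [4.0, 10.0, 20.0])
    def test_exhaustive_matches_double_loop(self, random_image, tau):
        gray = bt601(random_image)
        s = sample_pairs(random_image, tau=tau, seed=0, exhaustive=True)
        p_ref, f_ref = brute_force_ccpr_ccfr(random_image, gray, tau)
        assert ccpr(s, gray) == p_ref
        assert ccfr(s, gray) == f_ref

    def test_sampled_converges_to_exhaustive(self, random_image):
        gray = bt601(random_image)
        tau = 10.0
        exact = ccpr(sample_pairs(random_image, tau=tau, exhaustive=True), gray)
        vals = np.array([
            ccpr(sample_pairs(random_image, n=80, tau=tau, seed=s), gray)
            for s in range(200)
        ])
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - exact) < 3 * se + 1e-12


class TestCCPRCCFR:
    def test_full_preservation(self):
        img = np.array([[[0.0, 0, 0], [1.0, 1, 1]]])
        gray = np.array([[0.0, 1.0]])
        s = sample_pairs(img, tau=4, exhaustive=True)
        assert ccpr(s, gray) == 1.0

    def test_constant_gray_kills_ccpr(self, random_image):
        s = sample_pairs(random_image, tau=4, exhaustive=True)
        assert s.omega.any()
        assert ccpr(s, np.full(random_image.shape[:2], 0.5)) == 0.0

    def test_empty_omega_vacuous(self, caplog):
        img = np.full((2, 2, 3), 0.5)
        s = sample_pairs(img, tau=4, exhaustive=True)
        assert not s.omega.any()
        assert ccpr(s, np.zeros((2, 2)) + np.array([[0, 1], [0, 1]])) == 1.0

    def test_invented_contrast_zeroes_ccfr(self):
        # near-identical colours mapped to opposite gray extremes
        img = np.array([[[0.5, 0.5, 0.5], [0.505, 0.5, 0.5]]])
        gray = np.array([[0.0, 1.0]])
        s = sample_pairs(img, tau=4, exhaustive=True)
        assert s.color_diff[0] < 4
        assert ccfr(s, gray) == 0.0

    def test_empty_theta_vacuous(self, random_image):
        s = sample_pairs(random_image, tau=4, exhaustive=True)
        assert ccfr(s, np.full(random_image.shape[:2], 0.3)) == 1.0

    def test_ccfr_partial_violation(self):
        # 4 pixels: three mutually distant colours plus one near-twin;
        # engineered so exactly 1 of 4 gray-contrasting pairs is a violation
        img = np.array([[[0, 0, 0], [1, 1, 1], [1.0, 0, 0], [0.98, 0.0, 0.02]]],
                       dtype=float)
        gray = np.array([[0.0, 1.0, 0.5, 0.9]])
        tau = 10.0
        s = sample_pairs(img, tau=tau, exhaustive=True)
        gl = gray_lightness(gray.reshape(-1))
        gdiff = np.abs(gl[s.pairs[:, 0]] - gl[s.pairs[:, 1]])
        theta = gdiff > tau
        bad = int((s.color_diff[theta] <= tau).sum())
        assert ccfr(s, gray) == 1.0 - bad / int(theta.sum())
        assert bad >= 1  # the near-twin pair does get split

    def test_threshold_sweep_monotone_on_fixed_pairs(self, random_image):
        gray = bt601(random_image)
        s = sample_pairs(random_image, tau=4, exhaustive=True)
        vals = [ccpr(s, gray, tau_gray=t) for t in (4, 8, 12, 16, 20, 30)]
        assert all(b <= a for a, b in zip(vals, vals[1:]))

    def test_misaligned_shapes(self, random_image):
        s = sample_pairs(random_image, n=10, tau=4, seed=0)
        with pytest.raises(ValueError, match="shape"):
            ccpr(s, np.zeros((3, 3)))

    def test_byte_units(self, random_image):
        gray = bt601(random_image)
        s = sample_pairs(random_image, tau=30, exhaustive=True, units="byte")
        v = ccpr(s, gray)
        assert 0.0 <= v <= 1.0


class TestEScore:
    @pytest.mark.parametrize("p, f, expected", [
        (1.0, 1.0, 1.0),
        (0.8, 1.0, 8 / 9),
        (0.0, 0.9, 0.0),
        (0.0, 0.0, 0.0),
    ])
    def test_closed_form(self, p, f, expected):
        assert e_score(p, f) == pytest.approx(expected, abs=1e-12)

    def test_between_min_and_max(self):
        rng = np.random.default_rng(8)
        for p, f in rng.random((200, 2)):
            e = e_score(p, f)
            assert min(p, f) - 1e-12 <= e <= max(p, f) + 1e-12

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            e_score(1.2, 0.5)


class TestC2GSSIM:
    def test_identity_scores_one(self, random_image):
        from occgray.metrics import lightness
        ref = lightness(random_image) / 100.0
        p = C2GSSIMParams(window=5)
        assert c2g_ssim(random_image, ref, p) == pytest.approx(1.0, abs=1e-9)

    def test_zero_exponents_trivial_one(self, random_image):
        p = C2GSSIMParams(alpha=0, beta=0, gamma=0, window=5)
        assert c2g_ssim(random_image, np.zeros(random_image.shape[:2]), p) == 1.0

    def test_constant_gray_penalized_and_monotone_in_exponents(self):
        tile = np.zeros((16, 16, 3))
        tile[::2, ::2] = 1.0  # 2-level checkerboard-ish pattern
        flat = np.full((16, 16), 0.5)
        base = c2g_ssim(tile, flat, C2GSSIMParams(1, 1, 1, window=5))
        assert base < 1.0
        heavier = c2g_ssim(tile, flat, C2GSSIMParams(1, 2, 2, window=5))
        assert heavier < base

    def test_window_too_large(self, random_image):
        with pytest.raises(ValueError, match="window"):
            c2g_ssim(random_image, np.zeros(random_image.shape[:2]),
                     C2GSSIMParams(window=11))

    def test_bounded(self, random_image):
        g = bt601(random_image)
        v = c2g_ssim(random_image, g, C2GSSIMParams(window=5))
        assert 0.0 <= v <= 1.0
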