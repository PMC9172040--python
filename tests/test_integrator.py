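"""Sparse-matrix azimuthal integration against brute-force references."""

import numpy as np
import pytest

from azimint.calibration import GeometrySpec
from azimint.geometry import build_qmap
from azimint.integrator import (
    IntegratedCurve,
    RadialBinning,
    bin_areas,
    build_binning,
    build_weight_matrix,
    integrate_frame,
    poisson_errors,
    read_chi,
    write_chi,
)
from azimint.synthetic import default_geometry, make_flat_frame, oracle_integrate

from conftest import random_geometry

WL = 1.54


@pytest.fixture(scope="module")
def setup64():
    geom = default_geometry((64, 64))
    qmap = build_qmap(geom, WL)
    mask = np.zeros((64, 64), dtype=bool)
    binning = build_binning(qmap, mask, 1.0, geom)
    return geom, qmap, mask, binning


class TestBinning:
    def test_bin_count_follows_radial_step(self, setup64):
        geom, qmap, mask, b1 = setup64
        b2 = build_binning(qmap, mask, 2.0, geom)
        assert b1.n_bins == 2 * b2.n_bins or b1.n_bins == 2 * b2.n_bins + 1
        # r_max for a centered 64x64 beam is the half-diagonal ~ 45.25 px
        assert b1.n_bins == int(np.hypot(32, 32))

    def test_masked_radius_shrinks_binning(self, setup64):
        geom, qmap, _, b_full = setup64
        mask = np.ones((64, 64), dtype=bool)
        mask[24:40, 24:40] = False  # only a central block unmasked
        b = build_binning(qmap, mask, 1.0, geom)
        assert b.n_bins < b_full.n_bins
        assert b.q_edges[-1] < b_full.q_edges[-1]

    def test_degenerate_step_clamps_to_one_bin(self, setup64):
        geom, qmap, mask, _ = setup64
        b = build_binning(qmap, mask, 1e6, geom)
        assert b.n_bins == 1

    def test_fully_masked_rejected(self, setup64):
        geom, qmap, _, _ = setup64
        with pytest.raises(ValueError, match="masked"):
            build_binning(qmap, np.ones((64, 64), bool), 1.0, geom)

    def test_edges_bracket_centers(self, setup64):
        _, _, _, b = setup64
        assert np.all(b.q_centers > b.q_edges[:-1]) and np.all(b.q_centers < b.q_edges[1:])


class TestWeightMatrix:
    @pytest.mark.parametrize("k", [1, 2, 4, 8])
    def test_unmasked_columns_sum_to_one(self, setup64, k):
        geom, _, mask, binning = setup64
        W = build_weight_matrix(geom, WL, binning, mask, k)
        cs = W.column_sums()
        assert np.abs(cs - 1.0).max() < 1e-12

    def test_masked_columns_structurally_empty(self, setup64):
        geom, _, _, binning = setup64
        mask = np.zeros((64, 64), dtype=bool)
        mask[10, :] = True
        W = build_weight_matrix(geom, WL, binning, mask, 2)
        cols = W.C.tocsc()
        masked_flat = np.flatnonzero(mask.ravel())
        assert cols[:, masked_flat].nnz == 0

    def test_k1_is_binary_nearest_bin(self, setup64):
        geom, qmap, mask, binning = setup64
        W = build_weight_matrix(geom, WL, binning, mask, 1)
        assert np.all(W.C.data == 1.0)
        # each pixel lands in the bin containing its center q
        bins = np.searchsorted(binning.q_edges, qmap.q.ravel(), side="right") - 1
        bins = np.clip(bins, 0, binning.n_bins - 1)
        coo = W.C.tocoo()
        lut = dict(zip(coo.col, coo.row))
        assert all(lut[i] == bins[i] for i in range(0, 64 * 64, 97))

    def test_boundary_pixel_split_fractions(self):
        """k=8 on a pixel straddling a bin edge: weights match the brute-force
        count of its 64 subpixel assignments."""
        geom = default_geometry((16, 16))
        qmap = build_qmap(geom, WL)
        mask = np.zeros((16, 16), dtype=bool)
        binning = build_binning(qmap, mask, 1.0, geom)
        k = 8
        W = build_weight_matrix(geom, WL, binning, mask, k).C.tocsc()
        offsets = (np.arange(k) + 0.5) / k - 0.5
        checked_split = 0
        for (r, c) in [(0, 0), (3, 12), (10, 2), (15, 15), (5, 5)]:
            counts = {}
            for dv in offsets:
                for dh in offsets:
                    qs = build_qmap(geom, WL, np.array([r + dv]), np.array([c + dh])).q[0]
                    b = min(
                        max(int(np.searchsorted(binning.q_edges, qs, side="right")) - 1, 0),
                        binning.n_bins - 1,
                    )
                    counts[b] = counts.get(b, 0) + 1
            col = W[:, r * 16 + c].toarray().ravel()
            for b, n in counts.items():
                assert col[b] == pytest.approx(n / 64.0, abs=1e-12)
            if len(counts) > 1:
                checked_split += 1
                assert all(0 < col[b] < 1 for b in counts)
        assert checked_split >= 1  # at least one genuinely straddling pixel

    @pytest.mark.parametrize("k", [1, 4])
    def test_sparsity_bound(self, setup64, k):
        geom, _, mask, binning = setup64
        W = build_weight_matrix(geom, WL, binning, mask, k)
        n_unmasked = (~mask).sum()
        assert W.C.nnz <= k * k * n_unmasked
        if k == 1:
            assert W.C.nnz == n_unmasked


class TestAreas:
    def test_partition_of_unity(self, setup64):
        geom, _, mask, binning = setup64
        W = build_weight_matrix(geom, WL, binning, mask, 1)
        assert bin_areas(W).sum() == pytest.approx(64 * 64, rel=1e-12)

    def test_one_masked_pixel_drops_area_by_one(self, setup64):
        geom, _, _, binning = setup64
        mask = np.zeros((64, 64), dtype=bool)
        mask[30, 31] = True
        W = build_weight_matrix(geom, WL, binning, mask, 3)
        assert bin_areas(W).sum() == pytest.approx(64 * 64 - 1, rel=1e-12)

    def test_k1_areas_equal_bruteforce_counts(self, setup64):
        geom, qmap, mask, binning = setup64
        W = build_weight_matrix(geom, WL, binning, mask, 1)
        oracle = oracle_integrate(np.ones((64, 64)), qmap, binning, mask)
        emitted = bin_areas(W)[bin_areas(W) > 0]
        assert np.array_equal(emitted, oracle.A)


class TestIntegrate:
    @pytest.mark.parametrize("k", [1, 2, 8])
    def test_flat_field_constancy(self, setup64, k, rng):
        geom, _, _, binning = setup64
        mask = rng.random((64, 64)) < 0.1
        W = build_weight_matrix(geom, WL, binning, mask, k)
        curve = integrate_frame(make_flat_frame((64, 64), 7.5), W, binning)
        assert np.abs(curve.I - 7.5).max() < 7.5 * 1e-12

    def test_single_bin_arithmetic(self):
        geom = GeometrySpec((1.0, 1.0), 1000.0, (2, 2), (172.0, 172.0))
        qmap = build_qmap(geom, WL)
        mask = np.zeros((2, 2), bool)
        binning = build_binning(qmap, mask, 1e6, geom)
        W = build_weight_matrix(geom, WL, binning, mask, 1)
        curve = integrate_frame(np.full((2, 2), 5.0), W, binning)
        assert curve.n_points == 1
        assert curve.I[0] == 5.0 and curve.A[0] == 4.0

    def test_matches_per_pixel_loop_oracle(self, rng):
        """k=1 sparse path vs the naive per-pixel loop on random frames and
        random (tilted) calibrations."""
        for _ in range(5):
            geom = random_geometry(rng)
            qmap = build_qmap(geom, WL)
            mask = rng.random((64, 64)) < 0.1
            binning = build_binning(qmap, mask, float(rng.uniform(0.5, 3.0)), geom)
            W = build_weight_matrix(geom, WL, binning, mask, 1)
            frame = rng.poisson(40, (64, 64)).astype(float)
            got = integrate_frame(frame, W, binning)
            ref = oracle_integrate(frame, qmap, binning, mask)
            assert np.array_equal(got.q, ref.q)
            assert np.abs(got.I - ref.I).max() <= 1e-10 * np.abs(ref.I).max()

    @pytest.mark.parametrize("k", [1, 2, 4, 8])
    def test_intensity_conserved(self, setup64, k, rng):
        """sum_j A_j I_j equals the total counts of unmasked pixels."""
        geom, qmap, _, _ = setup64
        mask = rng.random((64, 64)) < 0.15
        binning = build_binning(qmap, mask, 1.0, geom)
        W = build_weight_matrix(geom, WL, binning, mask, k)
        frame = rng.poisson(25, (64, 64)).astype(float)
        curve = integrate_frame(frame, W, binning)
        total = frame[~mask].sum()
        assert np.abs((curve.A * curve.I).sum() - total) < 1e-9 * total

    def test_masked_pixels_opaque(self, setup64, rng):
        geom, _, _, binning = setup64
        mask = np.zeros((64, 64), bool)
        mask[5, 5] = mask[40, 22] = True
        W = build_weight_matrix(geom, WL, binning, mask, 2)
        frame = rng.poisson(30, (64, 64)).astype(float)
        a = integrate_frame(frame, W, binning)
        frame2 = frame.copy()
        frame2[5, 5] = 1e9
        frame2[40, 22] = -7
        b = integrate_frame(frame2, W, binning)
        assert np.array_equal(a.I, b.I) and np.array_equal(a.E, b.E)

    def test_negative_sentinels_excluded_per_frame(self, setup64):
        geom, _, mask, binning = setup64
        W = build_weight_matrix(geom, WL, binning, mask, 1)
        frame = np.full((64, 64), 9.0)
        frame[0, :] = -2.0  # detector gap marker row
        curve = integrate_frame(frame, W, binning)
        assert np.abs(curve.I - 9.0).max() < 1e-12  # still flat
        assert curve.A.sum() == pytest.approx(64 * 64 - 64)

    def test_shape_mismatch_rejected(self, setup64):
        geom, _, mask, binning = setup64
        W = build_weight_matrix(geom, WL, binning, mask, 1)
        with pytest.raises(ValueError, match="shape"):
            integrate_frame(np.zeros((32, 32)), W, binning)

    def test_oversampling_converges_to_analytic_profile(self):
        """For a frame whose value is a smooth function of q, the max error
        against the analytic profile near the beam center — where single
        pixels straddle bin borders and aliasing is worst — shrinks
        monotonically as k grows."""
        geom = default_geometry((128, 128))
        qmap = build_qmap(geom, WL)
        mask = np.zeros((128, 128), bool)
        profile = lambda q: 100.0 * (1.0 + np.cos(8.0 * q))
        frame = profile(qmap.q)
        binning = build_binning(qmap, mask, 2.0, geom)
        errs = []
        for k in (1, 2, 4, 8):
            W = build_weight_matrix(geom, WL, binning, mask, k)
            curve = integrate_frame(frame, W, binning)
            sel = curve.q < 0.3  # the low-q region the anti-aliasing targets
            errs.append(np.abs(curve.I[sel] - profile(curve.q[sel])).max())
        assert errs[3] < 0.7 * errs[0]
        assert all(b <= a for a, b in zip(errs, errs[1:]))  # monotone


class TestPoissonErrors:
    def test_formula(self):
        assert poisson_errors(np.array([5.0]), np.array([4.0]))[0] == pytest.approx(
            np.sqrt(1.25), rel=1e-12
        )

    def test_zero_intensity_zero_error(self):
        assert poisson_errors(np.array([0.0]), np.array([10.0]))[0] == 0.0

    def test_monte_carlo_calibration(self):
        """Empirical std of the bin mean over many Poisson frames matches
        E = sqrt(mu/A) (small MC here; the full check is in acceptance)."""
        rng = np.random.default_rng(42)
        mu, area, n = 9.0, 100, 2000
        means = rng.poisson(mu, size=(n, area)).mean(axis=1)
        predicted = np.sqrt(mu / area)
        assert means.std(ddof=1) == pytest.approx(predicted, rel=0.05)


class TestChiFile:
    def test_round_trip(self, tmp_path):
        curve = IntegratedCurve(
            q=np.array([0.1, 0.2, 0.3]), I=np.array([5.0, 4.0, 0.0]), E=np.array([0.5, 0.4, 0.0])
        )
        path = tmp_path / "c.chi"
        write_chi(curve, path)
        back = read_chi(path)
        assert back == curve
        assert back.n_points == 3

    def test_empty_curve_header_only(self, tmp_path):
        curve = IntegratedCurve(q=np.array([]), I=np.array([]), E=np.array([]))
        path = tmp_path / "empty.chi"
        write_chi(curve, path)
        lines = path.read_text().splitlines()
        assert all(line.startswith("#") for line in lines)
        assert read_chi(path).n_points == 0

    def test_q_strictly_increasing_in_file(self, tmp_path, setup64, rng):
        geom, _, mask, binning = setup64
        W = build_weight_matrix(geom, WL, binning, mask, 2)
        curve = integrate_frame(rng.poisson(20, (64, 64)).astype(float), W, binning)
        path = tmp_path / "run.chi"
        write_chi(curve, path)
        q = read_chi(path).q
        assert np.all(np.diff(q) > 0)
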