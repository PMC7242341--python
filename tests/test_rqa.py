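"""Recurrence analysis against brute-force oracles and hand-worked examples."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform

from eegrqa.rqa import (
    RecurrenceConfig, calibrate_radius, diagonal_line_lengths,
    embed_time_series, recurrence_matrix, rqa_from_signal, rqa_measures,
    vertical_line_lengths,
)

CHECKERBOARD = np.array(
    [[1, 0, 1, 0], [0, 1, 0, 1], [1, 0, 1, 0], [0, 1, 0, 1]], dtype=bool
)


# ---------------------------------------------------------------------------
# brute-force oracles (pure Python, independent of the implementation)
# ---------------------------------------------------------------------------

def brute_diag_lengths(R, theiler_w):
    n = len(R)
    lengths = []
    for off in range(-(n - 1), n):
        if abs(off) < theiler_w:
            continue
        cells = [R[i, i + off] for i in range(n) if 0 <= i + off < n]
        run = 0
        for c in cells + [0]:
            if c:
                run += 1
            elif run:
                lengths.append(run)
                run = 0
    return sorted(lengths)


def brute_vert_lengths(R):
    n = len(R)
    lengths = []
    for j in range(n):
        run = 0
        for c in list(R[:, j]) + [0]:
            if c:
                run += 1
            elif run:
                lengths.append(run)
                run = 0
    return sorted(lengths)


def brute_rqa(R, cfg):
    d = brute_diag_lengths(R, cfg.theiler_w)
    v = brute_vert_lengths(R)
    dq = [x for x in d if x >= cfg.lmin]
    vq = [x for x in v if x >= cfg.vmin]
    n = len(R)
    return {
        "Lmax": max(dq) if dq else 0.0,
        "Lmean": float(np.mean(dq)) if dq else np.nan,
        "TT": float(np.mean(vq)) if vq else np.nan,
        "DET": sum(dq) / sum(d) if sum(d) else np.nan,
        "LAM": sum(vq) / sum(v) if sum(v) else np.nan,
        "RR": (int(R.sum()) - int(np.trace(R))) / (n * (n - 1)),
    }


# ---------------------------------------------------------------------------
# embedding
# ---------------------------------------------------------------------------

class TestEmbedding:
    def test_identity_embedding(self):
        traj = embed_time_series([1, 2, 3, 4], m=1, tau=1)
        np.testing.assert_array_equal(traj, [[1], [2], [3], [4]])

    def test_pairs_embedding(self):
        traj = embed_time_series([1, 2, 3, 4], m=2, tau=1)
        np.testing.assert_array_equal(traj, [[1, 2], [2, 3], [3, 4]])

    def test_boundary_arithmetic(self):
        traj = embed_time_series(np.arange(10.0), m=3, tau=4)
        np.testing.assert_array_equal(traj, [[0, 4, 8], [1, 5, 9]])

    def test_too_short_reports_minimum(self):
        with pytest.raises(ValueError, match="at least 9"):
            embed_time_series(np.arange(8.0), m=3, tau=4)


# ---------------------------------------------------------------------------
# radius calibration
# ---------------------------------------------------------------------------

class TestCalibrateRadius:
    def test_two_point_geometry(self):
        traj = np.array([[0.0], [3.0]])
        assert calibrate_radius(traj, rr_target=0.5) == 3.0

    def test_realized_rate_within_band(self, rng):
        traj = rng.standard_normal((100, 1))
        eps = calibrate_radius(traj, rr_target=0.10)
        d = pdist(traj)
        realized = (d <= eps).mean()   # exhaustive pairwise oracle
        assert 0.09 <= realized <= 0.11

    def test_constant_trajectory_rejected(self):
        with pytest.raises(ValueError, match="zero-diameter"):
            calibrate_radius(np.ones((5, 2)))

    def test_rr_monotone_in_epsilon(self, rng):
        traj = rng.standard_normal((60, 3))
        eps_grid = np.linspace(0, 4, 25)
        rr = [(recurrence_matrix(traj, e).sum() - 60) / (60 * 59) for e in eps_grid]
        assert all(b >= a for a, b in zip(rr, rr[1:]))


# ---------------------------------------------------------------------------
# recurrence matrix
# ---------------------------------------------------------------------------

class TestRecurrenceMatrix:
    def test_diagonal_always_recurrent(self, rng):
        traj = rng.standard_normal((20, 3))
        R = recurrence_matrix(traj, 0.1)
        assert R.diagonal().all()

    def test_alternating_signal(self):
        traj = embed_time_series([0.0, 1.0, 0.0, 1.0], m=1, tau=1)
        R = recurrence_matrix(traj, 0.5)
        np.testing.assert_array_equal(R, CHECKERBOARD)

    def test_matches_double_loop(self, rng):
        traj = rng.standard_normal((8, 3))
        eps = 1.5
        R = recurrence_matrix(traj, eps)
        for i in range(8):
            for j in range(8):
                assert R[i, j] == (np.linalg.norm(traj[i] - traj[j]) <= eps)

    def test_row_permutation_conjugates_matrix(self, rng):
        traj = rng.standard_normal((15, 2))
        perm = rng.permutation(15)
        R = recurrence_matrix(traj, 1.0)
        R_perm = recurrence_matrix(traj[perm], 1.0)
        np.testing.assert_array_equal(R_perm, R[np.ix_(perm, perm)])


# ---------------------------------------------------------------------------
# line statistics
# ---------------------------------------------------------------------------

class TestLineLengths:
    def test_identity_has_no_off_loi_diagonals(self):
        assert diagonal_line_lengths(np.eye(10, dtype=bool), 1).size == 0

    def test_checkerboard_diagonals(self):
        assert sorted(diagonal_line_lengths(CHECKERBOARD, 1)) == [2, 2]

    def test_full_matrix_diagonal_census(self):
        lengths = sorted(diagonal_line_lengths(np.ones((10, 10), bool), 1))
        assert lengths == sorted(list(range(1, 10)) * 2)

    def test_full_matrix_verticals(self):
        assert list(vertical_line_lengths(np.ones((10, 10), bool))) == [10] * 10

    def test_identity_verticals(self):
        assert list(vertical_line_lengths(np.eye(10, dtype=bool))) == [1] * 10

    def test_random_matrix_matches_column_scan(self, rng):
        R = rng.random((12, 12)) < 0.4
        assert sorted(vertical_line_lengths(R)) == brute_vert_lengths(R)

    @pytest.mark.parametrize("theiler_w", [0, 1, 3])
    def test_random_matrix_matches_diag_scan(self, rng, theiler_w):
        R = rng.random((17, 17)) < 0.35
        assert sorted(diagonal_line_lengths(R, theiler_w)) == brute_diag_lengths(R, theiler_w)


class TestRqaMeasures:
    def test_full_matrix(self):
        res = rqa_measures(np.ones((16, 16), bool))
        assert res.Lmax == 15 and res.TT == 16

    def test_checkerboard(self):
        res = rqa_measures(CHECKERBOARD)
        assert res.Lmax == 2 and res.Lmean == 2

    def test_identity_matrix_undefined_measures(self):
        res = rqa_measures(np.eye(12, dtype=bool))
        assert res.Lmax == 0
        assert np.isnan(res.TT) and np.isnan(res.Lmean)

    def test_oracle_equivalence_on_random_matrices(self):
        """Exhaustive enumeration agrees exactly on 100 seeded matrices."""
        cfg = RecurrenceConfig()
        gen = np.random.default_rng(2024)
        for _ in range(100):
            n = int(gen.integers(4, 65))
            R = gen.random((n, n)) < gen.uniform(0.05, 0.6)
            R |= R.T
            np.fill_diagonal(R, True)
            res = rqa_measures(R, cfg)
            ref = brute_rqa(R, cfg)
            for key, want in ref.items():
                got = getattr(res, key)
                if np.isnan(want):
                    assert np.isnan(got), key
                else:
                    assert got == pytest.approx(want, abs=1e-12), key


class TestSignalLevelBehavior:
    def test_sine_more_deterministic_than_noise(self):
        """DET separates periodic from stochastic dynamics at matched RR."""
        cfg = RecurrenceConfig(max_points=None)
        gen = np.random.default_rng(11)
        t = np.arange(2000)
        for _ in range(5):
            sine = np.sin(2 * np.pi * t / 16 + gen.uniform(0, 2 * np.pi))
            noise = gen.standard_normal(2000)
            det_sine = rqa_from_signal(sine, cfg).DET
            det_noise = rqa_from_signal(noise, cfg).DET
            assert det_sine > 0.95
            assert det_sine > det_noise

    def test_analysis_window_caps_matrix_size(self, rng):
        x = rng.standard_normal(5000)
        cfg = RecurrenceConfig(max_points=200)
        res = rqa_from_signal(x, cfg)
        assert np.isfinite(res.RR)
        # RR realized near target despite windowing
        assert 0.08 <= res.RR <= 0.12

    def test_constant_signal_yields_nan(self):
        res = rqa_from_signal(np.ones(100), RecurrenceConfig())
        assert np.isnan(res.Lmax) and np.isnan(res.RR)
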