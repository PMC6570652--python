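import numpy as np
import pytest

from engramkit import repetition as rep
from engramkit.signals_io import TraceMatrix

FR = 20.0


def brute_force_overlap(mats: np.ndarray) -> np.ndarray:
    """Independent oracle: explicit double loop over ordered pairs i != j."""
    T, n, _ = mats.shape
    M = np.zeros((T, T))
    for a in range(T):
        for b in range(T):
            acc = 0.0
            for i in range(n):
                for j in range(n):
                    if i != j:
                        acc += mats[a, i, j] * mats[b, i, j]
            M[a, b] = acc / (n * (n - 1))
    return M


class TestSlidingCorrelations:
    def test_identical_traces_give_unit_correlation(self):
        rng = np.random.default_rng(0)
        row = rng.uniform(0, 1, 100)
        tm = TraceMatrix(np.vstack([row, row]))
        cw = rep.sliding_correlations(tm, FR)
        np.testing.assert_allclose(cw.matrices[:, 0, 1], 1.0, atol=1e-12)

    def test_constant_cell_zero_by_convention(self):
        rng = np.random.default_rng(1)
        tm = TraceMatrix(np.vstack([np.full(60, 3.0), rng.uniform(0, 1, 60)]))
        cw = rep.sliding_correlations(tm, FR)
        assert np.all(cw.matrices[:, 0, 1] == 0)
        assert np.all(cw.matrices[:, 0, 0] == 0)  # zero-variance diagonal
        assert np.all(cw.matrices[:, 1, 1] == 1)

    def test_matches_textbook_pearson(self):
        rng = np.random.default_rng(2)
        tm = TraceMatrix(rng.uniform(0, 1, (3, 20)))
        cw = rep.sliding_correlations(tm, FR, window_s=1.0, step_s=0.2)
        x, y = tm.values[0, :20], tm.values[1, :20]
        # direct formula, no library call
        mx, my = x.mean(), y.mean()
        r = ((x - mx) * (y - my)).sum() / np.sqrt(
            ((x - mx) ** 2).sum() * ((y - my) ** 2).sum()
        )
        assert abs(cw.matrices[0, 0, 1] - r) < 1e-12

    def test_window_midpoints(self):
        tm = TraceMatrix(np.random.default_rng(3).uniform(0, 1, (2, 40)))
        cw = rep.sliding_correlations(tm, FR)
        # first window frames 0..19, midpoint (0+19)/2/20 s
        assert abs(cw.midpoints[0] - 19 / 2 / FR) < 1e-12
        assert abs(cw.midpoints[1] - cw.midpoints[0] - 0.2) < 1e-12

    def test_too_short_trace(self):
        with pytest.raises(ValueError, match="short"):
            rep.sliding_correlations(TraceMatrix(np.zeros((2, 10))), FR)

    def test_symmetry_and_range(self):
        tm = TraceMatrix(np.random.default_rng(4).uniform(0, 1, (5, 60)))
        cw = rep.sliding_correlations(tm, FR)
        np.testing.assert_allclose(
            cw.matrices, cw.matrices.transpose(0, 2, 1), atol=1e-12
        )
        assert np.all(cw.matrices >= -1 - 1e-12) and np.all(cw.matrices <= 1 + 1e-12)


class TestOverlapMatrix:
    def _series(self, n, T, seed=0):
        tm = TraceMatrix(np.random.default_rng(seed).uniform(0, 1, (n, T)))
        return rep.sliding_correlations(tm, FR)

    def test_two_cell_closed_form(self):
        cw = self._series(2, 60)
        res = rep.overlap_matrix(cw)
        c12 = cw.matrices[:, 0, 1]
        np.testing.assert_allclose(res.M, np.outer(c12, c12), atol=1e-12)

    def test_equal_offdiagonals_give_c_squared(self):
        n = 4
        mats = np.zeros((2, n, n))
        c = 0.3
        for t in range(2):
            mats[t] = np.full((n, n), c)
            np.fill_diagonal(mats[t], 1.0)
        cw = rep.CorrelationWindowSeries(mats, np.array([0.0, 0.2]), 1.0, 0.2)
        res = rep.overlap_matrix(cw)
        np.testing.assert_allclose(res.M, c * c, atol=1e-12)

    def test_matches_brute_force(self):
        cw = self._series(4, 80, seed=5)
        res = rep.overlap_matrix(cw)
        np.testing.assert_allclose(res.M, brute_force_overlap(cw.matrices), atol=1e-12)

    def test_diagonal_nonnegative(self):
        res = rep.overlap_matrix(self._series(5, 100, seed=6))
        assert np.all(np.diag(res.M) >= 0)
        np.testing.assert_allclose(res.M, res.M.T, atol=1e-14)

    def test_permutation_invariance(self):
        tm = TraceMatrix(np.random.default_rng(7).uniform(0, 1, (5, 60)))
        perm = np.random.default_rng(8).permutation(5)
        r1 = rep.overlap_matrix(rep.sliding_correlations(tm, FR))
        r2 = rep.overlap_matrix(
            rep.sliding_correlations(TraceMatrix(tm.values[perm]), FR)
        )
        np.testing.assert_allclose(r1.M, r2.M, atol=1e-12)

    def test_span_restriction(self):
        cw = self._series(3, 200)
        full = rep.overlap_matrix(cw)
        restricted = rep.overlap_matrix(cw, span_s=3.0)
        assert restricted.M.shape[0] < full.M.shape[0]
        assert np.all(restricted.midpoints <= 3.0)

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            rep.overlap_matrix(self._series(1, 60))


class TestShuffleNull:
    def test_single_shuffle_deterministic(self):
        tm = TraceMatrix(np.random.default_rng(9).uniform(0, 1, (4, 100)))
        a = rep.overlap_shuffle_null(tm, FR, n_shuffles=1, seed=3, span_s=None)
        b = rep.overlap_shuffle_null(tm, FR, n_shuffles=1, seed=3, span_s=None)
        assert a.samples[0] == b.samples[0]

    def test_invalid_args(self):
        tm = TraceMatrix(np.random.default_rng(0).uniform(0, 1, (4, 100)))
        with pytest.raises(ValueError):
            rep.overlap_shuffle_null(tm, FR, n_shuffles=0)
        with pytest.raises(ValueError, match="scope"):
            rep.overlap_shuffle_null(tm, FR, n_shuffles=1, scope="bogus")

    def test_pure_noise_within_central_region(self):
        # original statistic should not be an outlier for structureless traces
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(100 + seed)
            tm = TraceMatrix(rng.uniform(0, 1, (6, 200)))
            null = rep.overlap_shuffle_null(
                tm, FR, n_shuffles=40, seed=seed, span_s=None
            )
            if 5.0 <= null.percentile <= 95.0:
                hits += 1
        assert hits >= 8

    def test_planted_structure_above_null(self, small_experiment):
        _, sset, _, _ = small_experiment
        eng = sset.group_traces("A", "engram")
        null = rep.overlap_shuffle_null(eng, FR, n_shuffles=100, seed=0, span_s=60.0)
        assert null.original > np.percentile(null.samples, 95)


class TestRepetitionReport:
    def test_identical_groups_ratio_one(self):
        from engramkit.signals_io import Cell, CellRegistry, Session, SessionSet

        rng = np.random.default_rng(11)
        block = rng.uniform(0, 1, (3, 100))
        vals = np.vstack([block, block])  # engram rows = copy of non-engram rows
        reg = CellRegistry(
            [Cell(f"c{i}", 0.0, 0.0, engram=(i < 3)) for i in range(6)]
        )
        sset = SessionSet(
            [Session("A", "awake", FR, TraceMatrix(vals))], reg
        )
        out = rep.repetition_report(sset, n_shuffles=5, seed=0, span_s=None)
        assert abs(out["ratio_engram_vs_nonengram"] - 1.0) < 1e-12

    def test_engram_ratio_exceeds_one_and_shuffle(self, small_experiment):
        _, sset, _, _ = small_experiment
        out = rep.repetition_report(sset, n_shuffles=50, seed=0, span_s=60.0)
        assert out["ratio_engram_vs_nonengram"] > 1.0
        assert (
            out["ratio_shuffled_vs_nonengram"] < out["ratio_engram_vs_nonengram"]
        )

    def test_small_group_rejected(self):
        from engramkit.signals_io import Cell, CellRegistry, Session, SessionSet

        reg = CellRegistry(
            [Cell(f"c{i}", 0.0, 0.0, engram=(i == 0)) for i in range(4)]
        )
        sset = SessionSet(
            [
                Session(
                    "A", "awake", FR,
                    TraceMatrix(np.random.default_rng(0).uniform(0, 1, (4, 60))),
                )
            ],
            reg,
        )
        with pytest.raises(ValueError, match="fewer than 2"):
            rep.repetition_report(sset, n_shuffles=1, span_s=None)
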