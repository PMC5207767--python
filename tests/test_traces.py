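"""Trace extraction, the penalized step counter and histogram aggregation."""

import numpy as np
import pandas as pd
import pytest

from cymage import simulate, spots, traces
from conftest import make_staircase


class TestExtractTrace:
    def test_constant_stack_gives_49v(self):
        stack = np.full((4, 32, 32), 3.0)
        aoi = spots.AOI(row=10, col=12)
        tr = traces.extract_trace(stack, aoi)
        assert tr.shape == (4,)
        assert (tr == 49 * 3.0).all()

    def test_rendered_spot_trace_matches_truth(self):
        spot = simulate.Spot(16.0, 16.0, 1, "Cy3", (6,), unit_intensity=900.0)
        field = simulate.SpotField([spot], 33, 33)
        cam = simulate.CameraModel(background_offset=0.0,
                                   background_gradient=(0, 0), read_noise_sd=0.0)
        movie = simulate.render_movie(field, cam, 10, noise=False)
        tr = traces.extract_trace(movie.expected, spots.AOI(row=16, col=16))
        assert tr[:6] == pytest.approx(900.0, rel=0.01)  # PSF mass in 7x7
        assert tr[6:] == pytest.approx(0.0, abs=1e-9)

    def test_local_background_correction_zeroes_offset(self):
        stack = np.full((3, 32, 32), 25.0)  # uniform residual offset
        tr = traces.extract_trace(stack, spots.AOI(row=15, col=15), local_background=True)
        assert tr == pytest.approx(0.0, abs=1e-9)

    def test_out_of_bounds_aoi_errors(self):
        with pytest.raises(ValueError):
            traces.extract_trace(np.zeros((2, 16, 16)), spots.AOI(row=1, col=8))


class TestNoiseEstimate:
    def test_gaussian_noise_scale_recovered(self, rng):
        x = rng.normal(0, 5.0, 4000)
        assert traces.estimate_noise_sd(x) == pytest.approx(5.0, rel=0.1)

    def test_insensitive_to_sparse_steps(self, rng):
        x = make_staircase([300], [100.0, 0.0], 600, noise_sd=2.0, rng=rng)
        assert traces.estimate_noise_sd(x) == pytest.approx(2.0, rel=0.15)


class TestCountBleachSteps:
    def test_noiseless_three_step_staircase_exact(self):
        x = make_staircase([10, 25, 40], [300.0, 200.0, 100.0, 0.0], 60)
        fit = traces.count_bleach_steps(x)
        assert fit.n_steps == 3
        assert fit.change_frames == [10, 25, 40]
        assert fit.accepted and fit.rejection_reason == traces.REASON_NONE
        assert fit.levels == pytest.approx([300.0, 200.0, 100.0, 0.0])

    def test_noiseless_staircases_up_to_six_steps(self, rng):
        for k in range(1, 7):
            T = 90
            cps = sorted(rng.choice(np.arange(1, T), size=k, replace=False).tolist())
            levels = [(k - j) * 120.0 for j in range(k + 1)]
            fit = traces.count_bleach_steps(make_staircase(cps, levels, T))
            assert fit.n_steps == k and fit.change_frames == cps

    def test_single_step_at_snr3_mostly_scored_one(self, rng):
        ok = 0
        n = 300
        for _ in range(n):
            b = int(rng.integers(5, 95))
            vals, _ = simulate.simulate_bleach_trace(1, 3.0, [b], 100, 1.0, rng)
            fit = traces.count_bleach_steps(vals)
            ok += fit.accepted and fit.n_steps == 1
        assert ok / n >= 0.90

    def test_rising_ramp_rejected_no_accepted_steps(self):
        fit = traces.count_bleach_steps(np.linspace(0, 50, 40))
        assert fit.n_steps == 0
        assert not fit.accepted and fit.rejection_reason == traces.REASON_UPWARD

    def test_flat_nonzero_trace_never_bleached(self, rng):
        x = 500.0 + rng.normal(0, 2.0, 50)
        fit = traces.count_bleach_steps(x)
        assert not fit.accepted
        assert fit.rejection_reason == traces.REASON_NEVER_BLEACHED

    def test_flat_zero_trace_accepted_no_steps(self, rng):
        fit = traces.count_bleach_steps(rng.normal(0, 2.0, 50))
        assert fit.accepted and fit.n_steps == 0

    def test_blinking_trace_rejected_as_upward(self):
        x = make_staircase([20, 30, 60], [200.0, 50.0, 200.0, 0.0], 80)
        fit = traces.count_bleach_steps(x)
        assert not fit.accepted and fit.rejection_reason == traces.REASON_UPWARD

    def test_matches_exhaustive_search_on_short_traces(self, rng):
        params = traces.StepFitParams()
        for _ in range(200):
            T = int(rng.integers(10, 31))
            k = int(rng.integers(0, 3))
            cps = sorted(rng.choice(np.arange(1, T), size=k, replace=False).tolist())
            heights = rng.uniform(3.0, 6.0, k)
            levels = list(np.concatenate([np.cumsum(heights[::-1])[::-1], [0.0]]))
            x = make_staircase(cps, levels, T, noise_sd=1.0, rng=rng)
            got = [int(v) for v in traces.fit_changepoints(x, 1.0, params)]
            want = [int(v) for v in traces.exhaustive_changepoints(x, 1.0, params, max_steps=4)]
            assert got == want

    def test_all_nan_errors(self):
        with pytest.raises(ValueError):
            traces.count_bleach_steps(np.full(10, np.nan))

    def test_short_trace_errors(self):
        with pytest.raises(ValueError):
            traces.count_bleach_steps(np.zeros(4))


def records(rows):
    return pd.DataFrame(rows, columns=["oocyte", "movie", "n_steps"])


class TestStepHistogram:
    def test_single_movie_counts_and_frequencies(self):
        h = traces.aggregate_step_histogram(
            records([(0, 0, 1), (0, 0, 1), (0, 0, 2)]), "encoded"
        )
        assert h.absolute_counts.tolist() == [2, 1]
        assert h.per_oocyte.loc[0].tolist() == pytest.approx([2 / 3, 1 / 3])
        assert h.n_traces == 3

    def test_per_oocyte_then_pooled(self):
        rows = [(0, 0, 1)] * 4 + [(0, 0, 2)] * 6 + [(1, 0, 1)] * 6 + [(1, 0, 2)] * 4
        h = traces.aggregate_step_histogram(records(rows))
        assert h.pooled_mean.tolist() == pytest.approx([0.5, 0.5])

    def test_histogram_conserves_accepted_traces(self, rng):
        rows = [
            (int(rng.integers(3)), int(rng.integers(2)), int(rng.integers(1, 6)))
            for _ in range(50)
        ]
        h = traces.aggregate_step_histogram(records(rows))
        assert h.absolute_counts.sum() == 50

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            traces.aggregate_step_histogram(records([]))


class TestCompareStepDistributions:
    def _hist(self, freq_per_oocyte):
        rows = []
        for oo, f1 in enumerate(freq_per_oocyte):
            n1 = int(round(f1 * 10))
            rows += [(oo, 0, 1)] * n1 + [(oo, 0, 2)] * (10 - n1)
        return traces.aggregate_step_histogram(records(rows), max_step=2)

    def test_identical_frequency_sets(self):
        a = self._hist([0.4, 0.6])
        b = self._hist([0.4, 0.6])
        out = traces.compare_step_distributions(a, b)
        assert (out["t"] == 0).all() and (out["p"] == 1).all()

    def test_swapping_groups_flips_sign(self):
        a = self._hist([0.2, 0.3, 0.4])
        b = self._hist([0.6, 0.7, 0.8])
        ab = traces.compare_step_distributions(a, b)
        ba = traces.compare_step_distributions(b, a)
        assert ab["t"].to_numpy() == pytest.approx(-ba["t"].to_numpy())
        assert ab["p"].to_numpy() == pytest.approx(ba["p"].to_numpy())

    def test_requires_two_oocytes(self):
        with pytest.raises(ValueError):
            traces.compare_step_distributions(self._hist([0.5]), self._hist([0.4, 0.6]))
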