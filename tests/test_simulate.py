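"""Synthetic movie generator: Poisson spot statistics, bleach-trace
construction, rendering conservation, and dataset reproducibility."""

import numpy as np
import pytest
from scipy import stats

from cymage import io as cio
from cymage import simulate as sim


def csr_spec(density_cy3=0.14, density_cy5=0.08, coloc=0.0, seed=0, **kw):
    return sim.ConditionSpec(
        condition="test",
        density_cy3=density_cy3,
        density_cy5=density_cy5,
        colocalized_fraction=coloc,
        fluor_count_distribution=(0.5, 0.3, 0.2),
        seed=seed,
        **kw,
    )


class TestSpotField:
    def test_zero_density_gives_empty_field(self):
        cy3, cy5, pairs = sim.simulate_spot_field(
            csr_spec(density_cy3=0.0, density_cy5=0.0), (64, 64)
        )
        assert cy3.spots == [] and cy5.spots == [] and pairs == []

    def test_spot_counts_follow_poisson_law(self):
        # 0.14 spots/um^2 over 1000 um^2 -> Poisson(140): check mean,
        # variance and a chi-square GOF on binned counts at alpha = 0.01
        area_px = 158  # 158^2 px * 0.04 um^2/px ~ 998.6 um^2
        lam = 0.14 * area_px * area_px * 0.04
        counts = []
        for seed in range(200):
            cy3, _, _ = sim.simulate_spot_field(
                csr_spec(seed=seed), (area_px, area_px)
            )
            counts.append(len(cy3.spots))
        counts = np.array(counts)
        assert counts.mean() == pytest.approx(lam, abs=3 * np.sqrt(lam / 200))
        assert counts.var(ddof=1) == pytest.approx(lam, rel=0.3)
        edges = stats.poisson.ppf([0.2, 0.4, 0.6, 0.8], lam)
        obs = np.histogram(counts, bins=[-np.inf, *edges, np.inf])[0]
        probs = np.diff([0, 0.2, 0.4, 0.6, 0.8, 1.0])
        exp_cdf = stats.poisson.cdf(edges, lam)
        probs = np.diff([0.0, *exp_cdf, 1.0])
        chi2 = ((obs - 200 * probs) ** 2 / (200 * probs)).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=4)

    def test_encoded_preset_parameters(self):
        spec = sim.encoded_preset()
        assert spec.density_cy3 == 0.14
        assert spec.density_cy5 == 0.08

    def test_mock_preset_single_step_dominated(self):
        spec = sim.mock_preset()
        assert spec.fluor_count_distribution[0] >= 0.8

    def test_colocalized_fraction_converges(self):
        f = 0.3
        n_pair = n_cy5 = 0
        for seed in range(30):
            _, cy5, pairs = sim.simulate_spot_field(
                csr_spec(coloc=f, seed=seed), (128, 128)
            )
            n_pair += len(pairs)
            n_cy5 += len(cy5.spots)
        se = np.sqrt(f * (1 - f) / n_cy5)
        assert n_pair / n_cy5 == pytest.approx(f, abs=3 * se)

    def test_pair_positions_differ_by_registration_offset(self):
        spec = csr_spec(coloc=1.0, seed=4, registration_offset=(1, 2))
        cy3, cy5, pairs = sim.simulate_spot_field(spec, (96, 96))
        assert pairs
        for i3, i5 in pairs:
            assert cy5.spots[i5].row == pytest.approx(cy3.spots[i3].row + 1)
            assert cy5.spots[i5].col == pytest.approx(cy3.spots[i3].col + 2)

    def test_fluorophore_counts_match_bleach_times(self):
        cy3, _, _ = sim.simulate_spot_field(csr_spec(seed=1), (64, 64))
        for s in cy3.spots:
            assert len(s.bleach_frames) == s.n_fluorophores >= 1
            assert list(s.bleach_frames) == sorted(s.bleach_frames)
            assert min(s.bleach_frames) >= 1

    def test_reproducible_from_seed(self):
        a = sim.simulate_spot_field(csr_spec(seed=9), (64, 64))
        b = sim.simulate_spot_field(csr_spec(seed=9), (64, 64))
        assert a[0].coordinates().tolist() == b[0].coordinates().tolist()
        assert a[2] == b[2]

    def test_zero_area_errors(self):
        with pytest.raises(ValueError):
            sim.simulate_spot_field(csr_spec(), (0, 64))

    def test_invalid_probability_vector_errors(self):
        with pytest.raises(ValueError):
            sim.ConditionSpec(
                condition="bad", density_cy3=0.1, density_cy5=0.1,
                colocalized_fraction=0.0, fluor_count_distribution=(0.5, 0.2),
            )


class TestBleachTrace:
    def test_no_fluorophores_is_flat_baseline(self):
        vals, steps = sim.simulate_bleach_trace(0, 100.0, [], 20)
        assert (vals == 0).all() and steps == []

    def test_single_fluorophore_single_step(self):
        vals, steps = sim.simulate_bleach_trace(1, 100.0, [7], 20, noise_sd=0.0)
        assert steps == [7]
        assert (vals[:7] == 100.0).all() and (vals[7:] == 0.0).all()

    def test_five_steps_reach_zero(self, rng):
        b = [3, 8, 12, 20, 30]
        vals, steps = sim.simulate_bleach_trace(5, 50.0, b, 40, noise_sd=1.0, rng=rng)
        assert steps == b
        assert vals[-8:].mean() == pytest.approx(0.0, abs=3 * 1.0 / np.sqrt(8))
        clean, _ = sim.simulate_bleach_trace(5, 50.0, b, 40)
        assert clean[0] == 250.0 and np.all(np.diff(clean) <= 0)

    def test_blinking_inserts_reversible_dips(self):
        rng = np.random.default_rng(3)
        vals, _ = sim.simulate_bleach_trace(
            2, 10.0, [90, 95], 80, rng=rng, blink_prob=0.2
        )
        assert (vals < 20.0 - 1e-9).any()  # transient dark excursions
        assert vals[0] == 20.0 or vals[1] == 20.0

    def test_negative_noise_errors(self):
        with pytest.raises(ValueError):
            sim.simulate_bleach_trace(1, 1.0, [2], 10, noise_sd=-1.0)


class TestRenderMovie:
    def test_empty_field_zero_noise_is_background_plane(self):
        field = sim.SpotField([], 32, 32)
        cam = sim.CameraModel(read_noise_sd=0.0)
        movie = sim.render_movie(field, cam, 3, noise=False)
        plane = cam.background_plane((32, 32))
        assert np.allclose(movie.expected[0], plane)
        assert np.array_equal(movie.frames[0], np.round(plane).astype(np.uint16))

    def test_gaussian_mass_conserved(self):
        spot = sim.Spot(16.0, 16.0, 3, "Cy3", (50, 60, 70), unit_intensity=500.0)
        field = sim.SpotField([spot], 33, 33)
        cam = sim.CameraModel(psf_sigma=2.0, background_offset=0.0,
                              background_gradient=(0.0, 0.0), read_noise_sd=0.0)
        movie = sim.render_movie(field, cam, 1, noise=False)
        assert movie.expected[0].sum() == pytest.approx(3 * 500.0, rel=0.01)

    def test_fixed_seed_bit_identical(self):
        spec = csr_spec(seed=5)
        field, _, _ = sim.simulate_spot_field(spec, (48, 48))
        cam = sim.CameraModel()
        a = sim.render_movie(field, cam, 5, rng=np.random.default_rng(11))
        b = sim.render_movie(field, cam, 5, rng=np.random.default_rng(11))
        assert np.array_equal(a.frames, b.frames)

    def test_live_fluorophores_decrease_over_time(self):
        spot = sim.Spot(10.0, 10.0, 2, "Cy3", (2, 4), unit_intensity=300.0)
        field = sim.SpotField([spot], 21, 21)
        cam = sim.CameraModel(background_offset=0.0, background_gradient=(0, 0),
                              read_noise_sd=0.0)
        movie = sim.render_movie(field, cam, 6, noise=False)
        sums = movie.expected.sum(axis=(1, 2))
        assert sums[0] == pytest.approx(600.0, rel=0.01)
        assert sums[3] == pytest.approx(300.0, rel=0.01)
        assert sums[5] == pytest.approx(0.0, abs=1e-6)

    def test_psf_wider_than_field_errors(self):
        field = sim.SpotField([], 8, 8)
        with pytest.raises(ValueError):
            sim.render_movie(field, sim.CameraModel(psf_sigma=10.0), 1)


class TestConditionDataset:
    def test_round_trip_and_determinism(self, tmp_path):
        spec = sim.encoded_preset(seed=21)
        cam = sim.CameraModel()
        p1 = sim.make_condition_dataset(spec, cam, (48, 48), 5, tmp_path / "a")
        p2 = sim.make_condition_dataset(spec, cam, (48, 48), 5, tmp_path / "b")
        s1 = cio.read_stack(p1["Cy3"], pixel_size=0.2)
        s2 = cio.read_stack(p2["Cy3"], pixel_size=0.2)
        assert np.array_equal(s1.frames, s2.frames)
        assert (p1["spots"].read_text() == p2["spots"].read_text())
        assert (p1["pairs"].read_text() == p2["pairs"].read_text())
        meta = cio.read_metadata(p1["metadata"])
        assert meta["spec"]["density_cy3"] == 0.14
        assert meta["spec"]["density_cy5"] == 0.08
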