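"""Positional information: prior uniformization, direct-method MI,
decoding maps, redundancy, and feature counts."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radialinfo.posinfo import (
    average_decoding_map,
    decode_joint,
    decode_single,
    distinct_features,
    fractional_redundancy,
    mutual_information,
    plugin_mi,
    uniformize_prior,
)
from radialinfo.preprocess import ProfileEnsemble, ensemble_stats
from radialinfo.profile_io import LineScan


def _scan_with_density(density, signal=None):
    n = len(density)
    pos = np.linspace(0.0, 100.0, n)
    channels = {"nuclear": np.asarray(density, float)}
    channels["psmad"] = np.asarray(signal if signal is not None else np.ones(n), float)
    return LineScan("s", "E12.5", "psd", pos, channels)


class TestUniformizePrior:
    def test_uniform_density_is_identity(self, rng):
        sig = rng.random(50)
        scan = _scan_with_density(np.ones(50), sig)
        warped = uniformize_prior(scan)
        np.testing.assert_allclose(warped.channel("psmad"), sig, atol=1e-9)

    def test_two_to_one_density_closed_form(self):
        # density 2 on the left half, 1 on the right: the left half carries
        # 2/3 of the nuclear mass, so it maps to the first 2/3 of the axis
        n = 600
        density = np.where(np.arange(n) < n // 2, 2.0, 1.0)
        signal = np.where(np.arange(n) < n // 2, 1.0, 0.0)
        warped = uniformize_prior(_scan_with_density(density, signal))
        boundary = np.flatnonzero(warped.channel("psmad") < 0.5)[0] / n
        assert boundary == pytest.approx(2.0 / 3.0, abs=0.01)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_warp_is_monotone_for_positive_density(self, seed):
        rng = np.random.default_rng(seed)
        density = rng.random(40) + 0.1
        scan = _scan_with_density(density, np.linspace(0, 1, 40))
        warped = uniformize_prior(scan)
        # a monotone signal stays monotone under a monotone reparameterization
        assert np.all(np.diff(warped.channel("psmad")) >= -1e-12)

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            uniformize_prior(_scan_with_density(np.zeros(20)))


class TestMutualInformation:
    def test_noiseless_staircase_is_exactly_three_bits(self):
        g = np.repeat(np.arange(8) / 7.0, 8)
        ens = ProfileEnsemble(np.linspace(0, 1, 64), np.vstack([g] * 3), "t")
        est = mutual_information(ens, n_bins_g=8, n_bins_x=8, extrapolate=False)
        assert est.value == pytest.approx(3.0, abs=1e-12)

    def test_independence_limit_near_zero(self):
        rng = np.random.default_rng(0)
        samples = 0.5 + rng.normal(0, 0.1, size=(1000, 50))
        ens = ProfileEnsemble(np.linspace(0, 1, 50), samples, "t")
        assert mutual_information(ens, seed=0).value <= 0.05

    def test_matches_bruteforce_histogram_oracle(self, rng):
        data = rng.random((6, 40))
        value = plugin_mi([data], 4, 4)
        xbin = np.floor(np.arange(40) * 4 / 40).astype(int)
        edges = np.linspace(data.min(), data.max(), 5)
        gbin = np.clip(np.searchsorted(edges, data, side="right") - 1, 0, 3)
        joint = np.zeros((4, 4))
        for s in range(6):
            for k in range(40):
                joint[xbin[k], gbin[s, k]] += 1
        joint /= joint.sum()
        px, pg = joint.sum(1), joint.sum(0)
        hand = sum(joint[i, j] * np.log2(joint[i, j] / (px[i] * pg[j]))
                   for i in range(4) for j in range(4) if joint[i, j] > 0)
        assert value == pytest.approx(hand, abs=1e-12)

    def test_invariant_under_affine_rescaling(self, rng):
        data = rng.random((8, 60))
        ens = ProfileEnsemble(np.linspace(0, 1, 60), data, "t")
        scaled = ProfileEnsemble(np.linspace(0, 1, 60), 3.7 * data - 1.2, "t")
        a = mutual_information(ens, seed=0)
        b = mutual_information(scaled, seed=0)
        assert a.value == pytest.approx(b.value, abs=1e-9)

    def test_decreases_monotonically_with_noise(self):
        rng = np.random.default_rng(3)
        x = np.linspace(0, 1, 60)
        values = []
        for sigma in (0.03, 0.06, 0.12, 0.24):
            samples = x + rng.normal(0, sigma, size=(200, 60))
            ens = ProfileEnsemble(x, samples, "t")
            values.append(mutual_information(ens, extrapolate=False).value)
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_joint_at_least_max_individual(self, rng):
        x = np.linspace(0, 1, 60)
        a = ProfileEnsemble(x, x + rng.normal(0, 0.08, (12, 60)), "a")
        b = ProfileEnsemble(x, np.sin(3 * x) + rng.normal(0, 0.1, (12, 60)), "b")
        stats = ensemble_stats({"a": a, "b": b})
        joint = mutual_information(stats, n_bins_g=16, seed=0).value
        singles = [mutual_information(e, n_bins_g=16, seed=0).value for e in (a, b)]
        assert joint >= max(singles) - 0.05

    def test_bounded_by_position_entropy(self, rng):
        data = rng.random((10, 80))
        ens = ProfileEnsemble(np.linspace(0, 1, 80), data, "t")
        est = mutual_information(ens, n_bins_g=8, n_bins_x=8, extrapolate=False)
        assert 0.0 <= est.value <= 3.0

    def test_undersampling_warns(self, rng):
        ens = ProfileEnsemble(np.linspace(0, 1, 10), rng.random((2, 10)), "t")
        with pytest.warns(RuntimeWarning, match="undersampled"):
            mutual_information(ens, n_bins_g=64, n_bins_x=10, extrapolate=False)


def _mono_ensemble(rng, n=8, nx=60, sigma=0.01):
    x = np.linspace(0, 1, nx)
    samples = np.vstack([x + rng.normal(0, sigma, nx) for _ in range(n)])
    return ProfileEnsemble(x, samples, "psmad")


class TestDecoding:
    def test_rows_integrate_to_one(self, rng):
        ens = _mono_ensemble(rng, sigma=0.05)
        dm = decode_single(ens, ens.samples[0])
        np.testing.assert_allclose(dm.row_integrals(), 1.0, atol=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_rows_normalize_for_random_ensembles(self, seed):
        rng = np.random.default_rng(seed)
        x = np.linspace(0, 1, 30)
        ens = ProfileEnsemble(x, rng.random((5, 30)), "g")
        dm = decode_single(ens, ens.samples[0])
        np.testing.assert_allclose(dm.row_integrals(), 1.0, atol=1e-6)

    def test_monotone_noiseless_mean_decodes_on_diagonal(self):
        x = np.linspace(0, 1, 60)
        ens = ProfileEnsemble(x, np.vstack([x] * 3), "psmad")  # sigma floored
        dm = decode_single(ens, ens.mean)
        np.testing.assert_allclose(dm.mode_positions(), ens.x, atol=1e-9)

    def test_constant_mean_gives_uniform_rows(self):
        x = np.linspace(0, 1, 40)
        samples = np.vstack([np.full(40, 0.5 + 0.1 * s) for s in (-1, 0, 1)])
        ens = ProfileEnsemble(x, samples, "g")
        dm = decode_single(ens, np.full(40, 0.5))
        # every row equals the (uniform) prior: perfectly flat density
        assert np.ptp(dm.density) < 1e-9
        np.testing.assert_allclose(dm.row_integrals(), 1.0, atol=1e-9)

    def test_three_position_toy_matches_direct_formula(self):
        x = np.array([0.0, 0.5, 1.0])
        mean, sd = np.array([0.0, 0.5, 1.0]), 0.1
        samples = np.vstack([mean - sd, mean + sd])  # population SD exactly 0.1
        ens = ProfileEnsemble(x, samples, "g")
        dm = decode_single(ens, np.full(3, 0.5))
        var = sd**2 * (1 + 1e-6)  # implementation's ridge regularization
        lik = np.exp(-0.5 * (0.5 - mean) ** 2 / var) / np.sqrt(var)
        expected = lik / (lik.sum() * 0.5)
        np.testing.assert_allclose(dm.density[0], expected, rtol=1e-6)
        assert dm.density[0][1] > 100 * dm.density[0][0]

    def test_k1_joint_reduces_to_single(self, rng):
        ens = _mono_ensemble(rng, sigma=0.05)
        stats = ensemble_stats({"psmad": ens})
        dj = decode_joint(stats, ens.samples[0][None, :])
        ds = decode_single(ens, ens.samples[0])
        np.testing.assert_allclose(dj.density, ds.density, atol=1e-12)

    def test_duplicated_channel_matches_single(self, rng):
        ens = _mono_ensemble(rng, sigma=0.05)
        dup = ProfileEnsemble(ens.x, ens.samples.copy(), "copy")
        stats = ensemble_stats({"psmad": ens, "copy": dup})
        dj = decode_joint(stats, np.vstack([ens.samples[0], ens.samples[0]]))
        ds = decode_single(ens, ens.samples[0])
        # ridge-regularized duplicate carries no extra information: modes agree
        # up to jitter in near-flat posterior rows
        assert np.abs(dj.mode_positions() - ds.mode_positions()).max() < 0.1
        assert np.median(np.abs(dj.mode_positions() - ds.mode_positions())) < 0.02

    def test_disjoint_halves_joint_resolves_ambiguity(self):
        rng = np.random.default_rng(5)
        nx = 60
        x = np.linspace(0, 1, nx)
        left = np.where(x < 0.5, 2 * x, 1.0)    # informative medially only
        right = np.where(x >= 0.5, 2 * x - 1, 0.0)  # informative laterally only
        mk = lambda base: np.vstack([base + rng.normal(0, 0.04, nx) for _ in range(10)])
        a = ProfileEnsemble(x, mk(left), "a")
        b = ProfileEnsemble(x, mk(right), "b")
        stats = ensemble_stats({"a": a, "b": b})
        dj = decode_joint(stats, np.vstack([left, right]))
        assert np.abs(dj.mode_positions() - x).max() < 0.08
        # the single-channel map is ambiguous on its flat half
        ds = decode_single(a, left)
        flat = x >= 0.6
        assert np.abs(ds.mode_positions()[flat] - x[flat]).max() > 0.2

    def test_sample_averaged_map_normalized(self, rng):
        ens = _mono_ensemble(rng, sigma=0.05)
        dm = average_decoding_map(ens)
        np.testing.assert_allclose(dm.row_integrals(), 1.0, atol=1e-6)


class TestRedundancyAndFeatures:
    def test_full_redundancy(self):
        assert fractional_redundancy([1.7, 1.7], 1.7) == pytest.approx(1.0)

    def test_independent_channels(self):
        assert fractional_redundancy([1.0, 2.0], 3.0) == pytest.approx(0.0)

    def test_measured_stage_bit_counts(self):
        # individual 2.23 and 1.44 bits vs 3.05 joint -> ~20% overlap
        assert fractional_redundancy([2.23, 1.44], 3.05) == pytest.approx(0.203, abs=5e-4)

    def test_zero_joint_rejected(self):
        with pytest.raises(ZeroDivisionError):
            fractional_redundancy([1.0], 0.0)

    @pytest.mark.parametrize("bits,raw,count", [
        (3.05, 8.28, 8), (3.17, 9.00, 9), (0.0, 1.0, 1),
    ])
    def test_distinct_feature_counts(self, bits, raw, count):
        value, rounded = distinct_features(bits)
        assert value == pytest.approx(raw, abs=5e-3)
        assert rounded == count
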