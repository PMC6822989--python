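import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.metrics import calinski_harabasz_score

from striaseq.config import AnalysisConfig
from striaseq.psth import PeriEventMatrix
from striaseq.response_typing import (
    ClusterResult,
    amplitude_normalize,
    band_powers,
    cluster,
    cutoff_sensitivity_sweep,
    fourier_features,
    level1_feature_matrix,
    phase_features,
    recovery_accuracy,
    separability_permutation_test,
)


def brute_force_ch(x, labels):
    """CH index from its definition: between/within dispersion ratio."""
    x = np.asarray(x, float)
    n, k = len(x), len(np.unique(labels))
    grand = x.mean(axis=0)
    b = w = 0.0
    for lab in np.unique(labels):
        grp = x[labels == lab]
        c = grp.mean(axis=0)
        b += len(grp) * np.sum((c - grand) ** 2)
        w += np.sum((grp - c) ** 2)
    return (b / (k - 1)) / (w / (n - k))


class TestBandPowers:
    N, FS = 357, 100.0

    def test_constant_vector_power_is_all_low_band(self):
        low, mid = band_powers(np.full(self.N, 3.0), self.FS)
        assert low > 0
        assert mid / low < 1e-2  # taper leakage only

    def test_half_hertz_sinusoid_is_low_band(self):
        t = np.arange(self.N) / self.FS
        low, mid = band_powers(np.sin(2 * np.pi * 0.5 * t), self.FS)
        assert low > 50 * mid

    def test_two_hertz_sinusoid_is_mid_band(self):
        from scipy.signal.windows import dpss

        t = np.arange(self.N) / self.FS
        x = np.sin(2 * np.pi * 2.0 * t)
        low, mid = band_powers(x, self.FS)
        tapers = dpss(self.N, NW=2, Kmax=3)
        spec = np.mean(
            [np.abs(np.fft.rfft(x * tp)) ** 2 / np.sum(tp**2) * self.N
             for tp in tapers],
            axis=0,
        )
        freqs = np.fft.rfftfreq(self.N, d=1 / self.FS)
        assert mid >= 0.95 * spec[freqs > 0].sum()

    def test_periodogram_path_satisfies_parseval(self, rng):
        x = rng.normal(size=self.N)
        low, mid = band_powers(x, self.FS, n_tapers=0)
        spec = np.abs(np.fft.rfft(x)) ** 2
        freqs = np.fft.rfftfreq(self.N, d=1 / self.FS)
        rest = spec[freqs >= 4.0].sum()
        # one-sided band sums recombine to n * sum(x^2) (odd n: no Nyquist)
        total = 2 * (low + mid + rest) - spec[0]
        assert total == pytest.approx(self.N * np.sum(x**2), rel=1e-9)

    def test_wrong_length_vector_rejected(self):
        pem = PeriEventMatrix("u", "DLS", np.zeros((1, 7, 51)), np.zeros((7, 51)),
                              0.0, 1.0, np.zeros((7, 50)))
        with pytest.raises(ValueError, match="expected 357"):
            fourier_features(pem)


class TestCluster:
    def _blobs(self, rng, centers, n=60, sd=1.0):
        pts = np.concatenate(
            [rng.normal(c, sd, size=(n, len(c))) for c in centers]
        )
        truth = np.repeat(np.arange(len(centers)), n)
        return pts, truth

    def test_two_separated_blobs_select_k2_with_full_recovery(self, rng):
        x, truth = self._blobs(rng, [(0, 0), (10, 10)])
        res = cluster(x, range(1, 11), AnalysisConfig(), rng=rng, n_perm=60)
        assert res.selected_k == 2
        agreement = max(
            np.mean((res.labels == lab) == (truth == 0))
            for lab in np.unique(res.labels)
        )
        assert agreement == 1.0

    def test_three_separated_blobs_select_k3(self, rng):
        x, _ = self._blobs(rng, [(0, 0), (12, 0), (0, 12)])
        res = cluster(x, range(1, 11), AnalysisConfig(), rng=rng, n_perm=60)
        assert res.selected_k == 3

    def test_single_gaussian_usually_declares_one_cluster(self):
        # the separability p is ~uniform on unstructured data, so K = 1
        # should be declared in roughly 1 - alpha of independent draws
        declared = []
        for seed in range(6):
            local = np.random.default_rng(seed)
            x = local.normal(size=(120, 2))
            res = cluster(x, range(1, 11), AnalysisConfig(), rng=local, n_perm=60)
            declared.append(res.selected_k == 1)
            if res.selected_k == 1:
                assert (res.labels == 1).all()
        assert sum(declared) >= 4

    def test_ch_matches_brute_force_on_small_instances(self, rng):
        for _ in range(10):
            x = rng.normal(size=(rng.integers(8, 30), 3))
            k = int(rng.integers(2, 5))
            labels = rng.integers(0, k, len(x))
            if len(np.unique(labels)) < 2:
                continue
            assert calinski_harabasz_score(x, labels) == pytest.approx(
                brute_force_ch(x, labels), rel=1e-12
            )

    def test_clustering_is_permutation_equivariant(self, rng):
        from sklearn.metrics import adjusted_rand_score

        x, _ = self._blobs(rng, [(0, 0), (8, 8)], n=25)
        perm = rng.permutation(len(x))
        a = cluster(x, range(2, 6), AnalysisConfig(), rng=rng, n_perm=20)
        b = cluster(x[perm], range(2, 6), AnalysisConfig(), rng=rng, n_perm=20)
        assert a.selected_k == b.selected_k
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="no evaluable K"):
            cluster(np.zeros((2, 2)), [5])


class TestSeparabilityPermutationTest:
    def test_separated_blobs_hit_the_p_floor(self, rng):
        x = np.concatenate(
            [rng.normal(0, 1, (50, 2)), rng.normal(12, 1, (50, 2))]
        )
        res = cluster(x, range(2, 6), AnalysisConfig(), rng=rng)
        p = separability_permutation_test(x, res, n_perm=100, rng=rng)
        assert p == pytest.approx(1 / 101)

    def test_zero_permutations_rejected(self, rng):
        res = ClusterResult(np.ones(4, int), {2: 1.0}, 2)
        with pytest.raises(ValueError, match="positive"):
            separability_permutation_test(np.zeros((4, 2)), res, n_perm=0)


class TestAmplitudeNormalize:
    def _pem(self, rates, f_mean):
        rates = np.asarray(rates, float).reshape(7, 51)
        return PeriEventMatrix("u", "DLS", rates[None], rates, f_mean, 1.0,
                               rates - f_mean)

    def test_baseline_everywhere_is_an_error(self):
        with pytest.raises(ValueError, match="flat"):
            amplitude_normalize(self._pem(np.full(357, 4.0), 4.0))

    def test_peak_normalizes_to_one(self):
        rates = np.full(357, 5.0)
        rates[100] = 10.0
        out = amplitude_normalize(self._pem(rates, 5.0))
        assert out.max() == pytest.approx(1.0)
        assert np.abs(out).max() <= 1.0

    def test_not_idempotent(self):
        # re-normalizing the normalized trace against its own recomputed
        # mean re-centers it, so the operation is not idempotent
        rates = np.full(357, 5.0)
        rates[10], rates[200] = 9.0, 3.0
        once = amplitude_normalize(self._pem(rates, 5.0))
        twice = amplitude_normalize(self._pem(once, float(once.mean())))
        assert not np.allclose(once, twice)


class TestPhaseFeatures:
    def test_zero_vector_gives_zero_features(self):
        assert np.allclose(phase_features(np.zeros(357)), 0.0)

    def test_windows_pick_up_their_events(self):
        v = np.zeros((7, 51))
        v[0, 26:51] = 1.0  # initiation: post-insertion bins
        init, execution, term = phase_features(v.reshape(-1))
        assert init == pytest.approx(1.0) and term == 0.0
        v = np.zeros((7, 51))
        v[6, 0:25] = -1.0  # termination: pre-port-entry bins
        init, execution, term = phase_features(v.reshape(-1))
        assert term == pytest.approx(-1.0) and init == 0.0
        v = np.zeros((7, 51))
        v[1:6, 13:38] = 0.5  # execution: around each press
        init, execution, term = phase_features(v.reshape(-1))
        assert execution == pytest.approx(0.5)


class TestTaxonomy:
    def test_phase_features_separate_archetypes(self, taxonomy_cohort, config):
        _, pems = taxonomy_cohort
        by_arch = {}
        for pem in pems:
            f = phase_features(amplitude_normalize(pem), config)
            by_arch.setdefault(pem.archetype, []).append(f)
        means = {a: np.mean(v, axis=0) for a, v in by_arch.items()}
        assert means["phasic_start"][0] > means["phasic_start"][2]
        assert means["phasic_stop"][2] > means["phasic_stop"][0]
        assert means["sustained_inh"][1] < 0 < means["sustained_exc"][1]

    def test_level1_recovery_on_midsize_cohort(self, taxonomy_cohort, config, rng):
        from striaseq.response_typing import classify_taxonomy

        _, pems = taxonomy_cohort
        tax = classify_taxonomy(pems, config, rng=rng, n_perm=50)
        assert recovery_accuracy(tax.table, "level1") >= 0.9

    def test_cutoff_sweep_default_cell_reproduces_default(
        self, taxonomy_cohort, config
    ):
        _, pems = taxonomy_cohort
        out = cutoff_sensitivity_sweep(pems, [1.0], [4.0], config, n_perm=30)
        assert len(out) == 1
        assert bool(out["matches_default"].iloc[0])

    def test_cutoff_sweep_degenerate_grid_rejected(self, taxonomy_cohort, config):
        _, pems = taxonomy_cohort
        with pytest.raises(ValueError, match="degenerate"):
            cutoff_sensitivity_sweep(pems, [4.0], [1.0], config)
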