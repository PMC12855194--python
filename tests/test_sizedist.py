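"""Size-distribution statistics: CSV I/O, mixture EM, overlap index, clustering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.cluster.hierarchy import linkage
from scipy.stats import norm

from phenoswitch import (
    DegenerateDataError,
    MixtureSpec,
    NotConvergedError,
    ParticleCSVError,
    ParticleSample,
    ValidationError,
    OverlapMatrix,
    bimodality_decision,
    classify_particles,
    cluster_overlap,
    fit_two_component_mixture,
    generate_mixture_sample,
    overlap_index,
    overlap_matrix,
    posterior_small,
    read_particle_csv,
    write_particle_csv,
)
from phenoswitch.sizedist import MixtureFit


def _sample(diameters, **kw):
    kw.setdefault("sample_id", "s")
    kw.setdefault("time_h", 24.0)
    return ParticleSample(diameters=np.asarray(diameters, dtype=float), **kw)


class TestParticleCSV:
    def test_two_row_file_one_sample(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("sample_id,time_h,diameter_um\nA,24,5.5\nA,24,14.25\n")
        samples = read_particle_csv(path)
        assert len(samples) == 1
        assert samples[0].sample_id == "A"
        assert samples[0].time_h == 24.0
        assert np.array_equal(samples[0].diameters, [5.5, 14.25])

    def test_negative_diameter_names_row(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("sample_id,time_h,diameter_um\nA,24,5.5\nA,24,-1\n")
        with pytest.raises(ParticleCSVError, match="row 3"):
            read_particle_csv(path)

    def test_non_numeric_diameter_names_row(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("sample_id,time_h,diameter_um\nA,24,abc\n")
        with pytest.raises(ParticleCSVError, match="row 2"):
            read_particle_csv(path)

    def test_missing_column_raises(self, tmp_path):
        path = tmp_path / "p.csv"
        path.write_text("sample_id,diameter_um\nA,5.5\n")
        with pytest.raises(ParticleCSVError, match="time_h"):
            read_particle_csv(path)

    def test_round_trip_is_bitwise(self, tmp_path, separated_spec):
        original = generate_mixture_sample(
            separated_spec, 500, seed=4, sample_id="rt", time_h=20.0
        )
        path = tmp_path / "rt.csv"
        write_particle_csv([original], path)
        (loaded,) = read_particle_csv(path)
        assert np.array_equal(loaded.diameters, original.diameters)
        assert loaded.sample_id == original.sample_id
        assert loaded.time_h == original.time_h


class TestMixtureEM:
    def test_recovers_separated_mixture(self, separated_spec):
        s = generate_mixture_sample(separated_spec, 10_000, seed=0)
        fit = fit_two_component_mixture(s)
        assert fit.converged
        assert abs(fit.mean_small - 5.0) < 0.2
        assert abs(fit.mean_large - 25.0) < 0.2
        assert abs(fit.weight_small - 0.5) < 0.02
        assert abs(fit.weight_small + fit.weight_large - 1.0) < 1e-9
        assert fit.mean_small <= fit.mean_large

    def test_identical_values_are_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_two_component_mixture(_sample(np.full(50, 7.0)))

    def test_too_few_points_is_degenerate(self):
        with pytest.raises(DegenerateDataError):
            fit_two_component_mixture(_sample([1.0, 2.0, 3.0]))

    def test_final_loglik_matches_direct_evaluation(self, rng):
        """Reported LL equals a brute-force mixture log-density sum at the fit."""
        x = np.concatenate([rng.normal(5, 1, 25), rng.normal(25, 5, 25)])
        fit = fit_two_component_mixture(_sample(x))
        direct = np.log(
            fit.weight_small * norm.pdf(x, fit.mean_small, fit.sd_small)
            + fit.weight_large * norm.pdf(x, fit.mean_large, fit.sd_large)
        ).sum()
        assert abs(fit.log_likelihood_2comp - direct) < 1e-8

    def test_loglik_non_decreasing_every_iteration(self, rng):
        """EM monotonicity over 20 random bimodal/unimodal datasets."""
        for _ in range(20):
            mu2 = rng.uniform(8, 40)
            x = np.concatenate(
                [
                    rng.normal(5, rng.uniform(0.5, 2), rng.integers(30, 200)),
                    rng.normal(mu2, rng.uniform(1, 6), rng.integers(30, 200)),
                ]
            )
            fit = fit_two_component_mixture(_sample(np.abs(x) + 0.1))
            assert np.all(np.diff(fit.log_likelihood_trace) >= -1e-9)

    def test_agrees_with_sklearn_on_separated_data(self, separated_spec):
        """Independent EM (scikit-learn) reaches the same maximum likelihood."""
        GaussianMixture = pytest.importorskip("sklearn.mixture").GaussianMixture
        s = generate_mixture_sample(separated_spec, 5_000, seed=1)
        fit = fit_two_component_mixture(s)
        gm = GaussianMixture(n_components=2, n_init=5, tol=1e-8, max_iter=500,
                             random_state=0).fit(s.diameters[:, None])
        sk_ll = gm.score(s.diameters[:, None]) * len(s)
        assert abs(fit.log_likelihood_2comp - sk_ll) < 1e-3 * abs(sk_ll)
        sk_means = np.sort(gm.means_.ravel())
        assert np.allclose([fit.mean_small, fit.mean_large], sk_means, atol=0.05)


class TestBimodalityDecision:
    def test_single_gaussian_is_unimodal(self, rng):
        x = rng.normal(10, 2, 5_000)
        fit = fit_two_component_mixture(_sample(x))
        assert bimodality_decision(fit) == "unimodal"

    def test_separated_mixture_is_bimodal(self, separated_spec):
        s = generate_mixture_sample(separated_spec, 5_000, seed=2)
        fit = fit_two_component_mixture(s)
        assert bimodality_decision(fit) == "bimodal"

    def test_delta_bic_exactly_at_threshold_is_unimodal(self):
        fit = MixtureFit(
            weight_small=0.5, weight_large=0.5, mean_small=5, mean_large=25,
            sd_small=1, sd_large=5, log_likelihood_2comp=-100.0,
            log_likelihood_1comp=-105.0, bic_2comp=210.0, bic_1comp=220.0,
            n_iterations=10, converged=True,
        )
        assert fit.bic_1comp - fit.bic_2comp == 10.0
        assert bimodality_decision(fit, delta_bic_threshold=10.0) == "unimodal"

    def test_refuses_non_converged_fit(self):
        fit = MixtureFit(
            weight_small=0.5, weight_large=0.5, mean_small=5, mean_large=25,
            sd_small=1, sd_large=5, log_likelihood_2comp=-100.0,
            log_likelihood_1comp=-105.0, bic_2comp=210.0, bic_1comp=260.0,
            n_iterations=500, converged=False,
        )
        with pytest.raises(NotConvergedError):
            bimodality_decision(fit)


class TestOverlapIndex:
    def test_self_overlap_is_near_one(self, rng):
        x = rng.normal(10, 2, 500)
        assert overlap_index(x, x) >= 0.99

    def test_disjoint_supports_are_near_zero(self, rng):
        a = rng.normal(5, 1, 500)
        b = rng.normal(500, 1, 500)
        assert overlap_index(a, b) <= 0.01

    def test_matches_closed_form_normal_overlap(self, rng):
        """eta(N(0,1), N(2,1)) -> 2*Phi(-1), the minimum-density overlap."""
        a = rng.normal(0, 1, 5_000)
        b = rng.normal(2, 1, 5_000)
        assert abs(overlap_index(a, b) - 2 * norm.cdf(-1)) < 0.03

    def test_degenerate_sample_raises(self):
        with pytest.raises(DegenerateDataError):
            overlap_index(np.full(10, 3.0), np.arange(1, 11, dtype=float))

    @given(
        loc=st.floats(1.0, 50.0),
        scale=st.floats(0.5, 5.0),
        seed=st.integers(0, 2**20),
    )
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bounded_and_symmetric(self, loc, scale, seed):
        r = np.random.default_rng(seed)
        a = r.normal(loc, scale, 100)
        b = r.normal(loc + r.uniform(0, 10), scale, 100)
        e1 = overlap_index(a, b)
        e2 = overlap_index(b, a)
        assert 0.0 <= e1 <= 1.0
        assert e1 == pytest.approx(e2, abs=1e-12)


class TestOverlapMatrix:
    def test_identical_samples_give_ones(self, rng):
        x = rng.normal(10, 2, 500)
        a = _sample(x, sample_id="a")
        b = _sample(x, sample_id="b")
        mat = overlap_matrix([a, b])
        assert np.all(mat.eta >= 0.99)
        assert np.array_equal(np.diag(mat.eta), [1.0, 1.0])

    def test_symmetry_is_exact(self, rng):
        samples = [_sample(rng.normal(5 + 5 * i, 1 + i, 300), sample_id=f"s{i}")
                   for i in range(3)]
        mat = overlap_matrix(samples)
        assert np.array_equal(mat.eta, mat.eta.T)

    def test_entries_equal_independent_pairwise_calls(self, rng):
        samples = [_sample(rng.normal(5 + 8 * i, 1.5, 300), sample_id=f"s{i}")
                   for i in range(3)]
        mat = overlap_matrix(samples)
        for i in range(3):
            for j in range(i + 1, 3):
                assert mat.eta[i, j] == overlap_index(samples[i], samples[j])

    def test_needs_two_samples(self, rng):
        with pytest.raises(ValidationError):
            overlap_matrix([_sample(rng.normal(5, 1, 50))])


class TestClusterOverlap:
    @staticmethod
    def _matrix(eta, labels=None):
        eta = np.asarray(eta, dtype=float)
        return OverlapMatrix(labels=labels or [f"s{i}" for i in range(len(eta))], eta=eta)

    def test_nearest_pair_merges_first(self):
        mat = self._matrix(
            [[1.0, 0.95, 0.10], [0.95, 1.0, 0.12], [0.10, 0.12, 1.0]]
        )
        tree = cluster_overlap(mat)
        first = set(tree.linkage_matrix[0, :2].astype(int))
        assert first == {0, 1}

    def test_three_item_heights_match_ward_d2_enumeration(self):
        """Merge heights reproduce a hand-rolled Ward-D2 (Lance-Williams) run."""
        eta = np.array([[1.0, 0.9, 0.3], [0.9, 1.0, 0.4], [0.3, 0.4, 1.0]])
        mat = self._matrix(eta)
        tree = cluster_overlap(mat)

        d = np.array([[np.linalg.norm(eta[i] - eta[j]) for j in range(3)] for i in range(3)])
        pairs = [(0, 1), (0, 2), (1, 2)]
        i, j = min(pairs, key=lambda p: d[p])
        (k,) = set(range(3)) - {i, j}
        h1 = d[i, j]
        h2 = np.sqrt((2 * d[i, k] ** 2 + 2 * d[j, k] ** 2 - d[i, j] ** 2) / 3)
        assert np.allclose(tree.heights, [h1, h2])

    def test_permutation_invariance(self, rng):
        samples = [_sample(rng.normal(5 + 4 * i, 1 + 0.2 * i, 200), sample_id=f"s{i}")
                   for i in range(4)]
        mat = overlap_matrix(samples)
        perm = [2, 0, 3, 1]
        mat_p = OverlapMatrix(
            labels=[mat.labels[i] for i in perm],
            eta=mat.eta[np.ix_(perm, perm)],
        )
        t1 = cluster_overlap(mat)
        t2 = cluster_overlap(mat_p)
        assert np.allclose(np.sort(t1.heights), np.sort(t2.heights))

    def test_fewer_than_three_items_raises(self):
        mat = self._matrix([[1.0, 0.5], [0.5, 1.0]])
        with pytest.raises(ValidationError):
            cluster_overlap(mat)

    def test_heights_non_decreasing(self, rng):
        samples = [_sample(rng.normal(5 + 3 * i, 1, 200), sample_id=f"s{i}")
                   for i in range(5)]
        tree = cluster_overlap(overlap_matrix(samples))
        assert np.all(np.diff(tree.heights) >= -1e-12)


class TestClassifyParticles:
    def test_counts_and_fraction(self):
        counts = classify_particles(_sample([5.0, 14.0]), threshold=13.0)
        assert (counts.count_small, counts.count_large) == (1, 1)
        assert counts.fraction_small == 0.5

    def test_threshold_boundary_is_small(self):
        counts = classify_particles(_sample([13.0]), threshold=13.0)
        assert counts.count_small == 1

    def test_all_below_threshold(self):
        counts = classify_particles(_sample([3.0, 5.0, 12.9]))
        assert counts.fraction_small == 1.0

    def test_empty_sample_raises(self):
        with pytest.raises(DegenerateDataError):
            classify_particles(_sample([]))

    def test_posterior_and_threshold_classification_agree(self):
        """With mixture mass cleanly split at 13 um the two rules coincide."""
        spec = MixtureSpec(weight_small=0.5, mean_small=6.0, sd_small=1.5,
                           mean_large=25.0, sd_large=3.0, detection_threshold=3.0)
        s = generate_mixture_sample(spec, 10_000, seed=6)
        fit = fit_two_component_mixture(s)
        by_posterior = posterior_small(fit, s.diameters) > 0.5
        by_threshold = s.diameters <= 13.0
        agreement = np.mean(by_posterior == by_threshold)
        assert agreement >= 0.99
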