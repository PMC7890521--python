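"""RDMs, percentile summarisation, correspondence, partial correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from salrsa.rsa import (RDM, DegenerateDataError, RDMTransform,
                        UndefinedResult, channel_histogram, compute_rdm,
                        correspondence, partial_correlation,
                        partial_correlation_profile,
                        per_channel_correspondence, percentile_transform,
                        profile_over_models, upper_triangle)


def pearson_oracle(u, v):
    """Pearson correlation from first principles (covariance / variances)."""
    uc, vc = u - u.mean(), v - v.mean()
    return float((uc * vc).sum() / np.sqrt((uc ** 2).sum() * (vc ** 2).sum()))


class TestComputeRdm:
    def test_identical_patterns_zero(self):
        X = np.array([[1.0, 2, 3], [1, 2, 3], [0, 5, 1]])
        rdm = compute_rdm(X)
        assert rdm.matrix[0, 1] == 0.0

    def test_anticorrelated_patterns_two(self):
        X = np.array([[1.0, 0, -1], [-1, 0, 1]])
        rdm = compute_rdm(X)
        assert rdm.matrix[0, 1] == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_entries_match_first_principles_pearson(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((6, 5))
        rdm = compute_rdm(X)
        for i in range(6):
            for j in range(i + 1, 6):
                assert rdm.matrix[i, j] == pytest.approx(
                    1 - pearson_oracle(X[i], X[j]), abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_symmetry_zero_diagonal(self, seed):
        rng = np.random.default_rng(100 + seed)
        rdm = compute_rdm(rng.uniform(0, 50, size=(12, 9)))
        m = rdm.matrix
        assert m.min() >= 0 and m.max() <= 2
        np.testing.assert_array_equal(m, m.T)
        np.testing.assert_array_equal(np.diag(m), 0.0)

    def test_unit_permutation_invariance(self, rng):
        X = rng.standard_normal((8, 20))
        a = compute_rdm(X).matrix
        b = compute_rdm(X[:, rng.permutation(20)]).matrix
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_pattern_raises_with_id(self):
        X = np.vstack([np.arange(4.0), np.full(4, 3.0), np.arange(4.0) ** 2])
        with pytest.raises(DegenerateDataError, match=r"\[1\]"):
            compute_rdm(X)

    def test_constant_pattern_dropped_on_request(self):
        X = np.vstack([np.arange(4.0), np.full(4, 3.0), np.arange(4.0) ** 2])
        rdm = compute_rdm(X, drop_degenerate=True)
        assert rdm.n == 2
        assert np.isfinite(rdm.matrix).all()

    def test_single_unit_rejected(self):
        with pytest.raises(ValueError, match="units"):
            compute_rdm(np.arange(6.0).reshape(6, 1))


class TestPercentile:
    def test_64_stimulus_rdm_has_2016_ranked_pairs(self, rng):
        rdm = compute_rdm(rng.standard_normal((64, 30)))
        assert rdm.n_pairs == 2016
        pct = percentile_transform(rdm)
        vals = np.sort(upper_triangle(pct.matrix))
        np.testing.assert_allclose(vals, np.arange(1, 2017) / 2016)

    def test_extremes_of_rank_scale(self, rng):
        rdm = compute_rdm(rng.standard_normal((64, 30)))
        pct = percentile_transform(rdm)
        tri_raw = upper_triangle(rdm.matrix)
        tri_pct = upper_triangle(pct.matrix)
        assert tri_pct[np.argmax(tri_raw)] == 1.0
        assert tri_pct[np.argmin(tri_raw)] == pytest.approx(1 / 2016)

    def test_ties_get_average_rank(self):
        m = np.zeros((4, 4))
        vals = [5.0, 2.0, 5.0, 1.0, 3.0, 4.0]  # two tied maxima
        iu = np.triu_indices(4, k=1)
        m[iu] = vals
        m = m + m.T
        pct = percentile_transform(RDM(m * 0.3))  # scaled into [0, 2]
        tri = upper_triangle(pct.matrix)
        # both 5.0s share the average of ranks 5 and 6
        assert tri[0] == tri[2] == pytest.approx(5.5 / 6)

    def test_preserves_symmetry_and_diagonal(self, rng):
        pct = percentile_transform(compute_rdm(rng.standard_normal((10, 8))))
        np.testing.assert_array_equal(pct.matrix, pct.matrix.T)
        np.testing.assert_array_equal(np.diag(pct.matrix), 0.0)


class TestCorrespondence:
    def test_self_correlation_is_one(self, rng):
        rdm = compute_rdm(rng.standard_normal((10, 6)))
        assert correspondence(rdm, rdm) == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_percentile_pearson_equals_raw_spearman(self, seed):
        """On tie-free data, Pearson over percentile forms is exactly the
        Spearman rank correlation of the raw dissimilarities."""
        rng = np.random.default_rng(seed)
        a = compute_rdm(rng.standard_normal((12, 15)))
        b = compute_rdm(rng.standard_normal((12, 15)))
        got = correspondence(percentile_transform(a), percentile_transform(b))
        want = stats.spearmanr(upper_triangle(a.matrix),
                               upper_triangle(b.matrix)).statistic
        assert got == pytest.approx(want, abs=1e-10)

    def test_mismatched_forms_rejected(self, rng):
        a = compute_rdm(rng.standard_normal((6, 5)))
        with pytest.raises(ValueError, match="form"):
            correspondence(a, percentile_transform(a))

    def test_zero_variance_flagged(self):
        flat = RDM(np.ones((4, 4)) - np.eye(4))
        with pytest.raises(DegenerateDataError):
            correspondence(flat, flat)


class TestPartialCorrelation:
    def test_uncorrelated_confound_reduces_to_plain_r(self):
        assert partial_correlation(0.62, 0.0, 0.0) == pytest.approx(0.62)

    def test_vanishing_numerator(self):
        assert partial_correlation(0.3 * 0.4, 0.3, 0.4) == pytest.approx(0.0)

    def test_degenerate_denominator_flagged_not_raised(self):
        res = partial_correlation(0.5, 1.0, 0.2)
        assert isinstance(res, UndefinedResult)
        assert np.isnan(float(res))

    def test_out_of_range_input_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation(1.2, 0.0, 0.0)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_residualize_and_correlate_oracle(self, seed):
        """Partial r from the formula equals correlating the least-squares
        residuals of l and x after regressing out y."""
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((400, 3)) @ rng.standard_normal((3, 3))
        l, x, y = z[:, 0], z[:, 1], z[:, 2]
        r = np.corrcoef(z.T)
        got = partial_correlation(r[0, 1], r[1, 2], r[0, 2])
        res_l = l - np.polyval(np.polyfit(y, l, 1), y)
        res_x = x - np.polyval(np.polyfit(y, x, 1), y)
        want = np.corrcoef(res_l, res_x)[0, 1]
        assert got == pytest.approx(want, abs=1e-10)

    def test_profile_emits_all_six_ordered_pairs(self, rng):
        areas = {a: percentile_transform(
            compute_rdm(rng.standard_normal((8, 10))))
            for a in ("V1", "V4", "IT")}
        layers = {f"layer{i}": percentile_transform(
            compute_rdm(rng.standard_normal((8, 10)))) for i in (1, 2)}
        prof = partial_correlation_profile(layers, areas)
        assert len(prof) == 12
        assert set(zip(prof["area"], prof["removed_area"])) == {
            (x, y) for x in areas for y in areas if x != y}
        assert prof["defined"].all()
        # audit columns agree with the formula
        row = prof.iloc[0]
        want = (row.r_lx - row.r_xy * row.r_ly) / np.sqrt(
            (1 - row.r_xy ** 2) * (1 - row.r_ly ** 2))
        assert row.r_partial == pytest.approx(want)


class TestPerChannel:
    def test_planted_channel_recovers_population_rdm(self, rng):
        """A channel whose activations copy a planted population's patterns
        correlates ~1 with that population's RDM."""
        patterns = rng.standard_normal((10, 36))
        pop_rdm = percentile_transform(compute_rdm(patterns))
        acts = rng.standard_normal((10, 6, 6, 3))
        acts[:, :, :, 1] = patterns.reshape(10, 6, 6)
        out = per_channel_correspondence(acts, pop_rdm)
        assert out.loc[1, "r"] == pytest.approx(1.0)
        assert not out["excluded"].any()

    def test_constant_channel_excluded_and_tallied(self, rng):
        acts = rng.standard_normal((8, 4, 4, 2))
        acts[:, :, :, 0] = 0.0  # silenced channel
        pop_rdm = percentile_transform(
            compute_rdm(rng.standard_normal((8, 12))))
        out = per_channel_correspondence(acts, pop_rdm)
        assert bool(out.loc[0, "excluded"])
        assert np.isnan(out.loc[0, "r"])
        assert not out.loc[1, "excluded"]

    def test_histogram_normalized_to_total_channels(self, rng):
        acts = rng.standard_normal((8, 4, 4, 5))
        acts[:, :, :, 2] = 0.0
        pop_rdm = percentile_transform(
            compute_rdm(rng.standard_normal((8, 12))))
        out = per_channel_correspondence(acts, pop_rdm)
        frac, edges = channel_histogram(out)
        assert frac.sum() == pytest.approx(4 / 5)


class TestProfileOverModels:
    def _table(self, rng, r=None):
        layers = ["layer1", "layer1_relu", "layer2"]
        areas = ["V1", "V4"]
        rows = [{"layer": l, "area": a,
                 "r": rng.uniform(-1, 1) if r is None else r}
                for l in layers for a in areas]
        return pd.DataFrame(rows)

    def test_single_replicate_sem_zero_with_warning(self, rng):
        with pytest.warns(UserWarning, match="single replicate"):
            prof = profile_over_models([self._table(rng)])
        assert (prof["sem"] == 0).all()

    def test_identical_replicates_sem_zero(self, rng):
        t = self._table(rng)
        prof = profile_over_models([t.copy(), t.copy(), t.copy()])
        np.testing.assert_allclose(prof["sem"], 0.0)
        np.testing.assert_allclose(prof["mean_r"], t["r"])

    def test_sem_tracks_sampling_distribution(self):
        """SEM over 10 replicates with known per-layer noise lands within
        30% of sigma/sqrt(10) on average over 20 trials."""
        sigma = 0.07
        base = np.random.default_rng(1)
        errs = []
        for _ in range(20):
            tables = []
            for _ in range(10):
                t = self._table(np.random.default_rng(0), r=0.0)
                t["r"] = base.normal(0.4, sigma, size=len(t))
                tables.append(t)
            prof = profile_over_models(tables)
            errs.append(prof["sem"].mean())
        assert abs(np.mean(errs) - sigma / np.sqrt(10)) < 0.3 * sigma / np.sqrt(10)

    def test_mismatched_layer_sets_rejected(self, rng):
        a = self._table(rng)
        b = self._table(rng).iloc[::-1].reset_index(drop=True)
        with pytest.raises(ValueError, match="different"):
            profile_over_models([a, b])


def test_rdm_transform_estimator(rng):
    X = rng.standard_normal((10, 8))
    raw = RDMTransform(form="raw").fit_transform(X)
    np.testing.assert_allclose(raw, compute_rdm(X).matrix)
    pct = RDMTransform(form="percentile").fit_transform(X)
    np.testing.assert_allclose(
        pct, percentile_transform(compute_rdm(X)).matrix)
    with pytest.raises(ValueError):
        RDMTransform(form="banana").fit(X)
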