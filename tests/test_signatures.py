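"""Two-pass NNLS decomposition, profile-likelihood CIs, cutoffs, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

import scarsig as ss
from scarsig.signatures import lrt_threshold, profile_likelihood_ci, two_pass_decompose


class TestNNLS:
    def test_exact_single_signature(self, W10):
        w = W10.iloc[:, [0]]
        h, e = ss.nnls_fit(100 * w.iloc[:, 0].to_numpy(), w.to_numpy())
        assert h[0] == pytest.approx(100, abs=1e-9)
        assert np.linalg.norm(e) < 1e-9

    def test_matches_grid_search_oracle(self):
        # exhaustive grid over (h1, h2) at step 0.01 as independent optimum
        W = np.array([[0.7, 0.2], [0.2, 0.5], [0.1, 0.3]])
        v = np.array([3.1, 2.0, 1.2])
        grid = np.arange(0, 8.0, 0.01)
        best, best_err = None, np.inf
        for h1, h2 in itertools.product(grid, grid):
            err = np.linalg.norm(v - W @ [h1, h2])
            if err < best_err:
                best, best_err = (h1, h2), err
        h, _ = ss.nnls_fit(v, W)
        assert abs(h[0] - best[0]) <= 0.02 and abs(h[1] - best[1]) <= 0.02

    def test_zero_catalog_gives_zero_exposures(self, W10):
        h, e = ss.nnls_fit(np.zeros(96), W10.to_numpy())
        assert (h == 0).all()

    def test_dimension_mismatch_is_error(self, W10):
        with pytest.raises(ValueError):
            ss.nnls_fit(np.ones(95), W10.to_numpy())

    def test_local_optimality_of_retained_exposures(self, W10, zero_cutoffs):
        rng = np.random.default_rng(0)
        mix = W10.to_numpy() @ rng.uniform(0, 100, 10)
        v = rng.poisson(mix).astype(float)
        fit = two_pass_decompose(v, W10, zero_cutoffs)
        base = np.linalg.norm(v - W10.to_numpy() @ fit.absolute)
        for i in np.flatnonzero(fit.absolute > 1):
            for eps in (0.99, 1.01):
                h = fit.absolute.copy()
                h[i] *= eps
                assert np.linalg.norm(v - W10.to_numpy() @ h) >= base - 1e-9

    def test_catalog_scale_equivariance(self, W10, zero_cutoffs):
        rng = np.random.default_rng(1)
        v = rng.poisson(W10.to_numpy() @ rng.uniform(0, 50, 10)).astype(float)
        f1 = two_pass_decompose(v, W10, zero_cutoffs)
        f3 = two_pass_decompose(3 * v, W10, zero_cutoffs)
        np.testing.assert_allclose(f3.absolute, 3 * f1.absolute, rtol=1e-6, atol=1e-6)
        np.testing.assert_allclose(f3.relative, f1.relative, rtol=1e-6, atol=1e-9)


class TestTwoPass:
    def test_zero_cutoffs_are_a_noop_filter(self, W10, zero_cutoffs):
        rng = np.random.default_rng(2)
        v = rng.poisson(W10.to_numpy() @ rng.uniform(0, 50, 10)).astype(float)
        fit = two_pass_decompose(v, W10, zero_cutoffs)
        h1, _ = ss.nnls_fit(v, W10.to_numpy())
        np.testing.assert_allclose(fit.absolute, h1, atol=1e-9)
        assert fit.retained.all()

    def test_subcutoff_signature_removed(self, W10):
        # construct a sample whose pass-1 relative exposure to S5 is ~0.05,
        # below the printed AC3-style cutoff of 0.0819406
        h_true = np.zeros(10)
        h_true[0] = 950.0
        h_true[4] = 50.0
        v = W10.to_numpy() @ h_true
        cutoffs = pd.Series(0.0, index=W10.columns)
        cutoffs["S5"] = 0.0819406
        fit = two_pass_decompose(v, W10, cutoffs)
        i = fit.signatures.index("S5")
        assert not fit.retained[i]
        assert fit.absolute[i] == 0

    def test_pure_sample_retains_generating_signature(self, W10):
        cutoffs = ss.default_cutoffs()[: 10]
        cutoffs.index = W10.columns
        v = 1000 * W10.iloc[:, 2].to_numpy()
        fit = two_pass_decompose(v, W10, cutoffs)
        i = fit.signatures.index("S3")
        assert fit.retained[i]
        assert fit.relative[i] == pytest.approx(1.0, abs=1e-6)

    def test_cutoff_monotonicity(self, W10):
        rng = np.random.default_rng(3)
        v = rng.poisson(W10.to_numpy() @ rng.uniform(0, 80, 10)).astype(float)
        kept_sets = []
        for c in (0.0, 0.02, 0.05, 0.15):
            fit = two_pass_decompose(v, W10, pd.Series(c, index=W10.columns))
            kept_sets.append(frozenset(np.flatnonzero(fit.retained)))
        for small, large in zip(kept_sets[1:], kept_sets[:-1]):
            assert small <= large

    def test_all_removed_warns(self, W10):
        v = W10.to_numpy() @ np.full(10, 10.0)
        with pytest.warns(UserWarning):
            fit = two_pass_decompose(v, W10, pd.Series(1.0, index=W10.columns))
        assert (fit.absolute == 0).all()


class TestProfileLikelihoodCI:
    def test_per_side_tail_probability(self):
        from scipy.stats import chi2

        assert chi2.sf(lrt_threshold(0.95), 1) == pytest.approx(0.025, abs=1e-12)

    def test_single_signature_interval_contains_truth(self):
        W = ss.make_signature_matrix(1, seed=5)
        v = 100 * W.iloc[:, 0].to_numpy()
        fit = two_pass_decompose(v, W, pd.Series(0.0, index=W.columns))
        lo, hi, _ = profile_likelihood_ci(v, W, fit, "S1")
        assert lo <= 100 <= hi

    def test_duplicate_signatures_give_zero_lower_bound(self):
        W1 = ss.make_signature_matrix(1, seed=6)
        W = pd.concat([W1, W1.rename(columns={"S1": "S1b"})], axis=1)
        v = 200 * W1.iloc[:, 0].to_numpy()
        fit = two_pass_decompose(v, W, pd.Series(0.0, index=W.columns))
        for k in W.columns:
            if not fit.retained[fit.signatures.index(k)]:
                continue
            lo, hi, _ = profile_likelihood_ci(v, W, fit, k)
            assert lo == 0.0

    def test_absent_signature_interval_includes_zero(self, W10, zero_cutoffs):
        # null simulation: S9 inactive; its CI should include 0 in >= 90%
        truth = np.zeros(10)
        truth[:3] = [250, 150, 100]
        mix = W10.to_numpy() @ truth
        mix = mix / mix.sum()
        include = 0
        reps = 40
        for sseq in np.random.SeedSequence(77).spawn(reps):
            v = np.random.default_rng(sseq).multinomial(500, mix).astype(float)
            fit = two_pass_decompose(v, W10, zero_cutoffs)
            i = fit.signatures.index("S9")
            if not fit.retained[i]:
                include += 1
                continue
            lo, _, _ = profile_likelihood_ci(v, W10, fit, "S9")
            include += lo == 0.0
        assert include >= 0.9 * reps

    def test_strong_signature_detected(self, W10, zero_cutoffs):
        # power simulation: relative exposure 0.4 at N=500 excludes zero
        truth = np.zeros(10)
        truth[:3] = [200, 200, 100]
        mix = W10.to_numpy() @ truth
        mix = mix / mix.sum()
        detected = 0
        reps = 40
        for sseq in np.random.SeedSequence(78).spawn(reps):
            v = np.random.default_rng(sseq).multinomial(500, mix).astype(float)
            fit = two_pass_decompose(v, W10, zero_cutoffs)
            lo, _, _ = profile_likelihood_ci(v, W10, fit, "S1")
            detected += lo > 0
        assert detected >= 0.9 * reps


class TestPerMbp:
    def test_division(self):
        assert ss.normalize_exposure_per_mbp(500, 50) == 10
        assert ss.normalize_exposure_per_mbp(0, 50) == 0

    def test_nonpositive_target_rejected(self):
        with pytest.raises(ValueError):
            ss.normalize_exposure_per_mbp(10, 0)

    def test_wes_wgs_densities_comparable(self, W10, zero_cutoffs):
        # equal per-Mbp truth at 50 vs 3200 Mbp targets
        rng = np.random.default_rng(5)
        per_mbp_truth = 2.0
        mix = W10.iloc[:, 0].to_numpy()
        vals = []
        for size in (50, 3200):
            n = int(per_mbp_truth * size)
            v = rng.multinomial(n, mix).astype(float)
            fit = two_pass_decompose(v, W10, zero_cutoffs)
            vals.append(ss.normalize_exposure_per_mbp(fit.absolute[0], size))
        assert vals[0] == pytest.approx(vals[1], rel=0.1)


class TestDeriveCutoffs:
    def _labelled_cohort(self, W10, rng, n=40, separable=True):
        cats, labels = [], []
        for i in range(n):
            pos = i % 2 == 0
            h = np.zeros(10)
            h[0] = 400
            h[3] = rng.uniform(0.3, 0.5) * 400 if pos else rng.uniform(0, 0.1) * 400
            v = rng.multinomial(400, (W10.to_numpy() @ h) / (W10.to_numpy() @ h).sum())
            cats.append(v.astype(float))
            labels.append(pos)
        catalog = pd.DataFrame(np.column_stack(cats), index=W10.index,
                               columns=[f"c{i}" for i in range(n)])
        lab = pd.DataFrame({"S4": labels}, index=catalog.columns)
        return catalog, lab

    def test_separable_labels_give_cutoff_between_classes(self, W10):
        rng = np.random.default_rng(8)
        catalog, labels = self._labelled_cohort(W10, rng)
        out = ss.derive_cutoffs(catalog, labels, W10)
        row = out[out.signature == "S4"].iloc[0]
        assert 0.05 < row.cutoff <= 0.35
        assert row.informative

    def test_random_labels_flagged_uninformative(self, W10):
        rng = np.random.default_rng(9)
        catalog, labels = self._labelled_cohort(W10, rng)
        labels["S4"] = rng.random(len(labels)) < 0.5  # shuffle away the signal
        out = ss.derive_cutoffs(catalog, labels, W10)
        row = out[out.signature == "S4"].iloc[0]
        assert row.youden_j < 0.4

    def test_single_class_labels_reported_missing(self, W10):
        rng = np.random.default_rng(10)
        catalog, labels = self._labelled_cohort(W10, rng)
        labels["S4"] = True
        out = ss.derive_cutoffs(catalog, labels, W10)
        row = out[out.signature == "S4"].iloc[0]
        assert np.isnan(row.cutoff) and row.note == "single-class"


class TestEnrichment:
    def test_identical_proportions_give_p_one(self):
        counts = pd.DataFrame(
            [{"signature": "A", "cohort_detected": 8, "cohort_total": 16,
              "background_detected": 800, "background_total": 1600}]
        )
        out = ss.enrichment_test(counts)
        assert out.p.iloc[0] == pytest.approx(1.0, abs=0.05)

    def test_fisher_p_matches_hypergeometric_enumeration(self):
        # 2x2 table (8, 3 | 700, 6342): two-sided p as the sum over tables
        # with point probability <= the observed one
        a, b, c, d = 8, 3, 700, 6342
        N, K, n = a + b + c + d, a + c, a + b
        p_obs = hypergeom.pmf(a, N, K, n)
        total = sum(
            hypergeom.pmf(x, N, K, n)
            for x in range(max(0, n - (N - K)), min(K, n) + 1)
            if hypergeom.pmf(x, N, K, n) <= p_obs * (1 + 1e-9)
        )
        counts = pd.DataFrame(
            [{"signature": "AC3", "cohort_detected": a, "cohort_total": a + b,
              "background_detected": c, "background_total": c + d}]
        )
        out = ss.enrichment_test(counts)
        assert out.p.iloc[0] == pytest.approx(total, rel=1e-6)

    def test_bh_keeps_single_strong_effect(self):
        # one signature with p ~ 1e-6 among 29 null signatures
        rng = np.random.default_rng(12)
        hits = 0
        reps = 50
        for _ in range(reps):
            rows = [{"signature": "AC3", "cohort_detected": 10, "cohort_total": 11,
                     "background_detected": 700, "background_total": 7042}]
            for i in range(29):
                det = int(rng.binomial(11, 0.3))
                rows.append({"signature": f"N{i}", "cohort_detected": det,
                             "cohort_total": 11,
                             "background_detected": int(0.3 * 7042),
                             "background_total": 7042})
            out = ss.enrichment_test(pd.DataFrame(rows))
            hits += out.set_index("signature").q["AC3"] < 0.05
        assert hits >= 0.95 * reps

    def test_zero_total_flagged(self):
        counts = pd.DataFrame(
            [{"signature": "A", "cohort_detected": 0, "cohort_total": 0,
              "background_detected": 5, "background_total": 10}]
        )
        out = ss.enrichment_test(counts)
        assert out.p.iloc[0] == 1.0 and out.flag.iloc[0] == "zero-total"
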