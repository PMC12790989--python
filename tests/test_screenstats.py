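import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from caretile import screenstats, simdata
from caretile._stats import bh_adjust
from caretile.screenstats import (
    WindowFit,
    fit_window_lmm,
    guide_lfc,
    guide_pvalues,
    merge_bins,
    normalize_cpm,
    scan_bins,
    timepoint_means,
)


def bh_bruteforce(p):
    """Textbook step-up: independent oracle for the BH implementation."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def reference_ml_loglik(y, day, guide, with_time=True):
    """Direct numerical ML of the random-intercept Gaussian likelihood.

    Independent of the package's profiled fit: builds the full covariance
    per group and optimizes (beta, log tau2, log sigma2) by Nelder-Mead.
    """
    y = np.asarray(y, float)
    day = np.asarray(day, float)
    groups = np.unique(guide)
    X = np.column_stack([np.ones_like(y), day]) if with_time else np.ones((y.size, 1))

    def negll(params):
        beta = params[: X.shape[1]]
        tau2, sigma2 = np.exp(params[-2]), np.exp(params[-1])
        total = 0.0
        for g in groups:
            mask = guide == g
            r = y[mask] - X[mask] @ beta
            V = sigma2 * np.eye(mask.sum()) + tau2
            sign, logdet = np.linalg.slogdet(V)
            if sign <= 0:
                return 1e12
            total += 0.5 * (logdet + r @ np.linalg.solve(V, r) + mask.sum() * np.log(2 * np.pi))
        return total

    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    s2 = max(resid.var(), 1e-6)
    best = np.inf
    for t0 in (-8.0, np.log(s2 / 2 + 1e-12), 1.0):
        x0 = np.concatenate([beta0, [t0, np.log(s2 + 1e-12)]])
        res = optimize.minimize(
            negll, x0, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000},
        )
        best = min(best, res.fun)
    return -best


class TestNormalizeCpm:
    def test_single_guide(self):
        df = pd.DataFrame({"s1": [7]}, index=["g1"])
        assert normalize_cpm(df).iloc[0, 0] == pytest.approx(1e6)

    def test_hand_arithmetic(self):
        df = pd.DataFrame({"s1": [1, 3]}, index=["g1", "g2"])
        out = normalize_cpm(df)
        assert out["s1"].tolist() == pytest.approx([250_000, 750_000])

    def test_column_sums_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            df = pd.DataFrame(rng.integers(0, 100, size=(20, 3)) + 1)
            sums = normalize_cpm(df).sum(axis=0)
            assert np.allclose(sums, 1e6, rtol=1e-6)

    def test_zeros_stay_zero(self):
        df = pd.DataFrame({"s1": [0, 5]})
        assert normalize_cpm(df).iloc[0, 0] == 0

    def test_all_zero_sample_errors_with_name(self):
        df = pd.DataFrame({"good": [1, 2], "bad": [0, 0]})
        with pytest.raises(ValueError, match="bad"):
            normalize_cpm(df)


class TestTimepointMeans:
    def test_replicate_mean(self):
        norm = pd.DataFrame({"a": [10.0], "b": [20.0]}, index=["g1"])
        samples = pd.DataFrame({"sample": ["a", "b"], "replicate": [1, 2], "day": [5, 5]})
        assert timepoint_means(norm, samples)[5.0].iloc[0] == 15

    def test_single_replicate_identity(self):
        norm = pd.DataFrame({"a": [10.0, 3.0]})
        samples = pd.DataFrame({"sample": ["a"], "replicate": [1], "day": [5]})
        assert timepoint_means(norm, samples)[5.0].tolist() == [10.0, 3.0]

    def test_three_replicates(self):
        norm = pd.DataFrame({"a": [0.0], "b": [0.0], "c": [3.0]})
        samples = pd.DataFrame(
            {"sample": ["a", "b", "c"], "replicate": [1, 2, 3], "day": [5, 5, 5]}
        )
        assert timepoint_means(norm, samples)[5.0].iloc[0] == 1

    def test_missing_sample_errors(self):
        norm = pd.DataFrame({"a": [1.0]})
        samples = pd.DataFrame({"sample": ["a", "zz"], "replicate": [1, 2], "day": [5, 5]})
        with pytest.raises(ValueError):
            timepoint_means(norm, samples)


class TestGuideLfc:
    def test_equal_means_zero(self):
        means = pd.DataFrame({5.0: [10.0], 33.0: [10.0]})
        assert guide_lfc(means, 5, 33).iloc[0] == 0

    def test_quarter_is_minus_two(self):
        means = pd.DataFrame({5.0: [100.0], 33.0: [25.0]})
        assert guide_lfc(means, 5, 33, pseudocount=0).iloc[0] == pytest.approx(-2)

    def test_pseudocount_symmetry_at_zero(self):
        means = pd.DataFrame({5.0: [0.0], 33.0: [0.0]})
        assert guide_lfc(means, 5, 33, pseudocount=1).iloc[0] == 0

    def test_negative_pseudocount_errors(self):
        means = pd.DataFrame({5.0: [1.0], 33.0: [1.0]})
        with pytest.raises(ValueError):
            guide_lfc(means, 5, 33, pseudocount=-1)


class TestGuidePvalues:
    @staticmethod
    def unit_controls():
        # two controls with mean 0 and sample sd exactly 1
        a = 1 / np.sqrt(2)
        return pd.Series([-a, a], index=["c1", "c2"])

    def test_lfc_at_control_mean_p_one(self):
        lfcs = pd.concat([self.unit_controls(), pd.Series({"g1": 0.0})])
        out = guide_pvalues(lfcs, {"c1", "c2"})
        assert out.loc["g1", "p"] == pytest.approx(1.0)

    def test_normal_quantile(self):
        lfcs = pd.concat([self.unit_controls(), pd.Series({"g1": 1.959964})])
        out = guide_pvalues(lfcs, {"c1", "c2"})
        assert out.loc["g1", "p"] == pytest.approx(0.05, abs=1e-6)

    def test_adj_p_geq_p(self):
        rng = np.random.default_rng(2)
        lfcs = pd.Series(rng.normal(size=50), index=[f"g{i}" for i in range(50)])
        ctrl = set(lfcs.index[:10])
        out = guide_pvalues(lfcs, ctrl)
        assert (out.adj_p >= out.p - 1e-12).all()

    def test_zero_control_sd_errors(self):
        lfcs = pd.Series([0.5, 0.5, 1.0], index=["c1", "c2", "g1"])
        with pytest.raises(ValueError):
            guide_pvalues(lfcs, {"c1", "c2"})

    def test_too_few_controls_errors(self):
        lfcs = pd.Series([0.5, 1.0], index=["c1", "g1"])
        with pytest.raises(ValueError):
            guide_pvalues(lfcs, {"c1"})


class TestBH:
    def test_hand_example(self):
        assert bh_adjust(np.array([0.01, 0.02, 0.03])).tolist() == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.allclose(bh_adjust(p), bh_bruteforce(p))


class TestFitWindowLmm:
    def test_constant_response(self):
        y = np.ones(8)
        day = np.tile([5.0, 33.0], 4)
        guide = np.repeat(["a", "b", "c", "d"], 2)
        fit = fit_window_lmm(y, day, guide)
        assert fit.lrt_stat <= 1e-6
        assert abs(fit.slope) < 1e-8

    def test_parameter_recovery(self):
        rng = np.random.default_rng(11)
        days = np.array([5.0, 20.0, 29.0, 33.0])
        n_guides = 6
        y, dd, gg = [], [], []
        for g in range(n_guides):
            b = rng.normal(0, 0.5)
            for d in days:
                y.append(b - 0.1 * d + rng.normal(0, 0.1))
                dd.append(d)
                gg.append(f"g{g}")
        fit = fit_window_lmm(np.array(y), np.array(dd), np.array(gg))
        assert fit.p < 0.01
        assert -0.15 <= fit.slope <= -0.05

    def test_small_instance_matches_direct_ml(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=6)
        day = np.tile([5.0, 33.0], 3)
        guide = np.repeat(["a", "b", "c"], 2)
        fit = fit_window_lmm(y, day, guide)
        llf = reference_ml_loglik(y, day, guide, with_time=True)
        llr = reference_ml_loglik(y, day, guide, with_time=False)
        assert 2 * (fit.ll_full - fit.ll_reduced) == pytest.approx(2 * (llf - llr), abs=1e-4)

    def test_lrt_nonnegative_random_instances(self):
        rng = np.random.default_rng(9)
        for _ in range(50):
            G = rng.integers(2, 6)
            days = np.sort(rng.choice([5.0, 20.0, 29.0, 33.0], size=2, replace=False))
            y = rng.normal(size=G * 2)
            fit = fit_window_lmm(y, np.tile(days, G), np.repeat(np.arange(G), 2))
            assert fit.lrt_stat >= 0

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fit_window_lmm(np.ones(4), np.array([5, 5, 5, 5.0]), np.array([1, 1, 2, 2]))
        with pytest.raises(ValueError):
            fit_window_lmm(np.ones(4), np.array([5, 33, 5, 33.0]), np.array([1, 1, 1, 1]))


class TestScanBins:
    def test_window_membership(self, small_library, screen_data):
        counts, samples = screen_data
        means = timepoint_means(normalize_cpm(counts), samples)
        fits = scan_bins(means, small_library, ("chrS", 0, 1000), window_bins=1)
        lib = small_library[~small_library.is_control]
        g = lib[(lib.start >= 300) & (lib.start < 400)].guide_id.iloc[0]
        touched = [i for i, f in enumerate(fits) if g in f.guides_used]
        assert touched == [2, 3, 4]

    def test_window_bins_validation(self, small_library, screen_data):
        counts, samples = screen_data
        means = timepoint_means(normalize_cpm(counts), samples)
        with pytest.raises(ValueError):
            scan_bins(means, small_library, ("chrS", 0, 1000), window_bins=-1)

    def test_planted_recovery_and_specificity(self, small_library, planted_truth, screen_data):
        counts, samples = screen_data
        means = timepoint_means(normalize_cpm(counts), samples)
        fits = scan_bins(means, small_library, ("chrS", 0, 20_000))
        sig = {f.start for f in fits if np.isfinite(f.adj_p) and f.adj_p < 0.05}
        for el in planted_truth.planted_elements:
            inside = {s for s in sig if el.start <= s < el.end}
            assert inside, f"no significant bin inside {el}"
        far = [
            f for f in fits
            if np.isfinite(f.adj_p)
            and all(f.start < el.start - 200 or f.start >= el.end + 200
                    for el in planted_truth.planted_elements)
        ]
        frac_far_sig = np.mean([f.adj_p < 0.05 for f in far])
        assert frac_far_sig < 0.05


def _bin(start, end, adj_p=0.01, slope=-1.0):
    return WindowFit("chrS", start, end, ["g"], 1.0, 1, adj_p, slope, 0.0, 0.0, adj_p=adj_p)


class TestMergeBins:
    def test_gap_400_merges(self):
        cares = merge_bins([_bin(100, 200), _bin(600, 700)])
        assert len(cares) == 1 and (cares[0].start, cares[0].end) == (100, 700)

    def test_gap_601_splits(self):
        cares = merge_bins([_bin(0, 100), _bin(701, 801)])
        assert len(cares) == 2

    @pytest.mark.parametrize("gap,expected", [(400, 1), (500, 1), (501, 2), (600, 2)])
    def test_gap_boundary(self, gap, expected):
        cares = merge_bins([_bin(0, 100), _bin(100 + gap, 200 + gap)])
        assert len(cares) == expected

    def test_single_bin(self):
        cares = merge_bins([_bin(0, 100)])
        assert (cares[0].start, cares[0].end) == (0, 100)

    def test_direction_aware(self):
        cares = merge_bins([_bin(0, 100, slope=-1.0), _bin(200, 300, slope=1.0)])
        assert len(cares) == 2
        assert {c.direction for c in cares} == {"depleted", "enriched"}

    def test_overlapping_bins_error(self):
        with pytest.raises(ValueError, match="overlapping"):
            merge_bins([_bin(0, 100), _bin(50, 150)])

    def test_insignificant_bins_ignored(self):
        assert merge_bins([_bin(0, 100, adj_p=0.5)]) == []


class TestScoreCares:
    def test_score_is_neglog10(self, small_library, planted_truth, screen_data):
        counts, samples = screen_data
        _, _, cares = screenstats.call_cares(
            counts, samples, small_library, ("chrS", 0, 20_000)
        )
        for c in cares:
            if not c.flagged:
                assert c.score == pytest.approx(-np.log10(c.adj_p))

    def test_planted_direction(self, small_library, planted_truth, screen_data):
        counts, samples = screen_data
        _, _, cares = screenstats.call_cares(
            counts, samples, small_library, ("chrS", 0, 20_000)
        )
        by_dir = {}
        for c in cares:
            for el in planted_truth.planted_elements:
                if c.start < el.end and c.end > el.start:
                    by_dir[el.direction] = c.direction
        assert by_dir.get("depleted") == "depleted"
        assert by_dir.get("enriched") == "enriched"

    def test_monotone_in_effect_size(self, small_library):
        scores = []
        for slope in (-0.004, -0.008, -0.016):
            el = simdata.PlantedElement("chrS", 5000, 5300, slope, "depleted")
            truth = simdata.ScreenTruth([el], set())
            best = []
            for seed in range(8):
                counts, samples = simdata.simulate_screen_counts(
                    small_library, truth, [5, 20, 29, 33], 2, 2e5, seed=seed
                )
                _, _, cares = screenstats.call_cares(
                    counts, samples, small_library, ("chrS", 4000, 6500)
                )
                best.append(max((c.score for c in cares if not c.flagged), default=0.0))
            scores.append(np.median(best))
        assert scores[0] <= scores[1] <= scores[2]

    def test_sensitivity_mode_runs(self, small_library, screen_data):
        counts, samples = screen_data
        _, fits, _ = screenstats.call_cares(
            counts, samples, small_library, ("chrS", 4000, 6000), collapse_replicates=False
        )
        tested = [f for f in fits if np.isfinite(f.p)]
        assert tested and all(f.lrt_stat >= 0 for f in tested)
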