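import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from odegp import (
    RhythmDataset,
    WaveSpec,
    cosinor_pvalue,
    gen_wave,
    lomb_scargle_pvalue,
    roc,
    run_benchmark,
    score_collection,
)


def rank_auc(scores, labels):
    """Mann-Whitney estimate of P(score_pos > score_neg), ties half-credit."""
    scores = np.asarray(scores, float)
    pos = scores[np.asarray(labels) == 1]
    neg = scores[np.asarray(labels) == 0]
    u = stats.mannwhitneyu(pos, neg, alternative="two-sided").statistic
    return u / (len(pos) * len(neg))


class TestROC:
    def test_perfect_separation(self):
        r = roc([1.0, 2.0, 3.0, -1.0, -2.0, -3.0], [1, 1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(1.0)

    def test_all_tied_scores(self):
        r = roc([5.0] * 6, [1, 1, 1, 0, 0, 0])
        assert r.auc == pytest.approx(0.5)

    def test_label_inversion_symmetry(self, rng):
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, 40)
        labels[:2] = [0, 1]  # both classes present
        a = roc(scores, labels).auc
        b = roc(scores, 1 - labels).auc
        assert a + b == pytest.approx(1.0, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc([1.0, 2.0], [1, 1])

    def test_endpoints(self, rng):
        r = roc(rng.normal(size=30), rng.permutation([0, 1] * 15))
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), ties=st.booleans())
    def test_trapezoid_equals_rank_statistic(self, seed, ties):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        scores = rng.normal(size=n)
        if ties:
            scores = np.round(scores)  # force heavy ties
        labels = rng.integers(0, 2, n)
        labels[:2] = [0, 1]
        assert roc(scores, labels).auc == pytest.approx(
            rank_auc(scores, labels), abs=1e-12
        )


class TestCosinor:
    def test_noiseless_cosine_detected(self):
        t = np.arange(0, 49, 3.0)
        ds = RhythmDataset(times=t, values=3 * np.cos(2 * np.pi * t / 24))
        assert cosinor_pvalue(ds, period_grid=[20, 24, 28]) < 1e-6

    def test_type_one_error_calibrated(self):
        """On pure noise at nominal alpha=0.05 the rejection rate stays in a
        sane band (single-period grid, no multiplicity)."""
        rejections = 0
        for seed in range(100):
            ds = gen_wave(WaveSpec(family="noise", sigma=1.0, seed=seed))
            p = cosinor_pvalue(ds, period_grid=[24.0])
            rejections += p < 0.05
        assert 0.01 <= rejections / 100 <= 0.10

    def test_grid_of_one_no_inflation(self):
        t = np.arange(0, 49, 3.0)
        rng = np.random.default_rng(0)
        ds = RhythmDataset(times=t, values=rng.normal(size=t.size))
        p1 = cosinor_pvalue(ds, period_grid=[24.0])
        p5 = cosinor_pvalue(ds, period_grid=[24.0] * 5)
        assert p5 == pytest.approx(min(1.0, 5 * p1))

    def test_degenerate_design_rejected(self):
        ds = RhythmDataset(times=[3.0] * 5, values=np.arange(5.0))
        with pytest.raises(ValueError, match="degenerate"):
            cosinor_pvalue(ds)


class TestLombScargle:
    def test_noiseless_sine_peak_power(self):
        """A pure sinusoid at a grid frequency peaks near (n-1)/2 in
        variance-normalized power and is highly significant."""
        t = np.arange(0, 96, 1.0)
        y = np.sin(2 * np.pi * t / 24)
        ds = RhythmDataset(times=t, values=y)
        from odegp.benchmark import _lsp_grid
        from scipy.signal import lombscargle

        z = lombscargle(t, y - y.mean(), 2 * np.pi * _lsp_grid(t)).max() / y.var()
        assert z == pytest.approx((t.size - 1) / 2, rel=0.05)
        assert lomb_scargle_pvalue(ds) < 1e-2

    def test_constant_data_insignificant(self):
        t = np.arange(0, 49, 3.0)
        ds = RhythmDataset(times=t, values=np.full(t.size, 2.0))
        assert lomb_scargle_pvalue(ds) == pytest.approx(1.0)

    def test_white_noise_power_exponential_null(self):
        """At a fixed frequency the variance-normalized power of white noise
        is Exp(1)-distributed (KS over 500 simulations)."""
        from scipy.signal import lombscargle

        t = np.arange(0, 96, 1.0)
        rng = np.random.default_rng(0)
        powers = []
        for _ in range(500):
            y = rng.normal(size=t.size)
            y = y - y.mean()
            powers.append(lombscargle(t, y, [2 * np.pi * 0.1, 1.0])[0] / y.var())
        assert stats.kstest(powers, lambda z: 1 - np.exp(-np.asarray(z))).pvalue > 0.01

    def test_white_noise_type_one_error_calibrated(self):
        """The peak P-value's rejection rate on pure noise at nominal 0.05
        stays in a sane band at the 17-point qPCR design."""
        rng = np.random.default_rng(7)
        t = np.arange(0, 49, 3.0)
        rej = 0
        for _ in range(500):
            ds = RhythmDataset(times=t, values=rng.normal(size=t.size))
            rej += lomb_scargle_pvalue(ds) < 0.05
        assert 0.01 <= rej / 500 <= 0.10

    def test_duplicate_row_invariance(self):
        t = np.arange(0, 49, 3.0)
        y = np.sin(2 * np.pi * t / 24) + 0.01 * np.cos(t)
        single = RhythmDataset(times=t, values=y)
        tripled = RhythmDataset(times=t, values=np.tile(y[:, None], (1, 3)))
        assert lomb_scargle_pvalue(single) == pytest.approx(
            lomb_scargle_pvalue(tripled), rel=1e-9
        )


class TestScoreCollection:
    def test_cosinor_strong_sine_score(self):
        ds = gen_wave(
            WaveSpec(family="stationary_symmetric", A1=3.0, A2=0.0,
                     tau1=24.0, tau2=24.0, sigma=0.0)
        )
        scores = score_collection([ds], "cosinor")
        assert scores[0] > 6  # p < 1e-6

    def test_adapter_contract(self):
        dss = [gen_wave(WaveSpec(family="noise", seed=s)) for s in range(3)]
        scores = score_collection(dss, lambda ds: float(ds.values.sum()))
        assert scores.shape == (3,)

    def test_failure_scored_as_worst(self):
        dss = [gen_wave(WaveSpec(family="noise", seed=s)) for s in range(3)]

        def flaky(ds):
            if ds.values[0, 0] == dss[1].values[0, 0]:
                raise RuntimeError("boom")
            return float(ds.values.sum())

        scores = score_collection(dss, flaky)
        assert scores[1] == scores.min()

    def test_unknown_detector_rejected(self):
        with pytest.raises(ValueError, match="unknown detector"):
            score_collection([], "jtk")


class TestRunBenchmark:
    def test_empty_detector_list(self):
        table = run_benchmark("fig2e", detectors=(), n_per_class=2, seed=0)
        assert len(table) == 0

    def test_fast_detectors_table_and_outputs(self, tmp_path):
        table = run_benchmark(
            "fig2e", detectors=("cosinor", "lomb_scargle"), n_per_class=10,
            seed=1, outdir=tmp_path,
        )
        assert set(table["detector"]) == {"cosinor", "lomb_scargle"}
        assert ((table["auc"] >= 0) & (table["auc"] <= 1)).all()
        assert (tmp_path / "auc_table.csv").exists()
        assert (tmp_path / "roc_cosinor.csv").exists()

    def test_monotone_difficulty_in_noise_for_cosinor(self):
        """Stationary symmetric waves: low-noise AUC >= high-noise AUC."""
        from dataclasses import replace
        from odegp.synthetic_waves import preset_pair

        osc, null = preset_pair("fig2b")
        aucs = {}
        for sigma in (0.1, 1.0):
            spec_o = replace(osc, sigma=sigma, missing_fraction=0.0)
            spec_n = replace(null, sigma=sigma, missing_fraction=0.0)
            table = run_benchmark(
                (spec_o, spec_n), detectors=("cosinor",), n_per_class=50, seed=4
            )
            aucs[sigma] = table["auc"].iloc[0]
        assert aucs[0.1] >= aucs[1.0]
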