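import numpy as np
import pandas as pd
import pytest

from starscan.benchmark_sim import builtin_model
from starscan.null_model import (ExpectedScoreModel, call_outliers,
                                 fit_expected_model, simulate_null)

SIM_KW = dict(seq_len=100_000, mu=1.25e-8, recomb_rate=1e-8,
              samples={"ref": 4, "tgt": 2}, ref_pop="ref", tgt_pop="tgt")


def synthetic_records(sstar, n_snps, rate=1e-8):
    return pd.DataFrame({"sstar": sstar, "n_snps": n_snps,
                         "recomb_rate": rate})


class TestSimulateNull:
    def test_deterministic_given_seed_and_expected_cardinality(self):
        null = builtin_model("null")
        r1 = simulate_null(null, n_reps=3, seed=9, **SIM_KW)
        r2 = simulate_null(null, n_reps=3, seed=9, **SIM_KW)
        assert r1.equals(r2)
        # 6 sliding 50 kb windows per 100 kb replicate x 2 target individuals
        assert len(r1) == 3 * 6 * 2

    def test_model_with_pulse_into_target_refused(self):
        ghost = builtin_model("ghost")
        with pytest.raises(ValueError, match="gene flow into target"):
            simulate_null(ghost, n_reps=1, seed=1, **SIM_KW)

    def test_zero_mutation_rate_gives_all_zero_scores(self):
        null = builtin_model("null")
        kw = dict(SIM_KW, mu=0.0)
        rec = simulate_null(null, n_reps=2, seed=3, **kw)
        assert (rec.sstar == 0).all()
        assert (rec.n_snps == 0).all()


class TestFitExpectedModel:
    def test_constant_score_surface_recovers_the_constant(self):
        rng = np.random.default_rng(0)
        rec = synthetic_records(np.full(6000, 12_345.0),
                                rng.integers(10, 60, size=6000))
        m = fit_expected_model(rec, (0.5, 0.9), min_records=1000)
        pred = m.predict(np.arange(12, 58), 1e-8, 0.9)
        assert np.all(np.abs(pred - 12_345.0) < 0.01 * 12_345.0)

    def test_median_matches_empirical_quantile_when_independent(self):
        rng = np.random.default_rng(1)
        scores = rng.gamma(2.0, 5000.0, size=20_000)
        rec = synthetic_records(scores, rng.integers(10, 60, size=20_000))
        m = fit_expected_model(rec, (0.5,), min_records=1000)
        empirical = np.quantile(scores, 0.5)
        pred = m.predict(np.arange(15, 55), 1e-8, 0.5)
        # binomial-order error on the median of 20k draws, plus smoothing
        assert np.all(np.abs(pred - empirical) < 0.05 * empirical)

    def test_quantile_surfaces_are_pointwise_monotone_in_q(self):
        rng = np.random.default_rng(2)
        n = rng.integers(10, 80, size=15_000)
        scores = rng.exponential(1000 + 100.0 * n)
        rec = synthetic_records(scores, n)
        m = fit_expected_model(rec, (0.5, 0.9, 0.99), min_records=1000)
        grid = np.arange(12, 78)
        p50 = m.predict(grid, 1e-8, 0.5)
        p90 = m.predict(grid, 1e-8, 0.9)
        p99 = m.predict(grid, 1e-8, 0.99)
        assert np.all(p50 <= p90) and np.all(p90 <= p99)

    def test_too_few_records_is_error(self):
        rec = synthetic_records([1.0] * 100, list(range(10, 110)))
        with pytest.raises(ValueError, match="positive-score null records"):
            fit_expected_model(rec, (0.9,), min_records=5000)

    def test_degenerate_mutation_counts_is_error(self):
        rec = synthetic_records(np.arange(1.0, 6001.0),
                                np.full(6000, 30))
        with pytest.raises(ValueError, match="distinct mutation counts"):
            fit_expected_model(rec, (0.9,), min_records=1000)

    def test_refit_on_same_records_is_bit_identical(self):
        rng = np.random.default_rng(4)
        rec = synthetic_records(rng.exponential(5000, 8000),
                                rng.integers(10, 60, 8000))
        m1 = fit_expected_model(rec, (0.9, 0.95), min_records=1000)
        m2 = fit_expected_model(rec, (0.9, 0.95), min_records=1000)
        assert m1.to_json() == m2.to_json()


class TestModelSerialization:
    def test_save_load_roundtrip_is_bit_identical(self, tmp_path):
        rng = np.random.default_rng(5)
        rec = synthetic_records(rng.exponential(5000, 8000),
                                rng.integers(10, 60, 8000))
        m = fit_expected_model(rec, (0.9,), min_records=1000)
        path = tmp_path / "model.json"
        m.save(path)
        back = ExpectedScoreModel.load(path)
        assert back.to_json() == m.to_json()
        x = np.linspace(12, 58, 37)
        assert np.array_equal(back.predict(x, 1e-8, 0.9),
                              m.predict(x, 1e-8, 0.9))

    def test_unknown_quantile_rejected(self):
        m = ExpectedScoreModel([0.9], np.arange(5), [1.0],
                               np.zeros((1, 5, 1)))
        with pytest.raises(ValueError, match="not in fitted grid"):
            m.predict(3, 1e-8, 0.95)


class TestCallOutliers:
    @pytest.fixture
    def flat_model(self):
        # expected S* = 1000 everywhere at q=0.9
        return ExpectedScoreModel([0.9], np.arange(0, 101, 10), [-8.0],
                                  np.full((1, 11, 1), 1000.0))

    def scores(self, sstar):
        return pd.DataFrame({
            "chrom": "1", "start": 0, "end": 50_000, "sample": "tgt_0",
            "sstar": sstar, "n_candidates": 3,
            "n_snps_window": 50, "chain": "", "recomb_rate": 1e-8})

    def test_zero_score_never_flagged(self, flat_model):
        out = call_outliers(self.scores([0.0]), flat_model, 0.9)
        assert not out.is_outlier.any()

    def test_exact_boundary_not_flagged(self, flat_model):
        out = call_outliers(self.scores([1000.0]), flat_model, 0.9)
        assert not out.is_outlier.any()

    def test_strict_exceedance_flagged(self, flat_model):
        out = call_outliers(self.scores([1000.5]), flat_model, 0.9)
        assert out.is_outlier.all()

    def test_covariates_outside_hull_are_clamped_with_warning(self, flat_model,
                                                              caplog):
        s = self.scores([500.0])
        s["n_snps_window"] = 10_000
        with caplog.at_level("WARNING"):
            out = call_outliers(s, flat_model, 0.9)
        assert "clamped" in caplog.text
        assert out.expected_sstar.iloc[0] == 1000.0

    def test_missing_rate_column_requires_recomb_argument(self, flat_model):
        s = self.scores([500.0]).drop(columns=["recomb_rate"])
        with pytest.raises(ValueError, match="recomb_rate"):
            call_outliers(s, flat_model, 0.9)
        out = call_outliers(s, flat_model, 0.9, recomb=1e-8)
        assert len(out) == 1
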