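import itertools

import numpy as np
import pytest

from mhcbench.evaluation import (
    BinderCutoff,
    DeviationRecord,
    UndefinedPerformanceError,
    aroc,
    blind_performance,
    cv_performance,
    deviation_band,
    deviation_tests,
    pearson_log,
)
from mhcbench.io import DatasetKey
from mhcbench.partitioning import partition_random

from conftest import make_dataset, random_peptides

CUTOFF = BinderCutoff(500.0)


def pair_counting_aroc(predicted, measured, threshold=500.0):
    """Independent oracle: exhaustive Mann-Whitney pair count."""
    binders = [p for p, m in zip(predicted, measured) if m < threshold]
    nonbinders = [p for p, m in zip(predicted, measured) if m >= threshold]
    wins = 0.0
    for b, n in itertools.product(binders, nonbinders):
        if b < n:  # lower predicted ic50 = predicted stronger
            wins += 1.0
        elif b == n:
            wins += 0.5
    return wins / (len(binders) * len(nonbinders))


class TestAroc:
    def test_perfect_separation(self):
        assert aroc([10, 20, 900, 1000], [100, 200, 600, 700], CUTOFF) == 1.0

    def test_all_tied_predictions(self):
        assert aroc([300] * 6, [100, 100, 100, 900, 900, 900], CUTOFF) == 0.5

    def test_worked_example_three_of_four_pairs(self):
        # binders predicted {10, 600}, non-binders predicted {300, 1000}:
        # correct pairs (10,300), (10,1000), (600,1000) -> 3/4
        value = aroc([10, 600, 300, 1000], [100, 200, 600, 700], CUTOFF)
        assert value == 0.75

    def test_matches_exhaustive_pair_counting(self, rng):
        for _ in range(200):
            n = int(rng.integers(4, 30))
            measured = 10 ** rng.uniform(0, 5, n)
            if not (np.any(measured < 500) and np.any(measured >= 500)):
                continue
            predicted = np.round(10 ** rng.uniform(0, 5, n), -1)  # induce ties
            assert aroc(predicted, measured, CUTOFF) == pytest.approx(
                pair_counting_aroc(predicted, measured)
            )

    def test_invariant_under_monotone_transform_of_predictions(self, rng):
        measured = 10 ** rng.uniform(0, 5, 40)
        measured[:5], measured[-5:] = 10.0, 5000.0
        predicted = 10 ** rng.uniform(0, 5, 40)
        base = aroc(predicted, measured, CUTOFF)
        assert aroc(predicted**3, measured, CUTOFF) == pytest.approx(base)
        assert aroc(np.log(predicted), measured, CUTOFF) == pytest.approx(base)

    def test_single_class_signalled(self):
        with pytest.raises(UndefinedPerformanceError):
            aroc([10, 20], [100, 200], CUTOFF)

    def test_binder_cutoff_is_strict(self):
        # a measurement of exactly 500 nM is a non-binder
        assert aroc([10, 1000], [499.9, 500.0], CUTOFF) == 1.0


class TestPearsonLog:
    def test_identity_is_one(self):
        x = [10.0, 100.0, 1000.0, 5000.0]
        assert pearson_log(x, x) == pytest.approx(1.0)

    def test_anti_linear_in_logs_is_minus_one(self):
        measured = [10.0, 100.0, 1000.0]
        predicted = [1000.0, 100.0, 10.0]
        assert pearson_log(predicted, measured) == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        predicted, measured = [10.0, 100.0, 10000.0], [20.0, 300.0, 5000.0]
        p, m = np.log10(predicted), np.log10(measured)
        num = np.sum((p - p.mean()) * (m - m.mean()))
        den = np.sqrt(np.sum((p - p.mean()) ** 2) * np.sum((m - m.mean()) ** 2))
        assert pearson_log(predicted, measured) == pytest.approx(num / den)

    def test_zero_variance_signalled(self):
        with pytest.raises(UndefinedPerformanceError):
            pearson_log([100.0, 100.0, 100.0], [10.0, 100.0, 1000.0])


def oracle_predictor(train, peptides):
    """Returns the measured value for known peptides (perfect predictor)."""
    lookup = {m.peptide: m.ic50 for m in train.measurements}
    return np.array([lookup[p] for p in peptides])


class TestCvPerformance:
    def _dataset(self, rng, n=50):
        peps = random_peptides(rng, n)
        ic50s = 10 ** rng.uniform(0, 5, n)
        return make_dataset(peps, ic50s)

    def test_oracle_predictor_scores_one(self, rng):
        ds = self._dataset(rng)

        def leaky_oracle(train, peptides):
            lookup = {m.peptide: m.ic50 for m in ds.measurements}
            return np.array([lookup[p] for p in peptides])

        fa = partition_random(ds, 5, seed=0)
        res = cv_performance(ds, fa, leaky_oracle, CUTOFF)
        assert res.record.value == 1.0

    def test_exactly_one_prediction_per_assigned_peptide(self, rng):
        ds = self._dataset(rng)
        fa = partition_random(ds, 5, seed=0)
        res = cv_performance(
            ds, fa, lambda tr, peps: 10 ** np.linspace(0, 4, len(peps)), CUTOFF
        )
        assert sorted(res.predictions["peptide"]) == sorted(ds.peptides)

    def test_pooled_equals_direct_for_training_independent_predictor(self, rng):
        # a predictor that ignores training data: pooled cv predictions are
        # exactly the direct predictions, so the pooled AROC matches
        ds = self._dataset(rng)
        fa = partition_random(ds, 5, seed=0)

        def fixed(train, peptides):
            h = [abs(hash(p)) % 10_000 + 1 for p in peptides]
            return np.array(h, dtype=float)

        res = cv_performance(ds, fa, fixed, CUTOFF)
        direct = aroc(fixed(ds, ds.peptides), ds.ic50s, CUTOFF)
        assert res.record.value == pytest.approx(direct)


class TestBlindPerformance:
    def test_oracle_predictor_scores_one(self, rng):
        peps = random_peptides(rng, 60)
        ic50s = 10 ** rng.uniform(0, 5, 60)
        train = make_dataset(peps, ic50s)
        blind = make_dataset(peps[:30], ic50s[:30])
        rec, preds = blind_performance(train, blind, oracle_predictor, CUTOFF)
        assert rec.value == 1.0
        assert len(preds) == 30

    def test_key_mismatch_rejected(self, rng):
        a = make_dataset(random_peptides(rng, 10), [100] * 10, allele="A")
        b = make_dataset(random_peptides(rng, 10), [100] * 10, allele="B")
        with pytest.raises(ValueError):
            blind_performance(a, b, oracle_predictor, CUTOFF)


def _records(absolutes):
    key = DatasetKey("A", 9)
    return [
        DeviationRecord(key, "cv_gs", cv_value=0.8, blind_value=0.8 - a)
        for a in absolutes
    ]


class TestDeviationBand:
    def test_equal_absolutes_all_small_by_strict_inequality(self):
        recs, threshold = deviation_band(_records([0.05, 0.05, 0.05]), [0.05, 0.05])
        assert threshold == pytest.approx(0.05)
        assert all(r.label == "small" for r in recs)

    def test_threshold_is_mean_of_reference(self):
        recs, threshold = deviation_band(_records([0.0, 0.2]), [0.0, 0.2])
        assert threshold == pytest.approx(0.1)
        assert [r.label for r in recs] == ["small", "large"]

    def test_threshold_frozen_to_reference_not_records(self):
        _, t1 = deviation_band(_records([0.3, 0.4]), [0.0, 0.2])
        _, t2 = deviation_band(_records([0.0, 0.01]), [0.0, 0.2])
        assert t1 == t2 == pytest.approx(0.1)


class TestDeviationTests:
    def test_all_zero_diffs(self):
        out = deviation_tests({"cv_gs": [0.0, 0.0, 0.0, 0.0]})
        row = out.iloc[0]
        assert row["t_one_sample"] == 0.0
        assert row["p_one_sample_two_sided"] == pytest.approx(1.0)

    def test_constant_nonzero_diffs_degenerate(self):
        out = deviation_tests({"cv_gs": [1.0, 1.0, 1.0, 1.0]})
        assert np.isinf(out.iloc[0]["t_one_sample"])

    def test_six_value_closed_form(self):
        d = np.array([0.05, -0.02, 0.08, 0.01, 0.03, 0.06])
        out = deviation_tests({"cv_gs": list(d)})
        row = out.iloc[0]
        t_expected = d.mean() / (d.std(ddof=1) / np.sqrt(6))
        assert row["t_one_sample"] == pytest.approx(t_expected)
        assert row["mean"] == pytest.approx(d.mean())
        assert row["sem"] == pytest.approx(d.std(ddof=1) / np.sqrt(6))

    def test_paired_tests_against_cv_rnd(self):
        diffs = {
            "cv_rnd": [0.10, 0.12, 0.08, 0.11, 0.09],
            "cv_gs": [0.02, 0.03, 0.01, 0.04, 0.02],
        }
        out = deviation_tests(diffs).set_index("strategy")
        # cv_gs deviations are uniformly closer to zero: both paired
        # one-sided tests should be significant
        assert out.loc["cv_gs", "p_paired_vs_rnd_signed"] < 0.05
        assert out.loc["cv_gs", "p_paired_vs_rnd_absolute"] < 0.05
        assert np.isnan(out.loc["cv_rnd", "p_paired_vs_rnd_signed"])

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            deviation_tests({"cv_gs": [0.1]})
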