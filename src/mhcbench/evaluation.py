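"""Performance measures and cv-vs-blind deviation statistics.

The central quantity is the AROC: the probability that a randomly chosen
binder (measured IC50 < 500 nM) is predicted to bind more strongly than a
randomly chosen non-binder, i.e. the rank-sum (Mann-Whitney) statistic with
ties counting one half.  Cross-validated performance pools the held-out
predictions of all folds into a single AROC; blind performance evaluates a
model trained on the full cross-validation set against an independent
dataset.  Deviations (cv - blind) feed the reliability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import Dataset, DatasetKey
from .partitioning import FoldAssignment, folds_to_train_test


class UndefinedPerformanceError(ValueError):
    """Performance is undefined (single-class labels or zero variance)."""


@dataclass(frozen=True)
class BinderCutoff:
    """Affinity threshold separating binders from non-binders, in nM.

    The conventional MHC-I epitope threshold is 500 nM; a peptide is a
    binder iff its measured IC50 is strictly below the threshold.
    """

    threshold: float = 500.0

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")

    def is_binder(self, ic50) -> np.ndarray:
        return np.asarray(ic50, dtype=float) < self.threshold


@dataclass
class PerformanceRecord:
    key: DatasetKey
    measure: str  # AROC | Pearson
    context: str  # cv_rnd | cv_sr | cv_gs | blind
    value: float


@dataclass
class DeviationRecord:
    key: DatasetKey
    cv_context: str
    cv_value: float
    blind_value: float
    label: str | None = None  # small | large, set by deviation_band

    @property
    def signed(self) -> float:
        return self.cv_value - self.blind_value

    @property
    def absolute(self) -> float:
        return abs(self.signed)


def aroc(predicted_ic50, measured_ic50, cutoff: BinderCutoff = BinderCutoff()) -> float:
    """Rank-based area under the ROC curve.

    Lower predicted IC50 ranks as stronger binding; tied predictions
    contribute one half.  Raises :class:`UndefinedPerformanceError` when
    the measured labels are single-class.
    """
    predicted = np.asarray(predicted_ic50, dtype=float)
    measured = np.asarray(measured_ic50, dtype=float)
    if predicted.shape != measured.shape:
        raise ValueError("prediction and measurement lists must align")
    labels = cutoff.is_binder(measured)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise UndefinedPerformanceError(
            f"AROC undefined: {n_pos} binders, {n_neg} non-binders"
        )
    # Mann-Whitney U from mid-ranks of the binding-strength score (-ic50)
    ranks = stats.rankdata(-predicted)
    u = ranks[labels].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pearson_log(predicted_ic50, measured_ic50) -> float:
    """Pearson correlation of log10-transformed IC50s."""
    predicted = np.log10(np.asarray(predicted_ic50, dtype=float))
    measured = np.log10(np.asarray(measured_ic50, dtype=float))
    if predicted.size != measured.size or predicted.size < 3:
        raise ValueError("need >= 3 aligned pairs")
    if np.ptp(predicted) == 0 or np.ptp(measured) == 0:
        raise UndefinedPerformanceError("zero variance after log transform")
    return float(stats.pearsonr(predicted, measured).statistic)


@dataclass
class CVResult:
    """Pooled cross-validated predictions and performance for one dataset."""

    record: PerformanceRecord
    pearson: float | None
    predictions: pd.DataFrame  # columns: peptide, measured, predicted, fold


def cv_performance(
    ds: Dataset,
    fa: FoldAssignment,
    fit_and_predict,
    cutoff: BinderCutoff = BinderCutoff(),
) -> CVResult:
    """Train/predict per fold, pool all held-out predictions, score once.

    A single-class test fold is tolerated (evaluation is pooled); a
    single-class pooled set raises :class:`UndefinedPerformanceError`.
    """
    rows = []
    for fold in range(fa.n_folds):
        train, test = folds_to_train_test(ds, fa, fold)
        if len(test) == 0:
            continue
        if len(train) == 0:
            raise ValueError(f"empty training set for fold {fold} of {ds.key}")
        preds = np.asarray(fit_and_predict(train, test.peptides), dtype=float)
        for m, p in zip(test.measurements, preds):
            rows.append((m.peptide, m.ic50, float(p), fold))
    pooled = pd.DataFrame(rows, columns=["peptide", "measured", "predicted", "fold"])
    value = aroc(pooled["predicted"], pooled["measured"], cutoff)
    try:
        r = pearson_log(pooled["predicted"], pooled["measured"])
    except (ValueError, UndefinedPerformanceError):
        r = None
    return CVResult(
        PerformanceRecord(ds.key, "AROC", fa.strategy, value), r, pooled
    )


def blind_performance(
    model_train: Dataset,
    blind: Dataset,
    fit_and_predict,
    cutoff: BinderCutoff = BinderCutoff(),
) -> tuple[PerformanceRecord, pd.DataFrame]:
    """Single fit on the full training set, evaluated on the blind set."""
    if model_train.key != blind.key:
        raise ValueError(f"key mismatch: {model_train.key} vs {blind.key}")
    preds = np.asarray(fit_and_predict(model_train, blind.peptides), dtype=float)
    value = aroc(preds, blind.ic50s, cutoff)
    frame = pd.DataFrame(
        {"peptide": blind.peptides, "measured": blind.ic50s, "predicted": preds}
    )
    return PerformanceRecord(blind.key, "AROC", "blind", value), frame


def deviation_band(
    records: list[DeviationRecord], reference: list[float]
) -> tuple[list[DeviationRecord], float]:
    """Label deviations small/large against a band from a reference method.

    The band half-width is the mean of the reference method's absolute
    cv-vs-blind deviations; a record is "large" iff its absolute deviation
    strictly exceeds that threshold.  The same frozen threshold applies to
    every method being labelled.
    """
    if len(reference) == 0:
        raise ValueError("reference deviations must be non-empty")
    threshold = float(np.mean(np.abs(reference)))
    for rec in records:
        # strictly greater, with a float-noise guard so a deviation equal
        # to the threshold is labelled small
        rec.label = "large" if rec.absolute > threshold + 1e-12 else "small"
    return records, threshold


def deviation_tests(diffs_by_strategy: dict[str, list[float]]) -> pd.DataFrame:
    """Significance tests on signed cv-blind deviations per strategy.

    Per strategy: one-sample t-test of the mean signed deviation against
    zero (one- and two-sided p reported), the mean and its standard error.
    Against ``cv_rnd`` (when present): paired t-tests of signed deviations
    and of absolute deviations, one-sided in the direction "the alternative
    strategy deviates less".  Lists must be aligned by dataset for pairing.
    """
    rows = []
    ref = diffs_by_strategy.get("cv_rnd")
    for strategy, diffs in diffs_by_strategy.items():
        d = np.asarray(diffs, dtype=float)
        if d.size < 2:
            raise ValueError(f"{strategy}: need >= 2 deviations")
        mean = float(d.mean())
        sem = float(stats.sem(d))
        if np.allclose(d, d[0]):
            t1 = np.inf if d[0] != 0 else 0.0
            p_two = 0.0 if d[0] != 0 else 1.0
            p_one = p_two / 2 if d[0] > 0 else 1 - p_two / 2
            if d[0] == 0:
                t1, p_two, p_one = 0.0, 1.0, 0.5
        else:
            res = stats.ttest_1samp(d, 0.0)
            t1, p_two = float(res.statistic), float(res.pvalue)
            p_one = float(stats.ttest_1samp(d, 0.0, alternative="greater").pvalue)
        row = {
            "strategy": strategy,
            "n": d.size,
            "mean": mean,
            "sem": sem,
            "t_one_sample": t1,
            "p_one_sample_two_sided": p_two,
            "p_one_sample_greater": p_one,
            "p_paired_vs_rnd_signed": np.nan,
            "p_paired_vs_rnd_absolute": np.nan,
        }
        if ref is not None and strategy != "cv_rnd":
            r = np.asarray(ref, dtype=float)
            if r.size != d.size:
                raise ValueError("paired tests require aligned deviation lists")
            row["p_paired_vs_rnd_signed"] = float(
                stats.ttest_rel(r, d, alternative="greater").pvalue
            )
            row["p_paired_vs_rnd_absolute"] = float(
                stats.ttest_rel(np.abs(r), np.abs(d), alternative="greater").pvalue
            )
        rows.append(row)
    return pd.DataFrame(rows)
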