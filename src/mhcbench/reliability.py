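"""Logistic-regression models of when a cross-validated estimate is unreliable.

Each (allele, length) dataset pair contributes a feature vector and a
binary label ("large" vs "small" cv-vs-blind deviation).  Two-feature
logistic models predict the probability of a large deviation; models are
scored by leave-one-out cross-validation (LOOCV) AROC with "large" as the
positive class.  Two named presets mirror the best training-set-only and
blind-set-only feature pairs, and a combined model takes the element-wise
maximum of the two presets' probabilities.  A probability cutoff of 0.2
splits datasets into reporting groups: benchmarks whose cross-validated
estimate can be trusted ("good") versus flagged ones ("bad").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .features import FEATURE_NAMES

#: best training-set feature pair
TRAIN_PAIR = ("log_size_cv", "ent_meas_cv")
#: best blind-set feature pair
BLIND_PAIR = ("entss_bl", "ent_pred_bl")

LARGE, SMALL = "large", "small"
DEFAULT_RIDGE = 1e-6
REPORT_CUTOFF = 0.2


@dataclass
class LogisticModel:
    feature_names: tuple[str, str]
    intercept: float
    coefficients: np.ndarray  # on standardized features
    means: np.ndarray
    scales: np.ndarray
    ridge: float

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Probability of a large deviation for raw (unstandardized) rows."""
        z = (np.asarray(x, dtype=float) - self.means) / self.scales
        logit = self.intercept + z @ self.coefficients
        return 1.0 / (1.0 + np.exp(-logit))


def _as_matrix(features, feature_pair) -> np.ndarray:
    if isinstance(features, pd.DataFrame):
        return features[list(feature_pair)].to_numpy(dtype=float)
    return np.asarray(features, dtype=float)


def _as_binary(labels) -> np.ndarray:
    y = np.asarray([1 if lab == LARGE else 0 for lab in labels])
    if y.min() == y.max():
        raise ValueError("both classes (small and large) must be present")
    return y


def fit_logistic(
    features, labels, feature_pair=TRAIN_PAIR, ridge: float = DEFAULT_RIDGE
) -> LogisticModel:
    """Penalised-maximum-likelihood logistic fit on standardized features.

    Maximises the log-likelihood minus ``(ridge / 2) * ||coefficients||^2``
    (intercept unpenalised).  The small default ridge (1e-6 on standardized
    coefficients) keeps the fit finite under complete separation, which
    happens routinely at LOOCV sample sizes.  Deterministic given the
    inputs.
    """
    x = _as_matrix(features, feature_pair)
    y = _as_binary(labels)
    if x.shape[0] < 2:
        raise ValueError("need at least 2 examples")
    means = x.mean(axis=0)
    scales = x.std(axis=0)
    scales[scales == 0] = 1.0
    z = (x - means) / scales
    clf = LogisticRegression(
        C=1.0 / max(ridge, 1e-12), solver="lbfgs", max_iter=10_000, tol=1e-10
    )
    clf.fit(z, y)
    if clf.n_iter_[0] >= 10_000:
        raise RuntimeError(f"logistic fit did not converge in {clf.n_iter_[0]} iterations")
    return LogisticModel(
        tuple(feature_pair),
        float(clf.intercept_[0]),
        clf.coef_[0].copy(),
        means,
        scales,
        ridge,
    )


def loocv_probabilities(
    features, labels, feature_pair=TRAIN_PAIR, ridge: float = DEFAULT_RIDGE
) -> np.ndarray:
    """Held-out probability of large deviation for every example."""
    x = _as_matrix(features, feature_pair)
    y_labels = list(labels)
    n = x.shape[0]
    if n < 3:
        raise ValueError("LOOCV needs at least 3 examples")
    probs = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        train_labels = [y_labels[j] for j in range(n) if j != i]
        if len(set(train_labels)) < 2:
            # single-class training fold (possible at tiny n): fall back
            # to a smoothed class prevalence so LOOCV still runs
            k = sum(1 for lab in train_labels if lab == LARGE)
            probs[i] = (k + 0.5) / (len(train_labels) + 1)
            continue
        model = fit_logistic(x[mask], train_labels, feature_pair, ridge)
        probs[i] = model.predict_proba(x[i : i + 1])[0]
    return probs


def loocv_evaluate(
    features, labels, feature_pair=TRAIN_PAIR, ridge: float = DEFAULT_RIDGE
) -> tuple[np.ndarray, float]:
    """LOOCV held-out probabilities and their AROC against the labels."""
    probs = loocv_probabilities(features, labels, feature_pair, ridge)
    return probs, probability_aroc(probs, labels)


def probability_aroc(probs, labels) -> float:
    """AROC of probabilities with 'large' as the positive class."""
    y = _as_binary(labels)
    from scipy.stats import rankdata

    ranks = rankdata(probs)
    n_pos = int(y.sum())
    n_neg = y.size - n_pos
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2
    return float(u / (n_pos * n_neg))


def pairwise_feature_search(
    features: pd.DataFrame,
    labels,
    ridge: float = DEFAULT_RIDGE,
    restrict_to: list[str] | None = None,
) -> pd.DataFrame:
    """LOOCV AROC for every unordered feature pair, ranked best-first.

    ``restrict_to`` limits the candidate features, e.g. to the cv-only
    (:data:`~mhcbench.features.CV_FEATURES`) or blind-only
    (:data:`~mhcbench.features.BLIND_FEATURES`) subsets, mirroring the
    separate training-set and blind-set model searches.
    """
    names = restrict_to if restrict_to is not None else FEATURE_NAMES
    names = [n for n in names if n in features.columns]
    rows = []
    for a, b in itertools.combinations(names, 2):
        _, auc = loocv_evaluate(features, labels, (a, b), ridge)
        rows.append({"feature_a": a, "feature_b": b, "loocv_aroc": auc})
    out = pd.DataFrame(rows).sort_values(
        ["loocv_aroc", "feature_a", "feature_b"], ascending=[False, True, True]
    )
    return out.reset_index(drop=True)


def combine_max(prob_a, prob_b) -> np.ndarray:
    """Element-wise maximum of two models' probabilities of large deviation."""
    a = np.asarray(prob_a, dtype=float)
    b = np.asarray(prob_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("probability lists must align")
    return np.maximum(a, b)


def loocv_combined(
    features: pd.DataFrame,
    labels,
    pair_a=TRAIN_PAIR,
    pair_b=BLIND_PAIR,
    ridge: float = DEFAULT_RIDGE,
) -> tuple[np.ndarray, float]:
    """LOOCV of the max-combined model with simultaneous exclusion.

    The held-out example is excluded from both component fits in the same
    LOOCV round — the only leakage-free reading of combining two LOOCV'd
    models.
    """
    pa = loocv_probabilities(features, labels, pair_a, ridge)
    pb = loocv_probabilities(features, labels, pair_b, ridge)
    combined = combine_max(pa, pb)
    return combined, probability_aroc(combined, labels)


def reporting_split(probabilities, cutoff: float = REPORT_CUTOFF) -> np.ndarray:
    """Partition datasets into 'good' / 'bad' at a strict probability cutoff.

    'bad' means the model flags the cross-validated estimate as likely
    unreliable (probability of large deviation strictly above the cutoff).
    """
    probs = np.asarray(probabilities, dtype=float)
    return np.where(probs > cutoff, "bad", "good")
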