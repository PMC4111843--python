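"""Dataset-composition features for a (cross-validation, blind) dataset pair.

Ten features summarise how large and how diverse the two datasets are:

- ``log_size_cv`` / ``log_size_bl``: natural log of the dataset sizes;
- ``entss_cv`` / ``entss_bl``: evenness of sequence-space coverage — the
  per-position Shannon entropy (nats) of the empirical amino-acid
  distribution, averaged over positions;
- ``ent_meas_*`` / ``ent_pred_*``: spread of measured / predicted
  affinities — entropy of log10(IC50) binned on [0, 5) with unit bins;
- ``prbol_meas`` / ``prbol_pred``: overlap of the cv and blind affinity
  histograms, the bin-wise sum of minima.

Small, unevenly sampled datasets and affinity distributions crowded around
the 500 nM binder cutoff are exactly the conditions under which a
cross-validated performance estimate stops generalising; these features
make those conditions measurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import AMINO_ACIDS, Dataset

FEATURE_NAMES = [
    "log_size_cv",
    "log_size_bl",
    "entss_cv",
    "entss_bl",
    "ent_meas_cv",
    "ent_meas_bl",
    "ent_pred_cv",
    "ent_pred_bl",
    "prbol_meas",
    "prbol_pred",
]

#: features computable from the cross-validation (training) set alone
CV_FEATURES = ["log_size_cv", "entss_cv", "ent_meas_cv", "ent_pred_cv"]
#: features computable from the blind set alone
BLIND_FEATURES = ["log_size_bl", "entss_bl", "ent_meas_bl", "ent_pred_bl"]

_N_BINS = 5


def _entropy(p: np.ndarray) -> float:
    """Shannon entropy in nats with the 0*log(0) = 0 convention."""
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def positional_entropy(peptides: list[str]) -> float:
    """Mean per-position amino-acid entropy (nats); 0 for constant sets."""
    if not peptides:
        raise ValueError("empty peptide list")
    lengths = {len(p) for p in peptides}
    if len(lengths) != 1:
        raise ValueError(f"mixed peptide lengths: {sorted(lengths)}")
    mat = np.array([[aa for aa in p] for p in peptides])
    ents = []
    for pos in range(mat.shape[1]):
        _, counts = np.unique(mat[:, pos], return_counts=True)
        ents.append(_entropy(counts / counts.sum()))
    return float(np.mean(ents))


@dataclass
class AffinityHistogram:
    """Empirical distribution of log10(IC50) over unit bins [0,1) .. [4,5).

    Values outside [0, 5) are clamped into the terminal bins; IC50s between
    1 nM and 100 uM fall inside the range by construction.
    """

    probabilities: np.ndarray

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if self.probabilities.shape != (_N_BINS,):
            raise ValueError("histogram must have exactly 5 bins")
        if np.any(self.probabilities < 0) or not np.isclose(
            self.probabilities.sum(), 1.0
        ):
            raise ValueError("probabilities must be non-negative and sum to 1")


def affinity_histogram(ic50s) -> AffinityHistogram:
    ic50s = np.asarray(ic50s, dtype=float)
    if ic50s.size == 0:
        raise ValueError("empty affinity list")
    if np.any(ic50s <= 0):
        raise ValueError("ic50 must be positive")
    logs = np.clip(np.log10(ic50s), 0.0, np.nextafter(float(_N_BINS), 0))
    bins = np.floor(logs).astype(int)
    counts = np.bincount(bins, minlength=_N_BINS).astype(float)
    return AffinityHistogram(counts / counts.sum())


def histogram_entropy(h: AffinityHistogram) -> float:
    return _entropy(h.probabilities)


def histogram_overlap(hx: AffinityHistogram, hy: AffinityHistogram) -> float:
    """Sum of bin-wise minima; 1 for identical, 0 for disjoint distributions."""
    return float(np.minimum(hx.probabilities, hy.probabilities).sum())


@dataclass
class FeatureVector:
    log_size_cv: float
    log_size_bl: float
    entss_cv: float
    entss_bl: float
    ent_meas_cv: float
    ent_meas_bl: float
    ent_pred_cv: float
    ent_pred_bl: float
    prbol_meas: float
    prbol_pred: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}


def feature_vector(
    cv: Dataset, blind: Dataset, cv_predictions, blind_predictions
) -> FeatureVector:
    """Assemble the ten composition features for a cv/blind dataset pair.

    ``cv_predictions`` are the pooled cross-validated predicted IC50s for
    the cv set; ``blind_predictions`` the blind-set predictions of the
    model trained on the full cv set.  Both aligned to their datasets.
    """
    if len(cv) == 0 or len(blind) == 0:
        raise ValueError("datasets must be non-empty")
    if cv.key != blind.key:
        raise ValueError(f"key mismatch: {cv.key} vs {blind.key}")
    cv_predictions = np.asarray(cv_predictions, dtype=float)
    blind_predictions = np.asarray(blind_predictions, dtype=float)
    if cv_predictions.size != len(cv) or blind_predictions.size != len(blind):
        raise ValueError("predictions must align with their datasets")

    h_meas_cv = affinity_histogram(cv.ic50s)
    h_meas_bl = affinity_histogram(blind.ic50s)
    h_pred_cv = affinity_histogram(cv_predictions)
    h_pred_bl = affinity_histogram(blind_predictions)
    return FeatureVector(
        log_size_cv=float(np.log(len(cv))),
        log_size_bl=float(np.log(len(blind))),
        entss_cv=positional_entropy(cv.peptides),
        entss_bl=positional_entropy(blind.peptides),
        ent_meas_cv=histogram_entropy(h_meas_cv),
        ent_meas_bl=histogram_entropy(h_meas_bl),
        ent_pred_cv=histogram_entropy(h_pred_cv),
        ent_pred_bl=histogram_entropy(h_pred_bl),
        prbol_meas=histogram_overlap(h_meas_cv, h_meas_bl),
        prbol_pred=histogram_overlap(h_pred_cv, h_pred_bl),
    )


MAX_ENTSS = float(np.log(len(AMINO_ACIDS)))
MAX_ENT_AFFINITY = float(np.log(_N_BINS))
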