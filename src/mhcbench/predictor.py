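"""A stand-in MHC-I binding predictor: a ridge-regression PSSM.

Affinities are regressed on the standard transformed scale
``y = 1 - log(ic50) / log(50000)`` (so 1 nM -> 1, 50000 nM -> 0) against a
one-indicator-per-(position, residue) encoding, giving a position-specific
scoring matrix per (allele, length) dataset.  This is a deliberately plain
linear model — enough specificity for the benchmark pipeline to have signal
to measure, with a closed-form deterministic fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AMINO_ACIDS, Dataset, DatasetKey

MAX_IC50 = 50000.0
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
_LOG_MAX = np.log(MAX_IC50)


def transform_affinity(ic50):
    """IC50 (nM) -> score in [0, 1]: 1 - log(ic50)/log(50000), clamped."""
    ic50 = np.asarray(ic50, dtype=float)
    if np.any(ic50 <= 0):
        raise ValueError("ic50 must be positive")
    return np.clip(1.0 - np.log(ic50) / _LOG_MAX, 0.0, 1.0)


def inverse_transform_affinity(score):
    """Score in [0, 1] -> IC50 in nM (inverse of :func:`transform_affinity`)."""
    score = np.asarray(score, dtype=float)
    return MAX_IC50 ** (1.0 - score)


def encode_peptides(peptides: list[str], length: int) -> np.ndarray:
    """(n, 20*length) indicator matrix, one block of 20 per position."""
    x = np.zeros((len(peptides), 20 * length))
    for r, pep in enumerate(peptides):
        if len(pep) != length:
            raise ValueError(f"peptide {pep!r} does not have length {length}")
        for pos, aa in enumerate(pep):
            x[r, pos * 20 + _AA_INDEX[aa]] = 1.0
    return x


@dataclass
class PSSMModel:
    key: DatasetKey
    weights: np.ndarray  # (length, 20)
    offset: float
    ridge_lambda: float

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.key.length, 20):
            raise ValueError(
                f"weights shape {self.weights.shape} != ({self.key.length}, 20)"
            )
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.offset):
            raise ValueError("non-finite model parameters")

    def score(self, peptides: list[str]) -> np.ndarray:
        """Transformed-scale score: offset + sum of per-position weights."""
        x = encode_peptides(peptides, self.key.length)
        return self.offset + x @ self.weights.ravel()


def fit_pssm(train: Dataset, ridge_lambda: float = 1.0, seed: int = 0) -> PSSMModel:
    """Ridge-regression PSSM fit by normal equations.

    Minimises ``||y - (offset + X w)||^2 + ridge_lambda * ||w||^2`` where y
    are transformed affinities; the offset is unpenalised.  ``seed`` is part
    of the predictor interface but unused: the solve is closed-form.
    """
    if len(train) == 0:
        raise ValueError("empty training set")
    length = train.key.length
    x = encode_peptides(train.peptides, length)
    y = transform_affinity(train.ic50s)

    n_feat = x.shape[1]
    xa = np.hstack([x, np.ones((x.shape[0], 1))])
    penalty = np.diag(np.r_[np.full(n_feat, ridge_lambda), 0.0])
    # tiny jitter on the intercept keeps the system nonsingular at n=1
    penalty[-1, -1] = 1e-10
    beta = np.linalg.solve(xa.T @ xa + penalty, xa.T @ y)
    return PSSMModel(train.key, beta[:n_feat].reshape(length, 20), float(beta[-1]), ridge_lambda)


def predict(model: PSSMModel, peptides: list[str]) -> np.ndarray:
    """Predicted IC50s (nM) for same-length peptides."""
    return inverse_transform_affinity(np.clip(model.score(peptides), 0.0, 1.0))


def make_ridge_predictor(ridge_lambda: float = 1.0):
    """A fit-and-predict callable: (train Dataset, peptides) -> predicted IC50s."""

    def fit_and_predict(train: Dataset, peptides: list[str]) -> np.ndarray:
        return predict(fit_pssm(train, ridge_lambda), peptides)

    return fit_and_predict


def save_pssm(model: PSSMModel, path) -> None:
    """TSV serialization: rows = positions, columns = residues, then offset."""
    frame = pd.DataFrame(
        model.weights,
        columns=list(AMINO_ACIDS),
        index=[f"pos{i+1}" for i in range(model.key.length)],
    )
    with open(path, "w") as fh:
        fh.write(f"# allele\t{model.key.allele}\n")
        fh.write(f"# length\t{model.key.length}\n")
        fh.write(f"# ridge_lambda\t{model.ridge_lambda}\n")
        fh.write(f"# offset\t{model.offset!r}\n")
        frame.to_csv(fh, sep="\t")


def load_pssm(path) -> PSSMModel:
    meta = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            k, v = line[1:].strip().split("\t")
            meta[k] = v
            body_start = i + 1
        else:
            break
    frame = pd.read_csv(
        pd.io.common.StringIO("".join(lines[body_start:])), sep="\t", index_col=0
    )
    key = DatasetKey(meta["allele"], int(meta["length"]))
    return PSSMModel(
        key, frame[list(AMINO_ACIDS)].to_numpy(), float(meta["offset"]), float(meta["ridge_lambda"])
    )
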