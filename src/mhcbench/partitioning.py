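"""Cross-validation fold assignment: random, similarity-reduced, grouped.

Three 5-fold strategies are provided:

``cv_rnd``
    plain random balanced partitioning of a dataset;
``cv_sr``
    Hobohm-1 similarity reduction first (separately within binders and
    non-binders), then random partitioning of the survivors;
``cv_gs``
    similar peptides are kept but grouped: similarity clusters computed
    over the whole collection are each assigned to a single fold, so no
    similar pair spans a train/test boundary and any peptide measured on
    several alleles lands in the same fold everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import BindingCollection, Dataset, DatasetKey
from .similarity import PeptideGraph, SimilarityPolicy, similarity_reduce_dataset


@dataclass
class FoldAssignment:
    strategy: str  # cv_rnd | cv_sr | cv_gs
    n_folds: int
    assignment: dict[tuple[DatasetKey, str], int]
    seed: int | None = None

    def fold_of(self, key: DatasetKey, peptide: str) -> int:
        return self.assignment[(key, peptide)]

    def peptides_for(self, key: DatasetKey) -> list[str]:
        return [p for (k, p) in self.assignment if k == key]


def _deal(peptides: list[str], n_folds: int, rng: np.random.Generator) -> dict[str, int]:
    """Shuffle then deal round-robin: fold sizes differ by at most one."""
    order = list(peptides)
    perm = rng.permutation(len(order))
    return {order[p]: i % n_folds for i, p in enumerate(perm)}


def partition_random(ds: Dataset, n_folds: int = 5, seed: int = 0) -> FoldAssignment:
    if len(ds) < n_folds:
        raise ValueError(f"dataset {ds.key} has {len(ds)} < {n_folds} measurements")
    rng = np.random.default_rng(seed)
    folds = _deal(ds.peptides, n_folds, rng)
    return FoldAssignment(
        "cv_rnd", n_folds, {(ds.key, p): f for p, f in folds.items()}, seed
    )


def partition_sr(
    ds: Dataset,
    policy: SimilarityPolicy,
    binder_cutoff: float = 500.0,
    n_folds: int = 5,
    seed: int = 0,
) -> FoldAssignment:
    reduced = similarity_reduce_dataset(ds, policy, binder_cutoff)
    if len(reduced) < n_folds:
        raise ValueError(
            f"dataset {ds.key} reduced to {len(reduced)} < {n_folds} measurements"
        )
    rng = np.random.default_rng(seed)
    folds = _deal(reduced.peptides, n_folds, rng)
    return FoldAssignment(
        "cv_sr", n_folds, {(ds.key, p): f for p, f in folds.items()}, seed
    )


def partition_gs(
    collection: BindingCollection, graph: PeptideGraph, n_folds: int = 5
) -> FoldAssignment:
    """Cluster-grouped fold assignment, consistent across alleles.

    Clusters (connected components of the similarity graph) are processed
    from largest to smallest; each cluster goes whole into one fold.  The
    fold is chosen by finding the allele with the most measurements inside
    the cluster and taking that allele's currently least-loaded fold, with
    running per-(allele, fold) peptide counts updated after each cluster.
    Ties: allele by name, fold by lowest index; cluster-size ties by the
    lexicographically smallest member peptide (pre-sorted in the graph).
    """
    allele_of_peptide: dict[str, list[str]] = {}
    for ds in collection:
        for pep in ds.peptides:
            allele_of_peptide.setdefault(pep, []).append(ds.key.allele)

    counts: dict[tuple[str, int], int] = {}
    fold_of: dict[str, int] = {}
    for cluster in graph.clusters:
        per_allele: dict[str, int] = {}
        for pep in cluster:
            for allele in allele_of_peptide.get(pep, []):
                per_allele[allele] = per_allele.get(allele, 0) + 1
        if not per_allele:
            continue
        top_allele = max(sorted(per_allele), key=lambda a: per_allele[a])
        fold = min(range(n_folds), key=lambda f: counts.get((top_allele, f), 0))
        for pep in cluster:
            fold_of[pep] = fold
            for allele in allele_of_peptide.get(pep, []):
                counts[(allele, fold)] = counts.get((allele, fold), 0) + 1

    assignment = {
        (ds.key, pep): fold_of[pep] for ds in collection for pep in ds.peptides
    }
    return FoldAssignment("cv_gs", n_folds, assignment)


def folds_to_train_test(
    ds: Dataset, fa: FoldAssignment, test_fold: int
) -> tuple[Dataset, Dataset]:
    """Split a dataset's assigned measurements into train/test for one fold."""
    if not (0 <= test_fold < fa.n_folds):
        raise ValueError(f"test_fold {test_fold} out of range [0, {fa.n_folds})")
    train, test = [], []
    for m in ds.measurements:
        fold = fa.assignment.get((ds.key, m.peptide))
        if fold is None:
            continue  # removed by similarity reduction
        (test if fold == test_fold else train).append(m)
    return Dataset(ds.key, train), Dataset(ds.key, test)
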