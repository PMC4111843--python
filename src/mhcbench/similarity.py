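"""Peptide sequence similarity: identity, Hobohm-1 reduction and clustering.

Two peptides are "similar" when they have the same length and at least a
threshold fraction (default 80%) of identical residues position by
position, ungapped.  This is the redundancy notion used throughout the
benchmark: redundancy reduction removes similar peptides, and the grouped
cross-validation strategy confines whole similarity clusters to single
folds so that no similar pair ever spans a train/test boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import BindingCollection, Dataset


@dataclass(frozen=True)
class SimilarityPolicy:
    """Similarity definition: identity threshold, equal lengths required."""

    identity_threshold: float = 0.8
    require_equal_length: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.identity_threshold <= 1):
            raise ValueError("identity_threshold must be in (0, 1]")
        if not self.require_equal_length:
            raise ValueError("cross-length similarity is not defined")


def sequence_identity(a: str, b: str) -> float:
    """Ungapped fractional identity; 0.0 by convention for unequal lengths."""
    if not a or not b:
        raise ValueError("peptides must be non-empty")
    if len(a) != len(b):
        return 0.0
    return sum(x == y for x, y in zip(a, b)) / len(a)


def is_similar(a: str, b: str, policy: SimilarityPolicy) -> bool:
    return len(a) == len(b) and sequence_identity(a, b) >= policy.identity_threshold


def has_similar(peptide: str, candidates, policy: SimilarityPolicy) -> bool:
    """True if ``peptide`` is similar to any candidate (same-length only)."""
    return any(
        len(c) == len(peptide) and is_similar(peptide, c, policy) for c in candidates
    )


def _encode(peptides: list[str]) -> np.ndarray:
    """Same-length peptides as an (n, L) byte matrix."""
    return np.frombuffer("".join(peptides).encode("ascii"), dtype=np.uint8).reshape(
        len(peptides), -1
    )


def neighbor_pairs(peptides: list[str], policy: SimilarityPolicy) -> list[tuple[int, int]]:
    """Index pairs (i < j) of similar peptides; peptides need not share length."""
    by_length: dict[int, list[int]] = {}
    for i, p in enumerate(peptides):
        by_length.setdefault(len(p), []).append(i)

    pairs: list[tuple[int, int]] = []
    for length, idx in by_length.items():
        if len(idx) < 2:
            continue
        mat = _encode([peptides[i] for i in idx])
        min_matches = int(np.ceil(policy.identity_threshold * length - 1e-9))
        # chunk rows to bound the broadcast at ~32M byte comparisons
        chunk = max(1, 32_000_000 // (mat.shape[0] * length))
        for start in range(0, len(idx), chunk):
            block = mat[start : start + chunk]
            matches = (block[:, None, :] == mat[None, :, :]).sum(axis=2)
            rows, cols = np.nonzero(matches >= min_matches)
            for r, c in zip(rows, cols):
                gi, gj = idx[start + r], idx[c]
                if gi < gj:
                    pairs.append((gi, gj))
    return pairs


def neighbor_counts(peptides: list[str], policy: SimilarityPolicy) -> list[int]:
    """Number of similar peptides (neighbors) each peptide has in the list."""
    counts = [0] * len(peptides)
    for i, j in neighbor_pairs(peptides, policy):
        counts[i] += 1
        counts[j] += 1
    return counts


def hobohm_reduce(peptides: list[str], policy: SimilarityPolicy) -> list[str]:
    """Hobohm-1-like redundancy reduction.

    Peptides are sorted by ascending neighbor count (ties broken by the
    peptide string) and greedily accepted into an initially empty set if
    not similar to any already-accepted peptide.  Neighbor counts are
    computed once on the input, not updated during acceptance.  The result
    contains no similar pair.
    """
    if len(set(peptides)) != len(peptides):
        raise ValueError("peptides must be unique")
    counts = neighbor_counts(peptides, policy)
    order = sorted(range(len(peptides)), key=lambda i: (counts[i], peptides[i]))

    adjacency: dict[int, set[int]] = {i: set() for i in range(len(peptides))}
    for i, j in neighbor_pairs(peptides, policy):
        adjacency[i].add(j)
        adjacency[j].add(i)

    accepted: list[int] = []
    accepted_set: set[int] = set()
    for i in order:
        if adjacency[i].isdisjoint(accepted_set):
            accepted.append(i)
            accepted_set.add(i)
    keep = sorted(accepted)
    return [peptides[i] for i in keep]


def similarity_reduce_dataset(
    ds: Dataset, policy: SimilarityPolicy, binder_cutoff: float = 500.0
) -> Dataset:
    """Redundancy-reduce a dataset separately within binders and non-binders.

    Binders (IC50 < ``binder_cutoff`` nM) and non-binders are Hobohm-reduced
    independently and the two survivors unioned, so the output may still
    contain a binder similar to a non-binder — the per-class procedure
    permits this.
    """
    if len(ds) == 0:
        raise ValueError("dataset is empty")
    binders = [m.peptide for m in ds.measurements if m.ic50 < binder_cutoff]
    nonbinders = [m.peptide for m in ds.measurements if m.ic50 >= binder_cutoff]
    survivors = set(hobohm_reduce(binders, policy)) | set(
        hobohm_reduce(nonbinders, policy)
    )
    return ds.subset(survivors)


@dataclass
class PeptideGraph:
    """Undirected similarity graph over the peptides of a whole collection.

    Nodes are distinct peptide strings pooled across alleles; edges join
    similar peptides; ``clusters`` are the connected components, sorted for
    deterministic downstream processing (descending size, then by smallest
    member peptide).
    """

    graph: nx.Graph
    clusters: list[list[str]]

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)


def build_peptide_graph(
    collection: BindingCollection, policy: SimilarityPolicy
) -> PeptideGraph:
    peptides = sorted(collection.all_peptides())
    g: nx.Graph = nx.Graph()
    g.add_nodes_from(peptides)
    g.add_edges_from(
        (peptides[i], peptides[j]) for i, j in neighbor_pairs(peptides, policy)
    )
    components = [sorted(c) for c in nx.connected_components(g)]
    components.sort(key=lambda c: (-len(c), c[0]))
    return PeptideGraph(g, components)
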