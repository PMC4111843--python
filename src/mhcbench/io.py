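"""Reading, writing and assembling peptide:MHC binding-affinity benchmark tables.

The benchmark dialect is a tab-separated file with a header row naming at
least the columns ``species``, ``mhc``, ``peptide_length``, ``sequence``,
``inequality`` and ``meas`` (extra columns are ignored).  Each row is one
IC50 measurement of a peptide against an MHC allele.  Measurements are
grouped into datasets keyed by the (allele, peptide length) pair, which is
the unit at which binding predictors are trained and benchmarked.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import pandas as pd

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)

#: canonical TSV column names
TSV_COLUMNS = ["species", "mhc", "peptide_length", "sequence", "inequality", "meas"]

_QUALIFIER_FROM_SYMBOL = {"=": "exact", "<": "less-than", ">": "greater-than"}
_SYMBOL_FROM_QUALIFIER = {v: k for k, v in _QUALIFIER_FROM_SYMBOL.items()}
QUALIFIERS = frozenset(_QUALIFIER_FROM_SYMBOL.values())


class MeasurementError(ValueError):
    """A row violates the measurement invariants."""


@dataclass(frozen=True)
class Measurement:
    """One peptide/allele/IC50 record.

    ``ic50`` is the half-maximal inhibitory concentration in nM; lower
    values mean stronger binding.  ``qualifier`` records inequality
    annotations from the assay ("<", ">") but all downstream computation
    treats the value as exact.
    """

    species: str
    allele: str
    length: int
    peptide: str
    qualifier: str
    ic50: float

    def __post_init__(self) -> None:
        if len(self.peptide) != self.length:
            raise MeasurementError(
                f"peptide {self.peptide!r} has length {len(self.peptide)}, "
                f"row claims {self.length}"
            )
        if not self.peptide or not _AA_SET.issuperset(self.peptide):
            raise MeasurementError(
                f"peptide {self.peptide!r} contains non-canonical residues"
            )
        if not (self.ic50 > 0 and math.isfinite(self.ic50)):
            raise MeasurementError(f"ic50 must be a positive real, got {self.ic50!r}")
        if self.qualifier not in QUALIFIERS:
            raise MeasurementError(f"unknown qualifier {self.qualifier!r}")


@dataclass(frozen=True, order=True)
class DatasetKey:
    """(MHC allele, peptide length) pair identifying one benchmark dataset."""

    allele: str
    length: int


@dataclass
class Dataset:
    """All measurements for one (allele, length) combination.

    Peptides are unique within a dataset; duplicate rows are merged
    upstream by :func:`read_binding_tsv` / :func:`build_collection`.
    """

    key: DatasetKey
    measurements: list[Measurement]

    def __post_init__(self) -> None:
        for m in self.measurements:
            if m.allele != self.key.allele or m.length != self.key.length:
                raise ValueError(f"measurement {m} does not match key {self.key}")
        peps = [m.peptide for m in self.measurements]
        if len(set(peps)) != len(peps):
            raise ValueError(f"duplicate peptides within dataset {self.key}")

    def __len__(self) -> int:
        return len(self.measurements)

    @property
    def peptides(self) -> list[str]:
        return [m.peptide for m in self.measurements]

    @property
    def ic50s(self) -> list[float]:
        return [m.ic50 for m in self.measurements]

    def subset(self, peptides: set[str]) -> "Dataset":
        return Dataset(self.key, [m for m in self.measurements if m.peptide in peptides])


@dataclass
class BindingCollection:
    """A labelled mapping of DatasetKey -> Dataset (e.g. one data release)."""

    datasets: dict[DatasetKey, Dataset]
    label: str
    n_rejected: int = 0
    rejection_reasons: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.datasets)

    def __iter__(self):
        return iter(self.datasets.values())

    @property
    def n_measurements(self) -> int:
        return sum(len(ds) for ds in self.datasets.values())

    def all_peptides(self) -> set[str]:
        """Distinct peptides pooled over all datasets."""
        out: set[str] = set()
        for ds in self:
            out.update(ds.peptides)
        return out


def _merge_duplicates(rows: list[Measurement]) -> list[Measurement]:
    """Merge duplicate (allele, length, peptide) rows.

    IC50s are averaged on the log scale (geometric mean), matching the log
    scale on which affinities are evaluated; the qualifier survives only if
    all duplicates agree, otherwise it falls back to "exact".
    """
    by_pep: dict[str, list[Measurement]] = {}
    for m in rows:
        by_pep.setdefault(m.peptide, []).append(m)
    out = []
    for group in by_pep.values():
        if len(group) == 1:
            out.append(group[0])
            continue
        gm = math.exp(sum(math.log(m.ic50) for m in group) / len(group))
        quals = {m.qualifier for m in group}
        qual = group[0].qualifier if len(quals) == 1 else "exact"
        out.append(replace(group[0], ic50=gm, qualifier=qual))
    return out


def build_collection(measurements: list[Measurement], label: str) -> BindingCollection:
    """Group measurements into (allele, length) datasets, merging duplicates."""
    by_key: dict[DatasetKey, list[Measurement]] = {}
    for m in measurements:
        by_key.setdefault(DatasetKey(m.allele, m.length), []).append(m)
    datasets = {
        key: Dataset(key, _merge_duplicates(rows)) for key, rows in sorted(by_key.items())
    }
    return BindingCollection(datasets, label)


def read_binding_tsv(path, label: str) -> BindingCollection:
    """Read a benchmark TSV into a :class:`BindingCollection`.

    Rows violating the measurement invariants (bad residues, length
    mismatch, non-positive or unparseable IC50) are rejected, counted on
    the returned collection and surfaced in ``rejection_reasons``.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str, comment=None)
    missing = [c for c in TSV_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if frame.empty:
        warnings.warn(f"{path}: no data rows", stacklevel=2)
        return BindingCollection({}, label)

    kept: list[Measurement] = []
    reasons: list[str] = []
    for idx, row in frame.iterrows():
        try:
            qual = str(row["inequality"]).strip()
            qual = _QUALIFIER_FROM_SYMBOL.get(qual, qual)
            m = Measurement(
                species=str(row["species"]).strip(),
                allele=str(row["mhc"]).strip(),
                length=int(row["peptide_length"]),
                peptide=str(row["sequence"]).strip(),
                qualifier=qual,
                ic50=float(row["meas"]),
            )
        except (MeasurementError, ValueError) as exc:
            reasons.append(f"row {idx}: {exc}")
            continue
        kept.append(m)

    collection = build_collection(kept, label)
    collection.n_rejected = len(reasons)
    collection.rejection_reasons = reasons
    return collection


def write_binding_tsv(collection: BindingCollection, path) -> None:
    """Write a collection back to the benchmark TSV dialect."""
    records = [
        {
            "species": m.species,
            "mhc": m.allele,
            "peptide_length": m.length,
            "sequence": m.peptide,
            "inequality": _SYMBOL_FROM_QUALIFIER[m.qualifier],
            "meas": m.ic50,
        }
        for ds in collection
        for m in ds.measurements
    ]
    pd.DataFrame(records, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def filter_min_size(collection: BindingCollection, min_size: int) -> BindingCollection:
    """Keep only datasets with at least ``min_size`` measurements.

    The benchmark convention is ``min_size=50``: smaller (allele, length)
    sets give too unstable a performance estimate to report.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    kept = {k: ds for k, ds in collection.datasets.items() if len(ds) >= min_size}
    return BindingCollection(kept, collection.label)


def construct_blind(
    old: BindingCollection,
    new: BindingCollection,
    identity_threshold: float = 0.8,
    min_size: int = 50,
) -> BindingCollection:
    """Build a blind benchmark from two data releases.

    Starting from measurements present in ``new`` but not in ``old`` (keyed
    by allele, length and peptide), peptides with >= ``identity_threshold``
    ungapped identity to any same-length ``old`` peptide are removed, the
    result is restricted to (allele, length) combinations present in
    ``old``, and datasets below ``min_size`` are dropped.
    """
    from .similarity import SimilarityPolicy, has_similar

    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must be in (0, 1]")
    policy = SimilarityPolicy(identity_threshold)

    old_triples = {
        (m.allele, m.length, m.peptide) for ds in old for m in ds.measurements
    }
    old_by_length: dict[int, list[str]] = {}
    for pep in old.all_peptides():
        old_by_length.setdefault(len(pep), []).append(pep)

    kept: list[Measurement] = []
    for ds in new:
        if ds.key not in old.datasets:
            continue
        for m in ds.measurements:
            if (m.allele, m.length, m.peptide) in old_triples:
                continue
            if has_similar(m.peptide, old_by_length.get(m.length, []), policy):
                continue
            kept.append(m)

    blind = build_collection(kept, "Blind")
    return filter_min_size(blind, min_size)
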