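"""Domain types shared across the pipeline.

The package passes a small set of concrete containers between stages:
count tables, per-sample metadata, taxonomy lookups, distance matrices,
microsatellite genotypes and aligned sequence sets.  Phylogenies are plain
``skbio.TreeNode`` objects and are not wrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

DNA = "DNA"
RNA = "RNA"

TAXONOMY_RANKS = ("phylum", "class", "order", "family", "genus")

#: metadata columns, in canonical serialization order
METADATA_COLUMNS = (
    "group",
    "farm_id",
    "x_km",
    "y_km",
    "sex",
    "weight_g",
    "body_length_mm",
    "tail_length_mm",
    "pregnant",
    "concentration_dna",
    "concentration_rna",
    "is_negative_control",
)


@dataclass
class FeatureTable:
    """Integer feature-by-sample count table tagged with its nucleic acid.

    ``counts`` has shape ``(len(feature_ids), len(sample_ids))``.
    ``dataset_label`` distinguishes the standing (DNA) from the active
    (RNA) community profile of the same individuals.
    """

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    dataset_label: str = DNA

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )

    # -- accessors ---------------------------------------------------------
    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_index(sample_id)]

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def relative_abundance(self) -> np.ndarray:
        """Column-normalized counts; all-zero columns stay zero."""
        sums = self.sample_sums().astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / sums[None, :]
        rel[:, sums == 0] = 0.0
        return rel

    # -- manipulation ------------------------------------------------------
    def copy(self) -> "FeatureTable":
        return FeatureTable(
            list(self.feature_ids), list(self.sample_ids),
            self.counts.copy(), self.dataset_label,
        )

    def drop_features(self, feature_ids: Iterable[str]) -> "FeatureTable":
        drop = set(feature_ids)
        keep = [i for i, f in enumerate(self.feature_ids) if f not in drop]
        return FeatureTable(
            [self.feature_ids[i] for i in keep], list(self.sample_ids),
            self.counts[keep, :], self.dataset_label,
        )

    def subset_samples(self, sample_ids: Iterable[str]) -> "FeatureTable":
        wanted = list(sample_ids)
        idx = [self.sample_index(s) for s in wanted]
        return FeatureTable(
            list(self.feature_ids), wanted, self.counts[:, idx], self.dataset_label
        )

    def drop_empty_features(self) -> "FeatureTable":
        keep = self.counts.sum(axis=1) > 0
        return FeatureTable(
            [f for f, k in zip(self.feature_ids, keep) if k],
            list(self.sample_ids), self.counts[keep, :], self.dataset_label,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=pd.Index(self.feature_ids, name="feature_id"),
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, dataset_label: str = DNA) -> "FeatureTable":
        return cls(list(frame.index.astype(str)), list(frame.columns.astype(str)),
                   frame.to_numpy(), dataset_label)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        return (
            self.feature_ids == other.feature_ids
            and self.sample_ids == other.sample_ids
            and self.dataset_label == other.dataset_label
            and np.array_equal(self.counts, other.counts)
        )


class SampleMetadata:
    """Per-sample records: group, farm, coordinates, host covariates,
    nucleic-acid concentrations and the negative-control flag.

    Backed by a DataFrame indexed by ``sample_id`` with the columns in
    :data:`METADATA_COLUMNS`.  Missing values are NaN/None in memory and
    empty strings on disk.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in METADATA_COLUMNS:
            if col not in frame.columns:
                frame[col] = np.nan
        frame = frame[list(METADATA_COLUMNS)]
        frame.index = frame.index.astype(str)
        frame.index.name = "sample_id"
        for col in ("pregnant", "is_negative_control"):
            frame[col] = frame[col].map(_as_bool)
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def groups(self) -> pd.Series:
        return self.frame["group"]

    def group_samples(self, group: str, include_controls: bool = False) -> list[str]:
        mask = self.frame["group"] == group
        if not include_controls:
            mask &= ~self.is_control()
        return list(self.frame.index[mask])

    def is_control(self) -> pd.Series:
        return self.frame["is_negative_control"].fillna(False).astype(bool)

    def control_ids(self) -> list[str]:
        return list(self.frame.index[self.is_control()])

    def concentrations(self, dataset_label: str) -> pd.Series:
        col = "concentration_dna" if dataset_label == DNA else "concentration_rna"
        return self.frame[col]

    def coordinates(self) -> pd.DataFrame:
        return self.frame[["x_km", "y_km"]]

    def subset(self, sample_ids: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        a, b = self.frame, other.frame
        if list(a.index) != list(b.index):
            return False
        for col in METADATA_COLUMNS:
            x, y = a[col], b[col]
            if x.dtype.kind == "f" or y.dtype.kind == "f":
                if not np.allclose(x.astype(float), y.astype(float), equal_nan=True):
                    return False
            else:
                if not (x.fillna("").astype(str) == y.fillna("").astype(str)).all():
                    return False
        return True


def _as_bool(value):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("true", "1"):
        return True
    if s in ("false", "0"):
        return False
    if s == "":
        return None
    raise ValueError(f"cannot interpret {value!r} as boolean")


class TaxonomyTable:
    """feature_id -> (phylum..genus) lookup; unknown ranks are 'Unclassified'."""

    UNCLASSIFIED = "Unclassified"

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for rank in TAXONOMY_RANKS:
            if rank not in frame.columns:
                frame[rank] = self.UNCLASSIFIED
        frame = frame[list(TAXONOMY_RANKS)]
        frame.index = frame.index.astype(str)
        frame.index.name = "feature_id"
        frame = frame.fillna(self.UNCLASSIFIED)
        self.frame = frame

    @property
    def feature_ids(self) -> list[str]:
        return list(self.frame.index)

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        return tuple(self.frame.loc[feature_id, list(TAXONOMY_RANKS)])

    def label_at(self, feature_id: str, level: str) -> str:
        """Taxon label at ``level``; unclassified features are pooled under
        the nearest classified parent rank, e.g. 'Unclassified_family_X'."""
        lineage = self.lineage(feature_id)
        idx = TAXONOMY_RANKS.index(level)
        name = lineage[idx]
        if name != self.UNCLASSIFIED:
            return name
        for j in range(idx - 1, -1, -1):
            if lineage[j] != self.UNCLASSIFIED:
                return f"Unclassified_{TAXONOMY_RANKS[j]}_{lineage[j]}"
        return self.UNCLASSIFIED

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TaxonomyTable):
            return NotImplemented
        return self.frame.equals(other.frame)


@dataclass
class DistanceMatrix:
    """Symmetric zero-diagonal matrix over a list of ids.

    Deliberately tolerant at construction: invalid content is reported by
    :func:`muskin.io.validate_bundle`-style checks, not by ``__init__``.
    """

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(f"values shape {self.values.shape} != ({n}, {n})")

    def violations(self) -> list[str]:
        out = []
        n = len(self.ids)
        if len(set(self.ids)) != n:
            out.append("duplicate ids")
        for i in range(n):
            if self.values[i, i] != 0:
                out.append(f"nonzero diagonal at {self.ids[i]}")
        ii, jj = np.nonzero(~np.isclose(self.values, self.values.T))
        for i, j in zip(ii, jj):
            if i < j:
                out.append(f"asymmetry at ({self.ids[i]}, {self.ids[j]})")
        if (self.values < 0).any():
            out.append("negative entries")
        return out

    def reorder(self, ids: list[str]) -> "DistanceMatrix":
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries, row-major (scipy 'condensed' order)."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=pd.Index(self.ids, name="id"),
                            columns=self.ids)


@dataclass
class GenotypeTable:
    """Microsatellite genotypes: unordered integer allele pairs per
    (individual, locus); a missing cell means the locus was not typed."""

    individuals: list[str]
    loci: list[str]
    calls: dict = field(default_factory=dict)  # (ind, locus) -> (a1, a2) sorted

    def set_call(self, individual: str, locus: str, alleles: tuple[int, int]) -> None:
        if len(alleles) != 2:
            raise ValueError("a genotype call holds exactly 2 alleles")
        self.calls[(individual, locus)] = tuple(sorted(int(a) for a in alleles))

    def get_call(self, individual: str, locus: str):
        return self.calls.get((individual, locus))

    def allele_frequencies(self, individual: str, locus: str):
        """Within-individual frequencies: homozygote 1.0, heterozygote 0.5/0.5."""
        call = self.get_call(individual, locus)
        if call is None:
            return None
        freqs: dict[int, float] = {}
        for a in call:
            freqs[a] = freqs.get(a, 0.0) + 0.5
        return freqs

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (self.individuals == other.individuals and self.loci == other.loci
                and self.calls == other.calls)


@dataclass
class SequenceSet:
    """Named nucleotide sequences over {A,C,G,T,N,-}; optionally aligned."""

    sequences: dict
    aligned: bool = False

    VALID = set("ACGTN-")

    def __post_init__(self) -> None:
        self.sequences = {str(k): str(v).upper() for k, v in self.sequences.items()}

    @property
    def ids(self) -> list[str]:
        return list(self.sequences)

    def __getitem__(self, key: str) -> str:
        return self.sequences[key]

    def __len__(self) -> int:
        return len(self.sequences)

    def violations(self) -> list[str]:
        out = []
        for sid, seq in self.sequences.items():
            bad = set(seq) - self.VALID
            if bad:
                out.append(f"sequence {sid}: invalid characters {sorted(bad)}")
        if self.aligned and self.sequences:
            lengths = {len(s) for s in self.sequences.values()}
            if len(lengths) > 1:
                out.append(f"aligned set has unequal lengths {sorted(lengths)}")
        return out

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceSet):
            return NotImplemented
        return self.sequences == other.sequences and self.aligned == other.aligned
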