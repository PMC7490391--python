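"""Taxonomic collapsing, top-taxa summaries and core-community partitioning.

A *core* taxon of a group is one present in at least 25% of that group's
individuals (boundary inclusive).  Across groups, core taxa partition into
``shared_all`` (core in every group), ``unique`` (core in exactly one
group) and ``partial`` (core in at least two but not all groups).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import TAXONOMY_RANKS, FeatureTable, TaxonomyTable

logger = logging.getLogger(__name__)

DEFAULT_PREVALENCE = 0.25

SHARED_ALL = "shared_all"
UNIQUE = "unique"
PARTIAL = "partial"
CATEGORIES = (SHARED_ALL, UNIQUE, PARTIAL)


def collapse_taxonomy(table: FeatureTable, taxonomy: TaxonomyTable,
                      level: str) -> FeatureTable:
    """Sum counts per (taxon, sample) at the requested rank.  Unclassified
    features are pooled under their nearest classified parent rank."""
    if level not in TAXONOMY_RANKS:
        raise ValueError(f"unknown level {level!r}; choose from {TAXONOMY_RANKS}")
    known = set(taxonomy.feature_ids)
    missing = [f for f in table.feature_ids if f not in known]
    if missing:
        raise ValueError(f"features without taxonomy record: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))

    labels = [taxonomy.label_at(f, level) for f in table.feature_ids]
    order = list(dict.fromkeys(sorted(labels)))
    index = {t: i for i, t in enumerate(order)}
    counts = np.zeros((len(order), len(table.sample_ids)), dtype=table.counts.dtype)
    for row, label in enumerate(labels):
        counts[index[label]] += table.counts[row]
    return FeatureTable(order, list(table.sample_ids), counts, table.dataset_label)


def top_taxa(tables_by_group: dict, k: int = 5, min_groups: int = 2) -> list[str]:
    """Taxa ranking in the top ``k`` by group-mean relative abundance in at
    least ``min_groups`` groups, ordered by overall mean abundance.

    Ties at rank k are broken by lexicographic taxon name."""
    if len(tables_by_group) < min_groups:
        raise ValueError(f"need at least {min_groups} groups")

    qualifying_counts: dict[str, int] = {}
    overall: dict[str, list[float]] = {}
    for group, table in tables_by_group.items():
        rel = table.relative_abundance()
        means = rel.mean(axis=1)
        ranked = sorted(zip(table.feature_ids, means), key=lambda t: (-t[1], t[0]))
        for taxon, _ in ranked[:k]:
            qualifying_counts[taxon] = qualifying_counts.get(taxon, 0) + 1
        for taxon, m in zip(table.feature_ids, means):
            overall.setdefault(taxon, []).append(float(m))

    selected = [t for t, c in qualifying_counts.items() if c >= min_groups]
    selected.sort(key=lambda t: (-float(np.mean(overall[t])), t))
    return selected


def pool_other(table: FeatureTable, keep: list[str],
               other_label: str = "Other") -> FeatureTable:
    """Summary helper: collapse all taxa outside ``keep`` into one row."""
    keep_set = set(keep)
    rows = [table.feature_ids.index(t) for t in keep if t in table.feature_ids]
    other = [i for i, t in enumerate(table.feature_ids) if t not in keep_set]
    counts = np.vstack([table.counts[rows, :],
                        table.counts[other, :].sum(axis=0, keepdims=True)])
    ids = [table.feature_ids[i] for i in rows] + [other_label]
    return FeatureTable(ids, list(table.sample_ids), counts, table.dataset_label)


def core_set(table: FeatureTable, group_samples: list,
             prevalence: float = DEFAULT_PREVALENCE) -> set:
    """Taxa present (count > 0) in at least ``prevalence`` of the group's
    samples, boundary inclusive."""
    if not group_samples:
        raise ValueError("group has no samples")
    sub = table.subset_samples(group_samples)
    frac = (sub.counts > 0).mean(axis=1)
    return {t for t, p in zip(sub.feature_ids, frac) if p >= prevalence}


@dataclass
class CorePartition:
    categories: dict                     # taxon -> category (over union of cores)
    core_by_group: dict                  # group -> core set
    fractions: dict = field(default_factory=dict)  # group -> {category: mean fraction}

    def taxa(self, category: str) -> set:
        return {t for t, c in self.categories.items() if c == category}

    def group_categories(self, group: str) -> dict:
        return {t: self.categories[t] for t in self.core_by_group[group]}

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(sorted(self.categories.items()),
                            columns=["taxon", "category"])


def partition_core(core_sets_by_group: dict) -> CorePartition:
    """Categorize the union of core taxa; invariant to group order."""
    if len(core_sets_by_group) < 2:
        raise ValueError("need at least 2 groups to partition core sets")
    sets = list(core_sets_by_group.values())
    categories: dict[str, str] = {}
    for taxon in set().union(*sets):
        n = sum(taxon in s for s in sets)
        if n == len(sets):
            categories[taxon] = SHARED_ALL
        elif n == 1:
            categories[taxon] = UNIQUE
        else:
            categories[taxon] = PARTIAL
    return CorePartition(categories=categories,
                         core_by_group=dict(core_sets_by_group))


def category_fraction(table: FeatureTable, group_samples: list,
                      partition: CorePartition, group: str) -> dict:
    """Mean per-individual fraction of *core* abundance attributable to
    each category of the group's core taxa.  Individuals with zero core
    abundance are excluded with a warning."""
    core = partition.core_by_group[group]
    if not core:
        raise ValueError(f"group {group!r} has an empty core set")
    sub = table.subset_samples(group_samples)
    idx_by_cat = {
        cat: [i for i, t in enumerate(sub.feature_ids)
              if t in core and partition.categories.get(t) == cat]
        for cat in CATEGORIES
    }
    core_idx = [i for i, t in enumerate(sub.feature_ids) if t in core]
    core_total = sub.counts[core_idx, :].sum(axis=0).astype(float)

    usable = core_total > 0
    if not usable.all():
        logger.warning("%d individuals in %s have zero core abundance; excluded",
                       int((~usable).sum()), group)
    if not usable.any():
        raise ValueError(f"no individual in {group!r} has core abundance")

    out = {}
    for cat, idx in idx_by_cat.items():
        cat_counts = sub.counts[idx, :].sum(axis=0).astype(float) if idx else \
            np.zeros(len(group_samples))
        out[cat] = float(np.mean(cat_counts[usable] / core_total[usable]))
    return out


def core_partition_analysis(table: FeatureTable, group_samples_by_group: dict,
                            prevalence: float = DEFAULT_PREVALENCE) -> CorePartition:
    """Full core analysis: per-group core sets, categories and mean
    per-individual category fractions."""
    cores = {g: core_set(table, samples, prevalence)
             for g, samples in group_samples_by_group.items()}
    partition = partition_core(cores)
    for g, samples in group_samples_by_group.items():
        if cores[g]:
            partition.fractions[g] = category_fraction(table, samples, partition, g)
    logger.info("core partition: %d shared, %d unique, %d partial taxa",
                len(partition.taxa(SHARED_ALL)), len(partition.taxa(UNIQUE)),
                len(partition.taxa(PARTIAL)))
    return partition
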