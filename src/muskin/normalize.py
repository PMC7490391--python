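"""Repeated-rarefaction reliability filter and equal-depth normalization.

Per sample: draw ``D`` reads without replacement ``R`` times; a feature's
*occurrence frequency* is the fraction of draws in which it appears at
least once.  Features whose occurrence frequency falls below the 10%
quantile (linear interpolation, computed per sample over that sample's
present features) are discarded, and a final draw of ``D`` reads is taken
exclusively from the selected features.  Samples whose depth cannot
support the procedure are flagged and excluded rather than erroring the
whole table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from ._rng import seed_sequence
from .types import FeatureTable

logger = logging.getLogger(__name__)

DEFAULT_DEPTH = 4000
DEFAULT_DRAWS = 1000
DEFAULT_QUANTILE = 0.10

FLAG_INSUFFICIENT_DEPTH = "excluded: insufficient depth"
FLAG_POST_FILTER_SHORTFALL = "excluded: post-filter depth shortfall"
FLAG_NO_FEATURES = "excluded: no present features"


@dataclass
class SampleNormalization:
    sample_id: str
    total_reads: int
    target_depth: int
    n_draws: int
    flag: Optional[str] = None
    selected: list = field(default_factory=list)
    excluded_read_fraction: float = 0.0
    occurrence: dict = field(default_factory=dict)


@dataclass
class NormalizationReport:
    samples: list

    def flagged(self) -> list:
        return [s for s in self.samples if s.flag is not None]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.sample_id, s.total_reads, s.target_depth, s.n_draws,
              len(s.selected), s.excluded_read_fraction, s.flag or "")
             for s in self.samples],
            columns=["sample_id", "total_reads", "depth", "draws",
                     "n_selected", "excluded_read_fraction", "flag"],
        )


def occurrence_frequency(sample_counts, depth: int = DEFAULT_DEPTH,
                         draws: int = DEFAULT_DRAWS, seed=None) -> np.ndarray:
    """Fraction of ``draws`` equal-depth subsamples (without replacement,
    i.e. multivariate hypergeometric) in which each feature appears."""
    counts = np.asarray(sample_counts, dtype=np.int64)
    total = int(counts.sum())
    if total < depth:
        raise ValueError(f"sample total {total} below draw depth {depth}")
    rng = np.random.default_rng(seed)
    subsamples = rng.multivariate_hypergeometric(counts, depth, size=draws)
    return (subsamples > 0).mean(axis=0)


def reliability_filter(occurrence_frequencies, present_mask,
                       quantile: float = DEFAULT_QUANTILE) -> np.ndarray:
    """Boolean selection over features: present features whose occurrence
    frequency equals or exceeds the ``quantile``-quantile of the present
    features' frequencies.

    The quantile uses linear interpolation between order statistics at
    plotting position q(n+1) (Weibull / type-6 rule), so e.g. nine 1.0s
    plus one 0.01 give a 10% quantile of 0.109."""
    freqs = np.asarray(occurrence_frequencies, dtype=float)
    present = np.asarray(present_mask, dtype=bool)
    if not present.any():
        return np.zeros_like(present)
    threshold = float(np.quantile(freqs[present], quantile, method="weibull"))
    return present & (freqs >= threshold)


def final_subsample(sample_counts, selected, depth: int, seed=None) -> np.ndarray:
    """One draw of ``depth`` reads without replacement restricted to the
    selected features; unselected features get 0."""
    counts = np.asarray(sample_counts, dtype=np.int64)
    selected = np.asarray(selected, dtype=bool)
    restricted = np.where(selected, counts, 0)
    total = int(restricted.sum())
    if total < depth:
        raise ValueError(f"restricted total {total} below draw depth {depth}")
    if total == depth:
        return restricted.copy()
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(restricted, depth)


def normalize_sample(sample_counts, depth: int, draws: int, quantile: float,
                     seed) -> tuple[Optional[np.ndarray], SampleNormalization]:
    counts = np.asarray(sample_counts, dtype=np.int64)
    total = int(counts.sum())
    record = SampleNormalization(sample_id="", total_reads=total,
                                 target_depth=depth, n_draws=draws)
    present = counts > 0
    if not present.any():
        record.flag = FLAG_NO_FEATURES
        return None, record
    if total < depth:
        record.flag = FLAG_INSUFFICIENT_DEPTH
        return None, record

    seeds = seed_sequence(seed).spawn(2)
    freqs = occurrence_frequency(counts, depth, draws, seed=seeds[0])
    selected = reliability_filter(freqs, present, quantile)
    record.occurrence = {int(i): float(freqs[i]) for i in np.nonzero(present)[0]}
    record.selected = list(np.nonzero(selected)[0])

    restricted_total = int(counts[selected].sum())
    record.excluded_read_fraction = 1.0 - restricted_total / total
    if restricted_total < depth:
        record.flag = FLAG_POST_FILTER_SHORTFALL
        return None, record

    normalized = final_subsample(counts, selected, depth, seed=seeds[1])
    return normalized, record


def normalize_table(table: FeatureTable, depth: int = DEFAULT_DEPTH,
                    draws: int = DEFAULT_DRAWS,
                    quantile: float = DEFAULT_QUANTILE,
                    seed: int = 0) -> tuple[FeatureTable, NormalizationReport]:
    """Apply the reliability filter and final subsampling to every sample.

    Samples that cannot be normalized are dropped (flagged in the report);
    features that end up all-zero are removed from the output table.
    Deterministic given ``seed`` (per-sample seeds are spawned from it).
    """
    sample_seeds = seed_sequence(seed).spawn(len(table.sample_ids))
    kept_ids: list[str] = []
    kept_cols: list[np.ndarray] = []
    records: list[SampleNormalization] = []

    for j, sid in enumerate(table.sample_ids):
        normalized, record = normalize_sample(
            table.counts[:, j], depth, draws, quantile, sample_seeds[j])
        record.sample_id = sid
        records.append(record)
        if normalized is not None:
            kept_ids.append(sid)
            kept_cols.append(normalized)

    if kept_cols:
        counts = np.stack(kept_cols, axis=1)
    else:
        counts = np.zeros((len(table.feature_ids), 0), dtype=np.int64)
    out = FeatureTable(list(table.feature_ids), kept_ids, counts,
                       table.dataset_label).drop_empty_features()
    n_flagged = sum(r.flag is not None for r in records)
    logger.info("normalized %s table to depth %d: kept %d/%d samples "
                "(%d flagged), %d features",
                table.dataset_label, depth, len(kept_ids),
                len(table.sample_ids), n_flagged, len(out.feature_ids))
    return out, NormalizationReport(records)


def presence_probability(total: int, count: int, depth: int) -> float:
    """Closed-form hypergeometric probability that a feature with ``count``
    reads out of ``total`` appears in a draw of ``depth`` reads:
    1 - C(total-count, depth)/C(total, depth)."""
    from scipy.stats import hypergeom

    return float(1.0 - hypergeom.pmf(0, total, count, depth))
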