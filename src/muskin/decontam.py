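"""Frequency-based contaminant classification.

Reagent contaminants arrive at a roughly constant ambient load per sample,
so their *relative* frequency varies inversely with the sample's nucleic
acid concentration.  For each feature we compare, in log-log space, two
one-parameter models of frequency f versus concentration c:

* contaminant:      log f = b - log c   (slope fixed at -1)
* non-contaminant:  log f = b          (slope 0)

both fit by least squares.  With residual sums SS_contam and SS_noncontam,
each on n-1 degrees of freedom, the score is

    P = F_cdf(SS_contam / SS_noncontam; n-1, n-1)

which is small when the inverse-frequency model fits far better.  A feature
is called a contaminant when P < threshold (default 0.1).  DNA and RNA
datasets are screened separately and the union of calls is removed from
both tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .types import FeatureTable, SampleMetadata

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD = 0.1
DEFAULT_MIN_SAMPLES = 5
DEFAULT_CONTROL_MIN_READS = 40


@dataclass
class ContaminantCall:
    feature_id: str
    dataset_label: str
    score_P: Optional[float]
    n_samples_used: int
    is_contaminant: bool


@dataclass
class ScreenReport:
    calls: list[ContaminantCall]
    union: set
    threshold: float
    removed_read_fraction: dict = field(default_factory=dict)

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.feature_id, c.dataset_label, c.score_P, c.n_samples_used,
              c.is_contaminant) for c in self.calls],
            columns=["feature_id", "dataset", "score_P", "n_samples_used", "call"],
        )


def frequency_score(relative_frequencies, concentrations,
                    min_samples: int = DEFAULT_MIN_SAMPLES) -> Optional[float]:
    """Score one feature; ``None`` (no call possible) when fewer than
    ``min_samples`` usable samples remain.

    Only samples with frequency > 0 and known concentration > 0 enter the
    fit.  A concentration <= 0 among otherwise usable samples is an input
    error.
    """
    f = np.asarray(relative_frequencies, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if f.shape != c.shape:
        raise ValueError("frequencies and concentrations differ in length")

    usable = (f > 0) & ~np.isnan(c)
    if np.any(c[usable] <= 0):
        raise ValueError("non-positive concentration among samples with signal")
    if usable.sum() < min_samples:
        return None

    log_f = np.log(f[usable])
    log_c = np.log(c[usable])
    n = usable.sum()

    resid_contam = (log_f + log_c) - np.mean(log_f + log_c)
    resid_flat = log_f - np.mean(log_f)
    ss_contam = float(resid_contam @ resid_contam)
    ss_flat = float(resid_flat @ resid_flat)

    if ss_contam == 0.0 and ss_flat == 0.0:
        # both models exact (constant f and constant c): uninformative
        return 1.0
    if ss_flat == 0.0:
        return 1.0
    return float(stats.f.cdf(ss_contam / ss_flat, n - 1, n - 1))


def eligible_controls(metadata: SampleMetadata, table: FeatureTable,
                      min_reads: int = DEFAULT_CONTROL_MIN_READS) -> list[str]:
    """Negative controls whose total reads in ``table`` equal or exceed
    ``min_reads`` (boundary inclusive)."""
    sums = dict(zip(table.sample_ids, table.sample_sums()))
    controls = [s for s in metadata.control_ids() if s in sums]
    if not controls:
        logger.warning("no negative controls found in %s table", table.dataset_label)
        return []
    kept = [s for s in controls if sums[s] >= min_reads]
    excluded = [(s, int(sums[s])) for s in controls if sums[s] < min_reads]
    if excluded:
        logger.info("excluded %d controls below %d reads: %s",
                    len(excluded), min_reads, excluded)
    return kept


def screen_dataset(table: FeatureTable, metadata: SampleMetadata,
                   threshold: float = DEFAULT_THRESHOLD,
                   min_samples: int = DEFAULT_MIN_SAMPLES,
                   control_min_reads: int = DEFAULT_CONTROL_MIN_READS,
                   ) -> list[ContaminantCall]:
    """Score every feature of one dataset.

    True samples plus eligible negative controls contribute frequencies;
    concentrations come from the metadata column matching the table's
    dataset label.  Features without a defined score are retained
    (conservative: no call)."""
    controls = set(eligible_controls(metadata, table, control_min_reads))
    all_controls = set(metadata.control_ids())
    used_samples = [s for s in table.sample_ids
                    if s not in all_controls or s in controls]

    sub = table.subset_samples(used_samples)
    rel = sub.relative_abundance()
    conc = metadata.concentrations(table.dataset_label).reindex(used_samples).to_numpy()

    calls = []
    for i, fid in enumerate(table.feature_ids):
        f = rel[i]
        usable = (f > 0) & ~np.isnan(conc) & (conc > 0)
        score = frequency_score(f[usable], conc[usable], min_samples) \
            if usable.sum() >= min_samples else None
        calls.append(ContaminantCall(
            feature_id=fid,
            dataset_label=table.dataset_label,
            score_P=score,
            n_samples_used=int(usable.sum()),
            is_contaminant=(score is not None and score < threshold),
        ))
    n_called = sum(c.is_contaminant for c in calls)
    logger.info("%s screen: %d/%d features called contaminant at P<%g",
                table.dataset_label, n_called, len(calls), threshold)
    return calls


def screen_and_filter(table_dna: FeatureTable, table_rna: Optional[FeatureTable],
                      metadata: SampleMetadata,
                      threshold: float = DEFAULT_THRESHOLD,
                      min_samples: int = DEFAULT_MIN_SAMPLES,
                      control_min_reads: int = DEFAULT_CONTROL_MIN_READS,
                      ) -> tuple[FeatureTable, Optional[FeatureTable], ScreenReport]:
    """Screen DNA and RNA datasets separately and remove the union of
    contaminant calls from both tables."""
    if not (0 <= threshold < 1):
        raise ValueError(f"threshold must be in [0, 1), got {threshold}")

    calls = screen_dataset(table_dna, metadata, threshold, min_samples,
                           control_min_reads)
    if table_rna is not None:
        calls += screen_dataset(table_rna, metadata, threshold, min_samples,
                                control_min_reads)

    union = {c.feature_id for c in calls if c.is_contaminant}

    removed_fraction: dict[str, float] = {}
    for table in (table_dna, table_rna):
        if table is None:
            continue
        in_table = [i for i, f in enumerate(table.feature_ids) if f in union]
        removed = table.counts[in_table, :].sum(axis=0)
        totals = table.sample_sums()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, removed / totals, 0.0)
        for s, v in zip(table.sample_ids, frac):
            removed_fraction[f"{table.dataset_label}:{s}"] = float(v)

    filtered_dna = table_dna.drop_features(union)
    filtered_rna = None if table_rna is None else table_rna.drop_features(union)
    logger.info("removed union of %d contaminant features from both tables",
                len(union))
    report = ScreenReport(calls=calls, union=union, threshold=threshold,
                          removed_read_fraction=removed_fraction)
    return filtered_dna, filtered_rna, report
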