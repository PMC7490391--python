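"""Group-equalized point-biserial indicator analysis.

The statistic is a weighted Pearson correlation between a taxon's
abundance (or presence) and membership of the target group set, with each
sample weighted by 1/n_group so every group contributes equal total
weight.  Significance comes from a one-sided permutation test of the
sample-to-group assignment; multiple testing is handled by
Benjamini-Hochberg step-up adjustment.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .types import FeatureTable


@dataclass
class IndicatorResult:
    taxon: str
    target_groups: tuple
    statistic: Optional[float]
    p_value: Optional[float]
    q_value: Optional[float]
    mode: str


def _weights(labels: np.ndarray) -> np.ndarray:
    _, inverse, counts = np.unique(labels, return_inverse=True, return_counts=True)
    return 1.0 / counts[inverse]


def _weighted_corr(x: np.ndarray, t: np.ndarray, w: np.ndarray) -> Optional[float]:
    wsum = w.sum()
    mx = (w * x).sum() / wsum
    mt = (w * t).sum() / wsum
    vx = (w * (x - mx) ** 2).sum()
    vt = (w * (t - mt) ** 2).sum()
    if vx <= 0 or vt <= 0:
        return None
    cov = (w * (x - mx) * (t - mt)).sum()
    return float(cov / np.sqrt(vx * vt))


def rg_statistic(values, group_labels, target_groups, mode: str = "abundance",
                 ) -> Optional[float]:
    """Group-equalized point-biserial correlation; ``None`` when the values
    or the target indicator are constant under the weights (undefined)."""
    x = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    if x.shape != labels.shape:
        raise ValueError("values and labels differ in length")
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 groups")
    if mode == "presence":
        x = (x > 0).astype(float)
    elif mode != "abundance":
        raise ValueError(f"unknown mode {mode!r}")
    target = set(target_groups) if not isinstance(target_groups, str) \
        else {target_groups}
    t = np.isin(labels, sorted(target)).astype(float)
    return _weighted_corr(x, t, _weights(labels))


def indicator_pvalue(values, group_labels, target_groups, nperm: int = 999,
                     seed: int = 0, mode: str = "abundance"):
    """One-sided permutation p-value for the r_g statistic:
    p = (1 + #{r_perm >= r_obs}) / (1 + nperm)."""
    if nperm < 99:
        raise ValueError("nperm must be >= 99")
    r_obs = rg_statistic(values, group_labels, target_groups, mode)
    if r_obs is None:
        return None, None

    x = np.asarray(values, dtype=float)
    if mode == "presence":
        x = (x > 0).astype(float)
    labels = np.asarray(group_labels)
    target = set(target_groups) if not isinstance(target_groups, str) \
        else {target_groups}
    t = np.isin(labels, sorted(target)).astype(float)
    w = _weights(labels)

    # permuting the assignment = permuting (t, w) jointly against x
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(len(x)) for _ in range(nperm)])
    tp = t[perms]                     # (nperm, n)
    wp = w[perms]

    wsum = w.sum()
    mx = (wp * x[None, :]).sum(axis=1) / wsum
    mt = (wp * tp).sum(axis=1) / wsum
    dx = x[None, :] - mx[:, None]
    dt = tp - mt[:, None]
    vx = (wp * dx ** 2).sum(axis=1)
    vt = (wp * dt ** 2).sum(axis=1)
    cov = (wp * dx * dt).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = cov / np.sqrt(vx * vt)
    r_perm = np.where(np.isfinite(r_perm), r_perm, -np.inf)

    p = (1.0 + (r_perm >= r_obs - 1e-12).sum()) / (1.0 + nperm)
    return r_obs, float(p)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def _candidate_targets(groups: list) -> list:
    """All non-trivial group subsets up to complementation (one of each
    complementary pair, the lexicographically smaller)."""
    out = []
    n = len(groups)
    for r in range(1, n // 2 + 1):
        for combo in itertools.combinations(sorted(groups), r):
            complement = tuple(sorted(set(groups) - set(combo)))
            if 2 * r < n or combo <= complement:
                out.append(combo)
    return out


def indicator_analysis(table: FeatureTable, group_labels, nperm: int = 999,
                       seed: int = 0, mode: str = "abundance",
                       targets: list | None = None) -> list:
    """Run the r_g permutation test for every (taxon, target-set) pair and
    attach BH-adjusted q-values (adjusted per target set across taxa)."""
    labels = np.asarray(group_labels)
    groups = sorted(set(labels))
    if targets is None:
        targets = _candidate_targets(groups)
    rel = table.relative_abundance()

    seeds = np.random.SeedSequence(seed).spawn(len(targets))
    results: list[IndicatorResult] = []
    for target, sseq in zip(targets, seeds):
        per_target: list[IndicatorResult] = []
        feature_seeds = sseq.spawn(len(table.feature_ids))
        for i, taxon in enumerate(table.feature_ids):
            r, p = indicator_pvalue(rel[i], labels, target, nperm,
                                    seed=feature_seeds[i], mode=mode)
            per_target.append(IndicatorResult(taxon, tuple(target), r, p, None, mode))
        defined = [res for res in per_target if res.p_value is not None]
        if defined:
            qs = bh_adjust([res.p_value for res in defined])
            for res, q in zip(defined, qs):
                res.q_value = float(q)
        results.extend(per_target)
    return results


def results_frame(results: list) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.taxon, "+".join(r.target_groups), r.statistic, r.p_value,
          r.q_value, r.mode) for r in results],
        columns=["taxon", "target", "r_g", "p", "q", "mode"],
    )
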