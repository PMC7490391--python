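"""Genetic and geographic distances plus (partial) Mantel tests.

Distance decay of community similarity is tested with a rank-based
(Spearman) Mantel statistic on upper-triangle entries and a one-sided
permutation test (simultaneous row/column permutation of the first
matrix).  Partial Mantel tests remove the effect of conditioning
matrices by recursive first-order partialling of the Spearman
correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
from scipy.stats import rankdata

from .types import DistanceMatrix, GenotypeTable

logger = logging.getLogger(__name__)

MAX_CHORD = (2.0 / np.pi) * np.sqrt(2.0)  # per-locus chord distance maximum


# ---------------------------------------------------------------------------
# sequence distance
# ---------------------------------------------------------------------------

def p_distance(seq_a: str, seq_b: str) -> float:
    """Proportion of differing nucleotide sites between two aligned
    sequences, with pairwise deletion of gap/N sites."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must be aligned to equal length")
    skip = set("N-")
    compared = 0
    mismatches = 0
    for a, b in zip(seq_a.upper(), seq_b.upper()):
        if a in skip or b in skip:
            continue
        compared += 1
        mismatches += a != b
    if compared == 0:
        raise ValueError("no comparable sites between sequences")
    return mismatches / compared


def p_distance_matrix(sequences: dict) -> DistanceMatrix:
    ids = list(sequences)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = p_distance(sequences[ids[i]],
                                                     sequences[ids[j]])
    return DistanceMatrix(ids, values)


# ---------------------------------------------------------------------------
# microsatellite distance
# ---------------------------------------------------------------------------

def chord_distance_locus(freq_a: dict, freq_b: dict) -> float:
    """Per-locus Cavalli-Sforza chord distance
    (2/pi) * sqrt(2 * (1 - sum_a sqrt(p_a q_a))) over the union of alleles."""
    alleles = set(freq_a) | set(freq_b)
    overlap = sum(np.sqrt(freq_a.get(a, 0.0) * freq_b.get(a, 0.0)) for a in alleles)
    overlap = min(overlap, 1.0)  # guard rounding
    return float((2.0 / np.pi) * np.sqrt(2.0 * (1.0 - overlap)))


def cavalli_sforza_distance(genotypes: GenotypeTable, unit_a: str,
                            unit_b: str) -> float:
    """Mean per-locus chord distance over loci typed in both individuals.
    Within-individual allele frequencies are 0, 0.5 or 1."""
    values = []
    for locus in genotypes.loci:
        fa = genotypes.allele_frequencies(unit_a, locus)
        fb = genotypes.allele_frequencies(unit_b, locus)
        if fa is None or fb is None:
            continue
        values.append(chord_distance_locus(fa, fb))
    if not values:
        raise ValueError(f"no shared typed loci between {unit_a!r} and {unit_b!r}")
    return float(np.mean(values))


def cavalli_sforza_matrix(genotypes: GenotypeTable) -> DistanceMatrix:
    ids = list(genotypes.individuals)
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = cavalli_sforza_distance(
                genotypes, ids[i], ids[j])
    return DistanceMatrix(ids, values)


# ---------------------------------------------------------------------------
# geography
# ---------------------------------------------------------------------------

def geographic_distance(coordinates) -> DistanceMatrix:
    """Euclidean pairwise distances from planar km coordinates.

    ``coordinates`` is a DataFrame indexed by id with columns x_km, y_km;
    rows with missing coordinates are excluded with a warning."""
    xy = coordinates[["x_km", "y_km"]].astype(float)
    complete = xy.notna().all(axis=1)
    if not complete.all():
        logger.warning("excluding %d ids with missing coordinates",
                       int((~complete).sum()))
    xy = xy[complete]
    pts = xy.to_numpy()
    diff = pts[:, None, :] - pts[None, :, :]
    values = np.sqrt((diff ** 2).sum(axis=2))
    return DistanceMatrix(list(xy.index), values)


# ---------------------------------------------------------------------------
# Mantel machinery
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    r: float
    p_value: float
    nperm: int
    conditioned_on: list = field(default_factory=list)


def _aligned(matrices: list) -> list:
    ids = matrices[0].ids
    for m in matrices[1:]:
        if set(m.ids) != set(ids):
            raise ValueError("distance matrices do not share ids")
    return [m if m.ids == ids else m.reorder(list(ids)) for m in matrices]


def _spearman(a: np.ndarray, b: np.ndarray) -> float:
    ra, rb = rankdata(a), rankdata(b)
    ra -= ra.mean()
    rb -= rb.mean()
    denom = np.sqrt((ra @ ra) * (rb @ rb))
    if denom == 0:
        raise ValueError("constant off-diagonal entries: correlation undefined")
    return float((ra @ rb) / denom)


def mantel(dm_a: DistanceMatrix, dm_b: DistanceMatrix, nperm: int = 1000,
           seed: int = 0) -> MantelResult:
    """Spearman Mantel test; one-sided p from simultaneous row/column
    permutations of the first matrix."""
    a, b = _aligned([dm_a, dm_b])
    n = len(a.ids)
    iu = np.triu_indices(n, k=1)
    ranks_a = _rank_matrix(a.values, iu)
    vb = rankdata(b.values[iu])
    r_obs = _pearson(ranks_a[iu], vb)

    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(nperm):
        perm = rng.permutation(n)
        rp = ranks_a[np.ix_(perm, perm)][iu]
        exceed += _pearson(rp, vb) >= r_obs - 1e-12
    p = (1.0 + exceed) / (1.0 + nperm)
    return MantelResult(float(r_obs), float(p), nperm)


def _rank_matrix(values: np.ndarray, iu) -> np.ndarray:
    """Full symmetric matrix holding the ranks of the upper-triangle
    entries (so permutations reindex precomputed ranks)."""
    ranks = rankdata(values[iu])
    full = np.zeros_like(values, dtype=float)
    full[iu] = ranks
    full = full + full.T
    return full


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx @ dx) * (dy @ dy))
    if denom == 0:
        raise ValueError("constant entries: correlation undefined")
    return float((dx @ dy) / denom)


def _partial_r(r_ab: float, r_ac: float, r_bc: float) -> float:
    denom = (1.0 - r_ac ** 2) * (1.0 - r_bc ** 2)
    if denom <= 0:
        raise ValueError("degenerate conditioning: |r| = 1 with a condition")
    return (r_ab - r_ac * r_bc) / np.sqrt(denom)


def _recursive_partial(vectors: list) -> float:
    """Partial correlation of vectors[0] and vectors[1] given the rest,
    by recursive first-order partialling of Spearman correlations."""
    k = len(vectors)
    corr = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            corr[i, j] = corr[j, i] = 1.0 if i == j else _spearman(
                vectors[i], vectors[j])

    def partial(i, j, conditions):
        if not conditions:
            return corr[i, j]
        c = conditions[-1]
        rest = conditions[:-1]
        return _partial_r(partial(i, j, rest), partial(i, c, rest),
                          partial(j, c, rest))

    return float(partial(0, 1, list(range(2, k))))


def partial_mantel(dm_a: DistanceMatrix, dm_b: DistanceMatrix,
                   conditions: list, nperm: int = 1000,
                   seed: int = 0) -> MantelResult:
    """Partial Mantel test of A vs B given conditioning matrices, permuting
    A and recomputing the partial statistic each time."""
    mats = _aligned([dm_a, dm_b] + list(conditions))
    n = len(mats[0].ids)
    iu = np.triu_indices(n, k=1)
    vecs = [m.values[iu] for m in mats]
    r_obs = _recursive_partial(vecs)

    a_full = mats[0].values
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(nperm):
        perm = rng.permutation(n)
        vperm = a_full[np.ix_(perm, perm)][iu]
        exceed += _recursive_partial([vperm] + vecs[1:]) >= r_obs - 1e-12
    p = (1.0 + exceed) / (1.0 + nperm)
    return MantelResult(float(r_obs), float(p), nperm,
                        conditioned_on=[f"C{i}" for i in range(len(conditions))])
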