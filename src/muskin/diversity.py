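"""Alpha diversity, phylogenetic diversity, beta-diversity distances,
principal-coordinates ordination and permutational variance partitioning.

Shannon entropy is in natural-log units.  Weighted UniFrac is the
normalized variant.  PERMANOVA uses sequential (Type-I) sums of squares
with free permutation of sample labels.  Faith's PD includes the path to
the root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .types import DistanceMatrix, FeatureTable

BETA_KINDS = ("bray_curtis", "jaccard", "unweighted_unifrac", "weighted_unifrac")


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def shannon(counts_vector) -> float:
    """Shannon entropy H = -sum p_i ln p_i over positive proportions."""
    counts = np.asarray(counts_vector, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon entropy undefined for an all-zero vector")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def chao1(counts_vector) -> float:
    """Bias-corrected Chao1: S_obs + F1(F1-1) / (2(F2+1))."""
    counts = np.asarray(counts_vector)
    if not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("Chao1 requires integer counts")
    counts = counts.astype(np.int64)
    s_obs = int((counts > 0).sum())
    f1 = int((counts == 1).sum())
    f2 = int((counts == 2).sum())
    return float(s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1)))


# ---------------------------------------------------------------------------
# phylogeny helpers
# ---------------------------------------------------------------------------

@dataclass
class BranchIndex:
    """Branch decomposition of a rooted tree restricted to a feature list:
    per non-root node, its branch length and the membership of each
    feature among its descendant tips."""

    lengths: np.ndarray        # (n_branches,)
    membership: np.ndarray     # (n_branches, n_features) bool

    @classmethod
    def build(cls, tree: TreeNode, feature_ids: list) -> "BranchIndex":
        index = {f: i for i, f in enumerate(feature_ids)}
        tips = {t.name for t in tree.tips()}
        missing = [f for f in feature_ids if f not in tips]
        if missing:
            raise ValueError(f"features not found as tree tips: {missing[:5]}"
                             + ("..." if len(missing) > 5 else ""))
        lengths = []
        rows = []
        for node in tree.postorder(include_self=False):
            row = np.zeros(len(feature_ids), dtype=bool)
            if node.is_tip():
                if node.name in index:
                    row[index[node.name]] = True
            else:
                for child in node.children:
                    row |= child._muskin_row
            node._muskin_row = row
            lengths.append(0.0 if node.length is None else float(node.length))
            rows.append(row)
        for node in tree.postorder(include_self=False):
            del node._muskin_row
        return cls(np.array(lengths), np.array(rows))


def faith_pd(presence_vector, tree: TreeNode, feature_ids: list,
             branch_index: BranchIndex | None = None) -> float:
    """Total branch length of the minimal subtree connecting the present
    tips and the root."""
    present = np.asarray(presence_vector, dtype=bool)
    bi = branch_index or BranchIndex.build(tree, feature_ids)
    covered = bi.membership[:, present].any(axis=1)
    return float(bi.lengths[covered].sum())


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def beta_distance(x, y, kind: str, tree: TreeNode | None = None,
                  feature_ids: list | None = None,
                  branch_index: BranchIndex | None = None) -> float:
    """Pairwise dissimilarity between two count columns over a shared
    feature universe."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples live in different feature universes")
    if x.sum() == 0 and y.sum() == 0:
        raise ValueError(f"{kind} undefined when both samples are empty")

    if kind == "bray_curtis":
        return float(np.abs(x - y).sum() / (x + y).sum())
    if kind == "jaccard":
        a, b = x > 0, y > 0
        union = (a | b).sum()
        return float(1.0 - (a & b).sum() / union)
    if kind in ("unweighted_unifrac", "weighted_unifrac"):
        if tree is None and branch_index is None:
            raise ValueError(f"{kind} requires a tree")
        bi = branch_index or BranchIndex.build(tree, feature_ids)
        if kind == "unweighted_unifrac":
            in_a = bi.membership[:, x > 0].any(axis=1)
            in_b = bi.membership[:, y > 0].any(axis=1)
            either = bi.lengths[in_a | in_b].sum()
            if either == 0:
                raise ValueError("unweighted UniFrac undefined: no covered branches")
            return float(bi.lengths[in_a ^ in_b].sum() / either)
        pa = bi.membership @ (x / x.sum()) if x.sum() > 0 else np.zeros(len(bi.lengths))
        pb = bi.membership @ (y / y.sum()) if y.sum() > 0 else np.zeros(len(bi.lengths))
        denom = (bi.lengths * (pa + pb)).sum()
        if denom == 0:
            raise ValueError("weighted UniFrac undefined: no covered branches")
        return float((bi.lengths * np.abs(pa - pb)).sum() / denom)
    raise ValueError(f"unknown beta-diversity kind {kind!r}")


def distance_matrix(table: FeatureTable, kind: str,
                    tree: TreeNode | None = None) -> DistanceMatrix:
    """All pairwise beta distances between the table's samples."""
    n = len(table.sample_ids)
    bi = None
    if kind in ("unweighted_unifrac", "weighted_unifrac"):
        bi = BranchIndex.build(tree, table.feature_ids)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = beta_distance(table.counts[:, i], table.counts[:, j], kind,
                              feature_ids=table.feature_ids, branch_index=bi)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(list(table.sample_ids), values)


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    ids: list
    coordinates: np.ndarray        # (n_samples, n_positive_axes)
    eigenvalues: np.ndarray        # all eigenvalues, descending (may be < 0)
    proportion_explained: np.ndarray  # per positive axis, of positive total

    def frame(self) -> pd.DataFrame:
        cols = [f"PCo{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.ids, columns=cols)


def _gower_center(d_squared: np.ndarray) -> np.ndarray:
    n = d_squared.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d_squared @ j


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classic metric multidimensional scaling (Gower double-centering +
    eigendecomposition).  Negative eigenvalues are reported, not corrected;
    coordinates are returned only for positive-eigenvalue axes."""
    g = _gower_center(dm.values ** 2)
    eigvals, eigvecs = np.linalg.eigh((g + g.T) / 2.0)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0])) if len(eigvals) else 0.0
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])[None, :]
    pos_total = eigvals[positive].sum()
    proportion = eigvals[positive] / pos_total if pos_total > 0 else eigvals[positive]
    return OrdinationResult(list(dm.ids), coords, eigvals, proportion)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaTerm:
    name: str
    df: int
    sum_of_squares: float
    pseudo_f: float
    r_squared: float
    p_value: float


@dataclass
class PermanovaResult:
    terms: list
    residual_ss: float
    residual_df: int
    total_ss: float

    def frame(self) -> pd.DataFrame:
        rows = [(t.name, t.df, t.sum_of_squares, t.pseudo_f, t.r_squared,
                 t.p_value) for t in self.terms]
        rows.append(("Residual", self.residual_df, self.residual_ss,
                     np.nan, self.residual_ss / self.total_ss, np.nan))
        rows.append(("Total", self.residual_df + sum(t.df for t in self.terms),
                     self.total_ss, np.nan, 1.0, np.nan))
        return pd.DataFrame(rows, columns=["term", "df", "SS", "pseudo_F",
                                           "R2", "p"])


def _dummy_design(labels) -> np.ndarray:
    labels = np.asarray(labels)
    levels = list(dict.fromkeys(labels))
    return np.column_stack([(labels == lv).astype(float) for lv in levels[1:]]) \
        if len(levels) > 1 else np.zeros((len(labels), 0))


def permanova(dm: DistanceMatrix, terms: dict, nperm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Sequential (Type-I) permutational MANOVA on a distance matrix.

    ``terms`` maps term name -> per-sample factor labels, in model order.
    Sums of squares come from projections of the Gower-centered inner
    product matrix (SS_term = tr(H_term G)); p-values from free permutation
    of sample identities, recomputing each term's pseudo-F.
    """
    if nperm < 1:
        raise ValueError("nperm must be >= 1")
    n = len(dm.ids)
    for name, labels in terms.items():
        if len(labels) != n:
            raise ValueError(f"term {name!r} has {len(labels)} labels for {n} samples")

    g = _gower_center(dm.values ** 2)
    ss_total = float(np.trace(g))

    # cumulative orthonormal bases (intercept first)
    design = np.ones((n, 1))
    hats = []
    dfs = []
    prev_rank = 1
    for name, labels in terms.items():
        design = np.column_stack([design, _dummy_design(labels)])
        q, r = np.linalg.qr(design)
        rank = int((np.abs(np.diag(r)) > 1e-9).sum())
        q = q[:, :rank]
        hats.append(q @ q.T)
        dfs.append(rank - prev_rank)
        prev_rank = rank

    residual_df = n - prev_rank
    if residual_df < 0:
        raise ValueError("model has more parameters than samples")

    def _decompose(gmat):
        ss = []
        prev = float(gmat.sum()) / n  # tr(H_intercept G) = 1'G1/n
        for h in hats:
            cur = float((h * gmat).sum())
            ss.append(cur - prev)
            prev = cur
        ss_res = float(np.trace(gmat)) - prev
        return np.array(ss), ss_res

    ss_terms, ss_res = _decompose(g)
    with np.errstate(invalid="ignore", divide="ignore"):
        f_obs = (ss_terms / np.maximum(dfs, 1)) / (ss_res / max(residual_df, 1))

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(hats))
    for _ in range(nperm):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = _decompose(gp)
        with np.errstate(invalid="ignore", divide="ignore"):
            f_p = (ss_p / np.maximum(dfs, 1)) / (ss_res_p / max(residual_df, 1))
        exceed += f_p >= f_obs
    p_values = (1.0 + exceed) / (1.0 + nperm)

    result_terms = [
        PermanovaTerm(name=name, df=int(df), sum_of_squares=float(ss),
                      pseudo_f=float(f), r_squared=float(ss / ss_total),
                      p_value=float(p))
        for name, df, ss, f, p in zip(terms, dfs, ss_terms, f_obs, p_values)
    ]
    return PermanovaResult(result_terms, float(ss_res), int(residual_df), ss_total)
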