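"""Random-intercept linear mixed models fit by REML, with marginal-R2
variance partitioning.

The model is y = X beta + Z u + eps with one random intercept per level of
a grouping factor (farm/cage), u ~ N(0, sigma2_u), eps ~ N(0, sigma2_e).
The REML criterion is profiled down to a one-dimensional optimization over
the variance ratio lambda = sigma2_u / sigma2_e; the block structure of
V = I + lambda Z Z' makes every evaluation O(n).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

RATIO_TOL = 1e-8


@dataclass
class MixedFit:
    beta: np.ndarray
    beta_names: list
    sigma2_u: float
    sigma2_e: float
    reml_criterion: float          # maximized REML log-likelihood (up to const)
    fitted_fixed: np.ndarray       # X beta-hat
    grouping: str = "group"
    response: str = "y"
    boundary: bool = False         # sigma2_u pinned at 0


def _group_slices(labels: np.ndarray):
    """Sorted order and per-group index arrays."""
    order = np.argsort(labels, kind="stable")
    sorted_labels = labels[order]
    boundaries = np.flatnonzero(np.r_[True, sorted_labels[1:] != sorted_labels[:-1]])
    sizes = np.diff(np.r_[boundaries, len(labels)])
    return order, boundaries, sizes


def _profiled(y: np.ndarray, x: np.ndarray, order, boundaries, sizes, lam: float):
    """GLS quantities at fixed variance ratio; returns (-2 restricted
    log-likelihood up to an additive constant, beta, sigma2_e)."""
    n, p = x.shape
    ys = y[order]
    xs = x[order, :]

    # V^-1 w = w - (lam / (1 + n_g lam)) * 1 1' w   per group block
    shrink = lam / (1.0 + sizes * lam)              # per group

    def vinv(mat):
        out = mat.copy()
        for b, s, sh in zip(boundaries, sizes, shrink):
            block = mat[b:b + s]
            out[b:b + s] = block - sh * block.sum(axis=0, keepdims=True)
        return out

    viy = vinv(ys[:, None])[:, 0]
    vix = vinv(xs)
    xtvx = xs.T @ vix
    xtvy = xs.T @ viy
    beta = np.linalg.solve(xtvx, xtvy)
    resid = ys - xs @ beta
    quad = float(resid @ vinv(resid[:, None])[:, 0])
    sigma2_e = quad / (n - p)

    logdet_v = float(np.log1p(sizes * lam).sum())
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    neg2ll = (n - p) * np.log(max(sigma2_e, 1e-300)) + logdet_v \
        + logdet_xtvx + (n - p)
    return neg2ll, beta, sigma2_e


def profiled_reml_criterion(y, x, grouping_labels, lam: float) -> float:
    """REML log-likelihood (up to a constant) at variance ratio ``lam``;
    exposed so optimization sanity can be probed externally."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    labels = np.asarray(grouping_labels)
    order, boundaries, sizes = _group_slices(labels)
    neg2ll, _, _ = _profiled(y, x, order, boundaries, sizes, lam)
    return -0.5 * neg2ll


def fit_random_intercept(response, fixed_design, grouping_labels,
                         design_names: list | None = None,
                         response_name: str = "y",
                         grouping_name: str = "group") -> MixedFit:
    """REML fit of a Gaussian random-intercept model.

    ``fixed_design`` must include any intercept column explicitly and be
    full rank.  A boundary fit (sigma2_u = 0) is allowed and flagged.
    """
    y = np.asarray(response, dtype=float)
    x = np.asarray(fixed_design, dtype=float)
    if x.ndim != 2 or x.shape[0] != len(y):
        raise ValueError("design shape does not match response")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    labels = np.asarray(grouping_labels)
    if len(set(labels)) < 2:
        raise ValueError("need at least 2 grouping levels")

    order, boundaries, sizes = _group_slices(labels)

    def objective(u: float) -> float:
        try:
            value = _profiled(y, x, order, boundaries, sizes, np.exp(u))[0]
        except np.linalg.LinAlgError:
            return 1e12
        return value if np.isfinite(value) else 1e12

    res = minimize_scalar(objective, bounds=(np.log(1e-10), np.log(1e8)),
                          method="bounded",
                          options={"xatol": RATIO_TOL / 10})
    lam = float(np.exp(res.x))
    neg2ll_zero, _, _ = _profiled(y, x, order, boundaries, sizes, 0.0)

    boundary = neg2ll_zero <= res.fun or lam < 1e-9
    if boundary:
        lam = 0.0
        neg2ll, beta, sigma2_e = _profiled(y, x, order, boundaries, sizes, 0.0)
    else:
        neg2ll, beta, sigma2_e = _profiled(y, x, order, boundaries, sizes, lam)

    names = design_names or [f"x{i}" for i in range(x.shape[1])]
    return MixedFit(
        beta=beta, beta_names=list(names),
        sigma2_u=float(lam * sigma2_e), sigma2_e=float(sigma2_e),
        reml_criterion=float(-0.5 * neg2ll),
        fitted_fixed=x @ beta,
        grouping=grouping_name, response=response_name,
        boundary=bool(boundary),
    )


def marginal_r2(fit: MixedFit) -> float:
    """Fraction of total variance explained by the fixed effects:
    var(X beta) / (var(X beta) + sigma2_u + sigma2_e)."""
    var_fixed = float(np.var(fit.fitted_fixed, ddof=1)) \
        if len(fit.fitted_fixed) > 1 else 0.0
    total = var_fixed + fit.sigma2_u + fit.sigma2_e
    return var_fixed / total if total > 0 else 0.0


def factor_share(full_fit: MixedFit, reduced_fits: dict) -> dict:
    """Drop-one share of explained variance per factor, in percent:
    (R2m_full - R2m_without) / R2m_full * 100, floored at 0.

    Shares need not sum to 100 when factors are correlated."""
    r2_full = marginal_r2(full_fit)
    if r2_full == 0:
        raise ValueError("full model explains no variance; shares undefined")
    return {
        factor: max(0.0, (r2_full - marginal_r2(reduced)) / r2_full * 100.0)
        for factor, reduced in reduced_fits.items()
    }


def design_matrix(frame: pd.DataFrame, covariates: list,
                  add_intercept: bool = True) -> tuple[np.ndarray, list]:
    """Dummy-coded fixed-effect design from metadata columns; booleans and
    strings become indicator columns, numerics enter as-is."""
    pieces = []
    names: list[str] = []
    if add_intercept:
        pieces.append(np.ones((len(frame), 1)))
        names.append("intercept")
    for cov in covariates:
        col = frame[cov]
        if col.dtype.kind in "fiu":
            pieces.append(col.to_numpy(dtype=float)[:, None])
            names.append(cov)
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            pieces.append(dummies.to_numpy(dtype=float))
            names.extend(dummies.columns)
    return np.column_stack(pieces), names
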