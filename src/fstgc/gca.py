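"""Bivariate Granger-causality estimation with exogenous covariates.

For an ordered region pair (x, y) the two-equation lag-p vector
autoregression

    x(t) = a_x0 + sum_i a_xx,i x(t-i) + sum_i a_xy,i y(t-i)
                + sum_j b_x,j z_j(t) + e_x(t)
    y(t) = a_y0 + sum_i a_yx,i x(t-i) + sum_i a_yy,i y(t-i)
                + sum_j b_y,j z_j(t) + e_y(t)

is estimated by ordinary least squares on rows t = p+1..T, with the
exogenous processes z_j (e.g. motion estimates, physiological noise)
entering contemporaneously.  Two directed-influence measures are
derived:

* the signed *path coefficient*: the sum over lags of the cross
  coefficients (a_yx for x -> y), which at p = 1 is the single lagged
  cross-regression coefficient and keeps its sign — this is the
  "connection strength" carried into the group analysis;
* the residual-based measure F_XtoY = ln(Var e_y,reduced / Var e_y,full),
  comparing y's prediction error with and without x's past (clipped at
  zero).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .preprocess import ROITimeSeries


@dataclass(frozen=True)
class BivariateVARFit:
    """OLS estimate of the two-equation bivariate VAR for one pair."""

    order_p: int
    n_obs: int
    alpha_x0: float
    alpha_y0: float
    alpha_xx: np.ndarray  # own lags in x's equation, length p
    alpha_xy: np.ndarray  # y's lags in x's equation, length p
    alpha_yx: np.ndarray  # x's lags in y's equation, length p
    alpha_yy: np.ndarray  # own lags in y's equation, length p
    beta_x: np.ndarray  # exogenous coefficients, length q
    beta_y: np.ndarray
    resid_x: np.ndarray
    resid_y: np.ndarray
    se_alpha_yx: np.ndarray  # OLS standard errors of alpha_yx
    se_alpha_xy: np.ndarray

    @property
    def resid_var_x(self) -> float:
        return float(np.mean(self.resid_x**2))

    @property
    def resid_var_y(self) -> float:
        return float(np.mean(self.resid_y**2))


@dataclass(frozen=True)
class GCAResult:
    """Per-subject directed-connectivity matrices over the pathway.

    ``path_matrix[j, i]`` is the signed coefficient-based influence of
    region i on region j; ``f_matrix[j, i]`` the residual-variance-ratio
    influence.  Diagonals are NaN (self-influence undefined).
    """

    subject_id: str
    region_labels: tuple[str, ...]
    path_matrix: np.ndarray
    f_matrix: np.ndarray | None
    order_p: int

    def path(self, source: str, target: str) -> float:
        i = self.region_labels.index(source)
        j = self.region_labels.index(target)
        return float(self.path_matrix[j, i])


def _lagged_design(
    x: np.ndarray, y: np.ndarray, z: np.ndarray | None, p: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Build the shared regressor matrix for both equations.

    Columns: intercept, x(t-1..t-p), y(t-1..t-p), z(t).  Returns the
    design, the x(t) and y(t) response vectors and q (# exogenous).
    """
    T = x.shape[0]
    rows = T - p
    cols = [np.ones(rows)]
    for i in range(1, p + 1):
        cols.append(x[p - i : T - i])
    for i in range(1, p + 1):
        cols.append(y[p - i : T - i])
    q = 0
    if z is not None and z.size:
        z = np.asarray(z, dtype=float)
        if z.ndim == 1:
            z = z[:, None]
        if z.shape[0] != T:
            raise ValueError("exogenous rows do not match series length")
        q = z.shape[1]
        cols.append(z[p:])
    design = np.column_stack(cols)
    return design, x[p:], y[p:], q


def fit_bivariate_var(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    p: int = 1,
) -> BivariateVARFit:
    """Estimate both equations of the bivariate VAR by OLS.

    Raises on series that are too short for the requested order
    (needs T - p > 2p + q + 1 residual degrees of freedom) or have zero
    variance.
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if p < 1:
        raise ValueError("model order p must be >= 1")
    T = x.shape[0]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero-variance series cannot be modelled")

    design, resp_x, resp_y, q = _lagged_design(x, y, z, p)
    k = design.shape[1]  # 1 + 2p + q
    if T - p <= 2 * p + q + 1:
        raise ValueError(
            f"series too short: T={T}, order p={p}, q={q} exogenous "
            f"(need T - p > 2p + q + 1)"
        )

    coef, *_ = np.linalg.lstsq(design, np.column_stack([resp_x, resp_y]), rcond=None)
    fitted = design @ coef
    resid_x = resp_x - fitted[:, 0]
    resid_y = resp_y - fitted[:, 1]

    # coefficient standard errors from (X'X)^-1 * sigma^2
    dof = design.shape[0] - k
    xtx_inv = np.linalg.pinv(design.T @ design)
    diag = np.clip(np.diag(xtx_inv), 0, None)
    s2_x = resid_x @ resid_x / max(dof, 1)
    s2_y = resid_y @ resid_y / max(dof, 1)
    se_y = np.sqrt(diag * s2_y)
    se_x = np.sqrt(diag * s2_x)

    sl_x = slice(1, 1 + p)  # lagged-x columns
    sl_y = slice(1 + p, 1 + 2 * p)  # lagged-y columns
    sl_z = slice(1 + 2 * p, k)
    return BivariateVARFit(
        order_p=p,
        n_obs=design.shape[0],
        alpha_x0=float(coef[0, 0]),
        alpha_y0=float(coef[0, 1]),
        alpha_xx=coef[sl_x, 0].copy(),
        alpha_xy=coef[sl_y, 0].copy(),
        alpha_yx=coef[sl_x, 1].copy(),
        alpha_yy=coef[sl_y, 1].copy(),
        beta_x=coef[sl_z, 0].copy(),
        beta_y=coef[sl_z, 1].copy(),
        resid_x=resid_x,
        resid_y=resid_y,
        se_alpha_yx=se_y[sl_x].copy(),
        se_alpha_xy=se_x[sl_y].copy(),
    )


def path_coefficient(
    fit: BivariateVARFit, direction: Literal["x->y", "y->x"] = "x->y"
) -> float:
    """Signed connection strength: sum over lags of the cross coefficients."""
    if direction == "x->y":
        return float(np.sum(fit.alpha_yx))
    if direction == "y->x":
        return float(np.sum(fit.alpha_xy))
    raise ValueError(f"direction must be 'x->y' or 'y->x', got {direction!r}")


def residual_influence(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    p: int = 1,
) -> tuple[float, float]:
    """Log residual-variance-ratio influences (F_XtoY, F_YtoX).

    F_XtoY = ln(Var e_y,reduced / Var e_y,full) where the reduced model
    for y omits x's lags; negative values from sampling jitter are
    clipped to zero.
    """
    full = fit_bivariate_var(x, y, z, p)
    f_x_to_y = _reduced_log_ratio(y, x, z, p, full.resid_var_y)
    f_y_to_x = _reduced_log_ratio(x, y, z, p, full.resid_var_x)
    return f_x_to_y, f_y_to_x


def _reduced_log_ratio(
    target: np.ndarray,
    other: np.ndarray,
    z: np.ndarray | None,
    p: int,
    full_var: float,
) -> float:
    """ln(var of target's AR(p)+z residual / full-model residual var)."""
    T = target.shape[0]
    cols = [np.ones(T - p)]
    for i in range(1, p + 1):
        cols.append(target[p - i : T - i])
    if z is not None and np.asarray(z).size:
        zz = np.asarray(z, dtype=float)
        if zz.ndim == 1:
            zz = zz[:, None]
        cols.append(zz[p:])
    design = np.column_stack(cols)
    resp = target[p:]
    coef, *_ = np.linalg.lstsq(design, resp, rcond=None)
    resid = resp - design @ coef
    reduced_var = float(np.mean(resid**2))
    if full_var <= 0:
        return float("inf")
    return max(0.0, float(np.log(reduced_var / full_var)))


def gca_matrix(
    ts: ROITimeSeries,
    z: np.ndarray | None = None,
    p: int = 1,
    standardize: bool = True,
    compute_f: bool = True,
) -> GCAResult:
    """Fit all ordered region pairs and assemble connectivity matrices.

    With ``standardize`` each region's series is z-scored first so path
    coefficients are comparable across subjects.  Entry (j, i) of the
    path matrix is the signed influence of region i on region j.
    """
    R = ts.n_regions
    if R < 2:
        raise ValueError("need at least two regions")
    data = ts.data
    sds = data.std(axis=0)
    zero = np.nonzero(sds == 0)[0]
    if zero.size:
        names = [ts.region_labels[i] for i in zero]
        raise ValueError(f"zero-variance region(s): {names}")
    if standardize:
        data = (data - data.mean(axis=0)) / sds

    path = np.full((R, R), np.nan)
    fmat = np.full((R, R), np.nan) if compute_f else None
    for i in range(R):  # source
        for j in range(R):  # target
            if i == j:
                continue
            x, y = data[:, i], data[:, j]
            fit = fit_bivariate_var(x, y, z, p)
            path[j, i] = path_coefficient(fit, "x->y")
            if compute_f:
                fmat[j, i] = _reduced_log_ratio(y, x, z, p, fit.resid_var_y)
    return GCAResult(
        subject_id=ts.subject_id,
        region_labels=ts.region_labels,
        path_matrix=path,
        f_matrix=fmat,
        order_p=p,
    )
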