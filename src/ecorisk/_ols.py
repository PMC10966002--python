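"""Closed-form OLS with t-based inference.

The screening and best-subset stages run tens of thousands of small
(n ~ 62) least-squares fits, so inference is computed directly from the
normal equations rather than through a modelling framework.  Results are
numerically equivalent to statsmodels.OLS (asserted in the test suite).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = ["OLSFit", "RankDeficientError", "ols_fit"]

# Residual sums of squares below this (relative to the response scale)
# are treated as an exact fit; see OLSFit.pvalues for the convention.
_RSS_REL_TOL = 1e-12


class RankDeficientError(ValueError):
    """Design matrix is rank deficient; names the collinear columns."""

    def __init__(self, columns: list[str]):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


@dataclass(frozen=True)
class OLSFit:
    """Coefficients and t-based inference for one least-squares fit.

    ``params`` etc. are indexed like the column names passed to
    :func:`ols_fit` (intercept first).  ``k`` counts every estimated
    regression coefficient including the intercept.  Exact (zero
    residual) fits report p = 0 for nonzero coefficients and p = 1 for
    zero ones, with degenerate point confidence intervals.
    """

    names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    conf_int: np.ndarray  # (k, 2)
    rss: float
    tss: float
    n: int
    k: int
    df_resid: int
    exact: bool = False
    extra: dict = field(default_factory=dict)

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def pvalue(self, name: str) -> float:
        return float(self.pvalues[self.names.index(name)])

    def ci(self, name: str) -> tuple[float, float]:
        lo, hi = self.conf_int[self.names.index(name)]
        return float(lo), float(hi)


def _collinear_columns(X: np.ndarray, names: list[str]) -> list[str]:
    """Columns whose addition does not increase the rank, scanning left to right."""
    bad = []
    rank = 0
    for j in range(X.shape[1]):
        r = np.linalg.matrix_rank(X[:, : j + 1])
        if r == rank:
            bad.append(names[j])
        rank = r
    return bad


def ols_fit(
    y: np.ndarray,
    X: np.ndarray,
    names: list[str] | tuple[str, ...],
    alpha: float = 0.05,
) -> OLSFit:
    """Least-squares fit of ``y`` on the columns of ``X`` (intercept included
    by the caller), with two-sided t inference on every coefficient.

    Raises
    ------
    RankDeficientError
        if the columns of ``X`` are linearly dependent.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    if n <= k:
        raise ValueError(f"need n > k for inference (n={n}, k={k})")
    names = tuple(names)

    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < k:
        raise RankDeficientError(_collinear_columns(X, list(names)))

    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    df = n - k

    scale = max(float(y @ y), 1.0)
    exact = rss <= _RSS_REL_TOL * scale
    xtx_inv = np.linalg.inv(X.T @ X)
    if exact:
        bse = np.zeros(k)
        tvals = np.where(np.abs(beta) > 1e-10, np.inf * np.sign(beta), 0.0)
        pvals = np.where(np.abs(beta) > 1e-10, 0.0, 1.0)
        ci = np.column_stack([beta, beta])
    else:
        sigma2 = rss / df
        bse = np.sqrt(np.clip(np.diag(xtx_inv), 0.0, None) * sigma2)
        with np.errstate(divide="ignore", invalid="ignore"):
            tvals = np.where(bse > 0, beta / bse, 0.0)
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        ci = np.column_stack([beta - tcrit * bse, beta + tcrit * bse])

    return OLSFit(
        names=names,
        params=beta,
        bse=bse,
        tvalues=tvals,
        pvalues=pvals,
        conf_int=ci,
        rss=rss,
        tss=tss,
        n=n,
        k=k,
        df_resid=df,
        exact=exact,
    )
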