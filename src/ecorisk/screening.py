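"""Stage 1 of the association analysis: per-factor linear screening.

Every variable is z-scored (sample SD, n-1 denominator), so a
bivariable slope equals the sample Pearson correlation and coefficients
are comparable across factors.  Each candidate exposure is fitted in
two models — unadjusted, and adjusted for the forced race & SES set —
and pooled for the multivariable stage when either model's two-sided
p-value falls below the screening threshold (0.1 by default; 0.2 / 0.3
as sensitivity settings).

When a candidate is highly correlated with the percent-white column
(|r| above the conflict threshold), that column is dropped from the
adjustment set for that factor only; the decision is logged per record.
No multiple-testing adjustment is applied at this stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._ols import OLSFit, RankDeficientError, ols_fit

__all__ = [
    "standardize",
    "fit_bivariable",
    "fit_adjusted",
    "race_collinearity_rule",
    "screen",
    "ScreeningRecord",
    "ScreeningResult",
]


def standardize(frame: pd.DataFrame | pd.Series):
    """Z-score columns to mean 0, SD 1 (sample SD, n-1 denominator).

    Missing values are ignored in the moments and preserved in the
    output.  Raises on constant columns, naming them.
    """
    if isinstance(frame, pd.Series):
        return standardize(frame.to_frame()).iloc[:, 0]
    means = frame.mean()
    sds = frame.std(ddof=1)
    constant = [str(c) for c in frame.columns if not np.isfinite(sds[c]) or sds[c] == 0]
    if constant:
        raise ValueError(f"constant columns cannot be standardized: {constant}")
    return (frame - means) / sds


def _complete(*series: pd.Series) -> pd.DataFrame:
    df = pd.concat(series, axis=1)
    return df.dropna()


def fit_bivariable(y: pd.Series, x: pd.Series, name: str | None = None) -> OLSFit:
    """OLS of y on x with intercept (Model 1).  On standardized data the
    slope equals the sample Pearson correlation."""
    name = name or (x.name if x.name is not None else "x")
    d = _complete(y.rename("__y"), x.rename(name))
    n = len(d)
    if n < 3:
        raise ValueError(f"need at least 3 complete observations (have {n})")
    X = np.column_stack([np.ones(n), d[name].to_numpy()])
    return ols_fit(d["__y"].to_numpy(), X, ["const", name])


def fit_adjusted(y: pd.Series, x: pd.Series, adjust: pd.DataFrame,
                 name: str | None = None) -> OLSFit:
    """OLS of y on x plus the adjustment columns (Model 2); inference on
    x's partial coefficient.  With an empty adjustment set this reduces
    exactly to :func:`fit_bivariable`."""
    name = name or (x.name if x.name is not None else "x")
    if adjust is None or adjust.shape[1] == 0:
        return fit_bivariable(y, x, name)
    if name in adjust.columns:
        raise ValueError(f"candidate {name!r} also appears in the adjustment set")
    d = _complete(y.rename("__y"), x.rename(name), *[adjust[c] for c in adjust.columns])
    n = len(d)
    if n <= 2 + adjust.shape[1]:
        raise ValueError(f"too few complete observations (n={n})")
    cols = [name, *adjust.columns]
    X = np.column_stack([np.ones(n)] + [d[c].to_numpy() for c in cols])
    return ols_fit(d["__y"].to_numpy(), X, ["const", *cols])


def race_collinearity_rule(
    x: pd.Series, race: pd.Series, threshold: float = 0.6
) -> bool:
    """True (drop race from this factor's adjustment set) iff
    |Pearson r(x, race)| > threshold, strictly."""
    d = _complete(x.rename("__x"), race.rename("__race"))
    r = float(d["__x"].corr(d["__race"]))
    return abs(r) > threshold


@dataclass(frozen=True)
class ScreeningRecord:
    variable: str
    est_unadj: float
    p_unadj: float
    est_adj: float
    p_adj: float
    race_dropped: bool
    pooled: bool
    n_unadj: int
    n_adj: int
    error: str | None = None


@dataclass(frozen=True)
class ScreeningResult:
    records: tuple[ScreeningRecord, ...]
    pooled: tuple[str, ...]
    p_threshold: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])


def screen(
    y: pd.Series,
    X: pd.DataFrame,
    adjust: pd.DataFrame,
    p_threshold: float = 0.1,
    race_col: str | None = "pct_white",
    race_r_threshold: float = 0.6,
) -> ScreeningResult:
    """Run both per-factor models for every column of ``X`` and pool the
    factors with min(p_unadj, p_adj) < ``p_threshold``.

    Per-factor failures (e.g. rank deficiency) are recorded, not fatal;
    the factor is excluded from the pool.
    """
    if not 0 < p_threshold < 1:
        raise ValueError("p_threshold must be in (0, 1)")
    records = []
    pooled = []
    for var in X.columns:
        x = X[var]
        try:
            adj = adjust
            race_dropped = False
            if race_col is not None and race_col in adjust.columns:
                race_dropped = race_collinearity_rule(
                    x, adjust[race_col], threshold=race_r_threshold
                )
                if race_dropped:
                    adj = adjust.drop(columns=[race_col])
            m1 = fit_bivariable(y, x, str(var))
            m2 = fit_adjusted(y, x, adj, str(var))
            keep = min(m1.pvalue(str(var)), m2.pvalue(str(var))) < p_threshold
            records.append(
                ScreeningRecord(
                    variable=str(var),
                    est_unadj=m1.coef(str(var)), p_unadj=m1.pvalue(str(var)),
                    est_adj=m2.coef(str(var)), p_adj=m2.pvalue(str(var)),
                    race_dropped=race_dropped, pooled=keep,
                    n_unadj=m1.n, n_adj=m2.n,
                )
            )
            if keep:
                pooled.append(str(var))
        except (ValueError, RankDeficientError) as exc:
            records.append(
                ScreeningRecord(
                    variable=str(var), est_unadj=np.nan, p_unadj=np.nan,
                    est_adj=np.nan, p_adj=np.nan, race_dropped=False,
                    pooled=False, n_unadj=0, n_adj=0, error=str(exc),
                )
            )
    return ScreeningResult(records=tuple(records), pooled=tuple(pooled),
                           p_threshold=p_threshold)
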