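"""Segmented log-linear (joinpoint) trend analysis of annual rates.

The model regresses ln(rate) on calendar year with a continuous
piecewise-linear (hinge) basis: ln r = a + b*t + sum_j g_j (t - c_j)+.
Each segment's slope converts to an annual percent change
APC = 100*(e^b - 1); the average APC over a span is the segment-length
weighted geometric mean, AAPC = 100*(exp(sum w_i b_i / sum w_i) - 1).

The number of joinpoints (0-2 by default) is chosen either by a
sequential permutation test on the RSS improvement — mirroring the
convention of the NCI joinpoint tool — or by BIC.  All candidate break
placements at observed years are searched exhaustively.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datagen import AnnualSeries, TrendSpec, generate_trend_series  # noqa: F401

__all__ = [
    "JoinpointModel",
    "JoinpointResults",
    "AAPCResult",
    "SegmentFit",
    "fit_fixed_joinpoints",
    "search_joinpoints",
    "aapc",
    "classify_trend",
]

_ZERO_SLOPE_TOL = 1e-10


@dataclass(frozen=True)
class SegmentFit:
    """One trend segment: [start, end] years, slope on the log scale,
    and the implied annual percent change with t-based inference."""

    start: int
    end: int
    slope: float
    slope_se: float
    apc: float
    apc_ci: tuple[float, float]
    pvalue: float


@dataclass(frozen=True)
class AAPCResult:
    estimate: float
    ci: tuple[float, float]
    pvalue: float


def _hinge_design(years: np.ndarray, breaks: tuple[int, ...]) -> np.ndarray:
    t = years - years[0]
    cols = [np.ones_like(t, dtype=float), t.astype(float)]
    for b in breaks:
        cols.append(np.clip(years - b, 0, None).astype(float))
    return np.column_stack(cols)


class JoinpointModel:
    """Segmented log-linear trend model for one annual rate series.

    Parameters
    ----------
    series
        AnnualSeries (strictly increasing years, positive rates).
    min_seg_obs
        Minimum observations per segment, counting both endpoints
        (break years belong to the segments on both sides).
    """

    def __init__(self, series: AnnualSeries, min_seg_obs: int = 3):
        if min_seg_obs < 2:
            raise ValueError("min_seg_obs must be at least 2")
        self.series = series
        self.min_seg_obs = min_seg_obs

    # -- fitting ---------------------------------------------------------

    def fit(self, breaks: tuple[int, ...] | list[int] = ()) -> "JoinpointResults":
        """Least-squares fit with the given (possibly empty) break years."""
        breaks = tuple(int(b) for b in breaks)
        self._check_breaks(breaks)
        years, rates = self.series.years, self.series.rates
        X = _hinge_design(years, breaks)
        n, p = X.shape
        if n <= p:
            raise ValueError(f"series too short for {len(breaks)} joinpoints (n={n})")
        logy = np.log(rates)
        beta, _, rank, _ = np.linalg.lstsq(X, logy, rcond=None)
        if rank < p:
            raise ValueError("degenerate design (coincident break years?)")
        resid = logy - X @ beta
        rss = float(resid @ resid)
        df = n - p
        scale = max(float(logy @ logy), 1.0)
        exact = rss <= 1e-12 * scale
        sigma2 = 0.0 if exact else rss / df
        cov = sigma2 * np.linalg.inv(X.T @ X)
        return JoinpointResults(
            model=self, breaks=breaks, params=beta, cov=cov, rss=rss,
            n=n, n_params=p, df_resid=df, exact=exact,
        )

    def fit_search(
        self,
        max_joinpoints: int = 2,
        selection: str = "permutation",
        n_perm: int = 499,
        alpha: float = 0.05,
        seed: int | None = None,
    ) -> "JoinpointResults":
        """Exhaustive search over break placements, model size chosen by a
        sequential permutation test (default) or BIC.

        The permutation test compares k against k+1 joinpoints with the
        statistic (RSS_k - RSS_{k+1}) / RSS_{k+1}; the null distribution
        is generated by permuting the k-model residuals.  Each test in
        the sequence runs at level alpha / max_joinpoints (Bonferroni).
        Falls back to k = 0 with a warning for series too short for any
        larger model.
        """
        if selection not in ("permutation", "bic"):
            raise ValueError("selection must be 'permutation' or 'bic'")
        trace: list[str] = []
        best = {}
        for k in range(max_joinpoints + 1):
            fit = self._best_for_k(k)
            if fit is None:
                trace.append(f"k={k}: no admissible placement (series too short); stopping")
                break
            best[k] = fit
        if not best:
            raise ValueError("series too short for even the 0-joinpoint model")
        if len(best) == 1:
            trace.append("warning: only the 0-joinpoint model is admissible")
            chosen = best[0]
            return chosen._with_trace(trace)

        if selection == "bic":
            bics = {k: f.bic for k, f in best.items()}
            k_sel = min(bics, key=lambda k: (bics[k], k))
            trace.extend(f"k={k}: BIC={b:.4f}" for k, b in sorted(bics.items()))
            trace.append(f"selected k={k_sel} by BIC")
            return best[k_sel]._with_trace(trace)

        rng = np.random.default_rng(
            np.random.SeedSequence(0 if seed is None else seed, spawn_key=(4,))
        )
        level = alpha / max_joinpoints
        k_sel = 0
        while k_sel + 1 in best:
            p = self._perm_test(best[k_sel], k_sel + 1, n_perm, rng)
            trace.append(f"permutation test k={k_sel} vs k={k_sel + 1}: p={p:.4f} (level {level:.4f})")
            if p < level:
                k_sel += 1
            else:
                break
        trace.append(f"selected k={k_sel} by sequential permutation test")
        return best[k_sel]._with_trace(trace)

    # -- internals -------------------------------------------------------

    def _check_breaks(self, breaks: tuple[int, ...]) -> None:
        years = self.series.years
        if list(breaks) != sorted(set(breaks)):
            raise ValueError("break years must be strictly increasing")
        for b in breaks:
            if not years[0] < b < years[-1]:
                raise ValueError(f"break year {b} not strictly inside the series")
        bounds = [years[0], *breaks, years[-1]]
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            n_obs = int(np.sum((years >= lo) & (years <= hi)))
            if n_obs < self.min_seg_obs:
                raise ValueError(
                    f"segment [{lo}, {hi}] has {n_obs} observations "
                    f"(minimum {self.min_seg_obs})"
                )

    def _candidate_breaks(self) -> list[int]:
        return [int(y) for y in self.series.years[1:-1]]

    def _placements(self, k: int):
        for combo in itertools.combinations(self._candidate_breaks(), k):
            try:
                self._check_breaks(combo)
            except ValueError:
                continue
            yield combo

    def _best_for_k(self, k: int) -> "JoinpointResults | None":
        best = None
        for combo in self._placements(k):
            try:
                fit = self.fit(combo)
            except ValueError:
                continue
            if best is None or fit.rss < best.rss - 1e-15:
                best = fit
        return best

    def _perm_test(self, null_fit: "JoinpointResults", k_alt: int,
                   n_perm: int, rng: np.random.Generator) -> float:
        alt = self._best_for_k(k_alt)
        if alt is None:
            return 1.0
        if null_fit.rss <= 1e-15:
            return 1.0  # null already exact; more breaks cannot help
        if alt.rss <= 1e-15:
            return 0.0  # exact fit only attainable with the extra break
        stat = (null_fit.rss - alt.rss) / alt.rss
        years = self.series.years
        fitted = _hinge_design(years, null_fit.breaks) @ null_fit.params
        resid = np.log(self.series.rates) - fitted
        exceed = 0
        for _ in range(n_perm):
            y_star = np.exp(fitted + rng.permutation(resid))
            m = JoinpointModel(AnnualSeries(years=years, rates=y_star),
                               min_seg_obs=self.min_seg_obs)
            f0 = m._best_for_k(len(null_fit.breaks))
            f1 = m._best_for_k(k_alt)
            if f0 is None or f1 is None or f1.rss <= 0:
                continue
            if (f0.rss - f1.rss) / f1.rss >= stat:
                exceed += 1
        return (1 + exceed) / (n_perm + 1)


@dataclass(frozen=True, eq=False)
class JoinpointResults:
    """Fitted segmented trend: per-segment APCs, overall AAPC, and the
    pieces (RSS, covariance) needed for model comparison."""

    model: JoinpointModel
    breaks: tuple[int, ...]
    params: np.ndarray
    cov: np.ndarray
    rss: float
    n: int
    n_params: int
    df_resid: int
    exact: bool
    trace: tuple[str, ...] = field(default_factory=tuple)

    def _with_trace(self, trace: list[str]) -> "JoinpointResults":
        return JoinpointResults(
            model=self.model, breaks=self.breaks, params=self.params, cov=self.cov,
            rss=self.rss, n=self.n, n_params=self.n_params, df_resid=self.df_resid,
            exact=self.exact, trace=tuple(trace),
        )

    @property
    def bic(self) -> float:
        rss = max(self.rss, 1e-300)  # floor guards the exact-fit limit
        return self.n * np.log(rss / self.n) + self.n_params * np.log(self.n)

    def _segment_bounds(self) -> list[tuple[int, int]]:
        years = self.model.series.years
        bounds = [int(years[0]), *self.breaks, int(years[-1])]
        return list(zip(bounds[:-1], bounds[1:]))

    def _slope_vector(self, seg: int) -> np.ndarray:
        c = np.zeros(self.n_params)
        c[1] = 1.0
        c[2 : 2 + seg] = 1.0
        return c

    def _linear_inference(self, c: np.ndarray) -> tuple[float, float, float, tuple[float, float]]:
        """Estimate, se, two-sided p and 95% CI for the contrast c'beta."""
        est = float(c @ self.params)
        se = float(np.sqrt(max(c @ self.cov @ c, 0.0)))
        if self.exact or se == 0.0:
            p = 0.0 if abs(est) > _ZERO_SLOPE_TOL else 1.0
            return est, 0.0, p, (est, est)
        t = est / se
        p = float(2.0 * stats.t.sf(abs(t), self.df_resid))
        tc = float(stats.t.ppf(0.975, self.df_resid))
        return est, se, p, (est - tc * se, est + tc * se)

    @property
    def segments(self) -> list[SegmentFit]:
        out = []
        for i, (lo, hi) in enumerate(self._segment_bounds()):
            b, se, p, (blo, bhi) = self._linear_inference(self._slope_vector(i))
            out.append(
                SegmentFit(
                    start=lo, end=hi, slope=b, slope_se=se,
                    apc=100.0 * float(np.expm1(b)),
                    apc_ci=(100.0 * float(np.expm1(blo)), 100.0 * float(np.expm1(bhi))),
                    pvalue=p,
                )
            )
        return out

    @property
    def apcs(self) -> list[float]:
        return [s.apc for s in self.segments]

    def aapc(self, year_range: tuple[int, int] | None = None) -> AAPCResult:
        """Average APC over ``year_range`` (default: the whole fitted span).

        The weighted log-scale slope sum(w_i b_i)/sum(w_i), with w_i the
        years of segment i inside the range, is a linear contrast of the
        fitted coefficients; its CI comes from the fit covariance (delta
        method) and transforms monotonically to the percent scale.
        """
        years = self.model.series.years
        lo = int(years[0]) if year_range is None else int(year_range[0])
        hi = int(years[-1]) if year_range is None else int(year_range[1])
        if hi <= lo:
            raise ValueError("empty year range")
        if lo < years[0] or hi > years[-1]:
            raise ValueError("range outside the fitted span")
        c = np.zeros(self.n_params)
        total = 0.0
        for i, (s, e) in enumerate(self._segment_bounds()):
            w = max(0, min(hi, e) - max(lo, s))
            if w > 0:
                c += w * self._slope_vector(i)
                total += w
        if total <= 0:
            raise ValueError("range does not overlap any segment")
        c /= total
        est, _, p, (blo, bhi) = self._linear_inference(c)
        return AAPCResult(
            estimate=100.0 * float(np.expm1(est)),
            ci=(100.0 * float(np.expm1(blo)), 100.0 * float(np.expm1(bhi))),
            pvalue=p,
        )

    def classify(self, alpha: float = 0.05) -> str:
        """'increasing' / 'decreasing' if the AAPC differs from zero at
        ``alpha`` (two-sided t), else 'stable'."""
        a = self.aapc()
        if a.pvalue < alpha and a.estimate > 0:
            return "increasing"
        if a.pvalue < alpha and a.estimate < 0:
            return "decreasing"
        return "stable"

    def summary(self) -> str:
        s = self.model.series
        lines = [
            f"Joinpoint fit: {s.cancer}/{s.sex}, years {s.years[0]}-{s.years[-1]}, "
            f"{len(self.breaks)} joinpoint(s) {list(self.breaks)}",
            f"n={self.n}  RSS={self.rss:.6g}  BIC={self.bic:.4f}",
            f"{'segment':>12}  {'APC%':>8}  {'95% CI':>20}  {'p':>8}",
        ]
        for seg in self.segments:
            lines.append(
                f"{seg.start}-{seg.end:>5}  {seg.apc:8.3f}  "
                f"[{seg.apc_ci[0]:8.3f}, {seg.apc_ci[1]:8.3f}]  {seg.pvalue:8.2e}"
            )
        a = self.aapc()
        lines.append(
            f"AAPC: {a.estimate:.3f}% [{a.ci[0]:.3f}, {a.ci[1]:.3f}] p={a.pvalue:.2e} "
            f"-> {self.classify()}"
        )
        return "\n".join(lines)

    def to_segments_table(self):
        import pandas as pd

        rows = [
            (s.start, s.end, s.apc, s.apc_ci[0], s.apc_ci[1], s.pvalue)
            for s in self.segments
        ]
        return pd.DataFrame(rows, columns=["start", "end", "apc", "lo", "hi", "p"])

    def plot(self, ax=None):
        """Observed rates (log scale) with the fitted segmented trend."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        s = self.model.series
        ax.plot(s.years, s.rates, "o", label="observed")
        fitted = np.exp(_hinge_design(s.years, self.breaks) @ self.params)
        ax.plot(s.years, fitted, "-", label="fitted")
        for b in self.breaks:
            ax.axvline(b, ls=":", color="grey")
        ax.set_yscale("log")
        ax.set_xlabel("year")
        ax.set_ylabel("rate per 100,000")
        ax.legend()
        return ax


# -- module-level operation surface -------------------------------------


def fit_fixed_joinpoints(series: AnnualSeries, breaks, min_seg_obs: int = 3) -> JoinpointResults:
    return JoinpointModel(series, min_seg_obs=min_seg_obs).fit(tuple(breaks))


def search_joinpoints(
    series: AnnualSeries,
    max_joinpoints: int = 2,
    min_seg_obs: int = 3,
    selection: str = "permutation",
    n_perm: int = 499,
    seed: int | None = None,
) -> JoinpointResults:
    return JoinpointModel(series, min_seg_obs=min_seg_obs).fit_search(
        max_joinpoints=max_joinpoints, selection=selection, n_perm=n_perm, seed=seed
    )


def aapc(fit: JoinpointResults, year_range: tuple[int, int] | None = None) -> AAPCResult:
    return fit.aapc(year_range)


def classify_trend(fit: JoinpointResults, alpha: float = 0.05) -> str:
    return fit.classify(alpha)
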