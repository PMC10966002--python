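"""Stage 2: correlation conflict graph, exhaustive best-subset search
by BIC, and pooling / pruning of the per-combination winners.

Highly correlated candidate pairs (|Pearson r| above a threshold, 0.6
main / 0.5 sensitivity) must not enter the same model; the pairs form
the edges of a conflict graph whose maximal independent sets are the
"compatible combinations".  Because the subset search below examines
every subset of each combination, enumerating only the maximal sets
loses no admissible model.

Within each combination, every subset (including the empty one) is
scored by BIC with the forced race & SES covariates always included;
the per-combination winners are pooled, models with adjusted R^2 below
0.3 are dropped, duplicates and nested groups collapsed, and the
survivors ranked by BIC with a dBIC < 2 comparability flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._ols import OLSFit, RankDeficientError, ols_fit

__all__ = [
    "ConflictGraph",
    "FittedModel",
    "SelectionResult",
    "build_conflict_graph",
    "enumerate_combinations",
    "n_subsets",
    "bic",
    "adjusted_r2",
    "best_subset",
    "pool_and_prune",
    "race_candidate_mode",
]

_BIC_RSS_FLOOR = 1e-300  # keeps BIC finite for exact fits; documented limit


# ---------------------------------------------------------------------------
# conflict graph and compatible combinations


@dataclass(frozen=True)
class ConflictGraph:
    """Candidate variables as nodes; an edge joins every pair whose
    pairwise-complete |Pearson r| strictly exceeds the threshold."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(sorted(self.graph.nodes))

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return tuple(sorted(tuple(sorted(e)) for e in self.graph.edges))

    def is_independent(self, subset) -> bool:
        sub = list(subset)
        return not any(
            self.graph.has_edge(a, b) for a, b in itertools.combinations(sub, 2)
        )


def build_conflict_graph(X: pd.DataFrame, r_threshold: float = 0.6) -> ConflictGraph:
    """Pairwise correlations on pairwise-complete observations; edge iff
    |r| > r_threshold (strict, so r = threshold exactly is no conflict)."""
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate variables")
    sds = X.std(ddof=1)
    constant = [str(c) for c in X.columns if not np.isfinite(sds[c]) or sds[c] == 0]
    if constant:
        raise ValueError(f"constant candidate columns: {constant}")
    corr = X.corr(method="pearson", min_periods=3)
    g = nx.Graph()
    g.add_nodes_from(str(c) for c in X.columns)
    cols = list(X.columns)
    for a, b in itertools.combinations(cols, 2):
        r = corr.loc[a, b]
        if np.isfinite(r) and abs(r) > r_threshold:
            g.add_edge(str(a), str(b), r=float(r))
    return ConflictGraph(graph=g, threshold=r_threshold)


def enumerate_combinations(g: ConflictGraph, max_nodes: int = 40) -> list[tuple[str, ...]]:
    """All maximal independent sets of the conflict graph, sorted
    deterministically (members sorted; list sorted lexicographically).

    Every independent set is a subset of some returned combination, so
    the downstream subset search loses no admissible model.
    """
    n = g.graph.number_of_nodes()
    if n > max_nodes:
        raise ValueError(
            f"{n} candidate variables exceed the enumeration ceiling "
            f"({max_nodes}); tighten the screening threshold or lower the "
            f"correlation threshold"
        )
    complement = nx.complement(g.graph)
    if complement.number_of_nodes() == 0:
        return []
    combos = {tuple(sorted(cl)) for cl in nx.find_cliques(complement)}
    return sorted(combos)


def n_subsets(p: int) -> int:
    """Number of variable subsets of a p-variable pool (2^p)."""
    if p < 0:
        raise ValueError("p must be nonnegative")
    return 2**p


# ---------------------------------------------------------------------------
# information criteria


def bic(rss: float, n: int, k: int) -> float:
    """Gaussian profile BIC, n*ln(RSS/n) + k*ln(n), constants dropped.

    ``k`` counts every estimated coefficient (intercept + forced +
    selected).  RSS is floored at 1e-300 so exact fits stay finite.
    """
    if n <= k:
        raise ValueError(f"need n > k (n={n}, k={k})")
    if rss < 0:
        raise ValueError("RSS must be nonnegative")
    return n * np.log(max(rss, _BIC_RSS_FLOOR) / n) + k * np.log(n)


def adjusted_r2(rss: float, tss: float, n: int, k: int) -> float:
    """1 - (RSS/(n-k)) / (TSS/(n-1))."""
    if n <= k:
        raise ValueError(f"need n > k (n={n}, k={k})")
    if tss <= 0:
        raise ValueError("TSS must be positive")
    return 1.0 - (rss / (n - k)) / (tss / (n - 1))


# ---------------------------------------------------------------------------
# fitted models


@dataclass(frozen=True, eq=False)
class FittedModel:
    """One candidate model: the selected subset plus forced covariates,
    with standardized coefficients and information criteria."""

    selected: tuple[str, ...]
    forced: tuple[str, ...]
    n: int
    k: int  # estimated coefficients incl. intercept
    rss: float
    tss: float
    bic: float
    adj_r2: float
    fit: OLSFit | None = None

    @property
    def key(self) -> tuple[str, ...]:
        return tuple(sorted(self.selected))

    def coefficients(self) -> pd.DataFrame:
        if self.fit is None:
            raise ValueError("model fitted without inference")
        f = self.fit
        return pd.DataFrame(
            {
                "estimate": f.params,
                "ci_lo": f.conf_int[:, 0],
                "ci_hi": f.conf_int[:, 1],
                "p": f.pvalues,
            },
            index=list(f.names),
        )


def _score_subset(y, cols, n):
    """RSS and rank check for one design (intercept + given columns)."""
    X = np.column_stack([np.ones(n)] + cols)
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        return None
    resid = y - X @ beta
    return float(resid @ resid)


def best_subset(
    y: pd.Series,
    combination,
    X: pd.DataFrame,
    forced: pd.DataFrame | None = None,
    max_size: int | None = None,
    hierarchy: dict[str, str] | None = None,
) -> FittedModel:
    """Minimize BIC over all subsets of ``combination`` (the empty subset
    included), with the forced covariates in every model.

    ``hierarchy`` maps child -> parent terms (e.g. latitude^2 -> latitude):
    a child is admitted only alongside its parent (weak hierarchy).
    Rank-deficient subsets are skipped.  Exact BIC ties break toward
    fewer variables, then lexicographic names.
    """
    combination = [str(v) for v in combination]
    if len(combination) > 25:
        raise ValueError(
            f"combination of {len(combination)} variables exceeds the "
            f"exhaustive-search guard (25)"
        )
    forced_names = [] if forced is None else [str(c) for c in forced.columns]
    overlap = set(combination) & set(forced_names)
    if overlap:
        raise ValueError(f"variables both forced and candidate: {sorted(overlap)}")
    hierarchy = hierarchy or {}

    data = pd.concat(
        [y.rename("__y"), X[combination]]
        + ([] if forced is None else [forced[c] for c in forced_names]),
        axis=1,
    ).dropna()
    n = len(data)
    yv = data["__y"].to_numpy()
    forced_cols = [data[c].to_numpy() for c in forced_names]
    col_of = {v: data[v].to_numpy() for v in combination}

    best = None  # (bic, size, key, subset, rss, k)
    sizes = range(0, (len(combination) if max_size is None else min(max_size, len(combination))) + 1)
    for size in sizes:
        for subset in itertools.combinations(sorted(combination), size):
            ok = all(
                hierarchy[v] in subset for v in subset if v in hierarchy
            )
            if not ok:
                continue
            k = 1 + len(forced_cols) + len(subset)
            if n <= k:
                continue
            rss = _score_subset(yv, forced_cols + [col_of[v] for v in subset], n)
            if rss is None:
                continue
            b = bic(rss, n, k)
            # ties break toward fewer variables, then lexicographic names
            cand = (b, len(subset), subset, rss, k)
            if best is None or cand[:3] < best[:3]:
                best = cand
    if best is None:
        raise RankDeficientError(forced_names)
    b, _, subset, rss, k = best

    names = ["const", *forced_names, *subset]
    Xfit = np.column_stack([np.ones(n)] + forced_cols + [col_of[v] for v in subset])
    fit = ols_fit(yv, Xfit, names)
    return FittedModel(
        selected=tuple(subset), forced=tuple(forced_names), n=n, k=k,
        rss=rss, tss=fit.tss, bic=b, adj_r2=adjusted_r2(rss, fit.tss, n, k),
        fit=fit,
    )


# ---------------------------------------------------------------------------
# pooling and pruning


@dataclass(frozen=True, eq=False)
class SelectionResult:
    """Ranked unique models after the adjusted-R^2 filter, duplicate
    removal and nested-group pruning.  ``empty`` is set when no model
    explains the required share of variation."""

    ranked: tuple[FittedModel, ...]
    comparable: tuple[FittedModel, ...]
    empty: bool
    audit: dict = field(default_factory=dict)

    @property
    def best(self) -> FittedModel | None:
        return self.ranked[0] if self.ranked else None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (",".join(m.selected) or "(forced only)", m.bic, m.adj_r2, m.n, m.k, i + 1,
             m in self.comparable)
            for i, m in enumerate(self.ranked)
        ]
        return pd.DataFrame(
            rows, columns=["subset", "bic", "adj_r2", "n", "k", "rank", "comparable"]
        )

    def summary(self) -> str:
        if self.empty:
            return (
                "No model explains the required share of variation "
                "(all candidates below the adjusted R^2 floor)."
            )
        lines = [f"{len(self.ranked)} unique model(s) after pruning; "
                 f"{len(self.comparable)} comparable (dBIC < "
                 f"{self.audit.get('delta_bic', 2.0)}):"]
        for i, m in enumerate(self.ranked):
            mark = "*" if m in self.comparable else " "
            lines.append(
                f"{mark} rank {i + 1}: {{{', '.join(m.selected) or 'forced only'}}} "
                f"BIC={m.bic:.3f} adjR2={m.adj_r2:.3f}"
            )
        return "\n".join(lines)


def _model_order(m: FittedModel) -> tuple:
    return (m.bic, len(m.selected), m.key)


def pool_and_prune(
    models: list[FittedModel],
    adj_r2_min: float = 0.3,
    delta_bic: float = 2.0,
) -> SelectionResult:
    """Filter by adjusted R^2, deduplicate identical subsets, collapse
    nested groups (connected components of the proper-subset relation,
    keeping the lowest-BIC member of each), rank by BIC, and flag the
    comparable set (BIC - best < delta_bic, strict)."""
    audit = {
        "n_pooled": len(models),
        "adj_r2_min": adj_r2_min,
        "delta_bic": delta_bic,
    }
    kept = [m for m in models if m.adj_r2 >= adj_r2_min]
    audit["n_dropped_r2"] = len(models) - len(kept)
    if not kept:
        audit["n_unique"] = 0
        return SelectionResult(ranked=(), comparable=(), empty=True, audit=audit)

    by_key: dict[tuple[str, ...], FittedModel] = {}
    for m in sorted(kept, key=_model_order):
        by_key.setdefault(m.key, m)
    unique = list(by_key.values())
    audit["n_unique"] = len(unique)

    g = nx.Graph()
    g.add_nodes_from(range(len(unique)))
    for i, j in itertools.combinations(range(len(unique)), 2):
        a, b = set(unique[i].key), set(unique[j].key)
        if a < b or b < a:
            g.add_edge(i, j)
    survivors = []
    for comp in nx.connected_components(g):
        survivors.append(min((unique[i] for i in comp), key=_model_order))
    audit["n_nested_groups"] = nx.number_connected_components(g)

    ranked = tuple(sorted(survivors, key=_model_order))
    best_bic = ranked[0].bic
    comparable = tuple(m for m in ranked if m.bic - best_bic < delta_bic)
    return SelectionResult(ranked=ranked, comparable=comparable, empty=False, audit=audit)


def race_candidate_mode(
    candidates: pd.DataFrame,
    forced: pd.DataFrame,
    race_col: str = "pct_white",
    enabled: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Move the percent-white column from the forced set into the
    candidate pool (sensitivity mode).  Default keeps it forced."""
    if not enabled:
        return candidates, forced
    if race_col not in forced.columns:
        raise ValueError(f"{race_col!r} not in the forced set")
    candidates = pd.concat([candidates, forced[[race_col]]], axis=1)
    return candidates, forced.drop(columns=[race_col])
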