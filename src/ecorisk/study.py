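"""Two-stage ecological exposure model for one county-level stratum.

``EcologicalStudy`` bundles the full association analysis for a single
cancer / age-group / sex stratum: z-scoring, per-factor screening
(unadjusted + race & SES-adjusted models, p < 0.1 pooling), the
correlation conflict graph, exhaustive per-combination best-subset
search by BIC, and pooling / pruning of the winners.  ``fit`` returns a
``StudyResults`` carrying the screening records, the ranked models and
the final best model with standardized coefficients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import screening as scr
from . import selection as sel

__all__ = ["EcologicalStudy", "StudyResults"]


class EcologicalStudy:
    """Model object for one stratum.

    Parameters
    ----------
    outcome
        County outcome (standardized incidence rates); z-scored on fit.
    exposures
        Candidate exposure columns (lagged period), counties x variables.
    forced
        Race & SES adjustment columns, included in every model unless
        the race-as-candidate sensitivity mode moves percent-white into
        the candidate pool.
    spatial
        Optional spatial terms (latitude, latitude squared); they join
        the candidate pool after screening-free admission and obey weak
        hierarchy (the squared term only enters alongside latitude).
    """

    def __init__(
        self,
        outcome: pd.Series,
        exposures: pd.DataFrame,
        forced: pd.DataFrame,
        spatial: pd.DataFrame | None = None,
        race_col: str = "pct_white",
    ):
        idx = outcome.index
        if not (exposures.index.equals(idx) and forced.index.equals(idx)):
            raise ValueError("outcome, exposures and forced must share the county index")
        if spatial is not None and not spatial.index.equals(idx):
            raise ValueError("spatial terms must share the county index")
        self.outcome = outcome
        self.exposures = exposures
        self.forced = forced
        self.spatial = spatial if spatial is not None else pd.DataFrame(index=idx)
        self.race_col = race_col

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        forced: list[str],
        spatial: list[str] | None = None,
        race_col: str = "pct_white",
    ) -> "EcologicalStudy":
        spatial = spatial or []
        candidates = [c for c in data.columns if c not in {outcome, *forced, *spatial}]
        return cls(
            outcome=data[outcome],
            exposures=data[candidates],
            forced=data[forced],
            spatial=data[spatial] if spatial else None,
            race_col=race_col,
        )

    def fit(
        self,
        screen_p: float = 0.1,
        conflict_r: float = 0.6,
        adj_r2_min: float = 0.3,
        delta_bic: float = 2.0,
        race_as_candidate: bool = False,
        hierarchy: dict[str, str] | None = None,
    ) -> "StudyResults":
        y = scr.standardize(self.outcome)
        X = scr.standardize(self.exposures)
        forced = scr.standardize(self.forced)
        spatial = scr.standardize(self.spatial) if self.spatial.shape[1] else self.spatial

        screened = scr.screen(
            y, X, forced, p_threshold=screen_p,
            race_col=self.race_col, race_r_threshold=conflict_r,
        )

        pool = X[list(screened.pooled)]
        if spatial.shape[1]:
            pool = pd.concat([pool, spatial], axis=1)
            if hierarchy is None and {"latitude", "latitude2"} <= set(spatial.columns):
                hierarchy = {"latitude2": "latitude"}
        pool, forced_used = sel.race_candidate_mode(
            pool, forced, race_col=self.race_col, enabled=race_as_candidate
        )

        if pool.shape[1] == 0:
            result = sel.SelectionResult(ranked=(), comparable=(), empty=True,
                                         audit={"n_pooled": 0, "delta_bic": delta_bic,
                                                "adj_r2_min": adj_r2_min})
            return StudyResults(self, screened, None, (), result,
                                dict(screen_p=screen_p, conflict_r=conflict_r,
                                     adj_r2_min=adj_r2_min, delta_bic=delta_bic,
                                     race_as_candidate=race_as_candidate))

        if pool.shape[1] >= 2:
            graph = sel.build_conflict_graph(pool, r_threshold=conflict_r)
            combos = sel.enumerate_combinations(graph)
        else:
            graph = None
            combos = [tuple(str(c) for c in pool.columns)]

        models = [
            sel.best_subset(y, combo, pool, forced_used, hierarchy=hierarchy)
            for combo in combos
        ]
        result = sel.pool_and_prune(models, adj_r2_min=adj_r2_min, delta_bic=delta_bic)
        result.audit.update(n_combinations=len(combos))
        return StudyResults(self, screened, graph, tuple(combos), result,
                            dict(screen_p=screen_p, conflict_r=conflict_r,
                                 adj_r2_min=adj_r2_min, delta_bic=delta_bic,
                                 race_as_candidate=race_as_candidate))


@dataclass(frozen=True, eq=False)
class StudyResults:
    """Everything the two-stage analysis produced for one stratum."""

    model: EcologicalStudy
    screening: scr.ScreeningResult
    conflict_graph: sel.ConflictGraph | None
    combinations: tuple[tuple[str, ...], ...]
    selection: sel.SelectionResult
    settings: dict = field(default_factory=dict)

    @property
    def best(self) -> sel.FittedModel | None:
        return self.selection.best

    def summary(self) -> str:
        lines = [
            f"Screening: {len(self.screening.pooled)} of "
            f"{len(self.screening.records)} factors pooled "
            f"(P < {self.screening.p_threshold})",
            f"Compatible combinations: {len(self.combinations)}",
            self.selection.summary(),
        ]
        if self.best is not None:
            lines.append("Best model coefficients:")
            lines.append(self.best.coefficients().to_string(float_format="%.4f"))
        return "\n".join(lines)

    def plot_coefficients(self, ax=None):
        """Standardized coefficients of the best model with 95% CIs."""
        if self.best is None:
            raise ValueError("no model survived selection")
        import matplotlib.pyplot as plt

        coefs = self.best.coefficients().drop(index="const")
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 0.5 * len(coefs) + 1))
        ypos = range(len(coefs))
        ax.errorbar(
            coefs["estimate"], list(ypos),
            xerr=[coefs["estimate"] - coefs["ci_lo"], coefs["ci_hi"] - coefs["estimate"]],
            fmt="o",
        )
        ax.axvline(0, color="grey", lw=0.8)
        ax.set_yticks(list(ypos), list(coefs.index))
        ax.set_xlabel("standardized coefficient (95% CI)")
        return ax
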