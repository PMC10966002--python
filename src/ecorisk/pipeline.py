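"""End-to-end orchestration: fixtures -> rates -> inclusion filter ->
screening -> selection (+ optional trend reports), with validated CSV
inputs and byte-stable report files.

Interchange formats are plain CSV/TSV with explicit schemas:

* exposures.csv  — wide, ``county`` index column + one column per variable
  (must include the forced race & SES columns, and optionally
  latitude / latitude2);
* counts.csv     — county,cancer,age_group,sex,age_band,cases,population;
* rates.csv      — county,cancer,age_group,sex,rate,cases (alternative
  to counts.csv when rates are precomputed);
* std_pop.csv    — age_band,weight;
* trend.csv      — year,rate,cancer,sex (optional).

Reruns with the same inputs and seed produce byte-identical outputs:
floats are written with a fixed format and the manifest carries no
timestamps.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import rates as rates_mod
from . import trends as trends_mod
from .datagen import AnnualSeries
from .study import EcologicalStudy

__all__ = ["PipelineConfig", "run_study", "sweep", "validate_inputs", "DataError", "ConfigError"]

FORCED_DEFAULT = ("poverty", "uninsured", "pct_white")
SPATIAL_DEFAULT = ("latitude", "latitude2")
_FLOAT_FMT = "%.10g"


class DataError(ValueError):
    """Input files violate the documented schemas (exit code 1)."""


class ConfigError(ValueError):
    """Configuration outside documented ranges (exit code 2)."""


@dataclass
class PipelineConfig:
    exposures: str = "exposures.csv"
    counts: str | None = None
    rates: str | None = None
    std_pop: str | None = None
    trend: str | None = None
    outdir: str = "report"
    screen_p: float = 0.1
    conflict_r: float = 0.6
    adj_r2_min: float = 0.3
    delta_bic: float = 2.0
    min_cases: int = 5
    min_fraction: float = 0.6
    max_joinpoints: int = 2
    race_as_candidate: bool = False
    joinpoint_selection: str = "permutation"
    n_perm: int = 499
    forced: tuple[str, ...] = FORCED_DEFAULT
    seed: int = 0

    def validate(self) -> None:
        if self.screen_p not in (0.1, 0.2, 0.3):
            raise ConfigError("screen_p must be one of 0.1, 0.2, 0.3")
        if self.conflict_r not in (0.5, 0.6):
            raise ConfigError("conflict_r must be 0.5 or 0.6")
        if not 0 <= self.adj_r2_min < 1:
            raise ConfigError("adj_r2_min must be in [0, 1)")
        if self.delta_bic <= 0:
            raise ConfigError("delta_bic must be positive")
        if not 0 < self.min_fraction < 1:
            raise ConfigError("min_fraction must be in (0, 1)")
        if self.min_cases < 0:
            raise ConfigError("min_cases must be nonnegative")
        if not 0 <= self.max_joinpoints <= 2:
            raise ConfigError("max_joinpoints must be 0, 1 or 2")
        if self.joinpoint_selection not in ("permutation", "bic"):
            raise ConfigError("joinpoint_selection must be 'permutation' or 'bic'")
        if self.counts is None and self.rates is None:
            raise ConfigError("provide either a counts or a rates file")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "forced" in raw:
            raw["forced"] = tuple(raw["forced"])
        return cls(**raw)


# ---------------------------------------------------------------------------
# validation


def validate_inputs(config: PipelineConfig) -> list[dict]:
    """Schema and cross-file consistency checks; returns machine-readable
    findings (level: error|warning) without mutating any input."""
    findings: list[dict] = []

    def finding(level, file, message):
        findings.append({"level": level, "file": str(file), "message": message})

    try:
        expo = pd.read_csv(config.exposures)
    except Exception as exc:  # unreadable / empty file
        finding("error", config.exposures, f"unreadable exposures file: {exc}")
        return findings
    if "county" not in expo.columns or expo.shape[1] < 2:
        finding("error", config.exposures, "exposures needs a county column plus variables")
        return findings
    if expo["county"].duplicated().any():
        finding("error", config.exposures, "duplicate county rows in exposures")
    expo_counties = set(expo["county"])

    other_counties = None
    if config.rates is not None:
        try:
            rt = pd.read_csv(config.rates)
        except Exception as exc:
            finding("error", config.rates, f"unreadable rates file: {exc}")
            return findings
        need = {"county", "cancer", "age_group", "sex", "rate", "cases"}
        missing = need - set(rt.columns)
        if missing:
            finding("error", config.rates, f"missing columns: {sorted(missing)}")
        else:
            if (rt["rate"] < 0).any():
                finding("error", config.rates, "negative rates")
            if (rt["cases"] < 0).any():
                finding("error", config.rates, "negative case counts")
            dup = rt.duplicated(subset=["county", "cancer", "age_group", "sex"])
            if dup.any():
                finding("error", config.rates, f"{int(dup.sum())} duplicate county-stratum rows")
            other_counties = set(rt["county"])
    if config.counts is not None:
        try:
            ct = pd.read_csv(config.counts)
        except Exception as exc:
            finding("error", config.counts, f"unreadable counts file: {exc}")
            return findings
        need = {"county", "cancer", "age_group", "sex", "age_band", "cases", "population"}
        missing = need - set(ct.columns)
        if missing:
            finding("error", config.counts, f"missing columns: {sorted(missing)}")
        else:
            if (ct["population"] <= 0).any():
                bad = ct.loc[ct["population"] <= 0, "county"].unique()
                finding("error", config.counts,
                        f"nonpositive population for counties: {sorted(map(str, bad))}")
            if (ct["cases"] < 0).any():
                finding("error", config.counts, "negative case counts")
            if other_counties is None:
                other_counties = set(ct["county"])
        if config.std_pop is None:
            finding("warning", config.counts,
                    "no standard population file; the built-in 2000 U.S. standard is used")
        else:
            try:
                rates_mod.StandardPopulation.from_csv(config.std_pop)
            except Exception as exc:
                finding("error", config.std_pop, str(exc))
    if other_counties is not None:
        for c in sorted(expo_counties - other_counties):
            finding("warning", config.exposures,
                    f"county {c} present in exposures but absent from the outcome data")
        for c in sorted(other_counties - expo_counties):
            finding("warning", config.exposures,
                    f"county {c} present in the outcome data but absent from exposures")
    if config.trend is not None:
        try:
            tr = pd.read_csv(config.trend)
            need = {"year", "rate", "cancer", "sex"}
            missing = need - set(tr.columns)
            if missing:
                finding("error", config.trend, f"missing columns: {sorted(missing)}")
            elif (tr["rate"] <= 0).any():
                finding("error", config.trend, "nonpositive rates (log-linear trend model)")
        except Exception as exc:
            finding("error", config.trend, f"unreadable trend file: {exc}")
    return findings


# ---------------------------------------------------------------------------
# stages


def _load_rate_table(config: PipelineConfig) -> pd.DataFrame:
    if config.rates is not None:
        return pd.read_csv(config.rates)
    counts = pd.read_csv(config.counts)
    std = (
        rates_mod.StandardPopulation.from_csv(config.std_pop)
        if config.std_pop is not None
        else rates_mod.us_standard_2000()
    )
    return rates_mod.rate_table_from_counts(counts, std)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT, lineterminator="\n")


def run_study(config: PipelineConfig) -> dict:
    """Run the full pipeline and write per-stratum reports + a manifest.

    Returns the manifest dict.  Strata failing the inclusion filter are
    listed in the manifest and skipped.
    """
    config.validate()
    findings = validate_inputs(config)
    errors = [f for f in findings if f["level"] == "error"]
    if errors:
        raise DataError("; ".join(f"{f['file']}: {f['message']}" for f in errors))

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    expo = pd.read_csv(config.exposures).set_index("county").sort_index()
    missing_forced = [c for c in config.forced if c not in expo.columns]
    if missing_forced:
        raise DataError(f"exposures file lacks forced columns: {missing_forced}")
    spatial_cols = [c for c in SPATIAL_DEFAULT if c in expo.columns]

    rate_table = _load_rate_table(config).sort_values(
        ["cancer", "age_group", "sex", "county"], kind="mergesort"
    )
    _write_tsv(rate_table, outdir / "rate_table.tsv")

    # the study's county universe is the exposure table ("62 counties")
    n_total = int(expo.index.nunique())
    incl = rates_mod.inclusion_filter(
        rate_table, n_total, min_fraction=config.min_fraction, min_cases=config.min_cases
    )
    _write_tsv(incl.qualifying, outdir / "inclusion.tsv")

    manifest: dict = {
        # outdir is where the report lands, not an analysis input: leaving it
        # out keeps reruns byte-identical regardless of destination
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items() if k != "outdir"},
        "findings": findings,
        "n_counties": n_total,
        "required_counties": incl.required_counties,
        "strata": {},
        "skipped_strata": [
            "/".join(map(str, k))
            for k in incl.qualifying.loc[~incl.qualifying["retained"],
                                         ["cancer", "age_group", "sex"]].itertuples(index=False)
        ],
    }

    for key in incl.retained:
        cancer, age_group, sex = key
        tag = f"{cancer}_{age_group}_{sex}".replace("/", "-")
        sub = rate_table[
            (rate_table["cancer"] == cancer)
            & (rate_table["age_group"] == age_group)
            & (rate_table["sex"] == sex)
        ].set_index("county")
        data = expo.join(sub["rate"], how="inner").dropna(subset=["rate"])
        candidates = [
            c for c in expo.columns
            if c not in {*config.forced, *spatial_cols}
        ]
        study = EcologicalStudy(
            outcome=data["rate"],
            exposures=data[candidates],
            forced=data[list(config.forced)],
            spatial=data[spatial_cols] if spatial_cols else None,
        )
        res = study.fit(
            screen_p=config.screen_p,
            conflict_r=config.conflict_r,
            adj_r2_min=config.adj_r2_min,
            delta_bic=config.delta_bic,
            race_as_candidate=config.race_as_candidate,
        )
        _write_tsv(res.screening.to_frame(), outdir / f"screening_{tag}.tsv")
        combos_df = pd.DataFrame(
            [(i, ",".join(c)) for i, c in enumerate(res.combinations)],
            columns=["id", "members"],
        )
        _write_tsv(combos_df, outdir / f"combinations_{tag}.tsv")
        _write_tsv(res.selection.to_frame(), outdir / f"models_{tag}.tsv")
        if res.best is not None:
            coefs = res.best.coefficients().reset_index(names="variable")
            _write_tsv(coefs, outdir / f"coefficients_{tag}.tsv")
        manifest["strata"]["/".join(key)] = {
            "n_counties": int(len(data)),
            "n_screened": len(res.screening.records),
            "n_pooled": len(res.screening.pooled),
            "n_combinations": len(res.combinations),
            "n_ranked": len(res.selection.ranked),
            "empty": res.selection.empty,
            "best_subset": list(res.best.selected) if res.best else None,
            "best_adj_r2": round(res.best.adj_r2, 10) if res.best else None,
        }

    if config.trend is not None:
        trend_df = pd.read_csv(config.trend)
        trend_rows = []
        trend_report = {}
        for (cancer, sex), grp in trend_df.groupby(["cancer", "sex"], sort=True):
            grp = grp.sort_values("year")
            series = AnnualSeries(
                years=grp["year"].to_numpy(), rates=grp["rate"].to_numpy(),
                cancer=str(cancer), sex=str(sex),
            )
            fit = trends_mod.search_joinpoints(
                series, max_joinpoints=config.max_joinpoints,
                selection=config.joinpoint_selection, n_perm=config.n_perm,
                seed=config.seed,
            )
            a = fit.aapc()
            for seg in fit.segments:
                trend_rows.append((cancer, sex, seg.start, seg.end, seg.apc,
                                   seg.apc_ci[0], seg.apc_ci[1], seg.pvalue))
            trend_report[f"{cancer}/{sex}"] = {
                "breaks": list(fit.breaks),
                "aapc": a.estimate, "aapc_lo": a.ci[0], "aapc_hi": a.ci[1],
                "aapc_p": a.pvalue, "classification": fit.classify(),
            }
        _write_tsv(
            pd.DataFrame(trend_rows, columns=["cancer", "sex", "start", "end",
                                              "apc", "lo", "hi", "p"]),
            outdir / "trend_segments.tsv",
        )
        manifest["trends"] = trend_report

    body = json.dumps(manifest, indent=2, sort_keys=True, allow_nan=False)
    manifest["manifest_sha256"] = hashlib.sha256(body.encode()).hexdigest()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, allow_nan=False) + "\n"
    )
    return manifest


def sweep(config: PipelineConfig,
          screen_ps=(0.1, 0.2, 0.3),
          conflict_rs=(0.5, 0.6)) -> pd.DataFrame:
    """Sensitivity sweep over screening p and conflict r thresholds.

    Runs the full study once per setting (into subdirectories of
    ``config.outdir``) and returns/writes a comparison table of the best
    subset per stratum per setting.
    """
    rows = []
    base_out = Path(config.outdir)
    for p, r in itertools.product(screen_ps, conflict_rs):
        cfg = PipelineConfig(**{**asdict(config),
                                "screen_p": p, "conflict_r": r,
                                "outdir": str(base_out / f"p{p}_r{r}")})
        manifest = run_study(cfg)
        for key, info in manifest["strata"].items():
            rows.append((key, p, r, info["n_pooled"],
                         ",".join(info["best_subset"] or []) or "(none)",
                         info["best_adj_r2"]))
    table = pd.DataFrame(
        rows, columns=["stratum", "screen_p", "conflict_r", "n_pooled",
                       "best_subset", "best_adj_r2"],
    ).sort_values(["stratum", "screen_p", "conflict_r"], kind="mergesort")
    base_out.mkdir(parents=True, exist_ok=True)
    _write_tsv(table, base_out / "sweep.tsv")
    return table
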