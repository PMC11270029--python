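"""End-to-end orchestration: filter -> score -> join weather -> estimate.

A :class:`RunConfig` fully determines a run: given the same inputs and
config, every output file is reproduced byte-for-byte. All intermediates
(scored table, exclusion log, design metadata, coefficient and
marginal-effects tables) are written to the output directory together
with a JSON manifest and a report with telescoping stage counts:

    read = estimated N + chairs + short + unscorable + unjoined + missing

Speech tables may carry raw text (scored in-package), precomputed token
counts, or an already-numeric outcome column (as the synthetic generator
emits); the filter and join stages behave identically in all three modes.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .meteo import BinScheme, add_exposure_lags, add_weather_features, binarize_covariate
from .panel import (
    FEEstimate,
    assign_age_quartile,
    assign_period,
    build_design,
    fit_fe_ols,
    fit_interaction,
)
from .readability import score_table

__all__ = ["RunConfig", "RunReport", "run", "make_trend"]

OUTCOMES = (
    "flesch_kincaid",
    "flesch",
    "rix",
    "avg_sentence_length",
    "avg_word_syllables",
)
INTERACTIONS = ("none", "age_quartile", "gender", "period")
TRENDS = ("none", "linear", "cubic")


@dataclass
class RunConfig:
    speeches_path: str = "speeches.csv"
    weather_path: str = "weather.csv"
    demographics_path: str | None = None
    out_dir: str = "run_out"
    bin_scheme: str = "full"
    outcome: str = "flesch_kincaid"
    interaction: str = "none"
    month_fe: str = "month_of_year"
    cluster_scheme: str = "month_by_city"
    cluster_month: str = "month_of_year"
    trend: str = "none"
    lag_offsets: Sequence[int] = ()
    topic_col: str | None = None
    pollution_col: str | None = None
    pollution_threshold: float = 50.0
    min_words: int = 25
    seed: int = 0
    # column mappings
    id_col: str = "speech_id"
    speaker_col: str = "speaker_id"
    city_col: str = "city"
    date_col: str = "date"
    chair_col: str = "is_chair"
    text_col: str = "text"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"outcome must be one of {OUTCOMES}")
        if self.interaction not in INTERACTIONS:
            raise ValueError(f"interaction must be one of {INTERACTIONS}")
        if self.trend not in TRENDS:
            raise ValueError(f"trend must be one of {TRENDS}")
        BinScheme.from_name(self.bin_scheme)
        if self.interaction in ("age_quartile", "gender") and not self.demographics_path:
            raise ValueError(f"interaction {self.interaction!r} needs demographics")


@dataclass
class RunReport:
    counts: dict
    coefficients: pd.DataFrame
    marginal_effects: pd.DataFrame | None
    config: dict
    version: str
    timings: dict = field(default_factory=dict)
    estimate: FEEstimate | None = None

    def to_text(self) -> str:
        lines = [
            f"heatspeech {self.version} run report",
            "",
            "stage counts:",
        ]
        for k, v in self.counts.items():
            lines.append(f"  {k:>14}: {v}")
        lines.append("")
        lines.append("coefficients (exposure terms relative to the comfort bin):")
        lines.append(self.coefficients.to_string(index=False))
        if self.marginal_effects is not None:
            lines.append("")
            lines.append("marginal effects by (bin, level):")
            lines.append(self.marginal_effects.to_string(index=False))
        lines.append("")
        for k, v in self.timings.items():
            lines.append(f"  {k} took {v:.2f}s")
        return "\n".join(lines) + "\n"


def make_trend(dates, order: int) -> pd.DataFrame:
    """Polynomial week-index trend columns, standardized for conditioning.

    The week index counts whole weeks since the earliest date in the run;
    powers 1..order (order 1 = linear, 3 = cubic) are each centred and
    scaled to unit variance.
    """
    if order not in (1, 3):
        raise ValueError("trend order must be 1 (linear) or 3 (cubic)")
    d = pd.to_datetime(pd.Series(dates).reset_index(drop=True))
    week = ((d - d.min()).dt.days // 7).astype(float)
    out = {}
    for p in range(1, order + 1):
        col = week**p
        sd = col.std(ddof=0)
        out[f"trend_week{p if p > 1 else ''}"] = (
            (col - col.mean()) / sd if sd > 0 else col * 0.0
        )
    return pd.DataFrame(out)


def _validate_columns(config: RunConfig, speeches: pd.DataFrame, weather: pd.DataFrame) -> None:
    """Every referenced column must exist before any computation starts."""
    need_sp = [config.id_col, config.speaker_col, config.city_col, config.date_col]
    missing = [c for c in need_sp if c not in speeches.columns]
    count_cols = {"total_words", "total_sentences", "total_syllables", "long_words"}
    has_counts = count_cols <= set(speeches.columns)
    if (
        config.text_col not in speeches.columns
        and not has_counts
        and config.outcome not in speeches.columns
    ):
        missing.append(f"{config.text_col} (or token counts / outcome column)")
    need_wx = [config.city_col, config.date_col, "t_mean", "t_dew", "precip", "u_wind", "v_wind"]
    missing += [f"weather:{c}" for c in need_wx if c not in weather.columns]
    if config.pollution_col and config.pollution_col not in weather.columns:
        missing.append(f"weather:{config.pollution_col}")
    if config.topic_col and config.topic_col not in speeches.columns:
        missing.append(config.topic_col)
    if missing:
        raise ValueError(f"missing input columns: {missing}")


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline and persist all artifacts to out_dir."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict[str, str] = {}

    t0 = time.perf_counter()
    speeches = pd.read_csv(config.speeches_path)
    weather = pd.read_csv(config.weather_path)
    _validate_columns(config, speeches, weather)
    n_read = len(speeches)
    timings["read"] = time.perf_counter() - t0

    # --- filter + score -------------------------------------------------
    t0 = time.perf_counter()
    count_cols = {"total_words", "total_sentences", "total_syllables", "long_words"}
    scorable = config.text_col in speeches.columns or count_cols <= set(speeches.columns)
    if scorable:
        scored, excl = score_table(
            speeches,
            text_col=config.text_col,
            id_col=config.id_col,
            chair_col=config.chair_col,
            min_words=config.min_words,
        )
    else:
        # outcome precomputed: only the chair filter applies
        if config.chair_col in speeches.columns:
            chair = speeches[config.chair_col].astype(bool)
        else:
            chair = pd.Series(False, index=speeches.index)
        excl = pd.DataFrame(
            {"speech_id": speeches.loc[chair, config.id_col], "reason": "chair"}
        )
        scored = speeches.loc[~chair].copy()
    reasons = excl["reason"].value_counts().to_dict() if len(excl) else {}
    excl_path = out / "exclusions.csv"
    excl.to_csv(excl_path, index=False)
    manifest["exclusions"] = excl_path.name
    scored_path = out / "scored.csv"
    scored.to_csv(scored_path, index=False)
    manifest["scored"] = scored_path.name
    timings["score"] = time.perf_counter() - t0
    if scored.empty:
        raise RuntimeError("score stage: no speeches survived the filters")

    # --- weather features ----------------------------------------------
    t0 = time.perf_counter()
    scheme = BinScheme.from_name(config.bin_scheme)
    feats = add_weather_features(weather, scheme)
    if config.pollution_col:
        feats["pollution_flag"] = binarize_covariate(
            feats[config.pollution_col].to_numpy(), config.pollution_threshold
        )
    lag_cols: list[str] = []
    offsets = [k for k in config.lag_offsets if k != 0]
    if offsets:
        feats = add_exposure_lags(feats, offsets, config.city_col, config.date_col)
        lag_cols = [f"temp_bin_lag{k}" for k in offsets]
    wx_path = out / "weather_features.csv"
    feats.to_csv(wx_path, index=False)
    manifest["weather_features"] = wx_path.name
    timings["weather"] = time.perf_counter() - t0

    # --- demographics / interaction variable ----------------------------
    demo_col = None
    n_missing_demo = 0
    if config.interaction in ("age_quartile", "gender"):
        demo = pd.read_csv(config.demographics_path)
        add_cols = [
            c for c in demo.columns
            if c != config.speaker_col and c not in scored.columns
        ]
        if add_cols:
            scored = scored.merge(
                demo[[config.speaker_col] + add_cols], on=config.speaker_col, how="left"
            )
        year = pd.to_datetime(scored[config.date_col]).dt.year
        if config.interaction == "age_quartile":
            scored["age_at_speech"] = year - scored["birth_year"]
            scored["demo_level"] = assign_age_quartile(
                scored["age_at_speech"].to_numpy(dtype=float)
            )
        else:
            scored["demo_level"] = scored["gender"]
        demo_col = "demo_level"
    elif config.interaction == "period":
        year = pd.to_datetime(scored[config.date_col]).dt.year
        scored["demo_level"] = assign_period(year.to_numpy())
        demo_col = "demo_level"
    if demo_col is not None:
        missing_demo = scored[demo_col].isna()
        n_missing_demo = int(missing_demo.sum())
        scored = scored.loc[~missing_demo].copy()

    # --- extra controls --------------------------------------------------
    extra: list[str] = []
    if config.trend != "none":
        order = 1 if config.trend == "linear" else 3
        trend = make_trend(scored[config.date_col], order)
        scored = pd.concat([scored.reset_index(drop=True), trend], axis=1)
        extra += list(trend.columns)
    if config.topic_col:
        topics = pd.get_dummies(
            scored[config.topic_col].astype(str), prefix="topic", drop_first=True
        ).astype(float)
        scored = pd.concat([scored.reset_index(drop=True), topics], axis=1)
        extra += list(topics.columns)

    wx_extra: list[str] = []
    if config.pollution_col:
        wx_extra.append("pollution_flag")

    # --- design ----------------------------------------------------------
    t0 = time.perf_counter()
    wx_design = feats
    if lag_cols:
        # lag exposure dummies enter as additional regressor blocks
        design, dlog = _design_with_lags(
            scored, wx_design, scheme, config, extra + wx_extra, lag_cols
        )
    else:
        design, dlog = build_design(
            scored,
            wx_design,
            scheme,
            outcome=config.outcome,
            extra_controls=extra + wx_extra,
            month_fe=config.month_fe,
            cluster_scheme=config.cluster_scheme,
            cluster_month=config.cluster_month,
            speaker_col=config.speaker_col,
            city_col=config.city_col,
            date_col=config.date_col,
            id_col=config.id_col,
        )
    timings["design"] = time.perf_counter() - t0

    # --- estimate --------------------------------------------------------
    t0 = time.perf_counter()
    if demo_col is not None:
        merged_levels = _aligned_demo(scored, wx_design, design, config, demo_col)
        est, me = fit_interaction(
            design, merged_levels, speaker_constant=config.interaction == "gender"
        )
    else:
        est = fit_fe_ols(design)
        me = None
    timings["estimate"] = time.perf_counter() - t0

    # --- report ----------------------------------------------------------
    counts = {
        "read": n_read,
        "chair_dropped": int(reasons.get("chair", 0)),
        "short_dropped": int(reasons.get("short", 0)),
        "unscorable": int(reasons.get("unscorable", 0)),
        "missing_demographic": n_missing_demo,
        "unjoined": dlog["unjoined"],
        "missing_field": dlog["missing_field"],
        "estimated": dlog["estimated"],
    }
    assert counts["read"] == sum(v for k, v in counts.items() if k != "read"), (
        "stage counts do not telescope"
    )
    coef = est.to_frame()
    coef_path = out / "coefficients.csv"
    coef.to_csv(coef_path, index=False)
    (out / "coefficients.json").write_text(
        coef.to_json(orient="records", indent=2, double_precision=15)
    )
    manifest["coefficients"] = coef_path.name
    if me is not None:
        me_path = out / "marginal_effects.csv"
        me.to_csv(me_path, index=False)
        manifest["marginal_effects"] = me_path.name
    meta = {
        "colnames": design.colnames,
        "exposure_cols": design.exposure_cols,
        "n_obs": design.n_obs,
        "n_clusters": design.n_clusters,
        "fe_levels": est.fe_levels,
        "dropped_columns": est.dropped_columns,
        "demeaning_iterations": est.demeaning_iterations,
        "converged": est.converged,
    }
    (out / "design_meta.json").write_text(json.dumps(meta, indent=2))
    manifest["design_meta"] = "design_meta.json"

    report = RunReport(
        counts=counts,
        coefficients=coef,
        marginal_effects=me,
        config=asdict(config) | {"lag_offsets": list(config.lag_offsets)},
        version=__version__,
        timings=timings,
        estimate=est,
    )
    (out / "report.json").write_text(
        json.dumps(
            {
                "counts": counts,
                "config": report.config,
                "version": __version__,
                "design_meta": meta,
            },
            indent=2,
        )
    )
    (out / "report.txt").write_text(report.to_text())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return report


def _design_with_lags(scored, feats, scheme, config, extra, lag_cols):
    """Rebuild the design with lag/lead bin-dummy blocks appended.

    Lag dummies are encoded against the same reference bin and named
    ``{bin}@lag{k}``; rows with a missing lagged day drop out via the
    standard missing-field accounting.
    """
    labels = scheme.non_reference_labels
    feats = feats.copy()
    for lc in lag_cols:
        k = lc.removeprefix("temp_bin_lag")
        for lab in labels:
            feats[f"{lab}@lag{k}"] = np.where(
                pd.isna(feats[lc]), np.nan, (feats[lc] == lab).astype(float)
            )
    lag_dummy_cols = [
        f"{lab}@lag{lc.removeprefix('temp_bin_lag')}" for lc in lag_cols for lab in labels
    ]
    return build_design(
        scored,
        feats,
        scheme,
        outcome=config.outcome,
        extra_controls=list(extra) + lag_dummy_cols,
        month_fe=config.month_fe,
        cluster_scheme=config.cluster_scheme,
        cluster_month=config.cluster_month,
        speaker_col=config.speaker_col,
        city_col=config.city_col,
        date_col=config.date_col,
        id_col=config.id_col,
    )


def _aligned_demo(scored, feats, design, config, demo_col):
    """Demographic level per design row (the design may have dropped rows)."""
    sp = scored.copy()
    sp[config.date_col] = pd.to_datetime(sp[config.date_col])
    lookup = sp.set_index(config.id_col)[demo_col]
    if design.row_ids is None:
        raise ValueError("design lacks row ids; cannot align demographics")
    return lookup.reindex(design.row_ids).to_numpy()
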