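"""End-to-end orchestration: simulate -> timeline -> color -> rank -> fit -> report.

Each stage reads the CSVs the previous stages wrote under ``outdir`` and
writes its own outputs there, so partial runs resume from cached stage
outputs.  A run manifest (config snapshot, seed, package version, input
digests, output paths) makes every run reproducible; with a fixed seed the
report tables are byte-identical across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import (
    ModelSpec,
    fit_hurdle,
    fit_lme,
    lrt,
    screen_collinearity,
    zero_inflation_check,
)
from .colorimetry import color_outcomes
from .config import MODELED_BEHAVIORS, PERIODS, StudyConfig
from .dominance import matrix_from_interactions, rank_age_correlation, rank_individuals
from .hormones import (
    build_timelines,
    hormone_outcomes,
    timeline_summary,
    timelines_to_frame,
)
from .synthetic import generate_study

log = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "timeline", "color", "rank", "fit", "report")

#: Behaviors carried into the hurdle-model stage (the modeled outcomes).
FIT_BEHAVIORS = ("female_approach", "grooming_female", "estrus_call", "male_holding")
#: Continuous outcomes fit by Gaussian mixed models on the log scale.
LME_OUTCOMES = (
    ("luminance", "log_luminance", "color"),
    ("rg_ratio", "rg_ratio", "color"),
    ("pdg", "log_pdg", "hormone"),
    ("e1c", "log_e1c", "hormone"),
    ("e1c_pdg_ratio", "log_e1c_pdg_ratio", "hormone"),
)


class SchemaError(RuntimeError):
    """An expected input file or column is missing."""


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise SchemaError(f"stage '{stage}' needs missing input file: {path}")
    return path


def _read_csv(path: Path, stage: str, columns: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(_require(path, stage))
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path} is missing column(s) {missing} (stage '{stage}')")
    return df


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write(df: pd.DataFrame, path: Path) -> Path:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.10g")
    return path


def run_pipeline(
    config: StudyConfig | str | Path | None = None,
    outdir: str | Path = "pregsignal_out",
    stages: tuple[str, ...] | list[str] = ALL_STAGES,
    seed: int | None = None,
    log_level: str = "INFO",
) -> dict:
    """Execute the selected stages in dependency order; returns the manifest."""
    logging.basicConfig(level=getattr(logging, log_level.upper(), logging.INFO))
    if config is None:
        config = StudyConfig()
    elif not isinstance(config, StudyConfig):
        config = StudyConfig.from_yaml(config)
    if seed is not None:
        config = StudyConfig.from_dict({**config.to_dict(), "rng_seed": int(seed)})
    outdir = Path(outdir)
    data = outdir / "data"
    results = outdir / "results"
    bad = [s for s in stages if s not in ALL_STAGES]
    if bad:
        raise ValueError(f"unknown stage(s) {bad}; choose from {ALL_STAGES}")
    stages = [s for s in ALL_STAGES if s in stages]

    outputs: dict[str, str] = {}
    decisions: list[str] = []

    if "simulate" in stages:
        study = generate_study(config)
        paths = study.write(data)
        outputs.update({f"data/{k}": str(v) for k, v in paths.items()})
        log.info("simulated study: %d focals, %d hormone samples",
                 len(study.focals), len(study.hormones))

    timelines = None
    if {"timeline", "color", "fit", "report"} & set(stages):
        hormones = _read_csv(
            data / "hormones.csv", "timeline",
            ("female_id", "date", "pdg_ug_g", "e1c_ng_g"),
        )
        roster = _read_csv(data / "roster.csv", "timeline", ("female_id", "age"))
        hormones["date"] = pd.to_datetime(hormones["date"])
        timelines = build_timelines(
            hormones, roster, config.study_start, config.study_end
        )

    if "timeline" in stages:
        outputs["timeline/labels"] = str(
            _write(timelines_to_frame(timelines), results / "timeline_labels.csv")
        )
        outputs["timeline/summary"] = str(
            _write(timeline_summary(timelines), results / "timeline_summary.csv")
        )
        hout = hormone_outcomes(hormones, timelines)
        outputs["timeline/hormone_outcomes"] = str(
            _write(hout, results / "hormone_outcomes.csv")
        )
        for f, tl in timelines.items():
            for fl in tl.flags:
                decisions.append(f"timeline {f}: {fl}")

    if "color" in stages:
        color = _read_csv(data / "color.csv", "color", ("female_id", "date", "lw", "mw"))
        color["date"] = pd.to_datetime(color["date"]).dt.date
        out = color_outcomes(color)
        out["period"] = [
            timelines[str(f)].label(d) if str(f) in timelines else "other"
            for f, d in zip(out["female_id"], out["date"])
        ]
        outputs["color/outcomes"] = str(_write(out, results / "color_outcomes.csv"))

    if "rank" in stages:
        inter = _read_csv(
            data / "interactions.csv", "rank", ("winner_id", "loser_id")
        )
        roster = _read_csv(data / "roster.csv", "rank", ("female_id", "age"))
        mat = matrix_from_interactions(inter)
        ranks = rank_individuals(mat)
        r_age = rank_age_correlation(ranks, roster)
        outputs["rank/matrix"] = str(
            _write(mat.reset_index(names="winner"), results / "agonistic_matrix.csv")
        )
        outputs["rank/scores"] = str(
            _write(ranks.reset_index(), results / "rank_scores.csv")
        )
        decisions.append(
            f"rank-age Pearson r = {r_age:.3f}; rank excluded from models "
            "(age retained) when |r| > 0.9"
        )
        outputs["rank/age_correlation"] = f"{r_age:.6f}"

    if "fit" in stages:
        fit_out = _run_fit_stage(config, data, results, timelines, decisions)
        outputs.update(fit_out)

    if "report" in stages:
        outputs.update(_run_report_stage(results, decisions))

    manifest = {
        "package_version": __version__,
        "seed": config.rng_seed,
        "config": config.to_dict(),
        "stages": list(stages),
        "input_digests": {
            p.name: _sha256(p) for p in sorted(data.glob("*.csv")) if p.exists()
        },
        "outputs": outputs,
        "decisions": decisions,
    }
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _labeled_focals(config, data, timelines) -> pd.DataFrame:
    focals = _read_csv(data / "focals.csv", "fit", ("female_id", "date"))
    roster = _read_csv(data / "roster.csv", "fit", ("female_id", "age"))
    focals["date"] = pd.to_datetime(focals["date"]).dt.date
    focals["period"] = [
        timelines[str(f)].label(d) if str(f) in timelines else "other"
        for f, d in zip(focals["female_id"], focals["date"])
    ]
    focals = focals.merge(roster[["female_id", "age"]], on="female_id", how="left")
    return focals


def _run_fit_stage(config, data, results, timelines, decisions) -> dict[str, str]:
    focals = _labeled_focals(config, data, timelines)
    n_other = int((focals["period"] == "other").sum())
    if n_other:
        decisions.append(f"fit: excluded {n_other} focal(s) labeled 'other'")
        focals = focals[focals["period"] != "other"]

    screen_behaviors = [
        b for b in (*MODELED_BEHAVIORS, "contact")
        if f"{b}_count" in focals.columns
    ]
    report, retained, dropped = screen_collinearity(focals, screen_behaviors)
    for drop, keep in dropped.items():
        decisions.append(f"collinearity: dropped {drop}, retained {keep}")

    lrt_rows, coef_rows = [], []
    spec_base = ModelSpec(response="", )
    for beh in FIT_BEHAVIORS:
        if beh in dropped:
            decisions.append(f"fit: {beh} dropped at screening, not modeled")
            continue
        spec = ModelSpec(response=beh)
        sub = focals[focals[f"{beh}_count"].notna()]
        # restrict to levels where the behavior is estimable (non-degenerate)
        full = fit_hurdle(sub, spec)
        null = fit_hurdle(sub, spec.null_spec())
        zi = zero_inflation_check(sub, spec)
        decisions.append(
            f"zero-inflation check {beh}: chose {zi.chosen} "
            f"(AIC {zi.aic_binomial:.1f} vs {zi.aic_zero_inflated:.1f})"
        )
        if full.binary is not None and null.binary is not None:
            res = lrt(full.binary, null.binary, label=beh)
            lrt_rows.append(_lrt_row(beh, "binary", res))
            tab = full.binary.coef_table()
            tab.insert(0, "part", "binary")
            tab.insert(0, "outcome", beh)
            coef_rows.append(tab)
            # re-leveled fit: month2-vs-month1 contrast
            relev = fit_hurdle(sub, spec.releveled("month1"))
            if relev.binary is not None:
                rtab = relev.binary.coef_table()
                rtab = rtab[rtab["term"] == "status[month2]"].copy()
                rtab["term"] = "status[month2 vs month1]"
                rtab.insert(0, "part", "binary")
                rtab.insert(0, "outcome", beh)
                coef_rows.append(rtab)
        else:
            decisions.append(f"fit: binary part degenerate for {beh}: {full.flags}")
        if full.count is not None and null.count is not None:
            res = lrt(full.count, null.count, label=beh)
            lrt_rows.append(_lrt_row(beh, "count", res))
            tab = full.count.coef_table()
            tab.insert(0, "part", "count")
            tab.insert(0, "outcome", beh)
            coef_rows.append(tab)
            # combined-hurdle accounting (both parts summed)
            lrt_rows.append(_lrt_row(beh, "combined", lrt(full, null, label=beh)))
        else:
            refusals = [f for f in full.flags if "refused" in f]
            for r in refusals:
                decisions.append(f"fit: {r}")

    # continuous outcomes: color and hormones
    color_path = results / "color_outcomes.csv"
    horm_path = results / "hormone_outcomes.csv"
    roster = _read_csv(data / "roster.csv", "fit", ("female_id", "age"))
    for name, col, src in LME_OUTCOMES:
        path = color_path if src == "color" else horm_path
        if not path.exists():
            decisions.append(f"fit: {name} skipped, missing {path.name}")
            continue
        df = pd.read_csv(path)
        df = df[df["period"].isin(PERIODS)]
        df = df.merge(roster[["female_id", "age"]], on="female_id", how="left")
        if df[col].isna().any() or len(df) < 10:
            decisions.append(f"fit: {name} skipped (insufficient data)")
            continue
        spec = ModelSpec(response=col)
        full = fit_lme(df, spec)
        null = fit_lme(df, spec.null_spec())
        res = lrt(full, null, label=name)
        lrt_rows.append(_lrt_row(name, "lme", res))
        tab = full.coef_table()
        tab.insert(0, "part", "lme")
        tab.insert(0, "outcome", name)
        coef_rows.append(tab)
        relev = fit_lme(df, spec.releveled("month1"))
        rtab = relev.coef_table()
        rtab = rtab[rtab["term"] == "status[month2]"].copy()
        rtab["term"] = "status[month2 vs month1]"
        rtab.insert(0, "part", "lme")
        rtab.insert(0, "outcome", name)
        coef_rows.append(rtab)
        for fl in full.flags:
            decisions.append(f"fit {name}: {fl}")

    out = {}
    out["fit/screen"] = str(_write(report, results / "collinearity_screen.csv"))
    out["fit/lrt"] = str(
        _write(pd.DataFrame(lrt_rows), results / "table_lrt.csv")
    )
    coef = (
        pd.concat(coef_rows, ignore_index=True)
        if coef_rows
        else pd.DataFrame(columns=["outcome", "part", "term", "estimate", "se", "z", "p"])
    )
    out["fit/coefficients"] = str(_write(coef, results / "table_coefficients.csv"))
    labeled = focals
    out["fit/labeled_focals"] = str(_write(labeled, results / "labeled_focals.csv"))
    return out


def _lrt_row(outcome, part, res) -> dict:
    return {
        "outcome": outcome,
        "part": part,
        "X2": res.statistic,
        "delta_df": res.delta_df,
        "p": res.p_value,
        "loglik_full": res.loglik_full,
        "loglik_null": res.loglik_null,
    }


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(x.std(ddof=1) / np.sqrt(x.size)) if x.size > 1 else 0.0


def render_report(results: Path, decisions: list[str] | None = None) -> dict[str, str]:
    """Per-period mean +/- SEM tables and figures from the fit outputs."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    decisions = decisions if decisions is not None else []
    out: dict[str, str] = {}
    rows = []
    focal_path = results / "labeled_focals.csv"
    if focal_path.exists():
        focals = pd.read_csv(focal_path)
        for beh in FIT_BEHAVIORS:
            col = f"{beh}_count"
            if col not in focals.columns:
                continue
            for period in PERIODS:
                sub = (focals.loc[focals["period"] == period, col] > 0).astype(float)
                if len(sub):
                    rows.append(
                        {
                            "outcome": beh,
                            "measure": "occurrence_probability",
                            "period": period,
                            "mean": float(sub.mean()),
                            "sem": _sem(sub.to_numpy()),
                            "n": int(len(sub)),
                        }
                    )
    color_path = results / "color_outcomes.csv"
    if color_path.exists():
        color = pd.read_csv(color_path)
        for col in ("luminance", "rg_ratio"):
            for period in PERIODS:
                sub = color.loc[color["period"] == period, col]
                if len(sub):
                    rows.append(
                        {
                            "outcome": col,
                            "measure": "mean",
                            "period": period,
                            "mean": float(sub.mean()),
                            "sem": _sem(sub.to_numpy()),
                            "n": int(len(sub)),
                        }
                    )
    means = pd.DataFrame(
        rows, columns=["outcome", "measure", "period", "mean", "sem", "n"]
    )
    if means.empty:
        log.warning("report: no fitted results found; writing empty report")
    out["report/period_means"] = str(_write(means, results / "report_period_means.csv"))

    if not means.empty:
        for measure, fname in (
            ("occurrence_probability", "fig_behavior_probabilities.png"),
            ("mean", "fig_color_outcomes.png"),
        ):
            sub = means[means["measure"] == measure]
            if sub.empty:
                continue
            outcomes = sorted(sub["outcome"].unique())
            fig, axes = plt.subplots(
                1, len(outcomes), figsize=(3.2 * len(outcomes), 3), squeeze=False
            )
            for ax, oc in zip(axes[0], outcomes):
                s = sub[sub["outcome"] == oc].set_index("period").reindex(list(PERIODS))
                ax.errorbar(range(len(PERIODS)), s["mean"], yerr=s["sem"], fmt="o-")
                ax.set_xticks(range(len(PERIODS)), PERIODS)
                ax.set_title(oc)
            fig.tight_layout()
            fig.savefig(results / fname, dpi=120)
            plt.close(fig)
            out[f"report/{fname}"] = str(results / fname)
    return out


def _run_report_stage(results: Path, decisions: list[str]) -> dict[str, str]:
    return render_report(results, decisions)
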