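"""Synthetic field-study generator.

Emits complete studies — roster, fecal hormone series, focal behavioral
records, face color records and agonistic interactions — with the
statistical structure the analysis stage assumes: hurdle-structured
behavior counts with crossed female/date random effects, a luteal PdG rise
anchoring each female's reproductive timeline, period-dependent
receptor-space color shifts, and a linear dominance hierarchy.  Ground
truth (planted conceptions, rates, hierarchy, random-effect SDs) is kept
alongside the data so recovery tests can score the pipeline.

Calibration of behavior rates is in expectation: for a behavior with
per-focal event rate r (period total / focals in period) the occurrence
probability is p = min(p_max, r/2) and the zero-truncated positive-count
mean is r/p, so expected period totals match the configured totals while
every behavior keeps >= 70% zero focals.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import (
    BEHAVIOR_DIRECTION,
    PERIODS,
    StudyConfig,
)
from .hormones import label_periods


# --------------------------------------------------------------------------
# zero-truncated negative binomial helpers


def ztnb_mean(mu: float, k: float) -> float:
    """Mean of a zero-truncated NB with underlying mean mu and size k."""
    p0 = (k / (k + mu)) ** k
    return mu / (1.0 - p0)


def ztnb_mu_from_mean(target: float, k: float) -> float:
    """Underlying NB mean whose zero-truncated mean equals ``target`` (> 1)."""
    if target <= 1.0:
        raise ValueError("zero-truncated mean must exceed 1")
    lo, hi = 1e-9, target
    return brentq(lambda m: ztnb_mean(m, k) - target, lo, hi, xtol=1e-10)


def sample_ztnb(rng: np.random.Generator, mu: np.ndarray, k: float) -> np.ndarray:
    """Zero-truncated NB draws by rejection (redraw zeros)."""
    mu = np.asarray(mu, dtype=float)
    out = np.zeros(mu.shape, dtype=int)
    todo = np.ones(mu.shape, dtype=bool)
    while todo.any():
        m = mu[todo]
        draw = rng.negative_binomial(k, k / (k + m))
        out[todo] = draw
        todo = out == 0
    return out


# Gauss-Hermite nodes for marginalizing the Gaussian random effects when
# calibrating: rates are targets for the *marginal* expectation, so the
# planted logit/log-mean offsets must undo the Jensen shift the random
# effects introduce.
_GH_X, _GH_W = np.polynomial.hermite_e.hermegauss(41)
_GH_W = _GH_W / _GH_W.sum()


def _marginal_occurrence(c: float, sd: float) -> float:
    return float(np.sum(_GH_W * expit(c + sd * _GH_X)))


def _marginal_ztnb_mean(log_mu: float, sd: float, k: float) -> float:
    mu = np.exp(log_mu + sd * _GH_X)
    return float(np.sum(_GH_W * mu / (1.0 - (k / (k + mu)) ** k)))


def _solve_occurrence_offset(p: float, sd: float) -> float:
    """Logit offset c with E_u[expit(c + u)] = p, u ~ N(0, sd^2)."""
    if sd == 0:
        return float(logit(p))
    return brentq(lambda c: _marginal_occurrence(c, sd) - p, -30.0, 30.0, xtol=1e-12)


def _solve_count_offset(target: float, sd: float, k: float) -> float:
    """Log-mean offset with marginal zero-truncated mean equal to ``target``."""
    if sd == 0:
        return float(np.log(ztnb_mu_from_mean(target, k)))
    lo, hi = np.log(1e-9), np.log(target) + 5.0
    return brentq(
        lambda lm: _marginal_ztnb_mean(lm, sd, k) - target, lo, hi, xtol=1e-12
    )


# --------------------------------------------------------------------------
# rate calibration


def calibrate_rates(config: StudyConfig) -> pd.DataFrame:
    """Per (behavior, period) occurrence probability and truncated-count mean.

    Total-parameterized behaviors are calibrated from the configured
    per-period event totals; grooming behaviors use configured occurrence
    probabilities directly.  The planted ``logit_occ`` and ``log_mu``
    offsets are solved so the *marginal* occurrence probability and
    truncated-count mean (after integrating over the crossed random
    effects) hit p_occurrence and zt_mean, keeping expected period totals
    on target.
    """
    alloc = config.focal_allocation()
    n_focals = {p: sum(alloc[p]) for p in PERIODS}
    sd_occ = float(np.hypot(config.re_sd_female_occ, config.re_sd_date_occ))
    sd_cnt = float(np.hypot(config.re_sd_female_count, config.re_sd_date_count))
    rows = []

    def add(beh, period, p, m):
        rows.append(
            {
                "behavior": beh,
                "period": period,
                "p_occurrence": p,
                "zt_mean": m,
                "logit_occ": _solve_occurrence_offset(p, sd_occ) if p > 0 else -np.inf,
                "log_mu": (
                    _solve_count_offset(m, sd_cnt, config.dispersion)
                    if m > 1.0
                    else -np.inf
                ),
            }
        )

    for beh, totals in config.behavior_totals.items():
        for period, total in zip(PERIODS, totals):
            rate = total / n_focals[period] if n_focals[period] else 0.0
            if rate <= 0:
                p, m = 0.0, 0.0
            else:
                p = min(config.occurrence_p_max, rate / config.min_positive_mean)
                m = rate / p
            add(beh, period, p, m)
    for beh, probs in config.groom_probs.items():
        for period, p in zip(PERIODS, probs):
            add(beh, period, float(p), config.groom_bout_mean if p > 0 else 0.0)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# generators


def generate_roster(
    config: StudyConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, dict]:
    """Roster plus planted ground truth (conceptions, ranks, deliveries).

    Ages follow the configured vector or are drawn without replacement from
    8-17 years; the dominance hierarchy is age-ordered (oldest = rank 1),
    which also plants the rank-age collinearity the analysis screens for.
    Each delivery date is the planted conception plus a gestation drawn
    around the 176.3-day species mean.
    """
    if config.n_females < 1:
        raise ValueError("cannot generate an empty roster")
    ids = [f"F{i + 1}" for i in range(config.n_females)]
    if config.ages is not None:
        ages = np.asarray(config.ages, dtype=int)
    else:
        pool = np.arange(8, 18)
        ages = rng.choice(pool, size=config.n_females, replace=config.n_females > pool.size)
    conceptions = config.conception_dates()
    gest = np.round(
        rng.normal(
            config.cycle.gestation_mean_days,
            config.cycle.gestation_sd_days,
            config.n_females,
        )
    ).astype(int)
    deliveries = [c + timedelta(days=int(g)) for c, g in zip(conceptions, gest)]
    # oldest female on top; ties broken by id for determinism
    order = sorted(range(config.n_females), key=lambda i: (-ages[i], ids[i]))
    rank = np.empty(config.n_females, dtype=int)
    for pos, i in enumerate(order):
        rank[i] = pos + 1
    roster = pd.DataFrame(
        {"female_id": ids, "age": ages, "delivery_date": deliveries}
    )
    truth = {
        "conception_dates": {i: c for i, c in zip(ids, conceptions)},
        "rank": {i: int(r) for i, r in zip(ids, rank)},
        "gestation_days": {i: int(g) for i, g in zip(ids, gest)},
    }
    return roster, truth


def generate_hormone_series(
    config: StudyConfig,
    true_conceptions: dict[str, date],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Fecal PdG/E1C series with a planted luteal rise per female.

    The planted rise date is conception + 2 days (so a classifier placing
    conception at the last fertile day, rise - 2, recovers the plant).
    PdG is Gaussian around the baseline mean before the rise, then jumps to
    the month-1 level and steps down to the month-2 level 30 days after
    conception (multiplicative lognormal noise while elevated).  E1C is
    flat apart from a follicular bump across the fertile window, so the
    E1C/PdG ratio is higher in month 2 than month 1.
    """
    cyc = config.cycle
    if cyc.cadence_days > 7:
        raise ValueError("sampling cadence must average at least one sample per 7 days")
    frames = []
    truth: dict = {"rise_dates": {}, "detectability_flags": {}}
    for female in sorted(true_conceptions):
        conception = true_conceptions[female]
        rise = conception + timedelta(days=2)
        month2_start = conception + timedelta(days=30)
        fertile_lo, fertile_hi = rise - timedelta(days=6), rise - timedelta(days=2)
        days = [
            config.study_start + timedelta(days=int(d))
            for d in range(0, config.n_days, cyc.cadence_days)
        ]
        keep = rng.random(len(days)) >= cyc.gap_prob
        days = [d for d, k in zip(days, keep) if k]
        pdg = np.empty(len(days))
        e1c = np.empty(len(days))
        for j, day in enumerate(days):
            if day < rise:
                pdg[j] = rng.normal(cyc.baseline_pdg_mean, cyc.baseline_pdg_sd)
            else:
                level = cyc.pdg_month1 if day < month2_start else cyc.pdg_month2
                pdg[j] = level * np.exp(rng.normal(0.0, cyc.noise_cv))
            lvl = cyc.e1c_level
            if fertile_lo <= day <= fertile_hi:
                lvl *= cyc.e1c_fertile_boost
            e1c[j] = lvl * np.exp(rng.normal(0.0, cyc.noise_cv))
        pdg = np.clip(pdg, 1e-6, None)
        frames.append(
            pd.DataFrame(
                {
                    "female_id": female,
                    "date": days,
                    "pdg_ug_g": np.round(pdg, 6),
                    "e1c_ng_g": np.round(e1c, 6),
                }
            )
        )
        truth["rise_dates"][female] = rise
        detectable = cyc.pdg_month1 >= cyc.baseline_pdg_mean + 2 * cyc.baseline_pdg_sd
        truth["detectability_flags"][female] = (
            [] if detectable else ["rise_below_detectability"]
        )
    return pd.concat(frames, ignore_index=True), truth


def _behavior_columns(config: StudyConfig) -> list[str]:
    return list(config.behavior_totals) + list(config.groom_probs) + ["contact"]


def generate_focals(
    config: StudyConfig,
    true_conceptions: dict[str, date],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, dict]:
    """Focal records with hurdle-structured counts and crossed random effects.

    Occurrence is Bernoulli on the logit scale (period rate + female + date
    random intercepts); positive counts are zero-truncated negative
    binomial with the random effects entering the log-mean.  Body contact
    is generated as a superset of female-directed grooming (plus an
    independent extra-occurrence probability), planting the strong
    grooming-contact collinearity the screening stage must catch.
    """
    rates = calibrate_rates(config)
    rate_lut = {
        (r.behavior, r.period): (r.p_occurrence, r.zt_mean, r.logit_occ, r.log_mu)
        for r in rates.itertuples()
    }
    alloc = config.focal_allocation()
    females = sorted(true_conceptions)

    all_days = [config.study_start + timedelta(days=d) for d in range(config.n_days)]
    u_date_occ = {d: rng.normal(0.0, config.re_sd_date_occ) for d in all_days}
    u_date_cnt = {d: rng.normal(0.0, config.re_sd_date_count) for d in all_days}
    u_fem_occ = {f: rng.normal(0.0, config.re_sd_female_occ) for f in females}
    u_fem_cnt = {f: rng.normal(0.0, config.re_sd_female_count) for f in females}

    behaviors = list(config.behavior_totals) + list(config.groom_probs)
    rows = []
    for fi, female in enumerate(females):
        labels = label_periods(
            true_conceptions[female], config.study_start, config.study_end
        )
        for period in PERIODS:
            days = sorted(d for d, lab in labels.items() if lab == period)
            if not days:
                raise ValueError(f"no study days labeled {period}: cannot place focals")
            n = alloc[period][fi]
            # multiple focal blocks per day are allowed once a period's days
            # are exhausted (6 blocks/day in the field design)
            picked = sorted(
                rng.choice(len(days), size=n, replace=n > len(days)).tolist()
            )
            for ix in picked:
                day = days[ix]
                rec = {"female_id": female, "date": day, "period": period}
                for beh in behaviors:
                    p, _, logit_occ, log_mu = rate_lut[(beh, period)]
                    if p <= 0.0:
                        count = 0
                    else:
                        p_adj = expit(logit_occ + u_fem_occ[female] + u_date_occ[day])
                        if rng.random() >= p_adj:
                            count = 0
                        else:
                            mu_adj = np.exp(
                                log_mu + u_fem_cnt[female] + u_date_cnt[day]
                            )
                            count = int(
                                sample_ztnb(
                                    rng, np.array([mu_adj]), config.dispersion
                                )[0]
                            )
                    rec[f"{beh}_count"] = count
                # grooming state durations: Gamma bout lengths when present
                for beh in config.groom_probs:
                    c = rec[f"{beh}_count"]
                    rec[f"{beh}_duration_s"] = (
                        float(
                            np.round(
                                rng.gamma(2.0, config.groom_duration_scale_s / 2.0, c).sum(),
                                1,
                            )
                        )
                        if c
                        else 0.0
                    )
                # body contact: superset of female-directed grooming
                g = rec["grooming_female_count"]
                extra = rng.random() < config.contact_extra_prob
                if g > 0:
                    rec["contact_count"] = g + int(rng.poisson(0.3))
                elif extra:
                    rec["contact_count"] = 1 + int(rng.poisson(0.5))
                else:
                    rec["contact_count"] = 0
                rows.append(rec)
    focals = pd.DataFrame(rows)
    truth = {
        "rates": rates.to_dict(orient="records"),
        "random_effects": {
            "female_occurrence": u_fem_occ,
            "female_count": u_fem_cnt,
        },
        "re_sds": {
            "female_occ": config.re_sd_female_occ,
            "date_occ": config.re_sd_date_occ,
            "female_count": config.re_sd_female_count,
            "date_count": config.re_sd_date_count,
        },
        # true status effects on the occurrence logit, PCP baseline
        "occurrence_logit_effects": {
            beh: {
                per: (
                    float(rate_lut[(beh, per)][2] - rate_lut[(beh, "PCP")][2])
                    if rate_lut[(beh, per)][0] > 0 and rate_lut[(beh, "PCP")][0] > 0
                    else None
                )
                for per in ("month1", "month2")
            }
            for beh in behaviors
        },
    }
    return focals, truth


def generate_color(
    config: StudyConfig,
    true_conceptions: dict[str, date],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-photo receptor captures drawn lognormally around period means."""
    for period in PERIODS:
        lw, mw = config.color.lw_mw(period)
        if lw <= 0 or mw <= 0:
            raise ValueError("configured LW/MW means must be positive")
    alloc = config.photo_allocation()
    females = sorted(true_conceptions)
    rows = []
    for fi, female in enumerate(females):
        labels = label_periods(
            true_conceptions[female], config.study_start, config.study_end
        )
        for period in PERIODS:
            days = sorted(d for d, lab in labels.items() if lab == period)
            n = alloc[period][fi]
            picked = sorted(rng.choice(len(days), size=n, replace=n > len(days)).tolist())
            lw0, mw0 = config.color.lw_mw(period)
            for ix in picked:
                lw = lw0 * np.exp(rng.normal(0.0, config.color.log_sd))
                mw = mw0 * np.exp(rng.normal(0.0, config.color.log_sd))
                rows.append(
                    {
                        "female_id": female,
                        "date": days[ix],
                        "period": period,
                        "lw": round(float(lw), 6),
                        "mw": round(float(mw), 6),
                    }
                )
    return pd.DataFrame(rows)


def generate_agonistic(
    config: StudyConfig,
    roster: pd.DataFrame,
    rank: dict[str, int],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Dyadic agonistic interactions from a linear hierarchy.

    P(i defeats j) = expit(steepness * (rank_j - rank_i)) with rank 1 on
    top, so steepness -> infinity makes the higher-ranked female win every
    interaction and steepness 0 makes outcomes symmetric.
    """
    ids = sorted(roster["female_id"].astype(str))
    if len(ids) < 2:
        raise ValueError("agonistic interactions need at least two females")
    behaviors = ["threat", "chase", "attack", "avoid", "retreat"]
    rows = []
    for _ in range(config.n_interactions):
        i, j = rng.choice(len(ids), size=2, replace=False)
        a, b = ids[int(i)], ids[int(j)]
        p_a = expit(config.hierarchy_steepness * (rank[b] - rank[a]))
        winner, loser = (a, b) if rng.random() < p_a else (b, a)
        day = config.study_start + timedelta(days=int(rng.integers(0, config.n_days)))
        rows.append(
            {
                "date": day,
                "winner_id": winner,
                "loser_id": loser,
                "behavior": behaviors[int(rng.integers(0, len(behaviors)))],
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# whole-study orchestration


@dataclass
class SyntheticStudy:
    """A generated study with its ground truth."""

    config: StudyConfig
    roster: pd.DataFrame
    hormones: pd.DataFrame
    focals: pd.DataFrame
    color: pd.DataFrame
    interactions: pd.DataFrame
    truth: dict

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in (
            ("roster", self.roster),
            ("hormones", self.hormones),
            ("focals", self.focals),
            ("color", self.color),
            ("interactions", self.interactions),
        ):
            p = outdir / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = p
        tpath = outdir / "truth.json"
        with open(tpath, "w", encoding="utf-8") as fh:
            json.dump(_jsonify(self.truth), fh, indent=2, sort_keys=True)
        paths["truth"] = tpath
        mpath = outdir / "metadata.json"
        with open(mpath, "w", encoding="utf-8") as fh:
            json.dump(
                {"rng_seed": self.config.rng_seed, "config": self.config.to_dict()},
                fh,
                indent=2,
                sort_keys=True,
            )
        paths["metadata"] = mpath
        return paths


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, date):
        return obj.isoformat()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def generate_study(config: StudyConfig | None = None) -> SyntheticStudy:
    """Generate a full synthetic study from one seed (fully deterministic)."""
    config = config or StudyConfig()
    rng = np.random.default_rng(config.rng_seed)
    roster, truth = generate_roster(config, rng)
    conceptions = truth["conception_dates"]
    hormones, h_truth = generate_hormone_series(config, conceptions, rng)
    truth.update(h_truth)
    focals, f_truth = generate_focals(config, conceptions, rng)
    truth.update(f_truth)
    color = generate_color(config, conceptions, rng)
    interactions = generate_agonistic(config, roster, truth["rank"], rng)
    truth["color_targets"] = {
        per: dict(zip(("lw", "mw"), config.color.lw_mw(per))) for per in PERIODS
    }
    truth["hierarchy_steepness"] = config.hierarchy_steepness
    return SyntheticStudy(
        config=config,
        roster=roster,
        hormones=hormones,
        focals=focals,
        color=color,
        interactions=interactions,
        truth=truth,
    )
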