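"""Reproductive-timeline classification from fecal hormone series.

The luteal onset is the first sample whose PdG concentration is at least
``k`` (default 2) sample standard deviations above the mean of the 3-4
immediately preceding baseline samples.  Because fecal PdG lags circulating
progesterone by 2-3 days, the peri-ovulatory days are rise-3 and rise-2 and
the fertile phase is the 5-day span rise-6 .. rise-2 (sperm survival plus
the peri-ovulatory days).  Conception is dated to the last fertile day,
cross-checked against the delivery date minus the 176.3-day mean gestation
of Japanese macaques.  Study days are then labeled PCP (the 30 days before
conception), month1/month2 (30-day blocks from conception), or other.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

GESTATION_DAYS = 176.3  # mean gestation length, days

log = logging.getLogger(__name__)


@dataclass
class ReproductiveTimeline:
    """Per-female classification of the study window."""

    female_id: str
    rise_date: date | None
    periovulatory_days: set[date]
    fertile_window: list[date]
    conception_date: date
    conception_source: str  # "hormonal", "backdated", or "hormonal+backdated"
    backdate_discrepancy_days: int | None
    delivery_date: date | None
    period_labels: dict[date, str]
    candidate_rises: list[date] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)

    def label(self, day: date) -> str:
        return self.period_labels.get(day, "other")


def detect_luteal_onset(
    pdg: np.ndarray | pd.Series,
    baseline_n: int | str = "auto",
    k: float = 2.0,
) -> int | None:
    """Index of the first sample marking the luteal-phase PdG rise.

    A sample qualifies when its PdG is >= mean + k*SD (sample SD, n-1
    denominator) of the ``baseline_n`` immediately preceding samples and
    strictly exceeds that baseline mean (the strict part resolves the
    degenerate zero-variance baseline, where the threshold alone would make
    every sample qualify).  ``baseline_n="auto"`` uses 4 preceding samples
    when available, else 3, favoring the more stable baseline.

    Returns the integer position of the rise sample, or None.
    """
    x = np.asarray(pdg, dtype=float)
    if baseline_n == "auto":
        min_base = 3
    else:
        min_base = int(baseline_n)
        if min_base not in (3, 4):
            raise ValueError("baseline_n must be 3, 4 or 'auto'")
    if x.size < min_base + 1:
        raise ValueError(
            f"series has {x.size} samples; need at least baseline_n+1 = {min_base + 1}"
        )
    for i in range(min_base, x.size):
        b = min(4, i) if baseline_n == "auto" else min_base
        base = x[i - b : i]
        mu = base.mean()
        sd = base.std(ddof=1)
        if x[i] >= mu + k * sd and x[i] > mu:
            return i
    return None


def candidate_rises(
    pdg: np.ndarray | pd.Series,
    baseline_n: int | str = "auto",
    k: float = 2.0,
) -> list[int]:
    """Positions opening each qualifying run (candidate cycle onsets).

    Consecutive qualifying samples belong to one episode; only the first
    sample of each episode is a candidate luteal onset.
    """
    x = np.asarray(pdg, dtype=float)
    min_base = 3 if baseline_n == "auto" else int(baseline_n)
    hits = []
    for i in range(min_base, x.size):
        b = min(4, i) if baseline_n == "auto" else min_base
        base = x[i - b : i]
        mu = base.mean()
        if x[i] >= mu + k * base.std(ddof=1) and x[i] > mu:
            hits.append(i)
    return [i for j, i in enumerate(hits) if j == 0 or hits[j - 1] != i - 1]


def build_windows(rise_date: date) -> tuple[set[date], list[date]]:
    """Peri-ovulatory days {rise-3, rise-2} and 5-day fertile window rise-6..rise-2."""
    peri = {rise_date - timedelta(days=3), rise_date - timedelta(days=2)}
    fertile = [rise_date - timedelta(days=d) for d in range(6, 1, -1)]
    return peri, fertile


def estimate_conception(
    fertile_windows: list[list[date]],
    delivery_date: date | None = None,
    gestation_days: float = GESTATION_DAYS,
) -> tuple[date, str, int | None]:
    """Most likely conception date from hormonal windows and/or delivery date.

    The hormonal estimate is the last day of a fertile window (latest
    possible fertilization).  The delivery-based estimate back-dates by the
    mean gestation, rounded to a whole day.  With both sources and several
    candidate windows, the window whose last day is nearest the back-dated
    estimate wins; the residual discrepancy in days is reported.
    """
    backdated = (
        delivery_date - timedelta(days=round(gestation_days))
        if delivery_date is not None
        else None
    )
    hormonal = [w[-1] for w in fertile_windows if w]
    if not hormonal and backdated is None:
        raise ValueError("need a hormonal fertile window or a delivery date")
    if not hormonal:
        return backdated, "backdated", None
    if backdated is None:
        return hormonal[0], "hormonal", None
    best = min(hormonal, key=lambda d: (abs((d - backdated).days), d))
    return best, "hormonal+backdated", (best - backdated).days


def label_periods(
    conception_date: date, study_start: date, study_end: date
) -> dict[date, str]:
    """Label every study day: PCP, month1, month2 or other.

    PCP = [conception-30, conception-1]; month1 = [conception,
    conception+29]; month2 = [conception+30, conception+59].  Pregnancy
    months are fixed 30-day blocks anchored at conception.
    """
    if not study_start <= conception_date <= study_end:
        raise ValueError("conception date outside the study window")
    labels = {}
    day = study_start
    while day <= study_end:
        off = (day - conception_date).days
        if -30 <= off <= -1:
            labels[day] = "PCP"
        elif 0 <= off <= 29:
            labels[day] = "month1"
        elif 30 <= off <= 59:
            labels[day] = "month2"
        else:
            labels[day] = "other"
        day += timedelta(days=1)
    return labels


def build_timeline(
    series: pd.DataFrame,
    study_start: date,
    study_end: date,
    delivery_date: date | None = None,
    baseline_n: int | str = "auto",
    k: float = 2.0,
    sustain_n: int = 2,
) -> ReproductiveTimeline:
    """Classify one female's study window from her hormone series.

    ``series`` needs columns female_id, date, pdg_ug_g (e1c_ng_g optional
    here).  Candidate luteal onsets are screened by the 2-SD rule; when a
    delivery date is available the candidate whose fertile window ends
    nearest the back-dated conception is chosen, otherwise the first
    candidate whose elevation is sustained (>= ``sustain_n`` of the
    following 3 samples also above its threshold) is used.  Earlier,
    non-sustained candidates are treated as non-conceptive cycles and fall
    into the "other" label.
    """
    s = series.sort_values("date").reset_index(drop=True)
    dates = [d.date() if hasattr(d, "date") else d for d in pd.to_datetime(s["date"])]
    pdg = s["pdg_ug_g"].to_numpy(dtype=float)
    female = str(s["female_id"].iloc[0])
    flags: list[str] = []

    cands = candidate_rises(pdg, baseline_n=baseline_n, k=k)
    sustained = []
    for i in cands:
        b = min(4, i) if baseline_n == "auto" else int(baseline_n)
        base = pdg[i - b : i]
        thr = base.mean() + k * base.std(ddof=1)
        follow = pdg[i + 1 : i + 4]
        if follow.size == 0 or (follow >= thr).sum() >= min(sustain_n, follow.size):
            sustained.append(i)
    pool = sustained if sustained else cands
    if not pool and delivery_date is None:
        raise ValueError(f"no PdG rise detected for {female} and no delivery date given")
    if not pool:
        flags.append("no_hormonal_rise")

    windows = [build_windows(dates[i])[1] for i in pool]
    conception, source, disc = estimate_conception(windows, delivery_date)
    if disc is not None and abs(disc) > 5:
        flags.append(f"backdate_discrepancy_{disc}d")

    if source == "backdated":
        rise_date = None
        peri: set[date] = set()
        fertile: list[date] = []
    else:
        chosen = next(w for w in windows if w[-1] == conception)
        rise_date = chosen[-1] + timedelta(days=2)
        peri, fertile = build_windows(rise_date)

    labels = label_periods(conception, study_start, study_end)
    return ReproductiveTimeline(
        female_id=female,
        rise_date=rise_date,
        periovulatory_days=peri,
        fertile_window=fertile,
        conception_date=conception,
        conception_source=source,
        backdate_discrepancy_days=disc,
        delivery_date=delivery_date,
        period_labels=labels,
        candidate_rises=[dates[i] for i in cands],
        flags=flags,
    )


def build_timelines(
    hormones: pd.DataFrame,
    roster: pd.DataFrame,
    study_start: date,
    study_end: date,
    **kwargs,
) -> dict[str, ReproductiveTimeline]:
    """One timeline per female, joining hormone series with roster deliveries."""
    deliveries = {}
    if "delivery_date" in roster.columns:
        for _, row in roster.iterrows():
            d = row["delivery_date"]
            if pd.notna(d):
                d = pd.Timestamp(d).date()
                deliveries[str(row["female_id"])] = d
    out = {}
    for female, grp in hormones.groupby("female_id", sort=True):
        out[str(female)] = build_timeline(
            grp,
            study_start,
            study_end,
            delivery_date=deliveries.get(str(female)),
            **kwargs,
        )
    return out


def hormone_outcomes(
    series: pd.DataFrame, timelines: dict[str, ReproductiveTimeline]
) -> pd.DataFrame:
    """Per-sample log-transformed outcomes with period labels.

    Returns columns female_id, date, period, log_pdg, log_e1c,
    log_e1c_pdg_ratio (natural logs).  Rows with a non-positive hormone
    value are excluded with a logged warning, since their log outcome is
    undefined.
    """
    df = series.copy()
    df["date"] = pd.to_datetime(df["date"]).dt.date
    bad = (df["pdg_ug_g"] <= 0) | (df["e1c_ng_g"] <= 0)
    if bad.all():
        raise ValueError("all hormone values are non-positive")
    if bad.any():
        log.warning(
            "excluding %d hormone sample(s) with non-positive values", int(bad.sum())
        )
        df = df.loc[~bad]
    df = df.reset_index(drop=True)
    out = pd.DataFrame(
        {
            "female_id": df["female_id"].astype(str),
            "date": df["date"],
            "period": [
                timelines[str(f)].label(d) if str(f) in timelines else "other"
                for f, d in zip(df["female_id"], df["date"])
            ],
            "log_pdg": np.log(df["pdg_ug_g"].to_numpy(dtype=float)),
            "log_e1c": np.log(df["e1c_ng_g"].to_numpy(dtype=float)),
        }
    )
    out["log_e1c_pdg_ratio"] = out["log_e1c"] - out["log_pdg"]
    return out


def timelines_to_frame(timelines: dict[str, ReproductiveTimeline]) -> pd.DataFrame:
    """Long table: one row per (female, study day) with its period label."""
    rows = []
    for female, tl in sorted(timelines.items()):
        for day, lab in sorted(tl.period_labels.items()):
            rows.append({"female_id": female, "date": day, "period": lab})
    return pd.DataFrame(rows)


def timeline_summary(timelines: dict[str, ReproductiveTimeline]) -> pd.DataFrame:
    rows = []
    for female, tl in sorted(timelines.items()):
        rows.append(
            {
                "female_id": female,
                "rise_date": tl.rise_date,
                "conception_date": tl.conception_date,
                "conception_source": tl.conception_source,
                "backdate_discrepancy_days": tl.backdate_discrepancy_days,
                "delivery_date": tl.delivery_date,
                "n_candidate_rises": len(tl.candidate_rises),
                "flags": ";".join(tl.flags),
            }
        )
    return pd.DataFrame(rows)
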