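"""Study configuration for the synthetic-study generator.

The defaults encode the design of a one-mating-season field study of five
conceiving adult female Japanese macaques: a December-March observation
window, 153 twenty-minute focal observations split 46/57/50 across the
pre-conceptive period (PCP) and the first two months of pregnancy, 88 face
photographs split 28/35/25, fecal hormone sampling every ~3 days with
weather dropouts, and per-behavior event totals matching the published
per-period tallies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import yaml

#: The three reproductive periods contrasted by every downstream model.
PERIODS = ("PCP", "month1", "month2")

#: Per-period event totals for the sexual-behavior taxonomy (PCP, month 1,
#: month 2).  These calibrate the generator's occurrence/count rates.
DEFAULT_BEHAVIOR_TOTALS: dict[str, tuple[int, int, int]] = {
    "female_approach": (130, 21, 82),
    "female_presentation": (0, 0, 0),
    "female_holding": (0, 0, 27),
    "estrus_call": (1809, 804, 3065),
    "copulation_call": (57, 0, 0),
    "male_approach": (137, 6, 27),
    "male_holding": (163, 0, 45),
    "mount": (138, 0, 0),
    "olfactory_inspection": (0, 0, 0),
}

#: Occurrence probabilities per period for grooming bouts, which are social
#: (not sexual) behaviors and are rate- rather than total-parameterized.
#: Female-directed grooming declines after conception.
DEFAULT_GROOM_PROBS: dict[str, tuple[float, float, float]] = {
    "grooming_female": (0.25, 0.12, 0.12),
    "grooming_male": (0.15, 0.10, 0.12),
}

#: Direction of each behavior, female->male ("f2m") or male->female ("m2f").
BEHAVIOR_DIRECTION: dict[str, str] = {
    "female_approach": "f2m",
    "female_presentation": "f2m",
    "female_holding": "f2m",
    "estrus_call": "f2m",
    "copulation_call": "f2m",
    "male_approach": "m2f",
    "male_holding": "m2f",
    "mount": "m2f",
    "olfactory_inspection": "m2f",
    "grooming_female": "f2m",
    "grooming_male": "m2f",
    "contact": "f2m",
}

#: Behaviors carried into the statistical stage (frequent enough to model).
MODELED_BEHAVIORS = (
    "female_approach",
    "grooming_female",
    "grooming_male",
    "estrus_call",
    "male_holding",
)


@dataclass
class CycleParams:
    """Fecal hormone profile parameters.

    PdG is in ug/g dry feces, E1C in ng/g.  The luteal/post-conception PdG
    level drops from month 1 to month 2 while E1C stays flat, so the
    E1C/PdG ratio rises in month 2 — the directions the analysis expects.
    """

    baseline_pdg_mean: float = 1.0
    baseline_pdg_sd: float = 0.1
    pdg_month1: float = 5.0
    pdg_month2: float = 3.5
    e1c_level: float = 10.0
    e1c_fertile_boost: float = 1.3  # follicular-phase bump over the fertile window
    noise_cv: float = 0.1  # multiplicative (lognormal) noise for elevated PdG and E1C
    cadence_days: int = 3
    gap_prob: float = 0.1  # per-scheduled-sample dropout (weather)
    gestation_mean_days: float = 176.3
    gestation_sd_days: float = 3.0


@dataclass
class ColorParams:
    """Per-period receptor-space face color targets.

    Period means are parameterized by luminance L = (LW+MW)/2 and
    red-green ratio r = (LW-MW)/(LW+MW), from which LW = L(1+r) and
    MW = L(1-r).  Defaults: faces darken from PCP to month 1 and become
    less red from month 1 to month 2.
    """

    luminance: Mapping[str, float] = field(
        default_factory=lambda: {"PCP": 1.00, "month1": 0.90, "month2": 0.88}
    )
    rg_ratio: Mapping[str, float] = field(
        default_factory=lambda: {"PCP": 0.10, "month1": 0.11, "month2": 0.07}
    )
    log_sd: float = 0.08  # lognormal photo-to-photo noise on LW and MW

    def lw_mw(self, period: str) -> tuple[float, float]:
        L, r = self.luminance[period], self.rg_ratio[period]
        return L * (1.0 + r), L * (1.0 - r)


@dataclass
class StudyConfig:
    """Complete synthetic-study design; defaults reproduce the field design."""

    n_females: int = 5
    ages: Sequence[int] | None = (8, 9, 11, 13, 17)
    study_start: date = date(2013, 12, 1)
    study_end: date = date(2014, 3, 15)
    #: conception day offsets from study_start; None -> evenly spread
    conception_offsets: Sequence[int] | None = (30, 33, 36, 40, 44)
    #: per-period, per-female focal counts; None -> auto-allocated
    focals_per_period: Mapping[str, Sequence[int]] | None = field(
        default_factory=lambda: {
            "PCP": (10, 9, 9, 9, 9),
            "month1": (12, 12, 11, 11, 11),
            "month2": (10, 10, 10, 10, 10),
        }
    )
    photos_per_period: Mapping[str, Sequence[int]] | None = field(
        default_factory=lambda: {
            "PCP": (6, 6, 6, 5, 5),
            "month1": (7, 7, 7, 7, 7),
            "month2": (5, 5, 5, 5, 5),
        }
    )
    cycle: CycleParams = field(default_factory=CycleParams)
    color: ColorParams = field(default_factory=ColorParams)
    behavior_totals: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_BEHAVIOR_TOTALS)
    )
    groom_probs: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GROOM_PROBS)
    )
    groom_bout_mean: float = 2.5  # zero-truncated mean grooming bouts per focal
    groom_duration_scale_s: float = 120.0  # Gamma scale for per-bout duration
    contact_extra_prob: float = 0.10  # body contact occurs beyond grooming with this prob
    #: occurrence-probability cap; keeps expected zero fraction >= 75%
    occurrence_p_max: float = 0.25
    #: floor on the zero-truncated positive-count mean used when calibrating
    min_positive_mean: float = 2.0
    dispersion: float = 1.5  # negative-binomial size parameter k
    # crossed Gaussian random-intercept SDs (female / calendar date)
    re_sd_female_occ: float = 0.3
    re_sd_date_occ: float = 0.3
    re_sd_female_count: float = 0.2
    re_sd_date_count: float = 0.2
    hierarchy_steepness: float = 5.0
    n_interactions: int = 200
    rng_seed: int = 0

    def __post_init__(self) -> None:
        # normalize sequence fields so configs round-trip through YAML
        if self.ages is not None:
            self.ages = tuple(int(a) for a in self.ages)
        if self.conception_offsets is not None:
            self.conception_offsets = tuple(int(o) for o in self.conception_offsets)
        if self.focals_per_period is not None:
            self.focals_per_period = {
                p: tuple(int(c) for c in v) for p, v in self.focals_per_period.items()
            }
        if self.photos_per_period is not None:
            self.photos_per_period = {
                p: tuple(int(c) for c in v) for p, v in self.photos_per_period.items()
            }
        self.behavior_totals = {
            k: tuple(int(c) for c in v) for k, v in self.behavior_totals.items()
        }
        self.groom_probs = {
            k: tuple(float(c) for c in v) for k, v in self.groom_probs.items()
        }
        if self.n_females < 1:
            raise ValueError("n_females must be >= 1")
        if self.study_end <= self.study_start:
            raise ValueError("study_end must follow study_start")
        if not 0.0 < self.occurrence_p_max <= 1.0:
            raise ValueError("occurrence_p_max must be in (0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        for period, (L, r) in (
            (p, (self.color.luminance[p], self.color.rg_ratio[p])) for p in PERIODS
        ):
            if L <= 0 or not -1 < r < 1:
                raise ValueError(f"invalid color target for {period}")
        for name, probs in self.groom_probs.items():
            if any(not 0 <= p <= 1 for p in probs):
                raise ValueError(f"occurrence probability out of [0,1] for {name}")
        if self.ages is not None and len(self.ages) != self.n_females:
            raise ValueError("ages must have one entry per female")
        if self.conception_offsets is not None and len(self.conception_offsets) != self.n_females:
            raise ValueError("conception_offsets must have one entry per female")

    # -- derived design quantities -------------------------------------

    @property
    def n_days(self) -> int:
        return (self.study_end - self.study_start).days + 1

    def conception_dates(self) -> list[date]:
        if self.conception_offsets is not None:
            offs = list(self.conception_offsets)
        else:
            # earliest: PCP must start inside the window; latest: month2 must end inside
            lo, hi = 30, self.n_days - 1 - 59
            if hi < lo:
                raise ValueError("study window too short for PCP + two pregnancy months")
            step = (hi - lo) / max(self.n_females - 1, 1)
            offs = [round(lo + i * step) for i in range(self.n_females)]
        return [self.study_start + timedelta(days=int(o)) for o in offs]

    def focal_allocation(self) -> dict[str, list[int]]:
        """Focal counts per (period, female); default design totals 46/57/50."""
        if self.focals_per_period is not None:
            out = {p: list(self.focals_per_period[p]) for p in PERIODS}
        else:
            out = {}
            for period, total in zip(PERIODS, (46, 57, 50)):
                base, extra = divmod(total, self.n_females)
                out[period] = [base + (1 if i < extra else 0) for i in range(self.n_females)]
        for period, counts in out.items():
            if len(counts) != self.n_females:
                raise ValueError(f"focal allocation for {period} must cover every female")
        return out

    def photo_allocation(self) -> dict[str, list[int]]:
        if self.photos_per_period is not None:
            return {p: list(self.photos_per_period[p]) for p in PERIODS}
        out = {}
        for period, total in zip(PERIODS, (28, 35, 25)):
            base, extra = divmod(total, self.n_females)
            out[period] = [base + (1 if i < extra else 0) for i in range(self.n_females)]
        return out

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["study_start"] = self.study_start.isoformat()
        d["study_end"] = self.study_end.isoformat()
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        d = dict(d)
        for key in ("study_start", "study_end"):
            if isinstance(d.get(key), str):
                d[key] = date.fromisoformat(d[key])
        if isinstance(d.get("cycle"), Mapping):
            d["cycle"] = CycleParams(**d["cycle"])
        if isinstance(d.get("color"), Mapping):
            d["color"] = ColorParams(**d["color"])
        if "behavior_totals" in d:
            d["behavior_totals"] = {
                k: tuple(v) for k, v in dict(d["behavior_totals"]).items()
            }
        if "groom_probs" in d:
            d["groom_probs"] = {k: tuple(v) for k, v in dict(d["groom_probs"]).items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
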