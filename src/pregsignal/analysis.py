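"""Statistical stage: hurdle and Gaussian mixed models with LRT comparison.

Every model carries reproductive status (PCP / month1 / month2) as the
predictor of interest plus age as a confounding covariate, with female
identity and observation date as crossed random intercepts.  Full models
are compared against null models with status removed (age retained) by
likelihood-ratio tests.  Behaviors are first screened for collinearity
(phi on occurrence flags, Pearson on counts); pairs above the threshold
collapse to one representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .mixedglm import (
    Binomial,
    CrossedGLMM,
    Gaussian,
    MixedGLMResult,
    TruncatedNegBinomial,
    ZeroInflatedBinomial,
    group_codes,
)

MIN_POSITIVES = 5  # below this, the truncated count part is refused


@dataclass(frozen=True)
class ModelSpec:
    """What to regress on what, and with which grouping structure."""

    response: str
    status_col: str = "period"
    age_col: str = "age"
    baseline: str = "PCP"
    levels: tuple[str, ...] = ("PCP", "month1", "month2")
    groups: tuple[str, ...] = ("female_id", "date")
    include_status: bool = True

    def null_spec(self) -> "ModelSpec":
        """The nested null: status removed, age retained."""
        return replace(self, include_status=False)

    def releveled(self, new_baseline: str) -> "ModelSpec":
        if new_baseline not in self.levels:
            raise ValueError(f"unknown status level {new_baseline!r}")
        return replace(self, baseline=new_baseline)


def build_design(data: pd.DataFrame, spec: ModelSpec, y):
    """Response, fixed-effect design and group codes for one model."""
    status = data[spec.status_col].astype(str)
    unknown = set(status) - set(spec.levels)
    if unknown:
        raise ValueError(f"rows with status outside model levels: {sorted(unknown)}")
    cols = [np.ones(len(data))]
    names = ["intercept"]
    if spec.include_status:
        for lev in spec.levels:
            if lev == spec.baseline:
                continue
            cols.append((status == lev).to_numpy(dtype=float))
            names.append(f"status[{lev}]")
    if spec.age_col:
        cols.append(data[spec.age_col].to_numpy(dtype=float))
        names.append("age")
    X = np.column_stack(cols)
    groups = {g: group_codes(data[g])[0] for g in spec.groups}
    return np.asarray(y, dtype=float), X, names, groups


def fit_glmm(data: pd.DataFrame, spec: ModelSpec, family, y=None) -> MixedGLMResult:
    if y is None:
        y = data[spec.response]
    yv, X, names, groups = build_design(data, spec, y)
    return CrossedGLMM(yv, X, groups, family, beta_names=names).fit()


# --------------------------------------------------------------------------
# collinearity screening


def screen_collinearity(
    focals: pd.DataFrame, behaviors: list[str], threshold: float = 0.7
) -> tuple[pd.DataFrame, list[str], dict[str, str]]:
    """Pairwise phi/Pearson screen over behavior occurrence flags and counts.

    Returns (report, retained, dropped) where ``dropped`` maps each removed
    behavior to the representative retained in its place.  Within a pair
    exceeding the threshold the more prevalent behavior is dropped — the
    broader category (e.g. body contact) is treated as an aggregate of the
    more specific one (e.g. grooming), which stays in the models.
    Zero-variance behaviors are reported and excluded from the screen.
    """
    counts = {b: focals[f"{b}_count"].to_numpy(dtype=float) for b in behaviors}
    flags = {b: (c > 0).astype(float) for b, c in counts.items()}
    degenerate = [b for b in behaviors if np.std(flags[b]) == 0]
    active = [b for b in behaviors if b not in degenerate]
    if len(active) < 2 or len(focals) < 10:
        raise ValueError("screen needs >= 2 non-degenerate behaviors and >= 10 focals")

    rows = []
    to_drop: dict[str, str] = {}
    for i, a in enumerate(active):
        for b in active[i + 1 :]:
            phi = float(np.corrcoef(flags[a], flags[b])[0, 1])
            pearson = float(np.corrcoef(counts[a], counts[b])[0, 1])
            exceeds = max(abs(phi), abs(pearson)) > threshold
            rows.append(
                {
                    "behavior_a": a,
                    "behavior_b": b,
                    "phi": phi,
                    "pearson_r": pearson,
                    "exceeds_threshold": exceeds,
                }
            )
            if exceeds:
                prev_a, prev_b = flags[a].mean(), flags[b].mean()
                drop, keep = (a, b) if prev_a >= prev_b else (b, a)
                if keep not in to_drop:
                    to_drop.setdefault(drop, keep)
    retained = [b for b in active if b not in to_drop]
    report = pd.DataFrame(rows)
    for b in degenerate:
        report = pd.concat(
            [
                report,
                pd.DataFrame(
                    [
                        {
                            "behavior_a": b,
                            "behavior_b": "",
                            "phi": np.nan,
                            "pearson_r": np.nan,
                            "exceeds_threshold": False,
                        }
                    ]
                ),
            ],
            ignore_index=True,
        )
    return report, retained, to_drop


# --------------------------------------------------------------------------
# hurdle models


@dataclass
class HurdleFit:
    """Two-part fit: occurrence (binomial) and positive counts (ZT-NB).

    The total log-likelihood decomposes exactly as binary part plus
    truncated count part on the positives.
    """

    response: str
    binary: MixedGLMResult | None
    count: MixedGLMResult | None
    flags: list[str] = field(default_factory=list)

    @property
    def loglik(self) -> float:
        ll = 0.0
        if self.binary is not None:
            ll += self.binary.loglik
        if self.count is not None:
            ll += self.count.loglik
        return ll

    @property
    def df_model(self) -> int:
        return sum(
            part.df_model for part in (self.binary, self.count) if part is not None
        )


class HurdleRefusal(RuntimeError):
    """Raised when a hurdle part cannot be estimated from the data."""


def fit_hurdle(
    data: pd.DataFrame,
    spec: ModelSpec,
    count_col: str | None = None,
    min_positives: int = MIN_POSITIVES,
    require_count_part: bool = False,
) -> HurdleFit:
    """Fit the two-part hurdle model for one behavior.

    The binary part models occurrence (count > 0); the count part models
    the zero-truncated positives.  A count part with fewer than
    ``min_positives`` positive observations is refused (reported in flags,
    or raised if ``require_count_part``); a response with no variation in
    occurrence leaves the binary part degenerate and unfit.
    """
    count_col = count_col or f"{spec.response}_count"
    counts = data[count_col].to_numpy(dtype=float)
    occ = (counts > 0).astype(float)
    flags = []

    binary = None
    if occ.min() == occ.max():
        flags.append("binary_part_degenerate: occurrence has no variation")
    else:
        binary = fit_glmm(data, spec, Binomial(), y=occ)
        for f in binary.flags:
            flags.append(f"binary:{f}")

    count = None
    pos = data.loc[counts > 0]
    if len(pos) < min_positives:
        msg = (
            f"count part refused: only {len(pos)} positive observations for "
            f"{spec.response} (need >= {min_positives})"
        )
        if require_count_part:
            raise HurdleRefusal(msg)
        flags.append(msg)
    else:
        count = fit_glmm(
            pos, spec, TruncatedNegBinomial(), y=pos[count_col].to_numpy(dtype=float)
        )
        for f in count.flags:
            flags.append(f"count:{f}")
    return HurdleFit(response=spec.response, binary=binary, count=count, flags=flags)


def fit_lme(data: pd.DataFrame, spec: ModelSpec) -> MixedGLMResult:
    """Gaussian mixed model on a continuous (typically log) outcome."""
    y = data[spec.response].to_numpy(dtype=float)
    return fit_glmm(data, spec, Gaussian(), y=y)


# --------------------------------------------------------------------------
# likelihood-ratio tests


@dataclass
class LRTResult:
    label: str
    statistic: float
    delta_df: int
    p_value: float
    loglik_full: float
    loglik_null: float


def lrt(full, null, label: str = "") -> LRTResult:
    """Full-vs-null likelihood-ratio test; X2 clipped at 0.

    Both arguments may be :class:`MixedGLMResult` or :class:`HurdleFit`
    (the latter sums both parts — the combined-hurdle accounting, giving
    delta_df = 4 for a 3-level factor present in both parts).
    """
    n_full = full.n_obs if hasattr(full, "n_obs") else None
    n_null = null.n_obs if hasattr(null, "n_obs") else None
    if n_full is not None and n_null is not None and n_full != n_null:
        raise ValueError("full and null models must be fit on the same rows")
    delta_df = full.df_model - null.df_model
    if delta_df < 1:
        raise ValueError("null model is not nested in the full model")
    stat = max(0.0, 2.0 * (full.loglik - null.loglik))
    return LRTResult(
        label=label,
        statistic=stat,
        delta_df=delta_df,
        p_value=float(chi2.sf(stat, delta_df)),
        loglik_full=full.loglik,
        loglik_null=null.loglik,
    )


def relevel_contrasts(
    data: pd.DataFrame,
    spec: ModelSpec,
    new_baseline: str,
    family=None,
    y=None,
) -> MixedGLMResult:
    """Refit with a new baseline level to expose the remaining contrast.

    Re-leveling is a reparameterization: the refit's log-likelihood matches
    the original within optimizer tolerance, only the coefficient meaning
    changes (e.g. month2 vs month1 once month1 is the baseline).
    """
    return fit_glmm(data, spec.releveled(new_baseline), family or Binomial(), y=y)


# --------------------------------------------------------------------------
# zero-inflation structure check


@dataclass
class ZeroInflationReport:
    aic_binomial: float
    aic_zero_inflated: float
    chosen: str
    inflation_estimate: float


def zero_inflation_check(
    data: pd.DataFrame, spec: ModelSpec, y=None
) -> ZeroInflationReport:
    """Compare plain-binomial vs zero-inflated binomial occurrence models.

    Both variants share the fixed-effect and random-intercept structure;
    the simpler model wins unless the zero-inflated variant's AIC is lower.
    """
    if y is None:
        y = (data[f"{spec.response}_count"] > 0).astype(float)
    plain = fit_glmm(data, spec, Binomial(), y=y)
    zi = fit_glmm(data, spec, ZeroInflatedBinomial(), y=y)
    aic_p = 2 * plain.df_model - 2 * plain.loglik
    aic_z = 2 * zi.df_model - 2 * zi.loglik
    return ZeroInflationReport(
        aic_binomial=aic_p,
        aic_zero_inflated=aic_z,
        chosen="binomial" if aic_p <= aic_z else "zero_inflated",
        inflation_estimate=zi.aux.get("zero_inflation", np.nan),
    )
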