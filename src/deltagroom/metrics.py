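"""Reciprocity statistics and inference on paired grooming events.

The per-pair reciprocity statistic is

    rho = |X - Y| / (X + Y)

which is 0 under perfect time-matching (X = Y), approaches 1 as the exchange
becomes one-sided, and is symmetric and scale-invariant.

Asymmetry within a unit (a dyad or an individual) is judged from the notched
95% confidence interval of the unit's median rho: the null hypothesis of
time-matched reciprocation (median rho = 0) is rejected when the lower
confidence limit is strictly positive.

Condition-level inference uses (i) a one-way repeated-measures ANOVA of rho
on comparison group (within-bout vs delayed) with the dyad as the random
effect, and (ii) a mixed-effects regression of reply duration on initial
duration, Y ~ X + (1|dyad), with a dyad-level random intercept.  Multiple
pairs from one dyad are not independent replicates; both analyses put the
dyad in the error structure to avoid pseudoreplication.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from .pairing import DELAYED, WITHIN_BOUT, Condition, PairedEvent

__all__ = [
    "rho",
    "rho_frame",
    "MedianCI",
    "median_ci",
    "asymmetry_test",
    "AnovaResult",
    "rm_anova",
    "MixedFit",
    "mixed_regression",
]

#: Notch half-width constant: median +/- NOTCH_CONSTANT * IQR / sqrt(n),
#: the standard notched-boxplot convention.
NOTCH_CONSTANT = 1.58


def rho(X: float, Y: float) -> float:
    """Per-pair reciprocity |X−Y|/(X+Y) for positive durations.

    0 means perfect time-matching; larger values mean asymmetry.
    """
    if X <= 0 or Y <= 0:
        raise ValueError(f"rho requires positive durations, got X={X}, Y={Y}")
    return abs(X - Y) / (X + Y)


def rho_frame(pairs: Iterable[PairedEvent]) -> pd.DataFrame:
    """Per-pair table with rho, condition, dyad and both participants."""
    rows = []
    for p in pairs:
        rows.append(
            (
                p.session_id,
                str(p.dyad),
                p.dyad.a,
                p.dyad.b,
                p.first_groomer,
                p.condition,
                float(p.X),
                float(p.Y),
                rho(p.X, p.Y),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["session_id", "dyad", "a", "b", "first_groomer", "condition", "X", "Y", "rho"],
    )


@dataclass(frozen=True)
class MedianCI:
    median: float
    lower: float
    upper: float
    n: int


def median_ci(
    values: Sequence[float],
    notch_constant: float = NOTCH_CONSTANT,
    floor_at_min: bool = True,
) -> MedianCI:
    """Notched 95% confidence interval for the sample median.

    Half-width is ``notch_constant * IQR / sqrt(n)``.  For data bounded
    below (rho is nonnegative) the lower limit is floored at the sample
    minimum (``floor_at_min``), so a unit whose median is 0 can never be
    flagged as asymmetric.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("median_ci: empty input")
    med = float(np.median(arr))
    q1, q3 = np.percentile(arr, [25, 75])
    half = notch_constant * (q3 - q1) / np.sqrt(arr.size)
    lower = med - half
    upper = med + half
    if floor_at_min:
        lower = max(lower, float(arr.min()))
        lower = min(lower, med)  # flooring never crosses the median
    return MedianCI(median=med, lower=float(lower), upper=float(upper), n=int(arr.size))


def asymmetry_test(
    pairs: Iterable[PairedEvent],
    by: Literal["dyad", "individual"] = "dyad",
    condition: Optional[Condition] = None,
    notch_constant: float = NOTCH_CONSTANT,
    floor_at_min: bool = True,
) -> pd.DataFrame:
    """Median-CI asymmetry test per dyad or per individual.

    The null hypothesis for each unit is time-matched reciprocation
    (median rho = 0); it is rejected when the lower 95% confidence limit of
    the unit's median rho is strictly positive.  In the per-individual
    analysis each pair is credited to both participants (a pair is an
    observation of either chimpanzee's grooming account).

    Returns a frame with columns ``unit, n, median, lower, upper, reject``;
    units with zero records for the requested condition are omitted.
    """
    df = rho_frame(pairs)
    if condition is not None:
        df = df[df["condition"] == condition]
    if by == "dyad":
        long = df[["dyad", "rho"]].rename(columns={"dyad": "unit"})
    elif by == "individual":
        long = pd.concat(
            [
                df[["a", "rho"]].rename(columns={"a": "unit"}),
                df[["b", "rho"]].rename(columns={"b": "unit"}),
            ],
            ignore_index=True,
        )
    else:
        raise ValueError(f"by must be 'dyad' or 'individual', got {by!r}")
    rows = []
    for unit, grp in long.groupby("unit", sort=True):
        ci = median_ci(grp["rho"].to_numpy(), notch_constant, floor_at_min)
        rows.append((unit, ci.n, ci.median, ci.lower, ci.upper, ci.lower > 0))
    return pd.DataFrame(rows, columns=["unit", "n", "median", "lower", "upper", "reject"])


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_num: int
    df_den: int
    p: float
    eta_sq: float
    mean_diff: float
    cohens_d: float
    n_dyads_both: int


def rm_anova(pairs: Iterable[PairedEvent]) -> AnovaResult:
    """One-way repeated-measures ANOVA of rho on comparison group.

    The dyad is the subject (random effect).  The F test is the two-stratum
    sums-of-squares decomposition on the dyad-by-condition cell means,
    restricted to dyads observed in both conditions (the within-subject
    contrast is undefined for the rest): SS_total over cells splits into a
    dyad stratum, the condition effect, and the dyad-by-condition residual
    which is the error term, giving F(1, n_both − 1).

    Effect sizes are computed on the full per-pair records: eta² is
    SS_condition/SS_total of the one-way split by condition; ``mean_diff``
    is mean rho (delayed) − mean rho (within-bout); Cohen's d divides that
    by the pooled standard deviation.
    """
    df = rho_frame(pairs)
    conditions = sorted(df["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("rm_anova: records must span both conditions")

    cells = df.groupby(["dyad", "condition"])["rho"].mean().unstack("condition")
    both = cells.dropna()
    n_both = len(both)
    if n_both < 2:
        raise ValueError(f"rm_anova: only {n_both} dyad(s) observed in both conditions")

    values = both.to_numpy()  # shape (n_both, 2)
    grand = values.mean()
    ss_total = float(((values - grand) ** 2).sum())
    ss_cond = float(n_both * ((values.mean(axis=0) - grand) ** 2).sum())
    ss_dyad = float(2 * ((values.mean(axis=1) - grand) ** 2).sum())
    ss_err = ss_total - ss_cond - ss_dyad
    df_num, df_den = 1, n_both - 1
    ms_err = ss_err / df_den
    F = float(ss_cond / df_num / ms_err) if ms_err > 0 else 0.0
    if ss_cond == 0.0:
        F = 0.0
    p = float(scipy.stats.f.sf(F, df_num, df_den)) if ms_err > 0 else (1.0 if F == 0 else 0.0)

    g_delayed = df.loc[df["condition"] == DELAYED, "rho"].to_numpy()
    g_within = df.loc[df["condition"] == WITHIN_BOUT, "rho"].to_numpy()
    mean_diff = float(g_delayed.mean() - g_within.mean())
    all_rho = df["rho"].to_numpy()
    grand_all = all_rho.mean()
    ss_total_pairs = float(((all_rho - grand_all) ** 2).sum())
    ss_cond_pairs = float(
        g_delayed.size * (g_delayed.mean() - grand_all) ** 2
        + g_within.size * (g_within.mean() - grand_all) ** 2
    )
    eta_sq = ss_cond_pairs / ss_total_pairs if ss_total_pairs > 0 else 0.0
    pooled_var = (
        (g_delayed.size - 1) * g_delayed.var(ddof=1) + (g_within.size - 1) * g_within.var(ddof=1)
    ) / (g_delayed.size + g_within.size - 2)
    cohens_d = mean_diff / np.sqrt(pooled_var) if pooled_var > 0 else 0.0
    return AnovaResult(
        F=F,
        df_num=df_num,
        df_den=df_den,
        p=p,
        eta_sq=float(eta_sq),
        mean_diff=mean_diff,
        cohens_d=float(cohens_d),
        n_dyads_both=n_both,
    )


@dataclass(frozen=True)
class MixedFit:
    alpha: float
    beta: float
    se_alpha: float
    se_beta: float
    p: float
    condition: Optional[Condition]
    n_pairs: int
    n_dyads: int
    singular: bool
    random_intercept_sd: float


def mixed_regression(
    pairs: Iterable[PairedEvent],
    condition: Optional[Condition] = None,
    lrt: bool = True,
) -> MixedFit:
    """Time-matching regression Y ~ X + (1|dyad).

    Fits reply duration on initial duration with a dyad-level random
    intercept.  Estimates and standard errors come from the REML fit; the
    p-value is a likelihood-ratio test (ML refits) of the full model against
    the random-effects-only null, referred to chi-square with 1 df.

    With a single dyad the model degrades gracefully to ordinary least
    squares (random-intercept variance 0) and is flagged ``singular``.
    A near-zero estimated random-intercept variance is likewise flagged,
    never raised.  ``lrt=False`` skips the two ML refits and reports
    ``p = nan`` (useful when only the estimates are needed).
    """
    df = rho_frame(pairs)
    if condition is not None:
        df = df[df["condition"] == condition]
    n_pairs = len(df)
    n_dyads = df["dyad"].nunique() if n_pairs else 0
    if n_pairs < 3:
        raise ValueError(f"mixed_regression: need >= 3 pairs, got {n_pairs}")

    if n_dyads < 2:
        ols = smf.ols("Y ~ X", data=df).fit()
        null = smf.ols("Y ~ 1", data=df).fit()
        lr = 2 * (ols.llf - null.llf)
        return MixedFit(
            alpha=float(ols.params["Intercept"]),
            beta=float(ols.params["X"]),
            se_alpha=float(ols.bse["Intercept"]),
            se_beta=float(ols.bse["X"]),
            p=float(scipy.stats.chi2.sf(max(lr, 0.0), 1)),
            condition=condition,
            n_pairs=n_pairs,
            n_dyads=n_dyads,
            singular=True,
            random_intercept_sd=0.0,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reml = smf.mixedlm("Y ~ X", data=df, groups=df["dyad"]).fit(reml=True)
        if lrt:
            full_ml = smf.mixedlm("Y ~ X", data=df, groups=df["dyad"]).fit(reml=False)
            null_ml = smf.mixedlm("Y ~ 1", data=df, groups=df["dyad"]).fit(reml=False)
    p_value = float("nan")
    if lrt:
        lr = 2 * (full_ml.llf - null_ml.llf)
        p_value = float(scipy.stats.chi2.sf(max(lr, 0.0), 1))
    # cov_re is already on the response scale in statsmodels MixedLM
    re_var = float(np.asarray(reml.cov_re)[0, 0])
    singular = bool(re_var <= 1e-8 * float(reml.scale))
    return MixedFit(
        alpha=float(reml.params["Intercept"]),
        beta=float(reml.params["X"]),
        se_alpha=float(reml.bse["Intercept"]),
        se_beta=float(reml.bse["X"]),
        p=p_value,
        condition=condition,
        n_pairs=n_pairs,
        n_dyads=n_dyads,
        singular=singular,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
    )
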