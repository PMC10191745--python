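"""Prevalence per 10,000 deliveries, binomial confidence intervals, and
calendar-year stratified results tables.

Prevalence of exposure is the number of pregnancies with at least one
qualifying dispensation divided by the number of enrolled pregnancies in
the period, reported per 10,000 with a 95% confidence interval.  The exact
Clopper-Pearson interval is the default (Wilson available); for a zero
numerator its upper bound reduces to the closed form 1 - (alpha/2)^(1/n).

All internal arithmetic is at full float precision; half-up rounding to
one decimal happens only at presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import beta
from statsmodels.stats.proportion import proportion_confint


class UndefinedEstimateError(ZeroDivisionError):
    """Raised when a prevalence denominator is zero."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (22.25 -> 22.3 at 1 digit), unlike the
    banker's rounding of the built-in ``round``."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def clopper_pearson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval on the proportion scale."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lo, hi


def wilson(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


_CI_METHODS = {"clopper_pearson": clopper_pearson, "wilson": wilson}


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Per-10,000 prevalence with 95% CI; rounded fields are presentation
    values, ``raw_*`` keep full precision."""

    numerator: int
    denominator: int
    rate_per_10k: float
    percent: float
    ci_low: float  # per-10,000 scale
    ci_high: float
    stratum: str = "overall"
    raw_rate_per_10k: float = 0.0
    raw_ci_low: float = 0.0
    raw_ci_high: float = 0.0


def prevalence_per_10k(
    numerator: int,
    denominator: int,
    stratum: str = "overall",
    method: str = "clopper_pearson",
    alpha: float = 0.05,
) -> PrevalenceEstimate:
    if denominator <= 0:
        raise UndefinedEstimateError("prevalence undefined for a zero denominator")
    if not 0 <= numerator <= denominator:
        raise ValueError("numerator must lie in [0, denominator]")
    p = numerator / denominator
    lo, hi = _CI_METHODS[method](numerator, denominator, alpha)
    return PrevalenceEstimate(
        numerator=numerator,
        denominator=denominator,
        rate_per_10k=round_half_up(1e4 * p, 1),
        percent=round_half_up(100 * p, 1),
        ci_low=round_half_up(1e4 * lo, 1),
        ci_high=round_half_up(1e4 * hi, 1),
        stratum=stratum,
        raw_rate_per_10k=1e4 * p,
        raw_ci_low=1e4 * lo,
        raw_ci_high=1e4 * hi,
    )


def proportion_pct(part: float, whole: float) -> float:
    """Percentage ``100 * part / whole`` rounded half-up to one decimal.

    Used both on raw counts and, presentation-side, on already-rounded
    per-10,000 rates (the convention in which published group shares such
    as 25.9/36.5 -> 71.0% are quoted).
    """
    if whole <= 0:
        raise ValueError("whole must be positive")
    if part < 0:
        raise ValueError("part must be non-negative")
    return round_half_up(100.0 * part / whole, 1)


def stratify_by_year(
    labels: pd.DataFrame,
    groups: Sequence[str] | None = None,
    years: Iterable[int] | None = None,
    method: str = "clopper_pearson",
) -> pd.DataFrame:
    """Per-year and overall prevalence per 10,000 deliveries for each group.

    ``labels`` needs columns ``delivery_year`` and ``group`` (one row per
    enrolled pregnancy).  Years with zero deliveries are omitted.  The
    overall stratum pools all years, so per-year numerators sum to it.
    """
    if groups is None:
        groups = sorted(labels["group"].unique())
    if years is None:
        years = sorted(labels["delivery_year"].unique())
    rows = []
    strata: list[tuple[str, pd.DataFrame]] = [
        (str(y), labels[labels["delivery_year"] == y]) for y in years
    ]
    strata.append(("overall", labels))
    for name, sub in strata:
        denom = len(sub)
        if denom == 0:
            continue
        for g in groups:
            est = prevalence_per_10k(
                int((sub["group"] == g).sum()), denom, stratum=name, method=method
            )
            rows.append(
                {
                    "stratum": name,
                    "group": g,
                    "numerator": est.numerator,
                    "denominator": est.denominator,
                    "rate_per_10k": est.rate_per_10k,
                    "percent": est.percent,
                    "ci_low_per_10k": est.ci_low,
                    "ci_high_per_10k": est.ci_high,
                }
            )
    return pd.DataFrame(rows)


def cohort_summary(episodes: pd.DataFrame) -> pd.DataFrame:
    """Cohort description per delivery year and overall.

    ``episodes`` needs ``delivery_year`` and ``caesarean`` columns;
    ``maternal_age`` is optional, and the age statistics are omitted when
    it is absent or entirely missing.
    """
    have_age = "maternal_age" in episodes.columns and episodes["maternal_age"].notna().any()
    rows = []
    strata = [(str(y), episodes[episodes["delivery_year"] == y])
              for y in sorted(episodes["delivery_year"].unique())]
    strata.append(("overall", episodes))
    for name, sub in strata:
        n = len(sub)
        if n == 0:
            continue
        caes = int(sub["caesarean"].sum())
        row = {
            "stratum": name,
            "n_deliveries": n,
            "caesarean_n": caes,
            "caesarean_pct": proportion_pct(caes, n),
        }
        if have_age:
            ages = sub["maternal_age"].dropna()
            row["mean_maternal_age"] = round_half_up(float(ages.mean()), 1)
            row["min_maternal_age"] = float(ages.min())
            row["max_maternal_age"] = float(ages.max())
        rows.append(row)
    return pd.DataFrame(rows)
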