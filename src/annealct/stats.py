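"""Repetition statistics: Student-t confidence intervals and margins.

For a sample of ``n`` repeated quality measurements with mean ``x_bar``
and sample standard deviation ``S`` (n-1 denominator), the margin of
error at confidence ``C`` is ``E = t_{alpha/2} * S / sqrt(n)`` with
``t_{alpha/2}`` the two-tailed Student-t critical value at ``n - 1``
degrees of freedom, and the confidence interval is ``x_bar -+ E``.

To reproduce a published table exactly, pass the critical value at the
table's printed precision via ``t_crit``; otherwise the full-precision
quantile is used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats as _sps

__all__ = [
    "SampleSummary",
    "CIReport",
    "TTestRecord",
    "t_critical",
    "margin_of_error",
    "confidence_interval",
    "t_test_statement",
]


@dataclass(frozen=True)
class SampleSummary:
    """Sample mean, standard deviation (ddof=1) and repetition count."""

    mean: float
    std: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("need at least 2 repetitions")
        if self.std < 0.0:
            raise ValueError("standard deviation must be >= 0")


@dataclass(frozen=True)
class CIReport:
    confidence: float
    t_crit: float
    margin: float
    lower: float
    upper: float


@dataclass(frozen=True)
class TTestRecord:
    statement: str
    df: int
    t_crit: float
    alpha: float
    hypothesized_mean: float
    decision: str  # "accept" or "reject" of H0: mu = hypothesized_mean


def t_critical(confidence: float, df: int) -> float:
    """Two-tailed Student-t critical value ``t_{alpha/2}``."""
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie strictly between 0 and 1")
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(_sps.t.ppf(0.5 + confidence / 2.0, df))


def margin_of_error(
    summary: SampleSummary,
    confidence: float = 0.95,
    t_crit: float | None = None,
) -> float:
    """Maximum error of estimate ``E = t_{alpha/2} S / sqrt(n)``."""
    if t_crit is None:
        t_crit = t_critical(confidence, summary.n - 1)
    return t_crit * summary.std / math.sqrt(summary.n)


def confidence_interval(
    summary: SampleSummary,
    confidence: float = 0.95,
    t_crit: float | None = None,
) -> CIReport:
    """Two-sided CI ``x_bar -+ E`` (bounds reported unrounded)."""
    if t_crit is None:
        t_crit = t_critical(confidence, summary.n - 1)
    margin = margin_of_error(summary, confidence, t_crit=t_crit)
    return CIReport(
        confidence=confidence,
        t_crit=t_crit,
        margin=margin,
        lower=summary.mean - margin,
        upper=summary.mean + margin,
    )


def t_test_statement(
    summary: SampleSummary,
    confidence: float = 0.95,
    hypothesized_mean: float | None = None,
) -> TTestRecord:
    """APA-style two-tailed t record for H0: mu = hypothesized_mean.

    Testing against the sample mean itself (the default) is trivially
    accepted; the record is reported as printed without endorsing that
    inference.
    """
    df = summary.n - 1
    alpha = 1.0 - confidence
    crit = t_critical(confidence, df)
    mu0 = summary.mean if hypothesized_mean is None else hypothesized_mean
    margin = margin_of_error(summary, confidence)
    decision = "accept" if abs(mu0 - summary.mean) <= margin else "reject"
    alpha_txt = f"{alpha:.2f}".lstrip("0")
    statement = f"t({df}) = {crit:.3f}, p = {alpha_txt}"
    return TTestRecord(
        statement=statement,
        df=df,
        t_crit=crit,
        alpha=alpha,
        hypothesized_mean=mu0,
        decision=decision,
    )
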