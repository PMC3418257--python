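"""Carrier-frequency estimation, detection prediction and fracture tables.

A rare variant found k times among n genotyped subjects has frequency
k/n with an exact Clopper-Pearson confidence interval; the equal-tailed
binomial quantile interval then predicts how many carriers a future study
of a given size should detect.  Carrier-by-fracture 2x2 tables are tested
with a two-sided Fisher exact test (point-probability rule) and summarised
by the sample odds ratio with a Wald confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .datasets import VOLUNTEER_CARRIER_COUNTS

__all__ = [
    "FrequencyEstimate",
    "ContingencyTable",
    "OddsRatioResult",
    "carrier_frequency",
    "carrier_frequency_from_records",
    "detection_interval",
    "fisher_exact",
    "odds_ratio",
    "fracture_table_from_records",
]


@dataclass
class FrequencyEstimate:
    """Per-subject carrier frequency with exact binomial CI."""

    carriers: int
    genotyped: int
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95


@dataclass
class ContingencyTable:
    """2x2 counts: (carrier, non-carrier) x (fractured, unfractured)."""

    a: int  # carrier, fractured
    b: int  # carrier, unfractured
    c: int  # non-carrier, fractured
    d: int  # non-carrier, unfractured

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")

    def require_margins(self) -> None:
        if min(self.a + self.b, self.c + self.d,
               self.a + self.c, self.b + self.d) == 0:
            raise ValueError("all margins must be positive for testing")


@dataclass
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    haldane_corrected: bool = False


def carrier_frequency(k: int, n: int, level: float = 0.95) -> FrequencyEstimate:
    """Exact Clopper-Pearson interval for a carrier count.

    The bounds are beta quantiles: low = Beta(alpha/2; k, n-k+1), high =
    Beta(1-alpha/2; k+1, n-k); k = 0 pins the lower bound at 0 and k = n
    the upper at 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k must be in [0, n]; got k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    hi = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return FrequencyEstimate(k, n, k / n, lo, hi, level)


def carrier_frequency_from_records(
    records, cohorts: Sequence[str] | None = None, level: float = 0.95
) -> FrequencyEstimate:
    """Carrier frequency over phenotype records, restricted by default to
    the volunteer-recruited cohorts so ascertainment does not inflate it."""
    from .synthetic_cohorts import records_to_frame
    import pandas as pd

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if cohorts is None:
        cohorts = tuple(VOLUNTEER_CARRIER_COUNTS)
    present = df[df["cohort"].isin(cohorts)]
    if present.empty:
        raise ValueError(f"no subjects found in cohorts {list(cohorts)}")
    return carrier_frequency(
        int(present["carrier"].sum()), int(len(present)), level
    )


def detection_interval(
    n_future: int = 3000, p: float = 0.004, coverage: float = 0.95
) -> tuple[int, int]:
    """Equal-tailed binomial quantile interval for the carrier count a
    future study of ``n_future`` subjects would detect.

    lo is the smallest integer with CDF >= (1-coverage)/2 and hi the
    smallest with CDF >= 1-(1-coverage)/2.
    """
    if n_future < 1:
        raise ValueError("n_future must be >= 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    alpha = 1.0 - coverage
    lo = int(stats.binom.ppf(alpha / 2, n_future, p))
    hi = int(stats.binom.ppf(1 - alpha / 2, n_future, p))
    return lo, hi


def fisher_exact(table: ContingencyTable, rel_tol: float = 1e-7) -> float:
    """Two-sided Fisher exact p-value by full hypergeometric enumeration.

    With margins fixed, the first cell ``a`` follows a hypergeometric
    distribution; the two-sided p sums the point probabilities of every
    table in the margin orbit whose probability is less than or equal to
    the observed table's (the point-probability / minimum-likelihood
    convention), with a relative tolerance for floating-point ties.
    """
    table.require_margins()
    a, b, c, d = table.a, table.b, table.c, table.d
    row1 = a + b
    col1 = a + c
    n = a + b + c + d
    support = np.arange(max(0, col1 - (c + d)), min(row1, col1) + 1)
    pmf = stats.hypergeom.pmf(support, n, row1, col1)
    p_obs = float(pmf[a - support[0]])
    keep = pmf <= p_obs * (1.0 + rel_tol)
    return float(min(1.0, pmf[keep].sum()))


def odds_ratio(table: ContingencyTable, level: float = 0.95) -> OddsRatioResult:
    """Sample odds ratio ad/(bc) with a Wald interval on the log scale.

    A zero cell triggers the Haldane-Anscombe correction (0.5 added to
    every cell), flagged in the result.
    """
    table.require_margins()
    cells = [table.a, table.b, table.c, table.d]
    corrected = 0 in cells
    if corrected:
        cells = [x + 0.5 for x in cells]
    a, b, c, d = cells
    or_ = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    zq = stats.norm.ppf(1 - (1 - level) / 2)
    log_or = np.log(or_)
    return OddsRatioResult(
        odds_ratio=float(or_),
        ci_low=float(np.exp(log_or - zq * se)),
        ci_high=float(np.exp(log_or + zq * se)),
        level=level,
        haldane_corrected=corrected,
    )


def fracture_table_from_records(records, cohort: str) -> ContingencyTable:
    """Carrier-by-incident-fracture 2x2 table for one cohort."""
    from .synthetic_cohorts import records_to_frame
    import pandas as pd

    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    sub = df[df["cohort"] == cohort]
    if sub.empty:
        raise ValueError(f"no subjects in cohort {cohort!r}")
    car = sub["carrier"] == 1
    frac = sub["incident_fracture"] == 1
    return ContingencyTable(
        a=int((car & frac).sum()), b=int((car & ~frac).sum()),
        c=int((~car & frac).sum()), d=int((~car & ~frac).sum()),
    )
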