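"""Carrier summaries against the cohort distribution.

Under the null hypothesis that the rare variant has no effect, carrier
Z-scores are draws from the within-cohort standard distribution, so their
mean should sit at zero.  Each site is summarised by the carriers' mean Z
and a two-sided one-sample t-test of mean = 0; the femoral-neck site — the
only measure common to every cohort — is additionally pooled across
studies by simple concatenation of within-study Z-scores, as if all
carriers were drawn from one global standard population.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["SiteSummary", "site_summary", "summarize_sites", "pool_fn"]


@dataclass
class SiteSummary:
    """Carriers' mean Z at one site with a one-sample test of mean = 0.

    ``n`` counts carrier *observations* at the site (a carrier missing the
    site contributes no row); ``p`` is two-sided and None when n = 1.
    """

    site: str
    mean_z: float
    n: int
    p: float | None


def _one_sample_p(values: np.ndarray) -> float | None:
    """Two-sided one-sample t-test against 0; degenerate zero-variance
    samples get p = 1 when already at the null mean, else p -> 0."""
    if len(values) < 2:
        return None
    if np.std(values, ddof=1) == 0.0:
        return 1.0 if float(np.mean(values)) == 0.0 else 0.0
    t = stats.ttest_1samp(values, popmean=0.0)
    return float(t.pvalue)


def site_summary(ztable: pd.DataFrame, site: str) -> SiteSummary:
    """Summarise carrier Z-scores at one site (twin-collapsed input)."""
    rows = ztable[(ztable["site"] == site) & (ztable["carrier"] == 1)]
    if rows.empty:
        raise ValueError(f"no carrier observations at site {site!r}")
    z = rows["z"].to_numpy(dtype=float)
    return SiteSummary(
        site=site, mean_z=float(np.mean(z)), n=len(z), p=_one_sample_p(z)
    )


def summarize_sites(ztable: pd.DataFrame) -> pd.DataFrame:
    """Per-site carrier summary table (site, mean_z, n, p) over every site
    with at least one carrier observation."""
    out = []
    for site in ztable["site"].unique():
        sub = ztable[(ztable["site"] == site) & (ztable["carrier"] == 1)]
        if sub.empty:
            continue
        s = site_summary(ztable, site)
        out.append({"site": s.site, "mean_z": s.mean_z, "n": s.n, "p": s.p})
    return pd.DataFrame(out, columns=["site", "mean_z", "n", "p"])


def pool_fn(
    ztables: Iterable[pd.DataFrame] | Sequence[pd.DataFrame],
    site: str = "FN",
) -> SiteSummary:
    """Pool carrier femoral-neck Z-scores across studies.

    Each study contributes its *within-study* Z-scores; pooling is plain
    concatenation — all populations treated as one global standard
    population.  Studies lacking the site are skipped with a warning.
    """
    parts = []
    for i, zt in enumerate(ztables):
        has = zt[(zt["site"] == site) & (zt["carrier"] == 1)]
        if has.empty:
            label = zt["cohort"].iloc[0] if len(zt) else f"study {i}"
            logger.warning(
                "study %s contributes no carrier %s Z-scores; skipped",
                label, site,
            )
            continue
        parts.append(has)
    if not parts:
        raise ValueError(f"no study contributed carrier {site} Z-scores")
    pooled = pd.concat(parts, ignore_index=True)
    return site_summary(pooled, site)
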