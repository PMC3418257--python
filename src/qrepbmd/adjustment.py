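"""Covariate adjustment of raw bone measures into within-cohort Z-scores.

Bone density depends strongly on age and body weight, and different
cohorts use different densitometers, so raw measures are never comparable
across studies.  Each (cohort, site) measure is regressed on a small
covariate set by ordinary least squares *within its own cohort*, and each
subject is expressed as a Z-score: the OLS residual divided by the sample
standard deviation of residuals.  The Z-scores are dimensionless SD units
around the cohort regression mean, invariant to affine changes of device
units — which is what justifies pooling carriers across devices.

Three covariate sets are supported: ``age``, ``age-weight`` and
``age-winv`` (age plus inverse weight, the presented default).  The
stiffness index is log_e transformed before fitting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from dataclasses import dataclass
from typing import Iterable, Mapping

from .synthetic_cohorts import SubjectRecord, records_to_frame

__all__ = [
    "COVARIATE_SETS",
    "AdjustmentModel",
    "fit_adjustment",
    "fit_all",
    "zscores",
    "collapse_twins",
]

#: covariate-set name -> design columns (derived from age/weight)
COVARIATE_SETS: dict[str, tuple[str, ...]] = {
    "age": ("age",),
    "age-weight": ("age", "weight"),
    "age-winv": ("age", "winv"),
}

#: sites whose measure is log_e transformed before regression
LOG_SITES = frozenset({"STIFF"})


@dataclass
class AdjustmentModel:
    """Fitted within-cohort regression for one site.

    ``coefficients`` maps 'intercept' and each covariate to its slope in
    (possibly log-transformed) device units; ``residual_sd`` uses the n-1
    sample denominator; ``transform`` is 'log' for log_e-fitted sites.
    """

    cohort: str
    site: str
    covariate_set: str
    coefficients: dict[str, float]
    residual_sd: float
    n_fit: int
    transform: str = "identity"

    def design_row(self, age: float, weight: float) -> dict[str, float]:
        cov = {"age": age, "weight": weight, "winv": 1.0 / weight}
        return {c: cov[c] for c in COVARIATE_SETS[self.covariate_set]}

    def predict(self, age: np.ndarray, weight: np.ndarray) -> np.ndarray:
        cov = {"age": np.asarray(age, float),
               "weight": np.asarray(weight, float)}
        cov["winv"] = 1.0 / cov["weight"]
        pred = np.full_like(cov["age"], self.coefficients["intercept"])
        for c in COVARIATE_SETS[self.covariate_set]:
            pred = pred + self.coefficients[c] * cov[c]
        return pred


def _as_frame(records) -> pd.DataFrame:
    if isinstance(records, pd.DataFrame):
        return records
    return records_to_frame(records)


def fit_adjustment(
    records: Iterable[SubjectRecord] | pd.DataFrame,
    cohort: str,
    site: str,
    covariate_set: str = "age-winv",
) -> AdjustmentModel:
    """OLS fit of one site's (possibly log-transformed) measure on the
    chosen covariates, within one cohort.

    Carriers are included in the fitting set: at ~0.4 % prevalence their
    leverage is negligible and carriers are compared to the whole-cohort
    distribution.

    Raises
    ------
    ValueError
        If the covariate set is unknown, the site is absent, too few
        non-missing subjects remain, the design is singular (a constant
        covariate is named), or the fit has zero residual variance.
    """
    if covariate_set not in COVARIATE_SETS:
        raise ValueError(
            f"unknown covariate set {covariate_set!r}; "
            f"choose from {sorted(COVARIATE_SETS)}"
        )
    df = _as_frame(records)
    df = df[df["cohort"] == cohort]
    if site not in df.columns or df[site].notna().sum() == 0:
        raise ValueError(f"no non-missing {site} values in cohort {cohort!r}")
    sub = df.loc[df[site].notna(), ["age", "weight", site]].astype(float)
    covs = COVARIATE_SETS[covariate_set]
    if "winv" in covs and (sub["weight"] <= 0).any():
        raise ValueError("weight must be positive for the age-winv set")
    n = len(sub)
    n_coef = len(covs) + 1
    if n < n_coef + 3:
        raise ValueError(
            f"cohort {cohort!r} site {site}: need at least {n_coef + 3} "
            f"subjects with data, got {n}"
        )
    X = pd.DataFrame({"intercept": np.ones(n)}, index=sub.index)
    source = {"age": sub["age"], "weight": sub["weight"],
              "winv": 1.0 / sub["weight"]}
    for c in covs:
        X[c] = source[c]
        if np.ptp(X[c].to_numpy()) == 0.0:
            raise ValueError(
                f"singular design: covariate {c!r} is constant in "
                f"cohort {cohort!r}"
            )
    y = sub[site].to_numpy()
    transform = "identity"
    if site in LOG_SITES:
        if (y <= 0).any():
            raise ValueError(f"{site} must be positive for log transform")
        y = np.log(y)
        transform = "log"
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError(
            f"singular design for cohort {cohort!r} site {site}"
        )
    fit = sm.OLS(y, X).fit()
    resid_sd = float(np.std(fit.resid, ddof=1))
    # numerically perfect fits leave only rounding-level residuals
    if resid_sd <= 1e-12 * max(1.0, float(np.abs(y).max())):
        raise ValueError(
            f"zero residual variance for cohort {cohort!r} site {site}: "
            "cannot standardize a perfect fit"
        )
    return AdjustmentModel(
        cohort=cohort, site=site, covariate_set=covariate_set,
        coefficients={k: float(v) for k, v in fit.params.items()},
        residual_sd=resid_sd, n_fit=n, transform=transform,
    )


def fit_all(
    records: Iterable[SubjectRecord] | pd.DataFrame,
    covariate_set: str = "age-winv",
) -> dict[tuple[str, str], AdjustmentModel]:
    """Fit every (cohort, site) combination present in the data."""
    df = _as_frame(records)
    from .synthetic_cohorts import META_COLUMNS
    sites = [c for c in df.columns if c not in META_COLUMNS]
    models = {}
    for cohort in df["cohort"].unique():
        cdf = df[df["cohort"] == cohort]
        for site in sites:
            if site in cdf.columns and cdf[site].notna().any():
                models[(cohort, site)] = fit_adjustment(
                    cdf, cohort, site, covariate_set
                )
    return models


def zscores(
    records: Iterable[SubjectRecord] | pd.DataFrame,
    models: Mapping[tuple[str, str], AdjustmentModel],
) -> pd.DataFrame:
    """Long-format Z-score table: one row per (subject, site) observation.

    z = OLS residual / residual SD, computed within the subject's own
    cohort.  Missing measures yield no row (never a zero).  Columns:
    ``subject_id, cohort, site, z, carrier, transform``.
    """
    df = _as_frame(records)
    fitted_cohorts = {c for c, _ in models}
    unknown = set(df["cohort"].unique()) - fitted_cohorts
    if unknown:
        raise ValueError(f"no fitted models for cohort(s): {sorted(unknown)}")
    parts = []
    for (cohort, site), model in models.items():
        cdf = df[(df["cohort"] == cohort) & df[site].notna()]
        if cdf.empty:
            continue
        y = cdf[site].to_numpy(dtype=float)
        if model.transform == "log":
            y = np.log(y)
        resid = y - model.predict(cdf["age"].to_numpy(),
                                  cdf["weight"].to_numpy())
        parts.append(pd.DataFrame({
            "subject_id": cdf["subject_id"].to_numpy(),
            "cohort": cohort,
            "site": site,
            "z": resid / model.residual_sd,
            "carrier": cdf["carrier"].to_numpy(dtype=int),
            "transform": model.transform,
        }))
    if not parts:
        return pd.DataFrame(
            columns=["subject_id", "cohort", "site", "z", "carrier", "transform"]
        )
    return pd.concat(parts, ignore_index=True)


def collapse_twins(
    ztable: pd.DataFrame,
    records: Iterable[SubjectRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Average monozygotic twin pairs into single pseudo-subjects.

    Each MZ pair becomes one row per site with the pair-mean z (the pair is
    one genetically unique individual); dizygotic twins remain separate.
    Raises if an MZ pair has discordant carrier flags, which would violate
    shared genotype.
    """
    df = _as_frame(records)
    mz = df[(df["zygosity"] == "MZ") & (df["twin_pair_id"].astype(str) != "")]
    if mz.empty:
        return ztable.copy()
    for pid, grp in mz.groupby("twin_pair_id"):
        if grp["carrier"].nunique() > 1:
            raise ValueError(
                f"MZ pair {pid!r} has discordant carrier flags"
            )
    pair_of = dict(zip(mz["subject_id"], mz["twin_pair_id"]))
    zt = ztable.copy()
    zt["_pair"] = zt["subject_id"].map(pair_of)
    singles = zt[zt["_pair"].isna()].drop(columns="_pair")
    paired = zt[zt["_pair"].notna()]
    collapsed = (
        paired.groupby(["_pair", "cohort", "site", "transform"], as_index=False)
        .agg(z=("z", "mean"), carrier=("carrier", "max"))
        .rename(columns={"_pair": "subject_id"})
    )
    collapsed["subject_id"] = collapsed["subject_id"].astype(str) + ":MZ"
    cols = ["subject_id", "cohort", "site", "z", "carrier", "transform"]
    return pd.concat([singles[cols], collapsed[cols]], ignore_index=True)
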