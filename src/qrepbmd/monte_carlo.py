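"""Empirical multivariate p-values for small carrier groups.

A handful of rare-variant carriers, each measured on several correlated
bone-density parameters, yields one number: the grand mean of all their
within-cohort Z-scores.  How surprising is that mean under the null?  The
answer here is obtained by Monte Carlo: repeatedly draw same-sized groups
from multivariate normal distributions with the inter-site correlation
observed in each cohort, and count the fraction of trials whose grand mean
is equal to or more negative than the observed one (a one-sided,
tie-inclusive lower tail).

Because every trial statistic is a linear combination of jointly normal
variables, the null distribution is itself normal with a variance that can
be written down exactly; :func:`closed_form_p` provides that analytic
counterpart and is carried alongside every empirical result as a built-in
cross-check.
"""

from __future__ import annotations

import logging

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: smallest eigenvalue tolerated after positive-definite repair
MIN_EIGENVALUE = 1e-8


class NotPositiveDefiniteError(ValueError):
    """Raised when a correlation matrix cannot be Cholesky-factorised.

    Callers should pass the matrix through :meth:`CorrelationModel.repaired`
    before sampling.
    """


@dataclass
class CorrelationModel:
    """Inter-site Pearson correlation matrix for one cohort's site panel.

    Parameters
    ----------
    sites
        Ordered site labels; ``R`` rows/columns follow this order.
    R
        Symmetric correlation matrix with unit diagonal.
    n_est
        Number of subjects the correlations were estimated from (None for
        matrices specified a priori).
    """

    sites: tuple[str, ...]
    R: np.ndarray
    n_est: int | None = None

    def __post_init__(self) -> None:
        self.sites = tuple(self.sites)
        self.R = np.asarray(self.R, dtype=float)
        k = len(self.sites)
        if self.R.shape != (k, k):
            raise ValueError(
                f"correlation matrix shape {self.R.shape} does not match "
                f"{k} sites"
            )
        if not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-10):
            raise ValueError("correlation matrix diagonal must be 1")
        # exact symmetry/diagonal so downstream algebra is clean
        self.R = (self.R + self.R.T) / 2.0
        np.fill_diagonal(self.R, 1.0)

    @property
    def k(self) -> int:
        return len(self.sites)

    @classmethod
    def identity(cls, sites: Sequence[str]) -> "CorrelationModel":
        return cls(tuple(sites), np.eye(len(sites)))

    @classmethod
    def equicorrelated(cls, sites: Sequence[str], rho: float) -> "CorrelationModel":
        k = len(sites)
        R = np.full((k, k), float(rho))
        np.fill_diagonal(R, 1.0)
        return cls(tuple(sites), R)

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.R)[0])

    def is_positive_definite(self, tol: float = 0.0) -> bool:
        return self.min_eigenvalue() > tol

    def repaired(self, min_eig: float = MIN_EIGENVALUE) -> "CorrelationModel":
        """Eigenvalue-clipped, diagonal-rescaled positive-definite repair.

        Eigenvalues below ``min_eig`` are raised to it, the matrix is
        rebuilt, and then rescaled to unit diagonal.  A matrix that is
        already comfortably positive definite is returned unchanged.
        """
        w, V = np.linalg.eigh(self.R)
        if w[0] >= min_eig:
            return self
        w = np.clip(w, min_eig, None)
        R = (V * w) @ V.T
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
        R = (R + R.T) / 2.0
        np.fill_diagonal(R, 1.0)
        return CorrelationModel(self.sites, R, self.n_est)

    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.R)
        except np.linalg.LinAlgError as exc:
            raise NotPositiveDefiniteError(
                "correlation matrix is not positive definite; apply "
                ".repaired() before sampling"
            ) from exc


@dataclass
class Block:
    """Carriers contributed by one study: ``n_carriers`` draws from MVN(0, R)."""

    study: str
    n_carriers: int
    correlation: CorrelationModel

    def __post_init__(self) -> None:
        if self.n_carriers < 1:
            raise ValueError(f"block {self.study!r}: n_carriers must be >= 1")


@dataclass
class GroupDesign:
    """Composition of a carrier group across studies with their own panels."""

    blocks: list[Block] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("design needs at least one block")

    @property
    def n_values(self) -> int:
        """Total number of carrier-by-site observations in one trial."""
        return sum(b.n_carriers * b.correlation.k for b in self.blocks)


@dataclass
class EmpiricalResult:
    """Outcome of one empirical p-value run."""

    observed_mean: float
    trials: int
    tail_count: int
    p_empirical: float
    p_closed_form: float
    seed: int
    plus_one: bool = False


def estimate_correlation(
    ztable: pd.DataFrame,
    cohort: str,
    min_pairs: int = 10,
) -> CorrelationModel:
    """Pairwise-complete Pearson correlations of Z-scores within one cohort.

    All cohort subjects enter, carriers included (at ~0.4 % prevalence their
    influence on R is negligible).  The raw matrix is forced to unit
    diagonal and passed through positive-definite repair so it is always
    usable for Cholesky sampling.

    Parameters
    ----------
    ztable
        Long-format Z-score table with columns ``subject_id``, ``cohort``,
        ``site``, ``z``.
    cohort
        Cohort label to estimate within.
    min_pairs
        Minimum pairwise-complete subject count required per site pair.
    """
    sub = ztable[ztable["cohort"] == cohort]
    wide = sub.pivot_table(index="subject_id", columns="site", values="z")
    sites = [s for s in sub["site"].unique() if s in wide.columns]
    wide = wide[sites]
    if len(sites) < 2:
        raise ValueError(f"cohort {cohort!r} has fewer than 2 sites")
    sds = wide.std(ddof=1)
    scale = 1.0 + wide.mean().abs()
    zero_var = sds[~(sds > 1e-12 * scale)].index.tolist()
    if zero_var:
        raise ValueError(
            f"zero-variance site(s) in cohort {cohort!r}: {zero_var}"
        )
    counts = wide.notna().astype(int)
    pair_n = counts.T @ counts
    off = ~np.eye(len(sites), dtype=bool)
    if (pair_n.to_numpy()[off] < min_pairs).any():
        raise ValueError(
            f"cohort {cohort!r}: fewer than {min_pairs} pairwise-complete "
            "subjects for at least one site pair"
        )
    R = wide.corr(method="pearson").to_numpy()
    np.fill_diagonal(R, 1.0)
    model = CorrelationModel(tuple(sites), R, n_est=int(wide.shape[0]))
    return model.repaired()


def closed_form_p(design: GroupDesign, observed_mean: float) -> float:
    """Analytic tail probability for the grand-mean trial statistic.

    One trial draws, for block *b*, ``n_b`` independent MVN(0, R_b)
    vectors of length ``k_b`` and averages every drawn value.  The sum of
    one MVN(0, R) vector has variance 1'R1, so the grand total has
    variance sum_b n_b * 1'R_b 1 and the grand mean

        V = (sum_b n_b * 1'R_b 1) / (sum_b n_b * k_b)^2.

    The lower-tail probability is Phi(m / sqrt(V)).
    """
    denom = design.n_values
    var_total = sum(
        b.n_carriers * float(b.correlation.R.sum()) for b in design.blocks
    )
    V = var_total / denom**2
    if V <= 0:
        raise ValueError("trial-statistic variance must be positive")
    return float(stats.norm.cdf(observed_mean / np.sqrt(V)))


def empirical_p(
    design: GroupDesign,
    observed_mean: float,
    trials: int,
    seed: int,
    plus_one: bool = False,
    chunk: int = 65536,
) -> EmpiricalResult:
    """Monte Carlo empirical p-value for a carrier group's grand mean Z.

    Each trial draws ``n_carriers`` independent MVN(0, R) vectors per block
    (Cholesky sampling from a fixed PCG64 stream) and computes the
    unweighted mean of all drawn values across blocks and sites.  The tail
    count ``c`` is the number of trials whose statistic is less than or
    equal to ``observed_mean`` — ties count as extreme — and the empirical
    p-value is the plain ratio c / trials.

    Parameters
    ----------
    design
        Study blocks with carrier counts and correlation models.
    observed_mean
        Observed carrier grand-mean Z-score (SD units).
    trials
        Number of Monte Carlo trials (>= 1).
    seed
        Seed for the random stream; identical seed, design and trials give
        an identical tail count.
    plus_one
        If True report (c + 1) / (trials + 1) instead of the plain ratio.
    chunk
        Trials simulated per vectorised batch (memory control only; does
        not affect the stream).
    """
    if trials < 1:
        raise ValueError("trials must be >= 1")
    chols = [b.correlation.cholesky() for b in design.blocks]
    # one PCG64 substream per block so the tail count is independent of
    # the chunking used to bound memory
    rngs = [
        np.random.default_rng(child)
        for child in np.random.SeedSequence(seed).spawn(len(design.blocks))
    ]
    denom = design.n_values
    c = 0
    done = 0
    while done < trials:
        t = min(chunk, trials - done)
        total = np.zeros(t)
        for b, L, rng in zip(design.blocks, chols, rngs):
            z = rng.standard_normal((t, b.n_carriers, b.correlation.k))
            # row sums of (z @ L.T) == z @ (column sums of L)
            total += z.reshape(t, -1) @ np.tile(L.sum(axis=0), b.n_carriers)
        c += int(np.count_nonzero(total / denom <= observed_mean))
        done += t
    if c == 0:
        logger.warning(
            "tail count is 0 after %d trials; the empirical p-value is only "
            "an upper-bound indicator — increase trials", trials
        )
    p_emp = (c + 1) / (trials + 1) if plus_one else c / trials
    return EmpiricalResult(
        observed_mean=float(observed_mean),
        trials=int(trials),
        tail_count=c,
        p_empirical=float(p_emp),
        p_closed_form=closed_form_p(design, observed_mean),
        seed=int(seed),
        plus_one=plus_one,
    )
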