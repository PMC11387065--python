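"""Diversity and specialization metrics for diet community tables.

Implements the per-sample and per-species building blocks of the diet
seasonality indicators: Bray-Curtis dissimilarity, dietary richness,
incidence-based (Chao2-family) rarefaction/extrapolation of total niche
width, and Bluethgen's d' specialization index.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from skbio.stats.distance import DistanceMatrix

from .diet_table import DietTable, DietTableError

logger = logging.getLogger(__name__)


def bray_curtis(counts, labels=None) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between abundance rows.

    BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i); 0 for identical rows, 1 for
    rows with disjoint support.
    """
    X = _as_matrix(counts)
    if labels is None:
        labels = _labels_of(counts, X.shape[0])
    if (X < 0).any():
        raise ValueError("negative abundances")
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = [str(labels[i]) for i in np.flatnonzero(totals == 0)]
        raise ValueError(f"all-zero rows: {bad}")
    # |x-y| summed = (x+y) - 2*min(x,y); vectorized via minimum broadcasting
    n = X.shape[0]
    D = np.zeros((n, n))
    for i in range(n):
        shared = np.minimum(X[i], X[i + 1:]).sum(axis=1)
        denom = totals[i] + totals[i + 1:]
        D[i, i + 1:] = 1.0 - 2.0 * shared / denom
    D = D + D.T
    return DistanceMatrix(D, ids=[str(l) for l in labels])


def bray_curtis_pair(x, y) -> float:
    """Bray-Curtis dissimilarity between two abundance vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    denom = x.sum() + y.sum()
    if denom == 0:
        raise ValueError("both vectors empty")
    return float(np.abs(x - y).sum() / denom)


def richness(counts) -> np.ndarray:
    """Number of taxa with strictly positive abundance per row."""
    X = _as_matrix(counts)
    return (X > 0).sum(axis=1)


@dataclass(frozen=True)
class IncidenceFrequencies:
    """Incidence summary of one species-season set of sampling units.

    ``T`` sampling units; ``Y[j]`` = number of units in which taxon j was
    detected (only detected taxa are kept, so 1 <= Y_j <= T); ``Q[k]`` =
    number of taxa detected in exactly k units.
    """

    T: int
    Y: np.ndarray

    def __post_init__(self):
        Y = np.asarray(self.Y, dtype=int)
        object.__setattr__(self, "Y", Y)
        if len(Y) and (Y.min() < 1 or Y.max() > self.T):
            raise ValueError("incidence frequencies must lie in 1..T")

    @property
    def S_obs(self) -> int:
        return int(len(self.Y))

    @property
    def Q(self) -> dict[int, int]:
        k, c = np.unique(self.Y, return_counts=True)
        return dict(zip(k.tolist(), c.tolist()))


def incidence_from_samples(counts) -> IncidenceFrequencies:
    """Tally incidence frequencies from a sampling-unit x taxon table."""
    X = _as_matrix(counts)
    if X.shape[0] < 1:
        raise ValueError("need at least one sampling unit")
    Y = (X > 0).sum(axis=0)
    return IncidenceFrequencies(T=X.shape[0], Y=Y[Y > 0])


def chao2_q0(inc: IncidenceFrequencies) -> float:
    """Chao2 estimate of the number of undetected taxa.

    Q0_hat = ((T-1)/T) * Q1^2 / (2 Q2) when Q2 > 0, else the bias-corrected
    ((T-1)/T) * Q1 (Q1 - 1) / 2.
    """
    Q = inc.Q
    q1, q2 = Q.get(1, 0), Q.get(2, 0)
    T = inc.T
    if q2 > 0:
        return (T - 1) / T * q1 * q1 / (2.0 * q2)
    return (T - 1) / T * q1 * (q1 - 1) / 2.0


def estimate_richness_at(inc: IncidenceFrequencies, t: int) -> float:
    """Expected taxon richness at ``t`` sampling units (TNW standardization).

    For t <= T this is the exact sample-size-based interpolation
    S(t) = S_obs - sum_j C(T - Y_j, t) / C(T, t), the mean richness over
    all size-t subsets of the T units. For t > T the Chao2 extrapolation
    S(T + t*) = S_obs + Q0_hat * [1 - (1 - Q1/(Q1 + T*Q0_hat))^t*] is used;
    when Q1 = 0 the asymptote is attained and S_obs is returned.
    Monotone non-decreasing in t, with S(T) = S_obs.
    """
    if t < 1:
        raise ValueError("t must be >= 1")
    T, Y = inc.T, inc.Y
    if t <= T:
        # C(T-Y, t)/C(T, t) in log space; zero when T - Y < t
        out = 0.0
        for y in Y:
            if T - y >= t:
                out += np.exp(
                    _lchoose(T - y, t) - _lchoose(T, t)
                )
        return float(inc.S_obs - out)
    q0 = chao2_q0(inc)
    q1 = inc.Q.get(1, 0)
    if q1 == 0 or q0 == 0:
        return float(inc.S_obs)
    if t > 2 * T:
        logger.info("extrapolating richness beyond twice the sample size (t=%d, T=%d)", t, T)
    tstar = t - T
    return float(inc.S_obs + q0 * (1.0 - (1.0 - q1 / (q1 + T * q0)) ** tstar))


def _lchoose(n: int, k: int) -> float:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


@dataclass(frozen=True)
class SpecializationResult:
    """Raw and standardized Bluethgen specialization per network row."""

    labels: list
    d: np.ndarray        # raw KL divergence (nats)
    d_min: float
    d_max: np.ndarray    # per-row upper bound ln(1/q_min)
    d_prime: np.ndarray  # standardized to [0, 1]

    def as_series(self) -> pd.Series:
        return pd.Series(self.d_prime, index=self.labels, name="d_prime")


def dprime(network, labels=None) -> SpecializationResult:
    """Bluethgen's d' for each consumer row of a consumer x resource matrix.

    With row shares p_ij = a_ij / A_i and network-wide resource shares
    q_j = A_j / m, the raw index is the Kullback-Leibler divergence
    d_i = sum_j p_ij ln(p_ij / q_j) (0 ln 0 := 0): 0 when a consumer uses
    resources in proportion to their availability across the whole network,
    large when it concentrates on resources rare in the network.
    Standardization treats weights as continuous, so d_min = 0 and
    d_max = ln(1/q_min) with q_min the smallest positive network share;
    d'_i = d_i / d_max, clipped to [0, 1].
    """
    A = _as_matrix(network).astype(float)
    if labels is None:
        labels = _labels_of(network, A.shape[0])
    row_tot = A.sum(axis=1)
    if (row_tot <= 0).any():
        bad = [str(labels[i]) for i in np.flatnonzero(row_tot <= 0)]
        raise ValueError(f"empty consumer rows: {bad}")
    col_tot = A.sum(axis=0)
    q = col_tot / col_tot.sum()
    q_min = q[q > 0].min()
    d_max = np.log(1.0 / q_min)
    P = A / row_tot[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(P > 0, P * np.log(P / q), 0.0)
    d = terms.sum(axis=1)
    d = np.maximum(d, 0.0)  # numerical floor; KL >= 0
    if d_max > 0:
        dp = np.clip(d / d_max, 0.0, 1.0)
    else:
        dp = np.zeros_like(d)
    return SpecializationResult(
        labels=[str(l) for l in labels],
        d=d,
        d_min=0.0,
        d_max=np.full_like(d, d_max),
        d_prime=dp,
    )


def herd_dprime(table: DietTable, season: str) -> pd.Series:
    """Mean herd-level d' per consumer species within one season.

    The network is all same-season samples x taxa; each sample's d'
    measures the uniqueness of that herd's diet relative to all herds
    foraging in the same season, and values are averaged per species.
    """
    sub = table.season_filter((season,))
    if len(sub.counts) < 2:
        raise DietTableError(f"need >= 2 samples in season {season!r}")
    res = dprime(sub.counts.values, labels=sub.sample_ids)
    per_sample = pd.Series(res.d_prime, index=sub.sample_ids)
    out = per_sample.groupby(sub.sample_meta["species"]).mean()
    out.name = "herd_dprime"
    return out


def species_dprime(table: DietTable, season: str) -> pd.Series:
    """d' of each species' mean seasonal diet profile relative to the others.

    Mean relative-abundance profiles per species form the network rows, so
    the index reflects between-species dietary partitioning in the season.
    """
    sub = table.season_filter((season,))
    rel = sub.counts.div(sub.counts.sum(axis=1), axis=0)
    means = rel.groupby(sub.sample_meta["species"]).mean()
    if len(means) < 2:
        raise DietTableError(f"need >= 2 species in season {season!r}")
    res = dprime(means.values, labels=means.index)
    out = pd.Series(res.d_prime, index=means.index, name="species_dprime")
    return out


def _as_matrix(x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        return x.values
    return np.atleast_2d(np.asarray(x))


def _labels_of(x, n: int):
    if isinstance(x, pd.DataFrame):
        return list(x.index)
    return [str(i) for i in range(n)]
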