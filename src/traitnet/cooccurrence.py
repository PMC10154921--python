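"""Probabilistic trait-pair co-occurrence within one community.

For a community of N species in which N_i species bear modality i and N_j
bear modality j, the null model places the N_j bearers of j uniformly at
random among the N species. The number q of species bearing both modalities
is then hypergeometric:

    P(q) = C(N_i, q) * C(N - N_i, N_j - q) / C(N, N_j)

with mean E = N_i * N_j / N, the *expected co-occurrence*. Pairs expected
to co-occur in fewer than one species (E < 1) carry no response diversity
and are filtered out before network construction; the observed overlap
Q_obs of each retained pair becomes the network edge weight.

Tail probabilities (P(q <= Q_obs), P(q >= Q_obs)) are reported for every
pair so that significance can be inspected or, optionally, used as an
additional retention filter.

Combinatorics are computed by log-factorial accumulation (via the log-gamma
function), which stays accurate in double precision for community sizes far
beyond anything a field survey produces.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .trait_data import SiteTreatmentCommunity, TraitMatrix


class CooccurrenceError(ValueError):
    """Raised on infeasible co-occurrence arguments."""


@dataclass(frozen=True)
class TraitPairStat:
    """Exact co-occurrence statistics for one unordered modality pair.

    Attributes
    ----------
    mod_i, mod_j : str
        Modality ids (stored in sorted order; the pair is unordered).
    n : int
        Community species richness N.
    n_i, n_j : int
        Species bearing each modality.
    q_obs : int
        Observed number of species bearing both.
    expected : float
        E = N_i * N_j / N.
    p_lt, p_gt : float
        Lower/upper tail probabilities of the hypergeometric null at q_obs.
        Both include the probability mass at q_obs, so p_lt + p_gt >= 1.
    """

    mod_i: str
    mod_j: str
    n: int
    n_i: int
    n_j: int
    q_obs: int
    expected: float
    p_lt: float
    p_gt: float

    @property
    def pair(self) -> tuple[str, str]:
        return (self.mod_i, self.mod_j)


def expected_cooccurrence(n_i: int, n_j: int, n: int) -> float:
    """Expected number of species bearing both modalities, N_i*N_j/N."""
    _check_counts(n_i, n_j, n)
    return n_i * n_j / n


def _check_counts(n_i: int, n_j: int, n: int) -> None:
    if n < 1:
        raise CooccurrenceError("community size N must be >= 1")
    if n_i < 0 or n_j < 0:
        raise CooccurrenceError("modality counts must be non-negative")
    if n_i > n or n_j > n:
        raise CooccurrenceError("modality counts cannot exceed community size")


def _log_binom(a: np.ndarray | int, b: np.ndarray | int) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def feasible_overlap(n_i: int, n_j: int, n: int) -> tuple[int, int]:
    """Inclusive [min, max] support of the overlap count q."""
    return max(0, n_i + n_j - n), min(n_i, n_j)


def cooccurrence_pmf(n_i: int, n_j: int, n: int, q: int | np.ndarray) -> np.ndarray | float:
    """Hypergeometric probability that exactly ``q`` species bear both modalities.

    Zero outside the feasible support; sums to 1 over the support.
    """
    _check_counts(n_i, n_j, n)
    q_arr = np.asarray(q)
    if np.any(q_arr < 0):
        raise CooccurrenceError("overlap count q must be non-negative")
    lo, hi = feasible_overlap(n_i, n_j, n)
    feas = (q_arr >= lo) & (q_arr <= hi)
    qf = np.where(feas, q_arr, lo)
    logp = (
        _log_binom(n_i, qf)
        + _log_binom(n - n_i, n_j - qf)
        - _log_binom(n, n_j)
    )
    p = np.where(feas, np.exp(logp), 0.0)
    return float(p) if np.isscalar(q) or q_arr.ndim == 0 else p


def cooccurrence_pvalues(stat_or_ni, n_j: int | None = None, n: int | None = None,
                         q_obs: int | None = None) -> tuple[float, float]:
    """Lower and upper tail probabilities at the observed overlap.

    Accepts either a :class:`TraitPairStat` or raw counts
    ``(n_i, n_j, n, q_obs)``. Both tails include the mass at ``q_obs``.
    """
    if isinstance(stat_or_ni, TraitPairStat):
        s = stat_or_ni
        n_i, n_j, n, q_obs = s.n_i, s.n_j, s.n, s.q_obs
    else:
        n_i = stat_or_ni
        if None in (n_j, n, q_obs):
            raise TypeError("raw-count form requires n_i, n_j, n, q_obs")
    lo, hi = feasible_overlap(n_i, n_j, n)
    if not lo <= q_obs <= hi:
        raise CooccurrenceError(
            f"observed overlap {q_obs} outside feasible range [{lo}, {hi}] "
            f"for N_i={n_i}, N_j={n_j}, N={n}"
        )
    support = np.arange(lo, hi + 1)
    pmf = cooccurrence_pmf(n_i, n_j, n, support)
    p_lt = float(pmf[support <= q_obs].sum())
    p_gt = float(pmf[support >= q_obs].sum())
    return min(p_lt, 1.0), min(p_gt, 1.0)


def score_trait_pairs(
    community: SiteTreatmentCommunity, traits: TraitMatrix
) -> list[TraitPairStat]:
    """Exact co-occurrence statistics for every modality pair in one community.

    Only pairs whose two modalities are each borne by at least one community
    species are scored; Q_obs is counted over the community's species only.
    """
    if not traits.binary:
        raise CooccurrenceError("trait matrix must be binarized before scoring")
    missing = sorted(community.presence - set(traits.taxa))
    if missing:
        raise CooccurrenceError(f"taxa absent from the trait table: {missing}")
    members = sorted(community.presence)
    n = len(members)
    if n == 0:
        return []
    idx = [traits.taxa.index(t) for t in members]
    sub = traits.scores[idx]  # species x modality incidence, community only
    counts = sub.sum(axis=0).astype(int)
    overlap = (sub.T @ sub).astype(int)

    stats: list[TraitPairStat] = []
    mod_ids = traits.modality_ids
    for a, b in combinations(range(len(mod_ids)), 2):
        n_i, n_j = int(counts[a]), int(counts[b])
        if n_i == 0 or n_j == 0:
            continue
        q = int(overlap[a, b])
        p_lt, p_gt = cooccurrence_pvalues(n_i, n_j, n, q)
        mi, mj = sorted((mod_ids[a], mod_ids[b]))
        stats.append(
            TraitPairStat(
                mod_i=mi, mod_j=mj, n=n, n_i=n_i, n_j=n_j, q_obs=q,
                expected=n_i * n_j / n, p_lt=p_lt, p_gt=p_gt,
            )
        )
    return stats


def filter_trait_pairs(
    stats: Iterable[TraitPairStat],
    e_threshold: float = 1.0,
    sig_alpha: float | None = None,
    exclude_within_trait: bool = False,
    traits: TraitMatrix | None = None,
) -> list[TraitPairStat]:
    """Retain the pairs that define network edges.

    A pair is kept when its expected co-occurrence is at least
    ``e_threshold`` (default 1: pairs expected to co-occur in fewer than one
    species are removed) AND it was actually observed in at least one
    species — a zero-weight edge carries no response diversity.

    ``sig_alpha`` optionally adds a positive-association significance filter
    (p_gt <= alpha); off by default. ``exclude_within_trait`` drops pairs of
    modalities belonging to the same parent trait (requires ``traits``).
    """
    if e_threshold < 0:
        raise CooccurrenceError("e_threshold must be >= 0")
    if exclude_within_trait and traits is None:
        raise CooccurrenceError("exclude_within_trait requires the trait matrix")
    kept = []
    for s in stats:
        if s.expected < e_threshold or s.q_obs < 1:
            continue
        if sig_alpha is not None and s.p_gt > sig_alpha:
            continue
        if exclude_within_trait and (
            traits.modality(s.mod_i).trait == traits.modality(s.mod_j).trait
        ):
            continue
        kept.append(s)
    return kept


def pairs_to_frame(
    stats: Sequence[TraitPairStat], site=None, treatment: str | None = None
) -> pd.DataFrame:
    """Tabulate pair statistics (CSV-ready)."""
    rows = [
        {
            "site": site, "treatment": treatment,
            "modality_i": s.mod_i, "modality_j": s.mod_j,
            "N": s.n, "N_i": s.n_i, "N_j": s.n_j, "Q_obs": s.q_obs,
            "E": s.expected, "p_lt": s.p_lt, "p_gt": s.p_gt,
        }
        for s in stats
    ]
    cols = ["site", "treatment", "modality_i", "modality_j",
            "N", "N_i", "N_j", "Q_obs", "E", "p_lt", "p_gt"]
    return pd.DataFrame(rows, columns=cols)


def write_pairs(stats: Sequence[TraitPairStat], path: str | Path,
                site=None, treatment: str | None = None) -> None:
    pairs_to_frame(stats, site=site, treatment=treatment).to_csv(path, index=False)
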