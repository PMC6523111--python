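"""Phylogenetic community structure: MPD, independent-swap nulls, NRI.

The Net Relatedness Index (NRI) asks whether the species co-occurring in a
plot are more (clustering) or less (overdispersion) related than expected by
chance.  For each plot we compute the mean pairwise patristic distance (MPD)
among its species, compare it to the distribution of MPDs in null
communities produced by the independent-swap algorithm (checkerboard swaps
that preserve every row and column total of the plot x species presence
matrix), and standardize:

    NRI = -(MPD_obs - mean(MPD_null)) / sd(MPD_null)

so positive NRI means clustering.  Significance uses the two-tailed rank of
the observed MPD among the null values: with R = 9999 randomizations and
alpha = 0.05, ranks >= 9750 or <= 250 are significant.

Null communities are sampled by a symmetric Metropolis chain: a 2x2
submatrix (two random rows, two random columns) is swapped whenever it forms
a checkerboard, which leaves the stationary distribution uniform over all
binary matrices with the observed margins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .tree_core import Phylogeny, patristic_distances

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "NRIResult",
    "mpd",
    "independent_swap",
    "rank_test",
    "nri",
    "run_pool_analysis",
    "results_to_frame",
    "read_community_csv",
]

# Number of successful checkerboard swaps between successive null samples,
# as a multiple of the count of 1-cells; the chain is burned in for one
# schedule before the first sample is taken.
SWAP_SCHEDULE_FACTOR = 10
# Attempt budget per sample, as a multiple of the swap target, guarding
# against matrices with no (or few) swappable checkerboards.
ATTEMPT_BUDGET_FACTOR = 100


# --------------------------------------------------------------------------
# community matrix container
# --------------------------------------------------------------------------
@dataclass
class CommunityMatrix:
    """Plots x species abundance matrix with a site id per plot.

    ``abundance`` is a DataFrame (rows = plot ids, columns = species labels,
    non-negative integers); ``sites`` maps each plot id to its site id.
    """

    abundance: pd.DataFrame
    sites: pd.Series

    def __post_init__(self) -> None:
        if (self.abundance.to_numpy() < 0).any():
            raise ValueError("negative abundances in community matrix")
        self.sites = self.sites.reindex(self.abundance.index)
        if self.sites.isna().any():
            raise ValueError("every plot needs a site id")

    @property
    def plot_ids(self) -> list:
        return list(self.abundance.index)

    @property
    def species(self) -> list[str]:
        return list(self.abundance.columns)

    def presence(self) -> pd.DataFrame:
        return (self.abundance > 0).astype(np.int8)

    def richness(self) -> pd.Series:
        return (self.abundance > 0).sum(axis=1)

    def validate_against_tree(self, tree: Phylogeny) -> None:
        missing = set(self.species) - set(tree.tip_labels)
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")


def read_community_csv(path) -> CommunityMatrix:
    """Read the community CSV layout: plot, site, then species columns."""
    df = pd.read_csv(path)
    plot_col, site_col = df.columns[0], df.columns[1]
    abundance = df.set_index(plot_col).drop(columns=[site_col]).astype(int)
    sites = df.set_index(plot_col)[site_col]
    return CommunityMatrix(abundance=abundance, sites=sites)


# --------------------------------------------------------------------------
# MPD
# --------------------------------------------------------------------------
def mpd(abundances, dist: pd.DataFrame | np.ndarray, weighted: bool = True) -> float:
    """Mean pairwise patristic distance among species present in one plot.

    Unweighted: the mean of d(i, j) over all unordered pairs of present
    species.  Weighted: sum_{i<j} a_i a_j d(i,j) / sum_{i<j} a_i a_j, i.e.
    pairs weighted by the product of abundances.

    Parameters
    ----------
    abundances
        Per-species counts, aligned with the rows of ``dist`` (a Series
        indexed like the distance matrix, or a plain array).
    dist
        Square patristic distance matrix.
    weighted
        Abundance-weight the pairs (default True).

    Raises
    ------
    ValueError
        If fewer than two species have positive abundance ("MPD undefined").
    """
    if isinstance(dist, pd.DataFrame):
        if isinstance(abundances, pd.Series):
            abundances = abundances.reindex(dist.index).fillna(0.0)
        dist = dist.to_numpy()
    a = np.asarray(abundances, dtype=float)
    present = a > 0
    if present.sum() < 2:
        raise ValueError("MPD undefined: fewer than 2 species present")
    if not weighted:
        a = present.astype(float)
    # dist has a zero diagonal, so a.D.a double-counts each unordered pair
    num = float(a @ dist @ a)
    s, q = a.sum(), (a * a).sum()
    return num / (s * s - q)


def _row_mpd(matrix: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Vectorized MPD of every row of a (weighted or binary) matrix.

    Rows with <2 positive entries yield NaN.
    """
    m = matrix.astype(float)
    num = np.einsum("ij,jk,ik->i", m, dist, m)
    s = m.sum(axis=1)
    q = (m * m).sum(axis=1)
    denom = s * s - q
    k = (m > 0).sum(axis=1)
    out = np.full(len(m), np.nan)
    ok = (k >= 2) & (denom > 0)
    out[ok] = num[ok] / denom[ok]
    return out


# --------------------------------------------------------------------------
# independent swap
# --------------------------------------------------------------------------
def _swap_kernel_py(mat, n_swaps, max_attempts, seed):  # pragma: no cover
    np.random.seed(seed)
    n_rows, n_cols = mat.shape
    done = 0
    attempts = 0
    while done < n_swaps and attempts < max_attempts:
        attempts += 1
        r1 = np.random.randint(0, n_rows)
        r2 = np.random.randint(0, n_rows)
        c1 = np.random.randint(0, n_cols)
        c2 = np.random.randint(0, n_cols)
        if r1 == r2 or c1 == c2:
            continue
        a, b = mat[r1, c1], mat[r1, c2]
        c, d = mat[r2, c1], mat[r2, c2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            mat[r1, c1] = 0
            mat[r2, c2] = 0
            mat[r1, c2] = 1
            mat[r2, c1] = 1
            done += 1
        elif a == 0 and d == 0 and b == 1 and c == 1:
            mat[r1, c1] = 1
            mat[r2, c2] = 1
            mat[r1, c2] = 0
            mat[r2, c1] = 0
            done += 1
    return done


try:  # jit the hot loop; the pure-Python path is identical
    from numba import njit

    _swap_kernel = njit(cache=False)(_swap_kernel_py)
except ImportError:  # pragma: no cover
    _swap_kernel = _swap_kernel_py


def independent_swap(
    presence: np.ndarray,
    n_successful_swaps: int,
    rng_seed: int,
) -> np.ndarray:
    """Randomize a binary matrix by 2x2 checkerboard swaps.

    Picks two random rows and two random columns and exchanges the 2x2
    checkerboard ([[1,0],[0,1]] <-> [[0,1],[1,0]]) whenever one is found,
    until ``n_successful_swaps`` swaps succeed or the attempt budget
    (:data:`ATTEMPT_BUDGET_FACTOR` x the target) runs out.  Row and column
    totals are always preserved.  A matrix with no swappable checkerboard is
    returned unchanged after the budget, with a logged warning.
    """
    mat = np.ascontiguousarray(np.asarray(presence, dtype=np.int8).copy())
    if not np.isin(mat, (0, 1)).all():
        raise ValueError("presence matrix must be binary")
    if n_successful_swaps < 0:
        raise ValueError("n_successful_swaps must be >= 0")
    if n_successful_swaps == 0 or min(mat.shape) < 2:
        return mat
    budget = ATTEMPT_BUDGET_FACTOR * max(n_successful_swaps, 1)
    done = _swap_kernel(mat, n_successful_swaps, budget, rng_seed % (2**31))
    if done < n_successful_swaps:
        logger.warning(
            "independent_swap: only %d/%d swaps after attempt budget",
            done,
            n_successful_swaps,
        )
    return mat


def _null_stream(presence: np.ndarray, n_null: int, rng: np.random.Generator):
    """Yield ``n_null`` null matrices from one swap chain.

    The chain is burned in for one full schedule, then a sample is emitted
    every SWAP_SCHEDULE_FACTOR x (#1-cells) successful swaps.
    """
    mat = np.ascontiguousarray(presence.astype(np.int8).copy())
    per_sample = max(SWAP_SCHEDULE_FACTOR * int(mat.sum()), 1)
    budget = ATTEMPT_BUDGET_FACTOR * per_sample
    seeds = rng.integers(0, 2**31 - 1, size=n_null + 1)
    # a random 0/1 extra swap per sample randomizes swap-count parity;
    # a fixed even count would trap matrices whose swap graph is bipartite
    # (every swap flips the parity class) in one class forever
    extra = rng.integers(0, 2, size=n_null + 1)
    _swap_kernel(mat, per_sample + int(extra[0]), budget, int(seeds[0]))
    for i in range(n_null):
        _swap_kernel(
            mat, per_sample + int(extra[i + 1]), budget, int(seeds[i + 1])
        )
        yield mat


# --------------------------------------------------------------------------
# rank test
# --------------------------------------------------------------------------
def rank_test(
    obs: float, nulls, alpha: float = 0.05
) -> tuple[int, bool, str]:
    """Two-tailed rank test of an observed value against null draws.

    The rank of the observation among the nulls-plus-observation is
    1 + #{null < obs} + 0.5 * #{null == obs}, rounded half up; with R nulls
    the result is significant iff rank >= ceil((1 - alpha/2) * (R + 1)) or
    rank <= floor((alpha/2) * (R + 1)).  (At R = 9999 and alpha = 0.05 the
    critical ranks are 9750 and 250.)

    Returns ``(rank, significant, direction)`` where direction is "high",
    "low" or "none".
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("rank_test needs at least one null value")
    r_float = 1.0 + np.count_nonzero(nulls < obs) + 0.5 * np.count_nonzero(
        nulls == obs
    )
    rank = int(math.floor(r_float + 0.5))  # round half up
    n_tot = nulls.size + 1
    hi = math.ceil((1 - alpha / 2) * n_tot)
    lo = math.floor((alpha / 2) * n_tot)
    if rank >= hi:
        return rank, True, "high"
    if rank <= lo:
        return rank, True, "low"
    return rank, False, "none"


def critical_ranks(n_randomizations: int, alpha: float = 0.05) -> tuple[int, int]:
    """(lower, upper) critical ranks of the two-tailed rank test."""
    n_tot = n_randomizations + 1
    return (
        math.floor((alpha / 2) * n_tot),
        math.ceil((1 - alpha / 2) * n_tot),
    )


# --------------------------------------------------------------------------
# NRI
# --------------------------------------------------------------------------
@dataclass
class NRIResult:
    """Per-plot NRI with its null distribution summary."""

    plot_id: object
    pool_mode: str
    mpd_obs: float
    null_mean: float
    null_sd: float
    nri: float
    rank: int
    n_randomizations: int
    significant: bool
    direction: str  # clustered | overdispersed | none
    degenerate: bool = False


def _permute_abundances(
    null_presence: np.ndarray,
    abundance: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Carry observed abundances onto a null presence matrix.

    Each species' positive abundance values are permuted uniformly at random
    across that species' occurrence cells in the null matrix (counts match
    because swaps preserve column totals).
    """
    out = np.zeros_like(abundance, dtype=float)
    for j in range(abundance.shape[1]):
        vals = abundance[abundance[:, j] > 0, j]
        rows = np.flatnonzero(null_presence[:, j])
        if len(vals) != len(rows):  # pragma: no cover - margin invariant
            raise AssertionError("column total changed under null")
        out[rng.permutation(rows), j] = vals
    return out


def _null_mpd_matrix(
    presence: np.ndarray,
    abundance: np.ndarray | None,
    dist: np.ndarray,
    n_rand: int,
    weighted: bool,
    rng: np.random.Generator,
) -> np.ndarray:
    """(n_rand x n_plots) matrix of null MPDs for every plot row."""
    out = np.empty((n_rand, presence.shape[0]))
    for i, null in enumerate(_null_stream(presence, n_rand, rng)):
        if weighted:
            null_ab = _permute_abundances(null, abundance, rng)
            out[i] = _row_mpd(null_ab, dist)
        else:
            out[i] = _row_mpd(null, dist)
    return out


def _summarize_plot(
    plot_id,
    pool_mode: str,
    mpd_obs: float,
    nulls: np.ndarray,
    n_rand: int,
    alpha: float,
) -> NRIResult:
    if not np.isfinite(mpd_obs):
        return NRIResult(
            plot_id, pool_mode, np.nan, np.nan, np.nan, np.nan, 0, n_rand,
            False, "none", degenerate=True,
        )
    null_mean = float(np.mean(nulls))
    null_sd = float(np.std(nulls, ddof=1))
    # guard against a null distribution that is constant up to float noise
    if null_sd <= 1e-12 * max(1.0, abs(null_mean)) or not np.isfinite(null_sd):
        return NRIResult(
            plot_id, pool_mode, mpd_obs, null_mean, null_sd, np.nan, 0,
            n_rand, False, "none", degenerate=True,
        )
    nri_val = -(mpd_obs - null_mean) / null_sd
    rank, sig, _ = rank_test(mpd_obs, nulls, alpha=alpha)
    if sig and nri_val > 0:
        direction = "clustered"
    elif sig and nri_val < 0:
        direction = "overdispersed"
    else:
        direction = "none"
    return NRIResult(
        plot_id, pool_mode, mpd_obs, null_mean, null_sd, float(nri_val),
        rank, n_rand, sig, direction,
    )


def _pool_nri(
    community: CommunityMatrix,
    dist: pd.DataFrame,
    plot_ids,
    pool: list[str],
    pool_mode: str,
    n_randomizations: int,
    weighted: bool,
    rng: np.random.Generator,
    alpha: float,
) -> list[NRIResult]:
    """NRI for a block of plots randomized within one species pool."""
    ab = community.abundance.loc[plot_ids, pool].to_numpy(dtype=float)
    d = dist.loc[pool, pool].to_numpy()
    presence = (ab > 0).astype(np.int8)
    obs = _row_mpd(ab if weighted else presence, d)
    nulls = _null_mpd_matrix(
        presence, ab if weighted else None, d, n_randomizations, weighted, rng
    )
    results = []
    for k, pid in enumerate(plot_ids):
        col = nulls[:, k]
        col = col[np.isfinite(col)]
        if np.isfinite(obs[k]) and col.size:
            res = _summarize_plot(
                pid, pool_mode, obs[k], col, n_randomizations, alpha
            )
        else:
            if not np.isfinite(obs[k]):
                logger.warning("plot %r: richness < 2, MPD undefined", pid)
            res = NRIResult(
                pid, pool_mode, float(obs[k]), np.nan, np.nan, np.nan, 0,
                n_randomizations, False, "none", degenerate=True,
            )
        results.append(res)
    return results


def nri(
    community: CommunityMatrix,
    tree: Phylogeny,
    plot_id,
    pool: set[str] | None = None,
    n_randomizations: int = 9999,
    weighted: bool = True,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> NRIResult:
    """Net Relatedness Index of one plot against an independent-swap null.

    The plot x species presence matrix restricted to ``pool`` (default: all
    species observed anywhere) is randomized ``n_randomizations`` times; the
    plot's null MPDs give the standardization mean/SD and the two-tailed
    rank.  Positive NRI = phylogenetic clustering.
    """
    community.validate_against_tree(tree)
    if pool is None:
        pres = community.presence()
        pool_list = [s for s in community.species if pres[s].any()]
    else:
        pool_list = [s for s in community.species if s in pool]
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    dist = patristic_distances(tree)
    rng = np.random.default_rng(rng_seed)
    results = _pool_nri(
        community, dist, community.plot_ids, pool_list, "regional",
        n_randomizations, weighted, rng, alpha,
    )
    by_id = {r.plot_id: r for r in results}
    return by_id[plot_id]


def run_pool_analysis(
    community: CommunityMatrix,
    tree: Phylogeny,
    mode: str = "regional",
    n_randomizations: int = 9999,
    weighted: bool = True,
    rng_seed: int = 0,
    alpha: float = 0.05,
    dist: pd.DataFrame | None = None,
) -> list[NRIResult]:
    """NRI for every plot under a regional or site-specific species pool.

    ``mode="regional"`` randomizes all plots jointly within the pool of all
    species observed anywhere; ``mode="site"`` runs one randomization per
    site, restricted to that site's plots and the species recorded there.
    Plots with richness < 2 (or a degenerate null) are reported as flagged
    rows, never dropped silently.
    """
    if mode not in ("regional", "site"):
        raise ValueError(f"unknown pool mode {mode!r}")
    community.validate_against_tree(tree)
    if dist is None:
        dist = patristic_distances(tree)
    rng = np.random.default_rng(rng_seed)
    pres = community.presence()
    if mode == "regional":
        pool = [s for s in community.species if pres[s].any()]
        return _pool_nri(
            community, dist, community.plot_ids, pool, "regional",
            n_randomizations, weighted, rng, alpha,
        )
    results: list[NRIResult] = []
    order = {p: i for i, p in enumerate(community.plot_ids)}
    for site in pd.unique(community.sites):
        plot_ids = [p for p in community.plot_ids if community.sites[p] == site]
        site_pres = pres.loc[plot_ids]
        pool = [s for s in community.species if site_pres[s].any()]
        results.extend(
            _pool_nri(
                community, dist, plot_ids, pool, "site",
                n_randomizations, weighted, rng, alpha,
            )
        )
    results.sort(key=lambda r: order[r.plot_id])
    return results


def results_to_frame(results: list[NRIResult]) -> pd.DataFrame:
    """Tabulate NRI results, one row per plot."""
    return pd.DataFrame([asdict(r) for r in results])
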