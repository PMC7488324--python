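"""Co-occurring driver pairs against a margin-preserving rewiring null.

The null model preserves both per-sample and per-gene alteration counts by
repeated checkerboard swaps (pick one-entries (s1,g1) and (s2,g2) with
(s1,g2) = (s2,g1) = 0 and exchange them).  Observed pair co-alteration rates
are compared to the permuted ones with the beta-inequality probability; a
pair "tends to co-occur" when, on average over permutations, the observed
rate beats the permuted rate with probability > 0.95.  Responder- and
non-responder-specific pair sets additionally require a differential
co-occurrence probability above 0.95 that also exceeds the 95th percentile
of its own permutation-null distribution.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .cohort_io import AlterationMatrix, TreatmentArm
from .diff_drivers import DiffThresholds, RateEvidence, beta_inequality_prob

logger = logging.getLogger(__name__)

__all__ = [
    "RewiringNull",
    "PairResult",
    "rewire_matrix",
    "build_null",
    "pair_cooccurrence_rate",
    "pair_tendency",
    "select_pairs",
    "pairs_to_frame",
]


@njit(cache=True)
def _rewire_core(status, rows, cols, n_swaps, max_attempts, seed):  # pragma: no cover
    np.random.seed(seed)
    n_ones = rows.shape[0]
    swaps = 0
    attempts = 0
    while swaps < n_swaps and attempts < max_attempts:
        attempts += 1
        i = np.random.randint(n_ones)
        j = np.random.randint(n_ones)
        r1, c1 = rows[i], cols[i]
        r2, c2 = rows[j], cols[j]
        if r1 == r2 or c1 == c2:
            continue
        if status[r1, c2] == 1 or status[r2, c1] == 1:
            continue
        status[r1, c1] = 0
        status[r2, c2] = 0
        status[r1, c2] = 1
        status[r2, c1] = 1
        cols[i] = c2
        cols[j] = c1
        swaps += 1
    return swaps


def rewire_matrix(
    matrix: AlterationMatrix,
    n_successful_swaps: int | None = None,
    seed: int = 0,
    swap_multiplier: int = 10,
) -> AlterationMatrix:
    """Degree-preserving randomization of a binary matrix by checkerboard swaps.

    Performs ``n_successful_swaps`` successful swaps (default: swap_multiplier
    x number of ones, a standard mixing budget for bipartite rewiring); row
    and column sums are preserved exactly.  Degenerate matrices with no valid
    swap are returned unchanged with a warning.
    """
    status = matrix.status.copy()
    rows, cols = np.nonzero(status)
    n_ones = len(rows)
    if matrix.n_samples < 2 or matrix.n_genes < 2 or n_ones < 2:
        warnings.warn("matrix too degenerate to rewire; returned unchanged")
        return AlterationMatrix(list(matrix.sample_ids), list(matrix.gene_ids), status)
    if n_successful_swaps is None:
        n_successful_swaps = swap_multiplier * n_ones
    max_attempts = max(200 * n_successful_swaps, 10_000)
    done = _rewire_core(
        status,
        rows.astype(np.int64),
        cols.astype(np.int64),
        n_successful_swaps,
        max_attempts,
        seed % (2**32),
    )
    if done < n_successful_swaps:
        warnings.warn(
            f"only {done}/{n_successful_swaps} swaps succeeded; matrix may be near-degenerate"
        )
    return AlterationMatrix(list(matrix.sample_ids), list(matrix.gene_ids), status)


@dataclass
class RewiringNull:
    """A set of margin-preserving permutations of one alteration matrix."""

    matrices: list[AlterationMatrix]
    seed: int
    n_swaps: int

    @property
    def n_permutations(self) -> int:
        return len(self.matrices)


def build_null(
    matrix: AlterationMatrix,
    n_permutations: int = 1000,
    seed: int = 0,
    swap_multiplier: int = 10,
) -> RewiringNull:
    """Generate ``n_permutations`` independent rewirings of ``matrix``.

    Each permutation starts from the observed matrix and applies its own
    budget of successful swaps with a distinct sub-seed.
    """
    n_ones = int(matrix.status.sum())
    n_swaps = swap_multiplier * n_ones
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_permutations)]
    perms = [
        rewire_matrix(matrix, n_swaps, seed=s, swap_multiplier=swap_multiplier)
        for s in child_seeds
    ]
    return RewiringNull(perms, seed, n_swaps)


def pair_cooccurrence_rate(
    matrix: AlterationMatrix, gene_a: str, gene_b: str, sample_subset: list[str] | None = None
) -> tuple[int, float]:
    """Count and rate of samples (in the subset) altered in both genes."""
    ia, ib = matrix.gene_index([gene_a, gene_b])
    if sample_subset is None:
        rows = matrix.status
    else:
        if len(sample_subset) == 0:
            raise ValueError("empty sample subset")
        rows = matrix.status[matrix.sample_index(sample_subset)]
    both = (rows[:, ia] & rows[:, ib]).sum()
    return int(both), float(both / rows.shape[0])


def pair_tendency(
    obs: RateEvidence,
    perm_counts: np.ndarray,
    n_subset: int,
    prior_a: float = 1.0,
    prior_b: float = 1.0,
) -> float:
    """Mean over permutations of P(observed co-rate > permuted co-rate).

    ``perm_counts`` holds the pair's co-alteration count in each permuted
    matrix, over the same sample subset of size ``n_subset``.
    """
    uniq, freq = np.unique(np.asarray(perm_counts, dtype=int), return_counts=True)
    total = freq.sum()
    acc = 0.0
    for k_perm, f in zip(uniq, freq):
        p = beta_inequality_prob(obs, RateEvidence(int(k_perm), n_subset, prior_a, prior_b))
        acc += p * f
    return acc / total


@dataclass
class PairResult:
    gene_a: str
    gene_b: str
    count_all: int
    count_resp: int
    count_nonresp: int
    n_all: int
    n_resp: int
    n_nonresp: int
    tendency_all: float
    tendency_resp: float
    tendency_nonresp: float
    p_diff_cooccurrence: float  # P(co-rate_resp > co-rate_nonresp)
    null_percentile_95: float  # 95th pct of that probability under permutation
    null_percentile_05: float  # 5th pct (selection bound for the NonResp side)
    memberships: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.gene_a >= self.gene_b:
            raise ValueError("pairs must be stored with gene_a < gene_b")

    @property
    def rate_all(self) -> float:
        return self.count_all / self.n_all

    @property
    def rate_resp(self) -> float:
        return self.count_resp / self.n_resp if self.n_resp else 0.0

    @property
    def rate_nonresp(self) -> float:
        return self.count_nonresp / self.n_nonresp if self.n_nonresp else 0.0


def _pair_counts(status: np.ndarray, pair_idx: np.ndarray) -> np.ndarray:
    """Co-alteration counts for the listed gene-column pairs."""
    co = status.T.astype(np.int32) @ status.astype(np.int32)
    return co[pair_idx[:, 0], pair_idx[:, 1]]


class _ProbCache:
    """Memoized P(p1 > p2) for integer count evidence at fixed group sizes."""

    def __init__(self, n1: int, n2: int, prior_a: float, prior_b: float) -> None:
        self.n1, self.n2 = n1, n2
        self.pa, self.pb = prior_a, prior_b
        self._cache: dict[tuple[int, int], float] = {}

    def __call__(self, k1: int, k2: int) -> float:
        key = (k1, k2)
        v = self._cache.get(key)
        if v is None:
            v = beta_inequality_prob(
                RateEvidence(k1, self.n1, self.pa, self.pb),
                RateEvidence(k2, self.n2, self.pa, self.pb),
            )
            self._cache[key] = v
        return v


def _mean_prob_table(obs_counts, perm_count_mat, n_subset, prior_a, prior_b):
    """Pair tendencies: mean over permutations of P(obs rate > permuted rate).

    perm_count_mat: (n_perms, n_pairs) permuted co-counts per pair.
    """
    cache = _ProbCache(n_subset, n_subset, prior_a, prior_b)
    n_perms, n_pairs = perm_count_mat.shape
    out = np.empty(n_pairs)
    for j in range(n_pairs):
        uniq, freq = np.unique(perm_count_mat[:, j], return_counts=True)
        k_obs = int(obs_counts[j])
        out[j] = sum(cache(k_obs, int(k)) * f for k, f in zip(uniq, freq)) / n_perms
    return out


def select_pairs(
    matrix: AlterationMatrix,
    arm: TreatmentArm,
    null: RewiringNull,
    thresholds: DiffThresholds = DiffThresholds(),
    prior_a: float = 1.0,
    prior_b: float = 1.0,
) -> list[PairResult]:
    """Assign General/Resp/NonResp co-occurring-pair memberships.

    Candidate pairs are all unordered gene pairs with both genes altered at
    least ``min_count`` times in the arm (pairs failing the count filter can
    never be selected).  The same full-matrix permutations provide the null
    for every subset: responder and non-responder views are obtained by
    splitting each permuted matrix by the true labels.
    """
    arm.validate_against(matrix)
    resp_idx = matrix.sample_index(arm.responders)
    non_idx = matrix.sample_index(arm.non_responders)
    all_idx = np.concatenate([resp_idx, non_idx])
    n_resp, n_non = len(resp_idx), len(non_idx)
    n_all = len(all_idx)

    counts = matrix.status[all_idx].sum(axis=0)
    cand_genes = np.flatnonzero(counts >= thresholds.min_count)
    if len(cand_genes) < 2:
        return []
    ia, ib = np.triu_indices(len(cand_genes), k=1)
    pair_idx = np.column_stack([cand_genes[ia], cand_genes[ib]])

    obs_all = _pair_counts(matrix.status[all_idx], pair_idx)
    obs_resp = _pair_counts(matrix.status[resp_idx], pair_idx)
    obs_non = _pair_counts(matrix.status[non_idx], pair_idx)

    n_perms = null.n_permutations
    perm_all = np.empty((n_perms, len(pair_idx)), dtype=np.int32)
    perm_resp = np.empty_like(perm_all)
    perm_non = np.empty_like(perm_all)
    for k, pm in enumerate(null.matrices):
        perm_all[k] = _pair_counts(pm.status[all_idx], pair_idx)
        perm_resp[k] = _pair_counts(pm.status[resp_idx], pair_idx)
        perm_non[k] = _pair_counts(pm.status[non_idx], pair_idx)

    tend_all = _mean_prob_table(obs_all, perm_all, n_all, prior_a, prior_b)
    tend_resp = _mean_prob_table(obs_resp, perm_resp, n_resp, prior_a, prior_b)
    tend_non = _mean_prob_table(obs_non, perm_non, n_non, prior_a, prior_b)

    # differential co-occurrence probability, observed and under the null
    diff_cache = _ProbCache(n_resp, n_non, prior_a, prior_b)
    results = []
    for j, (ga_i, gb_i) in enumerate(pair_idx):
        p_diff = diff_cache(int(obs_resp[j]), int(obs_non[j]))
        codes = perm_resp[:, j].astype(np.int64) * 1_000_000 + perm_non[:, j]
        uniq, inv = np.unique(codes, return_inverse=True)
        probs_u = np.array([diff_cache(int(c // 1_000_000), int(c % 1_000_000)) for c in uniq])
        null_p = probs_u[inv]
        q95 = float(np.quantile(null_p, 0.95))
        q05 = float(np.quantile(null_p, 0.05))
        ga, gb = matrix.gene_ids[ga_i], matrix.gene_ids[gb_i]
        if ga > gb:
            ga, gb = gb, ga
        res = PairResult(
            ga,
            gb,
            int(obs_all[j]),
            int(obs_resp[j]),
            int(obs_non[j]),
            n_all,
            n_resp,
            n_non,
            float(tend_all[j]),
            float(tend_resp[j]),
            float(tend_non[j]),
            float(p_diff),
            q95,
            q05,
        )
        t = thresholds
        if (
            tend_all[j] > t.min_prob
            and obs_all[j] >= t.min_count
            and res.rate_all >= t.min_rate
        ):
            res.memberships.add("General_Ps")
        if (
            tend_resp[j] > t.min_prob
            and p_diff > t.min_prob
            and p_diff > q95
            and obs_resp[j] >= t.min_count
            and res.rate_resp >= t.min_rate
        ):
            res.memberships.add("Resp_Ps")
        if (
            tend_non[j] > t.min_prob
            and (1.0 - p_diff) > t.min_prob
            and (1.0 - p_diff) > (1.0 - q05)
            and obs_non[j] >= t.min_count
            and res.rate_nonresp >= t.min_rate
        ):
            res.memberships.add("NonResp_Ps")
        if res.memberships:
            results.append(res)
    return results


def pairs_to_frame(results: list[PairResult]):
    import pandas as pd

    return pd.DataFrame(
        {
            "gene_a": [r.gene_a for r in results],
            "gene_b": [r.gene_b for r in results],
            "count_all": [r.count_all for r in results],
            "count_resp": [r.count_resp for r in results],
            "count_nonresp": [r.count_nonresp for r in results],
            "rate_all": [r.rate_all for r in results],
            "rate_resp": [r.rate_resp for r in results],
            "rate_nonresp": [r.rate_nonresp for r in results],
            "tendency_all": [r.tendency_all for r in results],
            "tendency_resp": [r.tendency_resp for r in results],
            "tendency_nonresp": [r.tendency_nonresp for r in results],
            "p_diff_cooccurrence": [r.p_diff_cooccurrence for r in results],
            "null_percentile_95": [r.null_percentile_95 for r in results],
            "memberships": [",".join(sorted(r.memberships)) for r in results],
        }
    )
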