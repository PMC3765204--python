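"""Voxel-wise exact inference comparing two cohorts' resection probabilities.

At every voxel where both cohorts are informative (the *testable* domain) the
resection results form a 2x2 table

    a = resected, cohort A      b = residual, cohort A     (a + b = T_A)
    c = resected, cohort B      d = residual, cohort B     (c + d = T_B)

which is tested with the two-sided Fisher exact test (sum of hypergeometric
point masses not exceeding the observed one) and summarized by the
conditional maximum-likelihood odds ratio (the root of
E[a | margins, psi] = a under Fisher's noncentral hypergeometric law).

Spatial dependence is handled nonparametrically: patients are relabeled to
the two cohorts (cohort sizes preserved, distinct assignments drawn without
replacement, identity excluded), the per-voxel Fisher p is recomputed under
each relabeling, and the adjusted p-value is the add-one rank of the observed
p in this per-voxel empirical null.  Multiple testing is controlled by an
empirical false discovery rate: the expected number of discoveries under the
relabeling null, divided by the observed number of discoveries, minimized
over thresholds to give a monotone q-value per voxel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln
from scipy.stats import hypergeom, rankdata

from .mapping import CohortMaps, build_cohort_maps
from .volumes_io import PatientCase, ValidationError, VoxelGrid

__all__ = [
    "FdrConfig",
    "fisher_two_sided",
    "conditional_mle_or",
    "log_odds_ratio",
    "two_sided_p_grid",
    "FisherLookup",
    "CohortComparison",
    "compare_maps",
    "PermutationNull",
    "permutation_null",
    "adjusted_p",
    "q_values",
    "VoxelComparison",
    "compare_cohorts",
]

#: Relative tolerance when comparing hypergeometric point masses for the
#: two-sided "as or more extreme" rule; absorbs floating-point noise in ties.
TIE_RTOL = 1e-7

_GRID_CACHE: dict[tuple[int, int], np.ndarray] = {}


@dataclass(frozen=True)
class FdrConfig:
    """False-discovery configuration; the default declaration threshold is a
    deliberately liberal 0.2."""

    fdr_threshold: float = 0.2

    def __post_init__(self) -> None:
        if not 0.0 < self.fdr_threshold < 1.0:
            raise ValidationError(f"fdr_threshold must be in (0, 1), got {self.fdr_threshold}")


def _unpack_table(table) -> tuple[int, int, int, int]:
    arr = np.asarray(table)
    if arr.shape == (2, 2):
        arr = arr.ravel()
    if arr.shape != (4,):
        raise ValidationError(f"expected a 2x2 table or 4 entries, got shape {arr.shape}")
    if np.any(arr < 0) or not np.all(arr == np.floor(arr)):
        raise ValidationError(f"table entries must be non-negative integers, got {arr}")
    a, b, c, d = (int(x) for x in arr)
    return a, b, c, d


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p-value of a single 2x2 table.

    Direct (uncached) enumeration of the hypergeometric support; the memoized
    vectorized path in :class:`FisherLookup` must agree with this bit for bit.
    Degenerate tables: all-zero -> NaN; one empty row or column -> 1.0 (only
    one table is attainable given the margins).
    """
    a, b, c, d = _unpack_table(table)
    m_a, m_b, k = a + b, c + d, a + c
    if m_a + m_b == 0:
        return float("nan")
    lo, hi = max(0, k - m_b), min(m_a, k)
    if lo == hi:
        return 1.0  # single attainable table given the margins
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, m_a + m_b, m_a, k)
    observed = pmf[a - lo]
    p = pmf[pmf <= observed * (1.0 + TIE_RTOL)].sum()
    return float(min(p, 1.0))


def _cond_expectation(log_psi: float, support: np.ndarray, log_w0: np.ndarray) -> float:
    log_w = log_w0 + support * log_psi
    log_w -= log_w.max()
    w = np.exp(log_w)
    return float((support * w).sum() / w.sum())


def conditional_mle_or(table) -> float:
    """Conditional maximum-likelihood estimate of the odds ratio.

    Solves E[a | margins, psi] = a under the noncentral hypergeometric law;
    returns +inf (resp. 0) when the observed cell sits at the upper (resp.
    lower) end of the attainable support, and NaN when the margins are
    degenerate (single-point support).
    """
    a, b, c, d = _unpack_table(table)
    m_a, m_b, k = a + b, c + d, a + c
    lo, hi = max(0, k - m_b), min(m_a, k)
    if m_a + m_b == 0 or lo == hi:
        return float("nan")
    if a == hi:
        return float("inf")
    if a == lo:
        return 0.0
    support = np.arange(lo, hi + 1)
    log_w0 = (
        gammaln(m_a + 1)
        - gammaln(support + 1)
        - gammaln(m_a - support + 1)
        + gammaln(m_b + 1)
        - gammaln(k - support + 1)
        - gammaln(m_b - k + support + 1)
    )
    f = lambda lp: _cond_expectation(lp, support, log_w0) - a
    left, right = -1.0, 1.0
    while f(left) > 0:
        left *= 2.0
        if left < -500:  # pragma: no cover - unreachable for non-boundary a
            return 0.0
    while f(right) < 0:
        right *= 2.0
        if right > 500:  # pragma: no cover
            return float("inf")
    return float(math.exp(brentq(f, left, right, xtol=1e-12, rtol=1e-14)))


def log_odds_ratio(table) -> float:
    """Natural log of the conditional-MLE odds ratio (+-inf at boundaries)."""
    psi = conditional_mle_or(table)
    if np.isnan(psi):
        return float("nan")
    with np.errstate(divide="ignore"):
        return float(np.log(psi))


def two_sided_p_grid(m_a: int, m_b: int) -> np.ndarray:
    """Two-sided Fisher p for *all* tables with row margins (m_a, m_b).

    Returns P with P[a, c] the p-value of the table (a, m_a - a, c, m_b - c);
    results are cached per margin pair, which is what makes the voxel-wise and
    permutation engines cheap (tables recur massively across voxels).
    """
    key = (int(m_a), int(m_b))
    cached = _GRID_CACHE.get(key)
    if cached is not None:
        return cached
    m_a, m_b = key
    P = np.full((m_a + 1, m_b + 1), np.nan)
    if m_a + m_b > 0:
        n = m_a + m_b
        for k in range(n + 1):
            lo, hi = max(0, k - m_b), min(m_a, k)
            if lo == hi:
                P[lo, k - lo] = 1.0  # single attainable table
                continue
            support = np.arange(lo, hi + 1)
            pmf = hypergeom.pmf(support, n, m_a, k)
            tie = pmf[None, :] <= pmf[:, None] * (1.0 + TIE_RTOL)
            p = np.where(tie, pmf[None, :], 0.0).sum(axis=1)
            P[support, k - support] = np.minimum(p, 1.0)
    _GRID_CACHE[key] = P
    return P


class FisherLookup:
    """Lazily-filled dense lookup of two-sided Fisher p-values.

    ``p[mA, a, mB, c]`` for all tables with row margins up to (max_a, max_b);
    margin-pair slices are computed on first use via :func:`two_sided_p_grid`.
    """

    def __init__(self, max_a: int, max_b: int):
        self.max_a, self.max_b = int(max_a), int(max_b)
        self._lut = np.full(
            (self.max_a + 1, self.max_a + 1, self.max_b + 1, self.max_b + 1), np.nan
        )
        self._filled = np.zeros((self.max_a + 1, self.max_b + 1), dtype=bool)

    def _ensure(self, m_a: int, m_b: int) -> None:
        if not self._filled[m_a, m_b]:
            self._lut[m_a, : m_a + 1, m_b, : m_b + 1] = two_sided_p_grid(m_a, m_b)
            self._filled[m_a, m_b] = True

    def p_many(
        self, t_a: np.ndarray, a: np.ndarray, t_b: np.ndarray, c: np.ndarray
    ) -> np.ndarray:
        """Vectorized p-values for tables (a, t_a - a, c, t_b - c)."""
        t_a = np.asarray(t_a, dtype=np.intp)
        t_b = np.asarray(t_b, dtype=np.intp)
        codes = np.unique(t_a * (self.max_b + 1) + t_b)
        for code in codes:
            self._ensure(int(code) // (self.max_b + 1), int(code) % (self.max_b + 1))
        return self._lut[t_a, np.asarray(a, np.intp), t_b, np.asarray(c, np.intp)]


def _check_comparable(maps_a: CohortMaps, maps_b: CohortMaps) -> None:
    if maps_a.hemisphere != maps_b.hemisphere:
        raise ValidationError(
            f"hemisphere mismatch: {maps_a.hemisphere!r} vs {maps_b.hemisphere!r}"
        )
    if not maps_a.grid.matches(maps_b.grid.shape, maps_b.grid.affine):
        raise ValidationError("cohort maps are on different grids")


@dataclass
class CohortComparison:
    """Per-voxel 2x2 tables, raw Fisher p and log conditional-MLE odds ratio.

    ``comparison_mask`` is the union of the two cohorts' informative voxels;
    ``testable_mask`` their intersection.  Maps are NaN off the testable
    domain (a 2x2 test with an empty cohort margin is undefined).
    """

    maps_a: CohortMaps
    maps_b: CohortMaps
    testable_mask: np.ndarray
    comparison_mask: np.ndarray
    p_raw: np.ndarray
    log_or: np.ndarray
    lookup: FisherLookup

    @property
    def grid(self) -> VoxelGrid:
        return self.maps_a.grid

    @property
    def hemisphere(self) -> str:
        return self.maps_a.hemisphere

    def tables(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Flat (a, b, c, d) arrays over the testable domain."""
        m = self.testable_mask
        ta, ra = self.maps_a.tumor_count[m], self.maps_a.residual_count[m]
        tb, rb = self.maps_b.tumor_count[m], self.maps_b.residual_count[m]
        return ta - ra, ra, tb - rb, rb


def compare_maps(maps_a: CohortMaps, maps_b: CohortMaps) -> CohortComparison:
    """Assemble per-voxel tables on the testable domain and compute the raw
    two-sided Fisher p and the log conditional-MLE odds ratio.

    Both statistics are memoized on the table entries, so each distinct table
    is computed once no matter how many voxels share it.
    """
    _check_comparable(maps_a, maps_b)
    testable = maps_a.informative_mask & maps_b.informative_mask
    comparison = maps_a.informative_mask | maps_b.informative_mask

    lookup = FisherLookup(maps_a.n_cases, maps_b.n_cases)
    a, b, c, d = _tables_on(maps_a, maps_b, testable)
    p_flat = lookup.p_many(a + b, a, c + d, c)

    # memoized conditional-MLE log-OR over distinct tables
    codes = (
        ((a * (maps_a.n_cases + 1) + b) * (maps_b.n_cases + 1) + c)
        * (maps_b.n_cases + 1)
        + d
    )
    uniq, inverse = np.unique(codes, return_inverse=True)
    n_b1 = maps_b.n_cases + 1
    lor_uniq = np.empty(len(uniq))
    for i, code in enumerate(uniq):
        code = int(code)
        dd = code % n_b1
        code //= n_b1
        cc = code % n_b1
        code //= n_b1
        bb = code % (maps_a.n_cases + 1)
        aa = code // (maps_a.n_cases + 1)
        lor_uniq[i] = log_odds_ratio((aa, bb, cc, dd))
    lor_flat = lor_uniq[inverse]

    shape = maps_a.grid.shape
    p_map = np.full(shape, np.nan)
    p_map[testable] = p_flat
    lor_map = np.full(shape, np.nan)
    lor_map[testable] = lor_flat
    return CohortComparison(
        maps_a=maps_a,
        maps_b=maps_b,
        testable_mask=testable,
        comparison_mask=comparison,
        p_raw=p_map,
        log_or=lor_map,
        lookup=lookup,
    )


def _tables_on(maps_a: CohortMaps, maps_b: CohortMaps, mask: np.ndarray):
    ta, ra = maps_a.tumor_count[mask], maps_a.residual_count[mask]
    tb, rb = maps_b.tumor_count[mask], maps_b.residual_count[mask]
    return ta - ra, ra, tb - rb, rb


@dataclass
class PermutationNull:
    """Per-voxel empirical null of Fisher p-values under cohort relabeling.

    ``null_p`` has shape (m, V) over the flattened testable domain;
    ``assignments`` records, per relabeling, the sorted indices (into the
    id-sorted pooled case list) assigned to cohort A.
    """

    m: int
    seed: int
    null_p: np.ndarray
    testable_mask: np.ndarray
    assignments: np.ndarray
    case_ids: tuple[str, ...]
    n_a: int

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)


def permutation_null(
    cases_a: Sequence[PatientCase],
    cases_b: Sequence[PatientCase],
    m: int = 2000,
    seed: int = 0,
    testable_mask: np.ndarray | None = None,
    lookup: FisherLookup | None = None,
) -> PermutationNull:
    """Empirical per-voxel null via relabeling patients to the two cohorts.

    ``m`` distinct non-identity assignments preserving the cohort sizes are
    drawn without replacement (rejection sampling against the set of seen
    assignments) from a seeded generator.  The pooled case list is sorted by
    patient id first, so the draw — hence the null — is invariant to the
    order in which cases are supplied within each cohort.
    """
    if m < 1:
        raise ValidationError(f"m must be >= 1, got {m}")
    n_a, n_b = len(cases_a), len(cases_b)
    if n_a == 0 or n_b == 0:
        raise ValidationError("both cohorts must be non-empty")
    pooled = sorted(list(cases_a) + list(cases_b), key=lambda case: case.id)
    ids = tuple(case.id for case in pooled)
    if len(set(ids)) != len(ids):
        raise ValidationError("case ids must be unique across the pooled cohorts")
    grid = pooled[0].grid
    sides = {case.side for case in pooled}
    if len(sides) != 1:
        raise ValidationError(f"pooled cases span several hemispheres: {sorted(sides)}")
    for case in pooled:
        grid.check_compatible(case.tumor.shape, case.grid.affine, context=f"case {case.id}")

    n = n_a + n_b
    bound = math.comb(n, n_a) - 1
    if m > bound:
        raise ValidationError(
            f"m={m} exceeds the number of distinct non-identity assignments "
            f"C({n},{n_a})-1 = {bound}"
        )

    if testable_mask is None:
        maps_a = build_cohort_maps(list(cases_a), hemisphere=pooled[0].side)
        maps_b = build_cohort_maps(list(cases_b), hemisphere=pooled[0].side)
        testable_mask = maps_a.informative_mask & maps_b.informative_mask
    if lookup is None:
        lookup = FisherLookup(n_a, n_b)

    flat = testable_mask.ravel()
    tum = np.stack([case.tumor.ravel()[flat] for case in pooled]).astype(np.float32)
    res = np.stack([case.residual.ravel()[flat] for case in pooled]).astype(np.float32)

    a_ids = {case.id for case in cases_a}
    identity = np.flatnonzero([cid in a_ids for cid in ids]).astype(np.intp)

    rng = np.random.default_rng(seed)
    seen = {identity.tobytes()}
    assignments = np.empty((m, n_a), dtype=np.intp)
    j = 0
    while j < m:
        sel = np.sort(rng.choice(n, size=n_a, replace=False)).astype(np.intp)
        key = sel.tobytes()
        if key in seen:
            continue
        seen.add(key)
        assignments[j] = sel
        j += 1

    n_vox = int(flat.sum())
    null_p = np.empty((m, n_vox))
    memb = np.zeros(n, dtype=np.float32)
    for j in range(m):
        memb[:] = 0.0
        memb[assignments[j]] = 1.0
        t_a = (memb @ tum).astype(np.intp)
        r_a = (memb @ res).astype(np.intp)
        t_b = ((1.0 - memb) @ tum).astype(np.intp)
        r_b = ((1.0 - memb) @ res).astype(np.intp)
        null_p[j] = lookup.p_many(t_a, t_a - r_a, t_b, t_b - r_b)
    return PermutationNull(
        m=m,
        seed=seed,
        null_p=null_p,
        testable_mask=testable_mask,
        assignments=assignments,
        case_ids=ids,
        n_a=n_a,
    )


def adjusted_p(p_raw: np.ndarray, null: PermutationNull) -> np.ndarray:
    """Add-one permutation rank of the observed p in the per-voxel null:

        p_adj(v) = (1 + #{j : null_p_j(v) <= p_raw(v)}) / (m + 1)

    which lies in [1/(m+1), 1] and is strictly positive by construction.
    Returns a map NaN off the testable domain.
    """
    pr = p_raw[null.testable_mask] if p_raw.shape == null.testable_mask.shape else np.asarray(p_raw)
    counts = (null.null_p <= pr[None, :]).sum(axis=0)
    padj = (1.0 + counts) / (null.m + 1.0)
    out = np.full(null.testable_mask.shape, np.nan)
    out[null.testable_mask] = padj
    return out


def _null_rank_cumulative(null: PermutationNull) -> np.ndarray:
    """cum[r] = #{(j, v) : rank of null_p_j(v) within its voxel's null <= r},
    ranks counted with ties ('max' method), r = 0..m."""
    ranks = rankdata(null.null_p, method="max", axis=0).astype(np.int64)
    counts = np.bincount(ranks.ravel(), minlength=null.m + 1)
    return np.cumsum(counts)


def q_values(
    p_adj_map: np.ndarray,
    null: PermutationNull,
    cfg: FdrConfig = FdrConfig(),
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical-FDR q-value map and the differential mask {q < threshold}.

    For each candidate threshold t (the distinct observed adjusted p-values):
    S(t) counts observed voxels with p_adj <= t, and the expected false
    discoveries F(t) average, over the m relabelings, the number of voxels
    whose *null* adjusted p-value — the add-one rank of the j-th relabeling's
    p among the other m - 1 relabelings, i.e. the j-th dataset treated
    exactly like the observed one — is <= t.  Then
    q(v) = min over t >= p_adj(v) of F(t)/max(S(t), 1), clipped to [0, 1],
    which is monotone non-decreasing in p_adj.
    """
    mask = null.testable_mask
    padj = p_adj_map[mask] if p_adj_map.shape == mask.shape else np.asarray(p_adj_map)
    m = null.m

    order = np.sort(padj)
    t_k = np.unique(order)
    s_k = np.searchsorted(order, t_k, side="right")

    cum = _null_rank_cumulative(null)
    # leave-self-out: the j-th relabeling, ranked against the other m - 1
    # plus itself as 'observed', has null adjusted p = r/(m+1) with r its
    # self-inclusive max-tie rank; r/(m+1) <= t  <=>  r <= t*(m+1)
    r_t = np.clip(np.floor(t_k * (m + 1) + 1e-9).astype(np.int64), 0, m)
    f_k = cum[r_t] / m

    ratio = f_k / np.maximum(s_k, 1)
    ratio = np.minimum.accumulate(ratio[::-1])[::-1]  # min over t >= t_k
    q_flat = np.clip(ratio[np.searchsorted(t_k, padj)], 0.0, 1.0)

    q_map = np.full(mask.shape, np.nan)
    q_map[mask] = q_flat
    differential = np.zeros(mask.shape, dtype=bool)
    differential[mask] = q_flat < cfg.fdr_threshold
    return q_map, differential


@dataclass
class VoxelComparison:
    """Full voxel-wise comparison of two cohorts: maps plus run metadata."""

    comparison: CohortComparison
    null: PermutationNull
    p_adj: np.ndarray
    q: np.ndarray
    differential: np.ndarray
    cfg: FdrConfig
    seed: int

    @property
    def grid(self) -> VoxelGrid:
        return self.comparison.grid

    @property
    def p_raw(self) -> np.ndarray:
        return self.comparison.p_raw

    @property
    def log_or(self) -> np.ndarray:
        return self.comparison.log_or

    @property
    def log_or_thresholded(self) -> np.ndarray:
        """Log odds ratio shown only where q is below the FDR threshold."""
        out = np.full(self.grid.shape, np.nan)
        out[self.differential] = self.comparison.log_or[self.differential]
        return out

    @property
    def testable_mask(self) -> np.ndarray:
        return self.comparison.testable_mask

    def summary(self) -> dict:
        return {
            "hemisphere": self.comparison.hemisphere,
            "n_a": self.comparison.maps_a.n_cases,
            "n_b": self.comparison.maps_b.n_cases,
            "comparison_voxels": int(np.count_nonzero(self.comparison.comparison_mask)),
            "testable_voxels": int(np.count_nonzero(self.comparison.testable_mask)),
            "differential_voxels": int(np.count_nonzero(self.differential)),
            "m": self.null.m,
            "seed": self.seed,
            "fdr_threshold": self.cfg.fdr_threshold,
        }


def compare_cohorts(
    cases_a: Sequence[PatientCase],
    cases_b: Sequence[PatientCase],
    m: int = 2000,
    seed: int = 0,
    cfg: FdrConfig = FdrConfig(),
) -> VoxelComparison:
    """End-to-end voxel-wise comparison for one hemisphere.

    Composition of :func:`compare_maps`, :func:`permutation_null`,
    :func:`adjusted_p` and :func:`q_values`, sharing one memoized Fisher
    lookup across the observed and relabeled cohorts.
    """
    if not cases_a or not cases_b:
        raise ValidationError("both cohorts must be non-empty")
    side = cases_a[0].side
    maps_a = build_cohort_maps(list(cases_a), hemisphere=side)
    maps_b = build_cohort_maps(list(cases_b), hemisphere=side)
    comparison = compare_maps(maps_a, maps_b)
    null = permutation_null(
        cases_a,
        cases_b,
        m=m,
        seed=seed,
        testable_mask=comparison.testable_mask,
        lookup=comparison.lookup,
    )
    p_adj = adjusted_p(comparison.p_raw, null)
    q, differential = q_values(p_adj, null, cfg)
    return VoxelComparison(
        comparison=comparison,
        null=null,
        p_adj=p_adj,
        q=q,
        differential=differential,
        cfg=cfg,
        seed=seed,
    )
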