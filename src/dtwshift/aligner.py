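"""Balanced, end-unanchored warping of two interpolated time series.

The query series Y (N points) is aligned to the reference series X
(M >= N points) under two constraints:

* multiple mapping — one point of either series may align to several
  consecutive points of the other;
* balance — exactly N distinct reference columns are aligned, i.e. exactly
  M - N reference columns are omitted.  Omissions may occur before the
  first and after the last aligned column, so the alignment is unanchored
  at the ends.

The optimal path minimizes the sum of squared expression differences over
aligned pairs (argmin-equivalent to Euclidean distance, and additive, as a
dynamic program requires).  The DP state is (i, j, k): the first i query
points aligned against the first j reference columns with exactly k columns
omitted so far.  Two layers are maintained per state — column j aligned
("A") or column j omitted ("O") — so that a column can never be matched
after having been omitted; this pair of matrices is what makes each cell
O(1), for an overall O(M * N * (M-N)) fill.

Per query point, the time shift is the mean time of its aligned reference
points minus its own time:  shift(Y_i) = mean(time(X_j..X_j+q)) - time(Y_i).
A positive raw shift therefore means the query point maps to *older*
reference times (the query runs ahead).  On the reporting scale used for
chronological ages, reporting_shift = log2(query_age / aligned_ref_age),
whose sign is flipped relative to the raw shift so that positive values
mean the query trajectory is *delayed* (it maps to younger reference ages).
"""

from __future__ import annotations

import dataclasses
import itertools
from functools import lru_cache

import numpy as np
from numba import njit

from .trajectory import InterpSeries, RawSeries, fit_spline, interpolate_uniform

__all__ = [
    "AlignmentPath",
    "ShiftProfile",
    "align",
    "brute_force_align",
    "shifts_from_path",
    "align_and_shift",
]

_DIAG, _EXT_X, _EXT_Y = 2, 3, 4  # traceback codes for the aligned layer


@dataclasses.dataclass
class AlignmentPath:
    """A balanced monotone warping path.

    ``pairs`` are 1-based (i, j) with i indexing the query and j the
    reference; ``omitted`` are the reference columns not used by any pair.
    ``swapped`` flags that the caller's series were exchanged because the
    nominal reference was the shorter series.
    """

    pairs: tuple
    omitted: frozenset
    cost: float
    query_len: int
    ref_len: int
    swapped: bool = False

    @property
    def n_omitted(self) -> int:
        return len(self.omitted)

    def validate(self) -> None:
        """Assert the balanced-path invariants; raises AssertionError."""
        N, M = self.query_len, self.ref_len
        pairs = list(self.pairs)
        assert pairs == sorted(pairs), "pairs must be lexicographically sorted"
        iv = [p[0] for p in pairs]
        jv = [p[1] for p in pairs]
        assert set(iv) == set(range(1, N + 1)), "every query point must align"
        cols = sorted(set(jv))
        assert len(cols) == N, "exactly N distinct reference columns"
        assert len(self.omitted) == M - N, "exactly M-N omitted columns"
        assert self.omitted.isdisjoint(cols), "omitted columns cannot align"
        assert self.omitted | set(cols) == set(range(1, M + 1))
        rank = {j: r for r, j in enumerate(cols)}
        for (i0, j0), (i1, j1) in zip(pairs, pairs[1:]):
            di, dr = i1 - i0, rank[j1] - rank[j0]
            assert di in (0, 1) and dr in (0, 1) and di + dr > 0, (
                "consecutive pairs must advance query and/or column rank by 1"
            )
        assert self.cost >= 0.0


@dataclasses.dataclass
class ShiftProfile:
    """Per-query-time-point time-shift estimates for one gene."""

    gene_id: str
    query_group: str
    ref_group: str
    query_times: np.ndarray
    shifts: np.ndarray
    reporting_shifts: np.ndarray | None = None
    cost: float = np.nan
    swapped: bool = False

    def __post_init__(self) -> None:
        self.query_times = np.asarray(self.query_times, dtype=float)
        self.shifts = np.asarray(self.shifts, dtype=float)
        if self.shifts.shape != self.query_times.shape:
            raise ValueError("shifts and query_times must match in length")
        if not np.isfinite(self.shifts).all():
            raise ValueError("shifts must be finite")

    @property
    def N(self) -> int:
        return int(self.shifts.size)

    def delay_scores(self) -> np.ndarray:
        """Shifts on the positive-means-delayed scale used for direction calls."""
        if self.reporting_shifts is not None:
            return self.reporting_shifts
        return -self.shifts


@njit(cache=False)
def _bstate(A, O, PA, PO, i, j, k):
    """Combined best of the aligned/omitted layers at a state; A wins ties."""
    if j == 0:
        if i == 0 and k == 0:
            return 0.0, 0
        return np.inf, 0
    a = A[i, j, k]
    o = O[i, j, k]
    if a < o or (a == o and PA[i, j, k] <= PO[i, j, k]):
        return a, PA[i, j, k]
    return o, PO[i, j, k]


@njit(cache=False)
def _fill(xv, yv, K, allow_many_query):
    M = xv.size
    N = yv.size
    A = np.full((N + 1, M + 1, K + 1), np.inf)
    O = np.full((N + 1, M + 1, K + 1), np.inf)
    PA = np.zeros((N + 1, M + 1, K + 1), np.int64)
    PO = np.zeros((N + 1, M + 1, K + 1), np.int64)
    CA = np.zeros((N + 1, M + 1, K + 1), np.uint8)
    for i in range(N + 1):
        for j in range(1, M + 1):
            kmax = min(j, K)
            for k in range(kmax + 1):
                if k >= 1:
                    bc, bp = _bstate(A, O, PA, PO, i, j - 1, k - 1)
                    O[i, j, k] = bc
                    PO[i, j, k] = bp
                if i >= 1:
                    diff = xv[j - 1] - yv[i - 1]
                    d = diff * diff
                    bc, bp = _bstate(A, O, PA, PO, i - 1, j - 1, k)
                    best = bc + d
                    bestp = bp + 1
                    code = _DIAG
                    bc, bp = _bstate(A, O, PA, PO, i, j - 1, k)
                    cand = bc + d
                    if cand < best or (cand == best and bp + 1 < bestp):
                        best = cand
                        bestp = bp + 1
                        code = _EXT_X
                    if allow_many_query:
                        cand = A[i - 1, j, k] + d
                        pc = PA[i - 1, j, k] + 1
                        if cand < best or (cand == best and pc < bestp):
                            best = cand
                            bestp = pc
                            code = _EXT_Y
                    A[i, j, k] = best
                    PA[i, j, k] = bestp
                    CA[i, j, k] = code
    return A, O, PA, PO, CA


def _best_layer(A, O, PA, PO, i, j, k) -> str:
    a, o = A[i, j, k], O[i, j, k]
    if a < o or (a == o and PA[i, j, k] <= PO[i, j, k]):
        return "A"
    return "O"


def _traceback(A, O, PA, PO, CA, N, M, K):
    i, j, k = N, M, K
    if not np.isfinite(min(A[i, j, k], O[i, j, k])):
        raise RuntimeError("no feasible balanced alignment")
    layer = _best_layer(A, O, PA, PO, i, j, k)
    cost = A[i, j, k] if layer == "A" else O[i, j, k]
    pairs: list[tuple[int, int]] = []
    omitted: list[int] = []
    while j > 0:
        if layer == "O":
            omitted.append(j)
            j -= 1
            k -= 1
            layer = _best_layer(A, O, PA, PO, i, j, k) if j > 0 else "A"
        else:
            code = CA[i, j, k]
            pairs.append((i, j))
            if code == _DIAG:
                i -= 1
                j -= 1
            elif code == _EXT_X:
                j -= 1
            else:  # _EXT_Y
                i -= 1
                continue  # stays on the aligned layer of the same column
            layer = _best_layer(A, O, PA, PO, i, j, k) if j > 0 else "A"
    pairs.reverse()
    omitted.reverse()
    return pairs, omitted, float(cost)


def _align_arrays(xv: np.ndarray, yv: np.ndarray, multi_map: str) -> AlignmentPath:
    M, N = xv.size, yv.size
    K = M - N
    A, O, PA, PO, CA = _fill(xv, yv, K, multi_map == "both")
    pairs, omitted, cost = _traceback(A, O, PA, PO, CA, N, M, K)
    path = AlignmentPath(
        pairs=tuple(pairs),
        omitted=frozenset(omitted),
        cost=cost,
        query_len=N,
        ref_len=M,
    )
    path.validate()
    return path


def align(X: InterpSeries, Y: InterpSeries, multi_map: str = "both") -> AlignmentPath:
    """Optimal balanced alignment of query Y onto reference X.

    If X is shorter than Y the roles are swapped internally and the
    returned path carries ``swapped=True`` (its query is then X).

    ``multi_map="both"`` permits many-to-one mapping in both directions;
    ``"query-only"`` restricts each reference column to a single query
    point, which under the balance constraint reduces to a one-to-one
    matching of the selected columns.
    """
    if multi_map not in ("both", "query-only"):
        raise ValueError("multi_map must be 'both' or 'query-only'")
    xv = np.asarray(X.values, dtype=float)
    yv = np.asarray(Y.values, dtype=float)
    if not (np.isfinite(xv).all() and np.isfinite(yv).all()):
        raise ValueError("expression values must be finite")
    if min(xv.size, yv.size) < 2:
        raise ValueError("need at least 2 interpolated points per series")
    if xv.size < yv.size:
        path = _align_arrays(yv, xv, multi_map)
        return dataclasses.replace(path, swapped=True)
    return _align_arrays(xv, yv, multi_map)


@lru_cache(maxsize=32)
def _grid_paths(N: int, multi_map: str):
    """All monotone lattice paths over the N x N selected-column grid."""
    paths: list[list[tuple[int, int]]] = []

    def rec(r: int, c: int, acc: list[tuple[int, int]]) -> None:
        if r == N - 1 and c == N - 1:
            paths.append(list(acc))
            return
        if r + 1 < N and c + 1 < N:
            acc.append((r + 1, c + 1))
            rec(r + 1, c + 1, acc)
            acc.pop()
        if c + 1 < N:
            acc.append((r, c + 1))
            rec(r, c + 1, acc)
            acc.pop()
        if multi_map == "both" and r + 1 < N:
            acc.append((r + 1, c))
            rec(r + 1, c, acc)
            acc.pop()

    rec(0, 0, [(0, 0)])
    lengths = np.array([len(p) for p in paths], dtype=np.int64)
    maxlen = int(lengths.max())
    pad = N * N  # index of an appended zero-cost slot
    idx = np.full((len(paths), maxlen), pad, dtype=np.int64)
    for pi, p in enumerate(paths):
        for step, (r, c) in enumerate(p):
            idx[pi, step] = r * N + c
    return paths, idx, lengths


def brute_force_align(
    X: InterpSeries, Y: InterpSeries, multi_map: str = "both"
) -> AlignmentPath:
    """Exhaustive oracle: enumerate every balanced monotone path.

    Enumerates all reference-column subsets of size N and, for each, every
    monotone multiple-mapping path over the N x N grid; ties are broken by
    (cost, number of pairs, lexicographically smallest omitted set).
    Guarded to M <= 12, N <= 6.
    """
    xv = np.asarray(X.values, dtype=float)
    yv = np.asarray(Y.values, dtype=float)
    M, N = xv.size, yv.size
    if M > 12 or N > 6 or N < 2 or M < N:
        raise ValueError("brute_force_align requires 2 <= N <= 6 and N <= M <= 12")
    D = (yv[:, None] - xv[None, :]) ** 2  # N x M
    paths, idx, lengths = _grid_paths(N, multi_map)
    best = None
    for cols in itertools.combinations(range(M), N):
        dsub = D[:, cols]
        flat = np.append(dsub.ravel(), 0.0)
        # accumulate sequentially along the path so the addition order
        # matches the DP's prefix sums bit for bit
        costs = np.zeros(len(paths))
        for step in range(idx.shape[1]):
            costs = costs + flat[idx[:, step]]
        order = np.lexsort((lengths, costs))
        pi = int(order[0])
        omitted = tuple(sorted(set(range(1, M + 1)) - {c + 1 for c in cols}))
        key = (float(costs[pi]), int(lengths[pi]), omitted)
        if best is None or key < best[0]:
            pairs = tuple((r + 1, cols[c] + 1) for r, c in paths[pi])
            best = (key, pairs)
    (cost, _, omitted), pairs = best
    path = AlignmentPath(
        pairs=pairs,
        omitted=frozenset(omitted),
        cost=cost,
        query_len=N,
        ref_len=M,
    )
    path.validate()
    return path


def _reference_cost(xv, yv, multi_map: str = "both"):
    """Pure-Python transliteration of the DP recurrence (cost, n_pairs).

    Kept independent of the compiled kernel as a bit-exactness check.
    """
    M, N = len(xv), len(yv)
    K = M - N
    INF = np.inf
    memo: dict = {}

    def B(i, j, k):
        if j == 0:
            return (0.0, 0) if (i == 0 and k == 0) else (INF, 0)
        a = A(i, j, k)
        o = O(i, j, k)
        return a if (a[0] < o[0] or (a[0] == o[0] and a[1] <= o[1])) else o

    def O(i, j, k):
        if k < 1 or k > j:
            return (INF, 0)
        key = ("O", i, j, k)
        if key not in memo:
            memo[key] = B(i, j - 1, k - 1)
        return memo[key]

    def A(i, j, k):
        if i < 1 or j < 1 or k > j:
            return (INF, 0)
        key = ("A", i, j, k)
        if key in memo:
            return memo[key]
        d = (xv[j - 1] - yv[i - 1]) ** 2
        cands = [B(i - 1, j - 1, k), B(i, j - 1, k)]
        if multi_map == "both":
            cands.append(A(i - 1, j, k))
        best = (INF, 0)
        for c, p in cands:
            cand = (c + d, p + 1)
            if cand[0] < best[0] or (cand[0] == best[0] and cand[1] < best[1]):
                best = cand
        memo[key] = best
        return best

    return B(N, M, K)


def shifts_from_path(
    path: AlignmentPath, X: InterpSeries, Y: InterpSeries
) -> ShiftProfile:
    """Convert an alignment path into per-query-point time shifts.

    ``X`` and ``Y`` are the same series the path was computed from (X the
    nominal reference, Y the nominal query).  When the path is flagged
    ``swapped`` the profile is reported on X's grid with inverted sign.
    """
    if path.swapped:
        ref_t, query_t = np.asarray(Y.times), np.asarray(X.times)
        query_gene, query_group, ref_group = X.gene_id, X.group, Y.group
        sign = -1.0
    else:
        ref_t, query_t = np.asarray(X.times), np.asarray(Y.times)
        query_gene, query_group, ref_group = Y.gene_id, Y.group, X.group
        sign = 1.0
    N = path.query_len
    pa = np.asarray(path.pairs, dtype=int)
    sums = np.zeros(N)
    counts = np.zeros(N)
    np.add.at(sums, pa[:, 0] - 1, ref_t[pa[:, 1] - 1])
    np.add.at(counts, pa[:, 0] - 1, 1.0)
    if np.any(counts == 0):
        raise RuntimeError("internal error: unaligned query point")
    aligned_ref_time = sums / counts
    shifts = aligned_ref_time - query_t
    reporting = None
    if np.all(query_t > 0) and np.all(aligned_ref_time > 0):
        # positive = query delayed (maps to younger reference ages)
        reporting = sign * np.log2(query_t / aligned_ref_time)
    return ShiftProfile(
        gene_id=query_gene,
        query_group=query_group,
        ref_group=ref_group,
        query_times=query_t,
        shifts=sign * shifts,
        reporting_shifts=reporting,
        cost=path.cost,
        swapped=path.swapped,
    )


def align_and_shift(
    seriesA: RawSeries,
    seriesB: RawSeries,
    K_A: int,
    K_B: int,
    direction: str = "B_to_A",
    df: float | str = 4.0,
    multi_map: str = "both",
) -> ShiftProfile:
    """One-call facade: fit both splines, interpolate, align, convert to shifts.

    ``direction="B_to_A"`` aligns B (query) onto A (reference); ``"A_to_B"``
    reverses the roles.  ``K_A``/``K_B`` are the interpolation grid sizes of
    A and B respectively.
    """
    if direction not in ("B_to_A", "A_to_B"):
        raise ValueError("direction must be 'B_to_A' or 'A_to_B'")
    if direction == "B_to_A":
        ref_s, query_s, K_ref, K_query = seriesA, seriesB, K_A, K_B
    else:
        ref_s, query_s, K_ref, K_query = seriesB, seriesA, K_B, K_A
    X = interpolate_uniform(fit_spline(ref_s, df=df), K_ref)
    Y = interpolate_uniform(fit_spline(query_s, df=df), K_query)
    path = align(X, Y, multi_map=multi_map)
    return shifts_from_path(path, X, Y)
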