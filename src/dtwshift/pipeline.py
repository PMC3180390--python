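"""Application-layer screen and post-processing around the aligner.

Genes are screened before alignment — the warping model is only meaningful
when the two groups follow broadly similar trajectories — with three
criteria, each at F-test / correlation p < alpha:

1. expression changes with age (polynomial regression F-test vs intercept);
2. expression differs between groups (ANCOVA: group main effect on top of
   a shared age polynomial);
3. the two groups' fitted trajectories correlate positively (Pearson on
   percentile-matched age grids, requiring r > 0).

After shift estimation, a gene is called delayed or accelerated when at
least 70% of its time points agree in shift direction (on the
positive-means-delayed scale; zero shifts count against consistency).
Shift profiles of called genes are grouped by k-means over many random
restarts; the modal partition (up to label permutation) and the fraction
of restarts reproducing it quantify clustering stability.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections import Counter

import numpy as np
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .aligner import ShiftProfile
from .trajectory import RawSeries, fit_spline

__all__ = [
    "GeneScreenResult",
    "DirectionCall",
    "ClusterResult",
    "screen_genes",
    "classify_direction",
    "cluster_shift_profiles",
    "correlate_profiles_across_regions",
    "silhouette_by_k",
]


@dataclasses.dataclass
class GeneScreenResult:
    gene_id: str
    age_F_p: float
    species_ancova_p: float
    pearson_r: float
    pearson_p: float
    passed: bool
    error: str | None = None


@dataclasses.dataclass
class DirectionCall:
    gene_id: str
    direction: str  # "delayed" | "accelerated" | "none"
    consistency: float


@dataclasses.dataclass
class ClusterResult:
    assignments: np.ndarray      # canonical modal partition, one label per gene
    k: int
    stability: float             # fraction of restarts reproducing the mode
    cluster_means: np.ndarray    # (k, n_points)
    band_lo: np.ndarray          # 5th percentile per cluster
    band_hi: np.ndarray          # 95th percentile per cluster
    gene_ids: list | None = None


def _poly_design(age: np.ndarray, degree: int) -> np.ndarray:
    # standardized powers keep the design well conditioned
    z = (age - age.mean()) / (age.std() if age.std() > 0 else 1.0)
    return np.column_stack([z**p for p in range(1, degree + 1)])


def _ols_rss(X: np.ndarray, y: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.sum((y - X @ beta) ** 2))


def _nested_f(rss0: float, rss1: float, df_extra: int, df_resid: int):
    if df_resid <= 0 or rss1 <= 0:
        return np.inf, 0.0
    F = max((rss0 - rss1) / df_extra / (rss1 / df_resid), 0.0)
    return F, float(stats.f.sf(F, df_extra, df_resid))


def _select_degree(age: np.ndarray, y: np.ndarray, max_degree: int = 3,
                   alpha: float = 0.05) -> int:
    """Highest polynomial degree whose top term adds significant fit."""
    n = age.size
    degree = 1
    for d in range(2, max_degree + 1):
        if n - (d + 1) <= 0:
            break
        X0 = np.column_stack([np.ones(n), _poly_design(age, d - 1)])
        X1 = np.column_stack([np.ones(n), _poly_design(age, d)])
        _, p = _nested_f(_ols_rss(X0, y), _ols_rss(X1, y), 1, n - (d + 1))
        if p < alpha:
            degree = d
    return degree


def screen_genes(
    dataset: dict[str, dict[str, RawSeries]],
    alpha: float = 0.05,
    poly_degree: int | str = "auto",
    df: float | str = 4.0,
    n_interp: int = 20,
) -> list[GeneScreenResult]:
    """Per-gene three-criterion screen ahead of shift estimation.

    ``dataset`` maps gene id -> {group: RawSeries} with exactly two groups.
    Degenerate designs are recorded as per-gene failures, never raised.
    """
    out: list[GeneScreenResult] = []
    for gid, groups in dataset.items():
        if len(groups) != 2:
            raise ValueError(f"gene {gid}: need exactly two groups")
        (ga, sa), (gb, sb) = sorted(groups.items())
        try:
            out.append(
                _screen_one(gid, sa, sb, alpha, poly_degree, df, n_interp)
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            out.append(
                GeneScreenResult(gid, np.nan, np.nan, np.nan, np.nan, False, str(exc))
            )
    return out


def _screen_one(gid, sa, sb, alpha, poly_degree, df, n_interp) -> GeneScreenResult:
    age = np.concatenate([sa.ages, sb.ages])
    y = np.concatenate([sa.values, sb.values])
    group = np.concatenate([np.zeros(sa.n), np.ones(sb.n)])
    n = age.size
    degree = (
        _select_degree(age, y) if poly_degree == "auto" else int(poly_degree)
    )
    P = _poly_design(age, degree)
    ones = np.ones(n)

    # (1) age effect: polynomial vs intercept
    X0 = ones[:, None]
    X_age = np.column_stack([ones, P])
    F1, p1 = _nested_f(_ols_rss(X0, y), _ols_rss(X_age, y), degree, n - degree - 1)

    # (2) group effect on top of the shared age polynomial
    X_full = np.column_stack([ones, P, group])
    F2, p2 = _nested_f(
        _ols_rss(X_age, y), _ols_rss(X_full, y), 1, n - degree - 2
    )

    # (3) trajectory correlation on percentile-matched age grids
    ma = fit_spline(sa, df=df)
    mb = fit_spline(sb, df=df)
    probs = np.linspace(0.0, 1.0, n_interp)
    ta = np.quantile(sa.ages, probs)
    tb = np.quantile(sb.ages, probs)
    va = ma.predict(ta)
    vb = mb.predict(tb)
    if np.std(va) == 0 or np.std(vb) == 0:
        r, p3 = np.nan, 1.0
    else:
        r, p3 = stats.pearsonr(va, vb)
    passed = bool(p1 < alpha and p2 < alpha and p3 < alpha and r > 0)
    return GeneScreenResult(gid, p1, p2, float(r), float(p3), passed)


def classify_direction(
    profile: ShiftProfile | np.ndarray,
    min_consistency: float = 0.7,
) -> DirectionCall:
    """Direction of heterochrony from the majority sign of the shifts.

    Input shifts are taken on the positive-means-delayed scale (for a
    :class:`ShiftProfile` this is its ``delay_scores``).  Consistency is the
    majority-sign fraction over *all* points — zero shifts count against it.
    """
    if isinstance(profile, ShiftProfile):
        gid = profile.gene_id
        values = profile.delay_scores()
    else:
        gid = ""
        values = np.asarray(profile, dtype=float)
    if values.size < 3:
        raise ValueError("need at least 3 time points for a direction call")
    pos = int(np.sum(values > 0))
    neg = int(np.sum(values < 0))
    if pos == 0 and neg == 0:
        return DirectionCall(gid, "none", 0.0)
    consistency = max(pos, neg) / values.size
    if consistency < min_consistency or pos == neg:
        return DirectionCall(gid, "none", consistency)
    return DirectionCall(gid, "delayed" if pos > neg else "accelerated", consistency)


def _canonical(labels: np.ndarray) -> tuple:
    """Relabel clusters by first appearance: label-permutation invariant."""
    mapping: dict[int, int] = {}
    out = []
    for lab in labels:
        if lab not in mapping:
            mapping[lab] = len(mapping)
        out.append(mapping[lab])
    return tuple(out)


def cluster_shift_profiles(
    profiles: np.ndarray | list,
    k: int,
    runs: int = 1000,
    rng: np.random.Generator | int | None = None,
    gene_ids: list | None = None,
) -> ClusterResult:
    """k-means over ``runs`` random restarts; stability = modal-partition rate.

    The modal partition is found after canonicalizing labels, so two runs
    that differ only by a label permutation count as the same partition.
    """
    if isinstance(profiles, list) and profiles and isinstance(profiles[0], ShiftProfile):
        if gene_ids is None:
            gene_ids = [p.gene_id for p in profiles]
        matrix = np.vstack([p.delay_scores() for p in profiles])
    else:
        matrix = np.atleast_2d(np.asarray(profiles, dtype=float))
    n = matrix.shape[0]
    if k > n:
        raise ValueError("k cannot exceed the number of profiles")
    rng = np.random.default_rng(rng)
    counts: Counter = Counter()
    for _ in range(runs):
        seed = int(rng.integers(0, 2**31 - 1))
        km = KMeans(n_clusters=k, n_init=1, random_state=seed)
        counts[_canonical(km.fit_predict(matrix))] += 1
    modal, freq = counts.most_common(1)[0]
    labels = np.array(modal)
    means = np.vstack([matrix[labels == c].mean(axis=0) for c in range(k)])
    lo = np.vstack([np.percentile(matrix[labels == c], 5, axis=0) for c in range(k)])
    hi = np.vstack([np.percentile(matrix[labels == c], 95, axis=0) for c in range(k)])
    return ClusterResult(
        assignments=labels,
        k=k,
        stability=freq / runs,
        cluster_means=means,
        band_lo=lo,
        band_hi=hi,
        gene_ids=gene_ids,
    )


def silhouette_by_k(
    profiles: np.ndarray, k_values=range(2, 7), rng=None
) -> dict[int, float]:
    """Silhouette score per candidate k, to aid choosing the cluster count."""
    matrix = np.atleast_2d(np.asarray(profiles, dtype=float))
    rng = np.random.default_rng(rng)
    out: dict[int, float] = {}
    for k in k_values:
        if k >= matrix.shape[0]:
            break
        seed = int(rng.integers(0, 2**31 - 1))
        labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(matrix)
        out[k] = float(silhouette_score(matrix, labels))
    return out


def correlate_profiles_across_regions(
    profilesA: dict[str, np.ndarray],
    profilesB: dict[str, np.ndarray],
    r_min: float = 0.5,
    alpha: float = 0.05,
) -> tuple[list[str], dict[str, tuple[float, float]]]:
    """Genes whose shift profiles agree across two tissue datasets.

    Returns the selected gene list (Pearson p < alpha and r > r_min) and the
    per-gene (r, p) records.  Constant profiles are excluded with a warning.
    """
    selected: list[str] = []
    records: dict[str, tuple[float, float]] = {}
    for gid in sorted(set(profilesA) & set(profilesB)):
        a = np.asarray(profilesA[gid], dtype=float)
        b = np.asarray(profilesB[gid], dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"gene {gid}: profile lengths differ")
        if np.std(a) == 0 or np.std(b) == 0:
            warnings.warn(f"gene {gid}: constant profile, correlation undefined")
            continue
        r, p = stats.pearsonr(a, b)
        records[gid] = (float(r), float(p))
        if p < alpha and r > r_min:
            selected.append(gid)
    return selected, records
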