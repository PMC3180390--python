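"""Monte-Carlo significance of per-point time shifts and FPR calibration.

The null hypothesis for a gene is that the two series share one underlying
trajectory (zero time shift).  The null is emulated on a gene-by-gene basis:
a spline model (``Smodel``) is fitted to one of the observed series (by
default the reference series), a Gaussian error model (``Nerror``) is built
from its residuals — keeping both the residual mean and variance — and
zero-shift pairs are simulated by evaluating ``Smodel`` at the real
observation ages of both groups and adding independent ``Nerror`` draws.

Each simulated pair runs through the full shift-estimation machinery.  The
pointwise p-value at query point i is the plain proportion of the B
simulations whose absolute shift is at least the absolute observed shift.
The gene-level statistic is the number of points with p below alpha.

The false positive rate of the per-gene count threshold c is calibrated by
generating G extra zero-shift "pseudo-real" pairs per gene, scoring each one
against a zero-shift background in the same way, and taking

    FPR(c) = P_null(count >= c) / P_real(count >= c),

capped at 1, where P_null averages over the G replicates of every gene.
The smallest c with FPR(c) at or below a target yields the gene-level call.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .aligner import ShiftProfile, align, shifts_from_path
from .trajectory import RawSeries, SplineModel, fit_spline, interpolate_uniform

__all__ = [
    "NoiseModel",
    "SignificanceConfig",
    "SignificanceResult",
    "CountDistributions",
    "build_null_model",
    "simulate_zero_shift_pair",
    "pointwise_pvalues",
    "run_gene_significance",
    "run_dataset_significance",
    "estimate_fpr",
    "fpr_curve",
    "choose_threshold",
]


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Gaussian error model estimated from spline residuals.

    The residual mean is retained (not forced to zero); the standard
    deviation uses the sample variance of the residuals.
    """

    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be non-negative")

    @classmethod
    def from_residuals(
        cls, residuals: np.ndarray, edf: float | None = None
    ) -> "NoiseModel":
        """Estimate the error model from smoother residuals.

        With ``edf`` given, the variance uses the smoother-corrected
        denominator n - edf (a linear smoother absorbs edf degrees of
        freedom, so the plain residual variance underestimates the error
        variance by a factor of about (n - edf)/n); without it, the plain
        sample variance is used.
        """
        r = np.asarray(residuals, dtype=float)
        n = r.size
        if n < 2:
            return cls(mean=float(np.mean(r)) if n else 0.0, sd=0.0)
        mean = float(np.mean(r))
        if edf is None:
            sd = float(np.std(r, ddof=1))
        else:
            denom = max(n - float(edf), 1.0)
            sd = float(np.sqrt(np.sum((r - mean) ** 2) / denom))
        return cls(mean=mean, sd=sd)


@dataclasses.dataclass
class SignificanceConfig:
    """Tunables of the per-gene Monte-Carlo test."""

    B: int = 1000          # zero-shift background simulations per gene
    G: int = 50            # pseudo-real zero-shift replicates per gene
    alpha: float = 0.05    # pointwise p-value cutoff
    K_ref: int = 40        # reference interpolation grid size (M)
    K_query: int = 20      # query interpolation grid size (N)
    df_real: float | str = 4.0   # spline df for the observed series
    df_sim: float | str = "gcv"  # spline df for simulated series
    source: str = "ref"          # which series seeds Smodel: "ref" or "query"
    shared_background: bool = True  # reuse the B sims for the G replicates
    pvalue_correction: bool = False  # (count+1)/(B+1) instead of count/B
    multi_map: str = "both"


@dataclasses.dataclass
class SignificanceResult:
    gene_id: str
    pointwise_p: np.ndarray
    n_significant: int
    alpha: float
    B: int
    G: int
    gene_significant: bool | None = None
    threshold_c: int | None = None
    fpr_at_c: float | None = None


@dataclasses.dataclass
class CountDistributions:
    """Per-gene significant-point counts: observed vs zero-shift replicates."""

    real_counts: np.ndarray          # (n_genes,)
    null_counts: np.ndarray          # (n_genes, G)

    def __post_init__(self) -> None:
        self.real_counts = np.asarray(self.real_counts)
        self.null_counts = np.atleast_2d(np.asarray(self.null_counts))
        if self.real_counts.size == 0 or self.null_counts.size == 0:
            raise ValueError("count distributions must be non-empty")


def build_null_model(
    series: RawSeries, df: float | str = 4.0
) -> tuple[SplineModel, NoiseModel]:
    """Fit Smodel to one series and derive Nerror from its residuals.

    The error variance uses the smoother-corrected denominator n - edf so
    that the simulated noise level is an unbiased estimate of the true one
    (required for the real/null count calibration to hold).
    """
    model = fit_spline(series, df=df)
    return model, NoiseModel.from_residuals(model.residuals, edf=model.edf)


def simulate_zero_shift_pair(
    model: SplineModel,
    noise: NoiseModel,
    times_a: np.ndarray,
    times_b: np.ndarray,
    rng: np.random.Generator,
) -> tuple[RawSeries, RawSeries]:
    """Two series sharing one mean trajectory, with independent noise draws.

    Both series are evaluated from the same spline at the given observation
    ages (which must lie inside the model domain), so the true time shift
    between them is zero.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    va = model.predict(times_a) + rng.normal(noise.mean, noise.sd, times_a.size)
    vb = model.predict(times_b) + rng.normal(noise.mean, noise.sd, times_b.size)
    a = RawSeries(model.gene_id, "sim_a", times_a, va)
    b = RawSeries(model.gene_id, "sim_b", times_b, vb)
    return a, b


def pointwise_pvalues(
    real: ShiftProfile | np.ndarray,
    sims: list | np.ndarray,
    correction: bool = False,
) -> np.ndarray:
    """p_i = #{b : |shift_sim(b,i)| >= |shift_real(i)|} / B (plain proportion).

    With ``correction`` the (count+1)/(B+1) variant is used instead.
    """
    real_shifts = real.shifts if isinstance(real, ShiftProfile) else np.asarray(real)
    if isinstance(sims, np.ndarray):
        sim_matrix = sims
    else:
        sim_matrix = np.vstack([s.shifts if isinstance(s, ShiftProfile) else s for s in sims])
    if sim_matrix.shape[1] != real_shifts.size:
        raise ValueError("simulated and real profiles must share the query grid")
    B = sim_matrix.shape[0]
    if B < 1:
        raise ValueError("need at least one simulation")
    counts = np.sum(np.abs(sim_matrix) >= np.abs(real_shifts)[None, :], axis=0)
    if correction:
        return (counts + 1.0) / (B + 1.0)
    return counts / float(B)


def _shift_profile(ref: RawSeries, query: RawSeries, cfg: SignificanceConfig,
                   df: float | str) -> ShiftProfile:
    X = interpolate_uniform(fit_spline(ref, df=df), cfg.K_ref)
    Y = interpolate_uniform(fit_spline(query, df=df), cfg.K_query)
    path = align(X, Y, multi_map=cfg.multi_map)
    return shifts_from_path(path, X, Y)


def run_gene_significance(
    pair: tuple[RawSeries, RawSeries],
    cfg: SignificanceConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[SignificanceResult, np.ndarray]:
    """Full per-gene Monte-Carlo test.

    ``pair`` is (reference_series, query_series).  Returns the gene's
    result (without the dataset-level threshold fields, which are filled in
    by :func:`run_dataset_significance`) and the G null counts.
    """
    cfg = cfg or SignificanceConfig()
    rng = np.random.default_rng(rng)
    ref, query = pair

    real = _shift_profile(ref, query, cfg, cfg.df_real)
    source = ref if cfg.source == "ref" else query
    model, noise = build_null_model(source, df=cfg.df_real)

    def sim_profile() -> np.ndarray:
        a, b = simulate_zero_shift_pair(model, noise, ref.ages, query.ages, rng)
        return _shift_profile(a, b, cfg, cfg.df_sim).shifts

    sim_matrix = np.vstack([sim_profile() for _ in range(cfg.B)])
    p = pointwise_pvalues(real, sim_matrix, correction=cfg.pvalue_correction)
    n_sig = int(np.sum(p < cfg.alpha))

    null_counts = np.empty(cfg.G, dtype=np.int64)
    for g in range(cfg.G):
        pseudo = sim_profile()
        if cfg.shared_background:
            background = sim_matrix
        else:
            background = np.vstack([sim_profile() for _ in range(cfg.B)])
        pg = pointwise_pvalues(pseudo, background, correction=cfg.pvalue_correction)
        null_counts[g] = int(np.sum(pg < cfg.alpha))

    result = SignificanceResult(
        gene_id=ref.gene_id,
        pointwise_p=p,
        n_significant=n_sig,
        alpha=cfg.alpha,
        B=cfg.B,
        G=cfg.G,
    )
    return result, null_counts


def run_dataset_significance(
    genes: dict[str, tuple[RawSeries, RawSeries]],
    cfg: SignificanceConfig | None = None,
    seed: int | None = None,
    target_fpr: float | None = 0.10,
) -> tuple[list[SignificanceResult], CountDistributions, dict]:
    """Run the per-gene test over a dataset and calibrate the count threshold.

    Each gene receives an independent random substream spawned from the
    master seed, so results are reproducible and independent of iteration
    interleaving.
    """
    cfg = cfg or SignificanceConfig()
    gene_ids = list(genes)
    streams = np.random.SeedSequence(seed).spawn(len(gene_ids))
    results: list[SignificanceResult] = []
    null_rows = []
    for gid, ss in zip(gene_ids, streams):
        res, nulls = run_gene_significance(
            genes[gid], cfg, np.random.default_rng(ss)
        )
        res.gene_id = gid
        results.append(res)
        null_rows.append(nulls)
    dists = CountDistributions(
        real_counts=np.array([r.n_significant for r in results]),
        null_counts=np.vstack(null_rows),
    )
    meta: dict = {"fpr_curve": fpr_curve(dists)}
    if target_fpr is not None:
        try:
            c = choose_threshold(dists, target_fpr)
        except ValueError:
            c = None
        meta["threshold_c"] = c
        if c is not None:
            f = estimate_fpr(dists, c)
            meta["fpr_at_c"] = f
            for r in results:
                r.threshold_c = c
                r.fpr_at_c = f
                r.gene_significant = r.n_significant >= c
    return results, dists, meta


def estimate_fpr(dists: CountDistributions, c: int) -> float:
    """FPR(c) = P_null(count >= c) / P_real(count >= c), capped at 1."""
    c = int(c)
    if c < 0:
        raise ValueError("threshold must be non-negative")
    p_real = float(np.mean(dists.real_counts >= c))
    if p_real == 0.0:
        raise ValueError("no genes at threshold")
    p_null = float(np.mean(dists.null_counts >= c))
    return min(1.0, p_null / p_real)


def fpr_curve(dists: CountDistributions) -> dict[int, float]:
    """FPR(c) for every c with a non-empty real tail."""
    curve: dict[int, float] = {}
    for c in range(int(dists.real_counts.max()) + 1):
        try:
            curve[c] = estimate_fpr(dists, c)
        except ValueError:
            break
    return curve


def choose_threshold(dists: CountDistributions, target_fpr: float) -> int:
    """Smallest count threshold c with FPR(c) <= target."""
    if not (0.0 < target_fpr <= 1.0):
        raise ValueError("target_fpr must lie in (0, 1]")
    curve = fpr_curve(dists)
    for c in sorted(curve):
        if curve[c] <= target_fpr:
            return c
    raise ValueError(
        f"target FPR {target_fpr} unreachable; achievable curve: {curve}"
    )
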