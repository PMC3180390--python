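"""Benchmark generator: time-series pairs with known injected heterochrony.

A pair is built from one analytic signal f(t) sampled on a fixed grid:

    series1(t) = f(t) + eps,        series2(t) = f(t + Delta(t)) + eps'

with independent Gaussian errors of equal sd.  Shifting the *model time*
of the second series by Delta means that aligning series2 (query) to
series1 (reference) should recover shifts of +Delta on the raw scale.
Because f is analytic, evaluating it beyond the sampling grid is exact —
there is no extrapolation issue — but estimated shifts remain bounded by
the reference domain, which produces the characteristic edge biases near
the ends of the age range.

Signals:
  * ``sine`` — sin(pi * t / 25), period 50, sampled on [1, 50] by default
    (one full period, grid variance ~ 0.5, so sd = 0.3 gives ~15% error
    variance).  Sampling more than one period would make a constant shift
    non-identifiable: the balanced, end-unanchored alignment could slide
    the match by a whole period.  The singular, non-periodic literal
    variant sin(pi * 25 / t) is available behind a flag.
  * ``linear``/``quadratic`` — y = a + b t + d t^2, sampled on [1, 20].

Noise is specified either as an sd or as the fraction r of total variance
attributable to error, resolved via sd^2 = r/(1-r) * var(f on the grid).

Shift families C1-C4 (reconstructions; exact published forms unavailable):
C1 rises linearly 0 -> 4, C2 falls 4 -> 0, C3 is a centre-peaked quadratic
0 -> 4 -> 0, C4 a centre-dipped quadratic 4 -> 0 -> 4, over the grid span.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

from .aligner import align, shifts_from_path
from .trajectory import RawSeries, fit_spline, interpolate_uniform

__all__ = [
    "SignalModel",
    "ShiftFunction",
    "NoiseSpec",
    "RecoveryReport",
    "ModelComparison",
    "sine_model",
    "poly_model",
    "constant_shift",
    "linear_shift",
    "quadratic_shift",
    "shift_family",
    "resolve_sd",
    "make_pair",
    "run_recovery",
    "interior_mean",
    "compare_shift_models",
]


@dataclasses.dataclass(frozen=True)
class SignalModel:
    """An analytic expression-trajectory model y = f(t) on a sampling grid."""

    kind: str  # "sine" | "linear" | "quadratic"
    coefficients: tuple
    time_grid: np.ndarray
    literal_sine: bool = False

    def __post_init__(self) -> None:
        grid = np.asarray(self.time_grid, dtype=float)
        if np.any(np.diff(grid) <= 0):
            raise ValueError("time grid must be strictly increasing")
        object.__setattr__(self, "time_grid", grid)
        if self.kind not in ("sine", "linear", "quadratic"):
            raise ValueError(f"unknown signal kind {self.kind!r}")

    def f(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.kind == "sine":
            period = self.coefficients[0]
            if self.literal_sine:
                return np.sin(np.pi * (period / 2.0) / t)
            return np.sin(2.0 * np.pi * t / period)
        a, b, d = self.coefficients
        return a + b * t + d * t * t


def sine_model(
    n: int = 20, span: tuple[float, float] = (1.0, 50.0),
    period: float = 50.0, literal: bool = False,
) -> SignalModel:
    """sin(pi*t/25) sampled at n uniform points; period 50 by default."""
    grid = np.linspace(span[0], span[1], n)
    return SignalModel("sine", (period,), grid, literal_sine=literal)


def poly_model(
    a: float, b: float, d: float,
    n: int = 20, span: tuple[float, float] = (1.0, 20.0),
) -> SignalModel:
    """y = a + b t + d t^2 sampled at n uniform points."""
    kind = "quadratic" if d != 0 else "linear"
    if b == 0 and d == 0:
        raise ValueError("constant signal: choose b or d nonzero")
    return SignalModel(kind, (float(a), float(b), float(d)), np.linspace(span[0], span[1], n))


@dataclasses.dataclass(frozen=True)
class ShiftFunction:
    """An injected time-shift profile Delta(t): constant, linear or quadratic."""

    kind: str
    poly_coeffs: tuple  # highest degree first, np.polyval convention

    def __call__(self, t) -> np.ndarray:
        return np.polyval(self.poly_coeffs, np.asarray(t, dtype=float))


def constant_shift(delta: float) -> ShiftFunction:
    return ShiftFunction("constant", (float(delta),))


def linear_shift(start: float, end: float, span: tuple[float, float]) -> ShiftFunction:
    t0, t1 = span
    slope = (end - start) / (t1 - t0)
    return ShiftFunction("linear", (slope, start - slope * t0))


def quadratic_shift(
    start: float, mid: float, end: float, span: tuple[float, float]
) -> ShiftFunction:
    t0, t1 = span
    tm = 0.5 * (t0 + t1)
    coeffs = np.polyfit([t0, tm, t1], [start, mid, end], 2)
    return ShiftFunction("quadratic", tuple(coeffs))


def shift_family(name: str, span: tuple[float, float], amplitude: float = 4.0) -> ShiftFunction:
    """The C1-C4 variable-shift families over a grid span (reconstructions)."""
    name = name.upper()
    if name == "C1":
        return linear_shift(0.0, amplitude, span)
    if name == "C2":
        return linear_shift(amplitude, 0.0, span)
    if name == "C3":
        return quadratic_shift(0.0, amplitude, 0.0, span)
    if name == "C4":
        return quadratic_shift(amplitude, 0.0, amplitude, span)
    raise ValueError("shift family must be one of C1, C2, C3, C4")


@dataclasses.dataclass(frozen=True)
class NoiseSpec:
    """Either an absolute error sd, or the error fraction r of total variance."""

    sd: float | None = None
    r: float | None = None

    def __post_init__(self) -> None:
        if (self.sd is None) == (self.r is None):
            raise ValueError("set exactly one of sd or r")
        if self.r is not None and not (0.0 < self.r < 1.0):
            raise ValueError("r must lie in (0, 1)")
        if self.sd is not None and self.sd < 0:
            raise ValueError("sd must be non-negative")


def resolve_sd(model: SignalModel, grid: np.ndarray | None, r: float) -> float:
    """sd such that sd^2 / (sd^2 + var_grid(f)) = r (sample variance)."""
    if not (0.0 < r < 1.0):
        raise ValueError("r must lie in (0, 1)")
    grid = model.time_grid if grid is None else np.asarray(grid, dtype=float)
    var_f = float(np.var(model.f(grid), ddof=1))
    if var_f <= 0:
        raise ValueError("constant signal on grid: error fraction undefined")
    return float(np.sqrt(r / (1.0 - r) * var_f))


def _noise_sd(model: SignalModel, noise: NoiseSpec) -> float:
    if noise.sd is not None:
        return noise.sd
    return resolve_sd(model, None, noise.r)


def make_pair(
    model: SignalModel,
    shift: ShiftFunction,
    noise: NoiseSpec,
    n: int | None = None,
    rng: np.random.Generator | int | None = None,
) -> tuple[RawSeries, RawSeries]:
    """Generate (reference, query): query values are f(t + Delta(t)) + noise.

    Aligning the query to the reference should recover +Delta on the raw
    shift scale.
    """
    rng = np.random.default_rng(rng)
    grid = model.time_grid
    if n is not None and n != grid.size:
        grid = np.linspace(grid[0], grid[-1], int(n))
    if grid.size < 5:
        raise ValueError("need at least 5 time points")
    delta = shift(grid)
    span = grid[-1] - grid[0]
    if np.max(np.abs(delta)) >= span:
        raise ValueError("injected shift exceeds the time-grid span")
    sd = _noise_sd(dataclasses.replace(model, time_grid=grid), noise)
    v1 = model.f(grid) + rng.normal(0.0, sd, grid.size)
    v2 = model.f(grid + delta) + rng.normal(0.0, sd, grid.size)
    ref = RawSeries("sim", "sp1", grid, v1)
    query = RawSeries("sim", "sp2", grid, v2)
    return ref, query


@dataclasses.dataclass
class RecoveryReport:
    """Aggregated shift-recovery statistics over R simulated replicates."""

    times: np.ndarray
    true_shift: np.ndarray
    mean_estimate: np.ndarray
    bias: np.ndarray
    rmse: np.ndarray
    band_lo: np.ndarray   # empirical 5th percentile over replicates
    band_hi: np.ndarray   # empirical 95th percentile
    R: int
    estimates: np.ndarray = dataclasses.field(repr=False, default=None)


def run_recovery(
    model: SignalModel,
    shift: ShiftFunction,
    noise: NoiseSpec,
    n: int = 20,
    N: int = 20,
    M: int = 40,
    R: int = 100,
    rng: np.random.Generator | int | None = None,
    df: float | str = "gcv",
    multi_map: str = "both",
) -> RecoveryReport:
    """R independent pair generations + shift estimation, aggregated.

    Per replicate: generate a pair with known Delta, fit both trajectories,
    interpolate the reference at M and the query at N uniform points, align,
    and record the raw shift estimates on the query grid.
    """
    if R < 1:
        raise ValueError("R must be at least 1")
    rng = np.random.default_rng(rng)
    estimates = np.empty((R, N))
    times = None
    for rep in range(R):
        ref, query = make_pair(model, shift, noise, n=n, rng=rng)
        X = interpolate_uniform(fit_spline(ref, df=df), M)
        Y = interpolate_uniform(fit_spline(query, df=df), N)
        prof = shifts_from_path(align(X, Y, multi_map=multi_map), X, Y)
        estimates[rep] = prof.shifts
        times = prof.query_times
    true = shift(times)
    mean = estimates.mean(axis=0)
    return RecoveryReport(
        times=times,
        true_shift=true,
        mean_estimate=mean,
        bias=mean - true,
        rmse=np.sqrt(np.mean((estimates - true[None, :]) ** 2, axis=0)),
        band_lo=np.percentile(estimates, 5, axis=0),
        band_hi=np.percentile(estimates, 95, axis=0),
        R=R,
        estimates=estimates,
    )


def interior_mean(report: RecoveryReport, frac: float = 0.5) -> float:
    """Mean of the per-point mean estimates over the central ``frac`` of points."""
    N = report.times.size
    drop = int(round(N * (1.0 - frac) / 2.0))
    sl = slice(drop, N - drop)
    return float(np.mean(report.mean_estimate[sl]))


@dataclasses.dataclass
class ModelComparison:
    """Nested F-test of quadratic vs linear shift-vs-time trend."""

    F: float
    p: float
    preferred: str  # "linear" | "quadratic"


def compare_shift_models(
    report: RecoveryReport, alpha: float = 0.05
) -> ModelComparison:
    """Does a quadratic in t describe the mean recovered shifts better
    than a straight line?  Nested-model F-test on the per-point means;
    ties and non-significant curvature prefer the linear model (parsimony).
    """
    t = report.times
    y = report.mean_estimate
    n = t.size
    if n < 6:
        raise ValueError("need at least 6 time points for the model comparison")
    tc = (t - t.mean()) / t.std()
    X1 = np.column_stack([np.ones(n), tc])
    X2 = np.column_stack([np.ones(n), tc, tc**2])
    if np.linalg.matrix_rank(X2) < 3:
        raise ValueError("rank-deficient design (degenerate time grid)")
    rss1 = float(np.sum((y - X1 @ np.linalg.lstsq(X1, y, rcond=None)[0]) ** 2))
    rss2 = float(np.sum((y - X2 @ np.linalg.lstsq(X2, y, rcond=None)[0]) ** 2))
    df2 = n - 3
    tiny = 1e-12 * max(float(np.sum(y**2)), 1.0)  # numerically-exact fits
    if rss2 <= tiny:
        F = np.inf if rss1 > tiny else 0.0
    else:
        F = (rss1 - rss2) / (rss2 / df2)
    F = max(F, 0.0)
    p = 1.0 if F == 0.0 else float(stats.f.sf(F, 1, df2))
    return ModelComparison(F=F, p=p, preferred="quadratic" if p < alpha else "linear")
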