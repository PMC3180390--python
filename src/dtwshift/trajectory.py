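"""Smooth age-expression trajectories.

Expression measured along ontogeny is noisy and the sampled ages are rarely
uniform, so each gene's trajectory within a sample group is modelled with a
natural cubic smoothing spline: the minimizer of

    sum_i w_i (y_i - s(x_i))^2  +  lam * int s''(t)^2 dt

over all twice-differentiable functions.  The smoothing level ``lam`` is set
either to hit a target effective degrees of freedom (the trace of the linear
smoother matrix) or by generalized cross-validation (GCV).  The fitted
trajectory is then resampled at uniformly spaced time points inside the
observed age range; no extrapolation is ever performed.

The penalized system is solved through the Demmler-Reinsch decomposition of
the natural-spline curvature penalty (Green & Silverman construction), which
makes the effective-df <-> lam mapping and the GCV score cheap enough to
re-fit thousands of simulated series.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict

import numpy as np
from scipy.linalg import eigh, solve
from scipy.optimize import brentq

__all__ = [
    "RawSeries",
    "SplineModel",
    "InterpSeries",
    "AgeTransform",
    "fit_spline",
    "interpolate_uniform",
    "transform_ages",
]


@dataclasses.dataclass
class RawSeries:
    """One group's observed (age, expression) pairs for one gene.

    Ages are sorted ascending on construction; expression values are kept in
    log2 units.  At least five observations are required so that a spline
    with ~4 effective degrees of freedom remains fittable.
    """

    gene_id: str
    group: str
    ages: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if ages.ndim != 1 or values.shape != ages.shape:
            raise ValueError("ages and values must be 1-D and equally long")
        if ages.size < 5:
            raise ValueError("insufficient observations: need at least 5 points")
        if not (np.isfinite(ages).all() and np.isfinite(values).all()):
            raise ValueError("ages and values must be finite (no missing data)")
        order = np.argsort(ages, kind="stable")
        self.ages = ages[order]
        self.values = values[order]

    @property
    def n(self) -> int:
        return int(self.ages.size)


@dataclasses.dataclass
class InterpSeries:
    """A fitted trajectory resampled at K uniformly spaced time points."""

    gene_id: str
    group: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        steps = np.diff(self.times)
        if self.times.size < 2 or np.any(steps <= 0):
            raise ValueError("interpolation grid must be strictly increasing")
        span = self.times[-1] - self.times[0]
        if np.any(np.abs(steps - steps[0]) > 1e-9 * max(span, 1.0)):
            raise ValueError("interpolation grid must be uniform")

    @property
    def K(self) -> int:
        return int(self.times.size)


@dataclasses.dataclass(frozen=True)
class AgeTransform:
    """log2 age axis, optionally offset by e.g. gestation length in years."""

    offset: float = 0.0

    def __post_init__(self) -> None:
        if self.offset < 0:
            raise ValueError("offset must be non-negative")

    def __call__(self, ages):
        return transform_ages(ages, self)


def transform_ages(ages, tr: AgeTransform) -> np.ndarray:
    """Map chronological ages to log2(age + offset); strictly monotone."""
    ages = np.asarray(ages, dtype=float)
    shifted = ages + tr.offset
    if np.any(shifted <= 0):
        raise ValueError("age + offset must be strictly positive")
    return np.log2(shifted)


class _SplineBasis:
    """Demmler-Reinsch decomposition for one (knots, weights) configuration.

    With K the natural-spline curvature penalty and W = diag(w), the fit at
    the knots is g = W^{-1/2} U diag(1/(1+lam*d)) U' W^{1/2} ybar where
    U diag(d) U' = W^{-1/2} K W^{-1/2}.  Effective df = sum 1/(1+lam*d).
    """

    def __init__(self, x: np.ndarray, w: np.ndarray):
        q = x.size
        if q < 4:
            raise ValueError("insufficient distinct ages for a cubic spline fit")
        h = np.diff(x)
        if np.any(h <= 0):
            raise ValueError("knots must be strictly increasing")
        D = np.zeros((q - 2, q))
        C = np.zeros((q - 2, q - 2))
        for i in range(q - 2):
            D[i, i] = 1.0 / h[i]
            D[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
            D[i, i + 2] = 1.0 / h[i + 1]
            C[i, i] = (h[i] + h[i + 1]) / 3.0
            if i > 0:
                C[i, i - 1] = C[i - 1, i] = h[i] / 6.0
        CinvD = solve(C, D, assume_a="pos")
        K = D.T @ CinvD
        sw = np.sqrt(w)
        Kt = K / np.outer(sw, sw)
        d, U = eigh((Kt + Kt.T) / 2.0)
        d = np.clip(d, 0.0, None)
        d[:2] = 0.0  # null space: linear functions
        self.x = x
        self.w = w
        self.sw = sw
        self.d = d
        self.U = U
        self.q = q
        self.CinvD = CinvD  # maps knot values to interior second derivatives
        pos = d[d > 0]
        self._scale = 1.0 / float(np.median(pos)) if pos.size else 1.0
        # fixed logarithmic lam grid for GCV (covers df from ~2 to ~q)
        self._gcv_lams = self._scale * np.exp(np.linspace(-12.0, 14.0, 79))
        self._gcv_shrink = (
            self._gcv_lams[:, None] * d[None, :]
            / (1.0 + self._gcv_lams[:, None] * d[None, :])
        )
        self._gcv_df = np.sum(1.0 - self._gcv_shrink, axis=1)

    def edf(self, lam: float) -> float:
        return float(np.sum(1.0 / (1.0 + lam * self.d)))

    def lam_for_df(self, df: float) -> float:
        if df >= self.q - 1e-9:
            return 0.0
        lo, hi = -40.0, 40.0
        f = lambda u: self.edf(self._scale * np.exp(u)) - df
        if f(hi) > 0:  # df at or below the linear limit of 2
            return self._scale * np.exp(hi)
        return self._scale * np.exp(brentq(f, lo, hi, xtol=1e-10))

    def fit(self, ybar: np.ndarray, lam: float) -> np.ndarray:
        yt = self.U.T @ (self.sw * ybar)
        return (self.U @ (yt / (1.0 + lam * self.d))) / self.sw

    def gcv_lam(
        self, ybar: np.ndarray, n_total: int, extra_ss: float,
        gamma: float = 1.0,
    ) -> float:
        """GCV-minimizing lam over the fixed logarithmic grid.

        ``gamma`` optionally inflates the model-complexity cost, GCV =
        (RSS/n) / (1 - gamma*df/n)^2 (values above 1 discourage the
        occasional undersmoothing of plain GCV, at the price of attenuating
        genuinely sharp trajectories; the default keeps the classic
        criterion).  The admissible df range is capped at min(q-1, n-1) to
        avoid the degenerate 0/0 limit at exact interpolation.
        """
        yt = self.U.T @ (self.sw * ybar)
        rss = np.sum((self._gcv_shrink * yt[None, :]) ** 2, axis=1) + extra_ss
        denom = 1.0 - gamma * self._gcv_df / n_total
        hi_df = max(2.5, min(self.q - 1.0, n_total - 1.0))
        score = np.where(
            (denom > 0) & (self._gcv_df <= hi_df),
            (rss / n_total) / np.maximum(denom, 1e-12) ** 2,
            np.inf,
        )
        return float(self._gcv_lams[int(np.argmin(score))])

    def second_derivatives(self, g: np.ndarray) -> np.ndarray:
        """Second derivatives of the natural spline at all knots (0 at ends)."""
        gamma = np.zeros(self.q)
        gamma[1:-1] = self.CinvD @ g
        return gamma


_BASIS_CACHE: "OrderedDict[bytes, _SplineBasis]" = OrderedDict()
_BASIS_CACHE_MAX = 128


def _prep_for(x: np.ndarray):
    """Unique-age decomposition + penalty basis, cached on the age vector."""
    key = x.tobytes()
    hit = _BASIS_CACHE.get(key)
    if hit is None:
        xu, inv, counts = np.unique(x, return_inverse=True, return_counts=True)
        if xu.size < 2:
            raise ValueError("constant-age series cannot be fitted")
        if xu.size < 4:
            raise ValueError("insufficient distinct ages for a cubic spline fit")
        hit = (xu, inv, _SplineBasis(xu, counts.astype(float)))
        _BASIS_CACHE[key] = hit
        if len(_BASIS_CACHE) > _BASIS_CACHE_MAX:
            _BASIS_CACHE.popitem(last=False)
    return hit


def _natural_eval(
    knots: np.ndarray, g: np.ndarray, gamma: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Evaluate the natural cubic spline through (knots, g) with second
    derivatives gamma at the knots (standard piecewise form)."""
    idx = np.clip(np.searchsorted(knots, t, side="right") - 1, 0, knots.size - 2)
    h = knots[idx + 1] - knots[idx]
    A = (knots[idx + 1] - t) / h
    B = (t - knots[idx]) / h
    return (
        A * g[idx]
        + B * g[idx + 1]
        + ((A**3 - A) * gamma[idx] + (B**3 - B) * gamma[idx + 1]) * h**2 / 6.0
    )


@dataclasses.dataclass
class SplineModel:
    """A fitted cubic smoothing spline for one gene/group trajectory."""

    gene_id: str
    group: str
    knots: np.ndarray
    knot_values: np.ndarray
    edf: float
    lam: float
    ages: np.ndarray
    observed: np.ndarray
    residuals: np.ndarray
    domain: tuple[float, float]
    gamma: np.ndarray = dataclasses.field(repr=False, default=None)

    def predict(self, t) -> np.ndarray:
        """Evaluate the spline inside the fitted domain (no extrapolation)."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        tol = 1e-9 * max(1.0, abs(lo), abs(hi))
        if np.any(t < lo - tol) or np.any(t > hi + tol):
            raise ValueError(
                f"evaluation outside fitted domain [{lo:g}, {hi:g}]"
            )
        return _natural_eval(
            self.knots, self.knot_values, self.gamma, np.clip(t, lo, hi)
        )


def fit_spline(series: RawSeries, df: float | str = 4.0) -> SplineModel:
    """Fit a natural cubic smoothing spline to one trajectory.

    Parameters
    ----------
    series
        Observed (age, expression) pairs; duplicate ages are handled by a
        weighted fit on the unique ages.
    df
        Target effective degrees of freedom (trace of the smoother matrix),
        matched within 0.1, or ``"gcv"`` to choose the smoothing level by
        generalized cross-validation.  Numeric targets must lie between 2
        (the linear limit) and the number of distinct ages (exact
        interpolation).
    """
    x, y = series.ages, series.values
    xu, inv, basis = _prep_for(x)
    w = basis.w
    ybar = np.bincount(inv, weights=y) / w
    extra_ss = float(np.sum((y - ybar[inv]) ** 2))

    if isinstance(df, str):
        if df != "gcv":
            raise ValueError("df must be a number or 'gcv'")
        lam = basis.gcv_lam(ybar, series.n, extra_ss)
    else:
        df = float(df)
        if not (2.0 <= df <= xu.size):
            raise ValueError(
                "df must lie between 2 and the number of distinct ages"
            )
        lam = basis.lam_for_df(df)

    g = basis.fit(ybar, lam)
    fitted = g[inv]
    return SplineModel(
        gene_id=series.gene_id,
        group=series.group,
        knots=xu,
        knot_values=g,
        edf=basis.edf(lam),
        lam=lam,
        ages=x,
        observed=y,
        residuals=y - fitted,
        domain=(float(xu[0]), float(xu[-1])),
        gamma=basis.second_derivatives(g),
    )


def interpolate_uniform(model: SplineModel, K: int) -> InterpSeries:
    """Resample a fitted trajectory at K uniform points spanning its domain."""
    K = int(K)
    if K < 2:
        raise ValueError("K must be at least 2")
    times = np.linspace(model.domain[0], model.domain[1], K)
    return InterpSeries(
        gene_id=model.gene_id,
        group=model.group,
        times=times,
        values=model.predict(times),
    )
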