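"""Tumor growth-curve analytics.

Covers the measurement side of the pipeline: the conventional caliper volume
formula, spline smoothing of growth curves, a parametric model of
post-radiotherapy growth dynamics, growth rates, measurer-bias residual
analysis, and method-agreement statistics (Bland–Altman, zero-volume
cross-tabulation, Pearson/Spearman correlations).

The growth model describes a tumor treated with radiotherapy (XRT) as the sum
of a Gaussian transient (the initial growth peak around the time of XRT), a
logistic regrowth phase, and a constant::

    V(t) = a exp(-(t - b)^2 / c^2) + d / (1 + exp(-f (t - g))) + d + h

with ``a`` the volume at the time of XRT (mm^3), ``b`` the Gaussian peak time
(days), ``c`` the post-XRT shrink timescale (days), ``d`` the logistic
regrowth amplitude (mm^3), ``f`` the fractional regrowth rate (1/day), ``g``
the regrowth midpoint time (days) and ``h`` a constant offset (mm^3).  The
standalone ``+ d`` term makes the late-time plateau ``2d + h``; the
``drop_extra_d`` switch removes it so that the plateau is ``d + h`` instead.

Model fitting follows the statsmodels convention: build a
:class:`TumorGrowthModel` from data, call :meth:`~TumorGrowthModel.fit`, and
read estimates off the returned :class:`TumorGrowthResults`.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import UnivariateSpline

__all__ = [
    "GrowthParams",
    "GrowthCurve",
    "CaliperRecord",
    "CorrelationResult",
    "TumorGrowthModel",
    "TumorGrowthResults",
    "caliper_volume",
    "eval_growth_model",
    "fit_growth_model",
    "spline_mean_volume",
    "growth_rates",
    "match_pairs",
    "caliper_residual_analysis",
    "correlations",
    "bland_altman",
    "zero_volume_crosstab",
    "read_caliper_csv",
    "curves_from_records",
    "curves_from_table",
    "read_volumes_xlsx",
    "write_volumes_csv",
]


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class GrowthParams:
    """Parameters of the Gaussian + logistic growth model."""

    a: float
    b: float
    c: float
    d: float
    f: float
    g: float
    h: float

    def __post_init__(self) -> None:
        vals = [self.a, self.b, self.c, self.d, self.f, self.g, self.h]
        if not all(np.isfinite(vals)):
            raise ValueError("growth parameters must be finite")
        if self.c <= 0:
            raise ValueError("c (shrink timescale) must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c, self.d, self.f, self.g, self.h])


@dataclass
class CaliperRecord:
    mouse_id: str
    day: float
    d_long_mm: float
    d_short_mm: float
    measurer: str = ""

    def __post_init__(self) -> None:
        lo, hi = sorted((float(self.d_long_mm), float(self.d_short_mm)))
        if lo < 0:
            raise ValueError("caliper distances must be non-negative")
        self.d_long_mm, self.d_short_mm = hi, lo

    def volume_mm3(self) -> float:
        return caliper_volume(self.d_long_mm, self.d_short_mm)


@dataclass
class GrowthCurve:
    """Per-mouse time series of (day post-implantation, volume mm^3)."""

    mouse_id: str
    method: str  # "caliper" or "ct"
    days: np.ndarray
    volumes: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.days.shape != self.volumes.shape or self.days.ndim != 1:
            raise ValueError("days and volumes must be 1-D arrays of equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any(self.volumes < 0):
            raise ValueError("volumes must be non-negative")

    def __len__(self) -> int:
        return len(self.days)


@dataclass
class CorrelationResult:
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float
    n: int
    undefined: bool = False


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def caliper_volume(m1: float, m2: float) -> float:
    """Caliper volume estimate ``V = 1/2 * d_long * d_short^2`` (mm^3).

    The longer of the two measurements is taken as ``d_long``; the result is
    therefore invariant to argument order.
    """
    if m1 < 0 or m2 < 0:
        raise ValueError("caliper measurements must be non-negative")
    d_short, d_long = sorted((float(m1), float(m2)))
    return 0.5 * d_long * d_short**2


def eval_growth_model(params: GrowthParams, t, drop_extra_d: bool = False):
    """Evaluate the growth model at times ``t`` (days)."""
    t = np.asarray(t, dtype=float)
    gauss = params.a * np.exp(-((t - params.b) ** 2) / params.c**2)
    logistic = params.d * stats.logistic.cdf(params.f * (t - params.g))
    extra = 0.0 if drop_extra_d else params.d
    return gauss + logistic + extra + params.h


def growth_rates(curve: GrowthCurve) -> tuple[np.ndarray, np.ndarray]:
    """Finite-difference growth rates (mm^3/day) at interval midpoints."""
    if len(curve) < 2:
        raise ValueError("need at least 2 points to compute growth rates")
    dt = np.diff(curve.days)
    rates = np.diff(curve.volumes) / dt
    mid = curve.days[:-1] + dt / 2.0
    return mid, rates


def spline_mean_volume(
    curve: GrowthCurve,
    t_lo: float = 8.0,
    t_hi: float = 20.0,
    smoothing: float | None = None,
    n_points: int = 10,
) -> float:
    """Mean volume over ``[t_lo, t_hi]`` from a second-order smoothing spline.

    The spline is evaluated at ``n_points`` evenly spaced days and averaged,
    which decouples the summary from the (possibly irregular) measurement
    schedule.  The smoothing factor defaults to ``n * sigma^2`` with the noise
    variance estimated from second differences of the curve, so exactly
    constant or linear curves are reproduced exactly.
    """
    if curve.days.min() > t_lo or curve.days.max() < t_hi:
        raise ValueError(
            f"curve [{curve.days.min()}, {curve.days.max()}] does not span "
            f"[{t_lo}, {t_hi}]"
        )
    if len(curve) < 3:
        raise ValueError("need at least 3 points for a second-order spline")
    if smoothing is None:
        if len(curve) >= 4:
            d2 = np.diff(curve.volumes, 2)
            sigma2 = float(np.mean(d2**2)) / 6.0  # var of 2nd diff of iid noise
            smoothing = len(curve) * sigma2
        else:
            smoothing = 0.0
    spl = UnivariateSpline(curve.days, curve.volumes, k=2, s=smoothing)
    t = np.linspace(t_lo, t_hi, n_points)
    return float(np.mean(spl(t)))


# ---------------------------------------------------------------------------
# Growth model fitting (Model / Results)
# ---------------------------------------------------------------------------


class TumorGrowthModel:
    """Gaussian + logistic growth model for one tumor's volume time series.

    Fitting is separable least squares: the amplitudes ``(a, d, h)`` enter
    linearly and are solved in closed form on a deterministic grid over the
    nonlinear parameters ``(b, c, f, g)``; the best grid point is then
    polished by bounded local least squares.  No random initialization is
    used, so fits are reproducible.
    """

    def __init__(
        self,
        days,
        volumes,
        rt_day: float,
        drop_extra_d: bool = False,
        mouse_id: str = "",
        weighted: bool = True,
    ) -> None:
        self.days = np.asarray(days, dtype=float)
        self.volumes = np.asarray(volumes, dtype=float)
        if self.days.ndim != 1 or self.days.shape != self.volumes.shape:
            raise ValueError("days and volumes must be 1-D and congruent")
        if len(self.days) < 7:
            raise ValueError("need at least 7 points to fit the growth model")
        self.rt_day = float(rt_day)
        self.drop_extra_d = bool(drop_extra_d)
        self.mouse_id = mouse_id
        # measurement errors are roughly proportional to volume, so fitting
        # is inverse-volume weighted (floored to avoid infinite weight at
        # zero-volume calls); disable with weighted=False for plain LS
        self.weighted = bool(weighted)
        self._sqrt_w = self._weights_from(self.volumes)

    def _weights_from(self, values: np.ndarray) -> np.ndarray:
        if not self.weighted or self.volumes.max() <= 0:
            return np.ones_like(self.volumes)
        floor = 0.05 * float(self.volumes.max())
        return 1.0 / np.sqrt(np.maximum(values, floor))

    @classmethod
    def from_curve(cls, curve: GrowthCurve, rt_day: float, **kw) -> "TumorGrowthModel":
        return cls(curve.days, curve.volumes, rt_day, mouse_id=curve.mouse_id, **kw)

    # -- internals ----------------------------------------------------------

    def _design(self, b, c, f, g):
        t = self.days
        G = np.exp(-((t - b) ** 2) / c**2)
        L = 1.0 / (1.0 + np.exp(-f * (t - g)))
        if not self.drop_extra_d:
            L = L + 1.0
        return G, L

    def _solve_amplitudes(self, b, c, f, g):
        """Amplitudes (a, d, h) by sign-constrained linear least squares.

        ``a`` (volume at the time of XRT) and ``d`` (maximum tumor volume)
        are physical volumes and constrained nonnegative; ``h`` is free
        (split into a difference of nonnegative parts for NNLS).
        """
        G, L = self._design(b, c, f, g)
        one = np.ones_like(G)
        A = np.column_stack([G, L, one, -one])
        sw = self._sqrt_w
        sol, _ = optimize.nnls(A * sw[:, None], self.volumes * sw)
        coef = np.array([sol[0], sol[1], sol[2] - sol[3]])
        resid = self.volumes - A[:, :3] @ coef
        return coef, float(np.sqrt(np.mean(resid**2)))

    def _grid_search(self, n_starts: int = 3):
        t = self.days
        y = self.volumes
        bs = np.linspace(self.rt_day - 5.0, self.rt_day + 5.0, 11)
        cs = np.geomspace(2.0, 30.0, 10)
        fs = np.geomspace(0.05, 2.0, 14)
        g_lo, g_hi = self.rt_day + 1.0, float(t.max())
        gs = np.linspace(g_lo, max(g_hi, g_lo + 1.0), 26)

        # Gaussian columns for all (b, c) pairs; logistic for all (f, g) pairs
        bc = np.array([(b, c) for b in bs for c in cs])
        fg = np.array([(f, g) for f in fs for g in gs])
        G = np.exp(-((t[None, :] - bc[:, 0:1]) ** 2) / bc[:, 1:2] ** 2)  # (nbc, T)
        L = 1.0 / (1.0 + np.exp(-fg[:, 0:1] * (t[None, :] - fg[:, 1:2])))  # (nfg, T)
        if not self.drop_extra_d:
            L = L + 1.0
        one = np.ones(len(t))

        # batched weighted 3x3 normal equations over the (bc x fg) cross
        w = self._sqrt_w**2
        GG = np.einsum("it,t,it->i", G, w, G)
        LL = np.einsum("jt,t,jt->j", L, w, L)
        GL = (G * w) @ L.T  # (nbc, nfg)
        G1 = G @ w
        L1 = L @ w
        Gy = (G * w) @ y
        Ly = (L * w) @ y
        n = float(w.sum())
        sy = float(w @ y)

        nbc, nfg = len(bc), len(fg)
        M = np.empty((nbc, nfg, 3, 3))
        M[..., 0, 0] = GG[:, None]
        M[..., 1, 1] = LL[None, :]
        M[..., 2, 2] = n
        M[..., 0, 1] = M[..., 1, 0] = GL
        M[..., 0, 2] = M[..., 2, 0] = G1[:, None]
        M[..., 1, 2] = M[..., 2, 1] = L1[None, :]
        rhs = np.empty((nbc, nfg, 3))
        rhs[..., 0] = Gy[:, None]
        rhs[..., 1] = Ly[None, :]
        rhs[..., 2] = sy
        # tiny Tikhonov jitter keeps near-collinear grid points solvable
        M = M + 1e-9 * np.eye(3)
        coef = np.linalg.solve(M, rhs[..., None])[..., 0]  # (nbc, nfg, 3)

        pred = (
            coef[..., 0:1] * G[:, None, :]
            + coef[..., 1:2] * L[None, :, :]
            + coef[..., 2:3]
        )
        sse = np.sum(w * (pred - y) ** 2, axis=-1)
        # prefer grid points whose unconstrained amplitudes are physical
        infeasible = (coef[..., 0] < 0) | (coef[..., 1] < 0)
        if not infeasible.all():
            sse = np.where(infeasible, np.inf, sse)
        # top candidates for multi-start polishing (local minima traps)
        flat = np.argsort(sse, axis=None)[:n_starts]
        out = []
        for k in flat:
            i, j = np.unravel_index(k, sse.shape)
            out.append((bc[i][0], bc[i][1], fg[j][0], fg[j][1]))
        return out

    # -- public API ---------------------------------------------------------

    def fit(self, polish: bool = True, reweight_iters: int = 0) -> "TumorGrowthResults":
        """Fit by separable weighted least squares.

        With ``reweight_iters > 0`` the inverse-volume weights are
        recomputed from the fitted curve instead of the noisy measurements
        (iteratively reweighted least squares); off by default — in
        simulation it does not improve parameter recovery and can reinforce
        a wrong mode.
        """
        res = self._fit_once(polish)
        for _ in range(max(0, int(reweight_iters))):
            if res.degenerate or not self.weighted:
                break
            pred = np.maximum(res.predict(self.days), 0.0)
            new_w = self._weights_from(pred)
            if np.allclose(new_w, self._sqrt_w, rtol=1e-6):
                break
            self._sqrt_w = new_w
            res = self._fit_once(polish)
        return res

    def _fit_once(self, polish: bool = True) -> "TumorGrowthResults":
        y = self.volumes
        if np.allclose(y, 0.0):
            params = GrowthParams(0.0, self.rt_day, 1.0, 0.0, 0.0, self.rt_day, 0.0)
            return TumorGrowthResults(self, params, 0.0, converged=True, degenerate=True)

        starts = self._grid_search(n_starts=5)
        b0, c0, f0, g0 = starts[0]
        converged = True
        if polish:
            t_max = float(self.days.max())
            # a fitted volume curve must stay nonnegative over the whole
            # experiment: hinge residuals on a dense time grid reject the
            # degenerate modes where d + h << 0 mimics regrowth
            t_dense = np.linspace(0.0, t_max, 61)
            scale = max(float(y.max()), 1.0)
            norm = float(np.sqrt(np.mean((self._sqrt_w * y) ** 2)))

            def resid(theta):
                b, c, f, g = theta
                coef, _ = self._solve_amplitudes(b, c, f, g)
                G, L = self._design(b, c, f, g)
                r = self._sqrt_w * (coef[0] * G + coef[1] * L + coef[2] - y)
                Gd = np.exp(-((t_dense - b) ** 2) / c**2)
                Ld = 1.0 / (1.0 + np.exp(-f * (t_dense - g)))
                if not self.drop_extra_d:
                    Ld = Ld + 1.0
                pred = coef[0] * Gd + coef[1] * Ld + coef[2]
                hinge = 5.0 * norm * np.minimum(pred, 0.0) / scale
                return np.concatenate([r, hinge])

            # same parameter ranges as the deterministic grid
            lb = [self.rt_day - 5.0, 2.0, 0.05, self.rt_day + 1.0]
            ub = [self.rt_day + 5.0, 30.0, 2.0, t_max]
            best_cost = np.inf
            for start in starts:
                theta0 = np.clip(start, lb, ub)
                sol = optimize.least_squares(
                    resid, theta0, bounds=(lb, ub), xtol=1e-12, ftol=1e-12, gtol=1e-12
                )
                if sol.cost < best_cost:
                    best_cost = sol.cost
                    b0, c0, f0, g0 = sol.x
                    converged = bool(sol.status > 0)
        coef, rms = self._solve_amplitudes(b0, c0, f0, g0)
        params = GrowthParams(coef[0], b0, c0, coef[1], f0, g0, coef[2])
        return TumorGrowthResults(self, params, rms, converged=converged)


@dataclass
class TumorGrowthResults:
    """Fitted growth-model parameters with residual diagnostics."""

    model: TumorGrowthModel
    params: GrowthParams
    residual_rms: float
    converged: bool = True
    degenerate: bool = False

    def predict(self, t) -> np.ndarray:
        return eval_growth_model(self.params, t, self.model.drop_extra_d)

    @property
    def residuals(self) -> np.ndarray:
        return self.model.volumes - self.predict(self.model.days)

    def summary(self) -> str:
        p = self.params
        buf = _io.StringIO()
        buf.write("Tumor growth model fit")
        if self.model.mouse_id:
            buf.write(f" (mouse {self.model.mouse_id})")
        buf.write("\n" + "-" * 46 + "\n")
        rows = [
            ("a (volume at XRT)", p.a, "mm^3"),
            ("b (Gaussian peak time)", p.b, "days"),
            ("c (shrink timescale)", p.c, "days"),
            ("d (regrowth amplitude)", p.d, "mm^3"),
            ("f (regrowth rate)", p.f, "1/day"),
            ("g (regrowth midpoint)", p.g, "days"),
            ("h (constant)", p.h, "mm^3"),
        ]
        for name, val, unit in rows:
            buf.write(f"{name:<26s} {val:12.4f} {unit}\n")
        buf.write("-" * 46 + "\n")
        buf.write(f"{'residual RMS':<26s} {self.residual_rms:12.4f} mm^3\n")
        buf.write(f"{'n points':<26s} {len(self.model.days):12d}\n")
        buf.write(f"{'converged':<26s} {str(self.converged):>12s}\n")
        if self.degenerate:
            buf.write("NOTE: degenerate fit (all-zero volume curve)\n")
        return buf.getvalue()


def fit_growth_model(
    curve: GrowthCurve, rt_day: float, drop_extra_d: bool = False
) -> TumorGrowthResults:
    """Convenience wrapper: fit the growth model to one curve."""
    return TumorGrowthModel.from_curve(curve, rt_day, drop_extra_d=drop_extra_d).fit()


# ---------------------------------------------------------------------------
# Method-agreement statistics
# ---------------------------------------------------------------------------


def correlations(x, y) -> CorrelationResult:
    """Pearson and Spearman correlations with two-sided p-values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and congruent")
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.std(x) == 0 or np.std(y) == 0:
        return CorrelationResult(np.nan, np.nan, np.nan, np.nan, len(x), undefined=True)
    pr = stats.pearsonr(x, y)
    sr = stats.spearmanr(x, y)
    return CorrelationResult(
        float(pr.statistic), float(pr.pvalue), float(sr.statistic), float(sr.pvalue), len(x)
    )


@dataclass
class BlandAltmanResult:
    means: np.ndarray
    differences: np.ndarray  # caliper - ct
    bias: float
    loa_low: float
    loa_high: float


def bland_altman(caliper, ct) -> BlandAltmanResult:
    """Bland–Altman agreement: difference (caliper − CT) vs pairwise mean."""
    caliper = np.asarray(caliper, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if caliper.shape != ct.shape or len(caliper) < 2:
        raise ValueError("need >= 2 matched pairs")
    diff = caliper - ct
    means = (caliper + ct) / 2.0
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return BlandAltmanResult(means, diff, bias, bias - 1.96 * sd, bias + 1.96 * sd)


@dataclass
class ZeroVolumeCrosstab:
    both: int
    caliper_only: int
    ct_only: int
    neither: int

    def as_array(self) -> np.ndarray:
        return np.array([[self.both, self.caliper_only], [self.ct_only, self.neither]])


def zero_volume_crosstab(caliper, ct) -> ZeroVolumeCrosstab:
    """Counts of exact-zero volume calls by each method and jointly."""
    caliper = np.asarray(caliper, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if caliper.shape != ct.shape:
        raise ValueError("mismatched pair arrays")
    cz = caliper == 0.0
    tz = ct == 0.0
    return ZeroVolumeCrosstab(
        both=int(np.sum(cz & tz)),
        caliper_only=int(np.sum(cz & ~tz)),
        ct_only=int(np.sum(~cz & tz)),
        neither=int(np.sum(~cz & ~tz)),
    )


def match_pairs(
    caliper_curves: list[GrowthCurve],
    ct_curves: list[GrowthCurve],
    interpolate: bool = False,
) -> pd.DataFrame:
    """Matched (mouse, day) volume pairs from the two measurement methods.

    Default matching requires exact day equality.  With ``interpolate=True``,
    days present in only one method are filled by linear interpolation of the
    other method's curve (only within its measured span), an explicitly
    looser mode for sparse schedules.
    """
    cal = {c.mouse_id: c for c in caliper_curves}
    ct = {c.mouse_id: c for c in ct_curves}
    rows = []
    for mouse in sorted(set(cal) & set(ct)):
        a, b = cal[mouse], ct[mouse]
        if interpolate:
            days = np.union1d(a.days, b.days)
            days = days[(days >= max(a.days.min(), b.days.min()))]
            days = days[(days <= min(a.days.max(), b.days.max()))]
            va = np.interp(days, a.days, a.volumes)
            vb = np.interp(days, b.days, b.volumes)
        else:
            days = np.intersect1d(a.days, b.days)
            va = a.volumes[np.isin(a.days, days)]
            vb = b.volumes[np.isin(b.days, days)]
        for d, x, y in zip(days, va, vb):
            rows.append({"mouse_id": mouse, "day": d, "caliper": x, "ct": y})
    return pd.DataFrame(rows, columns=["mouse_id", "day", "caliper", "ct"])


@dataclass
class ResidualAnalysis:
    residuals: pd.DataFrame  # mouse_id, day, caliper, ct, predicted, residual
    daily_mean_residual: pd.Series
    daily_mean_caliper: pd.Series
    correlation: CorrelationResult | None
    skipped: list[str] = field(default_factory=list)


def caliper_residual_analysis(
    caliper_curves: list[GrowthCurve],
    ct_curves: list[GrowthCurve],
    degree: int = 3,
    min_pairs: int = 5,
    smooth_predictor: bool = True,
) -> ResidualAnalysis:
    """Regress caliper volume on CT volume per mouse; analyze the residuals.

    A least-squares cubic polynomial predicting caliper volume from CT volume
    is fitted for each mouse, removing the effect of actual tumor volume on
    the recorded measurement.  Residuals are then averaged across mice per
    day and correlated with the daily mean caliper volume: a positive
    correlation indicates contextual measurement bias (small tumors recorded
    larger on days when the cohort's tumors are large).

    By default the CT predictor is spline-smoothed per mouse before the
    polynomial fit: regressing on the raw noisy CT values dilutes the fit
    (errors-in-variables) and leaves a spurious volume-tracking component in
    the residuals.  A mouse whose (smoothed) CT values span less than 10% of
    the cohort's volume range carries no usable volume signal and gets an
    intercept-only fit — a high-order polynomial on a near-constant
    predictor would fit noise instead.  ``smooth_predictor=False`` reproduces
    the plain regression on raw values.
    """
    pairs = match_pairs(caliper_curves, ct_curves)
    out = []
    skipped: list[str] = []
    global_max = float(pairs["ct"].max()) if len(pairs) else 0.0
    for mouse, grp in pairs.groupby("mouse_id"):
        if len(grp) < max(min_pairs, degree + 2):
            skipped.append(str(mouse))
            continue
        ct_vals = grp["ct"].to_numpy()
        cal_vals = grp["caliper"].to_numpy()
        predictor = ct_vals
        if smooth_predictor and len(ct_vals) >= 4:
            d2 = np.diff(ct_vals, 2)
            s = len(ct_vals) * float(np.mean(d2**2)) / 6.0
            predictor = UnivariateSpline(
                grp["day"].to_numpy(), ct_vals, k=2, s=s
            )(grp["day"].to_numpy())
        deg = degree
        if predictor.max() - predictor.min() < 0.1 * max(global_max, 1e-12):
            deg = 0
        coeffs = np.polyfit(predictor, cal_vals, deg)
        pred = np.polyval(coeffs, predictor)
        g = grp.copy()
        g["predicted"] = pred
        g["residual"] = g["caliper"] - pred
        out.append(g)
    if not out:
        empty = pd.DataFrame(
            columns=["mouse_id", "day", "caliper", "ct", "predicted", "residual"]
        )
        return ResidualAnalysis(empty, pd.Series(dtype=float), pd.Series(dtype=float), None, skipped)
    res = pd.concat(out, ignore_index=True)
    daily_res = res.groupby("day")["residual"].mean()
    daily_cal = res.groupby("day")["caliper"].mean()
    corr = None
    if len(daily_res) >= 3:
        scale = max(1.0, float(np.abs(daily_cal.to_numpy()).max()))
        if float(np.std(daily_res.to_numpy())) < 1e-9 * scale:
            # caliper is an exact function of CT: nothing left to correlate
            corr = CorrelationResult(np.nan, np.nan, np.nan, np.nan,
                                     len(daily_res), undefined=True)
        else:
            corr = correlations(daily_res.to_numpy(), daily_cal.to_numpy())
    return ResidualAnalysis(res, daily_res, daily_cal, corr, skipped)


# ---------------------------------------------------------------------------
# File interfaces
# ---------------------------------------------------------------------------


def read_caliper_csv(path) -> list[CaliperRecord]:
    """Read caliper records from CSV with columns mouse, day, d_long, d_short
    and optionally measurer."""
    df = pd.read_csv(path)
    cols = {c.lower().strip(): c for c in df.columns}
    required = ["mouse", "day", "d_long", "d_short"]
    missing = [c for c in required if c not in cols]
    if missing:
        raise ValueError(f"caliper CSV missing columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(
            CaliperRecord(
                mouse_id=str(row[cols["mouse"]]),
                day=float(row[cols["day"]]),
                d_long_mm=float(row[cols["d_long"]]),
                d_short_mm=float(row[cols["d_short"]]),
                measurer=str(row[cols["measurer"]]) if "measurer" in cols else "",
            )
        )
    return records


def curves_from_records(records: list[CaliperRecord]) -> list[GrowthCurve]:
    """Caliper growth curves (Eq.-style volumes) grouped by mouse."""
    by_mouse: dict[str, list[CaliperRecord]] = {}
    for r in records:
        by_mouse.setdefault(r.mouse_id, []).append(r)
    curves = []
    for mouse, recs in sorted(by_mouse.items()):
        recs = sorted(recs, key=lambda r: r.day)
        days = np.array([r.day for r in recs])
        vols = np.array([r.volume_mm3() for r in recs])
        curves.append(GrowthCurve(mouse, "caliper", days, vols))
    return curves


def curves_from_table(df: pd.DataFrame, method: str) -> list[GrowthCurve]:
    """Growth curves from a long table with columns mouse, day, volume."""
    cols = {c.lower().strip(): c for c in df.columns}
    for c in ("mouse", "day", "volume"):
        if c not in cols:
            raise ValueError(f"volume table missing column {c!r}")
    curves = []
    for mouse, grp in df.groupby(cols["mouse"]):
        grp = grp.sort_values(cols["day"])
        curves.append(
            GrowthCurve(
                str(mouse),
                method,
                grp[cols["day"]].to_numpy(dtype=float),
                grp[cols["volume"]].to_numpy(dtype=float),
            )
        )
    return curves


def read_volumes_xlsx(path, sheet_name=0, method: str = "ct") -> list[GrowthCurve]:
    """Growth curves from an Excel volume table (columns mouse, day, volume)."""
    df = pd.read_excel(path, sheet_name=sheet_name)
    return curves_from_table(df, method)


def write_volumes_csv(curves: list[GrowthCurve], path) -> pd.DataFrame:
    """Write growth curves to a long-format CSV; returns the written table."""
    rows = [
        {"mouse": c.mouse_id, "method": c.method, "day": d, "volume": v}
        for c in sorted(curves, key=lambda c: (c.mouse_id, c.method))
        for d, v in zip(c.days, c.volumes)
    ]
    df = pd.DataFrame(rows, columns=["mouse", "method", "day", "volume"])
    df.to_csv(path, index=False)
    return df
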