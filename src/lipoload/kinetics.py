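"""Loading and release kinetics.

Loading toward the equilibrium drug-to-lipid ratio is modelled as a single
exponential approach,

    dl(t) = dl_max * (1 - exp(-k t)),

the simplest law consistent with diffusion across a membrane toward a fixed
equilibrium; ``k`` is a lumped empirical rate (per hour).

Release under physiological (sink) conditions is modelled with two pools: a
fast "burst" pool — drug adsorbed to the outer membrane surface, shed
quickly on dilution into serum-containing medium — and a slow pool of
drug actually sequestered in cores/membranes:

    released(t) = f_a (1 - exp(-k_a t)) + (1 - f_a)(1 - exp(-k_e t))
    retained(t) = 1 - released(t)

with ``f_a`` the burst fraction, ``k_a`` the fast rate and ``k_e`` the slow
rate.  Only two release observations are typically printed (the early burst
and the long-time plateau), which cannot identify all three parameters, so
``k_a`` is fixed by the caller (default 4 / h, about a ten-minute
half-life) and :func:`calibrate_release` solves the remaining two-equation
system for ``(f_a, k_e)`` exactly.

Both models come with seeded least-squares fitting (``fit_loading``,
``fit_release``) whose determinism is guaranteed by fixed starting points
and tolerances.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "LoadingKinetics",
    "ReleaseModel",
    "TimeCourse",
    "FitDiagnostics",
    "loading_curve",
    "fit_loading",
    "calibrate_release",
    "release_curve",
    "fit_release",
    "DEFAULT_BURST_RATE_PER_H",
]

#: Default fast-pool rate (per hour); not identifiable from two printed
#: release points, so it is fixed rather than fitted.
DEFAULT_BURST_RATE_PER_H = 4.0


@dataclass(frozen=True)
class LoadingKinetics:
    """Single-exponential loading model: rate ``k`` (1/h) and plateau D:L."""

    k_per_h: float
    dl_max: float

    def __post_init__(self) -> None:
        if self.k_per_h < 0.0:
            raise ValueError(f"k_per_h must be >= 0, got {self.k_per_h}")
        if self.dl_max < 0.0:
            raise ValueError(f"dl_max must be >= 0, got {self.dl_max}")

    def dl(self, t_h: np.ndarray | float) -> np.ndarray | float:
        return self.dl_max * -np.expm1(-self.k_per_h * np.asarray(t_h, dtype=float))


@dataclass(frozen=True)
class ReleaseModel:
    """Two-pool (burst + slow) release model.

    ``burst_fraction`` of the loaded drug sits in the fast pool released at
    ``burst_rate_per_h``; the rest leaves at ``slow_rate_per_h``.
    """

    burst_fraction: float
    burst_rate_per_h: float
    slow_rate_per_h: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.burst_fraction <= 1.0):
            raise ValueError(
                f"burst_fraction must be in [0, 1], got {self.burst_fraction}"
            )
        if not (self.burst_rate_per_h >= self.slow_rate_per_h >= 0.0):
            raise ValueError(
                "rates must satisfy burst_rate >= slow_rate >= 0, got "
                f"k_a={self.burst_rate_per_h}, k_e={self.slow_rate_per_h}"
            )

    def released(self, t_h: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_h, dtype=float)
        fast = -np.expm1(-self.burst_rate_per_h * t)
        slow = -np.expm1(-self.slow_rate_per_h * t)
        return self.burst_fraction * fast + (1.0 - self.burst_fraction) * slow

    def retained(self, t_h: np.ndarray | float) -> np.ndarray | float:
        return 1.0 - self.released(t_h)


@dataclass(frozen=True)
class TimeCourse:
    """A measured or simulated (time, value) series.

    ``values`` are D:L ratios for loading data or retained fractions for
    release data; ``sigma`` is an optional per-point noise scale.
    """

    times_h: np.ndarray
    values: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_h, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times_h", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times_h and values must be 1-D and equal length")
        if t.size and np.any(np.diff(t) <= 0.0):
            raise ValueError("times_h must be strictly ascending")
        if not np.all(np.isfinite(v)):
            raise ValueError("values must be finite")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != t.shape:
                raise ValueError("sigma must match times_h in length")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time_h": self.times_h, "value": self.values})
        if self.sigma is not None:
            df["sigma"] = self.sigma
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeCourse":
        df = pd.read_csv(path)
        missing = {"time_h", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
        sigma = df["sigma"].to_numpy() if "sigma" in df.columns else None
        return cls(df["time_h"].to_numpy(), df["value"].to_numpy(), sigma)


@dataclass(frozen=True)
class FitDiagnostics:
    """Convergence and uncertainty summary attached to every fit."""

    converged: bool
    message: str
    residual_norm: float
    n_points: int
    stderr: tuple[float, ...]


def _check_times(times_h: Sequence[float]) -> np.ndarray:
    t = np.asarray(times_h, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("times must be non-negative")
    return t


def loading_curve(lk: LoadingKinetics, times_h: Sequence[float]) -> TimeCourse:
    """Evaluate the loading model dl(t) = dl_max (1 - e^{-kt}) at ``times_h``."""
    t = _check_times(times_h)
    return TimeCourse(t, np.asarray(lk.dl(t), dtype=float))


def fit_loading(tc: TimeCourse) -> tuple[LoadingKinetics, FitDiagnostics]:
    """Least-squares fit of (k, dl_max) to a loading time course.

    Needs at least 4 points.  Deterministic: fixed start (k = 1 / h,
    dl_max = max observed value) and fixed tolerances.  An all-zero series
    is degenerate and reported as non-converged with k = 0.
    """
    if tc.times_h.size < 4:
        raise ValueError("fit_loading needs at least 4 points")
    vmax = float(np.max(tc.values))
    if vmax <= 0.0:
        lk = LoadingKinetics(0.0, 0.0)
        return lk, FitDiagnostics(
            converged=False,
            message="degenerate: no positive values to fit",
            residual_norm=float(np.linalg.norm(tc.values)),
            n_points=tc.times_h.size,
            stderr=(np.nan, np.nan),
        )

    def model(t: np.ndarray, k: float, dl_max: float) -> np.ndarray:
        return dl_max * -np.expm1(-k * t)

    popt, pcov = optimize.curve_fit(
        model,
        tc.times_h,
        tc.values,
        p0=(1.0, vmax),
        sigma=tc.sigma,
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=10000,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    k, dl_max = (float(x) for x in popt)
    resid = tc.values - model(tc.times_h, k, dl_max)
    stderr = tuple(float(x) for x in np.sqrt(np.maximum(np.diag(pcov), 0.0)))
    lk = LoadingKinetics(k, dl_max)
    return lk, FitDiagnostics(
        converged=True,
        message="converged",
        residual_norm=float(np.linalg.norm(resid)),
        n_points=tc.times_h.size,
        stderr=stderr,
    )


def calibrate_release(
    released_at_t1: float,
    t1_h: float,
    released_at_t2: float,
    t2_h: float,
    k_a_per_h: float = DEFAULT_BURST_RATE_PER_H,
) -> ReleaseModel:
    """Solve the two-pool model exactly through two release observations.

    Given the cumulative fraction released by ``t1_h`` and by ``t2_h`` and
    a caller-fixed fast-pool rate, solves

        released(t_i) = f_a (1 - e^{-k_a t_i}) + (1 - f_a)(1 - e^{-k_e t_i})

    for (f_a, k_e).  The returned model reproduces both observations to
    better than 1e-9 absolute.  Raises with bracketing diagnostics when the
    observations are unreachable (e.g. later release below the floor the
    burst alone implies).
    """
    r1, r2 = released_at_t1, released_at_t2
    if not (0.0 <= r1 <= r2 < 1.0):
        raise ValueError(
            f"need 0 <= released_at_t1 <= released_at_t2 < 1, got {r1}, {r2}"
        )
    if not (0.0 < t1_h < t2_h):
        raise ValueError(f"need 0 < t1 < t2, got t1={t1_h}, t2={t2_h}")
    if not (k_a_per_h > 0.0):
        raise ValueError(f"k_a_per_h must be > 0, got {k_a_per_h}")

    if r1 == 0.0 and r2 == 0.0:
        return ReleaseModel(0.0, k_a_per_h, 0.0)

    e1a = -np.expm1(-k_a_per_h * t1_h)

    def f_a_of(k_e: float) -> float:
        e1e = -np.expm1(-k_e * t1_h)
        denom = e1a - e1e
        if denom <= 0.0:
            raise ValueError(
                "fast rate not faster than slow rate at t1; cannot separate pools"
            )
        return (r1 - e1e) / denom

    def r2_residual(k_e: float) -> float:
        f_a = f_a_of(k_e)
        e2a = -np.expm1(-k_a_per_h * t2_h)
        e2e = -np.expm1(-k_e * t2_h)
        return f_a * e2a + (1.0 - f_a) * e2e - r2

    lo, hi = 0.0, k_a_per_h * (1.0 - 1e-9)
    g_lo = r2_residual(lo)
    if g_lo > 1e-12:
        floor = g_lo + r2
        raise ValueError(
            f"no solution: even with slow rate 0 the burst pool alone releases "
            f"{floor:.6g} by t2={t2_h} h, above the observed {r2}; "
            f"bracket residuals g(0)={g_lo:.3g}"
        )
    g_hi = r2_residual(hi)
    if g_hi < 0.0:
        raise ValueError(
            f"no solution: observations require a slow rate above the fast "
            f"rate {k_a_per_h}/h; bracket residuals g(0)={g_lo:.3g}, "
            f"g(k_a)={g_hi:.3g}"
        )
    if abs(g_lo) <= 1e-12:
        k_e = 0.0
    else:
        k_e = optimize.brentq(r2_residual, lo, hi, xtol=1e-15, rtol=1e-14)
    f_a = float(np.clip(f_a_of(k_e), 0.0, 1.0))
    model = ReleaseModel(f_a, k_a_per_h, float(k_e))
    for t_obs, r_obs in ((t1_h, r1), (t2_h, r2)):
        err = abs(float(model.released(t_obs)) - r_obs)
        if err > 1e-9:
            raise RuntimeError(
                f"calibration round-trip failed at t={t_obs} h: |error|={err:.3g}"
            )
    return model


def release_curve(rm: ReleaseModel, times_h: Sequence[float]) -> TimeCourse:
    """Retained fraction 1 - released(t) at ``times_h``; retained(0) = 1."""
    t = _check_times(times_h)
    return TimeCourse(t, np.asarray(rm.retained(t), dtype=float))


def fit_release(
    tc: TimeCourse, k_a_per_h: float = DEFAULT_BURST_RATE_PER_H
) -> tuple[ReleaseModel, FitDiagnostics]:
    """Least-squares fit of (f_a, k_e) to a retained-fraction time course.

    ``k_a_per_h`` stays fixed (unidentifiable from sparse data).  Needs at
    least 5 points spanning burst and plateau.  Deterministic: fixed start
    (f_a = 0.2, k_e = 0.01 / h), bounded to 0 <= f_a <= 1 and
    0 <= k_e <= k_a.
    """
    if tc.times_h.size < 5:
        raise ValueError("fit_release needs at least 5 points")

    def residuals(p: np.ndarray) -> np.ndarray:
        f_a, k_e = p
        fast = -np.expm1(-k_a_per_h * tc.times_h)
        slow = -np.expm1(-k_e * tc.times_h)
        retained = 1.0 - (f_a * fast + (1.0 - f_a) * slow)
        r = retained - tc.values
        if tc.sigma is not None:
            r = r / tc.sigma
        return r

    res = optimize.least_squares(
        residuals,
        x0=np.array([0.2, 0.01]),
        bounds=([0.0, 0.0], [1.0, k_a_per_h]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    if not res.success:
        raise RuntimeError(f"release fit did not converge: {res.message}")
    f_a, k_e = (float(x) for x in res.x)
    # 1-sigma parameter errors from the Jacobian pseudo-inverse
    try:
        jtj_inv = np.linalg.pinv(res.jac.T @ res.jac)
        dof = max(tc.times_h.size - 2, 1)
        s2 = 2.0 * res.cost / dof
        stderr = tuple(float(x) for x in np.sqrt(np.maximum(np.diag(jtj_inv) * s2, 0.0)))
    except np.linalg.LinAlgError:
        stderr = (np.nan, np.nan)
    rm = ReleaseModel(f_a, k_a_per_h, min(k_e, k_a_per_h))
    return rm, FitDiagnostics(
        converged=True,
        message=res.message,
        residual_norm=float(np.linalg.norm(res.fun)),
        n_points=tc.times_h.size,
        stderr=stderr,
    )
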