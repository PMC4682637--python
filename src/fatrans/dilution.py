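"""Indicator-dilution curve algebra.

Curves are sampled, normalized tracer concentrations versus time, in units
of s^-1 (concentration times flow per injected amount), so that a
conservative tracer integrates to 1 (100%).  The module provides causal
convolution, constrained regularized deconvolution (nonnegative least
squares with a second-difference smoothness penalty), normalization, and
emulation of the effluent-fraction sampling schedule used in multiple
indicator dilution experiments (30 samples at 1 s, then 30 at 4 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "DilutionCurve",
    "SamplingSchedule",
    "DeconvolutionSettings",
    "default_schedule",
    "convolve_curve",
    "deconvolve_curve",
    "normalize_curve",
    "resample_schedule",
    "resample_uniform",
    "schedule_to_uniform",
    "l1_distance",
]


@dataclass(frozen=True)
class SamplingSchedule:
    """Effluent collection schedule: contiguous intervals with edges [s]."""

    edges: np.ndarray

    @property
    def times(self) -> np.ndarray:
        """Interval midpoints [s]."""
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)


def default_schedule() -> SamplingSchedule:
    """30 samples at 1.0 s^-1 then 30 at 0.25 s^-1 (spans 150 s)."""
    edges = np.concatenate([np.arange(0.0, 31.0), 30.0 + 4.0 * np.arange(1.0, 31.0)])
    return SamplingSchedule(edges=edges)


@dataclass(frozen=True)
class DilutionCurve:
    """Sampled tracer concentration vs time.

    times [s], values [s^-1].  ``uniform`` curves sample an underlying
    continuous function on an even grid; schedule-sampled curves hold
    interval means and carry their ``schedule``.
    """

    times: np.ndarray
    values: np.ndarray
    schedule: SamplingSchedule | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.ndim != 1 or t.shape != v.shape:
            raise ValueError("times and values must be matching 1-D arrays")
        if t.size >= 2 and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    @property
    def dt(self) -> float:
        steps = np.diff(self.times)
        if steps.size == 0 or not np.allclose(steps, steps[0], rtol=1e-8):
            raise ValueError("curve is not uniformly sampled")
        return float(steps[0])

    def integral(self) -> float:
        """Trapezoidal time integral (dimensionless recovered fraction)."""
        if self.schedule is not None:
            return float(np.sum(self.values * self.schedule.widths))
        return float(np.trapezoid(self.values, self.times))

    def mean_transit_time(self) -> float:
        """First moment / zeroth moment [s]."""
        m0 = np.trapezoid(self.values, self.times)
        m1 = np.trapezoid(self.values * self.times, self.times)
        return float(m1 / m0)


@dataclass(frozen=True)
class DeconvolutionSettings:
    """Settings of the regularized nonnegative deconvolution.

    smoothing_weight multiplies the squared second difference of the
    solution; the default was calibrated once so a noiseless round trip
    (deconvolve(convolve(f, h), h)) recovers f to better than 2% L1.
    """

    dt: float = 0.1
    smoothing_weight: float = 1e-4
    max_time: float = 60.0
    nonnegativity: bool = True

    def __post_init__(self) -> None:
        if not self.dt > 0:
            raise ValueError("dt must be positive")
        if self.smoothing_weight < 0:
            raise ValueError("smoothing_weight must be >= 0")


def _check_uniform_pair(f: DilutionCurve, h: DilutionCurve) -> float:
    dtf, dth = f.dt, h.dt
    if not np.isclose(dtf, dth, rtol=1e-8):
        raise ValueError(f"curves have mismatched sampling steps {dtf} != {dth}")
    return dtf


def convolve_curve(f: DilutionCurve, h: DilutionCurve) -> DilutionCurve:
    """Discrete causal convolution (f * h)(t), scaled by dt.

    Both curves must share the sampling step and start at their own t=0
    support; the area of the output is the product of the input areas.
    """
    dt = _check_uniform_pair(f, h)
    out = np.convolve(f.values, h.values)[: f.values.size] * dt
    t0 = f.times[0] + h.times[0]
    times = t0 + dt * np.arange(out.size)
    return DilutionCurve(times=times, values=out)


def _second_difference(n: int) -> np.ndarray:
    D = np.zeros((n - 2, n))
    for i in range(n - 2):
        D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return D


def deconvolve_curve(
    observed: DilutionCurve, h: DilutionCurve, settings: DeconvolutionSettings | None = None
) -> DilutionCurve:
    """Recover x from observed ~= x * h by constrained regularized least squares.

    Minimizes ||h*x - observed||^2 + w ||D2 x||^2 subject to x >= 0 (active
    by default), then renormalizes x to unit integral.  Deterministic for
    given settings.
    """
    from scipy.optimize import nnls
    from scipy.linalg import lstsq

    settings = settings or DeconvolutionSettings()
    dt = _check_uniform_pair(observed, h)
    y = observed.values
    if not np.any(y > 0):
        raise ValueError("observed curve is identically zero")
    n = min(int(round(settings.max_time / dt)) + 1, y.size)
    # causal convolution matrix: (A x)_i = dt * sum_j h_{i-j} x_j
    hv = h.values
    m = y.size
    A = np.zeros((m, n))
    for j in range(n):
        seg = hv[: m - j]
        A[j : j + seg.size, j] = seg * dt
    D = _second_difference(n) * np.sqrt(settings.smoothing_weight)
    A_aug = np.vstack([A, D])
    y_aug = np.concatenate([y, np.zeros(D.shape[0])])
    if settings.nonnegativity:
        x, rnorm = nnls(A_aug, y_aug)
    else:
        x = lstsq(A_aug, y_aug)[0]
        rnorm = float(np.linalg.norm(A_aug @ x - y_aug))
    times = observed.times[0] - h.times[0] + dt * np.arange(n)
    # clock starts at the inlet: shift support to t >= 0
    times = times - times[0] + max(times[0], 0.0)
    curve = DilutionCurve(times=times, values=x)
    return normalize_curve(curve)


def normalize_curve(c: DilutionCurve) -> DilutionCurve:
    """Scale so the trapezoidal (or schedule-weighted) integral is exactly 1."""
    area = c.integral()
    if not area > 0:
        raise ValueError("curve integral must be positive to normalize")
    return replace(c, values=c.values / area, normalized=True)


def resample_schedule(c: DilutionCurve, schedule: SamplingSchedule | None = None) -> DilutionCurve:
    """Sample a uniform curve as interval means (collected effluent fractions)."""
    schedule = schedule or default_schedule()
    if schedule.edges[0] < c.times[0] - 1e-9 or schedule.edges[-1] > c.times[-1] + 1e-9:
        raise ValueError("sampling schedule exceeds the curve support")
    t, v = c.times, c.values
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (v[1:] + v[:-1]) * np.diff(t))])
    cum_at = np.interp(schedule.edges, t, cum)
    means = np.diff(cum_at) / schedule.widths
    return DilutionCurve(times=schedule.times, values=means, schedule=schedule,
                         normalized=c.normalized)


def resample_uniform(c: DilutionCurve, dt: float) -> DilutionCurve:
    """Point-sample a uniform curve on a coarser/finer uniform dt grid."""
    times = np.arange(c.times[0], c.times[-1] + dt / 2, dt)
    values = np.interp(times, c.times, c.values)
    return DilutionCurve(times=times, values=values, normalized=c.normalized)


def schedule_to_uniform(c: DilutionCurve, dt: float, n_iter: int = 8) -> DilutionCurve:
    """Reconstruct a uniform curve from schedule samples (interval means).

    Starts from a monotone cubic through the interval midpoints (zero anchor
    at the schedule start) and iteratively corrects it so that its own
    interval means reproduce the samples; this removes the curvature bias of
    treating bin means as point values at a sharp peak.  Output >= 0.
    """
    if c.schedule is None:
        raise ValueError("curve carries no sampling schedule")
    edges = c.schedule.edges
    times = np.arange(edges[0], edges[-1] + dt / 2, dt)

    def build(samples: np.ndarray) -> np.ndarray:
        t_anchor = np.concatenate([[edges[0]], c.times, [edges[-1]]])
        v_anchor = np.concatenate([[0.0], samples, [samples[-1]]])
        return np.nan_to_num(PchipInterpolator(t_anchor, v_anchor, extrapolate=False)(times))

    target = c.values
    samples = target.copy()
    values = build(samples)
    for _ in range(n_iter):
        cur = DilutionCurve(times=times, values=np.clip(values, 0.0, None))
        means = resample_schedule(cur, c.schedule).values
        samples = samples + (target - means)
        values = build(samples)
    return DilutionCurve(times=times, values=np.clip(values, 0.0, None))


def l1_distance(a: DilutionCurve, b: DilutionCurve, relative_to: DilutionCurve | None = None) -> float:
    """Integrated absolute difference, optionally relative to a curve's area."""
    if a.times.shape != b.times.shape or not np.allclose(a.times, b.times):
        raise ValueError("curves must share a time grid")
    diff = float(np.trapezoid(np.abs(a.values - b.values), a.times))
    if relative_to is None:
        return diff
    return diff / relative_to.integral()
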