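"""Time-varying release-rate estimation and the time-rescaling transform.

The release intensity λ(t) is estimated by the density-function method:
each spike is replaced by a unit-mass Gaussian kernel and the kernels are
summed, so that ∫λ dt ≈ N up to the kernel mass leaking past the interval
ends.  The cumulative intensity Λ(t) = ∫₀ᵗ λ(s) ds maps the spike times
onto a unit-rate process (time-rescaling theorem); its inverse maps
unit-rate trains onto a prescribed rate profile, which is how the
synthetic generator produces inhomogeneous trains.

Ex-vivo recordings show a rate plateau followed by an S-shaped decay; the
module fits that profile with a four-parameter logistic,
``r(t) = r0 / (1 + exp(-beta_r (t - mu_r))) + rf`` (``beta_r < 0`` decays).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .sequences import SpikeSequence

__all__ = [
    "RateFunction",
    "LogisticRateParams",
    "RescaledSequence",
    "estimate_rate",
    "logistic_rate",
    "fit_logistic_rate",
    "cumulative_intensity",
    "rescale_sequence",
    "inverse_rescale",
]


@dataclass(frozen=True)
class RateFunction:
    """Non-negative intensity λ(t) sampled on a uniform grid (per second).

    Piecewise-linear between grid points, constant beyond the ends.  The
    cumulative intensity is evaluated exactly for the piecewise-linear
    interpolant (trapezoid rule on segments), so rescaling and its inverse
    are mutual inverses to round-off.
    """

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)
        if grid.size < 2 or grid.size != values.size:
            raise ValueError("grid and values must have equal length >= 2")
        steps = np.diff(grid)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("grid must be strictly increasing and uniform")
        if np.any(values < 0):
            raise ValueError("rate values must be non-negative")

    def __call__(self, t):
        return np.interp(t, self.grid, self.values)

    @property
    def duration(self) -> float:
        return float(self.grid[-1])

    def _cumulative_on_grid(self) -> np.ndarray:
        seg = 0.5 * (self.values[1:] + self.values[:-1]) * np.diff(self.grid)
        return np.concatenate([[0.0], np.cumsum(seg)])

    def cumulative(self, t):
        """Λ(t) = ∫₀ᵗ λ, exact for the piecewise-linear interpolant."""
        t = np.asarray(t, dtype=float)
        if np.any(t < self.grid[0] - 1e-12) or np.any(t > self.grid[-1] + 1e-12):
            raise ValueError("t outside the rate-function support")
        cum = self._cumulative_on_grid()
        idx = np.clip(np.searchsorted(self.grid, t, side="right") - 1, 0, len(self.grid) - 2)
        t0 = self.grid[idx]
        lam0 = self.values[idx]
        lam_t = self(t)
        out = cum[idx] + 0.5 * (lam0 + lam_t) * (t - t0)
        return out if out.ndim else float(out)

    def cumulative_inverse(self, tau):
        """t = Λ⁻¹(τ) by exact inversion of the per-segment quadratic."""
        tau = np.asarray(tau, dtype=float)
        cum = self._cumulative_on_grid()
        if np.any(tau < -1e-12) or np.any(tau > cum[-1] + 1e-9):
            raise ValueError("rate function exhausted: rescaled time beyond Lambda(T)")
        idx = np.clip(np.searchsorted(cum, tau, side="right") - 1, 0, len(cum) - 2)
        h = np.diff(self.grid)[idx]
        lam0 = self.values[idx]
        lam1 = self.values[idx + 1]
        a = tau - cum[idx]  # area to absorb within the segment
        slope = (lam1 - lam0) / h
        # solve lam0*x + slope*x^2/2 = a for x in [0, h]
        with np.errstate(invalid="ignore", divide="ignore"):
            x_lin = a / np.where(lam0 > 0, lam0, np.nan)
            disc = lam0**2 + 2.0 * slope * a
            x_quad = np.where(
                np.abs(slope) > 1e-300,
                (np.sqrt(np.maximum(disc, 0.0)) - lam0) / np.where(slope != 0, slope, 1.0),
                np.nan,
            )
        x = np.where(np.abs(slope) * h > 1e-12 * np.maximum(lam0, lam1), x_quad, x_lin)
        if np.any(~np.isfinite(x)):
            raise ValueError("degenerate rescaling: rate vanishes on a segment carrying mass")
        out = self.grid[idx] + np.clip(x, 0.0, h)
        return out if out.ndim else float(out)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.grid, self.values]),
                   delimiter=",", header="time_s,rate_per_s", comments="")

    @classmethod
    def from_csv(cls, path) -> "RateFunction":
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(grid=arr[:, 0], values=arr[:, 1])


@dataclass(frozen=True)
class LogisticRateParams:
    """Parameters of r(t) = r0/(1 + exp(-beta_r (t - mu_r))) + rf.

    ``r0`` is the plateau-to-floor amplitude (per second), ``rf`` the final
    rate (per second), ``beta_r`` the decay constant (per second; negative
    for decaying rates) and ``mu_r`` the midpoint time (seconds).  ``sse``
    is the residual sum of squares of the fit that produced them.
    """

    r0: float
    rf: float
    beta_r: float
    mu_r: float
    sse: float = 0.0

    def __call__(self, t):
        return logistic_rate(t, self.r0, self.rf, self.beta_r, self.mu_r)


def logistic_rate(t, r0, rf, beta_r, mu_r):
    return r0 / (1.0 + np.exp(-beta_r * (np.asarray(t, dtype=float) - mu_r))) + rf


def estimate_rate(seq: SpikeSequence, bandwidth: float = 10.0,
                  grid_step: float | None = None) -> RateFunction:
    """Density-function rate estimate: λ(t) = Σ_n ω(t - t_n).

    ω is a unit-mass Gaussian of standard deviation ``bandwidth`` (seconds).
    No boundary correction is applied, so ∫₀ᵀ λ dt falls short of N only by
    the kernel mass leaking past 0 and T.  ``grid_step`` defaults to
    bandwidth/10.
    """
    if seq.n < 1:
        raise ValueError("need at least one spike to estimate a rate")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    if grid_step is None:
        grid_step = bandwidth / 10.0
    n_grid = int(np.ceil(seq.duration / grid_step)) + 1
    grid = np.arange(n_grid) * grid_step
    values = np.zeros(n_grid)
    norm = 1.0 / (bandwidth * np.sqrt(2.0 * np.pi))
    half = int(np.ceil(8.0 * bandwidth / grid_step))  # +-8 sigma window
    centers = np.round(seq.times / grid_step).astype(int)
    for t_n, c in zip(seq.times, centers):
        lo = max(0, c - half)
        hi = min(n_grid, c + half + 1)
        x = grid[lo:hi] - t_n
        values[lo:hi] += norm * np.exp(-0.5 * (x / bandwidth) ** 2)
    return RateFunction(grid=grid, values=values)


def fit_logistic_rate(rate: RateFunction) -> LogisticRateParams:
    """Least-squares logistic fit to a sampled rate curve.

    Deterministic start: amplitude from the rate range, midpoint at the
    half-range crossing, decay-constant sign from the end-to-end slope (the
    logistic is multimodal in its parameters, so the start matters).
    """
    if rate.grid.size < 10:
        raise ValueError("need at least 10 grid points for a logistic fit")
    t, y = rate.grid, rate.values
    y_min, y_max = float(y.min()), float(y.max())
    span = max(y_max - y_min, 1e-12)
    decaying = y[-1] < y[0]
    half_level = y_min + 0.5 * span
    crossings = np.nonzero((y[:-1] - half_level) * (y[1:] - half_level) <= 0)[0]
    mu0 = float(t[crossings[-1] if decaying else crossings[0]]) if crossings.size else float(t[t.size // 2])
    beta0 = (-1.0 if decaying else 1.0) * 20.0 / max(rate.duration, 1e-9)

    def residuals(params):
        r0, rf, beta_r, mu_r = params
        return logistic_rate(t, r0, rf, beta_r, mu_r) - y

    x0 = np.array([span, y_min, beta0, mu0])
    sol = least_squares(residuals, x0, method="lm", max_nfev=20000)
    if not sol.success:
        raise RuntimeError(f"logistic fit did not converge; last iterate {sol.x}")
    r0, rf, beta_r, mu_r = sol.x
    return LogisticRateParams(r0=float(r0), rf=float(rf), beta_r=float(beta_r),
                              mu_r=float(mu_r), sse=float(2.0 * sol.cost))


def cumulative_intensity(rate: RateFunction, t) -> float:
    """Λ(t) = ∫₀ᵗ λ(s) ds (dimensionless); monotone non-decreasing in t."""
    return rate.cumulative(t)


@dataclass(frozen=True)
class RescaledSequence:
    """A spike sequence mapped through τ = Λ(t).

    ``rescaled_times`` are the τ_i, ``interspikes`` the u_i = Λ(t_i) - Λ(t_{i-1});
    when the rate was estimated from the same sequence the u_i have mean ≈ 1.
    """

    rescaled_times: np.ndarray
    interspikes: np.ndarray
    source: SpikeSequence
    rate: RateFunction

    @property
    def duration(self) -> float:
        return float(self.rate.cumulative(min(self.source.duration, self.rate.duration)))

    def to_sequence(self, label: str = "rescaled") -> SpikeSequence:
        return SpikeSequence(times=self.rescaled_times, duration=self.duration, label=label)


def rescale_sequence(seq: SpikeSequence, rate: RateFunction) -> RescaledSequence:
    """Apply the time-rescaling transform τ_i = Λ(t_i).

    The rate must be strictly positive wherever there are spikes; a rate
    vanishing over an inter-spike interval would collapse u_i to zero.
    """
    tau = np.asarray(rate.cumulative(seq.times))
    u = np.diff(tau)
    if seq.n >= 2 and np.any(u <= 0):
        raise ValueError("degenerate rescaling: rate vanishes over an interval containing spikes")
    return RescaledSequence(rescaled_times=tau, interspikes=u, source=seq, rate=rate)


def inverse_rescale(unit_seq: SpikeSequence, rate: RateFunction,
                    label: str = "inverse-rescaled") -> SpikeSequence:
    """Map unit-rate event times τ_i to t_i = Λ⁻¹(τ_i).

    Requires Λ(T) ≥ max τ_i; composing with rescale_sequence recovers the
    input within grid tolerance.
    """
    times = np.asarray(rate.cumulative_inverse(unit_seq.times))
    return SpikeSequence(times=times, duration=rate.duration, label=label)
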