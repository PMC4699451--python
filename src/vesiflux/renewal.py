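"""Renewal-process statistics: histograms, candidate models, SSE fitting.

A release train that is purely random gives exponential interspike times
and Poisson window counts; a partly deterministic (history-dependent)
train is captured by a gamma renewal process, whose window counts follow
the gamma-count distribution

    P(k) = G(p k, beta T) - G(p k + p, beta T),      beta = 1/theta,

with G the regularized lower incomplete gamma function and G(0, x) := 1
(required for the pmf to sum to 1 and for the p=1 Poisson reduction).
Shape p > 1 means underdispersion: the count variance-to-mean ratio
(Fano factor / dispersion index) drops below 1.

Models are fitted to density-normalized histograms by nonlinear least
squares (pdf at bin centers, pmf at integer counts) — the visual-fit
practice of the amperometry literature — and goodness of fit is
summarized by R² = 1 - SSE/SST.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.special import gammainc, gammaln

from .sequences import CountSeries, SpikeSequence, interspike_times, spike_counts

__all__ = [
    "SummaryStats",
    "HistogramData",
    "CountHistogram",
    "FitResult",
    "summary_stats",
    "interspike_bin_width",
    "make_histogram",
    "count_frequencies",
    "exponential_pdf",
    "poisson_pmf",
    "gamma_pdf",
    "gamma_count_pmf",
    "lognormal_pdf",
    "fit_histogram",
    "combined_fit",
    "model_report",
    "RESCALED_COUNT_WINDOW",
]

#: Count window for rescaled (unit-rate) sequences, in rescaled-time units.
RESCALED_COUNT_WINDOW = 4.0


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    median: float
    variance: float
    std: float
    cv: float
    dispersion: float | None = None  # variance/mean, reported for counts

    def as_dict(self) -> dict:
        d = {"mean": self.mean, "median": self.median, "variance": self.variance,
             "std": self.std, "cv": self.cv}
        if self.dispersion is not None:
            d["dispersion"] = self.dispersion
        return d


@dataclass(frozen=True)
class HistogramData:
    """Equal-width histogram with a unit-area density normalization."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        edges = np.asarray(self.bin_edges, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "counts", counts)
        if counts.size != edges.size - 1:
            raise ValueError("need len(counts) == len(bin_edges) - 1")
        if np.any(counts < 0):
            raise ValueError("histogram counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[1:] + self.bin_edges[:-1])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.bin_edges)

    @property
    def density(self) -> np.ndarray:
        total = self.counts.sum()
        if total == 0:
            return np.zeros_like(self.counts)
        return self.counts / (total * self.widths)

    def to_csv(self, path) -> None:
        np.savetxt(path, np.column_stack([self.bin_edges[:-1], self.bin_edges[1:],
                                          self.counts, self.density]),
                   delimiter=",", header="bin_start,bin_end,count,density", comments="")


@dataclass(frozen=True)
class CountHistogram:
    """Frequencies of integer window counts k = 0..max, with the window width."""

    k: np.ndarray
    frequency: np.ndarray  # probabilities, sum to 1
    window: float

    @property
    def mean(self) -> float:
        return float(np.sum(self.k * self.frequency))


@dataclass(frozen=True)
class FitResult:
    family: str
    params: dict
    sse: float
    r_squared: float
    r_squared_clamped: bool = False

    def as_dict(self) -> dict:
        return {"family": self.family, "params": dict(self.params), "sse": self.sse,
                "r_squared": self.r_squared, "r_squared_clamped": self.r_squared_clamped}


def summary_stats(x) -> SummaryStats:
    """Unbiased sample moments; adds the dispersion index for count data."""
    is_counts = isinstance(x, CountSeries)
    values = np.asarray(x.counts if is_counts else x, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for summary statistics")
    mean = float(values.mean())
    var = float(values.var(ddof=1))
    std = float(np.sqrt(var))
    return SummaryStats(
        mean=mean,
        median=float(np.median(values)),
        variance=var,
        std=std,
        cv=std / mean if mean > 0 else float("nan"),
        dispersion=(var / mean if mean > 0 else float("nan")) if is_counts else None,
    )


def interspike_bin_width(mu: float, sigma: float, n: int) -> float:
    """Histogram bin width for interspike data.

    h = (mu + 2.85 sigma)/sqrt(N) for N < 1000; for larger samples the
    scaled Scott's rule h = (mu + 2.85 sigma)(1/(2 sqrt(N)) + 1/(2 N^{1/3})).
    """
    if mu <= 0 or sigma < 0 or n < 2:
        raise ValueError("need mu > 0, sigma >= 0, n >= 2")
    base = mu + 2.85 * sigma
    if n < 1000:
        return base / np.sqrt(n)
    return base * (0.5 / np.sqrt(n) + 0.5 / n ** (1.0 / 3.0))


def make_histogram(values, h: float) -> HistogramData:
    """Equal-width histogram from 0 to ceil(max/h)*h with bin width h.

    Bins are right-closed, (jh, (j+1)h], matching positive interspike data
    (a value exactly at an edge belongs to the bin it terminates).
    """
    values = np.asarray(values, dtype=float)
    if h <= 0:
        raise ValueError("bin width must be positive")
    n_bins = max(int(np.ceil(values.max() / h)), 1) if values.size else 1
    edges = np.arange(n_bins + 1) * h
    idx = np.clip(np.searchsorted(edges, values, side="left") - 1, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    return HistogramData(bin_edges=edges, counts=counts)


def count_frequencies(series: CountSeries) -> CountHistogram:
    """Empirical pmf of the window counts on k = 0..max(counts)."""
    counts = series.counts
    k = np.arange(counts.max() + 1)
    freq = np.bincount(counts, minlength=k.size).astype(float)
    return CountHistogram(k=k, frequency=freq / freq.sum(), window=series.window)


# ---------------------------------------------------------------------------
# candidate densities / pmfs


def exponential_pdf(dt, lam):
    """f(δt) = λ exp(-λ δt) — interspike density of a Poisson train."""
    if lam <= 0:
        raise ValueError("lam must be positive")
    dt = np.asarray(dt, dtype=float)
    return lam * np.exp(-lam * dt)


def poisson_pmf(k, lam_t):
    """P(k) = (λT)^k e^{-λT} / k!, evaluated in log space."""
    if lam_t <= 0:
        raise ValueError("lam_t must be positive")
    k = np.asarray(k)
    return np.exp(k * np.log(lam_t) - lam_t - gammaln(k + 1.0))


def gamma_pdf(dt, p, theta):
    """Two-parameter gamma density with shape p and scale theta (mean pθ)."""
    if p <= 0 or theta <= 0:
        raise ValueError("p and theta must be positive")
    dt = np.asarray(dt, dtype=float)
    out = np.zeros_like(dt, dtype=float)
    pos = dt > 0
    x = dt[pos]
    out[pos] = np.exp((p - 1.0) * np.log(x) - x / theta - p * np.log(theta) - gammaln(p))
    return out if out.ndim else float(out)


def _reg_lower_gamma(a, x):
    """Regularized lower incomplete gamma with the convention G(0, x) = 1."""
    a = np.asarray(a, dtype=float)
    out = np.where(a > 0, gammainc(np.where(a > 0, a, 1.0), x), 1.0)
    return out


def gamma_count_pmf(k, p, beta, t_window):
    """Gamma-count pmf P(k) = G(pk, βT) - G(pk + p, βT).

    Window-count distribution of a gamma renewal process with interval
    shape p and rate β = 1/θ over a window of length T.
    """
    if p <= 0 or beta <= 0 or t_window <= 0:
        raise ValueError("p, beta and t_window must be positive")
    k = np.asarray(k, dtype=float)
    x = beta * t_window
    return _reg_lower_gamma(p * k, x) - _reg_lower_gamma(p * k + p, x)


def lognormal_pdf(dt, log_mean, log_sd):
    """Log-normal density; the median is exp(log_mean)."""
    if log_sd <= 0:
        raise ValueError("log_sd must be positive")
    dt = np.asarray(dt, dtype=float)
    out = np.zeros_like(dt, dtype=float)
    pos = dt > 0
    x = dt[pos]
    z = (np.log(x) - log_mean) / log_sd
    out[pos] = np.exp(-0.5 * z * z) / (x * log_sd * np.sqrt(2.0 * np.pi))
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# fitting

_ISI_FAMILIES = ("exponential", "gamma", "lognormal")
_COUNT_FAMILIES = ("poisson", "gamma_count")


def _moment_start(hist: HistogramData):
    """Moment estimates of (mean, var) from a density histogram."""
    w = hist.density * hist.widths
    if w.sum() <= 0:
        raise ValueError("empty histogram")
    w = w / w.sum()
    mu = float(np.sum(hist.centers * w))
    var = float(np.sum((hist.centers - mu) ** 2 * w))
    return mu, max(var, 1e-12)


def _finish_fit(family, names, sol, y) -> FitResult:
    if not sol.success:
        raise RuntimeError(f"{family} fit did not converge (last iterate {sol.x})")
    sse = float(2.0 * sol.cost)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - sse / sst if sst > 0 else 1.0
    clamped = r2 < 0
    return FitResult(family=family, params=dict(zip(names, map(float, sol.x))),
                     sse=sse, r_squared=max(r2, 0.0), r_squared_clamped=clamped)


def fit_histogram(hist, family: str) -> FitResult:
    """Least-squares fit of a model family to a density-normalized histogram.

    Interspike families (exponential, gamma, lognormal) are fitted with the
    pdf evaluated at bin centers against the unit-area density; count
    families (poisson, gamma_count) are fitted with the pmf at the integer
    counts against the empirical frequencies.  Empty bins stay in the SSE.
    Moment-based starts keep the gamma fit in its basin.
    """
    if family in _ISI_FAMILIES:
        if not isinstance(hist, HistogramData):
            raise TypeError(f"{family} expects an interspike HistogramData")
        if np.count_nonzero(hist.counts) < 3:
            raise ValueError("need at least 3 non-empty bins")
        y = hist.density
        x = hist.centers
        mu, var = _moment_start(hist)
        if family == "exponential":
            model = lambda q: exponential_pdf(x, q[0])
            x0, names, bounds = [1.0 / mu], ["lam"], ([1e-9], [np.inf])
        elif family == "gamma":
            model = lambda q: gamma_pdf(x, q[0], q[1])
            x0, names = [mu * mu / var, var / mu], ["p", "theta"]
            bounds = ([1e-3, 1e-9], [1e3, np.inf])
        else:
            s2 = np.log(1.0 + var / mu**2)
            model = lambda q: lognormal_pdf(x, q[0], q[1])
            x0, names = [np.log(mu) - 0.5 * s2, np.sqrt(s2)], ["log_mean", "log_sd"]
            bounds = ([-np.inf, 1e-9], [np.inf, np.inf])
    elif family in _COUNT_FAMILIES:
        if not isinstance(hist, CountHistogram):
            raise TypeError(f"{family} expects a CountHistogram")
        y = hist.frequency
        k = hist.k
        mean = hist.mean
        var = float(np.sum((k - mean) ** 2 * y))
        if family == "poisson":
            model = lambda q: poisson_pmf(k, q[0])
            x0, names, bounds = [max(mean, 1e-6)], ["lam_t"], ([1e-9], [np.inf])
        else:
            p0 = max(mean / max(var, 1e-9), 1e-2)  # underdispersed counts -> p > 1
            model = lambda q: gamma_count_pmf(k, q[0], q[1], hist.window)
            x0, names = [p0, p0 * mean / hist.window], ["p", "beta"]
            bounds = ([1e-3, 1e-9], [1e3, np.inf])
    else:
        raise ValueError(f"unknown family {family!r}")

    sol = least_squares(lambda q: model(q) - y, x0, bounds=bounds, max_nfev=20000)
    return _finish_fit(family, names, sol, y)


def combined_fit(isi_hist: HistogramData, count_hist: CountHistogram,
                 model: str) -> FitResult:
    """One parameter set fitted jointly to the ISI and count histograms.

    ``poisson_pair`` shares λ between the exponential pdf and the Poisson
    pmf (with λT = λ·window); ``gamma_pair`` shares (p, θ) between the
    gamma pdf and the gamma-count pmf (β = 1/θ).  Both histograms are
    probability-normalized, making the two SSE terms commensurate, and the
    total SSE_isi + SSE_count is minimized.
    """
    y_isi = isi_hist.density
    x = isi_hist.centers
    y_cnt = count_hist.frequency
    k = count_hist.k
    w = count_hist.window
    mu, var = _moment_start(isi_hist)

    if model == "poisson_pair":
        names, x0, bounds = ["lam"], [1.0 / mu], ([1e-9], [np.inf])

        def residuals(q):
            return np.concatenate([exponential_pdf(x, q[0]) - y_isi,
                                   poisson_pmf(k, q[0] * w) - y_cnt])
    elif model == "gamma_pair":
        names, x0 = ["p", "theta"], [mu * mu / var, var / mu]
        bounds = ([1e-3, 1e-9], [1e3, np.inf])

        def residuals(q):
            return np.concatenate([gamma_pdf(x, q[0], q[1]) - y_isi,
                                   gamma_count_pmf(k, q[0], 1.0 / q[1], w) - y_cnt])
    else:
        raise ValueError(f"unknown combined model {model!r}")

    sol = least_squares(residuals, x0, bounds=bounds, max_nfev=20000)
    y_all = np.concatenate([y_isi, y_cnt])
    return _finish_fit(model, names, sol, y_all)


def model_report(seq: SpikeSequence, count_window: float | None = None) -> dict:
    """Full renewal-statistics chain on one sequence, machine readable.

    Interspike histogram at the sample-size-dependent bin width, counts at
    ΔT = 4μ (or a supplied window), exponential/gamma fits to the ISI
    density, Poisson/gamma-count fits to the count frequencies, and the
    count dispersion index.
    """
    if seq.n < 100:
        raise ValueError("model_report needs at least 100 spikes")
    isi = interspike_times(seq)
    stats = summary_stats(isi)
    h = interspike_bin_width(stats.mean, stats.std, isi.size)
    isi_hist = make_histogram(isi, h)
    window = 4.0 * stats.mean if count_window is None else count_window
    counts = spike_counts(seq, window)
    cstats = summary_stats(counts)
    chist = count_frequencies(counts)
    report = {
        "n_spikes": seq.n,
        "duration": seq.duration,
        "interspike": stats.as_dict(),
        "counts": cstats.as_dict(),
        "binning": {"h": h, "count_window": window},
        "fits": {
            "exponential": fit_histogram(isi_hist, "exponential").as_dict(),
            "gamma": fit_histogram(isi_hist, "gamma").as_dict(),
            "poisson": fit_histogram(chist, "poisson").as_dict(),
            "gamma_count": fit_histogram(chist, "gamma_count").as_dict(),
        },
        "dispersion": cstats.dispersion,
    }
    return report
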