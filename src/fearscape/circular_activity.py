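"""Diel activity densities and Ridout-Linkie overlap coefficients.

Clock times are mapped onto the circle (24 h = 2*pi) and each species'
activity pattern is estimated by a von Mises kernel density. The overlap
coefficient Delta between two activity densities f and g,

    Delta = integral over the day of min(f, g),

ranges from 0 (fully partitioned schedules) to 1 (identical schedules).
Two estimators are provided:

* ``delta1`` — trapezoidal integration of min(f_hat, g_hat) on a grid,
  recommended for small samples;
* ``delta4`` — the average over the observed points of the clipped density
  ratios, recommended for larger samples.

Percentile bootstrap CIs, circular mean activity times with wraparound-aware
CIs, and the low/moderate/high categorisation complete the surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, time

import numpy as np
from scipy import optimize, special

__all__ = [
    "AngularSample",
    "ActivityDensity",
    "OverlapResult",
    "InsufficientSampleError",
    "UndefinedMeanError",
    "to_radians",
    "hours_to_radians",
    "radians_to_hours",
    "vonmises_kde",
    "kde_bandwidth",
    "delta1",
    "delta4",
    "estimate_overlap",
    "categorize_overlap",
    "circular_mean_time",
]

TWO_PI = 2.0 * np.pi


class InsufficientSampleError(ValueError):
    """Too few observations for the requested estimate."""


class UndefinedMeanError(ValueError):
    """The circular mean does not exist (resultant length ~ 0)."""


@dataclass(frozen=True)
class AngularSample:
    """Detection times of one species as angles on [0, 2*pi)."""

    angles: np.ndarray
    species: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, float)
        if np.any((a < 0) | (a >= TWO_PI)):
            raise ValueError("angles must lie in [0, 2*pi)")
        object.__setattr__(self, "angles", a)

    @property
    def n(self) -> int:
        return len(self.angles)


@dataclass(frozen=True)
class ActivityDensity:
    """Circular KDE evaluated on an equally spaced grid over [0, 2*pi)."""

    grid: np.ndarray
    values: np.ndarray
    concentration: float
    sample: AngularSample | None = None

    def __call__(self, theta) -> np.ndarray:
        """Density at arbitrary angles by periodic linear interpolation.

        The 512-point grid resolves any realistic diel bandwidth; exact
        kernel-mixture evaluation is available via :meth:`exact`.
        """
        theta = np.asarray(theta, float) % TWO_PI
        g = np.append(self.grid, TWO_PI)
        v = np.append(self.values, self.values[0])
        return np.interp(theta, g, v)

    def exact(self, theta) -> np.ndarray:
        """Exact kernel mixture evaluated at arbitrary angles."""
        if self.sample is None:
            raise ValueError("density has no attached sample to evaluate from")
        return _vm_mixture(np.asarray(theta, float), self.sample.angles,
                           self.concentration)


def to_radians(timestamp: datetime | time) -> float:
    """Clock time -> angle: 2*pi * (seconds since midnight) / 86400."""
    t = timestamp.time() if isinstance(timestamp, datetime) else timestamp
    secs = t.hour * 3600 + t.minute * 60 + t.second + t.microsecond / 1e6
    return TWO_PI * secs / 86400.0


def hours_to_radians(hours) -> np.ndarray:
    return np.asarray(hours, float) % 24.0 * TWO_PI / 24.0


def radians_to_hours(theta) -> np.ndarray:
    return np.asarray(theta, float) % TWO_PI * 24.0 / TWO_PI


def _vm_mixture(theta: np.ndarray, centers: np.ndarray, kappa: float) -> np.ndarray:
    # mean of vM(theta; center_i, kappa); evaluated via the closed form to
    # avoid n_grid x n broadcasting blowups for large samples
    theta = np.atleast_1d(theta)
    out = np.zeros_like(theta, dtype=float)
    # exp(k cos d)/I0(k) computed as exp(k(cos d - 1))/i0e(k): stable for any k
    norm = 1.0 / (TWO_PI * special.i0e(kappa))
    block = max(1, int(2e6 // max(len(centers), 1)))
    for i in range(0, len(theta), block):
        t = theta[i : i + block, None]
        out[i : i + block] = norm * np.exp(
            kappa * (np.cos(t - centers[None, :]) - 1.0)
        ).mean(axis=1)
    return out


def _kappa_ml(angles: np.ndarray) -> float:
    """Maximum-likelihood von Mises concentration from the resultant length."""
    c, s = np.cos(angles).mean(), np.sin(angles).mean()
    rbar = float(np.hypot(c, s))
    if rbar >= 1.0 - 1e-12:
        return 1e6
    if rbar < 1e-12:
        return 0.0

    def f(k):
        return special.i1e(k) / special.i0e(k) - rbar

    try:
        return float(optimize.brentq(f, 1e-8, 1e6))
    except ValueError:
        return 1e6


def kde_bandwidth(angles: np.ndarray, adjust: float = 1.0) -> float:
    """Plug-in kernel concentration for the circular KDE.

    The sample's ML concentration ``kappa_hat`` enters the standard
    n^(2/5)-scaled plug-in rule (asymptotic MISE minimiser for a von Mises
    reference density)

        kappa* = [ 3 n kappa_hat^2 I_2(2 kappa_hat)
                   / (4 sqrt(pi) I_0(kappa_hat)^2) ]^(2/5),

    multiplied by ``adjust`` (0.8 for Delta-hat-1, 1.0 for Delta-hat-4 by
    convention).
    """
    angles = np.asarray(angles, float)
    n = len(angles)
    k = _kappa_ml(angles)
    if k < 1e-8:
        return max(adjust * 0.5, 1e-3)
    # exponentially scaled Bessels: ive(2,2k)/i0e(k)^2 carries no residual
    num = 3.0 * n * k**2 * special.ive(2, 2 * k)
    den = 4.0 * np.sqrt(np.pi) * special.i0e(k) ** 2
    # cap at 1e6, beyond which the KDE is numerically a point mass anyway
    val = np.exp(min(np.log(num / den) * 0.4, np.log(1e6)))
    return float(adjust * val)


def vonmises_kde(
    sample: AngularSample,
    concentration: float | None = None,
    grid_size: int = 512,
    adjust: float = 1.0,
) -> ActivityDensity:
    """Von Mises kernel density estimate of a diel activity pattern.

    ``density(theta) = (1/n) sum_i vM(theta; theta_i, kappa)`` with the
    plug-in bandwidth when ``concentration`` is not supplied. The returned
    grid covers [0, 2*pi) inclusive of 0, exclusive of 2*pi; periodicity
    makes the value at 2*pi equal the value at 0.
    """
    if sample.n < 2:
        raise InsufficientSampleError(
            f"need >= 2 observations for a KDE, got {sample.n}"
        )
    kappa = (kde_bandwidth(sample.angles, adjust=adjust)
             if concentration is None else float(concentration))
    grid = np.linspace(0.0, TWO_PI, grid_size, endpoint=False)
    values = _kde_on_grid(sample.angles, kappa, grid_size)
    # renormalise: guards the unit-integral invariant against binning error
    values = values / _trapz_circular(values, grid)
    return ActivityDensity(grid, values, kappa, sample)


def _kde_on_grid(angles: np.ndarray, kappa: float, m: int) -> np.ndarray:
    """KDE on a regular circular grid via linear binning + FFT convolution.

    Spectrally accurate for any bandwidth the plug-in rule produces at
    realistic sample sizes; orders of magnitude faster than direct mixture
    evaluation, which matters inside the bootstrap.
    """
    n = len(angles)
    step = TWO_PI / m
    pos = (angles % TWO_PI) / step
    lo = np.floor(pos).astype(np.intp) % m
    frac = pos - np.floor(pos)
    counts = (np.bincount(lo, 1.0 - frac, minlength=m)
              + np.bincount((lo + 1) % m, frac, minlength=m))
    grid = np.arange(m) * step
    kernel = np.exp(kappa * (np.cos(grid) - 1.0)) / (TWO_PI * special.i0e(kappa))
    dens = np.fft.irfft(np.fft.rfft(counts) * np.fft.rfft(kernel), m) / n
    return np.maximum(dens, 0.0)


def _trapz_circular(values: np.ndarray, grid: np.ndarray) -> float:
    # close the circle: append the 0-point at 2*pi
    g = np.append(grid, TWO_PI)
    v = np.append(values, values[0])
    return float(np.trapezoid(v, g))


def delta1(f: ActivityDensity, g: ActivityDensity) -> float:
    """Grid estimator: trapezoidal integral of min(f, g) over the circle."""
    if len(f.grid) != len(g.grid) or not np.allclose(f.grid, g.grid):
        raise ValueError("densities must share the same grid")
    return min(1.0, _trapz_circular(np.minimum(f.values, g.values), f.grid))


def delta4(
    sample_a: AngularSample,
    sample_b: AngularSample,
    f: ActivityDensity | None = None,
    g: ActivityDensity | None = None,
) -> float:
    """Point estimator: averaged clipped density ratios at the observed times.

    ``0.5 * [ mean_i min(1, g(a_i)/f(a_i)) + mean_j min(1, f(b_j)/g(b_j)) ]``
    with f fitted to sample_a and g to sample_b.
    """
    if f is None:
        f = vonmises_kde(sample_a)
    if g is None:
        g = vonmises_kde(sample_b)
    fa, ga = f(sample_a.angles), g(sample_a.angles)
    fb, gb = f(sample_b.angles), g(sample_b.angles)
    if np.any(fa <= 0) or np.any(gb <= 0):
        raise ValueError("zero fitted density at an observed point")
    term_a = np.minimum(1.0, ga / fa).mean()
    term_b = np.minimum(1.0, fb / gb).mean()
    return float(0.5 * (term_a + term_b))


def categorize_overlap(delta: float) -> str:
    """low [0, 0.5) / moderate [0.5, 0.75] / high (0.75, 1]."""
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"overlap coefficient {delta} outside [0, 1]")
    if delta < 0.5:
        return "low"
    if delta <= 0.75:
        return "moderate"
    return "high"


@dataclass(frozen=True)
class OverlapResult:
    """Overlap estimate with bootstrap CI, category and mean activity times."""

    delta: float
    estimator: str
    ci_low: float
    ci_high: float
    n_boot: int
    category: str
    n_a: int
    n_b: int
    mean_time_a: tuple[float, float, float] | None = None
    mean_time_b: tuple[float, float, float] | None = None


def _point_estimate(a: AngularSample, b: AngularSample, estimator: str,
                    grid_size: int) -> float:
    if estimator == "Dhat1":
        f = vonmises_kde(a, grid_size=grid_size, adjust=0.8)
        g = vonmises_kde(b, grid_size=grid_size, adjust=0.8)
        return delta1(f, g)
    f = vonmises_kde(a, grid_size=grid_size, adjust=1.0)
    g = vonmises_kde(b, grid_size=grid_size, adjust=1.0)
    return delta4(a, b, f, g)


def estimate_overlap(
    sample_a: AngularSample,
    sample_b: AngularSample,
    small_threshold: int = 75,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
    grid_size: int = 512,
) -> OverlapResult:
    """Overlap coefficient with percentile-bootstrap 95% CI.

    Delta-hat-1 is used when the smaller sample has fewer than
    ``small_threshold`` detections, Delta-hat-4 otherwise. The bootstrap
    resamples each species' detections with replacement at its own size,
    refits both densities and recomputes Delta; the CI is the (2.5, 97.5)
    percentile band clipped to [0, 1].
    """
    if sample_a.n < 10 or sample_b.n < 10:
        raise InsufficientSampleError(
            f"need >= 10 observations per sample, got ({sample_a.n}, {sample_b.n})"
        )
    rng = np.random.default_rng(seed)
    estimator = ("Dhat1" if min(sample_a.n, sample_b.n) < small_threshold
                 else "Dhat4")
    delta = _point_estimate(sample_a, sample_b, estimator, grid_size)

    boots = np.empty(n_boot)
    for i in range(n_boot):
        ra = AngularSample(rng.choice(sample_a.angles, sample_a.n, replace=True))
        rb = AngularSample(rng.choice(sample_b.angles, sample_b.n, replace=True))
        boots[i] = _point_estimate(ra, rb, estimator, grid_size)
    lo, hi = np.percentile(boots, [2.5, 97.5])
    lo = float(np.clip(min(lo, delta), 0.0, 1.0))
    hi = float(np.clip(max(hi, delta), 0.0, 1.0))

    mt_a = circular_mean_time(sample_a, n_boot=n_boot, seed=rng)
    mt_b = circular_mean_time(sample_b, n_boot=n_boot, seed=rng)
    return OverlapResult(
        delta=float(np.clip(delta, 0.0, 1.0)), estimator=estimator,
        ci_low=lo, ci_high=hi, n_boot=n_boot,
        category=categorize_overlap(float(np.clip(delta, 0.0, 1.0))),
        n_a=sample_a.n, n_b=sample_b.n, mean_time_a=mt_a, mean_time_b=mt_b,
    )


def _circ_mean_hours(angles: np.ndarray) -> float:
    c, s = np.cos(angles).mean(), np.sin(angles).mean()
    r = np.hypot(c, s)
    if r < 1e-10:
        raise UndefinedMeanError("resultant length ~ 0: circular mean undefined")
    h = float(radians_to_hours(np.arctan2(s, c)))
    return 0.0 if h >= 24.0 - 1e-9 else h


def circular_mean_time(
    sample: AngularSample,
    n_boot: int = 1000,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float, float]:
    """Circular mean activity time in hours with a bootstrap 95% CI.

    The CI respects wraparound: bootstrap means are re-centred on the point
    estimate before taking percentiles, so an 0.2 h mean with mass on both
    sides of midnight gets a (23.9, 0.5)-style interval rather than (0, 24).
    Returns ``(mean, ci_low, ci_high)``, each in [0, 24).
    """
    if sample.n < 2:
        raise InsufficientSampleError("need >= 2 observations")
    mean = _circ_mean_hours(sample.angles)
    rng = np.random.default_rng(seed)
    devs = np.empty(n_boot)
    for i in range(n_boot):
        res = rng.choice(sample.angles, sample.n, replace=True)
        try:
            m = _circ_mean_hours(res)
        except ValueError:
            m = mean
        devs[i] = (m - mean + 12.0) % 24.0 - 12.0  # signed deviation, hours
    lo, hi = np.percentile(devs, [2.5, 97.5])
    return (mean, (mean + lo) % 24.0, (mean + hi) % 24.0)


def true_overlap(density_a, density_b, n_points: int = 20001) -> float:
    """Quadrature overlap of two true circular densities (callables on radians)."""
    theta = np.linspace(0.0, TWO_PI, n_points)
    fa, fb = density_a(theta), density_b(theta)
    return float(np.trapezoid(np.minimum(fa, fb), theta))
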