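"""Growth law, mean-field fixed points, linearized noise, and the simulator.

The colony grows exponentially between the detection and saturation densities,
so the fraction of time spent at density rho is p(rho) ~ 1/rho.  At fixed
density the AI concentration equilibrates quasi-statically (tau_a << tau_m) to
``a = tau_a * rho * <f_ext(m_i)>`` while each cell's MP abundance relaxes as

    dm_i = (-m_i/tau_m + rate(a) * f_int(m_i)) dt + sqrt(2) * sigma_m dW_i ,

whose deterministic fixed point defines the monotone mean mappings a_bar(rho)
and m_bar(rho).  Linearizing around the fixed point gives the stationary MP
variance, which internal feedback rescales by the factor
``F*/F = (1 - m f_int'(m)/f_int(m))^-1`` along with the effective correlation
time ``tau* = tau_m F*/F``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator
from scipy.optimize import brentq

from .params import BareExpressionRate, QSParameters, RegulationModel

__all__ = [
    "GrowthProfile",
    "FeedbackCurve",
    "FeedbackPair",
    "MeanFieldMaps",
    "ChannelStats",
    "SimulationEnsemble",
    "MultistabilityError",
    "StabilityError",
    "growth_trajectory",
    "density_distribution",
    "solve_fixed_point",
    "mean_field_maps",
    "linearized_stats",
    "simulate_population",
    "ensemble_statistics",
]


class MultistabilityError(RuntimeError):
    """The self-consistency relation has multiple roots."""


class StabilityError(ValueError):
    """The internal feedback violates the monotonicity/stability constraint."""


# ---------------------------------------------------------------------------
# growth law and input distribution


@dataclass(frozen=True)
class GrowthProfile:
    """Exponential density time course and the induced input distribution.

    ``density(t) = rho_minus * (rho_plus/rho_minus)^(t/T)`` maps uniform time
    onto ``p(rho) = 1/(rho * ln(rho_plus/rho_minus))``.
    """

    rho_minus: float
    rho_plus: float
    T: float

    @property
    def log_ratio(self) -> float:
        return math.log(self.rho_plus / self.rho_minus)

    @property
    def gamma(self) -> float:
        return self.log_ratio / self.T

    def density(self, t):
        t = np.asarray(t, dtype=float)
        if np.any(t < -1e-12) or np.any(t > self.T * (1 + 1e-12)):
            raise ValueError(f"time outside [0, {self.T}]")
        out = self.rho_minus * (self.rho_plus / self.rho_minus) ** (t / self.T)
        return float(out) if out.ndim == 0 else out

    def time_of_density(self, rho):
        rho = np.asarray(rho, dtype=float)
        out = self.T * np.log(rho / self.rho_minus) / self.log_ratio
        return float(out) if out.ndim == 0 else out

    def pdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        out = np.where(
            (rho >= self.rho_minus) & (rho <= self.rho_plus),
            1.0 / (rho * self.log_ratio),
            0.0,
        )
        return float(out) if out.ndim == 0 else out

    def cdf(self, rho):
        rho = np.asarray(rho, dtype=float)
        out = np.clip(np.log(rho / self.rho_minus) / self.log_ratio, 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def ppf(self, u):
        u = np.asarray(u, dtype=float)
        out = self.rho_minus * np.exp(u * self.log_ratio)
        return float(out) if out.ndim == 0 else out

    def entropy_bits(self) -> float:
        """Continuous entropy of p(rho) in bits, by quadrature."""
        val, _ = quad(
            lambda r: -self.pdf(r) * math.log2(self.pdf(r)),
            self.rho_minus,
            self.rho_plus,
            limit=200,
        )
        return val


class TabulatedGrowthProfile(GrowthProfile):
    """Growth profile for a non-exponential density time course.

    Built from samples of the density trajectory lambda(t); the input
    distribution is the push-forward of uniform time through it.
    """

    def __init__(self, t: np.ndarray, rho: np.ndarray):
        t = np.asarray(t, float)
        rho = np.asarray(rho, float)
        if np.any(np.diff(rho) <= 0):
            raise ValueError("density trajectory must be strictly increasing")
        object.__setattr__(self, "rho_minus", float(rho[0]))
        object.__setattr__(self, "rho_plus", float(rho[-1]))
        object.__setattr__(self, "T", float(t[-1] - t[0]))
        object.__setattr__(self, "_lam", PchipInterpolator(t - t[0], rho))
        object.__setattr__(self, "_cdf", PchipInterpolator(rho, (t - t[0]) / self.T))
        object.__setattr__(self, "_ppf", PchipInterpolator((t - t[0]) / self.T, rho))

    def density(self, t):
        return self._lam(t)

    def time_of_density(self, rho):
        return self._cdf(rho) * self.T

    def cdf(self, rho):
        return np.clip(self._cdf(rho), 0.0, 1.0)

    def ppf(self, u):
        return self._ppf(u)

    def pdf(self, rho):
        return self._cdf.derivative()(rho)


def growth_trajectory(params: QSParameters, t):
    """Cell density at time ``t`` of the growth period."""
    return density_distribution(params).density(t)


def density_distribution(params: QSParameters) -> GrowthProfile:
    """Growth profile and input density distribution for a parameter set."""
    return GrowthProfile(params.rho_minus, params.rho_plus, params.T)


# ---------------------------------------------------------------------------
# feedback curves


class FeedbackCurve:
    """A positive feedback curve f(m) together with its derivative.

    Analytic derivatives are used when supplied; tabulated curves are
    interpolated with a monotone cubic (PCHIP) spline; bare callables fall
    back to a central finite difference.
    """

    def __init__(self, f: Callable, df: Callable | None = None, name: str = ""):
        self._f = f
        self._df = df
        self.name = name

    def __call__(self, m):
        out = np.asarray(self._f(np.asarray(m, dtype=float)), dtype=float)
        return float(out) if out.ndim == 0 else out

    def derivative(self, m):
        m = np.asarray(m, dtype=float)
        if self._df is not None:
            out = np.asarray(self._df(m), dtype=float)
        else:
            eps = 1e-6 * np.maximum(np.abs(m), 1.0)
            out = (self._f(m + eps) - self._f(m - eps)) / (2 * eps)
        return float(out) if np.ndim(out) == 0 else out

    @classmethod
    def constant(cls, value: float, name: str = "") -> "FeedbackCurve":
        return cls(lambda m: np.full_like(np.asarray(m, float), value),
                   lambda m: np.zeros_like(np.asarray(m, float)), name=name)

    @classmethod
    def power_law(cls, exponent: float, m_ref: float, value_at_ref: float = 1.0,
                  name: str = "") -> "FeedbackCurve":
        """f(m) = value_at_ref * (m/m_ref)^exponent."""
        s = exponent
        return cls(
            lambda m: value_at_ref * (np.asarray(m, float) / m_ref) ** s,
            lambda m: value_at_ref * s / m_ref
            * (np.asarray(m, float) / m_ref) ** (s - 1),
            name=name,
        )

    @classmethod
    def from_table(cls, m: np.ndarray, values: np.ndarray,
                   name: str = "") -> "FeedbackCurve":
        spl = PchipInterpolator(np.asarray(m, float), np.asarray(values, float))
        return cls(spl, spl.derivative(), name=name)


@dataclass(frozen=True)
class FeedbackPair:
    """External (AI output) and internal (MP self-regulation) feedbacks."""

    f_ext: FeedbackCurve
    f_int: FeedbackCurve

    @classmethod
    def no_feedback(cls, params: QSParameters) -> "FeedbackPair":
        """Constant AI output anchored at the low-density boundary, f_int = 1."""
        f0 = params.a_minus / (params.tau_a * params.rho_minus)
        return cls(
            f_ext=FeedbackCurve.constant(f0, name="f_ext=const"),
            f_int=FeedbackCurve.constant(1.0, name="f_int=1"),
        )

    def check_stability(self, m_grid: np.ndarray) -> None:
        """Raise if f_int'(m)/f_int(m) >= 1/m anywhere on the grid."""
        f = self.f_int(m_grid)
        df = self.f_int.derivative(m_grid)
        if np.any(f <= 0):
            raise StabilityError("f_int must be positive")
        if np.any(m_grid * df / f >= 1.0):
            raise StabilityError(
                "internal feedback violates f_int'(m)/f_int(m) < 1/m "
                "(multistable channel)"
            )


# ---------------------------------------------------------------------------
# fixed points and mean-field maps


def solve_fixed_point(
    params: QSParameters,
    rate: BareExpressionRate,
    feedbacks: FeedbackPair,
    rho: float,
    m_bracket: tuple[float, float] | None = None,
    n_scan: int = 256,
) -> tuple[float, float]:
    """Joint fixed point (a_bar, m_bar) of the deterministic dynamics.

    Solves ``a = tau_a * rho * f_ext(m)`` and
    ``m = tau_m * rate(a) * f_int(m)``.  The self-consistency residual is
    scanned on a grid first; more than one sign change means the channel is
    multistable, which is rejected explicitly rather than silently picking a
    branch.
    """
    if m_bracket is None:
        m_lo = 1e-6 * params.m_minus
        m_hi = 50.0 * params.m_plus
    else:
        m_lo, m_hi = m_bracket

    def residual(m):
        a = params.tau_a * rho * feedbacks.f_ext(m)
        return params.tau_m * rate(a) * feedbacks.f_int(m) - m

    grid = np.geomspace(m_lo, m_hi, n_scan)
    res = np.array([residual(m) for m in grid])
    sign = np.sign(res)
    crossings = np.nonzero(np.diff(sign) != 0)[0]
    if len(crossings) == 0:
        raise RuntimeError(
            f"no fixed point found for rho={rho:g} in m-bracket "
            f"[{m_lo:g}, {m_hi:g}]"
        )
    if len(crossings) > 1:
        raise MultistabilityError(
            f"{len(crossings)} fixed points detected at rho={rho:g}; "
            "the channel is multistable"
        )
    i = crossings[0]
    m_bar = brentq(residual, grid[i], grid[i + 1], xtol=1e-12, rtol=1e-14)
    a_bar = params.tau_a * rho * feedbacks.f_ext(m_bar)
    return float(a_bar), float(m_bar)


class MeanFieldMaps:
    """Monotone mean mappings a_bar(rho), m_bar(rho) with derivatives."""

    def __init__(
        self,
        rho_range: tuple[float, float],
        a_bar: Callable,
        m_bar: Callable,
        a_bar_prime: Callable,
        m_bar_prime: Callable,
    ):
        self.rho_range = rho_range
        self._a = a_bar
        self._m = m_bar
        self._da = a_bar_prime
        self._dm = m_bar_prime

    def a_bar(self, rho):
        return self._a(rho)

    def m_bar(self, rho):
        return self._m(rho)

    def a_bar_prime(self, rho):
        return self._da(rho)

    def m_bar_prime(self, rho):
        return self._dm(rho)

    @property
    def m_range(self) -> tuple[float, float]:
        lo, hi = self.rho_range
        return float(self.m_bar(lo)), float(self.m_bar(hi))

    @classmethod
    def from_samples(
        cls, rho: np.ndarray, a_bar: np.ndarray, m_bar: np.ndarray
    ) -> "MeanFieldMaps":
        """Monotone-spline maps through fixed-point samples (log-rho knots)."""
        lrho = np.log(rho)
        if np.any(np.diff(a_bar) <= 0) or np.any(np.diff(m_bar) <= 0):
            raise ValueError("mean mappings must be strictly increasing")
        a_spl = PchipInterpolator(lrho, a_bar)
        m_spl = PchipInterpolator(lrho, m_bar)
        da = a_spl.derivative()
        dm = m_spl.derivative()
        return cls(
            rho_range=(float(rho[0]), float(rho[-1])),
            a_bar=lambda r: a_spl(np.log(r)),
            m_bar=lambda r: m_spl(np.log(r)),
            a_bar_prime=lambda r: da(np.log(r)) / np.asarray(r, float),
            m_bar_prime=lambda r: dm(np.log(r)) / np.asarray(r, float),
        )


def mean_field_maps(
    params: QSParameters,
    rate: BareExpressionRate,
    feedbacks: FeedbackPair,
    n: int = 257,
) -> MeanFieldMaps:
    """Solve the fixed points on a log-spaced density grid and interpolate."""
    rho = np.geomspace(params.rho_minus, params.rho_plus, n)
    a_vals = np.empty(n)
    m_vals = np.empty(n)
    for i, r in enumerate(rho):
        a_vals[i], m_vals[i] = solve_fixed_point(params, rate, feedbacks, r)
    return MeanFieldMaps.from_samples(rho, a_vals, m_vals)


# ---------------------------------------------------------------------------
# linearized fluctuation statistics


@dataclass(frozen=True)
class ChannelStats:
    """Stationary fluctuation statistics of the linearized channel.

    ``sigma_sq(rho)`` is the stationary MP variance in nM^2,
    ``delta_rho(rho) = Sigma/m_bar'`` the channel resolution,
    ``F_star(m)`` the feedback-modified Fano function,
    ``tau_star(m) = tau_m F*/F`` the effective correlation time, and
    ``sigma_m(m)`` the Langevin noise amplitude evaluated at the mean.
    """

    sigma_sq: Callable = field(repr=False)
    delta_rho: Callable = field(repr=False)
    F_star: Callable = field(repr=False)
    tau_star: Callable = field(repr=False)
    sigma_m: Callable = field(repr=False)

    def sigma(self, rho):
        return np.sqrt(self.sigma_sq(rho))


def linearized_stats(
    params: QSParameters,
    model: RegulationModel,
    feedbacks: FeedbackPair,
    maps: MeanFieldMaps,
    n_check: int = 256,
) -> ChannelStats:
    """Feedback-modified noise statistics in the self-averaging AI limit.

    The internal feedback rescales the bare Fano function by
    ``(1 - m f_int'(m)/f_int(m))^-1``; positivity of that factor is the
    stability constraint and is checked over the operating range.
    """
    kappa = params.noise_scale

    def feedback_factor(m):
        m = np.asarray(m, dtype=float)
        f = feedbacks.f_int(m)
        df = feedbacks.f_int.derivative(m)
        return 1.0 - m * df / f

    m_lo, m_hi = maps.m_range
    check = feedback_factor(np.linspace(m_lo, m_hi, n_check))
    if np.any(check <= 0):
        raise StabilityError(
            "feedback-modified Fano factor is not positive over the operating "
            "range; the channel would be multistable"
        )

    def F_star(m):
        return model.fano(m, extrapolate=True) / feedback_factor(m)

    def sigma_sq(rho):
        m = maps.m_bar(rho)
        return F_star(m) * m / kappa

    def delta_rho(rho):
        return np.sqrt(sigma_sq(rho)) / maps.m_bar_prime(rho)

    def tau_star(m):
        return params.tau_m / feedback_factor(m)

    def sigma_m(m):
        m = np.asarray(m, dtype=float)
        return np.sqrt(model.fano(m, extrapolate=True) * m / (kappa * params.tau_m))

    return ChannelStats(
        sigma_sq=sigma_sq,
        delta_rho=delta_rho,
        F_star=F_star,
        tau_star=tau_star,
        sigma_m=sigma_m,
    )


# ---------------------------------------------------------------------------
# stochastic population simulator


@dataclass
class SimulationEnsemble:
    """Trajectories of a simulated colony.

    ``m`` has shape (n_times, n_cells); ``a`` and ``rho`` are the shared AI
    concentration and cell density; ``m_det`` is the deterministic companion
    mean at which the noise amplitude was evaluated.
    """

    t: np.ndarray
    m: np.ndarray
    a: np.ndarray
    rho: np.ndarray
    m_det: np.ndarray
    mode: str
    dt: float
    seed: int | None
    params: QSParameters

    @property
    def n_cells(self) -> int:
        return self.m.shape[1]


def simulate_population(
    params: QSParameters,
    rate: BareExpressionRate,
    feedbacks: FeedbackPair,
    model: RegulationModel,
    mode: str = "fixed_density",
    rho: float | None = None,
    N: int = 100,
    dt: float | None = None,
    t_max: float | None = None,
    seed: int | None = None,
    noise_scale: float = 1.0,
    record_every: int = 1,
) -> SimulationEnsemble:
    """Euler-Maruyama simulation of the coupled colony dynamics.

    The AI concentration is quasi-static: at every step
    ``a_t = tau_a * rho_t * mean_i f_ext(m_i)``.  The Langevin amplitude is
    evaluated at the instantaneous deterministic mean (integrated alongside),
    and trajectories are clipped at zero.  ``noise_scale`` multiplies the
    noise amplitude (0 gives the deterministic skeleton).
    """
    if mode not in ("fixed_density", "growth"):
        raise ValueError(f"unknown mode {mode!r}")
    if N < 1:
        raise ValueError("N must be >= 1")
    if dt is None:
        dt = params.tau_m / 500.0
    if dt > params.tau_m / 100.0:
        raise ValueError("dt too large: require dt <= tau_m/100")
    profile = density_distribution(params)
    if mode == "fixed_density":
        if rho is None:
            raise ValueError("fixed_density mode requires rho")
        if t_max is None:
            t_max = 50.0 * params.tau_m
        rho_of_t = lambda t: rho
        _, m0 = solve_fixed_point(params, rate, feedbacks, rho)
    else:
        if t_max is None:
            t_max = params.T
        rho_of_t = lambda t: profile.density(min(t, params.T))
        _, m0 = solve_fixed_point(params, rate, feedbacks, params.rho_minus)

    n_steps = int(np.ceil(t_max / dt))
    rng = np.random.default_rng(seed)
    m = np.full(N, m0, dtype=float)
    m_det = m0
    n_rec = n_steps // record_every + 1
    t_out = np.empty(n_rec)
    m_out = np.empty((n_rec, N))
    a_out = np.empty(n_rec)
    rho_out = np.empty(n_rec)
    det_out = np.empty(n_rec)

    k = 0
    t = 0.0
    for step in range(n_steps + 1):
        rho_t = rho_of_t(t)
        a_t = params.tau_a * rho_t * float(np.mean(feedbacks.f_ext(m)))
        if step % record_every == 0 and k < n_rec:
            t_out[k] = t
            m_out[k] = m
            a_out[k] = a_t
            rho_out[k] = rho_t
            det_out[k] = m_det
            k += 1
        if step == n_steps:
            break
        # deterministic companion (its own quasi-static AI)
        a_det = params.tau_a * rho_t * feedbacks.f_ext(m_det)
        m_det = m_det + (-m_det / params.tau_m
                         + rate(a_det) * feedbacks.f_int(m_det)) * dt
        sig = noise_scale * float(
            np.sqrt(model.fano(m_det, extrapolate=True) * m_det
                    / (params.noise_scale * params.tau_m))
        )
        drift = -m / params.tau_m + rate(a_t) * feedbacks.f_int(m)
        m = m + drift * dt + math.sqrt(2.0 * dt) * sig * rng.standard_normal(N)
        np.clip(m, 0.0, None, out=m)
        if not np.all(np.isfinite(m)):
            raise RuntimeError(f"non-finite MP state at step {step}")
        t += dt

    return SimulationEnsemble(
        t=t_out[:k], m=m_out[:k], a=a_out[:k], rho=rho_out[:k], m_det=det_out[:k],
        mode=mode, dt=dt, seed=seed, params=params,
    )


def _autocorr_time(x: np.ndarray, dt: float) -> float:
    """Exponential autocorrelation time pooled over cells (columns of x)."""
    x = x - x.mean(axis=0, keepdims=True)
    n = x.shape[0]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(x, n=nfft, axis=0)
    acf = np.fft.irfft((f * np.conj(f)).real, n=nfft, axis=0)[:n]
    acf = acf.mean(axis=1)
    if acf[0] <= 0:
        return 0.0
    acf /= acf[0]
    # fit log-linear decay before the ACF tail turns noisy
    below = np.nonzero(acf < 0.2)[0]
    stop = int(below[0]) if below.size else len(acf)
    stop = max(stop, 4)
    lags = np.arange(stop)
    pos = acf[:stop] > 0
    if pos.sum() < 3:
        return dt
    slope = np.polyfit(lags[pos], np.log(acf[:stop][pos]), 1)[0]
    if slope >= 0:
        return dt
    return float(-dt / slope)


@dataclass(frozen=True)
class EnsembleStats:
    mean: float
    variance: float
    fano: float
    se_mean: float
    se_fano: float
    tau_est: float
    n_effective: float


def ensemble_statistics(ens: SimulationEnsemble, burn_in: float) -> EnsembleStats:
    """Stationary mean, variance and Fano factor with autocorrelation-aware
    standard errors.

    The Fano factor is reported in the parameter set's noise units
    (``kappa * variance / mean``), directly comparable to the Fano functions.
    Requires a stationary segment of at least ten correlation times.
    """
    sel = ens.t >= burn_in
    if sel.sum() < 10:
        raise ValueError("stationary segment too short after burn-in")
    x = ens.m[sel]
    dt_sample = float(np.mean(np.diff(ens.t[sel])))
    tau_est = _autocorr_time(x, dt_sample)
    seg = ens.t[sel][-1] - ens.t[sel][0]
    if seg < 10 * tau_est:
        raise ValueError(
            f"stationary segment ({seg:g}s) shorter than 10 correlation times "
            f"({tau_est:g}s)"
        )
    mean = float(x.mean())
    var = float(x.var(ddof=1))
    kappa = ens.params.noise_scale
    fano = kappa * var / mean if mean > 0 else 0.0
    n_eff = x.shape[1] * max(seg / (2.0 * tau_est), 1.0)
    se_mean = math.sqrt(var / n_eff)
    se_fano = fano * math.sqrt(2.0 / n_eff)
    return EnsembleStats(
        mean=mean, variance=var, fano=fano, se_mean=se_mean, se_fano=se_fano,
        tau_est=tau_est, n_effective=n_eff,
    )
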