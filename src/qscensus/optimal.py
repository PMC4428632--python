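"""Optimal feedback construction and the variational oracle.

Maximizing the small-noise mutual information over the external and internal
feedbacks is a calculus-of-variations problem.  Its stationary solution has a
closed form: the optimal MP standard deviation is proportional to the bare
Fano function,

    Sigma*(m) = F(m) / (sqrt(kappa) c),
    c^2 = ln( m+ f_int,- / (m- f_int,+) ) / \\int_{m-}^{m+} dm' / F(m'),

the optimal internal feedback is
``f_int*(m) = f_int,- (m/m-) exp(-c^2 \\int_{m-}^{m} dm'/F(m'))``, and the
optimal mean mapping is generalized histogram equalization: the input CDF is
matched to the normalized cumulative of 1/Sigma*, so the MP output density is
inversely proportional to its own standard deviation.  The resulting optimal
small-noise information is

    I* = 1/2 log2( ln(m+ f_int,-/(m- f_int,+)) *
                   kappa \\int dm / (2 pi e F(m)) ).

Because the closed form is derived, not printed, it is validated against
:func:`numerical_variational_optimizer`, a direct multi-start optimization of
the small-noise information functional over knot-parameterized feedback and
mapping curves.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.integrate import quad
from scipy.interpolate import PchipInterpolator
from scipy.optimize import minimize

from .dynamics import (
    ChannelStats,
    FeedbackCurve,
    FeedbackPair,
    GrowthProfile,
    MeanFieldMaps,
    StabilityError,
    density_distribution,
    linearized_stats,
)
from .params import (
    BareExpressionRate,
    QSParameters,
    RegulationModel,
    calibrate_bare_rate,
)

__all__ = [
    "OptimalInternalFeedback",
    "OptimalSolution",
    "Baseline",
    "VariationalResult",
    "fano_inverse_integral",
    "optimal_smallnoise_mi",
    "optimal_internal_feedback",
    "optimal_mp_mapping",
    "optimal_ai_mapping",
    "optimal_external_feedback",
    "optimal_solution",
    "feedback_fano_ratio",
    "no_feedback_baseline",
    "equalization_mapping",
    "numerical_variational_optimizer",
]

_2PIE = 2.0 * math.pi * math.e


def fano_inverse_integral(model: RegulationModel, m1: float, m2: float) -> float:
    """Closed form of \\int_{m1}^{m2} dm / F(m) for the two regulation models."""
    if model.kind == "tf" or model.b == 0:
        return (m2 - m1) * model.v / (1.0 + model.b)
    r = model.b / model.m_infty
    return model.v / r * math.log((1.0 + r * m2) / (1.0 + r * m1))


def _log_budget(params: QSParameters) -> float:
    """ln(m+ f_int,- / (m- f_int,+)): the feedback/bandwidth budget factor."""
    return math.log(
        params.m_plus * params.f_int_minus / (params.m_minus * params.f_int_plus)
    )


def optimal_smallnoise_mi(params: QSParameters, model: RegulationModel) -> float:
    """Optimal small-noise mutual information, in bits (closed form).

    Independent of the input distribution and of the AI range; it is the
    optimal small-noise capacity of the detection channel.  A value below
    zero bits simply means the small-noise budget is smaller than the noise;
    it is flagged, not raised.
    """
    L = _log_budget(params)
    J = fano_inverse_integral(model, params.m_minus, params.m_plus)
    arg = L * params.noise_scale * J / _2PIE
    if arg <= 1.0:
        warnings.warn(
            "optimal small-noise information is <= 0 bits; the small-noise "
            "approximation is unreliable here",
            stacklevel=2,
        )
    return 0.5 * math.log2(arg)


@dataclass(frozen=True)
class OptimalInternalFeedback:
    """Stationary solution of the internal-feedback variational problem."""

    c: float
    f_int: FeedbackCurve = field(repr=False)
    sigma_star: Callable = field(repr=False)
    model: RegulationModel
    params: QSParameters


def optimal_internal_feedback(
    params: QSParameters, model: RegulationModel
) -> OptimalInternalFeedback:
    """Optimal self-regulation profile with pinned boundary values.

    Enforces ``Sigma*(m) = F(m)/(sqrt(kappa) c)`` with the constant fixed by
    the endpoint budget; the stability constraint ``1 - m (ln f_int)' =
    m c^2 / F(m) > 0`` holds automatically.
    """
    L = _log_budget(params)
    J = fano_inverse_integral(model, params.m_minus, params.m_plus)
    c2 = L / J
    if c2 <= 0:
        raise StabilityError("feedback budget is non-positive")
    kappa = params.noise_scale
    m_minus = params.m_minus
    f_minus = params.f_int_minus

    def G(m):
        m = np.asarray(m, dtype=float)
        if model.kind == "tf" or model.b == 0:
            return (m - m_minus) * model.v / (1.0 + model.b)
        r = model.b / model.m_infty
        return model.v / r * np.log((1.0 + r * m) / (1.0 + r * m_minus))

    def f_int(m):
        m = np.asarray(m, dtype=float)
        return f_minus * (m / m_minus) * np.exp(-c2 * G(m))

    def df_int(m):
        m = np.asarray(m, dtype=float)
        return f_int(m) * (1.0 / m - c2 / model.fano(m, extrapolate=True))

    def sigma_star(m):
        m = np.asarray(m, dtype=float)
        out = model.fano(m, extrapolate=True) / math.sqrt(kappa * c2)
        return float(out) if np.ndim(out) == 0 else out

    return OptimalInternalFeedback(
        c=math.sqrt(c2),
        f_int=FeedbackCurve(f_int, df_int, name="f_int*"),
        sigma_star=sigma_star,
        model=model,
        params=params,
    )


@dataclass(frozen=True)
class MPMapping:
    """Optimal density-to-MP mapping by generalized equalization."""

    m_bar: Callable = field(repr=False)
    m_bar_prime: Callable = field(repr=False)
    rho_of_m: Callable = field(repr=False)
    Q: Callable = field(repr=False)
    profile: GrowthProfile

    def time_course(self, t):
        return self.m_bar(self.profile.density(t))


def optimal_mp_mapping(
    profile: GrowthProfile,
    internal: OptimalInternalFeedback,
) -> MPMapping:
    """Match the input CDF to the cumulative inverse noise of the channel.

    ``m_bar*(rho) = Q^{-1}(P(rho))`` with ``Q(m)`` the normalized cumulative
    of 1/Sigma*(m); the MP output density then satisfies q(m) ~ 1/Sigma*(m).
    With constant Sigma* this reduces to classical histogram equalization.
    """
    params = internal.params
    model = internal.model
    J = fano_inverse_integral(model, params.m_minus, params.m_plus)

    def Q(m):
        # cumulative of 1/Sigma* ~ 1/F
        m = np.asarray(m, dtype=float)
        if model.kind == "tf" or model.b == 0:
            num = (m - params.m_minus) * model.v / (1.0 + model.b)
        else:
            r = model.b / model.m_infty
            num = model.v / r * np.log((1.0 + r * m) / (1.0 + r * params.m_minus))
        return num / J

    if model.kind == "tf" or model.b == 0:
        def Q_inv(u):
            u = np.asarray(u, dtype=float)
            return params.m_minus + (params.m_plus - params.m_minus) * u
    else:
        r = model.b / model.m_infty
        A_lo = 1.0 + r * params.m_minus
        A_hi = 1.0 + r * params.m_plus

        def Q_inv(u):
            u = np.asarray(u, dtype=float)
            return (A_lo ** (1.0 - u) * A_hi**u - 1.0) / r

    def m_bar(rho):
        out = Q_inv(profile.cdf(rho))
        return float(out) if np.ndim(out) == 0 else out

    def m_bar_prime(rho):
        # dm/dP = J * F(m); chain rule through P(rho)
        m = m_bar(rho)
        out = (
            J
            * np.asarray(internal.model.fano(m, extrapolate=True), float)
            * np.asarray(profile.pdf(rho), float)
        )
        return float(out) if np.ndim(out) == 0 else out

    def rho_of_m(m):
        out = profile.ppf(Q(m))
        return float(out) if np.ndim(out) == 0 else out

    return MPMapping(
        m_bar=m_bar, m_bar_prime=m_bar_prime, rho_of_m=rho_of_m, Q=Q,
        profile=profile,
    )


def optimal_ai_mapping(
    params: QSParameters,
    rate: BareExpressionRate,
    internal: OptimalInternalFeedback,
    mapping: MPMapping,
) -> Callable:
    """AI concentration course implied by the optimal MP mapping.

    Inverts the self-consistency relation:
    ``a_bar*(rho) = rate^{-1}( m_bar*(rho) / (tau_m f_int*(m_bar*(rho))) )``.
    """

    def a_bar(rho):
        m = mapping.m_bar(rho)
        target = np.asarray(m, float) / (
            params.tau_m * np.asarray(internal.f_int(m), float)
        )
        out = rate.inverse(np.clip(
            target, rate.beta0 * (1 + 1e-15) + rate.beta1 * 1e-15, None
        ))
        return float(out) if np.ndim(out) == 0 else out

    return a_bar


def optimal_external_feedback(
    params: QSParameters,
    a_bar_star: Callable,
    mapping: MPMapping,
) -> FeedbackCurve:
    """Per-cell AI output rate that transforms growth into the optimal AI course.

    ``f_ext*(m) = a_bar*(rho(m)) / (tau_a rho(m))``; the reference scale
    ``f_- = a_-/(tau_a rho_-)`` gives the conventional normalization.
    """

    def f_ext(m):
        rho = mapping.rho_of_m(np.asarray(m, float))
        return np.asarray(a_bar_star(rho), float) / (params.tau_a * np.asarray(rho, float))

    return FeedbackCurve(f_ext, name="f_ext*")


@dataclass(frozen=True)
class OptimalSolution:
    """Complete optimal quorum-sensing response for one regulation model."""

    params: QSParameters
    model: RegulationModel
    profile: GrowthProfile
    rate: BareExpressionRate
    internal: OptimalInternalFeedback
    mapping: MPMapping = field(repr=False)
    a_bar_star: Callable = field(repr=False)
    f_ext_star: FeedbackCurve = field(repr=False)
    feedbacks: FeedbackPair = field(repr=False)
    maps: MeanFieldMaps = field(repr=False)
    stats: ChannelStats = field(repr=False)
    I_star_smallnoise: float = 0.0

    @property
    def f_int_star(self) -> FeedbackCurve:
        return self.internal.f_int

    @property
    def f_ext_scale(self) -> float:
        """Reference AI output rate f_- = a_-/(tau_a rho_-)."""
        return self.params.a_minus / (self.params.tau_a * self.params.rho_minus)


def optimal_solution(
    params: QSParameters,
    kind: str,
    profile: GrowthProfile | None = None,
    rate: BareExpressionRate | None = None,
) -> OptimalSolution:
    """Construct the full optimal response (feedbacks, mappings, statistics)."""
    model = RegulationModel.for_channel(params, kind)
    if profile is None:
        profile = density_distribution(params)
    if rate is None:
        rate = calibrate_bare_rate(params)
    internal = optimal_internal_feedback(params, model)
    mapping = optimal_mp_mapping(profile, internal)
    a_bar = optimal_ai_mapping(params, rate, internal, mapping)
    f_ext = optimal_external_feedback(params, a_bar, mapping)
    feedbacks = FeedbackPair(f_ext=f_ext, f_int=internal.f_int)

    def a_bar_prime(rho):
        rho = np.asarray(rho, float)
        eps = 1e-6
        return (a_bar(rho * (1 + eps)) - a_bar(rho * (1 - eps))) / (2 * eps * rho)

    maps = MeanFieldMaps(
        rho_range=(params.rho_minus, params.rho_plus),
        a_bar=a_bar,
        m_bar=mapping.m_bar,
        a_bar_prime=a_bar_prime,
        m_bar_prime=mapping.m_bar_prime,
    )
    stats = linearized_stats(params, model, feedbacks, maps)
    return OptimalSolution(
        params=params,
        model=model,
        profile=profile,
        rate=rate,
        internal=internal,
        mapping=mapping,
        a_bar_star=a_bar,
        f_ext_star=f_ext,
        feedbacks=feedbacks,
        maps=maps,
        stats=stats,
        I_star_smallnoise=optimal_smallnoise_mi(params, model),
    )


def feedback_fano_ratio(f_int: FeedbackCurve, m) -> float | np.ndarray:
    """Fano amplification factor of an internal feedback:
    ``F*/F = (1 - m f_int'(m)/f_int(m))^-1``."""
    m = np.asarray(m, dtype=float)
    f = np.asarray(f_int(m), float)
    df = np.asarray(f_int.derivative(m), float)
    denom = 1.0 - m * df / f
    if np.any(denom <= 0):
        raise StabilityError("feedback Fano ratio is not positive")
    out = 1.0 / denom
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Baseline:
    """Channel without any feedback: constant AI output, f_int = 1.

    The bare rate is calibrated with f_int = 1 so the baseline spans the same
    fixed MP range (m-, m+); its AI course is linear in density, anchored at
    the detection threshold (it cannot reach a+ when a+/a- exceeds
    rho+/rho-, which is inherent to a constant output rate).
    """

    params: QSParameters
    model: RegulationModel
    rate: BareExpressionRate
    feedbacks: FeedbackPair = field(repr=False)
    maps: MeanFieldMaps = field(repr=False)
    stats: ChannelStats = field(repr=False)


def no_feedback_baseline(params: QSParameters, kind: str) -> Baseline:
    """Reference channel with all feedbacks absent."""
    rate = calibrate_bare_rate(params, f_int_minus=1.0, f_int_plus=1.0)
    model = RegulationModel.for_channel(params, kind, f_int_plus=1.0)
    feedbacks = FeedbackPair.no_feedback(params)
    slope = params.a_minus / params.rho_minus

    def a_bar(rho):
        return slope * np.asarray(rho, float)

    def m_bar(rho):
        return params.tau_m * np.asarray(rate(a_bar(rho)), float)

    def m_bar_prime(rho):
        return params.tau_m * np.asarray(rate.derivative(a_bar(rho)), float) * slope

    maps = MeanFieldMaps(
        rho_range=(params.rho_minus, params.rho_plus),
        a_bar=a_bar,
        m_bar=m_bar,
        a_bar_prime=lambda rho: np.full_like(np.asarray(rho, float), slope),
        m_bar_prime=m_bar_prime,
    )
    stats = linearized_stats(params, model, feedbacks, maps)
    return Baseline(
        params=params, model=model, rate=rate, feedbacks=feedbacks,
        maps=maps, stats=stats,
    )


def equalization_mapping(profile: GrowthProfile, params: QSParameters) -> Callable:
    """Classical histogram equalization: the scaled input CDF."""

    def m_bar(rho):
        out = params.m_minus + (params.m_plus - params.m_minus) * np.asarray(
            profile.cdf(rho), float
        )
        return float(out) if np.ndim(out) == 0 else out

    return m_bar


@dataclass(frozen=True)
class VariationalResult:
    """Direct numerical optimum of the small-noise information functional."""

    value: float
    f_int: FeedbackCurve = field(repr=False)
    m_bar_of_cdf: Callable = field(repr=False)
    sigma_of_m: Callable = field(repr=False)
    diagnostics: dict = field(default_factory=dict)


def smallnoise_mi_of_curves(
    params: QSParameters,
    model: RegulationModel,
    u_spline: Callable,
    du_spline: Callable,
    m_of_P: Callable,
    dm_dP: Callable,
    n_grid: int = 801,
) -> float:
    """Small-noise MI of an arbitrary (f_int, mapping) pair, in bits.

    Written on the input-quantile grid: with m_bar'(rho) = (dm/dP) p(rho)
    the density terms cancel against the input entropy, leaving
    ``I = < log2( (dm/dP) / (sqrt(2 pi e) Sigma(m)) ) >_P``.
    """
    Pg = np.linspace(0.0, 1.0, n_grid)
    m = np.asarray(m_of_P(Pg), float)
    dm = np.asarray(dm_dP(Pg), float)
    stab = 1.0 - m * np.asarray(du_spline(m), float)
    if np.any(stab <= 0):
        raise StabilityError("stability constraint violated on the quantile grid")
    sigma = np.sqrt(
        m * np.asarray(model.fano(m, extrapolate=True), float)
        / (params.noise_scale * stab)
    )
    vals = np.log2(np.maximum(dm, 1e-300) / (math.sqrt(_2PIE) * sigma))
    # trapezoid on the uniform quantile grid
    return float(np.trapezoid(vals, Pg))


def numerical_variational_optimizer(
    params: QSParameters,
    model: RegulationModel,
    profile: GrowthProfile | None = None,
    n_knots: int = 16,
    seed: int = 0,
    n_starts: int = 3,
    n_grid: int = 801,
) -> VariationalResult:
    """Directly maximize the small-noise MI over feedback and mapping curves.

    The internal feedback is parameterized by the values of ln f_int on an
    MP knot grid (endpoints pinned to the boundary budget) and the mean
    mapping by positive increments on an input-quantile knot grid (so it is
    monotone and boundary-pinned by construction).  Multi-start L-BFGS with a
    recorded seed; serves as the independent oracle for the closed-form
    stationary solution.
    """
    if n_knots < 8:
        raise ValueError("n_knots must be >= 8")
    if profile is None:
        profile = density_distribution(params)
    m_lo, m_hi = params.m_minus, params.m_plus
    mk = np.linspace(m_lo, m_hi, n_knots)
    Pk = np.linspace(0.0, 1.0, n_knots)
    u_lo, u_hi = math.log(params.f_int_minus), math.log(params.f_int_plus)
    Pg = np.linspace(0.0, 1.0, n_grid)
    sqrt2pie = math.sqrt(_2PIE)
    kappa = params.noise_scale

    def unpack(theta):
        u = np.concatenate([[u_lo], theta[: n_knots - 2], [u_hi]])
        w = theta[n_knots - 2 :]
        inc = np.exp(w - w.max())
        inc = inc / inc.sum()
        mknots = m_lo + (m_hi - m_lo) * np.concatenate([[0.0], np.cumsum(inc)])
        mknots[-1] = m_hi
        return PchipInterpolator(mk, u), PchipInterpolator(Pk, mknots)

    def objective(theta):
        u_spl, m_spl = unpack(theta)
        m = m_spl(Pg)
        dm = m_spl.derivative()(Pg)
        stab = 1.0 - m * u_spl.derivative()(m)
        bad = stab <= 1e-3
        if np.any(bad):
            return 1e3 + 1e3 * float(np.sum(1e-3 - stab[bad]))
        sigma = np.sqrt(m * model.fano(m, extrapolate=True) / (kappa * stab))
        vals = np.log2(np.maximum(dm, 1e-300) / (sqrt2pie * sigma))
        return -float(np.trapezoid(vals, Pg))

    theta0 = np.concatenate(
        [np.linspace(u_lo, u_hi, n_knots)[1:-1], np.zeros(n_knots - 1)]
    )
    rng = np.random.default_rng(seed)
    best = None
    history = []
    for s in range(n_starts):
        theta = theta0 if s == 0 else theta0 + rng.normal(0.0, 0.2, theta0.shape)
        res = minimize(objective, theta, method="L-BFGS-B",
                       options={"maxiter": 500})
        history.append(float(-res.fun))
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= 1e3:
        raise RuntimeError(
            f"variational optimizer failed to find a stable profile; best "
            f"objective {None if best is None else -best.fun}"
        )
    u_spl, m_spl = unpack(best.x)
    du = u_spl.derivative()
    dm = m_spl.derivative()

    def sigma_of_m(m):
        m = np.asarray(m, float)
        stab = 1.0 - m * du(m)
        return np.sqrt(m * model.fano(m, extrapolate=True) / (kappa * stab))

    return VariationalResult(
        value=float(-best.fun),
        f_int=FeedbackCurve(lambda m: np.exp(u_spl(np.asarray(m, float))),
                            lambda m: np.exp(u_spl(np.asarray(m, float)))
                            * du(np.asarray(m, float)),
                            name="f_int (numerical)"),
        m_bar_of_cdf=lambda u: m_spl(np.asarray(u, float)),
        sigma_of_m=sigma_of_m,
        diagnostics={
            "starts": history,
            "n_knots": n_knots,
            "seed": seed,
            "converged": bool(best.success),
            "iterations": int(best.nit),
        },
    )
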