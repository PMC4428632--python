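"""Gaussian encoding p(m|rho), mutual information, and channel capacity.

The encoding scheme is a family of Gaussians N(m_bar(rho), Sigma^2(rho))
discretized on a density/MP grid.  Information is computed three ways:

* ``small_noise_mi`` — the 1-D quadrature lower bound
  ``I = H_rho + \\int p(rho) log2( m_bar'(rho) / (sqrt(2 pi e) Sigma) ) drho``;
* ``numerical_mi`` — the exact discrete mutual information of the gridded
  channel, with no small-noise approximation;
* ``blahut_arimoto`` — the capacity of the discrete channel by alternating
  maximization, bracketed between its lower and upper Arimoto bounds.

The small-noise capacity ``C = log2 \\int drho / (sqrt(2 pi e) delta_rho)``
is achieved by the input density p(rho) ~ 1/delta_rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .dynamics import ChannelStats, GrowthProfile, MeanFieldMaps

__all__ = [
    "DiscretizedChannel",
    "InfoResult",
    "ConvergenceError",
    "build_channel",
    "channel_from_curves",
    "input_distribution",
    "numerical_mi",
    "blahut_arimoto",
    "small_noise_mi",
    "small_noise_capacity",
    "distinguishable_states",
]

_SQRT_2PIE = math.sqrt(2.0 * math.pi * math.e)


class ConvergenceError(RuntimeError):
    """Iteration budget exhausted; carries the current capacity bracket."""

    def __init__(self, msg: str, lower: float, upper: float):
        super().__init__(msg)
        self.lower = lower
        self.upper = upper


@dataclass(frozen=True)
class InfoResult:
    """An information value in bits plus how it was obtained."""

    value: float
    method: str
    input_name: str = "1/rho"
    approximate: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __float__(self) -> float:
        return self.value


@dataclass(frozen=True)
class DiscretizedChannel:
    """Conditional probability matrix p(m|rho) on explicit grids.

    ``P[i, j]`` is the probability that the MP readout falls in bin ``j``
    given density ``rho_grid[i]``; rows are normalized.  ``truncation`` is
    ``"hard"`` (Gaussians renormalized on the MP range) or ``"none"``
    (grid extended so the Gaussians are essentially untruncated).
    """

    rho_grid: np.ndarray
    m_edges: np.ndarray
    P: np.ndarray
    truncation: str
    meta: dict = field(default_factory=dict)

    @property
    def m_centers(self) -> np.ndarray:
        return 0.5 * (self.m_edges[1:] + self.m_edges[:-1])

    @property
    def n_rho(self) -> int:
        return self.P.shape[0]

    @property
    def n_m(self) -> int:
        return self.P.shape[1]

    def validate(self, tol: float = 1e-10) -> None:
        rs = self.P.sum(axis=1)
        if np.any(np.abs(rs - 1.0) > tol):
            raise ValueError("channel rows are not normalized")
        if np.any(self.P < 0):
            raise ValueError("channel has negative entries")


def channel_from_curves(
    rho_grid: np.ndarray,
    means: np.ndarray,
    sigmas: np.ndarray,
    n_m: int = 512,
    truncation: str = "hard",
    m_range: tuple[float, float] | None = None,
    meta: dict | None = None,
) -> DiscretizedChannel:
    """Discretize Gaussian rows with bin-integrated (CDF-difference) mass."""
    means = np.asarray(means, float)
    sigmas = np.asarray(sigmas, float)
    if np.any(sigmas <= 0):
        raise ValueError(
            "Sigma = 0 encountered: a deterministic channel has divergent MI"
        )
    if truncation not in ("hard", "none"):
        raise ValueError(f"unknown truncation mode {truncation!r}")
    if m_range is None:
        m_range = (float(means.min()), float(means.max()))
    lo, hi = m_range
    if truncation == "none":
        pad = 6.0 * float(sigmas.max())
        lo, hi = lo - pad, hi + pad
    edges = np.linspace(lo, hi, n_m + 1)
    z_hi = (edges[None, 1:] - means[:, None]) / sigmas[:, None]
    z_lo = (edges[None, :-1] - means[:, None]) / sigmas[:, None]
    P = norm.cdf(z_hi) - norm.cdf(z_lo)
    rs = P.sum(axis=1, keepdims=True)
    if np.any(rs <= 0):
        raise ValueError("a channel row has no mass on the MP grid")
    P = P / rs
    return DiscretizedChannel(
        rho_grid=np.asarray(rho_grid, float),
        m_edges=edges,
        P=P,
        truncation=truncation,
        meta=dict(meta or {}),
    )


def build_channel(
    maps: MeanFieldMaps,
    stats: ChannelStats,
    n_rho: int = 512,
    n_m: int = 512,
    truncation: str = "hard",
    m_range: tuple[float, float] | None = None,
) -> DiscretizedChannel:
    """Build the discretized Gaussian channel from mean maps and noise stats.

    The density grid is log-spaced (the 1/rho input is uniform on it); the MP
    grid is linear over the mean curve's range, optionally extended so the
    Gaussians are untruncated.
    """
    rho_lo, rho_hi = maps.rho_range
    rho_grid = np.geomspace(rho_lo, rho_hi, n_rho)
    means = np.asarray(maps.m_bar(rho_grid), float)
    sigmas = np.sqrt(np.asarray(stats.sigma_sq(rho_grid), float))
    return channel_from_curves(
        rho_grid, means, sigmas, n_m=n_m, truncation=truncation,
        m_range=m_range,
        meta={"n_rho": n_rho, "n_m": n_m},
    )


def input_distribution(
    channel: DiscretizedChannel, profile: GrowthProfile | None = None
) -> np.ndarray:
    """Discrete input weights on the channel's density grid.

    With the default growth profile (p(rho) ~ 1/rho) and a log-spaced grid
    this is uniform; a custom profile is integrated bin-wise through its CDF.
    """
    n = channel.n_rho
    if profile is None:
        return np.full(n, 1.0 / n)
    r = channel.rho_grid
    edges = np.empty(n + 1)
    edges[1:-1] = np.sqrt(r[:-1] * r[1:])
    edges[0], edges[-1] = r[0], r[-1]
    p = np.diff(np.asarray(profile.cdf(edges), float))
    total = p.sum()
    if total <= 0:
        raise ValueError("input profile has no mass on the channel grid")
    return p / total


def _mi_bits(p: np.ndarray, P: np.ndarray) -> float:
    q = p @ P
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(P > 0, P, 1.0) / np.where(q > 0, q, 1.0)
        terms = P * np.log2(ratio)
    return float((p[:, None] * terms).sum())


def numerical_mi(
    channel: DiscretizedChannel, p: np.ndarray | None = None
) -> InfoResult:
    """Exact mutual information of the discretized channel, in bits.

    Zero-probability bins follow the 0*log 0 = 0 convention.
    """
    if p is None:
        p = np.full(channel.n_rho, 1.0 / channel.n_rho)
        input_name = "1/rho"
    else:
        p = np.asarray(p, float)
        if p.shape != (channel.n_rho,):
            raise ValueError("input distribution does not match the density grid")
        if abs(p.sum() - 1.0) > 1e-8:
            raise ValueError("input distribution must sum to 1")
        input_name = "custom"
    value = _mi_bits(p, channel.P)
    return InfoResult(
        value=value,
        method="numerical",
        input_name=input_name,
        diagnostics={"n_rho": channel.n_rho, "n_m": channel.n_m},
    )


def blahut_arimoto(
    channel: DiscretizedChannel,
    tol: float = 1e-6,
    max_iter: int = 200_000,
) -> InfoResult:
    """Channel capacity by the Blahut-Arimoto alternating maximization.

    Iterates until the gap between the Arimoto upper and lower capacity
    bounds falls below ``tol`` bits; raises :class:`ConvergenceError`
    carrying the bracket if the iteration budget runs out.  Returns the
    lower bound with the achieving input in the diagnostics.
    """
    P = channel.P
    n = channel.n_rho
    p = np.full(n, 1.0 / n)
    with np.errstate(divide="ignore"):
        logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    row_ent = (P * logP).sum(axis=1)
    ln2 = math.log(2.0)
    lower = upper = 0.0
    for it in range(1, max_iter + 1):
        q = p @ P
        log_q = np.log(np.where(q > 0, q, 1e-300))
        D = row_ent - P @ log_q  # per-input divergence, in nats
        upper = float(D.max())
        lower = float(p @ D)
        if upper - lower < tol * ln2:
            return InfoResult(
                value=lower / ln2,
                method="blahut_arimoto",
                input_name="capacity-achieving",
                diagnostics={
                    "upper_bits": upper / ln2,
                    "iterations": it,
                    "tol_bits": tol,
                    "p_star": p,
                },
            )
        p = p * np.exp(D - upper)
        p /= p.sum()
    raise ConvergenceError(
        f"Blahut-Arimoto did not reach a {tol:g}-bit bracket in "
        f"{max_iter} iterations (bracket [{lower / ln2:.6f}, {upper / ln2:.6f}])",
        lower=lower / ln2,
        upper=upper / ln2,
    )


def small_noise_mi(
    profile: GrowthProfile, maps: MeanFieldMaps, stats: ChannelStats
) -> InfoResult:
    """Small-noise (quadrature) mutual information lower bound, in bits."""
    rho_lo, rho_hi = maps.rho_range

    def integrand(rho):
        dm = float(maps.m_bar_prime(rho))
        sig = math.sqrt(float(stats.sigma_sq(rho)))
        arg = dm / (_SQRT_2PIE * sig)
        if not (arg > 0 and math.isfinite(arg)):
            raise FloatingPointError(
                f"non-finite small-noise integrand at rho={rho:g}"
            )
        return float(profile.pdf(rho)) * math.log2(arg)

    val, err = quad(integrand, rho_lo, rho_hi, limit=400)
    h_rho = profile.entropy_bits()
    return InfoResult(
        value=h_rho + val,
        method="small_noise",
        approximate=True,
        diagnostics={"H_rho_bits": h_rho, "quad_error": err,
                     "lower_bound": True},
    )


def small_noise_capacity(
    maps: MeanFieldMaps, stats: ChannelStats
) -> InfoResult:
    """Small-noise capacity and the input density achieving it.

    ``C = log2 \\int drho / (sqrt(2 pi e) delta_rho)``; the capacity input is
    ``p*(rho) ~ 1/delta_rho``.  The diagnostics carry the equivalent
    MP-domain form ``log2 \\int dm / (sqrt(2 pi e) Sigma_m(m))`` obtained by
    the substitution m = m_bar(rho).
    """
    rho_lo, rho_hi = maps.rho_range

    def inv_res(rho):
        return 1.0 / (_SQRT_2PIE * float(stats.delta_rho(rho)))

    Z, err = quad(inv_res, rho_lo, rho_hi, limit=400)
    if not (Z > 0 and math.isfinite(Z)):
        raise ValueError("divergent resolution integral")

    # MP-domain form: dm = m_bar'(rho) drho and Sigma_m(m_bar) = Sigma(rho)
    def inv_sigma(rho):
        dm = float(maps.m_bar_prime(rho))
        return dm / (_SQRT_2PIE * math.sqrt(float(stats.sigma_sq(rho))))

    Zm, _ = quad(inv_sigma, rho_lo, rho_hi, limit=400)

    def p_star(rho):
        return np.asarray(
            1.0 / (_SQRT_2PIE * np.sqrt(np.asarray(stats.sigma_sq(rho), float))
                   / np.abs(np.asarray(maps.m_bar_prime(rho), float)))
            / Z,
            float,
        )

    return InfoResult(
        value=math.log2(Z),
        method="small_noise_capacity",
        input_name="1/delta_rho",
        approximate=True,
        diagnostics={
            "m_domain_bits": math.log2(Zm),
            "quad_error": err,
            "p_star": p_star,
        },
    )


def distinguishable_states(I: float) -> tuple[int, int]:
    """Range of resolvable input states implied by ``I`` bits.

    Returns (floor, ceil) of 2**I, with 2**I first rounded to two decimals so
    that values such as 2.00 collapse to a single integer.
    """
    if I < 0:
        raise ValueError("information must be non-negative")
    x = round(2.0**I, 2)
    return int(math.floor(x)), int(math.ceil(x))
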