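"""Model parameters, unit conventions, and regulation-model noise functions.

The quorum-sensing channel is specified by boundary values for cell density
(``rho_minus``, ``rho_plus``), autoinducer (AI) concentration (``a_minus``,
``a_plus``), and monitor-protein (MP) concentration (``m_minus``, ``m_plus``),
two timescales (AI escape time ``tau_a``, MP lifetime ``tau_m``), the Hill
parameters of the bare AI-controlled expression rate, the transcriptional
burst size ``b``, the mean cell volume ``v``, and the boundary levels of MP
self-regulation (``f_int_minus``, ``f_int_plus``).

Concentrations are handled in nM throughout.  The Fano functions of the two
regulation models carry units of inverse volume, so the stationary variance
``Sigma^2 = F * m`` is only dimensionally consistent once a convention relates
nM to molecules per volume.  Two conventions are supported via
``QSParameters.units``:

* ``"raw"`` — nM values are treated as pure numbers with the cell volume
  absorbing the conversion (variance ``F * m``);
* ``"number_density"`` — concentrations are converted to molecules/um^3
  (variance ``F * m / conversion`` when expressed back in nM).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, fields, replace

import yaml

__all__ = [
    "NM_TO_PER_UM3",
    "QSParameters",
    "RegulationModel",
    "BareExpressionRate",
    "ParameterError",
    "CalibrationError",
    "load_parameters",
    "to_number_density",
    "from_number_density",
    "fano_bare",
    "calibrate_bare_rate",
]

#: molecules per um^3 per nM (Avogadro constant x 1e-9 mol/L x 1e-15 L/um^3)
NM_TO_PER_UM3 = 0.6022


class ParameterError(ValueError):
    """A parameter is missing or violates a model invariant."""


class CalibrationError(ValueError):
    """Boundary conditions admit no positive Hill-rate solution."""


@dataclass(frozen=True)
class QSParameters:
    """Complete parameter set of the quorum-sensing channel.

    Densities are in cells/um^3, concentrations in nM, times in seconds.
    ``T`` is the growth-period duration; if omitted it defaults to
    ``ln(rho_plus/rho_minus) * tau_m``, the dilution-limited regime in which
    the MP lifetime equals the cell-cycle period divided by ln 2.
    """

    rho_minus: float = 1e-4
    rho_plus: float = 1.0
    a_minus: float = 0.1
    a_plus: float = 1e6
    m_minus: float = 100.0
    m_plus: float = 600.0
    tau_a: float = 10.0
    tau_m: float = 1800.0
    T: float | None = None
    f_int_minus: float = 2.0
    f_int_plus: float = 0.5
    K: float = 15.0
    h: float = 2.0
    b: float = 20.0
    v: float = 1.0
    conversion: float = NM_TO_PER_UM3
    units: str = "raw"

    def __post_init__(self) -> None:
        if self.T is None:
            if self.rho_minus > 0 and self.rho_plus > self.rho_minus:
                object.__setattr__(
                    self, "T",
                    math.log(self.rho_plus / self.rho_minus) * self.tau_m,
                )
            else:
                object.__setattr__(self, "T", 1.0)  # validation will reject
        self._validate()

    def _validate(self) -> None:
        def require(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise ParameterError(f"{name}: {msg}")

        require(self.rho_minus > 0, "rho_minus", "must be > 0")
        require(self.rho_plus > self.rho_minus, "rho_plus", "must exceed rho_minus")
        require(self.a_minus > 0, "a_minus", "must be > 0")
        require(self.a_plus > self.a_minus, "a_plus", "must exceed a_minus")
        require(self.m_minus > 0, "m_minus", "must be > 0")
        require(self.m_plus > self.m_minus, "m_plus", "must exceed m_minus")
        require(self.tau_a > 0, "tau_a", "must be > 0")
        require(self.tau_m > 0, "tau_m", "must be > 0")
        require(self.T > 0, "T", "must be > 0")
        require(self.f_int_minus > 0, "f_int_minus", "must be > 0")
        require(self.f_int_plus > 0, "f_int_plus", "must be > 0")
        require(self.K > 0, "K", "must be > 0")
        require(self.h >= 1, "h", "must be >= 1")
        require(self.b >= 0, "b", "must be >= 0")
        require(self.v > 0, "v", "must be > 0")
        require(self.conversion > 0, "conversion", "must be > 0")
        require(self.units in ("raw", "number_density"), "units",
                "must be 'raw' or 'number_density'")
        if self.tau_a > self.tau_m / 10:
            warnings.warn(
                "tau_a is not small compared with tau_m; the quasi-static "
                "treatment of the AI concentration may be inaccurate",
                stacklevel=3,
            )

    @classmethod
    def table1(cls, **overrides) -> "QSParameters":
        """The built-in preset used for the headline information table."""
        return cls(**overrides)

    @property
    def noise_scale(self) -> float:
        """kappa such that the stationary MP variance in nM^2 is F*m/kappa."""
        return 1.0 if self.units == "raw" else self.conversion

    @property
    def gamma(self) -> float:
        """Exponential growth rate ln(rho_plus/rho_minus)/T in 1/s."""
        return math.log(self.rho_plus / self.rho_minus) / self.T

    def with_(self, **overrides) -> "QSParameters":
        return replace(self, **overrides)


def to_number_density(c, conversion: float = NM_TO_PER_UM3):
    """Convert a concentration in nM to molecules/um^3."""
    import numpy as np

    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be non-negative")
    out = c * conversion
    return float(out) if out.ndim == 0 else out


def from_number_density(n, conversion: float = NM_TO_PER_UM3):
    """Inverse of :func:`to_number_density`."""
    import numpy as np

    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("number density must be non-negative")
    out = n / conversion
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class RegulationModel:
    """Bare (no-feedback) Fano function of a MP regulation scheme.

    ``kind`` is ``"tf"`` for direct transcription-factor regulation, where the
    Fano function is the constant ``(1+b)/v``, or ``"srna"`` for regulation
    through a small RNA, where ``F(m) = (1 + b*m/m_infty)/v`` with ``m_infty``
    the MP saturation concentration without self-inhibition.
    """

    kind: str
    b: float
    v: float
    m_infty: float
    m_minus: float
    m_plus: float

    def __post_init__(self) -> None:
        if self.kind not in ("tf", "srna"):
            raise ParameterError(f"kind: unknown regulation model {self.kind!r}")
        if self.kind == "srna" and self.m_infty <= 0:
            raise ParameterError("m_infty: must be > 0 for sRNA regulation")

    @classmethod
    def for_channel(
        cls, params: QSParameters, kind: str, f_int_plus: float | None = None
    ) -> "RegulationModel":
        """Build the Fano model of a channel with high-density self-regulation
        level ``f_int_plus`` (defaults to the parameter set's value).

        The saturation concentration without self-inhibition is
        ``m_infty = max(m_plus, m_plus/f_int_plus)``; a channel without
        feedback (``f_int_plus = 1``) therefore has ``m_infty = m_plus``.
        """
        fp = params.f_int_plus if f_int_plus is None else f_int_plus
        m_infty = max(params.m_plus, params.m_plus / fp)
        return cls(
            kind=kind,
            b=params.b,
            v=params.v,
            m_infty=m_infty,
            m_minus=params.m_minus,
            m_plus=params.m_plus,
        )

    def fano(self, m, extrapolate: bool = False):
        return fano_bare(self, m, extrapolate=extrapolate)


def fano_bare(model: RegulationModel, m, extrapolate: bool = False):
    """Bare Fano function F(m) in 1/volume units.

    ``m`` must lie within the model's MP range unless ``extrapolate=True``;
    out-of-range evaluation is an explicit choice, never silent.
    """
    import numpy as np

    m = np.asarray(m, dtype=float)
    if not extrapolate:
        lo = model.m_minus * (1 - 1e-12)
        hi = max(model.m_plus, model.m_infty) * (1 + 1e-12)
        if np.any(m < lo) or np.any(m > hi):
            raise ValueError(
                f"MP concentration outside [{model.m_minus}, "
                f"{max(model.m_plus, model.m_infty)}] nM; pass extrapolate=True "
                "to evaluate anyway"
            )
    if model.kind == "tf":
        out = np.full_like(m, (1.0 + model.b) / model.v)
    else:
        out = (1.0 + model.b * m / model.m_infty) / model.v
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class BareExpressionRate:
    """Bare AI-controlled MP expression rate: Hill activation with basal term.

    ``rate(a) = beta0 + beta1 * a^h / (K^h + a^h)`` in nM/s.
    """

    beta0: float
    beta1: float
    K: float
    h: float

    def __call__(self, a):
        import numpy as np

        a = np.asarray(a, dtype=float)
        x = a**self.h
        out = self.beta0 + self.beta1 * x / (self.K**self.h + x)
        return float(out) if out.ndim == 0 else out

    def derivative(self, a):
        import numpy as np

        a = np.asarray(a, dtype=float)
        Kh = self.K**self.h
        x = a**self.h
        out = self.beta1 * self.h * Kh * x / (a * (Kh + x) ** 2)
        return float(out) if out.ndim == 0 else out

    def inverse(self, r):
        """AI concentration at which the rate equals ``r`` (analytic)."""
        import numpy as np

        r = np.asarray(r, dtype=float)
        x = (r - self.beta0) / self.beta1
        if np.any(x <= 0) or np.any(x >= 1):
            raise ValueError("requested rate outside the open range of the Hill curve")
        out = self.K * (x / (1.0 - x)) ** (1.0 / self.h)
        return float(out) if out.ndim == 0 else out


def calibrate_bare_rate(
    params: QSParameters,
    f_int_minus: float | None = None,
    f_int_plus: float | None = None,
) -> BareExpressionRate:
    """Fix the Hill rate so the channel hits its MP boundary conditions.

    Solves ``tau_m * rate(a_minus) * f_int_minus = m_minus`` and
    ``tau_m * rate(a_plus) * f_int_plus = m_plus`` for the basal level and
    inducible amplitude.  Pass ``f_int_minus = f_int_plus = 1`` to calibrate a
    channel without self-regulation over the same MP range.
    """
    if not (params.a_minus < params.K < params.a_plus):
        raise CalibrationError("Hill constant K must lie inside (a_minus, a_plus)")
    fm = params.f_int_minus if f_int_minus is None else f_int_minus
    fp = params.f_int_plus if f_int_plus is None else f_int_plus
    hill = lambda a: a**params.h / (params.K**params.h + a**params.h)
    h_lo, h_hi = hill(params.a_minus), hill(params.a_plus)
    r_lo = params.m_minus / (params.tau_m * fm)
    r_hi = params.m_plus / (params.tau_m * fp)
    beta1 = (r_hi - r_lo) / (h_hi - h_lo)
    beta0 = r_lo - beta1 * h_lo
    if beta1 <= 0:
        raise CalibrationError(
            "boundary conditions require a non-increasing rate; no positive "
            "Hill amplitude exists"
        )
    if beta0 < -1e-12 * beta1:
        raise CalibrationError("boundary conditions require a negative basal rate")
    return BareExpressionRate(beta0=max(beta0, 0.0), beta1=beta1, K=params.K, h=params.h)


_CONFIG_KEYS = {
    "rho_minus_per_um3": "rho_minus",
    "rho_plus_per_um3": "rho_plus",
    "a_minus_nM": "a_minus",
    "a_plus_nM": "a_plus",
    "m_minus_nM": "m_minus",
    "m_plus_nM": "m_plus",
    "tau_a_s": "tau_a",
    "tau_m_s": "tau_m",
    "T_s": "T",
    "f_int_minus": "f_int_minus",
    "f_int_plus": "f_int_plus",
    "K_nM": "K",
    "h": "h",
    "b": "b",
    "v_um3": "v",
    "conversion_per_um3_nM": "conversion",
    "units": "units",
}

_REQUIRED = [
    "rho_minus_per_um3", "rho_plus_per_um3", "a_minus_nM", "a_plus_nM",
    "m_minus_nM", "m_plus_nM", "f_int_minus", "f_int_plus", "K_nM", "h",
    "b", "v_um3",
]


def load_parameters(config) -> QSParameters:
    """Build a validated parameter set from a config mapping or YAML file.

    The config either names a preset (``preset: table1``), optionally with
    overriding keys, or supplies all required fields.  Keys carry explicit
    unit suffixes, e.g. ``a_minus_nM`` or ``tau_a_s``.
    """
    if isinstance(config, (str, bytes)) or hasattr(config, "read"):
        with open(config) as fh:  # type: ignore[arg-type]
            cfg = yaml.safe_load(fh)
    elif isinstance(config, dict):
        cfg = dict(config)
    else:
        raise TypeError("config must be a mapping or a path to a YAML file")
    if cfg is None:
        cfg = {}

    preset = cfg.pop("preset", None)
    unknown = set(cfg) - set(_CONFIG_KEYS)
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in cfg.items():
        name = _CONFIG_KEYS[k]
        if name != "units":
            try:
                v = float(v)  # tolerate YAML-1.1 scientific notation strings
            except (TypeError, ValueError):
                raise ParameterError(f"{k}: not a number: {v!r}") from None
        kwargs[name] = v

    if preset is not None:
        if preset != "table1":
            raise ParameterError(f"unknown preset {preset!r}")
        return QSParameters.table1(**kwargs)

    missing = [k for k in _REQUIRED if _CONFIG_KEYS[k] not in kwargs]
    if missing:
        raise ParameterError(f"missing config keys: {missing}")
    defaults = {f.name for f in fields(QSParameters)}
    assert set(kwargs) <= defaults
    return QSParameters(**kwargs)
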