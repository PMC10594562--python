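"""Two-state irreversible denaturation kinetics under arbitrary heating programs.

The model: a native protein converts irreversibly to a denatured state with a
first-order, temperature-dependent rate following the Arrhenius law

    k(T) = A * exp(-Ea / (R * T_K)),   T_K = T_celsius + 273.15.

For a heating program T(t) the surviving (still-soluble) fraction is

    S = exp( - integral k(T(t)) dt )

so survival under isothermal holds has a closed form and survival under linear
temperature ramps is obtained by quadrature.  Because denaturation is
irreversible and memoryless, losses accumulate monotonically along the program,
which is exactly the property a single-ramp thermal-shift experiment exploits:
any difference in denaturation rate between two conditions at any temperature
persists in the final soluble abundance.

Temperatures are degrees Celsius at every interface and converted to Kelvin
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq, least_squares

GAS_CONSTANT = 8.314  # J/(mol*K)
CELSIUS_OFFSET = 273.15

#: Default activation energy, J/mol — on the high side of the published range
#: for irreversible protein denaturation near the melting point, and chosen
#: so that, with kinetics calibrated to the 51 C mammalian-average melting
#: point, the 37->57 C @ 0.2 C/s ramp is equivalent to a ~52 C isothermal
#: 3-minute hold (the empirically observed equivalence).
DEFAULT_ACTIVATION_ENERGY = 550e3

#: The standard 10-point TPP temperature ladder (degrees C), ascending.  The
#: published protocol table contains an out-of-order value of 68.6 C between
#: 55.5 and 62 C which is almost certainly a transcription error for 58.6 C;
#: the corrected, sorted ladder is the default and the verbatim one is
#: available via ``tpp_ladder(verbatim=True)``.
TPP_LADDER = (37.0, 40.4, 44.0, 46.9, 49.8, 52.9, 55.5, 58.6, 62.0, 66.3)
TPP_LADDER_VERBATIM = (37.0, 40.4, 44.0, 46.9, 49.8, 52.9, 55.5, 68.6, 62.0, 66.3)

TPP_HOLD_SECONDS = 180.0
STPP_RAMP_START = 37.0
STPP_RAMP_RATE = 0.2  # C/s
STPP_EQUILIBRATION_SECONDS = 5.0
DEFAULT_TMAX = 57.0


class InvalidParameterError(ValueError):
    """A kinetic or program parameter is non-finite or out of range."""


class NoSolutionError(RuntimeError):
    """The requested equation has no solution in the admissible range."""


class NoTm50Error(NoSolutionError):
    """The melting curve never falls to 50% of its reference value."""


def tpp_ladder(verbatim: bool = False) -> tuple[float, ...]:
    """Return the 10-point TPP temperature ladder.

    ``verbatim=True`` returns the ladder exactly as printed in the protocol
    (with the out-of-order 68.6 C entry) instead of the corrected default.
    """
    return TPP_LADDER_VERBATIM if verbatim else TPP_LADDER


# ---------------------------------------------------------------------------
# Heating programs
# ---------------------------------------------------------------------------


def _check_temperature(value: float, what: str) -> None:
    if not math.isfinite(value) or not (0.0 <= value <= 100.0):
        raise InvalidParameterError(f"{what} must be within [0, 100] C, got {value!r}")


@dataclass(frozen=True)
class Hold:
    """Isothermal segment: ``duration`` seconds at ``temperature`` C."""

    temperature: float
    duration: float

    def __post_init__(self) -> None:
        _check_temperature(self.temperature, "hold temperature")
        if not math.isfinite(self.duration) or self.duration <= 0:
            raise InvalidParameterError(
                f"hold duration must be finite and > 0, got {self.duration!r}"
            )


@dataclass(frozen=True)
class Ramp:
    """Linear heating segment from ``start`` to ``end`` C at ``rate`` C/s."""

    start: float
    end: float
    rate: float

    def __post_init__(self) -> None:
        _check_temperature(self.start, "ramp start")
        _check_temperature(self.end, "ramp end")
        if not math.isfinite(self.rate) or self.rate <= 0:
            raise InvalidParameterError(f"ramp rate must be > 0, got {self.rate!r}")
        if self.end <= self.start:
            raise InvalidParameterError(
                f"ramp must heat upward: start={self.start}, end={self.end}"
            )

    @property
    def duration(self) -> float:
        return (self.end - self.start) / self.rate


Segment = Union[Hold, Ramp]


@dataclass(frozen=True)
class HeatingProgram:
    """An ordered sequence of holds and linear ramps.

    Named constructors build the three canonical programs:

    * :meth:`tpp_step` — a single 3-minute hold at one ladder temperature;
    * :meth:`stpp_up_ramp` — a brief 37 C equilibration followed by a linear
      ramp to ``t_max`` (default 57 C at 0.2 C/s);
    * :meth:`isothermal` — a 3-minute hold at ``t_max`` (constant-incubation
      comparison arm).
    """

    segments: tuple[Segment, ...]

    def __post_init__(self) -> None:
        if not self.segments:
            raise InvalidParameterError("heating program needs at least one segment")
        for seg in self.segments:
            if not isinstance(seg, (Hold, Ramp)):
                raise InvalidParameterError(f"unknown segment type: {seg!r}")

    @property
    def total_duration(self) -> float:
        return sum(seg.duration for seg in self.segments)

    def then(self, other: "HeatingProgram") -> "HeatingProgram":
        """Concatenate two programs."""
        return HeatingProgram(self.segments + other.segments)

    @classmethod
    def tpp_step(cls, temperature: float, duration: float = TPP_HOLD_SECONDS) -> "HeatingProgram":
        return cls((Hold(temperature, duration),))

    @classmethod
    def stpp_up_ramp(
        cls,
        t_max: float = DEFAULT_TMAX,
        rate: float = STPP_RAMP_RATE,
        start: float = STPP_RAMP_START,
        equilibration: float = STPP_EQUILIBRATION_SECONDS,
    ) -> "HeatingProgram":
        return cls((Hold(start, equilibration), Ramp(start, t_max, rate)))

    @classmethod
    def isothermal(cls, t_max: float, duration: float = TPP_HOLD_SECONDS) -> "HeatingProgram":
        return cls((Hold(t_max, duration),))


# ---------------------------------------------------------------------------
# Arrhenius kinetics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ArrheniusKinetics:
    """First-order denaturation rate k(T) = A exp(-Ea / (R T_K)).

    ``log_preexponential`` is ln(A / s^-1); ``-inf`` encodes A = 0 (a protein
    that never denatures).  ``activation_energy`` is in J/mol.
    """

    log_preexponential: float
    activation_energy: float

    def __post_init__(self) -> None:
        if math.isnan(self.log_preexponential) or self.log_preexponential == math.inf:
            raise InvalidParameterError(
                f"log_preexponential must be finite or -inf, got {self.log_preexponential!r}"
            )
        if not math.isfinite(self.activation_energy) or self.activation_energy < 0:
            raise InvalidParameterError(
                f"activation_energy must be finite and >= 0, got {self.activation_energy!r}"
            )

    def log_rate(self, temperature_c):
        """ln k(T) for temperature in C (vectorized)."""
        t_k = np.asarray(temperature_c, dtype=float) + CELSIUS_OFFSET
        return self.log_preexponential - self.activation_energy / (GAS_CONSTANT * t_k)

    def rate(self, temperature_c):
        """k(T) in s^-1 for temperature in C (vectorized)."""
        if self.log_preexponential == -math.inf:
            return np.zeros_like(np.asarray(temperature_c, dtype=float))[()]
        return np.exp(self.log_rate(temperature_c))

    def with_log_preexponential(self, log_a: float) -> "ArrheniusKinetics":
        return ArrheniusKinetics(log_a, self.activation_energy)


def _ramp_exponent(kinetics: ArrheniusKinetics, ramp: Ramp) -> float:
    """Integral of k(T(t)) dt over a linear ramp, by adaptive quadrature."""

    def rate_at(t: float) -> float:
        return float(kinetics.rate(ramp.start + ramp.rate * t))

    value, _err = quad(rate_at, 0.0, ramp.duration, epsabs=1e-12, epsrel=1e-10, limit=200)
    return value


def decay_exponent(kinetics: ArrheniusKinetics, program: HeatingProgram) -> float:
    """Integral of k(T(t)) dt over the whole program (so S = exp(-exponent))."""
    if kinetics.log_preexponential == -math.inf:
        return 0.0
    total = 0.0
    for seg in program.segments:
        if isinstance(seg, Hold):
            total += float(kinetics.rate(seg.temperature)) * seg.duration
        else:
            total += _ramp_exponent(kinetics, seg)
    return total


def survival_fraction(kinetics: ArrheniusKinetics, program: HeatingProgram) -> float:
    """Soluble fraction remaining after running ``program``.

    Holds are evaluated in closed form; ramps by adaptive quadrature with
    absolute tolerance well below 1e-9.  Always in [0, 1].
    """
    return math.exp(-decay_exponent(kinetics, program))


def isothermal_equivalent_temperature(
    kinetics: ArrheniusKinetics,
    program: HeatingProgram,
    reference_duration: float = TPP_HOLD_SECONDS,
) -> float:
    """Temperature T* such that a ``reference_duration`` hold at T* denatures
    exactly as much as ``program`` does, for the given kinetics.

    Solves exp(-k(T*) * reference_duration) = survival_fraction(program) by
    bracketed root finding on [0, 100] C to better than 0.01 C.  Raises
    :class:`NoSolutionError` when the program's survival is 0 or 1 (no finite
    isothermal equivalent) or when T* falls outside [0, 100] C.
    """
    exponent = decay_exponent(kinetics, program)
    if exponent <= 0 or not math.isfinite(exponent) or math.exp(-exponent) <= 0.0:
        raise NoSolutionError(
            "program survival is 0 or 1; no isothermal equivalent exists"
        )
    target_log_rate = math.log(exponent / reference_duration)

    def gap(t: float) -> float:
        return float(kinetics.log_rate(t)) - target_log_rate

    lo, hi = 0.0, 100.0
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo == 0.0:
        return lo
    if g_hi == 0.0:
        return hi
    if g_lo * g_hi > 0:
        raise NoSolutionError(
            "isothermal equivalent temperature falls outside [0, 100] C"
        )
    return float(brentq(gap, lo, hi, xtol=1e-4))


def calibrate_kinetics(
    target_tm50: float,
    activation_energy: float = DEFAULT_ACTIVATION_ENERGY,
    exposure: float = TPP_HOLD_SECONDS,
) -> ArrheniusKinetics:
    """Kinetics whose survival after an ``exposure``-second hold at
    ``target_tm50`` is exactly 1/2, i.e. the isothermal melting curve sampled
    with this exposure has its 50% point at ``target_tm50``.

    The pre-exponential factor has the closed form
    A = ln 2 / (exposure * exp(-Ea / (R T_K))).
    """
    if not (37.0 < target_tm50 < 70.0):
        raise InvalidParameterError(
            f"target_tm50 must be in (37, 70) C, got {target_tm50!r}"
        )
    if not math.isfinite(activation_energy) or activation_energy <= 0:
        raise InvalidParameterError("activation_energy must be finite and > 0")
    if not math.isfinite(exposure) or exposure <= 0:
        raise InvalidParameterError("exposure must be finite and > 0")
    t_k = target_tm50 + CELSIUS_OFFSET
    log_a = math.log(math.log(2.0) / exposure) + activation_energy / (GAS_CONSTANT * t_k)
    return ArrheniusKinetics(log_a, activation_energy)


# ---------------------------------------------------------------------------
# Sigmoid melting curves and T_m-50
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MeltCurveParams:
    """Descending sigmoid soluble-fraction curve.

    f(T) = (1 - plateau) / (1 + exp(steepness * (T - midpoint))) + plateau

    ``midpoint`` is the inflection temperature (C), ``steepness`` (1/C) > 0
    controls the transition width, and ``plateau`` in [0, 1) is the
    non-melting residual fraction at high temperature.
    """

    midpoint: float
    steepness: float
    plateau: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.midpoint):
            raise InvalidParameterError("midpoint must be finite")
        if not math.isfinite(self.steepness) or self.steepness <= 0:
            raise InvalidParameterError(f"steepness must be > 0, got {self.steepness!r}")
        if not (0.0 <= self.plateau < 1.0):
            raise InvalidParameterError(f"plateau must be in [0, 1), got {self.plateau!r}")

    def fraction(self, temperature_c):
        """Soluble fraction at temperature(s) in C (vectorized)."""
        t = np.asarray(temperature_c, dtype=float)
        return (1.0 - self.plateau) / (1.0 + np.exp(self.steepness * (t - self.midpoint))) + self.plateau


@dataclass(frozen=True)
class MeltCurveFit:
    """Result of :func:`fit_melt_curve`: parameters, residual sum of squares,
    and a flag marking degenerate fits (no melting transition in the data)."""

    params: MeltCurveParams
    rss: float
    ok: bool
    message: str = ""


def fit_melt_curve(temperatures: Sequence[float], fractions: Sequence[float]) -> MeltCurveFit:
    """Least-squares fit of the sigmoid melting model to (T, fraction) data.

    Deterministic: a fixed multi-start grid over plausible midpoints and
    steepnesses seeds bounded trust-region least squares, and the best
    residual wins.  Data incompatible with a melting transition (flat or
    rising) produce a flagged-failure result instead of raising.
    """
    t = np.asarray(temperatures, dtype=float)
    f = np.asarray(fractions, dtype=float)
    if t.ndim != 1 or t.shape != f.shape:
        raise InvalidParameterError("temperatures and fractions must be 1-D and equal length")
    if np.unique(t).size < 4:
        raise InvalidParameterError("need at least 4 distinct temperatures")
    if not np.all(np.isfinite(t)) or not np.all(np.isfinite(f)):
        raise InvalidParameterError("temperatures and fractions must be finite")

    span = float(f.max() - f.min())
    fallback = MeltCurveParams(float(np.median(t)), 0.5, min(max(float(f.min()), 0.0), 0.999))
    if span < 0.05:
        return MeltCurveFit(fallback, float(np.sum((f - f.mean()) ** 2)), False,
                            "no melting transition: fraction range < 0.05")

    lo_t, hi_t = float(t.min()), float(t.max())
    bounds = ([lo_t - 20.0, 1e-3, 0.0], [hi_t + 20.0, 10.0, 0.999])

    def residual(theta: np.ndarray) -> np.ndarray:
        mid, steep, plat = theta
        return (1.0 - plat) / (1.0 + np.exp(steep * (t - mid))) + plat - f

    best = None
    plateau0 = min(max(float(f.min()), 0.0), 0.99)
    for mid0 in np.linspace(lo_t, hi_t, 7):
        for steep0 in (0.1, 0.3, 0.6, 1.2):
            try:
                sol = least_squares(residual, x0=[mid0, steep0, plateau0],
                                    bounds=bounds, method="trf", xtol=1e-12, ftol=1e-12)
            except Exception:
                continue
            rss = float(np.sum(sol.fun ** 2))
            if best is None or rss < best[0] - 1e-15:
                best = (rss, sol.x)
    if best is None:
        return MeltCurveFit(fallback, math.inf, False, "optimizer failed on every start")
    rss, (mid, steep, plat) = best
    params = MeltCurveParams(float(mid), float(max(steep, 1e-3)), float(min(max(plat, 0.0), 0.999)))
    return MeltCurveFit(params, rss, True)


def tm50(curve: MeltCurveParams, reference_temperature: float = 37.0) -> float:
    """Temperature at which the curve falls to 50% of its value at the
    reference (lowest-ladder) temperature.

    Closed form from the sigmoid; raises :class:`NoTm50Error` when the 50%
    level lies at or below the plateau and is therefore never reached.
    """
    f_ref = float(curve.fraction(reference_temperature))
    if f_ref <= 0:
        raise InvalidParameterError("curve must be positive at the reference temperature")
    level = 0.5 * f_ref
    if level <= curve.plateau:
        raise NoTm50Error(
            f"50% of f({reference_temperature}) = {level:.4f} never reached: "
            f"plateau = {curve.plateau:.4f}"
        )
    # (1-p)/(1+exp(s(T-m))) = level - p  =>  T = m + ln((1-p)/(level-p) - 1)/s
    arg = (1.0 - curve.plateau) / (level - curve.plateau) - 1.0
    if arg <= 0:
        raise NoTm50Error("50% level lies above the curve over its whole range")
    return curve.midpoint + math.log(arg) / curve.steepness
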