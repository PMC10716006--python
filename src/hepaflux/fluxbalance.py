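"""Steady-state G6P flux balance: from isotope parameters to enzyme fluxes.

Glucose 6-phosphate (G6P) is the central hepatic node.  Under isotopic steady
state the fluxes toward G6P — glucokinase (GCK), glycogen phosphorylase (GP)
and gluconeogenesis (GNG) — balance the fluxes away from it: glucose-6-
phosphatase (G6Pase) and glycogen synthase (GS).  Glycolysis is deliberately
not a model flux (its intermediates cannot be sampled repeatedly in vivo), so
GCK and GNG are lower bounds; G6PC-independent glucose production is likewise
folded into the GP and G6Pase terms.

Six dimensionless isotope parameters, averaged over the isotopic steady
state, drive the solution:

* ``d_glc``  — dilution of infused [U-¹³C]glucose in blood glucose (m+6);
* ``d_udpglc`` — dilution of infused [1-²H]galactose in UDP-glucose (²H m+1);
* ``c_glc``  — fractional contribution of blood glucose to UDP-glucose
  (UDP-glucose m+6 over blood m+6: the direct pathway);
* ``c_udpglc`` — fractional contribution of UDP-glucose to blood glucose
  (blood ²H m+1 over UDP-glucose ²H m+1: glycogen/UDP-glucose cycling);
* ``f_glc``, ``f_udpglc`` — MIDA fractional gluconeogenic (new-F16P)
  contributions to blood glucose and UDP-glucose.

The default "g6p-balance" closure:

    Ra     = I6 / d_glc                    total glucose turnover
    EGP    = Ra - I6                       endogenous glucose production
    G6Pase = EGP / (1 - c_glc)             glucose-cycling correction
    Ru     = Igal / d_udpglc               UDP-glucose turnover
    GS     = Ru - Igal                     G6P-derived UDP-glucose synthesis
    T      = G6Pase + GS                   total G6P turnover
    GCK    = c_glc * T
    GNG    = f_udpglc * T                  (gluconeogenesis into G6P)
    GP     = T - GCK - GNG                 (balance remainder)

so GCK + GP + GNG = G6Pase + GS holds identically.  The closure registry
allows alternative equation sets to be registered and cross-validated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dataclass_fields
from typing import Callable

from .exceptions import (
    ConfigurationError,
    DomainError,
    IndeterminateError,
    InfeasibleParametersError,
)
from .protocol import InfusionProtocol

__all__ = [
    "PrimaryIsotopeParams",
    "FluxSet",
    "compute_dilution",
    "compute_exchange",
    "compute_turnover",
    "compute_clearance",
    "m3m6_ratio",
    "solve_fluxes",
    "register_closure",
    "available_closures",
    "BALANCE_TOL",
]

#: Numerical tolerance on the G6P balance identity.
BALANCE_TOL = 1e-9

#: Default isotopic purity of the infused tracers.
DEFAULT_PURITY = 0.99


@dataclass(frozen=True)
class PrimaryIsotopeParams:
    """The six steady-state isotope parameters for one animal (all dimensionless)."""

    d_glc: float
    d_udpglc: float
    c_glc: float
    c_udpglc: float
    f_glc: float
    f_udpglc: float

    def __post_init__(self):
        for name in ("d_glc", "d_udpglc"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise DomainError(f"{name} must be in (0,1], got {v}")
        for name in ("c_glc", "c_udpglc", "f_glc", "f_udpglc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise DomainError(f"{name} must be in [0,1], got {v}")

    @property
    def feasible(self) -> bool:
        """Whether the parameters admit a nonnegative phosphorylase flux."""
        return self.c_glc + self.f_udpglc <= 1.0 + 1e-12


@dataclass(frozen=True)
class FluxSet:
    """Solved hepatic carbohydrate fluxes, μmol·kg⁻¹·min⁻¹ unless noted.

    Attributes
    ----------
    ra, ru : float
        Total blood-glucose and UDP-glucose turnover (tracer included).
    egp : float
        Endogenous glucose production, ``ra - I6``.
    gck, g6pase, gs, gp, gng_g6p : float
        The five G6P-node fluxes (glucokinase, glucose-6-phosphatase,
        glycogen synthase, glycogen phosphorylase, gluconeogenesis into G6P).
    gng_blood : float
        Gluconeogenic flux into blood glucose, ``f_glc * ra`` — the quantity
        reported as "gluconeogenesis flux" in study figures.
    glucose_balance : float
        Net hepatic glucose output, ``g6pase - gck``.
    glycogen_balance : float
        Net glycogen deposition, ``gs - gp``.
    clearance : float or None
        Glucose clearance, mL·kg⁻¹·min⁻¹ (needs a blood glucose concentration).
    m3m6_glc, m3m6_udpglc : float or None
        Glycolytic-recycling ratios, dimensionless.
    """

    ra: float
    ru: float
    egp: float
    gck: float
    g6pase: float
    gs: float
    gp: float
    gng_g6p: float
    gng_blood: float
    glucose_balance: float
    glycogen_balance: float
    clearance: float | None = None
    m3m6_glc: float | None = None
    m3m6_udpglc: float | None = None
    closure: str = "g6p-balance"

    def __post_init__(self):
        for name in ("ra", "ru", "egp", "gck", "g6pase", "gs", "gp", "gng_g6p", "gng_blood"):
            v = getattr(self, name)
            if v < -BALANCE_TOL:
                raise DomainError(f"flux {name} is negative: {v}")
        if abs(self.balance_residual) > BALANCE_TOL * max(1.0, self.g6pase + self.gs):
            raise DomainError(
                f"G6P balance violated: GCK+GP+GNG - (G6Pase+GS) = {self.balance_residual:.3g}"
            )

    @property
    def balance_residual(self) -> float:
        """GCK + GP + GNG_G6P - (G6Pase + GS); zero for a valid flux set."""
        return (self.gck + self.gp + self.gng_g6p) - (self.g6pase + self.gs)

    def as_dict(self) -> dict[str, float | str | None]:
        return {f.name: getattr(self, f.name) for f in dataclass_fields(self)}


def compute_dilution(tracer_excess: float, tracer_purity: float = DEFAULT_PURITY) -> float:
    """Tracer dilution d = excess enrichment / isotopic purity.

    ``tracer_excess`` is the m+6 excess for blood glucose or the ²H m+1
    excess for UDP-glucose.
    """
    if not 0.0 < tracer_purity <= 1.0:
        raise DomainError(f"tracer purity must be in (0,1], got {tracer_purity}")
    if tracer_excess <= 0.0:
        raise IndeterminateError(
            "zero tracer excess implies infinite dilution; pool not labelled"
        )
    if tracer_excess > tracer_purity * (1.0 + 1e-9):
        raise DomainError(
            f"tracer excess {tracer_excess} exceeds purity {tracer_purity}: "
            "pool cannot be more enriched than the infusate"
        )
    return min(1.0, tracer_excess / tracer_purity)


def compute_exchange(
    m6_udpglc: float,
    m6_glc: float,
    h2_m1_glc: float,
    h2_m1_udpglc: float,
    noise_floor: float = 1e-9,
) -> tuple[float, float]:
    """Exchange fractions (c_glc, c_udpglc) between the two hexose pools.

    c_glc = UDP-glucose m+6 / blood m+6 (blood glucose -> UDP-glucose);
    c_udpglc = blood ²H m+1 / UDP-glucose ²H m+1 (UDP-glucose -> blood).
    """
    if m6_glc <= noise_floor:
        raise IndeterminateError(
            "blood glucose m+6 enrichment below noise floor", floor=noise_floor
        )
    if h2_m1_udpglc <= noise_floor:
        raise IndeterminateError(
            "UDP-glucose ²H m+1 enrichment below noise floor", floor=noise_floor
        )
    c_glc = m6_udpglc / m6_glc
    c_udpglc = h2_m1_glc / h2_m1_udpglc
    if not (0.0 <= c_glc <= 1.0 and 0.0 <= c_udpglc <= 1.0):
        raise DomainError(
            f"exchange fractions outside [0,1]: c_glc={c_glc:.4g}, c_udpglc={c_udpglc:.4g}"
        )
    return c_glc, c_udpglc


def compute_turnover(I: float, d: float) -> tuple[float, float]:
    """Pool turnover from tracer dilution: (total appearance I/d, endogenous I/d - I)."""
    if I <= 0:
        raise DomainError("infusion rate must be positive")
    if not 0.0 < d <= 1.0:
        raise DomainError(f"dilution must be in (0,1], got {d}")
    total = I / d
    return total, total - I


def compute_clearance(Ra: float, blood_glucose_mM: float) -> float:
    """Glucose clearance = turnover / concentration, mL·kg⁻¹·min⁻¹ (mM = μmol/mL)."""
    if blood_glucose_mM <= 0:
        raise DomainError("blood glucose concentration must be positive")
    if Ra < 0:
        raise DomainError("turnover must be nonnegative")
    return Ra / blood_glucose_mM


def m3m6_ratio(excess_m3: float, excess_m6: float, noise_floor: float = 1e-9) -> float:
    """Glycolytic recycling ratio m+3/m+6 from a pool's excess MID."""
    if excess_m6 <= noise_floor:
        raise IndeterminateError("m+6 excess below noise floor", floor=noise_floor)
    if excess_m3 < 0:
        raise DomainError("m+3 excess must be nonnegative")
    return excess_m3 / excess_m6


# --------------------------------------------------------------------------
# closure registry

ClosureFn = Callable[[PrimaryIsotopeParams, float, float], dict[str, float]]

_CLOSURES: dict[str, ClosureFn] = {}


def register_closure(name: str, fn: ClosureFn) -> None:
    """Register an alternative steady-state equation set under ``name``."""
    _CLOSURES[name] = fn


def available_closures() -> list[str]:
    return sorted(_CLOSURES)


def _g6p_balance_closure(params: PrimaryIsotopeParams, I6: float, Igal: float) -> dict[str, float]:
    if params.c_glc >= 1.0:
        raise DomainError(
            f"c_glc = {params.c_glc} >= 1: glucose-cycling correction diverges"
        )
    ra, egp = compute_turnover(I6, params.d_glc)
    ru, gs = compute_turnover(Igal, params.d_udpglc)
    g6pase = egp / (1.0 - params.c_glc)
    total_g6p = g6pase + gs
    gck = params.c_glc * total_g6p
    gng_g6p = params.f_udpglc * total_g6p
    gp = total_g6p - gck - gng_g6p
    if gp < 0:
        if gp > -1e-12 * max(1.0, total_g6p):
            gp = 0.0
        else:
            raise InfeasibleParametersError(
                f"c_glc + f_udpglc = {params.c_glc + params.f_udpglc:.4g} > 1 implies "
                f"negative glycogen phosphorylase flux ({gp:.4g})",
                value=gp,
            )
    return {
        "ra": ra,
        "ru": ru,
        "egp": egp,
        "gck": gck,
        "g6pase": g6pase,
        "gs": gs,
        "gp": gp,
        "gng_g6p": gng_g6p,
        "gng_blood": params.f_glc * ra,
        "glucose_balance": g6pase - gck,
        "glycogen_balance": gs - gp,
    }


register_closure("g6p-balance", _g6p_balance_closure)


def solve_fluxes(
    params: PrimaryIsotopeParams,
    protocol: InfusionProtocol,
    blood_glucose_mM: float | None = None,
    excess_m3m6: tuple[float, float] | None = None,
    closure: str = "g6p-balance",
) -> FluxSet:
    """Solve the steady-state flux balance for one animal.

    Parameters
    ----------
    params
        Steady-state-averaged isotope parameters.
    protocol
        Infusion protocol (supplies I6 and Igal).
    blood_glucose_mM
        Mean blood glucose over the steady-state window; enables clearance.
    excess_m3m6
        Optional ``(m3m6_glc, m3m6_udpglc)`` recycling ratios to carry along.
    closure
        Registered equation set; "g6p-balance" is the default.

    Raises
    ------
    InfeasibleParametersError
        If ``c_glc + f_udpglc > 1`` (negative phosphorylase share); never
        silently clipped.
    """
    try:
        fn = _CLOSURES[closure]
    except KeyError:
        raise ConfigurationError(
            f"unknown closure {closure!r}; available: {available_closures()}"
        )
    fluxes = fn(params, protocol.I6, protocol.Igal)
    clearance = (
        compute_clearance(fluxes["ra"], blood_glucose_mM)
        if blood_glucose_mM is not None
        else None
    )
    m3m6_glc = m3m6_udpglc = None
    if excess_m3m6 is not None:
        m3m6_glc, m3m6_udpglc = excess_m3m6
    return FluxSet(
        clearance=clearance,
        m3m6_glc=m3m6_glc,
        m3m6_udpglc=m3m6_udpglc,
        closure=closure,
        **fluxes,
    )
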