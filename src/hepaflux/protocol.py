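"""Infusion protocol: tracer identities, concentrations and molar infusion rates.

The triple-tracer protocol infuses [U-¹³C]glucose, [2-¹³C]glycerol and
[1-²H]galactose together with paracetamol (the urinary glucuronide reporter
of hepatic UDP-glucose) at a constant pump rate.  Flux equations need the
per-kilogram molar infusion rates of the glucose and galactose tracers,
I6 and Igal, in μmol·kg⁻¹·min⁻¹; molecular masses of the *labelled* species
are used for the conversion.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import DomainError

__all__ = ["TRACER_MASSES", "InfusionProtocol", "DEFAULT_PROTOCOL"]

#: Molecular masses (g/mol) of the labelled tracer species.
TRACER_MASSES: dict[str, float] = {
    "u13c_glucose": 186.11,  # C6H12O6 with six 13C
    "2_13c_glycerol": 93.09,  # C3H8O3 with one 13C
    "1_2h_galactose": 181.16,  # C6H12O6 with one 2H
    "paracetamol": 151.16,
}


@dataclass(frozen=True)
class InfusionProtocol:
    """Tracer concentrations, pump rate and body weight for one animal.

    Defaults are the study protocol: 2.5 mg/mL [U-¹³C]glucose, 16 mg/mL
    [2-¹³C]glycerol, 6 mg/mL [1-²H]galactose and 2 mg/mL paracetamol infused
    at 0.5 mL/h into an overnight-fasted adult mouse (~22 g).
    """

    glucose_conc_mg_ml: float = 2.5
    glycerol_conc_mg_ml: float = 16.0
    galactose_conc_mg_ml: float = 6.0
    paracetamol_conc_mg_ml: float = 2.0
    pump_rate_ml_h: float = 0.5
    body_weight_g: float = 22.0
    glucose_tracer_mass: float = TRACER_MASSES["u13c_glucose"]
    galactose_tracer_mass: float = TRACER_MASSES["1_2h_galactose"]

    def __post_init__(self):
        for name in (
            "glucose_conc_mg_ml",
            "glycerol_conc_mg_ml",
            "galactose_conc_mg_ml",
            "pump_rate_ml_h",
            "body_weight_g",
            "glucose_tracer_mass",
            "galactose_tracer_mass",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    @classmethod
    def from_rates(cls, I6: float, Igal: float, **kwargs) -> "InfusionProtocol":
        """Protocol with the given molar infusion rates (μmol·kg⁻¹·min⁻¹) directly.

        Useful when rates rather than concentrations are known; constructs an
        equivalent unit protocol (1 kg, unit masses, 0.06 mL/h) whose derived
        ``I6`` and ``Igal`` equal the arguments exactly.
        """
        if I6 <= 0 or Igal <= 0:
            raise DomainError("infusion rates must be positive")
        return cls(
            glucose_conc_mg_ml=I6,
            galactose_conc_mg_ml=Igal,
            pump_rate_ml_h=0.06,
            body_weight_g=1000.0,
            glucose_tracer_mass=1.0,
            galactose_tracer_mass=1.0,
            **kwargs,
        )

    def _molar_rate(self, conc_mg_ml: float, mass_g_mol: float) -> float:
        # mg/h -> umol/h -> umol/min, per kg body weight
        umol_per_h = 1000.0 * conc_mg_ml * self.pump_rate_ml_h / mass_g_mol
        return umol_per_h / 60.0 / (self.body_weight_g / 1000.0)

    @property
    def I6(self) -> float:
        """[U-¹³C]glucose infusion rate, μmol·kg⁻¹·min⁻¹."""
        return self._molar_rate(self.glucose_conc_mg_ml, self.glucose_tracer_mass)

    @property
    def Igal(self) -> float:
        """[1-²H]galactose infusion rate, μmol·kg⁻¹·min⁻¹."""
        return self._molar_rate(self.galactose_conc_mg_ml, self.galactose_tracer_mass)


DEFAULT_PROTOCOL = InfusionProtocol()
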