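"""Reference inputs: published steady-state isotope parameter means.

The original 2×2 mouse study (scrambled shRNA vs ChREBP-directed shRNA,
vehicle vs S4048 infusion) reported group means of the six primary isotope
parameters during isotopic steady state.  Those printed means are usable as
inputs: feeding them through the flux solver reproduces the study's flux
comparisons, and inverting them gives realistic group truths for the
synthetic cohort generator.
"""

from __future__ import annotations

import pandas as pd

from .fluxbalance import PrimaryIsotopeParams

__all__ = [
    "GROUPS",
    "REFERENCE_ISOTOPE_PARAMETERS",
    "reference_isotope_parameters",
    "reference_params",
]

#: The four experimental groups, as "{shrna}_{infusion}".
GROUPS = ("shSCR_vehicle", "shChREBP_vehicle", "shSCR_S4048", "shChREBP_S4048")

#: Group means of the six steady-state isotope parameters (dimensionless).
REFERENCE_ISOTOPE_PARAMETERS: dict[str, dict[str, float]] = {
    "shSCR_vehicle": {
        "d_glc": 0.033, "d_udpglc": 0.262, "c_glc": 0.215,
        "c_udpglc": 0.188, "f_glc": 0.786, "f_udpglc": 0.6651,
    },
    "shChREBP_vehicle": {
        "d_glc": 0.031, "d_udpglc": 0.242, "c_glc": 0.3211,
        "c_udpglc": 0.186, "f_glc": 0.751, "f_udpglc": 0.6498,
    },
    "shSCR_S4048": {
        "d_glc": 0.064, "d_udpglc": 0.161, "c_glc": 0.0562,
        "c_udpglc": 0.201, "f_glc": 0.756, "f_udpglc": 0.7519,
    },
    "shChREBP_S4048": {
        "d_glc": 0.059, "d_udpglc": 0.123, "c_glc": 0.0743,
        "c_udpglc": 0.233, "f_glc": 0.711, "f_udpglc": 0.7456,
    },
}


def reference_isotope_parameters() -> pd.DataFrame:
    """The reference group means as a DataFrame indexed by group."""
    df = pd.DataFrame.from_dict(REFERENCE_ISOTOPE_PARAMETERS, orient="index")
    df.index.name = "group"
    return df


def reference_params(group: str) -> PrimaryIsotopeParams:
    """Reference group means packed into a :class:`PrimaryIsotopeParams`."""
    try:
        values = REFERENCE_ISOTOPE_PARAMETERS[group]
    except KeyError:
        raise KeyError(f"unknown group {group!r}; expected one of {GROUPS}")
    return PrimaryIsotopeParams(**values)
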