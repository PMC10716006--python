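"""Mass isotopomer distribution analysis (MIDA) for the two-triose hexose polymer.

Hexoses made by gluconeogenesis are condensed from two triose phosphates.
During [2-¹³C]glycerol infusion each triose carries the label with the
precursor enrichment ``p``, so a *newly synthesized* fructose-1,6-bisphosphate
(F16P) molecule is m+0/m+1/m+2 with binomial weights (1-p)², 2p(1-p), p².
Sampled hexose pools (blood glucose, UDP-glucose) are mixtures of new and
pre-existing molecules; the fraction ``f`` of new molecules scales the whole
binomial pattern.  From the measured m+1 and m+2 excesses alone both ``p``
and ``f`` are identified:

    r = E2/E1 = p / (2(1-p))   =>   p = 2r / (1 + 2r)
    f = E2 / p²

Only the carbon-only derivative channel feeds these formulas, so the
[1-²H]galactose label cannot contaminate m+1; the [U-¹³C]glucose tracer and
its glycolytic recycling products appear at m+6 and m+3 and are disjoint from
the m+1/m+2 channel by mass.
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import DomainError, IndeterminateError
from .isotopes import Analyte

__all__ = [
    "MIDAResult",
    "theoretical_hexose_mid",
    "estimate_precursor_p",
    "fractional_synthesis",
    "analyze",
]

#: Below this m+1 excess the precursor enrichment is considered unidentifiable.
DEFAULT_NOISE_FLOOR = 1e-9


@dataclass(frozen=True)
class MIDAResult:
    """Precursor enrichment and fractional synthesis for one analyte measurement.

    Attributes
    ----------
    p : float
        Triose-phosphate ¹³C enrichment, in (0, 1).
    f : float
        Fractional contribution of newly synthesized F16P to the sampled
        hexose pool, in [0, 1].
    clipped : bool
        True when the raw ``f`` exceeded 1 and was clipped (measurement noise
        or a precursor-pool mismatch).
    """

    p: float
    f: float
    analyte: Analyte
    clipped: bool = False


def theoretical_hexose_mid(p: float) -> tuple[float, float, float]:
    """(m0, m1, m2) pattern of a hexose freshly assembled from two labelled trioses."""
    if not 0.0 <= p <= 1.0:
        raise DomainError(f"precursor enrichment p must be in [0,1], got {p}")
    return (1.0 - p) ** 2, 2.0 * p * (1.0 - p), p * p


def estimate_precursor_p(
    excess_m1: float,
    excess_m2: float,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
) -> float:
    """Invert the two-triose binomial: precursor enrichment from the m+2/m+1 ratio.

    Exact inverse of :func:`theoretical_hexose_mid` ratios and independent of
    the fractional synthesis, which cancels in the ratio.
    """
    if excess_m2 < 0:
        raise DomainError("excess_m2 must be >= 0")
    if excess_m1 <= noise_floor:
        raise IndeterminateError(
            f"m+1 excess {excess_m1:.3g} at or below noise floor {noise_floor:.3g}: "
            "precursor enrichment unidentifiable",
            floor=noise_floor,
        )
    r = excess_m2 / excess_m1
    return 2.0 * r / (1.0 + 2.0 * r)


def fractional_synthesis(excess_m2: float, p: float) -> tuple[float, bool]:
    """Fraction of the sampled pool that is newly synthesized: f = E2 / p².

    Returns ``(f, clipped)``; values marginally above 1 are clipped with the
    flag set rather than silently accepted.
    """
    if excess_m2 < 0:
        raise DomainError("excess_m2 must be >= 0")
    if p == 0.0:
        if excess_m2 > 0:
            raise DomainError("m+2 excess with zero precursor enrichment is inconsistent")
        return 0.0, False
    if not 0.0 < p <= 1.0:
        raise DomainError(f"precursor enrichment p must be in (0,1], got {p}")
    f = excess_m2 / (p * p)
    if f > 1.0:
        return 1.0, True
    return f, False


def analyze(
    excess_m1: float,
    excess_m2: float,
    analyte: Analyte,
    noise_floor: float = DEFAULT_NOISE_FLOOR,
    fallback_p: float | None = None,
) -> MIDAResult:
    """Full MIDA for one sample: estimate p, then f.

    If the m+1 excess is below the noise floor the per-analyte ``p`` is
    unidentifiable; ``fallback_p`` (typically the blood-glucose estimate for
    the same animal) is then used, and with no fallback and no m+2 signal the
    pool is reported as containing no newly synthesized material (f = 0,
    p = 0).
    """
    if excess_m1 > noise_floor:
        p = estimate_precursor_p(excess_m1, excess_m2, noise_floor)
    elif excess_m2 <= noise_floor:
        return MIDAResult(p=0.0, f=0.0, analyte=Analyte(analyte))
    elif fallback_p is not None and fallback_p > 0:
        p = fallback_p
    else:
        raise IndeterminateError(
            "m+1 excess below noise floor with m+2 signal present and no fallback p",
            floor=noise_floor,
        )
    f, clipped = fractional_synthesis(excess_m2, p)
    return MIDAResult(p=p, f=f, analyte=Analyte(analyte), clipped=clipped)
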