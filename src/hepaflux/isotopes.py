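"""Mass isotopomer distributions (MIDs) and natural-abundance correction.

A MID is the vector of fractional abundances of an analyte's isotopologues
m+0, m+1, ..., m+K separated by nominal mass shift.  For the hexose fragments
measured here K = 6.  Two GC derivatives of glucose are monitored:

* glucose **pentaacetate** retains the C1 hydrogen, so its mass shifts report
  both carbon (¹³C) and hydrogen (²H) labelling — the *combined* channel;
* glucose **aldonitrile pentaacetate** loses the C1 hydrogen during
  derivatization, so it reports carbon labelling only — the *carbon_only*
  channel.

Subtracting the two channels' m+1 excesses isolates the ²H (position-1)
enrichment contributed by the infused [1-²H]galactose.

Observed spectra are convolutions of the tracer-labelling pattern with the
natural isotope envelope of the whole derivative fragment (acetyl carbons
included: at natural abundance sixteen carbons alone put >15% of the signal
into m+1).  Correction builds the lower-triangular convolution matrix from
the fragment's elemental composition and inverts it by nonnegative least
squares, which stays stable when measurement noise would drive a direct
matrix inverse negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.optimize import nnls

from .exceptions import (
    ChannelMismatchError,
    ConfigurationError,
    InvalidMeasurementError,
)

__all__ = [
    "Analyte",
    "Channel",
    "MID",
    "FragmentFormula",
    "CorrectionMatrix",
    "NATURAL_ABUNDANCES",
    "GLUCOSE_PENTAACETATE",
    "GLUCOSE_ALDONITRILE_PENTAACETATE",
    "N_SHIFTS",
    "isotope_envelope",
    "normalize_mid",
    "build_correction_matrix",
    "correct_natural_abundance",
    "excess_mid",
    "deuterium_enrichment",
    "unlabeled_mid",
]

#: Number of mass shifts tracked for hexose fragments: m+0 ... m+6.
N_SHIFTS = 7

#: IUPAC natural isotope abundances, indexed by element symbol.  Each entry is
#: an array of fractional abundances by mass shift (index 0 = lightest).
NATURAL_ABUNDANCES: dict[str, np.ndarray] = {
    "C": np.array([1.0 - 0.0107, 0.0107]),
    "H": np.array([1.0 - 0.000115, 0.000115]),
    "N": np.array([1.0 - 0.00364, 0.00364]),
    "O": np.array([1.0 - 0.00038 - 0.00205, 0.00038, 0.00205]),
}


class Analyte(str, Enum):
    """The two sampled hexose pools."""

    BLOOD_GLUCOSE = "blood_glucose"
    UDP_GLUCOSE = "udp_glucose"


class Channel(str, Enum):
    """GC derivative channel: which labels the fragment mass reports."""

    CARBON_ONLY = "carbon_only"  # aldonitrile pentaacetate, C1-H lost
    COMBINED = "combined"  # pentaacetate, C1-H retained (13C + 2H)


@dataclass(frozen=True)
class FragmentFormula:
    """Elemental composition of a measured derivative fragment.

    Parameters
    ----------
    counts
        Element symbol -> atom count for the whole fragment (derivatization
        groups included; they contribute natural-abundance signal).
    abundances
        Optional per-element override of :data:`NATURAL_ABUNDANCES`.
    tracer_element
        Element whose labelled positions are excluded from the natural
        envelope when building correction-matrix columns; carbon for hexose
        tracers.
    """

    counts: dict[str, int]
    abundances: dict[str, np.ndarray] | None = None
    tracer_element: str = "C"

    def __post_init__(self):
        for elem, n in self.counts.items():
            if n < 0:
                raise ConfigurationError(f"negative atom count for {elem}: {n}")
        for elem, table in (self.abundances or {}).items():
            table = np.asarray(table, dtype=float)
            if np.any(table < 0) or np.any(table > 1) or abs(table.sum() - 1.0) > 1e-9:
                raise ConfigurationError(
                    f"isotope abundances for {elem} must lie in [0,1] and sum to 1"
                )

    def abundance_table(self, element: str) -> np.ndarray:
        if self.abundances and element in self.abundances:
            return np.asarray(self.abundances[element], dtype=float)
        try:
            return NATURAL_ABUNDANCES[element]
        except KeyError:
            raise ConfigurationError(f"no isotope abundance table for element {element!r}")


#: Default fragment formulas for the two glucose derivatives.  The molecular
#: species are monitored; both are configurable since different instruments
#: may monitor sub-fragments.
GLUCOSE_PENTAACETATE = FragmentFormula({"C": 16, "H": 22, "O": 11})
GLUCOSE_ALDONITRILE_PENTAACETATE = FragmentFormula({"C": 16, "H": 21, "N": 1, "O": 10})

DEFAULT_FORMULAS: dict[Channel, FragmentFormula] = {
    Channel.COMBINED: GLUCOSE_PENTAACETATE,
    Channel.CARBON_ONLY: GLUCOSE_ALDONITRILE_PENTAACETATE,
}


@dataclass(frozen=True)
class MID:
    """A normalized mass isotopomer distribution for one measurement.

    ``abundances[k]`` is the fractional abundance of the m+k isotopologue.
    """

    abundances: np.ndarray
    analyte: Analyte
    channel: Channel

    def __post_init__(self):
        arr = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "abundances", arr)
        if arr.ndim != 1:
            raise InvalidMeasurementError("MID abundances must be a 1-D vector")
        if np.any(arr < -1e-12):
            raise InvalidMeasurementError("MID abundances must be nonnegative")
        if abs(arr.sum() - 1.0) > 1e-9:
            raise InvalidMeasurementError(
                f"MID abundances must sum to 1 (got {arr.sum():.6g})"
            )

    def __len__(self) -> int:
        return len(self.abundances)

    def __getitem__(self, k: int) -> float:
        return float(self.abundances[k])


def normalize_mid(
    raw_intensities,
    analyte: Analyte = Analyte.BLOOD_GLUCOSE,
    channel: Channel = Channel.CARBON_ONLY,
) -> MID:
    """Normalize raw isotopologue intensities to fractional abundances.

    Raises
    ------
    InvalidMeasurementError
        If any entry is negative or all entries are zero.
    """
    raw = np.asarray(raw_intensities, dtype=float)
    if raw.ndim != 1:
        raise InvalidMeasurementError("intensities must be a 1-D vector")
    if np.any(raw < 0):
        raise InvalidMeasurementError("intensities must be nonnegative")
    total = raw.sum()
    if total <= 0:
        raise InvalidMeasurementError("all-zero intensity vector")
    return MID(raw / total, Analyte(analyte), Channel(channel))


def isotope_envelope(
    formula: FragmentFormula,
    max_shift: int,
    exclude: dict[str, int] | None = None,
) -> np.ndarray:
    """Natural-abundance isotopologue envelope of a fragment, truncated at ``max_shift``.

    The envelope is the convolution over elements of per-atom isotope
    distributions; ``exclude`` removes atoms (e.g. tracer-labelled carbons)
    from the natural-abundance pool.  The returned vector is *not*
    renormalized after truncation, so it sums to <= 1.
    """
    exclude = exclude or {}
    env = np.array([1.0])
    for elem, n in formula.counts.items():
        n_eff = n - exclude.get(elem, 0)
        if n_eff < 0:
            raise ConfigurationError(
                f"cannot exclude {exclude[elem]} {elem} atoms from a fragment with {n}"
            )
        per_atom = formula.abundance_table(elem)
        for _ in range(n_eff):
            env = np.convolve(env, per_atom)
            if len(env) > max_shift + 1:
                env = env[: max_shift + 1]  # higher shifts can never fold back down
    out = np.zeros(max_shift + 1)
    out[: len(env)] = env[: max_shift + 1]
    return out


@dataclass(frozen=True)
class CorrectionMatrix:
    """Lower-triangular matrix mapping tracer-label MIDs to observed MIDs.

    Column ``j`` is the natural-abundance envelope of a molecule already
    carrying ``j`` tracer labels (those positions excluded from the natural
    pool), shifted to start at offset ``j`` and truncated at m+K.
    """

    matrix: np.ndarray
    formula: FragmentFormula = field(compare=False, default=GLUCOSE_PENTAACETATE)

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ConfigurationError("correction matrix must be square")
        if np.any(np.triu(m, 1) != 0):
            raise ConfigurationError("correction matrix must be lower-triangular")
        if np.any(np.diag(m) <= 0):
            raise ConfigurationError("correction matrix has a zero diagonal: not invertible")
        if np.any(m.sum(axis=0) > 1 + 1e-9):
            raise ConfigurationError("correction-matrix columns must sum to <= 1")

    @property
    def size(self) -> int:
        return self.matrix.shape[0]


def build_correction_matrix(formula: FragmentFormula, K: int = N_SHIFTS - 1) -> CorrectionMatrix:
    """Build the (K+1)x(K+1) natural-abundance correction matrix for a fragment.

    Parameters
    ----------
    formula
        Elemental composition of the measured derivative fragment.
    K
        Highest tracked mass shift (6 for hexoses: m+0 ... m+6).
    """
    if K < 1:
        raise ConfigurationError("K must be >= 1")
    n_tracer = formula.counts.get(formula.tracer_element, 0)
    if n_tracer < K:
        raise ConfigurationError(
            f"fragment has only {n_tracer} {formula.tracer_element} atoms, "
            f"cannot carry {K} tracer labels"
        )
    M = np.zeros((K + 1, K + 1))
    for j in range(K + 1):
        env = isotope_envelope(formula, K - j, exclude={formula.tracer_element: j})
        M[j:, j] = env
    return CorrectionMatrix(M, formula)


def correct_natural_abundance(
    observed: MID,
    M: CorrectionMatrix,
    residual_tolerance: float = 0.02,
) -> tuple[MID, float, bool]:
    """Remove natural-abundance contributions from an observed MID.

    Solves ``M @ x ~= observed`` by nonnegative least squares and renormalizes
    ``x`` to sum 1.  For a noise-free convolved input this is the exact
    pre-image of the convolution.

    Returns
    -------
    corrected : MID
    residual_norm : float
        Euclidean norm of ``M @ x - observed``; large values mean the spectrum
        is inconsistent with the fragment formula.
    quality_ok : bool
        ``residual_norm <= residual_tolerance``.  Recorded, never raised: a
        poor fit is a diagnostic, not a hard failure.
    """
    y = observed.abundances
    if len(y) != M.size:
        raise InvalidMeasurementError(
            f"observed MID length {len(y)} does not match matrix size {M.size}"
        )
    x, residual = nnls(M.matrix, y)
    total = x.sum()
    if total <= 0:
        raise InvalidMeasurementError("correction produced an all-zero distribution")
    corrected = MID(x / total, observed.analyte, observed.channel)
    return corrected, float(residual), bool(residual <= residual_tolerance)


def unlabeled_mid(analyte: Analyte, channel: Channel, K: int = N_SHIFTS - 1) -> MID:
    """Corrected-space MID of a fully unlabeled analyte: the unit vector at m+0."""
    arr = np.zeros(K + 1)
    arr[0] = 1.0
    return MID(arr, Analyte(analyte), Channel(channel))


def excess_mid(corrected: MID, baseline: MID | None = None) -> tuple[np.ndarray, float]:
    """Tracer-attributable enrichment above baseline, element-wise.

    Negative differences (noise) are clipped to zero; the total clipped
    magnitude is returned as a diagnostic.  The default baseline is the
    theoretical unlabeled analyte (unit vector at m+0 in corrected space).
    """
    if baseline is None:
        baseline = unlabeled_mid(corrected.analyte, corrected.channel, len(corrected) - 1)
    if len(baseline) != len(corrected):
        raise InvalidMeasurementError("corrected and baseline MIDs differ in length")
    diff = corrected.abundances - baseline.abundances
    clipped = float(-diff[diff < 0].sum())
    return np.clip(diff, 0.0, None), clipped


def deuterium_enrichment(combined: MID, carbon_only: MID) -> float:
    """²H (m+1) enrichment of a sample from its two derivative channels.

    The pentaacetate (combined) channel sees ¹³C *and* ²H at m+1; the
    aldonitrile (carbon-only) channel loses the C1 hydrogen and with it the
    [1-²H] label.  Their m+1 excess difference is therefore the ²H enrichment,
    floored at zero.
    """
    if combined.analyte != carbon_only.analyte:
        raise ChannelMismatchError(
            f"channels describe different analytes: "
            f"{combined.analyte.value} vs {carbon_only.analyte.value}"
        )
    if combined.channel != Channel.COMBINED or carbon_only.channel != Channel.CARBON_ONLY:
        raise ChannelMismatchError(
            "deuterium_enrichment needs one combined and one carbon_only MID"
        )
    ex_comb, _ = excess_mid(combined)
    ex_carb, _ = excess_mid(carbon_only)
    return max(0.0, float(ex_comb[1] - ex_carb[1]))
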