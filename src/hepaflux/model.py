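"""The fitted-model interface: :class:`HepaticFluxModel` and :class:`FluxResults`.

The model is built from a long-format sample table of mass isotopomer
measurements (one row per animal x time x matrix x derivative channel) plus
the infusion protocol.  ``fit()`` runs the full analysis:

1. normalize and natural-abundance-correct every MID (per-channel matrices);
2. derive per-time enrichment series (m+6, ²H m+1, MIDA m+1/m+2, m+3) for
   blood glucose and UDP-glucose;
3. check the fixed isotopic-steady-state window (240-360 min) for plateau
   and average the per-time isotope parameters over it;
4. solve the G6P flux balance per animal;
5. summarize per group and, when the 2x2 design is present, run the
   two-way-ANOVA + Tukey contrast scheme.

Animals whose data cannot be processed are collected with reasons instead of
aborting the fit; results for the remaining animals are still produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from .exceptions import HepafluxError, SchemaError
from .fluxbalance import PrimaryIsotopeParams, solve_fluxes
from .isotopes import (
    DEFAULT_FORMULAS,
    Channel,
    FragmentFormula,
    build_correction_matrix,
)
from .protocol import DEFAULT_PROTOCOL, InfusionProtocol
from .simulate import SCHEMA_COLUMNS
from .stats import (
    DEFAULT_DRIFT_THRESHOLD,
    DEFAULT_WINDOW,
    compare_groups,
    detect_steady_state,
)

__all__ = ["AnalysisConfig", "HepaticFluxModel", "FluxResults"]

_MATRIX_TO_ANALYTE = {
    "blood_spot": "blood_glucose",
    "blood_glucose": "blood_glucose",
    "urine": "udp_glucose",
    "udp_glucose": "udp_glucose",
}

#: Flux columns reported per animal and summarized per group.
FLUX_COLUMNS = [
    "ra", "ru", "egp", "gck", "g6pase", "gs", "gp", "gng_g6p", "gng_blood",
    "glucose_balance", "glycogen_balance", "clearance", "m3m6_glc", "m3m6_udpglc",
]

PARAM_COLUMNS = ["d_glc", "d_udpglc", "c_glc", "c_udpglc", "f_glc", "f_udpglc"]


class AnalysisConfig(BaseModel):
    """Tunable analysis settings with study-protocol defaults."""

    model_config = {"arbitrary_types_allowed": True}

    purity: float = Field(0.99, gt=0, le=1, description="isotopic purity of infused tracers")
    window_start: float = 240.0
    window_end: float = 360.0
    drift_threshold: float = DEFAULT_DRIFT_THRESHOLD
    noise_floor: float = Field(1e-6, description="enrichment below which ratios are indeterminate")
    residual_tolerance: float = Field(0.02, description="NNLS residual above which fit quality is flagged")
    closure: str = "g6p-balance"
    alpha: float = 0.05

    @property
    def window(self) -> tuple[float, float]:
        return (self.window_start, self.window_end)


@dataclass
class FluxResults:
    """Results of a fitted :class:`HepaticFluxModel`.

    Attributes
    ----------
    corrected_mids : DataFrame
        Tidy corrected-MID table with residual-norm and clipping diagnostics.
    timecourses : DataFrame
        Per animal x time enrichment and parameter series.
    isotope_params : DataFrame
        Per-animal steady-state isotope parameters (the six-parameter table)
        with window diagnostics.
    fluxes : DataFrame
        Per-animal solved fluxes, μmol·kg⁻¹·min⁻¹.
    group_summary : DataFrame
        Mean ± SEM per group for parameters and fluxes.
    comparisons : list
        :class:`~hepaflux.stats.GroupComparisonResult` per outcome (empty when
        no 2x2 design is present).
    failures : DataFrame
        Animals that could not be analyzed, with reasons.
    """

    corrected_mids: pd.DataFrame
    timecourses: pd.DataFrame
    isotope_params: pd.DataFrame
    fluxes: pd.DataFrame
    group_summary: pd.DataFrame
    comparisons: list = field(default_factory=list)
    failures: pd.DataFrame = field(default_factory=pd.DataFrame)
    config: AnalysisConfig = field(default_factory=AnalysisConfig)

    def summary(self) -> str:
        """Human-readable fit summary: design, parameters and fluxes per group."""
        lines = ["Hepatic carbohydrate flux analysis", "=" * 60]
        n_animals = self.fluxes["animal_id"].nunique() if len(self.fluxes) else 0
        lines.append(f"Animals analyzed: {n_animals}   failed: {len(self.failures)}")
        lines.append(f"Steady-state window: {self.config.window} min, "
                     f"drift threshold {self.config.drift_threshold:.0%}")
        lines.append(f"Closure: {self.config.closure}")
        if len(self.isotope_params):
            lines.append("\nSteady-state isotope parameters (group mean ± SEM):")
            lines.append(_group_mean_sem(self.isotope_params, PARAM_COLUMNS).to_string())
        if len(self.fluxes):
            lines.append("\nFluxes, μmol·kg⁻¹·min⁻¹ (group mean ± SEM):")
            main = ["ra", "ru", "gck", "g6pase", "gs", "gp", "gng_g6p", "gng_blood"]
            lines.append(_group_mean_sem(self.fluxes, main).to_string())
        for comp in self.comparisons:
            sig = comp.significant_contrasts
            if len(sig):
                lines.append(f"\nSignificant contrasts for {comp.outcome}:")
                lines.append(sig[["family", "group1", "group2", "p_adj"]].to_string(index=False))
        if len(self.failures):
            lines.append("\nExcluded animals:")
            lines.append(self.failures.to_string(index=False))
        return "\n".join(lines)

    def plot_fluxes(self, flux_names: list[str] | None = None, ax=None):
        """Bar plot of group mean ± SEM for the main fluxes."""
        import matplotlib.pyplot as plt

        flux_names = flux_names or ["gck", "g6pase", "gs", "gp", "gng_g6p"]
        if ax is None:
            _, ax = plt.subplots(figsize=(1.8 * len(flux_names) + 2, 4))
        groups = sorted(self.fluxes["group"].unique())
        width = 0.8 / len(groups)
        x = np.arange(len(flux_names))
        for i, g in enumerate(groups):
            sub = self.fluxes[self.fluxes["group"] == g]
            means = [sub[f].mean() for f in flux_names]
            sems = [sub[f].sem() for f in flux_names]
            ax.bar(x + i * width, means, width, yerr=sems, capsize=3, label=g)
        ax.set_xticks(x + 0.4 - width / 2)
        ax.set_xticklabels([f.upper() for f in flux_names])
        ax.set_ylabel("flux (μmol·kg⁻¹·min⁻¹)")
        ax.legend(fontsize=8)
        return ax


def _group_mean_sem(df: pd.DataFrame, columns: list[str]) -> pd.DataFrame:
    present = [c for c in columns if c in df.columns]
    g = df.groupby("group")[present]
    mean, sem = g.mean(), g.sem()
    out = pd.DataFrame(index=mean.index)
    for c in present:
        out[c] = [f"{m:.3g} ± {s:.2g}" if np.isfinite(s) else f"{m:.3g}"
                  for m, s in zip(mean[c], sem[c])]
    return out


def _validate_schema(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in SCHEMA_COLUMNS if c not in data.columns]
    if missing:
        raise SchemaError(f"input table is missing columns {missing}")
    if data.empty:
        raise SchemaError("input table has no rows")
    bad_matrix = set(data["matrix"].unique()) - set(_MATRIX_TO_ANALYTE)
    if bad_matrix:
        raise SchemaError(f"unknown matrix values {sorted(bad_matrix)}")
    # canonicalize matrix labels so downstream stages see one spelling
    canonical = {"blood_glucose": "blood_spot", "udp_glucose": "urine"}
    data["matrix"] = data["matrix"].replace(canonical)
    bad_channel = set(data["channel"].unique()) - {c.value for c in Channel}
    if bad_channel:
        raise SchemaError(f"unknown channel values {sorted(bad_channel)}")
    return data


class HepaticFluxModel:
    """Steady-state hepatic carbohydrate flux model for one infusion cohort.

    Parameters
    ----------
    data
        Long-format sample table (see :data:`hepaflux.simulate.SCHEMA_COLUMNS`);
        ``m0...m6`` may be raw intensities or fractions — rows are normalized
        either way.
    protocol
        A shared :class:`InfusionProtocol` or a mapping ``animal_id -> protocol``
        (e.g. for per-animal body weights).
    blood_glucose
        Optional steady-state blood glucose (mM): a scalar, a mapping
        ``animal_id -> mM``, or a DataFrame with ``animal_id``, ``time_min``,
        ``glucose_mM`` (averaged over the window).  Enables clearance.
    config
        :class:`AnalysisConfig` overrides.
    formulas
        Per-channel :class:`FragmentFormula` overrides for the correction
        matrices.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        protocol: InfusionProtocol | Mapping[str, InfusionProtocol] = DEFAULT_PROTOCOL,
        blood_glucose: Any = None,
        config: AnalysisConfig | None = None,
        formulas: dict[Channel, FragmentFormula] | None = None,
    ):
        self.data = _validate_schema(data.copy())
        self.protocol = protocol
        self.blood_glucose = blood_glucose
        self.config = config or AnalysisConfig()
        self.formulas = formulas or DEFAULT_FORMULAS

    @classmethod
    def from_csv(cls, path, sep: str | None = None, **kwargs) -> "HepaticFluxModel":
        """Build the model from a CSV/TSV sample table."""
        df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
        return cls(df, **kwargs)

    # -- helpers -----------------------------------------------------------

    def _protocol_for(self, animal_id: str) -> InfusionProtocol:
        if isinstance(self.protocol, InfusionProtocol):
            return self.protocol
        return self.protocol[animal_id]

    def _glucose_for(self, animal_id: str) -> float | None:
        bg = self.blood_glucose
        if bg is None:
            return None
        if np.isscalar(bg):
            return float(bg)
        if isinstance(bg, pd.DataFrame):
            sub = bg[bg["animal_id"] == animal_id]
            w = self.config.window
            sub = sub[(sub["time_min"] >= w[0]) & (sub["time_min"] <= w[1])]
            return float(sub["glucose_mM"].mean()) if len(sub) else None
        return float(bg.get(animal_id)) if animal_id in bg else None

    # -- pipeline stages ---------------------------------------------------

    def correct(self) -> pd.DataFrame:
        """Stage 1: normalize and natural-abundance-correct every sample row.

        Vectorized over rows but numerically identical to applying
        :func:`~hepaflux.isotopes.normalize_mid`,
        :func:`~hepaflux.isotopes.correct_natural_abundance` and
        :func:`~hepaflux.isotopes.excess_mid` per sample.
        """
        from scipy.optimize import nnls

        cfg = self.config
        mcols = [f"m{i}" for i in range(7)]
        raw = self.data[mcols].to_numpy(dtype=float)
        if np.any(raw < 0):
            raise SchemaError("negative isotopologue intensities in input")
        sums = raw.sum(axis=1)
        if np.any(sums <= 0):
            bad = self.data.loc[sums <= 0, "animal_id"].unique()
            raise SchemaError(f"all-zero intensity rows for animals {list(bad)}")
        norm = raw / sums[:, None]

        channels = self.data["channel"].to_numpy()
        corrected = np.empty_like(norm)
        residuals = np.empty(len(norm))
        for ch, formula in self.formulas.items():
            M = build_correction_matrix(formula).matrix
            for i in np.nonzero(channels == ch.value)[0]:
                x, r = nnls(M, norm[i])
                corrected[i] = x / x.sum()
                residuals[i] = r

        out = self.data[["animal_id", "group", "time_min", "matrix", "channel"]].copy()
        for k in range(7):
            out[f"c{k}"] = corrected[:, k]
        for k in range(1, 7):
            out[f"ex{k}"] = corrected[:, k]  # excess over the unlabeled baseline e0
        out["residual_norm"] = residuals
        out["clipped_mass"] = 1.0 - corrected[:, 0]  # m+0 deficit vs unlabeled baseline
        out["quality_ok"] = residuals <= cfg.residual_tolerance
        return out

    def derive_timecourses(self, corrected: pd.DataFrame) -> pd.DataFrame:
        """Stage 2: per animal x time enrichment series and per-time parameters.

        Parameter values are NaN at times where their denominators sit below
        the configured noise floor (e.g. t = 0, before any label arrives).
        """
        floor = self.config.noise_floor
        purity = self.config.purity
        piv = corrected.pivot_table(
            index=["animal_id", "group", "time_min"],
            columns=["matrix", "channel"],
            values=["ex1", "ex2", "ex3", "ex6"],
            aggfunc="first",
        )
        n = len(piv)

        def col(value: str, matrix: str, channel: Channel) -> np.ndarray:
            key = (value, matrix, channel.value)
            if key in piv.columns:
                return piv[key].to_numpy(dtype=float)
            return np.full(n, np.nan)

        def pooled(value: str, matrix: str) -> np.ndarray:
            # 13C-only species (m+2, m+3, m+6) are identical in both derivative
            # channels, so both spectra are averaged; m+1 stays channel-specific
            # because the combined channel carries the 2H label there.
            both = np.stack(
                [col(value, matrix, Channel.CARBON_ONLY),
                 col(value, matrix, Channel.COMBINED)]
            )
            count = (~np.isnan(both)).sum(axis=0)
            total = np.nansum(both, axis=0)
            return np.where(count > 0, total / np.maximum(count, 1), np.nan)

        b_m1 = col("ex1", "blood_spot", Channel.CARBON_ONLY)
        b_m2 = pooled("ex2", "blood_spot")
        b_m3 = pooled("ex3", "blood_spot")
        b_m6 = pooled("ex6", "blood_spot")
        b_comb1 = col("ex1", "blood_spot", Channel.COMBINED)
        u_m1 = col("ex1", "urine", Channel.CARBON_ONLY)
        u_m2 = pooled("ex2", "urine")
        u_m3 = pooled("ex3", "urine")
        u_m6 = pooled("ex6", "urine")
        u_comb1 = col("ex1", "urine", Channel.COMBINED)

        with np.errstate(invalid="ignore", divide="ignore"):
            blood_h2 = np.clip(b_comb1 - b_m1, 0.0, None)
            udp_h2 = np.clip(u_comb1 - u_m1, 0.0, None)
            d_glc = np.where(b_m6 > floor, b_m6 / purity, np.nan)
            d_udpglc = np.where(udp_h2 > floor, udp_h2 / purity, np.nan)
            c_glc = np.where(b_m6 > floor, u_m6 / b_m6, np.nan)
            c_udpglc = np.where(udp_h2 > floor, blood_h2 / udp_h2, np.nan)
            p_blood, f_blood = _mida_arrays(b_m1, b_m2, floor, fallback_p=None)
            p_udp, f_udp = _mida_arrays(u_m1, u_m2, floor, fallback_p=p_blood)
            m3m6_glc = np.where(b_m6 > floor, b_m3 / b_m6, np.nan)
            m3m6_udpglc = np.where(u_m6 > floor, u_m3 / u_m6, np.nan)

        out = piv.index.to_frame(index=False)
        series = {
            "blood_m1": b_m1, "blood_m2": b_m2, "blood_m3": b_m3, "blood_m6": b_m6,
            "blood_h2m1": blood_h2,
            "udp_m1": u_m1, "udp_m2": u_m2, "udp_m3": u_m3, "udp_m6": u_m6,
            "udp_h2m1": udp_h2,
            "d_glc": d_glc, "d_udpglc": d_udpglc,
            "c_glc": c_glc, "c_udpglc": c_udpglc,
            "p_blood": p_blood, "f_blood": f_blood,
            "p_udp": p_udp, "f_udp": f_udp,
            "m3m6_glc": m3m6_glc, "m3m6_udpglc": m3m6_udpglc,
        }
        for name, arr in series.items():
            out[name] = arr
        return out

    def fit(self) -> FluxResults:
        """Run the full pipeline and return a :class:`FluxResults`.

        Per-animal steady-state parameters are computed from the
        window-averaged excess enrichments (ratio of means), which avoids the
        Jensen bias that averaging per-time ratios would introduce on the
        noisiest (MIDA) parameters; the per-time parameter series remain
        available in ``timecourses`` as diagnostics.
        """
        from . import mida
        from .fluxbalance import compute_dilution, compute_exchange, m3m6_ratio
        from .isotopes import Analyte

        cfg = self.config
        corrected = self.correct()
        courses = self.derive_timecourses(corrected)

        param_rows, flux_rows, failures = [], [], []
        enrichment_cols = [
            "blood_m1", "blood_m2", "blood_m3", "blood_m6", "blood_h2m1",
            "udp_m1", "udp_m2", "udp_m3", "udp_m6", "udp_h2m1",
        ]
        for (animal, group), sub in courses.groupby(["animal_id", "group"]):
            try:
                diag = {}
                for series_col, name in (("blood_m6", "blood"), ("udp_h2m1", "urine")):
                    s = sub.dropna(subset=[series_col]) if series_col in sub else pd.DataFrame()
                    if len(s) == 0:
                        raise SchemaError(f"no {name} enrichment series for {animal}")
                    w = detect_steady_state(
                        s["time_min"], s[series_col],
                        window=cfg.window, drift_threshold=cfg.drift_threshold,
                        label=animal,
                    )
                    diag[f"drift_{name}"] = w.drift
                    diag[f"plateau_{name}"] = w.passed
                present = [c for c in enrichment_cols if c in sub.columns]
                m, n_window = _average_over_window(sub, present, cfg.window)
                d_glc = compute_dilution(m["blood_m6"], cfg.purity)
                d_udpglc = compute_dilution(m["udp_h2m1"], cfg.purity)
                c_glc, c_udpglc = compute_exchange(
                    m["udp_m6"], m["blood_m6"], m["blood_h2m1"], m["udp_h2m1"],
                    noise_floor=cfg.noise_floor,
                )
                blood = mida.analyze(
                    m["blood_m1"], m["blood_m2"], Analyte.BLOOD_GLUCOSE,
                    noise_floor=cfg.noise_floor,
                )
                udp = mida.analyze(
                    m["udp_m1"], m["udp_m2"], Analyte.UDP_GLUCOSE,
                    noise_floor=cfg.noise_floor,
                    fallback_p=blood.p if blood.p > 0 else None,
                )
                params = PrimaryIsotopeParams(
                    d_glc=d_glc, d_udpglc=d_udpglc,
                    c_glc=c_glc, c_udpglc=c_udpglc,
                    f_glc=blood.f, f_udpglc=udp.f,
                )
                m3m6 = tuple(
                    m3m6_ratio(m[f"{pool}_m3"], m[f"{pool}_m6"], cfg.noise_floor)
                    if m[f"{pool}_m6"] > cfg.noise_floor
                    else np.nan
                    for pool in ("blood", "udp")
                )
                glc = self._glucose_for(animal)
                fluxset = solve_fluxes(
                    params, self._protocol_for(animal),
                    blood_glucose_mM=glc,
                    excess_m3m6=m3m6,
                    closure=cfg.closure,
                )
            except (HepafluxError, KeyError) as exc:
                failures.append({"animal_id": animal, "group": group, "reason": str(exc)})
                continue
            param_rows.append(
                {"animal_id": animal, "group": group, **vars(params),
                 "n_window": n_window, **diag,
                 "p_blood": blood.p, "p_udp": udp.p,
                 "f_clipped": blood.clipped or udp.clipped}
            )
            flux_rows.append({"animal_id": animal, "group": group, **fluxset.as_dict()})

        params_df = pd.DataFrame(param_rows)
        fluxes_df = pd.DataFrame(flux_rows)
        group_summary = _summarize_groups(params_df, fluxes_df)
        comparisons = _maybe_compare(fluxes_df, params_df, cfg)
        return FluxResults(
            corrected_mids=corrected,
            timecourses=courses,
            isotope_params=params_df,
            fluxes=fluxes_df,
            group_summary=group_summary,
            comparisons=comparisons,
            failures=pd.DataFrame(failures, columns=["animal_id", "group", "reason"]),
            config=cfg,
        )


def _mida_arrays(m1, m2, floor, fallback_p=None):
    """Vectorized MIDA matching :func:`hepaflux.mida.analyze` semantics.

    p from the m+2/m+1 ratio where m+1 clears the floor; where both excesses
    are at the floor the pool holds no new material (p = f = 0); where only
    m+1 is below the floor a fallback p (blood estimate) is used if given.
    """
    with np.errstate(invalid="ignore", divide="ignore"):
        identifiable = m1 > floor
        r = np.where(identifiable, m2 / np.where(identifiable, m1, 1.0), np.nan)
        p = np.where(identifiable, 2.0 * r / (1.0 + 2.0 * r), np.nan)
        unlabeled = ~identifiable & (m2 <= floor) & ~np.isnan(m2)
        p = np.where(unlabeled, 0.0, p)
        if fallback_p is not None:
            use_fb = ~identifiable & (m2 > floor) & (fallback_p > 0)
            p = np.where(use_fb, fallback_p, p)
        f = np.where(p > 0, m2 / np.where(p > 0, p, 1.0) ** 2, np.where(unlabeled, 0.0, np.nan))
        f = np.minimum(f, 1.0)  # marginal overshoots from noise are clipped
    return p, f


def _average_over_window(sub: pd.DataFrame, columns, window) -> tuple[pd.Series, int]:
    mask = (sub["time_min"] >= window[0]) & (sub["time_min"] <= window[1])
    if not mask.any():
        raise SchemaError(f"no samples inside steady-state window {window}")
    means = sub.loc[mask, columns].mean()
    return means, int(mask.sum())


def _split_group(group: str) -> tuple[str, str] | None:
    parts = str(group).split("_", 1)
    return (parts[0], parts[1]) if len(parts) == 2 else None


def _summarize_groups(params_df: pd.DataFrame, fluxes_df: pd.DataFrame) -> pd.DataFrame:
    if fluxes_df.empty:
        return pd.DataFrame()
    merged = params_df.merge(
        fluxes_df.drop(columns=["closure"], errors="ignore"),
        on=["animal_id", "group"],
    )
    value_cols = [c for c in PARAM_COLUMNS + FLUX_COLUMNS if c in merged.columns]
    g = merged.groupby("group")[value_cols]
    summary = pd.concat({"mean": g.mean(), "sem": g.sem(), "n": g.count()}, axis=1)
    return summary.swaplevel(axis=1).sort_index(axis=1)


def _maybe_compare(fluxes_df: pd.DataFrame, params_df: pd.DataFrame, cfg: AnalysisConfig):
    """Run the 2x2 contrast scheme when group labels parse as shRNA_infusion."""
    if fluxes_df.empty:
        return []
    factors = fluxes_df["group"].map(_split_group)
    if factors.isna().any():
        return []
    table = fluxes_df.copy()
    table["shrna"] = [f[0] for f in factors]
    table["infusion"] = [f[1] for f in factors]
    if table["shrna"].nunique() != 2 or table["infusion"].nunique() != 2:
        return []
    if table.groupby(["shrna", "infusion"]).size().min() < 2:
        return []
    outcomes = [c for c in FLUX_COLUMNS if c in table.columns and table[c].notna().any()]
    return compare_groups(table, outcomes, alpha=cfg.alpha)
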