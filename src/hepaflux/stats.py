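"""Steady-state window handling and 2x2 group statistics.

The study's averaging rule is fixed: isotope parameters are means over the
isotopic steady state, 240-360 min after infusion start.  Rather than
adaptively shrinking the window, :func:`detect_steady_state` keeps it and
attaches a plateau diagnostic (relative drift of the enrichment across the
window), so a slowly-equilibrating animal is flagged, never silently
re-windowed.

Group comparisons follow the study's scheme: two-way ANOVA (shRNA, infusion,
interaction; type-II sums of squares) followed by Tukey HSD on the four cell
means, reporting only the four contrasts of the */# convention — the shRNA
effect within each infusion and the infusion effect within each shRNA — at
alpha = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import DesignError, DomainError

__all__ = [
    "SteadyStateWindow",
    "GroupComparisonResult",
    "detect_steady_state",
    "average_window",
    "compare_groups",
    "DEFAULT_WINDOW",
    "DEFAULT_DRIFT_THRESHOLD",
]

DEFAULT_WINDOW = (240.0, 360.0)
DEFAULT_DRIFT_THRESHOLD = 0.10
ALPHA = 0.05


@dataclass(frozen=True)
class SteadyStateWindow:
    """The averaging window plus its plateau diagnostic for one series."""

    start: float
    end: float
    drift: float  #: relative change of the enrichment across the window
    passed: bool
    n_points: int

    def __post_init__(self):
        if not self.start < self.end:
            raise DomainError("window start must precede end")


def detect_steady_state(
    times,
    values,
    window: tuple[float, float] = DEFAULT_WINDOW,
    drift_threshold: float = DEFAULT_DRIFT_THRESHOLD,
    min_points: int = 3,
    label: str = "",
) -> SteadyStateWindow:
    """Check a single enrichment time series for plateau inside the fixed window.

    Drift is ``(last - first) / |last|`` over in-window samples; a
    mono-exponential series with time constant tau has closed-form drift
    ``(exp(-t0/tau) - exp(-t1/tau)) / (1 - exp(-t1/tau))``, under 2% for
    tau = 60 min on the default window and above 20% for tau = 300 min.

    Raises
    ------
    DomainError
        If fewer than ``min_points`` samples fall inside the window; the
        message names ``label`` (typically the animal id).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.shape != values.shape:
        raise DomainError("times and values must have equal length")
    mask = (times >= window[0]) & (times <= window[1])
    n = int(mask.sum())
    if n < min_points:
        raise DomainError(
            f"only {n} samples inside window {window} for {label or 'series'}; "
            f"need >= {min_points}"
        )
    order = np.argsort(times[mask])
    in_window = values[mask][order]
    last = in_window[-1]
    drift = 0.0 if last == 0 else float((last - in_window[0]) / abs(last))
    return SteadyStateWindow(
        start=window[0], end=window[1],
        drift=drift, passed=bool(abs(drift) <= drift_threshold), n_points=n,
    )


def average_window(
    series: pd.DataFrame,
    value_columns: list[str],
    window: tuple[float, float] = DEFAULT_WINDOW,
    time_column: str = "time_min",
) -> tuple[pd.Series, int]:
    """Unweighted mean of per-time parameter values inside the window.

    Returns the means and the number of in-window samples ``n``; ``n = 1``
    is allowed but should be surfaced as a warning by callers.
    """
    mask = (series[time_column] >= window[0]) & (series[time_column] <= window[1])
    sub = series.loc[mask, value_columns]
    if sub.empty:
        raise DomainError(f"no samples inside window {window}")
    return sub.mean(), int(mask.sum())


@dataclass(frozen=True)
class GroupComparisonResult:
    """Two-way ANOVA + Tukey contrasts for one outcome.

    ``contrasts`` has one row per contrast of the */# scheme with columns
    ``family`` ("shrna_within_infusion" or "infusion_within_shrna"),
    ``group1``, ``group2``, ``p_adj`` and ``significant``.
    """

    outcome: str
    anova: pd.DataFrame
    contrasts: pd.DataFrame
    cell_summary: pd.DataFrame  # mean, sem, n per (shrna, infusion) cell

    @property
    def significant_contrasts(self) -> pd.DataFrame:
        return self.contrasts[self.contrasts["significant"]]


def _paper_contrasts(shrna_levels, infusion_levels):
    """The four contrasts of the */# convention on a 2x2 design."""
    pairs = []
    for inf in infusion_levels:  # * : shRNA effect within infusion
        pairs.append((f"{shrna_levels[0]}|{inf}", f"{shrna_levels[1]}|{inf}", "shrna_within_infusion"))
    for sh in shrna_levels:  # # : infusion effect within shRNA
        pairs.append((f"{sh}|{infusion_levels[0]}", f"{sh}|{infusion_levels[1]}", "infusion_within_shrna"))
    return pairs


def compare_groups(
    data: pd.DataFrame,
    outcomes: list[str],
    shrna_column: str = "shrna",
    infusion_column: str = "infusion",
    alpha: float = ALPHA,
) -> list[GroupComparisonResult]:
    """Two-way ANOVA + Tukey post-hoc contrasts for each outcome column.

    ``data`` is one row per animal with factor columns and outcome columns.
    Requires a full 2x2 design with >= 2 animals per cell.
    """
    shrna_levels = sorted(data[shrna_column].dropna().unique())
    infusion_levels = sorted(data[infusion_column].dropna().unique())
    if len(shrna_levels) != 2 or len(infusion_levels) != 2:
        raise DesignError(
            f"need a 2x2 design; got shRNA levels {shrna_levels}, "
            f"infusion levels {infusion_levels}"
        )
    counts = data.groupby([shrna_column, infusion_column]).size()
    if len(counts) < 4 or counts.min() < 2:
        raise DesignError(f"every design cell needs >= 2 animals; got\n{counts}")

    results = []
    for outcome in outcomes:
        sub = data[[shrna_column, infusion_column, outcome]].dropna().copy()
        sub = sub.rename(columns={shrna_column: "shrna", infusion_column: "infusion"})
        model = smf.ols(f"Q('{outcome}') ~ C(shrna) * C(infusion)", data=sub).fit()
        anova = sm.stats.anova_lm(model, typ=2)

        cell = sub["shrna"].astype(str) + "|" + sub["infusion"].astype(str)
        tukey = pairwise_tukeyhsd(sub[outcome].to_numpy(), cell.to_numpy(), alpha=alpha)
        tukey_df = pd.DataFrame(
            tukey.summary().data[1:], columns=tukey.summary().data[0]
        )
        wanted = _paper_contrasts(shrna_levels, infusion_levels)
        rows = []
        for g1, g2, family in wanted:
            hit = tukey_df[
                ((tukey_df["group1"] == g1) & (tukey_df["group2"] == g2))
                | ((tukey_df["group1"] == g2) & (tukey_df["group2"] == g1))
            ]
            if hit.empty:
                raise DesignError(f"Tukey table is missing contrast {g1} vs {g2}")
            row = hit.iloc[0]
            rows.append(
                {
                    "family": family,
                    "group1": g1,
                    "group2": g2,
                    "meandiff": float(row["meandiff"]),
                    "p_adj": float(row["p-adj"]),
                    "significant": bool(row["reject"]),
                }
            )
        summary = (
            sub.groupby(["shrna", "infusion"])[outcome]
            .agg(mean="mean", sem="sem", n="count")
            .reset_index()
        )
        results.append(
            GroupComparisonResult(
                outcome=outcome,
                anova=anova,
                contrasts=pd.DataFrame(rows),
                cell_summary=summary,
            )
        )
    return results
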