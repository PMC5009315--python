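"""Median-effect dose-response fitting and combination-index synergy scoring.

The median-effect model relates dose D to fraction affected fa through
fa/fu = (D/Dm)^m with fu = 1 - fa, Dm the dose producing half effect and
m the sigmoidicity of the curve. Taking logs linearizes it:
log10(fa/fu) = m*log10(D) - m*log10(Dm), so (m, Dm) come from ordinary
least squares on the transformed points and r is the correlation of that
fit.

For a combination delivering doses (d1, d2) at observed effect fa, the
combination index (mutually exclusive, two-term form) is

    CI = d1/Dx1(fa) + d2/Dx2(fa),    Dx = Dm * (fa/fu)^(1/m)

where Dx is the dose of each agent *alone* needed for that effect.
CI < 1 flags synergy, CI = 1 (Loewe) additivity, CI > 1 antagonism.
Non-constant-ratio designs are supported: every combination point is
scored independently. Isobologram coordinates (equi-effect additivity
lines plus normalized combination points) are exported for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DoseResponsePoint",
    "FaValue",
    "MedianEffectFit",
    "CombinationIndexEntry",
    "viability_to_fa",
    "median_effect_fit",
    "dose_for_effect",
    "effect_at_dose",
    "combination_index",
    "classify_ci",
    "isobologram",
    "read_dose_response",
    "write_ci_table",
]

ADDITIVITY_BAND = 0.1  # |CI - 1| within this band is called additive


class DoseResponsePoint(NamedTuple):
    """One dose with its fraction affected, both on the open scale."""

    dose: float
    fa: float


class FaValue(NamedTuple):
    fa: float
    clipped: bool


@dataclass(frozen=True)
class MedianEffectFit:
    """Parameters of the linearized median-effect fit.

    flagged marks a non-monotone fit (m <= 0), which cannot be inverted
    for effect doses and is excluded from CI scoring.
    """

    m: float
    Dm: float
    r: float
    n_points: int = 0

    def __post_init__(self) -> None:
        if self.Dm <= 0:
            raise ValueError("Dm must be positive")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")

    @property
    def flagged(self) -> bool:
        return self.m <= 0


class CombinationIndexEntry(NamedTuple):
    """One combination point's CI with its single-agent equivalent doses."""

    d1: float
    d2: float
    fa_observed: float
    Dx1: float
    Dx2: float
    CI: float
    classification: str


def viability_to_fa(treated_signal: float, control_signal: float, epsilon: float = 1e-4) -> FaValue:
    """Fraction affected from a viability readout: fa = 1 - treated/control.

    Values outside (0, 1) — no measurable effect, stimulation, or complete
    kill — are clipped into [epsilon, 1 - epsilon] so the log-linearization
    stays defined, and flagged; flagged points are excluded from fits by
    default.
    """
    if control_signal <= 0:
        raise ValueError(f"control signal must be positive, got {control_signal}")
    if not (0 < epsilon < 0.5):
        raise ValueError("epsilon must lie in (0, 0.5)")
    fa = 1.0 - treated_signal / control_signal
    clipped = not (epsilon <= fa <= 1.0 - epsilon)
    return FaValue(fa=float(np.clip(fa, epsilon, 1.0 - epsilon)), clipped=clipped)


def median_effect_fit(points: Iterable[DoseResponsePoint | tuple]) -> MedianEffectFit:
    """Least-squares median-effect line through (log10 D, log10 fa/fu).

    Needs at least two distinct doses with fa strictly inside (0, 1).
    A fit with m <= 0 (effect decreasing with dose) is returned flagged
    rather than rejected, so the caller can inspect the data.
    """
    pts = [DoseResponsePoint(float(d), float(f)) for d, f in points]
    if len(pts) < 2:
        raise ValueError("median-effect fit needs >= 2 dose-response points")
    for d, f in pts:
        if d <= 0:
            raise ValueError(f"dose must be positive, got {d}")
        if not (0 < f < 1):
            raise ValueError(f"fraction affected must lie strictly in (0, 1), got {f}")
    doses = np.array([p.dose for p in pts])
    fas = np.array([p.fa for p in pts])
    if np.unique(doses).size < 2:
        raise ValueError("all doses are identical; the median-effect line is undetermined")
    x = np.log10(doses)
    y = np.log10(fas / (1.0 - fas))
    res = stats.linregress(x, y)
    m = float(res.slope)
    r = float(res.rvalue) if np.isfinite(res.rvalue) else 0.0
    if m == 0:
        # flat response: Dm is undefined; report the geometric mid-dose, flagged
        dm = float(10 ** x.mean())
    else:
        dm = float(10 ** (-res.intercept / m))
    return MedianEffectFit(m=m, Dm=dm, r=max(-1.0, min(1.0, r)), n_points=len(pts))


def _require_valid(fit: MedianEffectFit, who: str) -> None:
    if fit.flagged:
        raise ValueError(f"{who}: fit is flagged (m = {fit.m} <= 0) and cannot be inverted")


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose of the agent alone producing fraction affected fa.

    Inverts the median-effect equation: Dx = Dm * (fa/fu)^(1/m).
    """
    _require_valid(fit, "dose_for_effect")
    if not (0 < fa < 1):
        raise ValueError(f"fa must lie strictly in (0, 1), got {fa}")
    return float(fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m))


def effect_at_dose(fit: MedianEffectFit, dose: float) -> float:
    """Fraction affected predicted at a dose: fa = 1 / (1 + (Dm/D)^m)."""
    _require_valid(fit, "effect_at_dose")
    if dose <= 0:
        raise ValueError(f"dose must be positive, got {dose}")
    return float(1.0 / (1.0 + (fit.Dm / dose) ** fit.m))


def classify_ci(ci: float, band: float = ADDITIVITY_BAND) -> str:
    if ci < 1.0 - band:
        return "synergy"
    if ci > 1.0 + band:
        return "antagonism"
    return "additive"


def combination_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    d1: float,
    d2: float,
    fa_combo: float,
    band: float = ADDITIVITY_BAND,
) -> CombinationIndexEntry:
    """Two-term (mutually exclusive) combination index at one observed point.

    CI = d1/Dx1 + d2/Dx2 where Dx is each single agent's dose for the
    combination's observed effect. Either dose may be zero (degenerate
    single-agent consistency check) but not both.
    """
    if d1 < 0 or d2 < 0 or (d1 == 0 and d2 == 0):
        raise ValueError("doses must be nonnegative and not both zero")
    if not (0 < fa_combo < 1):
        raise ValueError(f"fa_combo must lie strictly in (0, 1), got {fa_combo}")
    dx1 = dose_for_effect(fit_a, fa_combo)
    dx2 = dose_for_effect(fit_b, fa_combo)
    ci = d1 / dx1 + d2 / dx2
    return CombinationIndexEntry(
        d1=d1,
        d2=d2,
        fa_observed=fa_combo,
        Dx1=dx1,
        Dx2=dx2,
        CI=ci,
        classification=classify_ci(ci, band),
    )


def isobologram(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fa_levels: Sequence[float],
    combination_points: Sequence[CombinationIndexEntry] = (),
) -> pd.DataFrame:
    """Coordinates for an isobologram plot.

    For each fa level the additivity line runs from (Dx1, 0) to (0, Dx2).
    Combination points are reported in normalized coordinates
    (d1/Dx1, d2/Dx2) at their own observed effect; their coordinate sum is
    the CI, so synergistic points fall below the unit additivity line.
    Rows carry kind = "additivity_line" or "combination".
    """
    rows = []
    for fa in fa_levels:
        dx1 = dose_for_effect(fit_a, fa)
        dx2 = dose_for_effect(fit_b, fa)
        rows.append(
            {"kind": "additivity_line", "fa": fa, "x": dx1, "y": 0.0, "x_norm": 1.0, "y_norm": 0.0}
        )
        rows.append(
            {"kind": "additivity_line", "fa": fa, "x": 0.0, "y": dx2, "x_norm": 0.0, "y_norm": 1.0}
        )
    for entry in combination_points:
        rows.append(
            {
                "kind": "combination",
                "fa": entry.fa_observed,
                "x": entry.d1,
                "y": entry.d2,
                "x_norm": entry.d1 / entry.Dx1,
                "y_norm": entry.d2 / entry.Dx2,
            }
        )
    return pd.DataFrame(rows, columns=["kind", "fa", "x", "y", "x_norm", "y_norm"])


def read_dose_response(path) -> dict[str, list[DoseResponsePoint]]:
    """TSV with columns agent, dose, fa -> per-agent point lists."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("agent", "dose", "fa") if c not in df.columns]
    if missing:
        raise ValueError(f"dose-response table missing columns: {missing}")
    out: dict[str, list[DoseResponsePoint]] = {}
    for agent, block in df.groupby("agent", sort=False):
        out[str(agent)] = [
            DoseResponsePoint(float(d), float(f)) for d, f in zip(block["dose"], block["fa"])
        ]
    return out


def write_ci_table(entries: Sequence[CombinationIndexEntry], path) -> None:
    """TSV with fixed columns: d1, d2, fa, Dx1, Dx2, CI, classification."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("d1\td2\tfa\tDx1\tDx2\tCI\tclassification\n")
        for e in entries:
            fh.write(
                f"{e.d1:g}\t{e.d2:g}\t{e.fa_observed:g}\t{e.Dx1:g}\t{e.Dx2:g}"
                f"\t{e.CI:.6g}\t{e.classification}\n"
            )
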