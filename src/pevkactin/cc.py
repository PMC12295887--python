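"""Critical-concentration estimation from steady-state pyrene intensities.

In a steady-state pyrene assay the fluorescence above baseline is
proportional to polymer mass, which for total actin ``c`` above the
critical concentration ``Cc`` is ``c - Cc``.  Plotting steady-state
intensity against total actin therefore gives a line whose x-intercept is
``Cc`` — the classical construction.  This module fits that line to points
with signal above baseline noise, bootstraps the residuals for a
confidence interval, and compares two conditions (e.g. with and without a
nucleator, whose seeding activity must leave the fixed point untouched).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SteadyStateSeries",
    "CcFit",
    "CcComparison",
    "fit_cc",
    "compare_cc",
    "read_series",
    "write_series",
]


class CcFitError(RuntimeError):
    """Raised when the steady-state series cannot support a Cc fit."""


@dataclass
class SteadyStateSeries:
    """(actin concentration, steady-state intensity) pairs for one condition."""

    actin_conc: np.ndarray
    intensity: np.ndarray
    condition: str = ""

    def __post_init__(self) -> None:
        self.actin_conc = np.asarray(self.actin_conc, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.actin_conc.shape != self.intensity.shape:
            raise ValueError("actin_conc and intensity must have equal length")
        if self.actin_conc.size < 3:
            raise ValueError("a steady-state series needs at least 3 points")
        if np.any(self.actin_conc < 0):
            raise ValueError("actin concentrations must be non-negative")
        if np.any(np.diff(self.actin_conc) <= 0):
            raise ValueError("actin concentrations must be strictly increasing")


@dataclass
class CcFit:
    """Line fit above Cc and the derived critical concentration (µM)."""

    slope: float
    intercept: float
    cc: float
    cc_ci: tuple[float, float]
    n_points_used: int
    used_mask: np.ndarray = field(repr=False, default=None)


@dataclass
class CcComparison:
    delta_cc: float
    delta_ci: tuple[float, float]
    same_cc: bool
    fit_a: CcFit
    fit_b: CcFit


def _line_fit(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _cc_from_line(slope: float, intercept: float) -> float:
    return max(0.0, -intercept / slope)


def _select_points(series: SteadyStateSeries, blank: float | None,
                   noise_sd: float | None) -> tuple[np.ndarray, float, float]:
    """Flag points above the baseline-noise threshold (baseline + 3·sd)."""
    x, y = series.actin_conc, series.intensity
    if blank is None:
        baseline = float(y[0])  # lowest-concentration point stands in for a blank
    else:
        baseline = float(blank)
    if noise_sd is None:
        # robust residual scale about a provisional all-points line
        s, i = _line_fit(x, y)
        resid = y - (s * x + i)
        noise_sd = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    mask = y > baseline + 3.0 * noise_sd
    return mask, float(baseline), float(noise_sd)


def fit_cc(
    series: SteadyStateSeries,
    bootstrap_n: int = 1000,
    seed: int | None = None,
    blank: float | None = None,
    noise_sd: float | None = None,
) -> CcFit:
    """Estimate the critical concentration as the x-intercept of the
    least-squares line through points with intensity above baseline noise.

    ``cc = max(0, -intercept/slope)`` on blank-subtracted intensities.
    When a ``blank`` (signal of a polymer-free sample) is supplied it is
    subtracted before the intercept computation and serves as the
    selection baseline; otherwise intensities are taken as already
    blank-subtracted and the lowest-concentration point stands in for the
    baseline of the selection threshold (baseline + 3·noise_sd).  The
    confidence interval is a 95% percentile interval from ``bootstrap_n``
    residual-bootstrap refits.

    Raises
    ------
    CcFitError
        if fewer than 3 points rise above the noise threshold, or if the
        fitted slope is not positive (a polymerization signal must
        increase with actin concentration).
    """
    mask, baseline, noise_sd = _select_points(series, blank, noise_sd)
    if mask.sum() < 3:
        raise CcFitError(
            f"only {int(mask.sum())} point(s) above baseline+3·noise "
            f"(baseline={baseline:g}, noise_sd={noise_sd:g}); need >= 3"
        )
    x = series.actin_conc[mask]
    y = series.intensity[mask] - (blank if blank is not None else 0.0)
    slope, intercept = _line_fit(x, y)
    if slope <= 0:
        raise CcFitError(f"fitted slope {slope:g} is not positive")
    cc = _cc_from_line(slope, intercept)

    rng = np.random.default_rng(seed)
    yhat = slope * x + intercept
    resid = y - yhat
    boots = np.empty(bootstrap_n)
    for b in range(bootstrap_n):
        yb = yhat + rng.choice(resid, size=resid.size, replace=True)
        sb, ib = _line_fit(x, yb)
        boots[b] = _cc_from_line(sb, ib) if sb > 0 else np.nan
    boots = boots[np.isfinite(boots)]
    if boots.size:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = cc
    # percentile interval widened, if needed, to contain the point estimate
    ci = (min(float(lo), cc), max(float(hi), cc))
    return CcFit(slope=slope, intercept=intercept, cc=cc, cc_ci=ci,
                 n_points_used=int(mask.sum()), used_mask=mask)


def compare_cc(
    a: SteadyStateSeries,
    b: SteadyStateSeries,
    bootstrap_n: int = 1000,
    seed: int | None = None,
    **fit_kwargs,
) -> CcComparison:
    """Difference in critical concentration between two conditions.

    ``delta_cc = cc_a - cc_b`` with a paired-bootstrap 95% CI (residuals
    of both fits resampled jointly per replicate); ``same_cc`` is true iff
    the interval contains zero.
    """
    fit_a = fit_cc(a, bootstrap_n=0, seed=seed, **fit_kwargs)
    fit_b = fit_cc(b, bootstrap_n=0, seed=seed, **fit_kwargs)
    blank = fit_kwargs.get("blank") or 0.0
    rng = np.random.default_rng(seed)
    deltas = np.empty(bootstrap_n)
    xa, ya = a.actin_conc[fit_a.used_mask], a.intensity[fit_a.used_mask] - blank
    xb, yb = b.actin_conc[fit_b.used_mask], b.intensity[fit_b.used_mask] - blank
    ra = ya - (fit_a.slope * xa + fit_a.intercept)
    rb = yb - (fit_b.slope * xb + fit_b.intercept)
    for i in range(bootstrap_n):
        ya_b = fit_a.slope * xa + fit_a.intercept + rng.choice(ra, ra.size)
        yb_b = fit_b.slope * xb + fit_b.intercept + rng.choice(rb, rb.size)
        sa, ia = _line_fit(xa, ya_b)
        sb, ib = _line_fit(xb, yb_b)
        ca = _cc_from_line(sa, ia) if sa > 0 else np.nan
        cb = _cc_from_line(sb, ib) if sb > 0 else np.nan
        deltas[i] = ca - cb
    deltas = deltas[np.isfinite(deltas)]
    delta = fit_a.cc - fit_b.cc
    if deltas.size:
        lo, hi = (float(v) for v in np.percentile(deltas, [2.5, 97.5]))
    else:
        lo = hi = delta
    same = lo <= 0.0 <= hi
    return CcComparison(delta_cc=delta, delta_ci=(lo, hi), same_cc=same,
                        fit_a=fit_a, fit_b=fit_b)


def write_series(series_list, path) -> None:
    """Tabular text: actin_uM,intensity_au,condition."""
    frames = [pd.DataFrame({"actin_uM": s.actin_conc, "intensity_au": s.intensity,
                            "condition": s.condition}) for s in series_list]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_series(path) -> list[SteadyStateSeries]:
    df = pd.read_csv(path)
    required = {"actin_uM", "intensity_au"}
    if not required.issubset(df.columns):
        raise ValueError(f"series file must have columns {sorted(required)}")
    if "condition" not in df.columns:
        df["condition"] = ""
    out = []
    for cond, grp in df.groupby("condition", sort=False):
        grp = grp.sort_values("actin_uM")
        out.append(SteadyStateSeries(grp["actin_uM"].to_numpy(),
                                     grp["intensity_au"].to_numpy(),
                                     condition=str(cond)))
    return out
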