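"""Enzyme-kinetics confirmation analytics.

Michaelis–Menten fitting (v = Vmax·S/(Km+S)), IC50 four-parameter-logistic
fitting, Dixon regression (1/v against inhibitor concentration at several
substrate concentrations), inhibition-type classification from Km/Vmax fold
changes, and substrate-selectivity ratios.

Inhibition mechanisms and their apparent Michaelis–Menten parameters at a
fixed inhibitor concentration I with inhibition constant Ki:

==============  =======================  =======================
mechanism       apparent Km              apparent Vmax
==============  =======================  =======================
competitive     Km·(1 + I/Ki)            Vmax
noncompetitive  Km                       Vmax/(1 + I/Ki)
uncompetitive   Km/(1 + I/Ki)            Vmax/(1 + I/Ki)
==============  =======================  =======================

Classification treats a fold change within ``tol`` (default 15%) of 1.0 as
"unchanged"; a Km fold up with Vmax unchanged is competitive, Km unchanged
with Vmax down is noncompetitive, both down is uncompetitive, Km up with
Vmax down is mixed, both unchanged is no inhibition.  The remaining sign
combinations (Vmax up, or Km down alone) are inconsistent with simple
reversible inhibition and classify as "none".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

KINETICS_COLUMNS = ("substrate", "inhibitor", "substrate_conc_uM", "inhibitor_conc_uM", "rate_uM_min")


@dataclass(frozen=True)
class KineticsMeasurement:
    """One initial-rate observation: [S] and [I] in µM, rate in µM/min."""

    substrate: str
    inhibitor: str
    substrate_conc: float
    inhibitor_conc: float
    rate: float

    def __post_init__(self) -> None:
        if self.substrate_conc < 0 or self.inhibitor_conc < 0 or self.rate < 0:
            raise ValueError("concentrations and rates must be non-negative")


@dataclass(frozen=True)
class MMFit:
    km: float  # µM
    vmax: float  # µM/min
    km_se: float
    vmax_se: float
    rss: float
    n: int


@dataclass(frozen=True)
class InhibitionCall:
    type: str  # competitive | noncompetitive | uncompetitive | mixed | none
    km_fold: float
    vmax_fold: float
    tol: float


@dataclass(frozen=True)
class IC50Fit:
    ic50: float  # µM
    hill: float
    top: float  # % activity asymptotes
    bottom: float
    ic50_se: float


@dataclass(frozen=True)
class DixonLine:
    substrate_conc: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class DixonResult:
    lines: tuple[DixonLine, ...]
    intersection_i: float | None  # inhibitor conc at the line crossing (µM)
    intersection_y: float | None  # 1/v at the crossing
    implied_type: str
    n_zero_rates_dropped: int = 0


def read_kinetics_csv(path: str | Path) -> list[KineticsMeasurement]:
    df = pd.read_csv(path)
    missing = [c for c in KINETICS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return [
        KineticsMeasurement(
            substrate=str(r.substrate),
            inhibitor=str(r.inhibitor),
            substrate_conc=float(r.substrate_conc_uM),
            inhibitor_conc=float(r.inhibitor_conc_uM),
            rate=float(r.rate_uM_min),
        )
        for r in df.itertuples()
    ]


def measurements_to_frame(data: Sequence[KineticsMeasurement]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "substrate": [m.substrate for m in data],
            "inhibitor": [m.inhibitor for m in data],
            "substrate_conc_uM": [m.substrate_conc for m in data],
            "inhibitor_conc_uM": [m.inhibitor_conc for m in data],
            "rate_uM_min": [m.rate for m in data],
        }
    )


def residual_activity(area_sample: float, area_control: float) -> float:
    """Residual enzyme activity in percent: 100 × sample peak area / control peak area."""
    if area_control <= 0:
        raise ValueError("control peak area must be positive")
    if area_sample < 0:
        raise ValueError("sample peak area must be non-negative")
    return 100.0 * area_sample / area_control


def _mm(s: np.ndarray, vmax: float, km: float) -> np.ndarray:
    return vmax * s / (km + s)


def fit_michaelis_menten(data: Sequence[KineticsMeasurement] | pd.DataFrame) -> MMFit:
    """Nonlinear least-squares fit of v = Vmax·S/(Km+S) at a single inhibitor concentration.

    Initial guesses: Vmax₀ = max observed rate; Km₀ = S at half-maximal rate.
    Parameters are bounded positive.
    """
    if isinstance(data, pd.DataFrame):
        s = data["substrate_conc_uM"].to_numpy(dtype=float)
        v = data["rate_uM_min"].to_numpy(dtype=float)
        i_levels = set(data["inhibitor_conc_uM"]) if "inhibitor_conc_uM" in data else {0.0}
    else:
        s = np.array([m.substrate_conc for m in data], dtype=float)
        v = np.array([m.rate for m in data], dtype=float)
        i_levels = {m.inhibitor_conc for m in data}
    if len(i_levels) > 1:
        raise ValueError("fit_michaelis_menten expects data at one inhibitor concentration")
    if len(np.unique(s)) < 4:
        raise ValueError("need >= 4 distinct substrate concentrations")
    vmax0 = float(v.max())
    km0 = float(s[np.argmin(np.abs(v - vmax0 / 2))])
    km0 = max(km0, 1e-6)
    popt, pcov = curve_fit(
        _mm,
        s,
        v,
        p0=[vmax0, km0],
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        maxfev=20000,
    )
    vmax, km = float(popt[0]), float(popt[1])
    resid = v - _mm(s, *popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    return MMFit(km=km, vmax=vmax, km_se=float(se[1]), vmax_se=float(se[0]),
                 rss=float(resid @ resid), n=len(s))


def fold_change(param_with_inhibitor: float, param_control: float) -> float:
    """Ratio of an apparent kinetic parameter to its control value (unrounded)."""
    if param_control <= 0 or param_with_inhibitor <= 0:
        raise ValueError("parameters must be positive")
    return param_with_inhibitor / param_control


def classify_inhibition(km_fold: float, vmax_fold: float, tol: float = 0.15) -> InhibitionCall:
    """Categorical inhibition call from Km and Vmax fold changes (see module docstring)."""
    if km_fold <= 0 or vmax_fold <= 0:
        raise ValueError("fold changes must be positive")
    km_up = km_fold - 1 > tol
    km_down = 1 - km_fold > tol
    v_down = 1 - vmax_fold > tol
    v_up = vmax_fold - 1 > tol
    km_flat = not (km_up or km_down)
    v_flat = not (v_down or v_up)
    if km_up and v_flat:
        call = "competitive"
    elif km_flat and v_down:
        call = "noncompetitive"
    elif km_down and v_down:
        call = "uncompetitive"
    elif km_up and v_down:
        call = "mixed"
    else:
        call = "none"
    return InhibitionCall(type=call, km_fold=km_fold, vmax_fold=vmax_fold, tol=tol)


def dixon_regression(
    data: Sequence[KineticsMeasurement] | pd.DataFrame,
    parallel_rtol: float = 0.05,
) -> DixonResult:
    """Dixon analysis: OLS of 1/v on [I] per substrate concentration.

    Uses the two extreme substrate concentrations for the intersection.
    Implied type: near-parallel lines (relative slope difference below
    ``parallel_rtol``) → uncompetitive; intersection at I < 0 above the
    I-axis → competitive; on the I-axis → noncompetitive; slopes ≈ 0 → none.
    Rates of exactly zero are dropped (1/v undefined) with a logged count.
    """
    df = data if isinstance(data, pd.DataFrame) else measurements_to_frame(data)
    n_zero = int((df["rate_uM_min"] == 0).sum())
    if n_zero:
        logger.warning("dropping %d zero-rate points from Dixon analysis", n_zero)
        df = df[df["rate_uM_min"] > 0]
    s_levels = sorted(df["substrate_conc_uM"].unique())
    if len(s_levels) < 2:
        raise ValueError("Dixon analysis needs >= 2 substrate concentrations")
    lines: list[DixonLine] = []
    for s in s_levels:
        sub = df[df["substrate_conc_uM"] == s]
        i_vals = sub["inhibitor_conc_uM"].to_numpy(dtype=float)
        if len(np.unique(i_vals)) < 3:
            raise ValueError(f"need >= 3 inhibitor concentrations at S={s}")
        inv_v = 1.0 / sub["rate_uM_min"].to_numpy(dtype=float)
        slope, intercept = np.polyfit(i_vals, inv_v, 1)
        lines.append(DixonLine(substrate_conc=float(s), slope=float(slope), intercept=float(intercept)))

    lo, hi = lines[0], lines[-1]
    scale = max(abs(lo.slope), abs(hi.slope))
    typical_y = np.median(1.0 / df["rate_uM_min"])
    if scale < 1e-12 * max(typical_y, 1.0):
        return DixonResult(tuple(lines), None, None, "none", n_zero)
    if abs(lo.slope - hi.slope) < parallel_rtol * scale:
        return DixonResult(tuple(lines), None, None, "uncompetitive", n_zero)
    xi = (hi.intercept - lo.intercept) / (lo.slope - hi.slope)
    yi = lo.slope * xi + lo.intercept
    if xi < 0 and yi > parallel_rtol * typical_y:
        implied = "competitive"
    elif xi < 0:
        implied = "noncompetitive"
    else:
        implied = "mixed"
    return DixonResult(tuple(lines), float(xi), float(yi), implied, n_zero)


def _logistic4(c: np.ndarray, top: float, bottom: float, ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + (c / ic50) ** hill)


def fit_ic50(
    inhibitor_concs: Sequence[float],
    residual_activities: Sequence[float],
) -> IC50Fit:
    """Four-parameter logistic fit of residual activity (%) against [I] (µM).

    The IC50 is the concentration at the curve midpoint between the fitted
    asymptotes.  Activity must decrease with concentration; a monotone
    increase (or no transition within the tested range) raises ``ValueError``.
    """
    c = np.asarray(inhibitor_concs, dtype=float)
    a = np.asarray(residual_activities, dtype=float)
    if len(np.unique(c[c > 0])) < 5:
        raise ValueError("need >= 5 positive inhibitor concentrations spanning the transition")
    order = np.argsort(c)
    c, a = c[order], a[order]
    if a[-1] >= a[0]:
        raise ValueError("activities do not decrease with concentration; cannot fit IC50")
    if a.max() - a.min() < 10:
        raise ValueError("no transition in the tested range; IC50 not determinable")
    mask = c > 0  # logistic is undefined at c = 0; use positive doses
    c_fit, a_fit = c[mask], a[mask]
    mid = (a.max() + a.min()) / 2
    ic50_0 = float(c_fit[np.argmin(np.abs(a_fit - mid))])
    popt, pcov = curve_fit(
        _logistic4,
        c_fit,
        a_fit,
        p0=[a.max(), a.min(), ic50_0, 1.0],
        bounds=([0, -10, 1e-9, 0.1], [200, 100, 1e9, 10]),
        maxfev=20000,
    )
    top, bottom, ic50, hill = (float(x) for x in popt)
    se = np.sqrt(np.clip(np.diag(pcov), 0, np.inf))
    if bottom >= top:
        raise ValueError("degenerate logistic fit (bottom >= top)")
    return IC50Fit(ic50=ic50, hill=hill, top=top, bottom=bottom, ic50_se=float(se[2]))


def selectivity_ratio(km_a: float, km_b: float) -> float:
    """Km ratio between two substrates (selectivity); round only at reporting time."""
    if km_b <= 0 or km_a <= 0:
        raise ValueError("Km values must be positive")
    return km_a / km_b


def kinetics_report(
    fits: dict[tuple[str, str], MMFit],
    control_label: str = "control",
    tol: float = 0.15,
) -> pd.DataFrame:
    """Tabular report of Km/Vmax per (inhibitor, substrate) with fold-change rows.

    *fits* maps (inhibitor, substrate) → MMFit; the control condition is the
    inhibitor named ``control_label``.  The layout mirrors a classical
    kinetics table: one row per condition with per-substrate Km and Vmax
    columns plus cross-substrate selectivity ratios, followed by one
    fold-change row per inhibitor (relative to control) carrying the
    inhibition-type call per substrate.
    """
    substrates = sorted({s for (_, s) in fits})
    inhibitors = [control_label] + sorted({i for (i, _) in fits if i != control_label})
    rows = []
    for inh in inhibitors:
        row: dict[str, object] = {"condition": inh}
        for sub in substrates:
            fit = fits.get((inh, sub))
            row[f"Km_{sub}_uM"] = fit.km if fit else np.nan
            row[f"Vmax_{sub}_uM_min"] = fit.vmax if fit else np.nan
        if len(substrates) == 2 and all(fits.get((inh, s)) for s in substrates):
            a, b = substrates
            row["Km_ratio"] = round(selectivity_ratio(fits[(inh, b)].km, fits[(inh, a)].km), 2)
            row["Vmax_ratio"] = round(
                selectivity_ratio(fits[(inh, b)].vmax, fits[(inh, a)].vmax), 2
            )
        rows.append(row)
    for inh in inhibitors[1:]:
        row = {"condition": f"{inh} / {control_label}"}
        for sub in substrates:
            fit = fits.get((inh, sub))
            ctrl = fits.get((control_label, sub))
            if fit and ctrl:
                kf = fold_change(fit.km, ctrl.km)
                vf = fold_change(fit.vmax, ctrl.vmax)
                row[f"Km_{sub}_uM"] = round(kf, 2)
                row[f"Vmax_{sub}_uM_min"] = round(vf, 2)
                row[f"call_{sub}"] = classify_inhibition(kf, vf, tol).type
        rows.append(row)
    return pd.DataFrame(rows)
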