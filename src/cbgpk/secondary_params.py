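"""Secondary / exposure parameters: AUCs, Cmax/Tmax, terminal half-life, Vss.

Two AUC pathways are deliberately exposed: the model closed form (exact
modal integration via :func:`cbgpk.structural_model.profile_auc`) when
structural parameters are known, and the non-compartmental linear-up/
log-down trapezoid with ``C_last / lambda_z`` tail extrapolation when only a
sampled curve exists.  ``lambda_z`` is picked by log-linear least squares
over the 3-6 terminal points (after Cmax) with the best adjusted R^2, the
common NCA convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structural_model import ConcentrationCurve, StructuralParams


@dataclass
class ExposureSummary:
    """Per-profile derived exposure metrics (molar scale)."""

    auc24: float
    auc_inf: float
    cmax: float
    tmax: float
    t_half: float
    vss: float | None
    auc_ratio_met_parent: float | None


def _coerce(times, conc):
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.shape != c.shape or t.ndim != 1:
        raise ValueError("times and concentrations must be matching 1-d arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return t, c


def _interp_at(t, c, x):
    """Concentration at x: log-linear inside declining positive segments,
    linear otherwise."""
    i = int(np.searchsorted(t, x))
    if i == 0:
        return c[0]
    if t[i - 1] == x:
        return c[i - 1]
    t0, t1, c0, c1 = t[i - 1], t[i], c[i - 1], c[i]
    if c0 > c1 > 0:
        return c0 * (c1 / c0) ** ((x - t0) / (t1 - t0))
    return c0 + (c1 - c0) * (x - t0) / (t1 - t0)


def auc_trapezoid(times, conc, t_start=0.0, t_end=None, extrapolate=False, lambda_z=None):
    """Linear-up/log-down trapezoidal AUC over [t_start, t_end] (nmol.h/L).

    ``t_end = None`` or ``inf`` integrates to the last sample and, when
    ``extrapolate`` is set, adds the tail ``C_last / lambda_z`` (lambda_z
    estimated from the terminal points unless supplied).  The grid must
    cover the requested interval otherwise.
    """
    t, c = _coerce(times, conc)
    if t_end is None:
        t_end = math.inf
    infinite = math.isinf(t_end)
    if infinite and not extrapolate:
        t_end = t[-1]
        infinite = False
    if not infinite and (t_start < t[0] or t_end > t[-1] + 1e-12):
        raise ValueError("curve does not cover the requested interval")
    if t_start >= (t[-1] if infinite else t_end):
        raise ValueError("need t_start < t_end within the curve")

    stop = t[-1] if infinite else t_end
    # clip the grid to [t_start, stop] with interpolated boundary values
    inside = (t > t_start) & (t < stop)
    tt = np.concatenate(([t_start], t[inside], [stop]))
    cc = np.concatenate(([_interp_at(t, c, t_start)], c[inside], [_interp_at(t, c, stop)]))

    total = 0.0
    for i in range(len(tt) - 1):
        dt = tt[i + 1] - tt[i]
        c0, c1 = cc[i], cc[i + 1]
        if c0 > c1 > 0:
            total += dt * (c0 - c1) / math.log(c0 / c1)
        else:
            total += dt * 0.5 * (c0 + c1)
    if infinite:
        if lambda_z is None:
            lambda_z = fit_lambda_z(t, c)["lambda_z"]
        if not lambda_z > 0:
            raise ValueError("lambda_z unavailable for extrapolation")
        total += cc[-1] / lambda_z
    return float(total)


def aumc_trapezoid(times, conc, extrapolate=False, lambda_z=None):
    """Linear-trapezoid AUMC (first moment), optionally extrapolated."""
    t, c = _coerce(times, conc)
    total = float(np.trapezoid(t * c, t))
    if extrapolate:
        if lambda_z is None:
            lambda_z = fit_lambda_z(t, c)["lambda_z"]
        total += c[-1] * t[-1] / lambda_z + c[-1] / lambda_z**2
    return total


def cmax_tmax(times, conc):
    """Maximum concentration and its time; ties go to the earliest time."""
    t, c = _coerce(times, conc)
    if len(t) == 0:
        raise ValueError("empty curve")
    i = int(np.argmax(c))  # argmax returns the first maximum
    return float(c[i]), float(t[i])


def fit_lambda_z(times, conc, n_points: int | None = None) -> dict:
    """Terminal log-linear regression.

    With ``n_points`` unset, the window with the best adjusted R^2 among the
    last 3..6 points strictly after Tmax is chosen.  All candidate
    concentrations must be strictly positive.
    """
    t, c = _coerce(times, conc)
    i_max = int(np.argmax(c))
    tail_t, tail_c = t[i_max + 1 :], c[i_max + 1 :]
    if n_points is not None:
        sizes = [n_points]
    else:
        sizes = range(3, 7)
    best = None
    for k in sizes:
        if k < 3 or k > len(tail_t):
            continue
        ts, cs = tail_t[-k:], tail_c[-k:]
        if np.any(cs <= 0):
            raise ValueError("non-positive terminal concentrations")
        y = np.log(cs)
        slope, intercept = np.polyfit(ts, y, 1)
        if slope >= 0:
            continue
        resid = y - (slope * ts + intercept)
        sst = float(np.sum((y - y.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / sst if sst > 0 else 1.0
        r2adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        if best is None or r2adj > best["r2_adj"] + 1e-12:
            best = {
                "lambda_z": -slope,
                "t_half": math.log(2.0) / -slope,
                "intercept": math.exp(intercept),
                "n_points": k,
                "r2_adj": r2adj,
            }
    if best is None:
        raise ValueError("no declining terminal phase with >= 3 positive points")
    return best


def terminal_half_life(times, conc, n_points: int | None = None) -> float:
    """Terminal half-life (h) from the log-linear regression."""
    return fit_lambda_z(times, conc, n_points)["t_half"]


def vss(params: StructuralParams) -> float:
    """Steady-state volume of distribution: central plus peripheral (L/kg)."""
    return params.Vc + params.Vp


def auc_ratio(curve: ConcentrationCurve, t_start=None, t_end=None, extrapolate=False) -> float:
    """Metabolite-to-parent AUC ratio on the molar scale (common interval)."""
    if t_start is None:
        t_start = float(curve.times[0])
    ap = auc_trapezoid(curve.times, curve.c_parent, t_start, t_end, extrapolate)
    if ap == 0:
        raise ValueError("parent AUC is zero")
    am = auc_trapezoid(curve.times, curve.c_metabolite, t_start, t_end, extrapolate)
    return am / ap


def exposure_summary(
    curve: ConcentrationCurve,
    analyte: str = "parent",
    params: StructuralParams | None = None,
) -> ExposureSummary:
    """NCA-style summary of one sampled profile.

    ``params``, when provided, contributes Vss (= Vc + Vp); everything else
    is computed from the curve alone.
    """
    c = curve.c_parent if analyte == "parent" else curve.c_metabolite
    lz = fit_lambda_z(curve.times, c)
    return ExposureSummary(
        auc24=auc_trapezoid(curve.times, c, 0.0, 24.0),
        auc_inf=auc_trapezoid(curve.times, c, 0.0, None, extrapolate=True, lambda_z=lz["lambda_z"]),
        cmax=cmax_tmax(curve.times, c)[0],
        tmax=cmax_tmax(curve.times, c)[1],
        t_half=lz["t_half"],
        vss=vss(params) if params is not None else None,
        auc_ratio_met_parent=auc_ratio(curve, extrapolate=True) if analyte == "parent" else None,
    )


def nca_table(ds) -> pd.DataFrame:
    """Per subject/occasion/analyte NCA metrics from a long-format dataset.

    For the IV occasion the observed Vss is added via the moment method,
    ``Vss = D * AUMC / AUC^2``.
    """
    rows = []
    obs = ds.observations()
    for (sid, occ), grp in obs.groupby(["ID", "OCC"]):
        dose_row = ds.df[(ds.df["ID"] == sid) & (ds.df["OCC"] == occ) & (ds.df["DVID"] == 0)]
        amt = float(dose_row["AMT"].iloc[0])
        form = dose_row["FORM"].iloc[0]
        for dvid, name in ((1, "parent"), (2, "metabolite")):
            g = grp[grp["DVID"] == dvid].sort_values("TIME")
            t, c = g["TIME"].to_numpy(), g["DV"].to_numpy()
            if len(t) < 4:
                continue
            if t[0] > 0:
                # concentration starts at zero: doses are infused (IV) or
                # absorbed from a depot (oral), never an instantaneous bolus
                t = np.concatenate(([0.0], t))
                c = np.concatenate(([0.0], c))
            row = {"ID": sid, "OCC": occ, "FORM": form, "analyte": name}
            try:
                lz = fit_lambda_z(t, c)
                row["t_half"] = lz["t_half"]
                row["auc_inf"] = auc_trapezoid(t, c, 0.0, None, True, lz["lambda_z"])
                if form == "none" and dvid == 1:
                    aumc = aumc_trapezoid(t, c, True, lz["lambda_z"])
                    row["vss_obs"] = amt * aumc / row["auc_inf"] ** 2
            except ValueError:
                row["t_half"] = np.nan
                row["auc_inf"] = np.nan
            row["auc24"] = auc_trapezoid(t, c, 0.0, 24.0)
            row["cmax"], row["tmax"] = cmax_tmax(t, c)
            rows.append(row)
    return pd.DataFrame(rows)
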