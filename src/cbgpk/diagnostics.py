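"""Goodness-of-fit machinery: visual predictive checks and weighted residuals.

The VPC simulates replicate studies under the candidate population model on
the dataset's own design (same subjects, occasions and nominal times),
computes the 10th/50th/90th percentiles of each replicate per time bin, and
summarizes each percentile's 90% prediction band (5th-95th across
replicates), stratified by analyte and occasion formulation.  Binning is one
bin per nominal sampling time, appropriate for this nominal-time rich
design.

Residuals: IWRES uses the empirical Bayes (conditional-mode) predictions,
``(obs - ipred) / (b * ipred)``; PWRES standardizes against the marginal
mean and standard deviation of each design point, approximated by Monte
Carlo simulation from the population model.  Plots are conveniences; the
numbers are the tested surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import (
    FitResult,
    _group_predictions,
    _IDX,
    _JointPosterior,
    _Problem,
    _theta_arrays,
)
from .population_model import IOV_PARAMS, PARAM_NAMES, PopulationModel
from .synthetic_data import PKDataset

_PCTS = (10.0, 50.0, 90.0)


@dataclass
class VpcResult:
    """Long-format VPC table.

    One row per (formulation, analyte, time bin): observed percentiles and
    the simulated 90% band around each percentile.
    """

    table: pd.DataFrame
    n_sim: int

    def strata(self):
        return sorted(set(zip(self.table["FORM"], self.table["analyte"])))


def _simulate_group_obs(group, pop: PopulationModel, fm, n, rng):
    """One replicate of a group's observation cube under the population model."""
    eta = np.empty((n, 9))
    for p in PARAM_NAMES:
        mu = float(pop.transform(p, pop.typical[p]))
        om = pop.omega(p)
        eta[:, _IDX[p]] = mu + (rng.standard_normal(n) * om if om > 0 else 0.0)
    kappa = None
    if group.route == "oral":
        kappa = np.empty((n, 3))
        for j, p in enumerate(IOV_PARAMS):
            mean = pop.covariates.get(p, {}).get(group.formulation, 0.0)
            ga = pop.gamma(p)
            kappa[:, j] = mean + (rng.standard_normal(n) * ga if ga > 0 else 0.0)
    th = _theta_arrays(eta, kappa, fm)
    pred = _group_predictions(group, th)
    b = np.array([pop.b1, pop.b2])
    eps = rng.standard_normal(pred.shape)
    return np.maximum(pred * (1.0 + b[None, None, :] * eps), 0.0)


def vpc(
    ds: PKDataset,
    pop: PopulationModel,
    n_sim: int = 500,
    bins=None,
    seed=None,
) -> VpcResult:
    """Visual predictive check of ``ds`` against ``pop``.

    ``bins`` defaults to the dataset's nominal post-dose sampling times (one
    bin per time).  Empty bins are dropped with a warning.  Reproducible
    given ``seed``.
    """
    if n_sim < 100:
        raise ValueError("need n_sim >= 100 for stable percentile bands")
    rng = np.random.default_rng(seed)
    prob = _Problem(ds)
    fm = 0.75
    rows = []
    for g in prob.groups:
        if bins is None:
            centers = g.times
        else:
            centers = np.asarray(bins, dtype=float)
        # map each observation column to its nearest bin center
        col_bin = np.argmin(np.abs(g.times[None, :] - centers[:, None]), axis=0)

        sims = np.empty((n_sim, len(centers), 2, len(_PCTS)))
        sims.fill(np.nan)
        for r in range(n_sim):
            cube = _simulate_group_obs(g, pop, fm, prob.n, rng)
            cube = np.where(g.mask, cube, np.nan)
            for ib in range(len(centers)):
                cols = np.where(col_bin == ib)[0]
                if len(cols) == 0:
                    continue
                for a in range(2):
                    v = cube[:, cols, a]
                    v = v[~np.isnan(v)]
                    if len(v):
                        sims[r, ib, a, :] = np.percentile(v, _PCTS)

        for ib, center in enumerate(centers):
            cols = np.where(col_bin == ib)[0]
            for a, analyte in enumerate(("parent", "metabolite")):
                v = g.obs[:, cols, a] if len(cols) else np.array([])
                v = v[~np.isnan(v)] if len(cols) else v
                if v.size == 0:
                    warnings.warn(f"empty VPC bin at t={center} ({g.formulation}/{analyte})")
                    continue
                obs_p = np.percentile(v, _PCTS)
                row = {
                    "FORM": g.formulation,
                    "analyte": analyte,
                    "time": float(center),
                    "n_obs": int(v.size),
                }
                for j, q in enumerate((10, 50, 90)):
                    sim_q = sims[:, ib, a, j]
                    sim_q = sim_q[~np.isnan(sim_q)]
                    row[f"obs_p{q}"] = float(obs_p[j])
                    row[f"sim_p{q}"] = float(np.median(sim_q))
                    row[f"band_p{q}_lo"] = float(np.percentile(sim_q, 5))
                    row[f"band_p{q}_hi"] = float(np.percentile(sim_q, 95))
                rows.append(row)
    return VpcResult(table=pd.DataFrame(rows), n_sim=n_sim)


def residual_table(ds: PKDataset, fit: FitResult, n_sim: int = 300, seed=None):
    """Population- and individual-weighted residuals.

    Returns ``(table, summary)``; the table has one row per quantifiable
    observation with PRED (marginal mean), IPRED (conditional-mode
    prediction), IWRES and PWRES; the summary reports the fraction of
    |residual| > 2 and the number of zero predictions excluded.
    """
    rng = np.random.default_rng(seed)
    prob = _Problem(ds)
    model = fit.model
    fm = float(model.fixed.get("Fm", 0.75))
    b = np.array([model.b1, model.b2])

    post = _JointPosterior(prob, model, fit.settings, fm)
    z0 = np.tile(
        np.concatenate([post.mu] + [post.kmeans[g.key] for g in prob.oral_groups]),
        (prob.n, 1),
    )
    if fit.ebe_state.get("zhat") is not None and fit.ebe_state["zhat"].shape == z0.shape:
        z0 = fit.ebe_state["zhat"]
    zhat = post.modes(z0, maxiter=fit.settings.ebe_maxiter)
    eta_hat, kappa_hat = post.unpack(zhat)

    rows = []
    n_excluded = 0
    for g in prob.groups:
        ipred = _group_predictions(g, _theta_arrays(eta_hat, kappa_hat.get(g.key), fm))
        # marginal mean/sd by simulation
        acc = np.zeros((n_sim,) + ipred.shape)
        for r in range(n_sim):
            acc[r] = _simulate_group_obs(g, model, fm, prob.n, rng)
        m = acc.mean(axis=0)
        s = acc.std(axis=0, ddof=1)
        for i, sid in enumerate(prob.subjects):
            for j, t in enumerate(g.times):
                for a, analyte in enumerate(("parent", "metabolite")):
                    if not g.mask[i, j, a]:
                        continue
                    y = g.obs[i, j, a]
                    f = ipred[i, j, a]
                    if f <= 0 or s[i, j, a] <= 0:
                        n_excluded += 1
                        continue
                    if fit.settings.error_model == "proportional":
                        iw = (y - f) / (b[a] * f)
                    else:
                        iw = (y - f) / b[a]
                    rows.append(
                        {
                            "ID": sid,
                            "FORM": g.formulation,
                            "TIME": float(t),
                            "analyte": analyte,
                            "DV": float(y),
                            "PRED": float(m[i, j, a]),
                            "IPRED": float(f),
                            "IWRES": float(iw),
                            "PWRES": float((y - m[i, j, a]) / s[i, j, a]),
                        }
                    )
    table = pd.DataFrame(rows)
    summary = {
        "frac_iwres_gt2": float((table["IWRES"].abs() > 2).mean()) if len(table) else np.nan,
        "frac_pwres_gt2": float((table["PWRES"].abs() > 2).mean()) if len(table) else np.nan,
        "n_excluded_zero_pred": n_excluded,
        "n_residuals": int(len(table)),
    }
    return table, summary


def plot_vpc(result: VpcResult, path):
    """Write a standard VPC figure (one panel per stratum) to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    strata = result.strata()
    ncol = min(3, len(strata))
    nrow = (len(strata) + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4.5 * ncol, 3.5 * nrow), squeeze=False)
    for k, (form, analyte) in enumerate(strata):
        ax = axes[k // ncol][k % ncol]
        sub = result.table[
            (result.table["FORM"] == form) & (result.table["analyte"] == analyte)
        ].sort_values("time")
        for q, color in ((10, "tab:blue"), (50, "tab:red"), (90, "tab:blue")):
            ax.fill_between(
                sub["time"], sub[f"band_p{q}_lo"], sub[f"band_p{q}_hi"],
                alpha=0.25, color=color, lw=0,
            )
            ax.plot(sub["time"], sub[f"obs_p{q}"], color=color, lw=1.2)
        ax.set_yscale("log")
        ax.set_title(f"{analyte} / {form}")
        ax.set_xlabel("time (h)")
        ax.set_ylabel("concentration (nmol/L)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
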