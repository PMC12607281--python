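"""Nonlinear mixed-effects estimation of the CBG/CBG-G population model.

The marginal likelihood is maximized by stochastic approximation EM (SAEM)
with Metropolis-within-Gibbs sampling of the individual parameters, the
classical algorithm for this model family.  Latent variables are

* ``eta``   — per subject, the transformed individual parameter vector
  (location absorbed: prior ``N(mu, Omega)`` with diagonal ``Omega``);
* ``kappa`` — per subject and oral occasion, the occasion shift of
  F, ka and beta (prior mean = the formulation-covariate coefficient on the
  transformed scale, variance ``Gamma``).

With this parameterization the complete-data model is a Gaussian linear
model in (mu, covariate coefficients, Omega, Gamma) and the M-step is in
closed form; the residual proportions likewise update in closed form from
the simulated residuals.  The metabolized fraction Fm is a fixed constant
(0.75) and is never estimated.

Parameters with no random effect (Q) receive a small "working" variability
during sampling — annealed from ``working_sd_start`` to ``working_sd`` over
the exploration phase — so their typical value also has a closed-form
update; the working standard deviation is an algorithmic device and is not
reported as IIV.

The marginal -2*log-likelihood (for AIC/BIC and covariate decisions) is
computed after convergence by a Laplace approximation around the empirical
Bayes modes.  BIC uses N = number of subjects.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .population_model import (
    CATEGORIES,
    IIV_PARAMS,
    IOV_PARAMS,
    PARAM_NAMES,
    PopulationModel,
    sd_to_percent,
)
from .secondary_params import auc_trapezoid, cmax_tmax, fit_lambda_z
from .structural_model import _iv_modal, _modal_setup, _oral_modal
from .synthetic_data import PKDataset

_IDX = {p: i for i, p in enumerate(PARAM_NAMES)}
_IOV_COLS = [_IDX[p] for p in IOV_PARAMS]  # F, ka, beta


# ---------------------------------------------------------------------------
# settings and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EstimationSettings:
    """SAEM controls; the defaults suit the study-sized rich designs."""

    n_phase1: int = 400  # exploration iterations (step size 1)
    n_phase2: int = 200  # stochastic-approximation iterations
    n_starts: int = 2  # phase-1 chains; the best by complete likelihood continues
    gm_temp_start: float = 4.0  # initial temperature of the population moves
    mh_sweeps: int = 2  # Metropolis sweeps per latent block per iteration
    subset: int = 3  # coordinates perturbed per eta proposal
    covariate_params: tuple = ("ka", "beta")  # formulation effect on these
    error_model: str = "proportional"  # or "additive"
    screen_init: bool = True  # coarse likelihood screen of Q/Vc/Vm starts
    working_sd: float = 0.05  # final working SD for no-variability params
    working_sd_start: float = 0.35
    sa_power: float = 0.8  # SA step = 1/(k - n_phase1)^sa_power
    target_accept: float = 0.3
    omega_floor: float = 1e-3  # below this an omega is collapsed to 0
    compute_ll: bool = True  # Laplace -2LL after the SAEM run
    ebe_maxiter: int = 300
    free_params: tuple = tuple(PARAM_NAMES)  # structural typicals to estimate


@dataclass
class FitResult:
    """Population estimates plus likelihood metrics and run metadata."""

    model: PopulationModel
    minus2ll: float
    aic: float
    bic: float
    n_params: int
    n_subjects: int
    converged: bool
    trace: pd.DataFrame
    se: dict
    algorithm: str
    seed: object
    dataset_hash: str
    settings: EstimationSettings
    ebe_state: dict = field(repr=False, default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Parameter table mirroring the reported layout (typical, IIV%,
        IOV%, category values, residual proportions)."""
        m = self.model
        rows = []
        for p in PARAM_NAMES:
            rows.append(
                {
                    "parameter": p,
                    "estimate": m.typical[p],
                    "iiv_percent": m.iiv_percent.get(p, np.nan),
                    "iov_percent": m.iov_percent.get(p, np.nan),
                }
            )
        rows.append({"parameter": "Fm", "estimate": m.fixed.get("Fm", 0.75)})
        for p, cats in m.covariates.items():
            for cat, coef in cats.items():
                rows.append(
                    {
                        "parameter": f"{p}_{cat}",
                        "estimate": m.category_typical(p, cat),
                    }
                )
        rows.append({"parameter": "b1", "estimate": m.b1})
        rows.append({"parameter": "b2", "estimate": m.b2})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dataset -> vectorized fitting problem
# ---------------------------------------------------------------------------


class _Group:
    """One occasion template (same route/formulation/dose/schedule) across
    subjects, with an (n_subjects, n_times, 2) NaN-masked observation cube."""

    def __init__(self, key, route, formulation, amount, dur, times, obs):
        self.key = key
        self.route = route
        self.formulation = formulation
        self.amount = amount
        self.dur = dur
        self.times = times
        self.obs = obs
        self.mask = ~np.isnan(obs)
        self.n_obs_analyte = self.mask.sum(axis=(0, 1))


class _Problem:
    def __init__(self, ds: PKDataset):
        df = ds.df
        self.subjects = ds.subjects
        self.n = len(self.subjects)
        self.sub_index = {s: i for i, s in enumerate(self.subjects)}
        obs = ds.observations()
        obs = obs[obs["TIME"] > 0]

        groups = {}
        for (sid, occ), grp in df.groupby(["ID", "OCC"]):
            dose = grp[grp["DVID"] == 0].iloc[0]
            form = dose["FORM"]
            route = "iv" if form == "none" else "oral"
            o = obs[(obs["ID"] == sid) & (obs["OCC"] == occ)]
            if o.empty:
                continue
            times = tuple(sorted(o["TIME"].unique()))
            key = (route, form, float(dose["AMT"]), float(dose["DUR"]), times)
            groups.setdefault(key, []).append((sid, o))

        self.groups = []
        for key, members in groups.items():
            route, form, amount, dur, times = key
            t = np.asarray(times, dtype=float)
            cube = np.full((self.n, len(t), 2), np.nan)
            tpos = {v: j for j, v in enumerate(times)}
            seen = set()
            for sid, o in members:
                if sid in seen:
                    raise ValueError(
                        "multiple occasions with an identical template for one "
                        "subject are not supported; renumber occasions"
                    )
                seen.add(sid)
                i = self.sub_index[sid]
                for _, r in o.iterrows():
                    cube[i, tpos[r["TIME"]], int(r["DVID"]) - 1] = r["DV"]
            self.groups.append(_Group(key, route, form, amount, dur, t, cube))
        # stable order: IV first, then oral by formulation
        self.groups.sort(key=lambda g: (g.route != "iv", g.formulation))
        self.oral_groups = [g for g in self.groups if g.route == "oral"]

        quant = obs.groupby("ID")["DVID"].nunique()
        if (quant >= 2).sum() < 2:
            raise ValueError(
                "no quantifiable data: need >= 2 subjects with observations on both analytes"
            )


def _theta_arrays(eta, kappa, fm):
    """Transformed latent matrix -> structural parameter arrays."""
    th = {}
    for p in PARAM_NAMES:
        col = eta[:, _IDX[p]]
        th[p] = 1.0 / (1.0 + np.exp(-col)) if p == "F" else np.exp(col)
    if kappa is not None:
        phiF = eta[:, 0] + kappa[:, 0]
        th["F"] = 1.0 / (1.0 + np.exp(-phiF))
        th["ka"] = np.exp(eta[:, 1] + kappa[:, 1])
        th["beta"] = np.exp(eta[:, 2] + kappa[:, 2])
    th["Fm"] = np.full(eta.shape[0], fm)
    return th


def _group_predictions(group: _Group, th: dict):
    lam, row1, _, row3, U = _modal_setup(
        th["Cl"], th["Vc"], th["Q"], th["Vp"], th["Fm"], th["Clm"], th["Vm"]
    )
    if group.route == "oral":
        Y = _oral_modal(group.times, lam, U, th["F"] * group.amount, th["ka"], th["beta"])
    else:
        Y = _iv_modal(group.times, lam, U, np.float64(group.amount), group.dur)
    c1 = np.einsum("nm,ntm->nt", row1, Y) / th["Vc"][:, None]
    c3 = np.einsum("nm,ntm->nt", row3, Y) / th["Vm"][:, None]
    return np.stack([c1, c3], axis=2)


_LOG2PI = math.log(2.0 * math.pi)


def _obs_loglik(group: _Group, pred, b, error_model):
    """(n,) per-subject observation log-likelihood."""
    out = np.zeros(pred.shape[0])
    for a in range(2):
        m = group.mask[:, :, a]
        if not m.any():
            continue
        y = group.obs[:, :, a]
        f = np.maximum(pred[:, :, a], 1e-12)
        if error_model == "proportional":
            sd = b[a] * f
        else:
            sd = np.full_like(f, b[a])
        z = np.where(m, (y - f) / sd, 0.0)
        ll = -0.5 * (z * z + _LOG2PI) - np.where(m, np.log(sd), 0.0)
        out += np.where(m, ll, 0.0).sum(axis=1)
    return out


# ---------------------------------------------------------------------------
# NCA-informed initial values
# ---------------------------------------------------------------------------


def _peel_biexponential(t, c, dose, lz):
    """Classic curve peeling of an IV profile: terminal line from the
    lambda-z fit, early residuals give the distribution exponential, and the
    macro constants convert to (Cl, Vc, Q, Vp) via the standard bolus
    formulas.  Returns None when the early phase is not resolvable."""
    B = lz["intercept"]
    beta_z = lz["lambda_z"]
    early = t <= 1.0
    term = B * np.exp(-beta_z * t[early])
    resid = c[early] - term
    # keep only points where the fast mode clearly dominates the terminal
    # line, otherwise lambda-z noise flattens the distribution slope
    keep = (resid > 0.5 * term) & (resid > 0.02 * np.max(c))
    if keep.sum() < 3:
        return None
    te, re_ = t[early][keep], resid[keep]
    slope, inter = np.polyfit(te, np.log(re_), 1)
    alpha = -slope
    if alpha <= 3.0 * beta_z:
        return None
    A = math.exp(inter)
    k21 = (A * beta_z + B * alpha) / (A + B)
    k10 = alpha * beta_z / k21
    k12 = alpha + beta_z - k21 - k10
    if k12 <= 0 or k21 <= 0 or k10 <= 0:
        return None
    vc = dose / (A + B)
    return {"Cl": k10 * vc, "Vc": vc, "Q": k12 * vc, "Vp": k12 * vc / k21}


def nca_initial_values(ds: PKDataset, fm: float = 0.75) -> PopulationModel:
    """Crude non-compartmental starting values for the SAEM run.

    Cl from IV dose/AUC, Vc from the IV peak, Vss from Cl * MRT, Q from the
    early IV distribution slope, F from the oral/IV dose-normalized AUC
    ratio, ka from 1/Tmax(oral), Clm from the IV metabolite AUC with the
    fixed Fm.  Any quantity that cannot be computed falls back to a generic
    default.  Variabilities start at 30% IIV / 15% IOV, b at 0.3.
    """
    obs = ds.observations()
    obs = obs[obs["TIME"] > 0]
    cl_i, vc_i, vss_i, q_i, f_i, clm_i = [], [], [], [], [], []
    ka_i: dict = {}
    for (sid, occ), grp in ds.df.groupby(["ID", "OCC"]):
        dose = grp[grp["DVID"] == 0].iloc[0]
        amt = float(dose["AMT"])
        o = obs[(obs["ID"] == sid) & (obs["OCC"] == occ)]
        par = o[o["DVID"] == 1].sort_values("TIME")
        met = o[o["DVID"] == 2].sort_values("TIME")
        t, c = par["TIME"].to_numpy(), par["DV"].to_numpy()
        if len(t) < 5:
            continue
        try:
            lz = fit_lambda_z(t, c)
            auc = auc_trapezoid(t, c, 0.0, None, True, lz["lambda_z"])
        except ValueError:
            continue
        if dose["FORM"] == "none":
            cl = amt / auc
            cl_i.append(cl)
            cmax = cmax_tmax(t, c)[0]
            if cmax > 0:
                vc_i.append(amt / cmax)
            aumc = float(np.trapezoid(t * c, t)) + c[-1] * t[-1] / lz["lambda_z"] + c[-1] / lz[
                "lambda_z"
            ] ** 2
            vss_i.append(cl * aumc / auc)
            micro = _peel_biexponential(t, c, amt, lz)
            if micro is not None:
                q_i.append(micro)  # dict with Cl, Vc, Q, Vp
            if len(met) >= 5:
                tm, cm = met["TIME"].to_numpy(), met["DV"].to_numpy()
                try:
                    lzm = fit_lambda_z(tm, cm)
                    aucm = auc_trapezoid(tm, cm, 0.0, None, True, lzm["lambda_z"])
                    clm_i.append(fm * amt / aucm)
                except ValueError:
                    pass
            f_i.append(("iv", amt, auc))
        else:
            f_i.append(("oral", amt, auc))
            ka_i.setdefault(dose["FORM"], []).append(1.0 / max(cmax_tmax(t, c)[1], 0.1))

    cl0 = float(np.exp(np.mean(np.log(cl_i)))) if cl_i else 1.0
    vc0 = float(np.exp(np.mean(np.log(vc_i)))) if vc_i else 10.0
    vss0 = float(np.median(vss_i)) if vss_i else 3.0 * vc0
    vp0 = max(vss0 - vc0, 0.2 * vc0)
    if q_i:
        # curve-peeling succeeded for at least one subject: use its full
        # micro-constant picture of the two-compartment disposition
        vc0 = float(np.exp(np.mean(np.log([m["Vc"] for m in q_i]))))
        q0 = float(np.exp(np.mean(np.log([m["Q"] for m in q_i]))))
        vp0 = float(np.exp(np.mean(np.log([m["Vp"] for m in q_i]))))
    else:
        q0 = 3.0 * cl0
    iv_aucs = [a / d for r, d, a in f_i if r == "iv"]
    oral_aucs = [a / d for r, d, a in f_i if r == "oral"]
    if iv_aucs and oral_aucs:
        f0 = float(np.clip(np.mean(oral_aucs) / np.mean(iv_aucs), 0.02, 0.95))
    else:
        f0 = 0.5
    ka_cat = {
        form: float(np.clip(np.median(v), 0.05, 10.0)) for form, v in ka_i.items() if v
    }
    ka0 = ka_cat.get("micellar") or (float(np.median(list(ka_cat.values()))) if ka_cat else 1.0)
    covariates = {}
    if "micellar" in ka_cat and "oil" in ka_cat and ka_cat["oil"] != ka_cat["micellar"]:
        covariates = {"ka": {"oil": math.log(ka_cat["oil"] / ka_cat["micellar"])}}
    clm0 = float(np.exp(np.mean(np.log(clm_i)))) if clm_i else 0.1 * cl0
    vm0 = clm0  # start at a 1/h metabolite turnover
    return PopulationModel(
        typical={
            "F": f0,
            "ka": ka0,
            "beta": 1.2,
            "Cl": cl0,
            "Vc": vc0,
            "Q": q0,
            "Vp": vp0,
            "Vm": vm0,
            "Clm": clm0,
        },
        iiv_percent={p: 30.0 for p in IIV_PARAMS},
        iov_percent={p: 15.0 for p in IOV_PARAMS},
        covariates=covariates,
        b1=0.5,
        b2=0.5,
        fixed={"Fm": fm},
    )


def _screen_initial_values(prob: _Problem, init: PopulationModel, fm: float) -> PopulationModel:
    """Coarse likelihood screen of the initial typical values.

    The sampling schedule starts only at the end of the 5-minute infusion,
    so non-compartmental starts barely see the fast distribution phase, and
    the metabolite turnover is not observable at all by moment methods.  A
    small multiplier grid over (Q, Vc, Vm) evaluated at the population
    typical prediction (no random effects, wide residual) reliably places
    the SAEM start in the right basin without any per-subject work.
    """
    b = np.array([0.5, 0.5])
    best, best_ll = None, -np.inf
    base = dict(init.typical)
    for qm in (1.0, 3.0, 10.0, 30.0):
        for vcm in (0.7, 1.0, 1.5):
            for vmm in (0.3, 1.0, 3.0):
                typ = dict(base)
                typ["Q"] = base["Q"] * qm
                typ["Vc"] = base["Vc"] * vcm
                typ["Vm"] = base["Vm"] * vmm
                cand = PopulationModel(
                    typical=typ,
                    iiv_percent=dict(init.iiv_percent),
                    iov_percent=dict(init.iov_percent),
                    covariates={k: dict(v) for k, v in init.covariates.items()},
                    b1=init.b1,
                    b2=init.b2,
                    fixed=dict(init.fixed),
                )
                eta = np.tile(
                    [float(cand.transform(p, typ[p])) for p in PARAM_NAMES], (prob.n, 1)
                )
                ll = 0.0
                for g in prob.groups:
                    kap = None
                    if g.route == "oral":
                        kap = np.zeros((prob.n, 3))
                        for j, p in enumerate(IOV_PARAMS):
                            kap[:, j] = cand.covariates.get(p, {}).get(g.formulation, 0.0)
                    pred = _group_predictions(g, _theta_arrays(eta, kap, fm))
                    ll += _obs_loglik(g, pred, b, "proportional").sum()
                if ll > best_ll:
                    best, best_ll = cand, ll
    return best


# ---------------------------------------------------------------------------
# the SAEM machine
# ---------------------------------------------------------------------------


class _Saem:
    def __init__(self, prob: _Problem, init: PopulationModel, settings, rng, fm):
        self.prob = prob
        self.s = settings
        self.rng = rng
        self.fm = fm
        n = prob.n

        self.mu = np.array(
            [float(init.transform(p, init.typical[p])) for p in PARAM_NAMES]
        )
        self.omega = np.array(
            [max(init.omega(p), 1e-8) if p in IIV_PARAMS else 0.0 for p in PARAM_NAMES]
        )
        self.gamma = np.array([max(init.gamma(p), 1e-8) for p in IOV_PARAMS])
        self.b = np.array([max(init.b1, 0.05), max(init.b2, 0.05)])
        self.cov = {
            p: dict(init.covariates.get(p, {})) for p in settings.covariate_params
        }
        self.use_cov = bool(settings.covariate_params)

        self.eta = np.tile(self.mu, (n, 1))
        self.kappa = {
            g.key: np.tile(self._kappa_mean(g), (n, 1)) for g in prob.oral_groups
        }
        self.ll = {}
        self.pred = {}
        self.prop_scale = {"eta": 0.4, **{g.key: 0.4 for g in prob.oral_groups}}
        self.trace_rows = []

    # -- helpers ------------------------------------------------------------

    def _kappa_mean(self, group) -> np.ndarray:
        m = np.zeros(3)
        if self.use_cov and group.formulation in CATEGORIES:
            for j, p in enumerate(IOV_PARAMS):
                m[j] = self.cov.get(p, {}).get(group.formulation, 0.0)
        return m

    def _omega_work(self, frac: float) -> np.ndarray:
        """Sampling SDs: estimated omegas, with the annealed working SD for
        parameters without IIV."""
        w = self.omega.copy()
        # hold the exploratory width for the first part of phase 1, then decay
        r = max(0.0, min((frac - 0.4) / 0.6, 1.0))
        ws = self.s.working_sd_start * (1.0 - r) + self.s.working_sd * r
        for i, p in enumerate(PARAM_NAMES):
            if p not in IIV_PARAMS:
                w[i] = ws
        return np.maximum(w, 1e-3)

    def _refresh(self, group):
        kap = self.kappa.get(group.key)
        th = _theta_arrays(self.eta, kap, self.fm)
        pred = _group_predictions(group, th)
        self.pred[group.key] = pred
        self.ll[group.key] = _obs_loglik(group, pred, self.b, self.s.error_model)

    def _eta_prior(self, eta, w):
        z = (eta - self.mu) / w
        return -0.5 * (z * z).sum(axis=1) - np.log(w).sum()

    def _kappa_prior(self, group, kap):
        mean = self._kappa_mean(group)
        g = np.maximum(self.gamma, 1e-3)
        z = (kap - mean) / g
        return -0.5 * (z * z).sum(axis=1) - np.log(g).sum()

    # -- Metropolis sweeps ---------------------------------------------------

    def _sweep_eta(self, w):
        s = self.s
        n = self.prob.n
        idx = self.rng.choice(len(PARAM_NAMES), size=min(s.subset, len(PARAM_NAMES)), replace=False)
        prop = self.eta.copy()
        step = self.prop_scale["eta"] * np.maximum(w[idx], 0.05)
        prop[:, idx] += self.rng.standard_normal((n, len(idx))) * step
        new_ll, new_pred = {}, {}
        delta = self._eta_prior(prop, w) - self._eta_prior(self.eta, w)
        for g in self.prob.groups:
            th = _theta_arrays(prop, self.kappa.get(g.key), self.fm)
            pred = _group_predictions(g, th)
            ll = _obs_loglik(g, pred, self.b, s.error_model)
            new_ll[g.key], new_pred[g.key] = ll, pred
            delta += ll - self.ll[g.key]
        acc = np.log(self.rng.uniform(size=n)) < delta
        self.eta[acc] = prop[acc]
        for g in self.prob.groups:
            self.ll[g.key][acc] = new_ll[g.key][acc]
            self.pred[g.key][acc] = new_pred[g.key][acc]
        self._adapt("eta", acc.mean())

    def _sweep_kappa(self, group, w):
        s = self.s
        n = self.prob.n
        kap = self.kappa[group.key]
        prop = kap + self.rng.standard_normal((n, 3)) * (
            self.prop_scale[group.key] * np.maximum(self.gamma, 0.1)
        )
        th = _theta_arrays(self.eta, prop, self.fm)
        pred = _group_predictions(group, th)
        ll = _obs_loglik(group, pred, self.b, s.error_model)
        delta = (
            ll
            - self.ll[group.key]
            + self._kappa_prior(group, prop)
            - self._kappa_prior(group, kap)
        )
        acc = np.log(self.rng.uniform(size=n)) < delta
        kap[acc] = prop[acc]
        self.ll[group.key][acc] = ll[acc]
        self.pred[group.key][acc] = pred[acc]
        self._adapt(group.key, acc.mean())

    # correlated directions of weak identification:
    # (Q,Vc) (Q,Vp) (Vc,Vp) (Cl,Vc) (Vm,Clm) and the full disposition triple
    _PAIRS = ((5, 4), (5, 6), (4, 6), (3, 4), (7, 8), (5, 4, 6))

    def _sweep_group_move(self, temperature: float = 1.0):
        """Population-level move: shift one latent coordinate (or a
        correlated set) for every subject together with its location mu.

        The eta prior is invariant under the joint shift, so acceptance is
        decided by the total data likelihood alone; this carries the whole
        population along weakly identified ridges (notably the distribution
        parameters, whose fast phase the 5-minute-infusion schedule barely
        samples) far faster than subject-level moves can.  A mild annealed
        temperature lets the population cross shallow likelihood barriers
        early in the exploration phase.
        """
        if self.rng.uniform() < 0.5:
            cols = [int(self.rng.integers(len(PARAM_NAMES)))]
        else:
            cols = list(self._PAIRS[int(self.rng.integers(len(self._PAIRS)))])
        delta = self.rng.normal(0.0, 0.3, size=len(cols))
        prop = self.eta.copy()
        prop[:, cols] += delta
        dll = 0.0
        new_ll, new_pred = {}, {}
        for g in self.prob.groups:
            th = _theta_arrays(prop, self.kappa.get(g.key), self.fm)
            pred = _group_predictions(g, th)
            ll = _obs_loglik(g, pred, self.b, self.s.error_model)
            new_ll[g.key], new_pred[g.key] = ll, pred
            dll += float((ll - self.ll[g.key]).sum())
        if math.log(self.rng.uniform()) < dll / max(temperature, 1.0):
            self.eta = prop
            self.mu[cols] += delta
            self.ll = new_ll
            self.pred = new_pred

    def _recenter_kappa(self):
        """Remove the location degeneracy between eta and kappa.

        The mean reference-category occasion shift is moved into the
        subject-level latents: phi on every oral occasion is unchanged, and
        F/ka/beta play no role on the IV occasion, so the likelihood (and
        every cached prediction) is untouched while the typical values
        absorb the location.
        """
        ref = [g for g in self.prob.oral_groups if g.formulation == CATEGORIES[0]]
        if not ref:
            return
        delta = self.kappa[ref[0].key].mean(axis=0)
        for g in self.prob.oral_groups:
            self.kappa[g.key] -= delta
        self.eta[:, _IOV_COLS] += delta

    def _adapt(self, key, rate):
        self.prop_scale[key] *= math.exp(0.1 * (rate - self.s.target_accept))
        self.prop_scale[key] = min(max(self.prop_scale[key], 0.01), 10.0)

    # -- sufficient statistics / M-step --------------------------------------

    def _residual_stats(self):
        ss = np.zeros(2)
        cnt = np.zeros(2)
        for g in self.prob.groups:
            pred = self.pred[g.key]
            for a in range(2):
                m = g.mask[:, :, a]
                if not m.any():
                    continue
                f = np.maximum(pred[:, :, a], 1e-12)
                if self.s.error_model == "proportional":
                    r = (g.obs[:, :, a] - f) / f
                else:
                    r = g.obs[:, :, a] - f
                ss[a] += np.where(m, r * r, 0.0).sum()
                cnt[a] += m.sum()
        return ss, cnt

    def run(self, n_iter_1, n_iter_2):
        prob, s = self.prob, self.s
        for g in prob.groups:
            self._refresh(g)

        stats = None
        total = n_iter_1 + n_iter_2
        for k in range(total):
            frac = min(k / n_iter_1, 1.0) if n_iter_1 > 0 else 1.0
            w = self._omega_work(frac)
            for _ in range(s.mh_sweeps):
                self._sweep_eta(w)
                for g in prob.oral_groups:
                    self._sweep_kappa(g, w)
            if k < n_iter_1:
                t = self.s.gm_temp_start
                temp = max(1.0, t * (1.0 - frac / 0.7)) if frac < 0.7 else 1.0
                for _ in range(2):
                    self._sweep_group_move(temp)
            self._recenter_kappa()

            ss, cnt = self._residual_stats()
            new = {
                "e1": self.eta.mean(axis=0),
                "e2": (self.eta**2).mean(axis=0),
                "k1": {key: kap.mean(axis=0) for key, kap in self.kappa.items()},
                "k2": {key: (kap**2).mean(axis=0) for key, kap in self.kappa.items()},
                "r": ss / np.maximum(cnt, 1),
            }
            if stats is None or k < n_iter_1:
                step = 1.0
            else:
                step = 1.0 / (k - n_iter_1 + 1) ** s.sa_power
            if stats is None:
                stats = new
            else:
                stats = _sa_blend(stats, new, step)
            self._m_step(stats, anneal=(k < n_iter_1))

            self.trace_rows.append(
                {
                    "iteration": len(self.trace_rows) + 1,
                    "complete_ll": float(
                        sum(self.ll[g.key].sum() for g in prob.groups)
                    ),
                    **{f"mu_{p}": self.mu[_IDX[p]] for p in PARAM_NAMES},
                    **{f"omega_{p}": self.omega[_IDX[p]] for p in IIV_PARAMS},
                    "b1": self.b[0],
                    "b2": self.b[1],
                }
            )

    def _m_step(self, stats, anneal):
        s = self.s
        free = set(s.free_params)
        for i, p in enumerate(PARAM_NAMES):
            if p in free:
                self.mu[i] = stats["e1"][i]
        var = stats["e2"] - stats["e1"] ** 2
        for i, p in enumerate(PARAM_NAMES):
            if p in IIV_PARAMS:
                v = max(var[i], 1e-8)
                if anneal:
                    v = max(v, 0.95 * self.omega[i] ** 2)
                self.omega[i] = math.sqrt(v)

        # occasion level: covariate coefficients and IOV variance
        if self.prob.oral_groups:
            g2 = np.zeros(3)
            n_cat = 0
            for g in self.prob.oral_groups:
                k1, k2 = stats["k1"][g.key], stats["k2"][g.key]
                mean = np.zeros(3)
                if self.use_cov and g.formulation != CATEGORIES[0]:
                    for j, p in enumerate(IOV_PARAMS):
                        if p in self.cov:
                            self.cov[p][g.formulation] = float(k1[j])
                            mean[j] = k1[j]
                g2 += k2 - 2.0 * mean * k1 + mean**2
                n_cat += 1
            v = np.maximum(g2 / n_cat, 1e-8)
            if anneal:
                v = np.maximum(v, (0.95 * self.gamma) ** 2)
            self.gamma = np.sqrt(v)

        bnew = np.sqrt(np.maximum(stats["r"], 1e-10))
        if anneal:
            bnew = np.maximum(bnew, 0.95 * self.b)
        self.b = bnew

    # -- export --------------------------------------------------------------

    def population_model(self) -> PopulationModel:
        typical = {
            p: float(PopulationModel.inverse_transform(p, self.mu[_IDX[p]]))
            for p in PARAM_NAMES
        }
        iiv = {}
        for p in IIV_PARAMS:
            om = self.omega[_IDX[p]]
            if om < self.s.omega_floor:
                warnings.warn(f"IIV for {p} collapsed to 0 (singular variance)")
                om = 0.0
            iiv[p] = sd_to_percent(om, PopulationModel.transform_name(p))
        iov = {
            p: sd_to_percent(self.gamma[j], PopulationModel.transform_name(p))
            for j, p in enumerate(IOV_PARAMS)
        }
        covariates = {
            p: {c: float(v) for c, v in d.items()} for p, d in self.cov.items() if d
        }
        return PopulationModel(
            typical=typical,
            iiv_percent=iiv,
            iov_percent=iov,
            covariates=covariates,
            b1=float(self.b[0]),
            b2=float(self.b[1]),
            fixed={"Fm": self.fm},
        )


def _sa_blend(old, new, step):
    out = {}
    for k, v in new.items():
        if isinstance(v, dict):
            out[k] = {kk: old[k][kk] + step * (vv - old[k][kk]) for kk, vv in v.items()}
        else:
            out[k] = old[k] + step * (v - old[k])
    return out


# ---------------------------------------------------------------------------
# EBEs, Laplace likelihood
# ---------------------------------------------------------------------------


class _JointPosterior:
    """Per-subject joint negative log density of (eta, kappas), batched over
    subjects so finite differences vectorize across the population."""

    def __init__(self, prob, model: PopulationModel, settings, fm):
        self.prob = prob
        self.s = settings
        self.fm = fm
        self.mu = np.array([float(model.transform(p, model.typical[p])) for p in PARAM_NAMES])
        self.omega = np.array(
            [
                max(model.omega(p), settings.working_sd) if p in IIV_PARAMS else settings.working_sd
                for p in PARAM_NAMES
            ]
        )
        self.gamma = np.maximum(
            np.array([model.gamma(p) for p in IOV_PARAMS]), 1e-3
        )
        self.b = np.array([model.b1, model.b2])
        self.kmeans = {}
        for g in prob.oral_groups:
            m = np.zeros(3)
            for j, p in enumerate(IOV_PARAMS):
                m[j] = model.covariates.get(p, {}).get(g.formulation, 0.0)
            self.kmeans[g.key] = m
        self.dim = 9 + 3 * len(prob.oral_groups)

    def unpack(self, z):
        eta = z[:, :9]
        kappas = {
            g.key: z[:, 9 + 3 * i : 12 + 3 * i] for i, g in enumerate(self.prob.oral_groups)
        }
        return eta, kappas

    def nll(self, z):
        eta, kappas = self.unpack(z)
        out = np.zeros(z.shape[0])
        ze = (eta - self.mu) / self.omega
        out += 0.5 * (ze * ze).sum(axis=1) + np.log(self.omega).sum()
        for g in self.prob.groups:
            kap = kappas.get(g.key)
            th = _theta_arrays(eta, kap, self.fm)
            pred = _group_predictions(g, th)
            out -= _obs_loglik(g, pred, self.b, self.s.error_model)
        for g in self.prob.oral_groups:
            zk = (kappas[g.key] - self.kmeans[g.key]) / self.gamma
            out += 0.5 * (zk * zk).sum(axis=1) + np.log(self.gamma).sum()
        return out

    def scales(self) -> np.ndarray:
        """Prior standard deviations per latent coordinate, floored; used to
        precondition the mode search and the Hessian finite differences."""
        parts = [np.maximum(self.omega, 0.05)]
        for _ in self.prob.oral_groups:
            parts.append(np.maximum(self.gamma, 0.05))
        return np.concatenate(parts)

    def grad_scaled(self, u, s, f0=None, h=1e-4):
        """Batched forward-difference gradient in standardized coordinates."""
        if f0 is None:
            f0 = self.nll(u * s)
        gr = np.empty_like(u)
        for j in range(u.shape[1]):
            up = u.copy()
            up[:, j] += h
            gr[:, j] = (self.nll(up * s) - f0) / h
        return gr

    def modes(self, z0, maxiter=120):
        """Batched mode search (per-subject independent, jointly optimized
        in prior-standardized coordinates)."""
        from scipy.optimize import minimize

        s = self.scales()
        shape = z0.shape
        u0 = z0 / s

        def fun(x):
            u = x.reshape(shape)
            f = self.nll(u * s)
            g = self.grad_scaled(u, s, f)
            return float(f.sum()), g.ravel()

        res = minimize(
            fun, u0.ravel(), jac=True, method="L-BFGS-B",
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-5},
        )
        return res.x.reshape(shape) * s

    def laplace_minus2ll(self, zhat) -> float:
        n, d = zhat.shape
        s = self.scales()
        u = zhat / s
        f = self.nll(zhat)
        g0 = self.grad_scaled(u, s, f)
        H = np.empty((n, d, d))
        h = 1e-3
        for j in range(d):
            up = u.copy()
            up[:, j] += h
            H[:, :, j] = (self.grad_scaled(up, s) - g0) / h
        H = 0.5 * (H + np.transpose(H, (0, 2, 1)))
        logdet = np.empty(n)
        for i in range(n):
            Hi = H[i]
            for jitter in (0.0, 1e-6, 1e-3, 1e-1):
                try:
                    L = np.linalg.cholesky(Hi + jitter * np.eye(d))
                    logdet[i] = 2.0 * np.log(np.diag(L)).sum()
                    break
                except np.linalg.LinAlgError:
                    continue
            else:  # pragma: no cover - pathological curvature
                logdet[i] = np.linalg.slogdet(Hi + np.eye(d))[1]
        # det on the z scale: H_z = S^-1 H_u S^-1
        logdet = logdet - 2.0 * np.log(s).sum()
        ll = -f + 0.5 * d * _LOG2PI - 0.5 * logdet
        return float(-2.0 * ll.sum())


def _count_params(settings: EstimationSettings) -> int:
    p = len(settings.free_params)  # typical values
    p += len(settings.covariate_params)  # one oil coefficient each
    p += len([q for q in IIV_PARAMS])  # omegas
    p += len(IOV_PARAMS)  # gammas
    p += 2  # b1, b2
    return p


def _dataset_hash(ds: PKDataset) -> str:
    return f"{int(pd.util.hash_pandas_object(ds.df.fillna(-1)).sum()):x}"


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------


def fit_nlme(
    ds: PKDataset,
    init: PopulationModel | None = None,
    fixed: dict | None = None,
    settings: EstimationSettings | None = None,
    seed=None,
) -> FitResult:
    """Maximum-likelihood population fit with Fm fixed.

    ``fixed`` defaults to ``{"Fm": 0.75}``; requesting a fixed parameter in
    ``settings.free_params`` is an error.  Reproducible given ``seed``.
    """
    settings = settings or EstimationSettings()
    fixed = {"Fm": 0.75} if fixed is None else dict(fixed)
    for p in settings.free_params:
        if p in fixed:
            raise ValueError(f"parameter is fixed: {p}")
    fm = float(fixed.get("Fm", 0.75))

    prob = _Problem(ds)
    if init is None:
        init = nca_initial_values(ds, fm)
    if settings.screen_init:
        init = _screen_initial_values(prob, init, fm)
    rng = np.random.default_rng(seed)

    n_starts = max(settings.n_starts, 1)
    chains = [
        _Saem(prob, init, settings, child, fm) for child in rng.spawn(n_starts)
    ]
    for chain in chains:
        chain.run(settings.n_phase1, 0)
    if n_starts > 1:
        # keep the chain whose latent state explains the data best at the
        # end of exploration (mean complete log-likelihood, last 20 iters)
        scores = [
            float(
                pd.DataFrame(c.trace_rows)["complete_ll"].tail(20).mean()
            )
            for c in chains
        ]
        machine = chains[int(np.argmax(scores))]
    else:
        machine = chains[0]
    machine.run(0, settings.n_phase2)
    model = machine.population_model()
    trace = pd.DataFrame(machine.trace_rows)

    # convergence heuristic: drift of the typical values over the last
    # quarter of the SA phase, on the transformed scale
    tail = trace.iloc[-max(settings.n_phase2 // 4, 5) :]
    drift = 0.0
    for p in PARAM_NAMES:
        col = tail[f"mu_{p}"].to_numpy()
        drift = max(drift, float(np.ptp(col)))
    converged = bool(drift < 0.15)

    minus2ll = math.nan
    ebe_state = {}
    if settings.compute_ll:
        post = _JointPosterior(prob, model, settings, fm)
        z0 = np.concatenate(
            [machine.eta] + [machine.kappa[g.key] for g in prob.oral_groups], axis=1
        )
        zhat = post.modes(z0, maxiter=settings.ebe_maxiter)
        minus2ll = post.laplace_minus2ll(zhat)
        ebe_state = {"zhat": zhat, "posterior_dim": post.dim}

    n_par = _count_params(settings)
    aic = minus2ll + 2 * n_par
    bic = minus2ll + n_par * math.log(prob.n)
    se = _approx_se(model, prob)
    return FitResult(
        model=model,
        minus2ll=minus2ll,
        aic=aic,
        bic=bic,
        n_params=n_par,
        n_subjects=prob.n,
        converged=converged,
        trace=trace,
        se=se,
        algorithm=(
            "SAEM (Metropolis-within-Gibbs, closed-form M-step); "
            "marginal likelihood by Laplace approximation at the EBEs; "
            "BIC sample size = number of subjects"
        ),
        seed=seed,
        dataset_hash=_dataset_hash(ds),
        settings=settings,
    )


def compare_covariate_models(base: FitResult, extended: FitResult) -> dict:
    """Formulation-covariate retention decision by BIC.

    Returns ``delta_bic = BIC(base) - BIC(extended)`` and ``retain`` true
    when the reduction reaches 10; the likelihood-ratio statistic is
    reported alongside for nested pairs.
    """
    if base.dataset_hash != extended.dataset_hash:
        raise ValueError("fits were obtained on different datasets")
    delta = base.bic - extended.bic
    return {
        "delta_bic": float(delta),
        "retain": bool(delta >= 10.0),
        "lr_statistic": float(base.minus2ll - extended.minus2ll),
        "df": int(extended.n_params - base.n_params),
    }


def compute_ebes(ds: PKDataset, fit: FitResult):
    """Empirical Bayes estimates (conditional modes) and eta shrinkage.

    Returns ``(table, shrinkage)``: a per-subject parameter table and a dict
    of shrinkage percentages ``1 - sd(eta_hat)/omega`` (NaN where a
    parameter has no estimated IIV).  A subject with no observations keeps
    eta = 0, i.e. the typical value.
    """
    prob = _Problem(ds)
    model = fit.model
    post = _JointPosterior(prob, model, fit.settings, float(model.fixed.get("Fm", 0.75)))
    mu = post.mu
    z0 = np.tile(
        np.concatenate([mu] + [post.kmeans[g.key] for g in prob.oral_groups]),
        (prob.n, 1),
    )
    if fit.ebe_state.get("zhat") is not None and fit.ebe_state["zhat"].shape == z0.shape:
        z0 = fit.ebe_state["zhat"]
    zhat = post.modes(z0, maxiter=fit.settings.ebe_maxiter)
    eta_hat = zhat[:, :9] - mu

    rows = []
    for i, sid in enumerate(prob.subjects):
        row = {"ID": sid}
        for p in PARAM_NAMES:
            row[p] = float(PopulationModel.inverse_transform(p, zhat[i, _IDX[p]]))
            row[f"eta_{p}"] = float(eta_hat[i, _IDX[p]])
        rows.append(row)
    table = pd.DataFrame(rows)

    shrinkage = {}
    for p in PARAM_NAMES:
        om = model.omega(p) if p in IIV_PARAMS else 0.0
        if om <= 0:
            shrinkage[p] = math.nan
            continue
        sd = float(np.std(eta_hat[:, _IDX[p]], ddof=1)) if prob.n > 1 else 0.0
        shrinkage[p] = 100.0 * (1.0 - sd / om)
    return table, shrinkage


def bootstrap(
    ds: PKDataset,
    fit: FitResult,
    n_replicates: int = 200,
    seed=None,
    settings: EstimationSettings | None = None,
) -> dict:
    """Non-parametric bootstrap: subjects resampled with replacement, refit
    per replicate, percentile 95% CI per reported parameter.

    Non-converged replicates are counted and excluded.  Replicate fits reuse
    the point estimates as initial values and skip the Laplace likelihood.
    """
    if n_replicates < 2:
        raise ValueError("need n_replicates >= 2")
    rng = np.random.default_rng(seed)
    settings = settings or replace(fit.settings, compute_ll=False)
    subjects = PKDataset(ds.df).subjects
    rows = []
    n_failed = 0
    for r in range(n_replicates):
        pick = rng.choice(subjects, size=len(subjects), replace=True)
        sub = ds.subset(pick, renumber=True)
        try:
            res = fit_nlme(
                sub,
                init=fit.model,
                fixed=dict(fit.model.fixed),
                settings=settings,
                seed=rng.integers(2**31 - 1),
            )
        except ValueError:
            n_failed += 1
            continue
        if not res.converged:
            n_failed += 1
            continue
        rec = {f"typical_{p}": res.model.typical[p] for p in PARAM_NAMES}
        rec.update({"b1": res.model.b1, "b2": res.model.b2})
        for p, d in res.model.covariates.items():
            for c, v in d.items():
                rec[f"cov_{p}_{c}"] = v
        rows.append(rec)
    if not rows:
        raise ValueError("all bootstrap replicates failed")
    tab = pd.DataFrame(rows)
    ci = tab.quantile([0.025, 0.5, 0.975]).T
    ci.columns = ["ci_lower", "median", "ci_upper"]
    return {
        "n_replicates": n_replicates,
        "n_failed": n_failed,
        "replicates": tab,
        "ci": ci,
    }


def convergence_assessment(
    ds: PKDataset,
    init: PopulationModel,
    n_runs: int = 20,
    perturbation: float = 0.3,
    seed=None,
    settings: EstimationSettings | None = None,
) -> dict:
    """Refit from randomly perturbed initial values; dispersion of the final
    estimates measures the stability of the SAEM search."""
    if n_runs < 2:
        raise ValueError("need >= 2 runs")
    rng = np.random.default_rng(seed)
    settings = settings or EstimationSettings(compute_ll=False)
    rows = []
    for r in range(n_runs):
        typ = {}
        for p in PARAM_NAMES:
            phi = float(init.transform(p, init.typical[p]))
            phi += rng.uniform(-perturbation, perturbation)
            typ[p] = float(init.inverse_transform(p, phi))
        pert = PopulationModel(
            typical=typ,
            iiv_percent=dict(init.iiv_percent),
            iov_percent=dict(init.iov_percent),
            covariates={k: dict(v) for k, v in init.covariates.items()},
            b1=init.b1,
            b2=init.b2,
            fixed=dict(init.fixed),
        )
        res = fit_nlme(ds, init=pert, fixed=dict(init.fixed), settings=settings,
                       seed=rng.integers(2**31 - 1))
        rec = {f"typical_{p}": res.model.typical[p] for p in PARAM_NAMES}
        rec["converged"] = res.converged
        rows.append(rec)
    tab = pd.DataFrame(rows)
    cv = {}
    for p in PARAM_NAMES:
        v = tab[f"typical_{p}"].to_numpy()
        cv[p] = float(100.0 * np.std(v, ddof=1) / np.mean(v))
    return {"runs": tab, "cv_percent": cv}


def _approx_se(model: PopulationModel, prob: _Problem) -> dict:
    """First-order standard errors for the typical values.

    Between-subject information only (``omega/sqrt(n)`` on the transformed
    scale, delta-method back-transformed); a deliberate, documented
    approximation — the bootstrap is the reference uncertainty measure.
    """
    se = {}
    for p in PARAM_NAMES:
        om = model.omega(p)
        phi_se = (om if om > 0 else 0.1) / math.sqrt(prob.n)
        th = model.typical[p]
        if p == "F":
            se[p] = th * (1 - th) * phi_se
        else:
            se[p] = th * phi_se
    return se
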