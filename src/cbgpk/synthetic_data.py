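"""Synthetic crossover studies with the statistical structure the fit assumes.

The generator emulates the equine study design: each subject undergoes an IV
occasion (1 mg/kg infused over 5 min) and two oral occasions (10 mg/kg
micellar, 10 mg/kg oil) with complete washout, sampled at 0 (pre-dose),
5, 10, 15, 30, 45 min and 1, 2, 4, 6, 8, 12, 24, 36, 48, 72 h.  Body weights
are drawn from a truncated normal (451 +/- 49.4 kg); doses are per-kg so the
weight enters the dataset only as a covariate column.  Subject-level IIV,
occasion-level IOV, proportional residual error and LOQ censoring are all
applied exactly as the population model defines them, and the generating
("truth") parameters are returned separately so they can never leak into a
fitting table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population_model import (
    IOV_PARAMS,
    IIV_PARAMS,
    PopulationModel,
    apply_residual_error,
    realize_individual,
)
from .structural_model import (
    IV_INFUSION_H,
    DoseEvent,
    mg_per_kg_to_nmol_per_kg,
    solve_profile,
)

#: nominal sampling schedule of the study, h
STUDY_TIMES = (
    0.0,
    5 / 60,
    10 / 60,
    15 / 60,
    0.5,
    0.75,
    1.0,
    2.0,
    4.0,
    6.0,
    8.0,
    12.0,
    24.0,
    36.0,
    48.0,
    72.0,
)

#: dataset dialect columns (NONMEM-like long format)
COLUMNS = ("ID", "OCC", "TIME", "DVID", "DV", "AMT", "DUR", "FORM", "BW", "BLQ")


@dataclass(frozen=True)
class StudyDesign:
    """Crossover design: occasions, schedule, weights, LOQs."""

    n_subjects: int = 8
    bw_mean: float = 451.0
    bw_sd: float = 49.4
    #: (formulation, dose mg/kg, infusion duration h) per occasion;
    #: formulation "none" marks the IV occasion
    occasions: tuple = (
        ("none", 1.0, IV_INFUSION_H),
        ("micellar", 10.0, 0.0),
        ("oil", 10.0, 0.0),
    )
    sampling_times: tuple = STUDY_TIMES
    loq_parent: float = 0.0004
    loq_metabolite: float = 0.0008

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        t = np.asarray(self.sampling_times)
        if np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")
        if self.loq_parent < 0 or self.loq_metabolite < 0:
            raise ValueError("LOQs must be >= 0")


@dataclass
class PKDataset:
    """Long-format dosing-and-concentration table (one row per record).

    Columns: ID (subject), OCC (occasion), TIME (h), DVID (0 dose row,
    1 parent, 2 metabolite), DV (nmol/L, NaN on dose rows), AMT (nmol/kg,
    dose rows only), DUR (infusion h), FORM (micellar|oil|none), BW (kg),
    BLQ (0/1).
    """

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}")
        self.df = self.df.loc[:, list(COLUMNS)].reset_index(drop=True)
        self.validate()

    def validate(self):
        df = self.df
        if (df["TIME"] < 0).any():
            raise ValueError("negative TIME")
        obs = df[df["DVID"] > 0]
        if (obs["DV"].dropna() < 0).any():
            raise ValueError("negative observation")
        dose = df[df["DVID"] == 0]
        if dose["DV"].notna().any():
            bad = dose[dose["DV"].notna()].index[0]
            raise ValueError(f"DV present on dose row (row {bad})")
        for (sid, occ), grp in df.groupby(["ID", "OCC"]):
            d = grp[grp["DVID"] == 0]
            if len(d) != 1:
                raise ValueError(f"subject {sid} occasion {occ} needs exactly one dose row")
            if (grp[grp["DVID"] > 0]["TIME"] < d["TIME"].iloc[0]).any():
                raise ValueError(f"subject {sid} occasion {occ}: observation precedes the dose")

    # -- convenience accessors ---------------------------------------------

    @property
    def subjects(self):
        return sorted(self.df["ID"].unique())

    def observations(self, quantifiable_only: bool = True) -> pd.DataFrame:
        obs = self.df[self.df["DVID"] > 0]
        if quantifiable_only:
            obs = obs[(obs["BLQ"] == 0) & obs["DV"].notna()]
        return obs

    def n_quantifiable(self) -> int:
        return len(self.observations())

    def subset(self, subjects, renumber: bool = False) -> "PKDataset":
        """Rows for the given subjects; with ``renumber`` the (possibly
        repeated) selection is relabeled 1..k, as bootstrap resampling needs."""
        if not renumber:
            return PKDataset(self.df[self.df["ID"].isin(set(subjects))].copy())
        parts = []
        for new_id, sid in enumerate(subjects, start=1):
            part = self.df[self.df["ID"] == sid].copy()
            part["ID"] = new_id
            parts.append(part)
        return PKDataset(pd.concat(parts, ignore_index=True))


def _draw_weight(rng, mean, sd):
    while True:
        bw = rng.normal(mean, sd)
        if bw > 0:
            return float(bw)


def generate_study(pop: PopulationModel, design: StudyDesign | None = None, seed=None):
    """Simulate one full crossover study.

    Returns ``(dataset, truth)`` where ``truth`` is a dict with the
    population configuration and the per-subject-occasion generating
    parameters and random-effect draws (the sidecar content).  The same seed
    reproduces the dataset exactly.
    """
    design = design or StudyDesign()
    rng = np.random.default_rng(seed)
    times = np.asarray(design.sampling_times, dtype=float)
    post = times[times > 0]

    rows = []
    truth_rows = []
    for i in range(1, design.n_subjects + 1):
        bw = _draw_weight(rng, design.bw_mean, design.bw_sd)
        eta_iiv = {
            p: rng.normal(0.0, pop.omega(p)) if pop.omega(p) > 0 else 0.0 for p in IIV_PARAMS
        }
        for occ, (form, dose_mg, dur) in enumerate(design.occasions, start=1):
            oral = form != "none"
            if oral:
                eta_iov = {
                    p: rng.normal(0.0, pop.gamma(p)) if pop.gamma(p) > 0 else 0.0
                    for p in IOV_PARAMS
                }
                params = realize_individual(pop, form, eta_iiv, eta_iov)
            else:
                eta_iov = {}
                params = realize_individual(pop, "micellar", eta_iiv, {})
            amt = mg_per_kg_to_nmol_per_kg(dose_mg)
            ev = DoseEvent(
                0.0,
                "oral" if oral else "iv",
                amt,
                infusion_duration=0.0 if oral else dur,
                formulation=form if oral else "none",
            )
            curve = solve_profile(params, [ev], post)
            obs_p, obs_m = apply_residual_error(curve, pop.b1, pop.b2, rng)

            rows.append((i, occ, 0.0, 0, np.nan, amt, ev.infusion_duration, form, bw, 0))
            # pre-dose records are blank/BLOQ by construction
            rows.append((i, occ, 0.0, 1, 0.0, np.nan, 0.0, form, bw, 1))
            rows.append((i, occ, 0.0, 2, 0.0, np.nan, 0.0, form, bw, 1))
            for j, t in enumerate(post):
                rows.append((i, occ, t, 1, obs_p[j], np.nan, 0.0, form, bw, 0))
                rows.append((i, occ, t, 2, obs_m[j], np.nan, 0.0, form, bw, 0))

            rec = {"subject": i, "occasion": occ, "formulation": form, "bw": bw}
            rec.update({f"eta_iiv_{p}": v for p, v in eta_iiv.items()})
            rec.update({f"eta_iov_{p}": v for p, v in eta_iov.items()})
            rec.update(
                {
                    p: getattr(params, p)
                    for p in ("F", "ka", "beta", "Cl", "Vc", "Q", "Vp", "Fm", "Clm", "Vm")
                }
            )
            truth_rows.append(rec)

    df = pd.DataFrame(rows, columns=list(COLUMNS))
    ds = censor_loq(PKDataset(df), design.loq_parent, design.loq_metabolite)
    truth = {"population": pop.to_dict(), "individuals": truth_rows}
    return ds, truth


def censor_loq(ds: PKDataset, loq_parent: float, loq_metabolite: float) -> PKDataset:
    """Flag observations below the limit of quantification.

    Flagged rows stay in the table (with BLQ = 1) but are excluded from
    fitting.  A zero LOQ flags nothing beyond what is already flagged.
    """
    if loq_parent < 0 or loq_metabolite < 0:
        raise ValueError("LOQs must be >= 0")
    df = ds.df.copy()
    for dvid, loq in ((1, loq_parent), (2, loq_metabolite)):
        m = (df["DVID"] == dvid) & df["DV"].notna() & (df["DV"] < loq)
        df.loc[m, "BLQ"] = 1
    return PKDataset(df)
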