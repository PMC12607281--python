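"""Population layer: typical values, random effects, covariates, residual error.

Individual structural parameters arise from the typical values by
exponential (log-normal) perturbation,

    theta_i = theta_typ * exp(cov) * exp(eta_IIV) * exp(eta_IOV),

except the oral bioavailability F, which is logit-normal so that every
realized F stays in (0, 1).  Between-subject variability (IIV) is drawn once
per subject, between-occasion variability (IOV) independently per treatment
occasion, and the formulation category acts as an additive shift on the
transformed scale of ka and beta (micellar is the reference).  The
observation model is proportional: C_obs = C_pred (1 + b eps), eps ~ N(0,1),
with separate proportions for parent (b1) and metabolite (b2).

Variability magnitudes are configured as the percentages reported for the
fitted model; for log-normal parameters the percentage is read as a
coefficient of variation, ``omega = sqrt(ln(1 + (pct/100)^2))``, while for
the logit-scale F it is the standard deviation of eta itself divided by 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .structural_model import ConcentrationCurve, StructuralParams

#: canonical parameter order for the population model
PARAM_NAMES = ("F", "ka", "beta", "Cl", "Vc", "Q", "Vp", "Vm", "Clm")
#: parameters carrying inter-individual variability (Q has none)
IIV_PARAMS = ("F", "ka", "beta", "Cl", "Vc", "Vp", "Vm", "Clm")
#: parameters carrying inter-occasion variability (oral occasions only)
IOV_PARAMS = ("F", "ka", "beta")
#: known formulation categories; micellar is the reference
CATEGORIES = ("micellar", "oil")


def percent_to_sd(percent: float, transform: str = "log") -> float:
    """Variability percentage -> standard deviation on the transformed scale."""
    if percent < 0:
        raise ValueError("variability percentage must be >= 0")
    if transform == "log":
        return math.sqrt(math.log(1.0 + (percent / 100.0) ** 2))
    if transform == "logit":
        return percent / 100.0
    raise ValueError("transform must be 'log' or 'logit'")


def sd_to_percent(sd: float, transform: str = "log") -> float:
    """Inverse of :func:`percent_to_sd`, used when reporting fits."""
    if transform == "log":
        return 100.0 * math.sqrt(math.exp(sd * sd) - 1.0)
    if transform == "logit":
        return 100.0 * sd
    raise ValueError("transform must be 'log' or 'logit'")


def _logit(x):
    return np.log(x / (1.0 - x))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class PopulationModel:
    """Typical values plus the stochastic structure around them.

    ``covariates`` maps parameter name -> {category: additive coefficient on
    the transformed scale}; the reference category (micellar) is implicit.
    ``fixed`` holds constants that are never estimated (the metabolized
    fraction Fm).
    """

    typical: dict
    iiv_percent: dict = field(default_factory=dict)
    iov_percent: dict = field(default_factory=dict)
    covariates: dict = field(default_factory=dict)
    b1: float = 0.0
    b2: float = 0.0
    fixed: dict = field(default_factory=lambda: {"Fm": 0.75})

    def __post_init__(self):
        missing = [p for p in PARAM_NAMES if p not in self.typical]
        if missing:
            raise ValueError(f"typical values missing for {missing}")
        if self.b1 < 0 or self.b2 < 0:
            raise ValueError("residual proportions must be >= 0")
        for d in (self.iiv_percent, self.iov_percent):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative variability percentage for {k}")
        if not 0 <= self.fixed.get("Fm", 0.75) <= 1:
            raise ValueError("Fm must lie in [0, 1]")

    # -- transforms ---------------------------------------------------------

    @staticmethod
    def transform_name(param: str) -> str:
        return "logit" if param == "F" else "log"

    @staticmethod
    def transform(param: str, value):
        return _logit(np.asarray(value, dtype=float)) if param == "F" else np.log(value)

    @staticmethod
    def inverse_transform(param: str, value):
        return _expit(value) if param == "F" else np.exp(value)

    # -- variability accessors ---------------------------------------------

    def omega(self, param: str) -> float:
        """IIV standard deviation on the transformed scale (0 if absent)."""
        return percent_to_sd(self.iiv_percent.get(param, 0.0), self.transform_name(param))

    def gamma(self, param: str) -> float:
        """IOV standard deviation on the transformed scale (0 if absent)."""
        return percent_to_sd(self.iov_percent.get(param, 0.0), self.transform_name(param))

    def covariate_shift(self, param: str, category: str) -> float:
        if category not in CATEGORIES:
            raise ValueError(
                f"unknown formulation category {category!r}; known: {', '.join(CATEGORIES)}"
            )
        return self.covariates.get(param, {}).get(category, 0.0)

    def category_typical(self, param: str, category: str) -> float:
        """Typical value adjusted for the formulation category."""
        phi = float(self.transform(param, self.typical[param]))
        phi += self.covariate_shift(param, category)
        return float(self.inverse_transform(param, phi))

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "typical": dict(self.typical),
            "iiv_percent": dict(self.iiv_percent),
            "iov_percent": dict(self.iov_percent),
            "covariates": {k: dict(v) for k, v in self.covariates.items()},
            "residual_error": {"b1": self.b1, "b2": self.b2},
            "fixed": dict(self.fixed),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationModel":
        return cls(
            typical=dict(d["typical"]),
            iiv_percent=dict(d.get("iiv_percent", {})),
            iov_percent=dict(d.get("iov_percent", {})),
            covariates={k: dict(v) for k, v in d.get("covariates", {}).items()},
            b1=float(d.get("residual_error", {}).get("b1", 0.0)),
            b2=float(d.get("residual_error", {}).get("b2", 0.0)),
            fixed=dict(d.get("fixed", {"Fm": 0.75})),
        )


def published_model() -> PopulationModel:
    """The fitted equine CBG/CBG-G population model (final covariate model).

    Typical values and variability percentages as estimated on the eight-horse
    crossover study; the oil-category absorption coefficients are stored on
    the log scale relative to the micellar reference (0.31/0.99 for ka,
    0.70/1.59 for beta); Fm is fixed at 0.75.
    """
    return PopulationModel(
        typical={
            "F": 0.28,
            "ka": 0.99,
            "beta": 1.59,
            "Cl": 1.67,
            "Vc": 32.15,
            "Q": 154.5,
            "Vp": 36.12,
            "Vm": 0.0047,
            "Clm": 0.016,
        },
        iiv_percent={
            "F": 25.52,
            "ka": 46.64,
            "beta": 26.01,
            "Cl": 27.95,
            "Vc": 66.74,
            "Vp": 21.22,
            "Vm": 53.58,
            "Clm": 32.23,
        },
        iov_percent={"F": 13.93, "ka": 37.99, "beta": 12.8},
        covariates={
            "ka": {"oil": math.log(0.31 / 0.99)},
            "beta": {"oil": math.log(0.70 / 1.59)},
        },
        b1=0.29,
        b2=0.41,
    )


@dataclass
class IndividualRealization:
    """One subject-occasion draw and the structural parameters it implies."""

    subject: int
    occasion: int
    formulation: str
    eta_iiv: dict
    eta_iov: dict
    params: StructuralParams


def realize_individual(
    pop: PopulationModel,
    formulation: str = "micellar",
    eta_iiv: dict | None = None,
    eta_iov: dict | None = None,
) -> StructuralParams:
    """Map population parameters and random-effect draws to one individual.

    With all etas zero and the reference category, the result equals the
    category-adjusted typical values; Fm stays at its fixed value.
    """
    eta_iiv = eta_iiv or {}
    eta_iov = eta_iov or {}
    values = {}
    for p in PARAM_NAMES:
        phi = float(pop.transform(p, pop.typical[p]))
        phi += pop.covariate_shift(p, formulation)
        phi += float(eta_iiv.get(p, 0.0)) + float(eta_iov.get(p, 0.0))
        values[p] = float(pop.inverse_transform(p, phi))
    return StructuralParams(
        F=values["F"],
        ka=values["ka"],
        beta=values["beta"],
        Cl=values["Cl"],
        Vc=values["Vc"],
        Q=values["Q"],
        Vp=values["Vp"],
        Fm=float(pop.fixed.get("Fm", 0.75)),
        Clm=values["Clm"],
        Vm=values["Vm"],
    )


def sample_eta_arrays(pop: PopulationModel, n: int, rng, which: str = "iiv") -> dict:
    """Draw eta arrays (n,) per parameter; parameters without variability get 0."""
    out = {}
    params = IIV_PARAMS if which == "iiv" else IOV_PARAMS
    for p in params:
        sd = pop.omega(p) if which == "iiv" else pop.gamma(p)
        out[p] = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
    return out


def sample_parameter_arrays(
    pop: PopulationModel,
    n: int,
    formulation: str = "micellar",
    rng=None,
    eta_iiv: dict | None = None,
    eta_iov: dict | None = None,
    include_iov: bool = True,
) -> dict:
    """Vectorized individual-parameter draws for Monte Carlo work.

    Returns a dict of (n,) arrays for every structural parameter including
    the fixed Fm.  Supplying ``eta_iiv``/``eta_iov`` reuses existing draws
    (e.g. to correlate occasions within a subject).
    """
    rng = np.random.default_rng(rng)
    if eta_iiv is None:
        eta_iiv = sample_eta_arrays(pop, n, rng, "iiv")
    if eta_iov is None:
        eta_iov = sample_eta_arrays(pop, n, rng, "iov") if include_iov else {}
    out = {}
    for p in PARAM_NAMES:
        phi = float(pop.transform(p, pop.typical[p])) + pop.covariate_shift(p, formulation)
        phi = phi + eta_iiv.get(p, 0.0) + eta_iov.get(p, 0.0)
        out[p] = np.broadcast_to(np.asarray(pop.inverse_transform(p, phi), dtype=float), (n,)).copy()
    out["Fm"] = np.full(n, float(pop.fixed.get("Fm", 0.75)))
    return out


def sample_population(
    pop: PopulationModel,
    n: int,
    design=None,
    seed=None,
) -> list[IndividualRealization]:
    """Sample ``n`` subjects across a crossover design.

    ``design`` is a sequence of occasion formulations (default the study's
    three occasions: IV reference coded as micellar with no IOV, then the
    two oral formulations).  IIV is drawn once per subject, IOV
    independently per oral occasion; given the same seed the realization set
    is identical.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    if design is None:
        design = ["iv", "micellar", "oil"]
    realizations = []
    for i in range(n):
        eta_iiv = {
            p: rng.normal(0.0, pop.omega(p)) if pop.omega(p) > 0 else 0.0 for p in IIV_PARAMS
        }
        for occ, form in enumerate(design, start=1):
            if form == "iv":
                eta_iov = {}
                params = realize_individual(pop, "micellar", eta_iiv, eta_iov)
                # no depot on the IV occasion; F plays no role there
                realizations.append(
                    IndividualRealization(i + 1, occ, "none", dict(eta_iiv), {}, params)
                )
            else:
                eta_iov = {
                    p: rng.normal(0.0, pop.gamma(p)) if pop.gamma(p) > 0 else 0.0
                    for p in IOV_PARAMS
                }
                params = realize_individual(pop, form, eta_iiv, eta_iov)
                realizations.append(
                    IndividualRealization(i + 1, occ, form, dict(eta_iiv), eta_iov, params)
                )
    return realizations


def apply_residual_error(curve: ConcentrationCurve, b1: float, b2: float, rng=None):
    """Proportional observation noise per analyte, truncated at zero.

    Returns (observed parent, observed metabolite) arrays; a zero prediction
    stays zero regardless of the noise draw.
    """
    if b1 < 0 or b2 < 0:
        raise ValueError("residual proportions must be >= 0")
    rng = np.random.default_rng(rng)
    eps1 = rng.standard_normal(len(curve.times))
    eps2 = rng.standard_normal(len(curve.times))
    obs_p = np.maximum(curve.c_parent * (1.0 + b1 * eps1), 0.0)
    obs_m = np.maximum(curve.c_metabolite * (1.0 + b2 * eps2), 0.0)
    return obs_p, obs_m
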