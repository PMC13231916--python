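"""Population layer: inter-individual variability, CYP2C19 covariate, residual error.

Random effects are log-normal (additive on the log scale) with a diagonal
omega matrix on V, CL1, CL2 and Tswitch.  The CYP2C19 covariate is a
proportional shift of the late intrinsic clearance: carriers of
reduced-function alleles (intermediate and poor metabolizers) have
CL2 multiplied by ``exp(beta_geno)``.  Residual error is combined
additive + proportional:  y = f * (1 + eps_p) + eps_a.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace as _dc_replace
from importlib import resources

import numpy as np
import yaml

from .model_core import StructuralParams

__all__ = [
    "GENOTYPE_CLASSES",
    "REDUCED_FUNCTION",
    "STUDY_GENOTYPE_COUNTS",
    "PopulationParams",
    "PatientCovariates",
    "IndividualEffects",
    "default_population",
    "load_population_yaml",
    "individual_params",
    "sample_effects",
    "sample_genotypes",
    "apply_residual_error",
    "cv_from_omega",
    "omega_from_cv",
]

#: CYP2C19 metabolizer classes: normal, intermediate, rapid, poor, ultrarapid.
GENOTYPE_CLASSES = ("NM", "IM", "RM", "PM", "UM")

#: Classes carrying reduced-function alleles; these receive the CL2 shift.
REDUCED_FUNCTION = frozenset({"IM", "PM"})

#: Metabolizer counts observed in the 31-patient cohort (NM, IM, RM, PM, UM).
STUDY_GENOTYPE_COUNTS = {"NM": 12, "IM": 12, "RM": 5, "PM": 1, "UM": 1}

#: Random-effect names, in canonical order.
ETA_NAMES = ("V", "CL1", "CL2", "Tswitch")


def cv_from_omega(omega):
    """Percent CV of a log-normal variate: sqrt(exp(omega^2) - 1) * 100."""
    omega = np.asarray(omega, dtype=float)
    if np.any(omega < 0):
        raise ValueError("omega must be >= 0")
    return np.sqrt(np.expm1(omega ** 2)) * 100.0


def omega_from_cv(cv_percent):
    """Inverse of :func:`cv_from_omega`: omega = sqrt(ln(1 + (cv/100)^2))."""
    cv = np.asarray(cv_percent, dtype=float)
    if np.any(cv < 0):
        raise ValueError("cv must be >= 0")
    return np.sqrt(np.log1p((cv / 100.0) ** 2))


@dataclass(frozen=True)
class PopulationParams:
    """Fixed effects, IIV standard deviations, covariate and error parameters."""

    theta: StructuralParams
    omega_V: float = 0.0
    omega_CL1: float = 0.0
    omega_CL2: float = 0.0
    omega_Tswitch: float = 0.0
    beta_geno: float = 0.0
    sigma_add: float = 0.0
    sigma_prop: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega_V", "omega_CL1", "omega_CL2", "omega_Tswitch",
                     "sigma_add", "sigma_prop"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def omegas(self) -> np.ndarray:
        return np.array([self.omega_V, self.omega_CL1, self.omega_CL2,
                         self.omega_Tswitch])

    def replace(self, **kwargs) -> "PopulationParams":
        return _dc_replace(self, **kwargs)


@dataclass(frozen=True)
class PatientCovariates:
    weight: float
    genotype_class: str = "NM"
    height: float | None = None  # cm
    sex: str | None = None       # "M" / "F"

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if self.genotype_class not in GENOTYPE_CLASSES:
            raise ValueError(
                f"unknown genotype class {self.genotype_class!r}; "
                f"valid levels: {', '.join(GENOTYPE_CLASSES)}")

    @property
    def reduced_function(self) -> bool:
        return self.genotype_class in REDUCED_FUNCTION


@dataclass(frozen=True)
class IndividualEffects:
    """Log-scale random effects (eta) on V, CL1, CL2 and Tswitch."""

    eta_V: float = 0.0
    eta_CL1: float = 0.0
    eta_CL2: float = 0.0
    eta_Tswitch: float = 0.0

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.as_array())):
            raise ValueError("random effects must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.eta_V, self.eta_CL1, self.eta_CL2,
                         self.eta_Tswitch])

    @classmethod
    def from_array(cls, eta) -> "IndividualEffects":
        eta = np.asarray(eta, dtype=float)
        return cls(*eta.tolist())


def _as_population(payload: dict) -> PopulationParams:
    theta = StructuralParams(**payload["theta"])
    cv = payload.get("iiv_cv_percent", {})
    omegas = {f"omega_{k}": float(omega_from_cv(v)) for k, v in cv.items()}
    return PopulationParams(
        theta=theta,
        beta_geno=payload.get("beta_geno", 0.0),
        sigma_add=payload.get("sigma_add", 0.0),
        sigma_prop=payload.get("sigma_prop", 0.0),
        **omegas,
    )


def load_population_yaml(path) -> PopulationParams:
    """Read a population parameter file (same layout as the packaged defaults)."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return _as_population(payload)


def default_population() -> PopulationParams:
    """The published final-model estimates shipped with the package."""
    ref = resources.files("voripk.data") / "published_model.yaml"
    payload = yaml.safe_load(ref.read_text())
    return _as_population(payload)


def published_metadata() -> dict:
    """Raw payload of the packaged parameter file (RSEs, shrinkage, %CVs)."""
    ref = resources.files("voripk.data") / "published_model.yaml"
    return yaml.safe_load(ref.read_text())


def individual_params(pop: PopulationParams, cov: PatientCovariates,
                      eta: IndividualEffects) -> StructuralParams:
    """Individual structural parameters from typical values, covariates and etas.

    V_i = theta_V * exp(eta_V), similarly CL1 and Tswitch;
    CL2_i = theta_CL2 * exp(beta * 1[IM or PM]) * exp(eta_CL2).
    k, CLseq0 and Thalf_seq carry no IIV.
    """
    th = pop.theta
    geno_mult = math.exp(pop.beta_geno) if cov.reduced_function else 1.0
    return StructuralParams(
        V=th.V * math.exp(eta.eta_V),
        CL1=th.CL1 * math.exp(eta.eta_CL1),
        CL2=th.CL2 * geno_mult * math.exp(eta.eta_CL2),
        Tswitch=th.Tswitch * math.exp(eta.eta_Tswitch),
        k=th.k,
        CLseq0=th.CLseq0,
        Thalf_seq=th.Thalf_seq,
    )


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_effects_array(pop: PopulationParams, n: int, seed=None) -> np.ndarray:
    """n independent eta vectors, shape (n, 4), each component N(0, omega^2)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    return rng.standard_normal((int(n), 4)) * pop.omegas[None, :]


def sample_effects(pop: PopulationParams, n: int, seed=None) -> list[IndividualEffects]:
    """As :func:`sample_effects_array`, wrapped as IndividualEffects objects."""
    arr = sample_effects_array(pop, n, seed)
    return [IndividualEffects.from_array(row) for row in arr]


def sample_genotypes(n: int, seed=None, frequencies=None,
                     exact_counts: bool = False) -> list[str]:
    """Sample CYP2C19 metabolizer classes.

    By default draws from the cohort frequencies (12/31 NM, 12/31 IM,
    5/31 RM, 1/31 PM, 1/31 UM).  ``exact_counts=True`` with n = 31
    reproduces the cohort composition exactly (and proportionally rounds
    for other n, largest-remainder method), shuffled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    counts = np.array([STUDY_GENOTYPE_COUNTS[g] for g in GENOTYPE_CLASSES],
                      dtype=float)
    if frequencies is None:
        freqs = counts / counts.sum()
    else:
        freqs = np.asarray([frequencies[g] for g in GENOTYPE_CLASSES], dtype=float)
        if np.any(freqs < 0) or not math.isclose(freqs.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("frequencies must be >= 0 and sum to 1")
    if exact_counts:
        ideal = freqs * n
        alloc = np.floor(ideal).astype(int)
        rem = ideal - alloc
        for idx in np.argsort(-rem)[: n - alloc.sum()]:
            alloc[idx] += 1
        labels = np.repeat(np.array(GENOTYPE_CLASSES), alloc)
        rng.shuffle(labels)
        return labels.tolist()
    draws = rng.choice(len(GENOTYPE_CLASSES), size=n, p=freqs)
    return [GENOTYPE_CLASSES[i] for i in draws]


def apply_residual_error(true_conc, pop: PopulationParams, seed=None):
    """Combined residual error y = f*(1+eps_p) + eps_a, floored at zero.

    Returns ``(observed, floored)`` where ``floored`` flags draws that were
    negative before flooring.
    """
    f = np.asarray(true_conc, dtype=float)
    if np.any(f < 0):
        raise ValueError("true concentrations must be >= 0")
    rng = _rng(seed)
    eps_p = rng.standard_normal(f.shape) * pop.sigma_prop
    eps_a = rng.standard_normal(f.shape) * pop.sigma_add
    y = f * (1.0 + eps_p) + eps_a
    floored = y < 0
    return np.where(floored, 0.0, y), floored
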