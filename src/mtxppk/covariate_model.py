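"""Covariate and variability model mapping subjects to PK parameters.

Typical (population) parameter values are products of a base value and
one multiplicative factor per covariate: continuous covariates enter as
powers of their median-normalized value, the bleomycin co-medication
flag enters on the log scale as ``exp(coef * flag)``.  Individual
parameters multiply the typical value by ``exp(eta)`` with
``eta ~ N(0, omega^2)``.  Residual error supports additive,
proportional and combined forms.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import yaml

from .structural_pk import PKParameters

__all__ = [
    "CovariateRecord",
    "ReferenceMedians",
    "FixedEffects",
    "RandomEffects",
    "ErrorModel",
    "typical_cl",
    "typical_vc",
    "individual_params",
    "apply_error",
    "sample_error",
    "load_config",
    "load_default_config",
]


@dataclass(frozen=True)
class CovariateRecord:
    """One subject's model covariates.

    egfr in mL/min/1.73 m², bw in kg, tbil in μmol/L, alb in g/L,
    blm ∈ {0, 1} (bleomycin co-medication).
    """

    egfr: float
    bw: float
    tbil: float
    alb: float
    blm: int = 0

    def __post_init__(self) -> None:
        for name in ("egfr", "bw", "tbil", "alb"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (got {getattr(self, name)})")
        if self.blm not in (0, 1):
            raise ValueError(f"blm must be 0 or 1 (got {self.blm})")


@dataclass(frozen=True)
class ReferenceMedians:
    """Population medians used to standardize continuous covariates."""

    egfr: float = 102.2
    bw: float = 47.0
    tbil: float = 15.3
    alb: float = 40.9

    def as_dict(self) -> dict:
        return {"egfr": self.egfr, "bw": self.bw, "tbil": self.tbil, "alb": self.alb}


@dataclass(frozen=True)
class FixedEffects:
    """Fixed-effect coefficients of the final covariate model.

    Defaults are the final-model estimates: typical CL 12.88 L/h and Vc
    72.04 L, power exponents on median-normalized eGFR/BW/TBIL/ALB, a
    log-scale bleomycin shift of 0.08, and Q/Vp fixed at 1.08 L/h and
    94.94 L.
    """

    theta_cl: float = 12.88
    theta_vc: float = 72.04
    beta_egfr_cl: float = 0.23
    beta_bw_cl: float = 0.39
    beta_tbil_cl: float = -0.05
    beta_alb_cl: float = -0.18
    beta_blm_cl: float = 0.08
    beta_bw_vc: float = 0.31
    q_fixed: float = 1.08
    vp_fixed: float = 94.94

    def __post_init__(self) -> None:
        for name in ("theta_cl", "theta_vc", "q_fixed", "vp_fixed"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive (got {getattr(self, name)})")

    def with_(self, **kwargs) -> "FixedEffects":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RandomEffects:
    """Log-scale inter-individual deviations and their SDs.

    ``eta_cl``/``eta_vc`` are one subject's deviations; ``omega_cl`` /
    ``omega_vc`` are the population SDs.  The default ω values are the
    package's interpretation of the reported IIV magnitudes (stored as
    log-scale SDs), user-settable.
    """

    eta_cl: float = 0.0
    eta_vc: float = 0.0
    omega_cl: float = 0.30
    omega_vc: float = 0.32

    def __post_init__(self) -> None:
        if self.omega_cl < 0 or self.omega_vc < 0:
            raise ValueError("omega values must be non-negative")


@dataclass(frozen=True)
class ErrorModel:
    """Residual (within-subject) error model.

    kind ∈ {additive, proportional, combined}; the final-model default is
    proportional with σ = 0.37.
    """

    kind: str = "proportional"
    sigma_add: float = 0.0
    sigma_prop: float = 0.37
    #: lower truncation for proportional ε draws, keeping 1 + ε > 0 so
    #: simulated concentrations cannot flip sign; configurable.
    eps_floor: float = -0.999

    def __post_init__(self) -> None:
        if self.kind not in ("additive", "proportional", "combined"):
            raise ValueError(f"unknown error-model kind {self.kind!r}")
        if self.sigma_add < 0 or self.sigma_prop < 0:
            raise ValueError("sigma values must be non-negative")

    def variance(self, pred):
        """Residual variance at a (conditional) prediction."""
        pred = np.asarray(pred, dtype=float)
        if self.kind == "additive":
            return np.full_like(pred, self.sigma_add**2)
        if self.kind == "proportional":
            return (self.sigma_prop * pred) ** 2
        return self.sigma_add**2 + (self.sigma_prop * pred) ** 2


def typical_cl(
    cov: CovariateRecord,
    fe: FixedEffects = FixedEffects(),
    ref: ReferenceMedians = ReferenceMedians(),
) -> float:
    """Typical clearance (L/h) of a subject with covariates ``cov``.

    ``CL = θ_cl · (eGFR/ref)^β_egfr · (BW/ref)^β_bw · e^(BLM·β_blm)
          · (TBIL/ref)^β_tbil · (ALB/ref)^β_alb``
    """
    return float(
        fe.theta_cl
        * (cov.egfr / ref.egfr) ** fe.beta_egfr_cl
        * (cov.bw / ref.bw) ** fe.beta_bw_cl
        * np.exp(cov.blm * fe.beta_blm_cl)
        * (cov.tbil / ref.tbil) ** fe.beta_tbil_cl
        * (cov.alb / ref.alb) ** fe.beta_alb_cl
    )


def typical_vc(
    cov: CovariateRecord,
    fe: FixedEffects = FixedEffects(),
    ref: ReferenceMedians = ReferenceMedians(),
) -> float:
    """Typical central volume (L): ``Vc = θ_vc · (BW/ref)^β_bw_vc``."""
    return float(fe.theta_vc * (cov.bw / ref.bw) ** fe.beta_bw_vc)


def individual_params(
    cov: CovariateRecord,
    fe: FixedEffects = FixedEffects(),
    eta: RandomEffects = RandomEffects(),
    ref: ReferenceMedians = ReferenceMedians(),
) -> PKParameters:
    """Individual PK parameters: typical values scaled by ``exp(eta)``.

    Q and Vp carry no inter-individual variability (fixed in the final
    model) and equal their population values.
    """
    return PKParameters(
        cl=typical_cl(cov, fe, ref) * float(np.exp(eta.eta_cl)),
        vc=typical_vc(cov, fe, ref) * float(np.exp(eta.eta_vc)),
        q=fe.q_fixed,
        vp=fe.vp_fixed,
    )


def apply_error(pred, err: ErrorModel, eps1, eps2=0.0):
    """Map a predicted concentration and residual draw(s) to an observation.

    additive: ``pred + ε1``; proportional: ``pred·(1 + ε1)``;
    combined: ``pred·(1 + ε1) + ε2``.
    """
    pred = np.asarray(pred, dtype=float)
    if np.any(pred < 0):
        raise ValueError("predicted concentrations must be non-negative")
    if err.kind == "additive":
        return pred + eps1
    if err.kind == "proportional":
        return pred * (1.0 + np.asarray(eps1))
    return pred * (1.0 + np.asarray(eps1)) + eps2


def sample_error(pred, err: ErrorModel, rng: np.random.Generator):
    """Draw observed concentrations from the residual-error model.

    Proportional ε draws are truncated below at ``err.eps_floor`` so a
    simulated concentration cannot become negative through the
    multiplicative component; additive noise is left untruncated (the
    estimation likelihood, not truncation, handles negative values).
    """
    pred = np.asarray(pred, dtype=float)
    if err.kind == "additive":
        return pred + rng.normal(0.0, err.sigma_add, size=pred.shape)
    eps1 = rng.normal(0.0, err.sigma_prop, size=pred.shape)
    eps1 = np.maximum(eps1, err.eps_floor)
    if err.kind == "proportional":
        return pred * (1.0 + eps1)
    return pred * (1.0 + eps1) + rng.normal(0.0, err.sigma_add, size=pred.shape)


# ---------------------------------------------------------------------------
# configuration


def _config_from_mapping(raw: dict) -> dict:
    fe = FixedEffects(**raw.get("fixed_effects", {}))
    iiv = raw.get("iiv", {})
    err_raw = dict(raw.get("error", {}))
    err = ErrorModel(**err_raw)
    ref = ReferenceMedians(**raw.get("reference_medians", {}))
    return {
        "fixed_effects": fe,
        "omega_cl": float(iiv.get("omega_cl", 0.30)),
        "omega_vc": float(iiv.get("omega_vc", 0.32)),
        "error": err,
        "reference_medians": ref,
        "molar_mass_g_per_mol": float(raw.get("molar_mass_g_per_mol", 454.44)),
    }


def load_config(path) -> dict:
    """Load fixed-effect / IIV / error / reference defaults from YAML."""
    with open(Path(path), "r") as fh:
        raw = yaml.safe_load(fh)
    return _config_from_mapping(raw or {})


def load_default_config() -> dict:
    """The shipped default configuration (final-model estimates)."""
    text = importlib.resources.files("mtxppk").joinpath("defaults.yaml").read_text()
    return _config_from_mapping(yaml.safe_load(text))
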