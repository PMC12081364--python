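"""Nonlinear mixed-effects estimation for the infusion PK model.

The marginal likelihood of each subject is approximated FOCE-style: the
subject's random effects are optimized to their conditional mode (a
damped Gauss-Newton inner search, vectorized across all subjects), and
the Laplace/Gauss-Newton curvature correction is added, with the
residual variance evaluated at the conditional prediction (interaction).
The objective function value (OFV) is −2 × the approximate log marginal
likelihood, the scale on which likelihood-ratio ΔOFV tests and AIC/BIC
operate.

Estimated parameters are kept positive through a log transform during
the outer quasi-Newton search; standard errors come from the inverse of
the numerically differentiated Hessian of the OFV at the optimum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .covariate_model import ErrorModel, ReferenceMedians
from .structural_pk import conc_at_times, conc_at_times_mammillary, hybrid_exponents_mammillary

__all__ = [
    "DATASET_COLUMNS",
    "DatasetError",
    "EventDataset",
    "read_dataset",
    "write_dataset",
    "CovariateEffect",
    "ParamSpec",
    "ModelSpec",
    "base_model_spec",
    "final_model_spec",
    "FitResult",
    "predict",
    "ofv",
    "fit",
    "information_criteria",
    "cwres",
    "simulate_observations",
]

DATASET_COLUMNS = ["ID", "TIME", "EVID", "AMT", "DUR", "DV", "BQL",
                   "EGFR", "BW", "TBIL", "ALB", "BLM"]

_COV_COLUMNS = {"egfr": "EGFR", "bw": "BW", "tbil": "TBIL", "alb": "ALB", "blm": "BLM"}

_VAR_FLOOR = 1.0e-30  # guards log(σ²) when a predicted concentration is ~0

_LS_LADDER = 0.5 ** np.arange(11)  # backtracking scales for the inner search


class DatasetError(ValueError):
    """Raised when an event-record table violates the dialect contract."""


# ---------------------------------------------------------------------------
# event-record dataset


class EventDataset:
    """Event-record table (dose + observation rows) compiled for estimation.

    The canonical on-disk dialect is a flat CSV with header
    ``ID,TIME,EVID,AMT,DUR,DV,BQL,EGFR,BW,TBIL,ALB,BLM``: EVID 1 rows are
    infusion doses (AMT in μmol over DUR hours), EVID 0 rows are
    observations (DV in μmol/L, BQL flags values below the quantitation
    limit), and empty cells mean "not applicable".  Covariates are
    carried per subject.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)
        self._compile()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, validate: bool = True) -> "EventDataset":
        df = df.copy()
        missing = [c for c in DATASET_COLUMNS if c not in df.columns]
        if missing:
            raise DatasetError(f"missing required columns: {missing}")
        df = df[DATASET_COLUMNS]
        if validate:
            _validate_events(df)
        df = df.sort_values(["ID", "TIME", "EVID"], ascending=[True, True, False],
                            kind="stable").reset_index(drop=True)
        return cls(df)

    def _compile(self) -> None:
        df = self.df
        self.subject_ids = np.asarray(sorted(df["ID"].unique()))
        index = {sid: i for i, sid in enumerate(self.subject_ids)}
        self.n_subjects = len(self.subject_ids)

        obs = df[df["EVID"] == 0]
        self.obs_rows = obs.index.to_numpy()
        self.obs_time = obs["TIME"].to_numpy(dtype=float)
        self.obs_y = obs["DV"].to_numpy(dtype=float)
        self.obs_bql = obs["BQL"].fillna(0).to_numpy(dtype=int)
        self.obs_sidx = np.asarray([index[s] for s in obs["ID"]])
        self.n_obs = len(obs)

        doses = df[df["EVID"] == 1]
        kmax = max((doses.groupby("ID").size().max() if len(doses) else 1), 1)
        seg_start = np.zeros((self.n_subjects, kmax))
        seg_dur = np.ones((self.n_subjects, kmax))
        seg_rate = np.zeros((self.n_subjects, kmax))
        counts = np.zeros(self.n_subjects, dtype=int)
        for sid, t, amt, dur in zip(doses["ID"], doses["TIME"],
                                    doses["AMT"], doses["DUR"]):
            i = index[sid]
            k = counts[i]
            seg_start[i, k] = t
            seg_dur[i, k] = dur
            seg_rate[i, k] = amt / dur
            counts[i] += 1
        self.seg_start, self.seg_dur, self.seg_rate = seg_start, seg_dur, seg_rate

        cov = {}
        first = df.groupby("ID", sort=True).first()
        for name, col in _COV_COLUMNS.items():
            cov[name] = first[col].to_numpy(dtype=float)
        self.covariates = cov

    # -- convenience -------------------------------------------------------

    def observations(self) -> pd.DataFrame:
        return self.df[self.df["EVID"] == 0].copy()

    def subset_subjects(self, ids: Sequence, relabel: bool = True) -> "EventDataset":
        """Dataset restricted to ``ids`` (with repetition — bootstrap resampling).

        Repeated draws of the same subject are relabeled as distinct
        subjects so the hierarchical structure is preserved.
        """
        frames = []
        for new_id, sid in enumerate(ids, start=1):
            block = self.df[self.df["ID"] == sid].copy()
            if relabel:
                block["ID"] = new_id
            frames.append(block)
        return EventDataset.from_dataframe(pd.concat(frames, ignore_index=True),
                                           validate=False)


def _validate_events(df: pd.DataFrame) -> None:
    errors = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        evid = row.EVID
        if evid not in (0, 1):
            errors.append(f"row {row_no}: EVID must be 0 or 1 (got {evid})")
            continue
        if not np.isfinite(row.TIME) or row.TIME < 0:
            errors.append(f"row {row_no}: TIME must be a non-negative number")
        if evid == 1:
            if not (np.isfinite(row.AMT) and row.AMT > 0):
                errors.append(f"row {row_no}: dose row needs AMT > 0")
            if not (np.isfinite(row.DUR) and row.DUR > 0):
                errors.append(f"row {row_no}: dose row needs DUR > 0")
            if np.isfinite(row.DV):
                errors.append(f"row {row_no}: dose row must not carry DV")
        else:
            if not np.isfinite(row.DV):
                errors.append(f"row {row_no}: observation row needs DV")
            if np.isfinite(row.AMT):
                errors.append(f"row {row_no}: observation row must not carry AMT")
        for cov in ("EGFR", "BW", "TBIL", "ALB"):
            v = getattr(row, cov)
            if not (np.isfinite(v) and v > 0):
                errors.append(f"row {row_no}: {cov} must be positive")
        if row.BLM not in (0, 1):
            errors.append(f"row {row_no}: BLM must be 0 or 1")
    for sid, block in df.groupby("ID"):
        t = block["TIME"].to_numpy()
        if np.any(np.diff(t) < 0):
            errors.append(f"subject {sid}: TIME not sorted")
    if errors:
        raise DatasetError("; ".join(errors[:20]) +
                           (f" (+{len(errors) - 20} more)" if len(errors) > 20 else ""))


def read_dataset(path) -> EventDataset:
    """Read and validate an event-record CSV (strict dialect)."""
    df = pd.read_csv(path)
    return EventDataset.from_dataframe(df, validate=True)


def write_dataset(dataset, path) -> None:
    """Write an event-record table in the canonical CSV dialect."""
    df = dataset.df if isinstance(dataset, EventDataset) else dataset
    df.to_csv(path, index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class ParamSpec:
    init: float
    fixed: bool = False


@dataclass(frozen=True)
class CovariateEffect:
    """One covariate-parameter relation in the model.

    ``form`` is "power" (median-normalized power) for continuous
    covariates or "exp" (log-scale shift of an indicator) for binary
    ones.
    """

    param: str
    cov: str
    form: str
    init: float = 0.1
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.form not in ("power", "exp"):
            raise ValueError(f"unknown covariate form {self.form!r}")

    @property
    def name(self) -> str:
        return f"beta_{self.cov}_{self.param}"


_STRUCTURAL_NAMES = {1: ("cl", "vc"), 2: ("cl", "vc", "q", "vp"),
                     3: ("cl", "vc", "q", "vp", "q2", "vp2")}


@dataclass(frozen=True)
class ModelSpec:
    """Structural + covariate + variability model for one fit."""

    n_compartments: int = 2
    structural: tuple = ()          # ((name, ParamSpec), ...)
    covariates: tuple = ()          # CovariateEffect, ...
    iiv: tuple = ()                 # ((param, ParamSpec for omega), ...)
    error_kind: str = "proportional"
    sigma: tuple = ()               # (("prop"|"add", ParamSpec), ...)
    refs: ReferenceMedians = ReferenceMedians()

    def __post_init__(self) -> None:
        names = _STRUCTURAL_NAMES.get(self.n_compartments)
        if names is None:
            raise ValueError("n_compartments must be 1, 2 or 3")
        have = tuple(n for n, _ in self.structural)
        if have != names:
            raise ValueError(f"structural parameters must be {names} (got {have})")
        estimated = (any(not ps.fixed for _, ps in self.structural)
                     or any(not e.fixed for e in self.covariates)
                     or any(not ps.fixed for _, ps in self.iiv)
                     or any(not ps.fixed for _, ps in self.sigma))
        if not estimated:
            raise ValueError("at least one parameter must be estimated")
        for eff in self.covariates:
            if eff.cov not in _COV_COLUMNS:
                raise ValueError(f"unknown covariate {eff.cov!r}")

    # -- manipulation helpers (used by stepwise search) --------------------

    def with_covariate(self, eff: CovariateEffect) -> "ModelSpec":
        if any(e.param == eff.param and e.cov == eff.cov for e in self.covariates):
            raise ValueError(f"{eff.name} already in model")
        return replace(self, covariates=self.covariates + (eff,))

    def without_covariate(self, param: str, cov: str) -> "ModelSpec":
        kept = tuple(e for e in self.covariates
                     if not (e.param == param and e.cov == cov))
        if len(kept) == len(self.covariates):
            raise ValueError(f"beta_{cov}_{param} not in model")
        return replace(self, covariates=kept)

    def with_inits(self, estimates: dict) -> "ModelSpec":
        """Spec with initial values replaced by ``estimates`` (warm start)."""
        structural = tuple(
            (n, ParamSpec(float(estimates.get(n, ps.init)), ps.fixed))
            for n, ps in self.structural)
        covariates = tuple(
            replace(e, init=float(estimates.get(e.name, e.init)))
            for e in self.covariates)
        iiv = tuple(
            (p, ParamSpec(max(float(estimates.get(f"omega_{p}", ps.init)), 1e-3),
                          ps.fixed))
            for p, ps in self.iiv)
        sigma = tuple(
            (k, ParamSpec(float(estimates.get(f"sigma_{k}", ps.init)), ps.fixed))
            for k, ps in self.sigma)
        return replace(self, structural=structural, covariates=covariates,
                       iiv=iiv, sigma=sigma)

    def param_names(self) -> list:
        names = [n for n, _ in self.structural]
        names += [e.name for e in self.covariates]
        names += [f"omega_{p}" for p, _ in self.iiv]
        names += [f"sigma_{k}" for k, _ in self.sigma]
        return names

    def initial_estimates(self) -> dict:
        out = {n: ps.init for n, ps in self.structural}
        out.update({e.name: e.init for e in self.covariates})
        out.update({f"omega_{p}": ps.init for p, ps in self.iiv})
        out.update({f"sigma_{k}": ps.init for k, ps in self.sigma})
        return out


def base_model_spec(
    n_compartments: int = 2,
    error_kind: str = "proportional",
    cl_init: float = 10.0,
    vc_init: float = 50.0,
    q_init: float = 1.08,
    vp_init: float = 94.94,
    fix_q_vp: bool = True,
    omega_init: float = 0.3,
    sigma_init: float = 0.3,
    refs: ReferenceMedians = ReferenceMedians(),
) -> ModelSpec:
    """Covariate-free structural model with IIV on CL and Vc."""
    names = _STRUCTURAL_NAMES[n_compartments]
    inits = {"cl": ParamSpec(cl_init), "vc": ParamSpec(vc_init),
             "q": ParamSpec(q_init, fixed=fix_q_vp),
             "vp": ParamSpec(vp_init, fixed=fix_q_vp),
             "q2": ParamSpec(0.5, fixed=False), "vp2": ParamSpec(50.0, fixed=False)}
    structural = tuple((n, inits[n]) for n in names)
    sigma = (("prop", ParamSpec(sigma_init)),) if error_kind == "proportional" else (
        (("add", ParamSpec(sigma_init)),) if error_kind == "additive" else
        (("prop", ParamSpec(sigma_init)), ("add", ParamSpec(sigma_init))))
    return ModelSpec(
        n_compartments=n_compartments,
        structural=structural,
        covariates=(),
        iiv=(("cl", ParamSpec(omega_init)), ("vc", ParamSpec(omega_init))),
        error_kind=error_kind,
        sigma=sigma,
        refs=refs,
    )


FINAL_MODEL_COVARIATES = (
    CovariateEffect("cl", "egfr", "power", init=0.1),
    CovariateEffect("cl", "bw", "power", init=0.1),
    CovariateEffect("vc", "bw", "power", init=0.1),
    CovariateEffect("cl", "blm", "exp", init=0.0),
    CovariateEffect("cl", "tbil", "power", init=0.0),
    CovariateEffect("cl", "alb", "power", init=0.0),
)


def final_model_spec(
    refs: ReferenceMedians = ReferenceMedians(),
    **base_kwargs,
) -> ModelSpec:
    """The published final model structure: two compartments, Q/Vp fixed,
    eGFR/BW/BLM/TBIL/ALB on CL and BW on Vc, proportional error."""
    spec = base_model_spec(refs=refs, **base_kwargs)
    return replace(spec, covariates=FINAL_MODEL_COVARIATES)


# ---------------------------------------------------------------------------
# compiled model: estimates -> predictions


class _CompiledModel:
    def __init__(self, spec: ModelSpec, dataset: EventDataset):
        self.spec = spec
        self.ds = dataset
        for eff in spec.covariates:
            if eff.cov not in dataset.covariates:
                raise DatasetError(f"covariate {eff.cov!r} absent from dataset")
        self.iiv_params = [p for p, ps in spec.iiv if ps.init > 0 or not ps.fixed]
        self.q_eta = len(self.iiv_params)
        # numerical guard: tiny additive variance floor tied to the data
        # scale so the objective stays finite when a trial parameter set
        # predicts ~zero concentrations under proportional error
        scale = float(np.median(np.abs(dataset.obs_y))) if dataset.n_obs else 1.0
        self.var_floor = max((1.0e-4 * max(scale, 1.0e-6)) ** 2, _VAR_FLOOR)
        # per-observation segment views
        s = dataset.obs_sidx
        self.o_start = dataset.seg_start[s]
        self.o_dur = dataset.seg_dur[s]
        self.o_rate = dataset.seg_rate[s]

    def typical(self, est: dict) -> dict:
        """Per-subject typical structural parameters given estimates."""
        ds, spec = self.ds, self.spec
        out = {}
        for name, _ in spec.structural:
            val = np.full(ds.n_subjects, float(est[name]))
            for eff in spec.covariates:
                if eff.param != name:
                    continue
                beta = float(est[eff.name])
                x = ds.covariates[eff.cov]
                if eff.form == "power":
                    ref = getattr(spec.refs, eff.cov)
                    val = val * (x / ref) ** beta
                else:
                    val = val * np.exp(beta * x)
            out[name] = val
        return out

    def pred_fn(self, est: dict) -> Callable:
        """Closure ``f(eta) -> (N,) concentrations`` for the inner search.

        The returned callable also carries a ``batch`` attribute mapping
        an ``(M, S, q)`` stack of random-effect matrices to ``(M, N)``
        predictions in a single vectorized evaluation.
        """
        typ = self.typical(est)
        ds = self.ds
        s = ds.obs_sidx
        spec = self.spec

        def f_batch(etas: np.ndarray) -> np.ndarray:
            ind = {}
            for name, _ in spec.structural:
                arr = typ[name][s]
                if name in self.iiv_params:
                    j = self.iiv_params.index(name)
                    arr = arr * np.exp(etas[..., s, j])
                ind[name] = arr
            if spec.n_compartments <= 2:
                q = ind["q"] if spec.n_compartments == 2 else 0.0
                vp = ind["vp"] if spec.n_compartments == 2 else 1.0
                return conc_at_times(ds.obs_time, self.o_start, self.o_dur,
                                     self.o_rate, ind["cl"], ind["vc"], q, vp)
            etas2 = etas if etas.ndim == 3 else etas[None]
            out = np.empty(etas2.shape[:1] + (ds.n_obs,))
            for m in range(etas2.shape[0]):
                ind_m = {k: v.copy() for k, v in typ.items()}
                for j, p in enumerate(self.iiv_params):
                    ind_m[p] = ind_m[p] * np.exp(etas2[m, :, j])
                lam = np.empty((ds.n_subjects, 3))
                coef = np.empty((ds.n_subjects, 3))
                for i in range(ds.n_subjects):
                    lam[i], coef[i] = hybrid_exponents_mammillary(
                        ind_m["cl"][i], ind_m["vc"][i],
                        [ind_m["q"][i], ind_m["q2"][i]],
                        [ind_m["vp"][i], ind_m["vp2"][i]])
                out[m] = conc_at_times_mammillary(
                    ds.obs_time, self.o_start, self.o_dur, self.o_rate,
                    lam[s], coef[s])
            return out if etas.ndim == 3 else out[0]

        def f(eta: np.ndarray) -> np.ndarray:
            return f_batch(eta)

        f.batch = f_batch
        return f

    def error_model(self, est: dict) -> ErrorModel:
        kind = self.spec.error_kind
        return ErrorModel(kind=kind,
                          sigma_add=float(est.get("sigma_add", 0.0)),
                          sigma_prop=float(est.get("sigma_prop", 0.0)))

    def omega2(self, est: dict) -> np.ndarray:
        return np.asarray([float(est[f"omega_{p}"]) ** 2 for p in self.iiv_params])


# ---------------------------------------------------------------------------
# FOCE/Laplace marginal -2 log-likelihood (generic core)


def laplace_neg2ll(
    y: np.ndarray,
    sidx: np.ndarray,
    n_subjects: int,
    pred_fn: Callable,
    omega2: np.ndarray,
    error: ErrorModel,
    inner_tol: float = 1.0e-6,
    max_iter: int = 60,
    return_details: bool = False,
    var_floor: float = _VAR_FLOOR,
    eta0: Optional[np.ndarray] = None,
    n_quad: int = 1,
):
    """FOCE-type approximate −2 log marginal likelihood.

    ``pred_fn(eta)`` maps an ``(S, q)`` matrix of random effects to the
    ``(N,)`` vector of predicted concentrations.  The conditional mode of
    each subject's ``eta`` is found by a damped, vectorized Newton
    search; with ``n_quad == 1`` the marginal likelihood is the Laplace
    approximation at the mode (Gauss-Newton curvature, residual variance
    at the conditional prediction — FOCE with interaction).  With
    ``n_quad > 1`` the integral is refined by adaptive Gauss-Hermite
    quadrature with ``n_quad`` nodes per random-effect dimension,
    centered at the mode and scaled by the local curvature.

    With ``q == 0`` the result reduces exactly to the closed-form
    Gaussian −2 log-likelihood of independent residuals.
    """
    y = np.asarray(y, dtype=float)
    sidx = np.asarray(sidx)
    q = len(omega2)
    n = y.size

    def variance(f):
        return np.maximum(error.variance(f), var_floor)

    def dvar_df(f):
        if error.kind == "additive":
            return np.zeros_like(f)
        return 2.0 * error.sigma_prop**2 * f

    if q == 0:
        f = pred_fn(np.zeros((n_subjects, 0)))
        s2 = variance(f)
        r = y - f
        total = float(np.sum(np.log(2.0 * np.pi * s2) + r * r / s2))
        if return_details:
            return total, {"eta": np.zeros((n_subjects, 0)), "ipred": f,
                           "per_subject": np.bincount(
                               sidx, np.log(2 * np.pi * s2) + r * r / s2,
                               minlength=n_subjects)}
        return total

    if np.any(omega2 <= 0):
        raise ValueError("omega2 entries must be positive for active random effects")

    fd = 1.0e-4
    batch = getattr(pred_fn, "batch", None)
    if batch is None:
        def batch(etas):
            return np.stack([pred_fn(e) for e in etas])
    pairs = [(k, l) for k in range(q) for l in range(k + 1, q)]

    def eval_block(eta):
        """One batched evaluation: f/σ²/residual/objective at ``eta``,
        FD gradient of f per eta component, and the full FD Hessian of
        the conditional objective."""
        points = [eta]
        for k in range(q):
            ek = np.zeros((1, q)); ek[0, k] = fd
            points.append(eta + ek)
            points.append(eta - ek)
        for k, l in pairs:
            ekl = np.zeros((1, q)); ekl[0, k] = fd; ekl[0, l] = fd
            points.append(eta + ekl)
            points.append(eta - ekl)
        stack = np.stack(points)
        F = batch(stack)
        S2 = variance(F)
        R = y[None, :] - F
        per = np.log(2.0 * np.pi * S2) + R * R / S2
        H = np.empty((len(points), n_subjects))
        for m in range(len(points)):
            H[m] = np.bincount(sidx, per[m], minlength=n_subjects)
        H += (stack * stack / omega2).sum(axis=2)
        f, s2, r, h = F[0], S2[0], R[0], H[0]
        g_obs = np.empty((n, q))
        for k in range(q):
            g_obs[:, k] = (F[1 + 2 * k] - F[2 + 2 * k]) / (2.0 * fd)
        hess = np.empty((n_subjects, q, q))
        for k in range(q):
            hess[:, k, k] = (H[1 + 2 * k] - 2.0 * h + H[2 + 2 * k]) / fd**2
        base = 1 + 2 * q
        for idx, (k, l) in enumerate(pairs):
            off = (H[base + 2 * idx] + H[base + 2 * idx + 1]
                   - H[1 + 2 * k] - H[2 + 2 * k]
                   - H[1 + 2 * l] - H[2 + 2 * l] + 2.0 * h) / (2.0 * fd**2)
            hess[:, k, l] = off
            hess[:, l, k] = off
        return f, s2, r, h, g_obs, hess

    if eta0 is not None and eta0.shape == (n_subjects, q):
        eta = np.asarray(eta0, dtype=float).copy()
    else:
        eta = np.zeros((n_subjects, q))
    converged = False
    stalled = np.zeros(n_subjects, dtype=bool)
    f, s2, r, h, g_obs, hess_fd = eval_block(eta)
    diag_idx = np.arange(q)
    for _ in range(max_iter):
        dv = dvar_df(f)
        inv_s2 = 1.0 / s2
        grad = np.empty((n_subjects, q))
        for k in range(q):
            gk = g_obs[:, k]
            term = dv * gk * (inv_s2 - (r * r) * inv_s2**2) - 2.0 * r * gk * inv_s2
            grad[:, k] = np.bincount(sidx, term, minlength=n_subjects)
        grad += 2.0 * eta / omega2

        gnorm = np.abs(grad).max(axis=1)
        active = (gnorm > inner_tol) & ~stalled
        if not np.any(active):
            converged = True
            break
        # Newton with the FD Hessian where it is positive definite,
        # otherwise the Gauss-Newton surrogate (always PD)
        gn = np.zeros((n_subjects, q, q))
        for k in range(q):
            for l in range(k, q):
                v = np.bincount(sidx, 2.0 * g_obs[:, k] * g_obs[:, l] * inv_s2,
                                minlength=n_subjects)
                gn[:, k, l] = v
                gn[:, l, k] = v
        gn[:, diag_idx, diag_idx] += 2.0 / omega2
        bad = ~np.isfinite(hess_fd).all(axis=(1, 2))
        if q == 1:
            bad |= hess_fd[:, 0, 0] <= 1.0e-10
        else:
            with np.errstate(all="ignore"):
                safe_h = np.where(np.isfinite(hess_fd), hess_fd, 0.0)
                bad |= np.linalg.eigvalsh(safe_h)[:, 0] <= 1.0e-10
        hess_use = np.where(bad[:, None, None], gn, hess_fd)

        step_dir = np.linalg.solve(hess_use, grad[:, :, None])[:, :, 0]
        # cap the step length without bending the (descent) direction
        norms = np.linalg.norm(step_dir, axis=1)
        step_dir *= np.minimum(1.0, 10.0 / np.maximum(norms, 1.0e-300))[:, None]
        step_dir[~active] = 0.0
        # full Newton step first; backtracking ladder only for subjects
        # that reject it (one extra batched call)
        def cond_h(eta_pt):
            fpt = pred_fn(eta_pt)
            s2p = variance(fpt)
            rp = y - fpt
            hp = np.bincount(sidx, np.log(2.0 * np.pi * s2p) + rp * rp / s2p,
                             minlength=n_subjects)
            return hp + (eta_pt * eta_pt / omega2).sum(axis=1)

        eta_full = np.clip(eta - step_dir, -35.0, 35.0)
        h_full = cond_h(eta_full)
        dec_full = np.isfinite(h_full) & (h_full < h - 1.0e-12)
        eta_next = np.where((active & dec_full)[:, None], eta_full, eta)
        need_ls = active & ~dec_full
        if np.any(need_ls):
            cand = np.clip(eta[None] - _LS_LADDER[:, None, None] * step_dir[None],
                           -35.0, 35.0)
            Fc = batch(cand)
            S2c = variance(Fc)
            Rc = y[None, :] - Fc
            perc = np.log(2.0 * np.pi * S2c) + Rc * Rc / S2c
            Hc = np.empty((len(_LS_LADDER), n_subjects))
            for m in range(len(_LS_LADDER)):
                Hc[m] = np.bincount(sidx, perc[m], minlength=n_subjects)
            Hc += (cand * cand / omega2).sum(axis=2)
            dec = np.isfinite(Hc) & (Hc < h[None, :] - 1.0e-12)
            any_dec = dec.any(axis=0)
            first = dec.argmax(axis=0)  # largest admissible scale per subject
            rows = np.flatnonzero(need_ls & any_dec)
            eta_next[rows] = cand[first[rows], rows]
            accept = active & (dec_full | any_dec)
        else:
            accept = active & dec_full
        stalled |= active & ~accept  # mode located to line-search precision
        if not np.any(accept):
            continue
        eta = eta_next
        f, s2, r, h, g_obs, hess_fd = eval_block(eta)

    # Laplace correction with Gauss-Newton curvature at the mode
    inv_s2 = 1.0 / s2
    gmat = np.zeros((n_subjects, q, q))
    for k in range(q):
        for l in range(k, q):
            gkl = np.bincount(sidx, g_obs[:, k] * g_obs[:, l] * inv_s2,
                              minlength=n_subjects)
            gmat[:, k, l] = gkl
            gmat[:, l, k] = gkl
    curv = gmat.copy()
    curv[:, np.arange(q), np.arange(q)] += 1.0 / omega2
    sign, logdet = np.linalg.slogdet(curv)
    per_subject = h + float(np.sum(np.log(omega2))) + logdet

    if n_quad > 1:
        # adaptive Gauss-Hermite refinement around the mode, scaled by
        # the local curvature: exact marginal likelihood as n_quad grows
        nodes, wts = np.polynomial.hermite.hermgauss(n_quad)
        grid = np.meshgrid(*([nodes] * q), indexing="ij")
        z = np.stack([g_.ravel() for g_ in grid], axis=1)          # (G, q)
        wgrid = np.meshgrid(*([wts] * q), indexing="ij")
        log_wg = np.log(np.prod(np.stack([w_.ravel() for w_ in wgrid]), axis=0))
        sigma_hat = np.linalg.inv(curv)                            # (S, q, q)
        a_chol = np.linalg.cholesky(sigma_hat)
        etas_g = eta[None] + np.sqrt(2.0) * np.einsum("sij,gj->gsi", a_chol, z)
        Fg = batch(etas_g)
        S2g = variance(Fg)
        Rg = y[None, :] - Fg
        perg = np.log(2.0 * np.pi * S2g) + Rg * Rg / S2g
        Hg = np.empty((len(z), n_subjects))
        for m in range(len(z)):
            Hg[m] = np.bincount(sidx, perg[m], minlength=n_subjects)
        Hg += (etas_g * etas_g / omega2).sum(axis=2)
        Hg += q * np.log(2.0 * np.pi) + float(np.sum(np.log(omega2)))
        a = -0.5 * Hg + (z * z).sum(axis=1)[:, None] + log_wg[:, None]
        amax = a.max(axis=0)
        lse = amax + np.log(np.exp(a - amax).sum(axis=0))
        _, logdet_sig = np.linalg.slogdet(sigma_hat)
        per_subject = -q * np.log(2.0) - logdet_sig - 2.0 * lse

    total = float(per_subject.sum())
    if return_details:
        return total, {"eta": eta, "ipred": f, "g_obs": g_obs, "s2": s2,
                       "per_subject": per_subject, "converged": converged}
    return total


# ---------------------------------------------------------------------------
# public operations


def information_criteria(ofv_value: float, p: int, n: int):
    """AIC/BIC on the OFV (−2 log-likelihood) scale:
    ``AIC = OFV + 2p``, ``BIC = OFV + p·ln(n)``."""
    if p < 1 or n < 1:
        raise ValueError("p and n must be >= 1")
    return ofv_value + 2.0 * p, ofv_value + p * math.log(n)


def ofv(spec: ModelSpec, estimates: dict, dataset: EventDataset,
        n_quad: int = 1) -> float:
    """OFV (−2 approximate log marginal likelihood) at given estimates."""
    model = _CompiledModel(spec, dataset)
    return laplace_neg2ll(dataset.obs_y, dataset.obs_sidx, dataset.n_subjects,
                          model.pred_fn(estimates), model.omega2(estimates),
                          model.error_model(estimates), var_floor=model.var_floor,
                          n_quad=n_quad)


def predict(spec: ModelSpec, estimates: dict, dataset: EventDataset):
    """Population (PRED, eta = 0) and individual (IPRED, eta at the
    conditional modes) predicted concentrations for every observation."""
    model = _CompiledModel(spec, dataset)
    pfn = model.pred_fn(estimates)
    pred = pfn(np.zeros((dataset.n_subjects, model.q_eta)))
    om = model.omega2(estimates) if model.q_eta else np.empty(0)
    if model.q_eta == 0 or not np.any(om > 0):
        return pred, pred.copy()
    om = np.where(om > 0, om, 1.0e-12)  # pin zero-variance etas at ~0
    _, details = laplace_neg2ll(dataset.obs_y, dataset.obs_sidx, dataset.n_subjects,
                                pfn, om,
                                model.error_model(estimates), return_details=True,
                                var_floor=model.var_floor)
    return pred, details["ipred"]


@dataclass
class FitResult:
    """Outcome of one NLME fit."""

    estimates: dict
    se: dict
    rse: dict
    ci_lower: dict
    ci_upper: dict
    ofv: float
    aic: float
    bic: float
    n_params: int
    n_obs: int
    n_subjects: int
    eta_modes: pd.DataFrame
    eta_shrinkage: dict
    converged: bool
    boundary: list
    spec: ModelSpec
    seed: int = 0

    def summary(self) -> pd.DataFrame:
        names = self.spec.param_names()
        return pd.DataFrame({
            "parameter": names,
            "estimate": [self.estimates[n] for n in names],
            "se": [self.se.get(n, np.nan) for n in names],
            "rse": [self.rse.get(n, np.nan) for n in names],
            "ci95_lower": [self.ci_lower.get(n, np.nan) for n in names],
            "ci95_upper": [self.ci_upper.get(n, np.nan) for n in names],
        })

    def to_dict(self) -> dict:
        return {
            "estimates": {k: float(v) for k, v in self.estimates.items()},
            "se": {k: float(v) for k, v in self.se.items()},
            "rse": {k: float(v) for k, v in self.rse.items()},
            "ci95": {k: [float(self.ci_lower[k]), float(self.ci_upper[k])]
                     for k in self.ci_lower},
            "ofv": float(self.ofv),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "n_params": int(self.n_params),
            "n_obs": int(self.n_obs),
            "n_subjects": int(self.n_subjects),
            "eta_shrinkage": {k: float(v) for k, v in self.eta_shrinkage.items()},
            "converged": bool(self.converged),
            "boundary": list(self.boundary),
            "seed": int(self.seed),
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def report_text(self) -> str:
        lines = [f"OFV  {self.ofv:.3f}", f"AIC  {self.aic:.3f}",
                 f"BIC  {self.bic:.3f}",
                 f"n_obs {self.n_obs}  n_subjects {self.n_subjects}  "
                 f"p {self.n_params}  converged {self.converged}"]
        for _, row in self.summary().iterrows():
            lines.append(f"{row['parameter']:>16s} {row['estimate']:12.5g}"
                         f"  (RSE {row['rse']:.3g}, "
                         f"CI {row['ci95_lower']:.5g}..{row['ci95_upper']:.5g})")
        return "\n".join(lines)


def _free_params(spec: ModelSpec):
    """(name, transform) of every estimated parameter, in report order."""
    free = []
    for n, ps in spec.structural:
        if not ps.fixed:
            free.append((n, "log"))
    for e in spec.covariates:
        if not e.fixed:
            free.append((e.name, "id"))
    for p, ps in spec.iiv:
        if not ps.fixed:
            free.append((f"omega_{p}", "log"))
    for k, ps in spec.sigma:
        if not ps.fixed:
            free.append((f"sigma_{k}", "log"))
    return free


_BOUNDS = {"log": (math.log(1.0e-6), math.log(1.0e6)), "id": (-50.0, 50.0)}
_OMEGA_BOUNDARY = 1.0e-4


def fit(spec: ModelSpec, dataset: EventDataset, seed: int = 0,
        maxiter: int = 400, staged_init: bool = False,
        n_quad: int = 1, compute_se: bool = True) -> FitResult:
    """Estimate the model by minimizing the FOCE OFV.

    Positive parameters are searched on the log scale; standard errors
    and 95% CIs come from the inverse curvature of the OFV at the
    optimum (delta method back to the natural scale).  ω estimated at
    its lower boundary (< 1e-4) is reported as 0 with a boundary flag.
    Deterministic given the spec and dataset; ``seed`` is recorded for
    provenance.

    With ``staged_init``, fixed effects and σ are first fit with the
    random effects switched off (an exact, fast Gaussian likelihood) and
    the full FOCE search starts from those values.  Off by default: on
    strongly heterogeneous data the no-IIV stage can wander into a
    degenerate basin, so it is only worth enabling when the initial
    values are known to be far off and the data are rich.
    """
    if staged_init and any(not ps.fixed for _, ps in spec.iiv):
        stage0 = replace(spec, iiv=tuple(
            (p, ParamSpec(0.0, fixed=True)) for p, _ in spec.iiv))
        pre = fit(stage0, dataset, seed=seed, maxiter=maxiter, staged_init=False)
        warm = {k: v for k, v in pre.estimates.items() if not k.startswith("omega")}
        spec = spec.with_inits({**spec.initial_estimates(), **warm})
    model = _CompiledModel(spec, dataset)
    free = _free_params(spec)
    est0 = spec.initial_estimates()

    def to_z(est):
        return np.asarray([math.log(est[n]) if tr == "log" else est[n]
                           for n, tr in free])

    def to_est(z):
        est = dict(est0)
        for (n, tr), v in zip(free, z):
            est[n] = math.exp(v) if tr == "log" else float(v)
        return est

    warm = {"eta": None}

    def objective(z):
        est = to_est(z)
        try:
            if model.q_eta:
                v, det = laplace_neg2ll(
                    dataset.obs_y, dataset.obs_sidx, dataset.n_subjects,
                    model.pred_fn(est), model.omega2(est),
                    model.error_model(est), var_floor=model.var_floor,
                    return_details=True, eta0=warm["eta"], n_quad=n_quad)
                warm["eta"] = det["eta"]
            else:
                v = laplace_neg2ll(
                    dataset.obs_y, dataset.obs_sidx, dataset.n_subjects,
                    model.pred_fn(est), model.omega2(est),
                    model.error_model(est), var_floor=model.var_floor)
        except np.linalg.LinAlgError:
            return 1.0e12
        return v if np.isfinite(v) else 1.0e12

    z0 = to_z(est0)
    bounds = [_BOUNDS[tr] for _, tr in free]
    f_init = objective(z0)
    # monotone log-compression of the objective far above its starting
    # value: the minimizer is unchanged but line searches stay on a sane
    # scale even where a trial point is astronomically bad
    cap = f_init + 10.0

    def compressed(z):
        v = objective(z)
        return v if v <= cap else cap + math.log1p(v - cap)

    res = optimize.minimize(compressed, z0, method="L-BFGS-B", bounds=bounds,
                            options={"maxiter": maxiter, "ftol": 1.0e-8,
                                     "gtol": 1.0e-4, "eps": 1.0e-5})
    z_hat = res.x
    est = to_est(z_hat)
    ofv_hat = float(objective(z_hat))

    # curvature -> standard errors (natural scale via delta method)
    p = len(free)
    if compute_se:
        try:
            hz = _fd_hessian(objective, z_hat, ofv_hat)
            cov_z = 2.0 * np.linalg.pinv(hz)
            jac = np.asarray([est[n] if tr == "log" else 1.0 for n, tr in free])
            cov_nat = cov_z * np.outer(jac, jac)
            diag = np.clip(np.diag(cov_nat), 0.0, None)
            se = {n: float(np.sqrt(d)) for (n, _), d in zip(free, diag)}
        except (np.linalg.LinAlgError, ValueError):
            se = {n: float("nan") for n, _ in free}
    else:
        se = {n: float("nan") for n, _ in free}

    boundary = []
    for pname, _ in spec.iiv:
        key = f"omega_{pname}"
        if key in est and est[key] < _OMEGA_BOUNDARY:
            est[key] = 0.0
            boundary.append(key)

    rse = {n: (se[n] / abs(est[n]) if est[n] not in (0, 0.0) else float("nan"))
           for n in se}
    ci_lo = {n: est[n] - 1.959964 * se[n] for n in se}
    ci_hi = {n: est[n] + 1.959964 * se[n] for n in se}

    aic, bic = information_criteria(ofv_hat, p, dataset.n_obs)

    # conditional modes and shrinkage at the optimum
    if model.q_eta and all(f"omega_{pn}" not in boundary for pn in model.iiv_params):
        _, details = laplace_neg2ll(dataset.obs_y, dataset.obs_sidx,
                                    dataset.n_subjects, model.pred_fn(est),
                                    model.omega2(est), model.error_model(est),
                                    return_details=True, var_floor=model.var_floor)
        eta = details["eta"]
    else:
        eta = np.zeros((dataset.n_subjects, model.q_eta))
    eta_df = pd.DataFrame(eta, columns=[f"eta_{p}" for p in model.iiv_params])
    eta_df.insert(0, "ID", dataset.subject_ids)
    shrink = {}
    for j, pname in enumerate(model.iiv_params):
        om = est.get(f"omega_{pname}", 0.0)
        shrink[f"eta_{pname}"] = (1.0 - float(np.std(eta[:, j], ddof=1)) / om
                                  if om > 0 and len(eta) > 1 else float("nan"))

    return FitResult(
        estimates=est, se=se, rse=rse, ci_lower=ci_lo, ci_upper=ci_hi,
        ofv=ofv_hat, aic=aic, bic=bic, n_params=p, n_obs=dataset.n_obs,
        n_subjects=dataset.n_subjects, eta_modes=eta_df, eta_shrinkage=shrink,
        converged=bool(res.success), boundary=boundary, spec=spec, seed=seed,
    )


def _fd_hessian(fun, x, f0, step: float = 5.0e-4) -> np.ndarray:
    """Finite-difference Hessian: central on the diagonal, forward
    cross-differences off it (symmetric by construction)."""
    p = len(x)
    hess = np.empty((p, p))
    fp = np.empty(p)
    for i in range(p):
        e = np.zeros(p)
        e[i] = step
        fp[i] = fun(x + e)
        hess[i, i] = (fp[i] - 2.0 * f0 + fun(x - e)) / step**2
    for i in range(p):
        for j in range(i + 1, p):
            e = np.zeros(p)
            e[i] = step
            e[j] = step
            hess[i, j] = hess[j, i] = (
                fun(x + e) - fp[i] - fp[j] + f0) / step**2
    return hess


def cwres(spec: ModelSpec, fitresult: FitResult, dataset: EventDataset) -> np.ndarray:
    """Conditional weighted residuals (FOCE linearization).

    Per subject, ``CWRES = L⁻¹ (y − E)`` with ``E = f(η̂) − G·η̂`` (the
    conditional prediction corrected back to η = 0 through the local
    gradient G) and ``L`` the Cholesky factor of the linearized total
    variance ``V = G Ω Gᵀ + diag(σ²(f(η̂)))``.  With ω = 0 and additive
    error this reduces exactly to the raw residual over σ.
    """
    model = _CompiledModel(spec, dataset)
    est = fitresult.estimates
    err = model.error_model(est)
    if model.q_eta == 0 or any(est.get(f"omega_{p}", 0.0) == 0.0
                               for p in model.iiv_params):
        pfn = model.pred_fn(est)
        f = pfn(np.zeros((dataset.n_subjects, model.q_eta)))
        s2 = np.maximum(err.variance(f), _VAR_FLOOR)
        return (dataset.obs_y - f) / np.sqrt(s2)
    _, details = laplace_neg2ll(dataset.obs_y, dataset.obs_sidx, dataset.n_subjects,
                                model.pred_fn(est), model.omega2(est), err,
                                return_details=True, var_floor=model.var_floor)
    eta = details["eta"]
    g_obs = details["g_obs"]
    f = details["ipred"]
    omega2 = model.omega2(est)
    e_lin = f - (g_obs * eta[dataset.obs_sidx]).sum(axis=1)
    resid = dataset.obs_y - e_lin
    s2 = np.maximum(err.variance(f), model.var_floor)
    out = np.empty(dataset.n_obs)
    from scipy.linalg import cholesky as _chol, solve_triangular
    for i in range(dataset.n_subjects):
        mask = dataset.obs_sidx == i
        g_i = g_obs[mask]
        v_i = g_i @ (omega2[:, None] * g_i.T) + np.diag(s2[mask])
        try:
            lower = _chol(v_i, lower=True)
        except np.linalg.LinAlgError as exc:
            raise FloatingPointError(
                f"singular linearized variance for subject "
                f"{dataset.subject_ids[i]}") from exc
        out[mask] = solve_triangular(lower, resid[mask], lower=True)
    return out


def simulate_observations(spec: ModelSpec, estimates: dict,
                          dataset: EventDataset, n_sim: int,
                          seed) -> np.ndarray:
    """Simulate replicate observation vectors at the dataset's design.

    Returns an ``(n_sim, n_obs)`` array: each replicate draws fresh
    subject random effects and residual errors at the observed dosing
    histories, covariates and sampling times.

    Each subject consumes an independent random stream derived from
    ``(seed, subject id)``, so the result is invariant to subject
    relabeling/reordering and to subsetting the cohort.
    """
    from zlib import crc32

    if isinstance(seed, np.random.Generator):  # accept a Generator too
        seed = int(seed.integers(0, 2**31 - 1))
    model = _CompiledModel(spec, dataset)
    pfn = model.pred_fn(estimates)
    err = model.error_model(estimates)
    omega = np.sqrt(model.omega2(estimates))
    q = model.q_eta
    etas = np.zeros((n_sim, dataset.n_subjects, q))
    eps1 = np.empty((n_sim, dataset.n_obs))
    eps2 = np.empty((n_sim, dataset.n_obs))
    for i, sid in enumerate(dataset.subject_ids):
        rng_i = np.random.default_rng(
            np.random.SeedSequence([seed, crc32(str(sid).encode())]))
        if q:
            etas[:, i, :] = rng_i.normal(0.0, omega, size=(n_sim, q))
        mask = dataset.obs_sidx == i
        n_i = int(mask.sum())
        eps1[:, mask] = rng_i.normal(0.0, 1.0, size=(n_sim, n_i))
        eps2[:, mask] = rng_i.normal(0.0, 1.0, size=(n_sim, n_i))
    out = np.empty((n_sim, dataset.n_obs))
    chunk = max(1, int(5.0e6 // max(dataset.n_obs, 1)))
    for lo in range(0, n_sim, chunk):
        hi = min(lo + chunk, n_sim)
        f = pfn.batch(etas[lo:hi])
        if err.kind == "additive":
            out[lo:hi] = f + err.sigma_add * eps1[lo:hi]
        else:
            e1 = np.maximum(err.sigma_prop * eps1[lo:hi], err.eps_floor)
            out[lo:hi] = f * (1.0 + e1)
            if err.kind == "combined":
                out[lo:hi] += err.sigma_add * eps2[lo:hi]
    return out
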