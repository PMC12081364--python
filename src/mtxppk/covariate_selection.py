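"""Stepwise covariate model building by likelihood-ratio ΔOFV.

Forward inclusion accepts, at each round, the candidate whose addition
lowers the OFV the most, provided the drop is at least 6.64 (the χ²₁
critical value at P = 0.01); backward elimination removes a covariate
whose deletion raises the OFV by no more than 10.83 (χ²₁ at P = 0.001),
least-supported first, until every remaining covariate is defended.
The full trail of trial fits is recorded so the search is auditable as
a model-development table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .estimation import CovariateEffect, EventDataset, FitResult, ModelSpec, fit

__all__ = [
    "FORWARD_THRESHOLD",
    "BACKWARD_THRESHOLD",
    "CANONICAL_ORDER",
    "CandidateCovariate",
    "StepRecord",
    "lrt_thresholds",
    "forward_step",
    "backward_step",
    "run_stepwise",
    "trail_table",
]

FORWARD_THRESHOLD = 6.64   # χ²(1) at P = 0.01, as conventionally rounded
BACKWARD_THRESHOLD = 10.83  # χ²(1) at P = 0.001

#: deterministic tie-break order for candidates with equal ΔOFV
CANONICAL_ORDER = ("egfr", "bw", "blm", "tbil", "alb")

_TIE_TOL = 1.0e-6


def lrt_thresholds() -> tuple:
    """(forward, backward) ΔOFV thresholds: χ²₁ critical values at
    0.01 and 0.001 (6.6349 and 10.8276, rounded as reported)."""
    return FORWARD_THRESHOLD, BACKWARD_THRESHOLD


@dataclass(frozen=True)
class CandidateCovariate:
    """A covariate-parameter relation offered to the search.

    ``group`` marks mutually exclusive candidates (collinear
    alternatives such as body weight vs body surface area): once one
    member enters the model the others leave the pool.
    """

    cov: str
    param: str
    form: str
    group: Optional[str] = None

    def __post_init__(self) -> None:
        if self.form not in ("power", "exp"):
            raise ValueError(f"unknown form {self.form!r}")

    @property
    def label(self) -> str:
        return f"{self.cov} on {self.param}"

    def effect(self, init: float = 0.0) -> CovariateEffect:
        return CovariateEffect(self.param, self.cov, self.form, init=init)


@dataclass(frozen=True)
class StepRecord:
    """One trial in the stepwise search."""

    phase: str          # "forward" | "backward"
    action: str
    ofv_before: float
    ofv_after: float
    decision: str       # "accept" | "reject" | "failed"

    @property
    def delta(self) -> float:
        return self.ofv_after - self.ofv_before


def _candidate_rank(c: CandidateCovariate) -> tuple:
    try:
        return (0, CANONICAL_ORDER.index(c.cov), c.param)
    except ValueError:
        return (1, c.cov, c.param)


def _fit_quiet(spec: ModelSpec, dataset: EventDataset, seed: int,
               warm: Optional[dict]) -> Optional[FitResult]:
    try:
        if warm:
            spec = spec.with_inits({**spec.initial_estimates(), **warm})
        return fit(spec, dataset, seed=seed)
    except (ValueError, FloatingPointError, np.linalg.LinAlgError):
        return None


def forward_step(
    spec: ModelSpec,
    candidates: Sequence[CandidateCovariate],
    dataset: EventDataset,
    current_fit: Optional[FitResult] = None,
    seed: int = 0,
):
    """Try each candidate on top of ``spec``; accept the largest OFV drop
    if it reaches the forward threshold.

    Returns ``(accepted_candidate_or_None, records, new_spec, new_fit)``.
    A candidate whose trial fit fails is recorded as failed and skipped.
    """
    if current_fit is None:
        current_fit = fit(spec, dataset, seed=seed)
    warm = {k: v for k, v in current_fit.estimates.items()}
    records = []
    trials = []
    for cand in sorted(candidates, key=_candidate_rank):
        trial_spec = spec.with_covariate(cand.effect())
        res = _fit_quiet(trial_spec, dataset, seed, warm)
        if res is None:
            records.append(StepRecord("forward", f"Add {cand.label}",
                                      current_fit.ofv, float("nan"), "failed"))
            continue
        trials.append((cand, trial_spec, res))
        records.append(StepRecord("forward", f"Add {cand.label}",
                                  current_fit.ofv, res.ofv, "pending"))
    best = None
    for cand, tspec, res in trials:
        drop = current_fit.ofv - res.ofv
        if drop >= FORWARD_THRESHOLD and (
                best is None or res.ofv < best[2].ofv - _TIE_TOL):
            best = (cand, tspec, res)
    records = [
        StepRecord(r.phase, r.action, r.ofv_before, r.ofv_after,
                   "accept" if best is not None and
                   r.action == f"Add {best[0].label}" else
                   ("failed" if r.decision == "failed" else "reject"))
        for r in records
    ]
    if best is None:
        return None, records, spec, current_fit
    return best[0], records, best[1], best[2]


def backward_step(
    spec: ModelSpec,
    dataset: EventDataset,
    current_fit: Optional[FitResult] = None,
    seed: int = 0,
):
    """Refit with each included covariate removed; drop the least
    supported one unless its removal raises the OFV beyond the backward
    threshold.

    Returns ``(removed_effect_or_None, records, new_spec, new_fit)``.
    """
    if not spec.covariates:
        return None, [], spec, current_fit
    if current_fit is None:
        current_fit = fit(spec, dataset, seed=seed)
    warm = {k: v for k, v in current_fit.estimates.items()
            if not k.startswith("beta_")}
    records = []
    weakest = None
    for eff in sorted(spec.covariates,
                      key=lambda e: _candidate_rank(
                          CandidateCovariate(e.cov, e.param, e.form))):
        reduced = spec.without_covariate(eff.param, eff.cov)
        res = _fit_quiet(reduced, dataset, seed, warm)
        if res is None:
            records.append(StepRecord("backward",
                                      f"Remove {eff.cov} on {eff.param}",
                                      current_fit.ofv, float("nan"), "failed"))
            continue
        rise = res.ofv - current_fit.ofv
        records.append(StepRecord("backward", f"Remove {eff.cov} on {eff.param}",
                                  current_fit.ofv, res.ofv, "pending"))
        if rise <= BACKWARD_THRESHOLD and (
                weakest is None or res.ofv < weakest[2].ofv - _TIE_TOL):
            weakest = (eff, reduced, res)
    records = [
        StepRecord(r.phase, r.action, r.ofv_before, r.ofv_after,
                   "accept" if weakest is not None and
                   r.action == f"Remove {weakest[0].cov} on {weakest[0].param}"
                   else ("failed" if r.decision == "failed" else "reject"))
        for r in records
    ]
    if weakest is None:
        return None, records, spec, current_fit
    return weakest[0], records, weakest[1], weakest[2]


def run_stepwise(
    base_spec: ModelSpec,
    candidates: Sequence[CandidateCovariate],
    dataset: EventDataset,
    seed: int = 0,
):
    """Forward steps to exhaustion, then backward steps to stability.

    Returns ``(final_spec, trail)`` with the trail an ordered list of
    StepRecord mirroring a model-development table.
    """
    pool = list(candidates)
    trail = []
    current = fit(base_spec, dataset, seed=seed)
    spec = base_spec
    while pool:
        accepted, records, spec, current = forward_step(
            spec, pool, dataset, current_fit=current, seed=seed)
        trail.extend(records)
        if accepted is None:
            break
        pool = [c for c in pool
                if not (c.cov == accepted.cov and c.param == accepted.param)
                and not (accepted.group is not None and c.group == accepted.group)]
    while spec.covariates:
        removed, records, spec, current = backward_step(
            spec, dataset, current_fit=current, seed=seed)
        trail.extend(records)
        if removed is None:
            break
    return spec, trail


def trail_table(trail: Sequence[StepRecord]) -> pd.DataFrame:
    """Stepwise trail as a model-development table (CSV-exportable)."""
    return pd.DataFrame({
        "model_no": np.arange(1, len(trail) + 1),
        "phase": [r.phase for r in trail],
        "description": [r.action for r in trail],
        "ofv": [r.ofv_after for r in trail],
        "delta_ofv": [r.delta for r in trail],
        "decision": [r.decision for r in trail],
    })
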