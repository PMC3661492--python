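"""Stepwise covariate selection for the capture-event stage.

A maximum-likelihood binomial GLM (logit link, fitted by IRLS through
statsmodels) is refitted with each candidate added or removed in turn; the
move with the greatest AIC reduction is taken.  Steps stop when the accepted
addition no longer reduces the residual deviance by more than ``stop_frac``
(default 1%) of the current model's deviance, or when no move improves the
AIC.  A covariate and its log-transform are never allowed in the same model
(they share a ``source`` field and would be near-collinear).

Selection runs on observed tows only and without year effects: it screens the
fixed covariates the fishers report, not the annual variation.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .covariates import CovariateSpec, _spec_columns

__all__ = ["GlmFit", "StepRecord", "StepTrace", "SeparationError",
           "fit_binomial_glm", "step_select"]

#: coefficient magnitude beyond which we declare (quasi-)separation
SEPARATION_BOUND = 30.0


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: diverging coefficients."""


@dataclass
class GlmFit:
    """A fitted binomial GLM: named coefficients and fit statistics."""

    params: pd.Series
    llf: float
    deviance: float
    aic: float
    n_params: int
    converged: bool
    n_iter: int
    separation: bool = False


def fit_binomial_glm(X, y, max_iter: int = 100, tol: float = 1e-8) -> GlmFit:
    """Fit a logit-link binomial GLM by IRLS; intercept added automatically.

    Raises ``ValueError`` naming collinear columns on a singular design, and
    flags (without raising) quasi-separation via ``GlmFit.separation`` when a
    coefficient exceeds +/-30.
    """
    X = pd.DataFrame(X).astype(float)
    y = np.asarray(y, dtype=float)
    if len(X) < X.shape[1] + 1:
        raise ValueError("fewer rows than parameters")
    Xc = sm.add_constant(X, has_constant="add")
    rank = np.linalg.matrix_rank(Xc.to_numpy())
    if rank < Xc.shape[1]:
        r = np.linalg.qr(Xc.to_numpy(), mode="r")
        bad = [Xc.columns[j] for j in range(Xc.shape[1])
               if abs(r[j, j]) < 1e-8 * max(1.0, abs(r[0, 0]))]
        raise ValueError(f"singular design; collinear column(s): {bad}")
    model = sm.GLM(y, Xc, family=sm.families.Binomial())
    import warnings
    with warnings.catch_warnings():
        # near-separated fits spray numerical warnings from the IRLS internals
        # and the (lazily evaluated) log-likelihood; separation is detected
        # and flagged explicitly below instead
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=max_iter, tol=tol)
        params = pd.Series(res.params, index=Xc.columns)
        out = GlmFit(params=params, llf=float(res.llf),
                     deviance=float(res.deviance), aic=float(res.aic),
                     n_params=int(Xc.shape[1]),
                     converged=bool(res.converged),
                     n_iter=int(res.fit_history["iteration"]),
                     separation=bool(np.any(np.abs(params.to_numpy())
                                            > SEPARATION_BOUND)))
    return out


@dataclass
class StepRecord:
    action: str                  # "add" or "remove"
    covariate: str
    aic_before: float
    aic_after: float
    deviance_before: float
    deviance_after: float

    @property
    def rel_deviance_reduction(self) -> float:
        return (self.deviance_before - self.deviance_after) / self.deviance_before


@dataclass
class StepTrace:
    records: list = field(default_factory=list)
    stop_reason: str = ""

    def to_frame(self) -> pd.DataFrame:
        rows = [{
            "action": r.action, "covariate": r.covariate,
            "aic_before": r.aic_before, "aic_after": r.aic_after,
            "deviance_before": r.deviance_before,
            "deviance_after": r.deviance_after,
            "rel_deviance_reduction": r.rel_deviance_reduction,
        } for r in self.records]
        return pd.DataFrame(rows)


def _design_for(frame: pd.DataFrame, specs: list) -> pd.DataFrame:
    if not specs:
        return pd.DataFrame(index=frame.index)
    return pd.concat([_spec_columns(frame, s) for s in specs], axis=1)


def step_select(frame: pd.DataFrame, y, candidates: list,
                stop_frac: float = 0.01, start: list | None = None):
    """Greedy bidirectional AIC search over candidate covariates.

    Parameters
    ----------
    frame : DataFrame
        Covariate-annotated observed tows (source columns for every spec).
    y : array
        Binary capture-event indicator.
    candidates : list of CovariateSpec
        Candidate pool; specs sharing a ``source`` are mutually exclusive.
    stop_frac : float
        Smallest worthwhile relative deviance reduction of an accepted
        addition (1% rule).
    start : list of CovariateSpec, optional
        Starting model (default: intercept only).

    Returns
    -------
    (selected, StepTrace)
        Selected specs in candidate order (deterministic regardless of the
        order candidates are supplied in).
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    y = np.asarray(y, dtype=float)
    frame = frame.reset_index(drop=True)
    by_name = {c.name: c for c in candidates}
    if len(by_name) != len(candidates):
        raise ValueError("candidate names must be unique")

    current: list[str] = [c.name for c in (start or [])]
    cur = fit_binomial_glm(_design_for(frame, [by_name[n] for n in current]), y)
    trace = StepTrace()

    while True:
        sources_in = {by_name[n].source for n in current}
        moves = []  # (aic, action, name, fit)
        for name, spec in sorted(by_name.items()):
            if name in current:
                continue
            if spec.source in sources_in:
                continue  # raw-vs-log exclusivity
            try:
                fit = fit_binomial_glm(
                    _design_for(frame, [by_name[n] for n in current] + [spec]), y)
            except ValueError:
                continue
            if fit.separation:
                continue
            moves.append((fit.aic, "add", name, fit))
        for name in sorted(current):
            rest = [by_name[n] for n in current if n != name]
            fit = fit_binomial_glm(_design_for(frame, rest), y)
            moves.append((fit.aic, "remove", name, fit))

        if not moves:
            trace.stop_reason = "no admissible move"
            break
        aic, action, name, fit = min(moves, key=lambda m: (m[0], m[2]))
        if aic >= cur.aic:
            trace.stop_reason = "no AIC reduction"
            break
        rec = StepRecord(action=action, covariate=name,
                         aic_before=cur.aic, aic_after=aic,
                         deviance_before=cur.deviance,
                         deviance_after=fit.deviance)
        if action == "add" and rec.rel_deviance_reduction <= stop_frac:
            trace.stop_reason = (
                f"deviance reduction {rec.rel_deviance_reduction:.3%} <= "
                f"{stop_frac:.0%} rule")
            break
        trace.records.append(rec)
        if action == "add":
            current.append(name)
        else:
            current.remove(name)
        cur = fit

    selected = [c for c in candidates if c.name in current]
    return selected, trace
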