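"""Information criteria for auxiliary-variable selection.

All criteria estimate (twice the sample size times) a Kullback–Leibler risk
of the plug-in predictive distribution of the primary variables x = (y, z).
Naming follows the evaluation;estimation convention: ``AIC_xb`` evaluates on
x and estimates from the observables b = (y, a), ``AIC_xy`` estimates from y
alone, etc.  ``RISKHAT_xb`` is the fully misspecification-robust form whose
penalty uses the sandwich matrices; under correct specification it reduces
to ``AIC_xb``, and with no latent part and no auxiliary variable to TIC.

The decision rule: the auxiliary variable is declared useful only when the
criterion of the joint fit is strictly below that of the y-only fit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AuxselError, DataError
from .info_matrices import InfoMatrices, estimate_all
from .models import Dataset, EMSettings, FitResult, fit_em, logdensity_y

__all__ = [
    "CriterionValue",
    "SelectionResult",
    "penalty_riskhat",
    "penalty_aic_xb",
    "risk_hat_xb",
    "aic_xb",
    "aic_xy",
    "aic_yb",
    "aic_yy",
    "tic",
    "select",
]

logger = logging.getLogger(__name__)

NO_AUX_LABEL = "(no auxiliary)"


@dataclass
class CriterionValue:
    """One criterion evaluation with its penalty decomposition."""

    name: str
    value: float
    goodness_term: float
    penalty_terms: dict
    fit_ref: FitResult
    n: int

    def __post_init__(self):
        total = self.goodness_term + sum(self.penalty_terms.values())
        if not np.isfinite(total) or abs(total - self.value) > 1e-8 * max(1.0, abs(self.value)):
            raise AuxselError("criterion value does not match its decomposition")


@dataclass
class SelectionResult:
    """Criterion values across candidate auxiliary variables and the winner."""

    candidates: list  # [(label, CriterionValue)], first entry is the no-aux model
    best_label: str
    decision_rule: str
    failed: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for label, cv in self.candidates:
            row = {"label": label, "criterion": cv.name, "value": cv.value,
                   "goodness": cv.goodness_term}
            for k, v in cv.penalty_terms.items():
                row[f"penalty:{k}"] = v
            rows.append(row)
        return pd.DataFrame(rows)


def _mean_loglik_y(fit: FitResult, data: Dataset) -> float:
    """Average y-marginal log-likelihood at the theta-part of the fit."""
    return float(np.mean(logdensity_y(fit.params.theta(), data.y)))


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DataError(msg)


def penalty_riskhat(I_b, J_b, K_by, I_zy) -> tuple:
    """The two sandwich penalty traces: 2tr(Ib^-1 Kby), tr(Izy Ib^-1 Jb Ib^-1)."""
    A = np.linalg.inv(I_b)
    return (
        2.0 * float(np.trace(A @ K_by)),
        float(np.trace(I_zy @ A @ J_b @ A)),
    )


def penalty_aic_xb(I_b, I_x, I_y) -> tuple:
    """The two correct-specification penalty traces: tr(Ix Ib^-1), tr(Iy Ib^-1)."""
    A = np.linalg.inv(I_b)
    return float(np.trace(I_x @ A)), float(np.trace(I_y @ A))


def risk_hat_xb(fit: FitResult, mats: InfoMatrices, data: Dataset) -> CriterionValue:
    """Sandwich-form risk estimate for the joint fit.

    value = -2n * mean log p(y; theta_b) + 2 tr(I_b^{-1} K_by)
            + tr(I_zy I_b^{-1} J_b I_b^{-1}).
    """
    n = data.n
    goodness = -2.0 * n * _mean_loglik_y(fit, data)
    p1, p2 = penalty_riskhat(mats.I_b, mats.J_b, mats.K_by, mats.I_zy)
    return CriterionValue(
        name="RISKHAT_xb",
        value=goodness + p1 + p2,
        goodness_term=goodness,
        penalty_terms={"2tr(Ib^-1 Kby)": p1, "tr(Izy Ib^-1 Jb Ib^-1)": p2},
        fit_ref=fit,
        n=n,
    )


def aic_xb(fit: FitResult, mats: InfoMatrices, data: Dataset) -> CriterionValue:
    """Correct-specification form for the joint fit.

    value = -2n * mean log p(y; theta_b) + tr(I_x I_b^{-1}) + tr(I_y I_b^{-1}).
    """
    _require(fit.objective == "b", "aic_xb needs a joint (auxiliary) fit")
    n = data.n
    goodness = -2.0 * n * _mean_loglik_y(fit, data)
    p1, p2 = penalty_aic_xb(mats.I_b, mats.I_x, mats.I_y)
    return CriterionValue(
        name="AIC_xb",
        value=goodness + p1 + p2,
        goodness_term=goodness,
        penalty_terms={"tr(Ix Ib^-1)": p1, "tr(Iy Ib^-1)": p2},
        fit_ref=fit,
        n=n,
    )


def aic_xy(fit_y: FitResult, mats_y: InfoMatrices, data: Dataset) -> CriterionValue:
    """Latent-part criterion for the y-only fit.

    value = -2n * mean log p(y; theta_y) + tr(I_x I_y^{-1}) + d.
    """
    _require(fit_y.objective == "y" and not fit_y.params.has_aux,
             "aic_xy needs the no-auxiliary fit (f = 0)")
    n = data.n
    d = fit_y.params.d
    A = np.linalg.inv(mats_y.I_y)
    goodness = -2.0 * n * fit_y.loglik_per_obs
    p1 = float(np.trace(mats_y.I_x @ A))
    return CriterionValue(
        name="AIC_xy",
        value=goodness + p1 + d,
        goodness_term=goodness,
        penalty_terms={"tr(Ix Iy^-1)": p1, "d": float(d)},
        fit_ref=fit_y,
        n=n,
    )


def aic_yb(fit: FitResult, mats: InfoMatrices, data: Dataset) -> CriterionValue:
    """Observed-part criterion for the joint fit: -2n l_y(theta_b) + 2 tr(I_y I_b^{-1})."""
    n = data.n
    A = np.linalg.inv(mats.I_b)
    goodness = -2.0 * n * _mean_loglik_y(fit, data)
    p1 = 2.0 * float(np.trace(mats.I_y @ A))
    return CriterionValue(
        name="AIC_yb",
        value=goodness + p1,
        goodness_term=goodness,
        penalty_terms={"2tr(Iy Ib^-1)": p1},
        fit_ref=fit,
        n=n,
    )


def aic_yy(fit_y: FitResult, data: Dataset) -> CriterionValue:
    """Classical AIC of the y-only fit: -2n l_y(theta_y) + 2d."""
    _require(fit_y.objective == "y" and not fit_y.params.has_aux,
             "aic_yy needs the no-auxiliary fit")
    n = data.n
    goodness = -2.0 * n * fit_y.loglik_per_obs
    d = float(fit_y.params.d)
    return CriterionValue(
        name="AIC_yy",
        value=goodness + 2.0 * d,
        goodness_term=goodness,
        penalty_terms={"2d": 2.0 * d},
        fit_ref=fit_y,
        n=n,
    )


def tic(fit_y: FitResult, mats_y: InfoMatrices, data: Dataset) -> CriterionValue:
    """Takeuchi's criterion of the y-only fit: -2n l_y + 2 tr(I_y^{-1} J_y)."""
    _require(fit_y.objective == "y" and not fit_y.params.has_aux,
             "tic needs the no-auxiliary fit")
    n = data.n
    A = np.linalg.inv(mats_y.I_b)
    goodness = -2.0 * n * fit_y.loglik_per_obs
    p1 = 2.0 * float(np.trace(A @ mats_y.J_b))
    return CriterionValue(
        name="TIC",
        value=goodness + p1,
        goodness_term=goodness,
        penalty_terms={"2tr(Iy^-1 Jy)": p1},
        fit_ref=fit_y,
        n=n,
    )


def select(
    frame: pd.DataFrame,
    primary: str,
    aux_cols: list,
    criterion: str = "x",
    settings: Optional[EMSettings] = None,
    latent_col: Optional[str] = None,
) -> SelectionResult:
    """Compare the no-auxiliary model against one joint model per candidate.

    ``criterion="x"`` targets prediction of the complete primary vector
    (compares the joint-fit criterion against the latent-part criterion of
    the y-only fit); ``criterion="y"`` targets the observed part only.  Ties
    break toward the no-auxiliary model.  A candidate whose fit degenerates
    is excluded and recorded in ``failed``.
    """
    if criterion not in ("x", "y"):
        raise DataError("criterion must be 'x' or 'y'")
    if primary not in frame.columns:
        raise DataError(f"primary column {primary!r} not in table")
    for c in aux_cols:
        if c not in frame.columns:
            raise DataError(f"auxiliary column {c!r} not in table")
    settings = settings or EMSettings()

    y = frame[primary].to_numpy(dtype=float)
    data_y = Dataset(y=y)
    fit_y = fit_em(data_y, use_auxiliary=False, settings=settings)
    if criterion == "x":
        mats_y = estimate_all(fit_y, data_y, use_auxiliary=False)
        base = aic_xy(fit_y, mats_y, data_y)
        rule = "candidate selected only when AIC_xb < AIC_xy"
    else:
        base = aic_yy(fit_y, data_y)
        rule = "candidate selected only when AIC_yb < AIC_yy"

    candidates = [(NO_AUX_LABEL, base)]
    failed = {}
    for label in aux_cols:
        data_b = Dataset(y=y, a=frame[label].to_numpy(dtype=float))
        try:
            fit_b = fit_em(data_b, use_auxiliary=True, settings=settings)
            mats_b = estimate_all(fit_b, data_b, use_auxiliary=True)
            cv = (aic_xb if criterion == "x" else aic_yb)(fit_b, mats_b, data_b)
        except AuxselError as exc:
            logger.warning("candidate %s failed: %s", label, exc)
            failed[label] = str(exc)
            continue
        candidates.append((label, cv))

    best_label, best_value = NO_AUX_LABEL, base.value
    for label, cv in candidates[1:]:
        if cv.value < best_value:  # strict: ties keep the no-auxiliary model
            best_label, best_value = label, cv.value
    return SelectionResult(
        candidates=candidates,
        best_label=best_label,
        decision_rule=rule,
        failed=failed,
    )
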