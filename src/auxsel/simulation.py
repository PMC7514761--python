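"""Generative truth, exact risk evaluation, and the replicated experiments.

The truth is a two-component mixture with label probability 0.6, component
means -/+ 1.2 and shared variance 0.7 for y.  Two auxiliary regimes:

* case1 — a depends on the label (means +/- 1.8, variance 0.49): informative;
* case2 — a is drawn from the same marginal mixture but independently of
  (y, z): pure noise with an identical marginal.

The two cases share one (y, z) stream per replicate (paired generation), so
quantities depending only on the y-fit coincide across cases.

Losses against the truth are evaluated by Gauss–Hermite quadrature; the
complete-data loss takes the minimum over the two component-label
assignments of the fitted parameters, since mixture labels are not
identifiable from the observed data.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import roots_hermite

from .criteria import aic_xb, aic_xy
from .errors import AuxselError, DataError, EvaluationError
from .info_matrices import estimate_all
from .models import Dataset, EMSettings, GMM2Params, fit_em, logdensity_x, logdensity_y

__all__ = [
    "TrueModel",
    "ExperimentConfig",
    "generate",
    "generate_paired",
    "true_loss_x",
    "true_loss_y",
    "run_replicates",
    "run_bias_experiment",
    "run_selection_experiment",
]

logger = logging.getLogger(__name__)

CASES = ("case1", "case2")


@dataclass(frozen=True)
class TrueModel:
    """Constants of the generative truth."""

    case_id: str = "case1"
    pi1: float = 0.6
    mu1y: float = -1.2
    mu2y: float = 1.2
    sigma_y2: float = 0.7
    mu1a: float = 1.8
    mu2a: float = -1.8
    sigma_a2: float = 0.49

    def __post_init__(self):
        if self.case_id not in CASES:
            raise DataError(f"case_id must be one of {CASES}")

    @property
    def theta0(self) -> GMM2Params:
        return GMM2Params(self.pi1, self.mu1y, self.mu2y, self.sigma_y2)

    @property
    def beta0(self) -> GMM2Params:
        """Full joint parameter; the truth for case1 (a independent of y given z)."""
        return GMM2Params(
            self.pi1, self.mu1y, self.mu2y, self.sigma_y2,
            self.mu1a, self.mu2a, self.sigma_a2, 0.0,
        )


@dataclass
class ExperimentConfig:
    """Replicated-experiment configuration.

    Reduced default scale (T=2000, n=100); the full published scale is
    T=10^4 with n up to 5000.
    """

    n_per_dataset: tuple = (100,)
    n_replicates: int = 2000
    seed: int = 0
    cases: tuple = CASES
    em: EMSettings = field(default_factory=lambda: EMSettings(tol=1e-8, max_iter=500))
    quad_nodes: int = 64
    n_jobs: int = 1

    def __post_init__(self):
        if self.n_replicates < 1:
            raise DataError("n_replicates must be >= 1")
        if self.seed is None:
            raise DataError("seed is mandatory")


def generate_paired(n: int, rng: np.random.Generator):
    """One replicate of (y, z, a1, a2): a1 label-linked, a2 independent noise."""
    z = (rng.random(n) < 0.6).astype(int)
    y = np.where(z == 1, -1.2, 1.2) + np.sqrt(0.7) * rng.standard_normal(n)
    a1 = np.where(z == 1, 1.8, -1.8) + 0.7 * rng.standard_normal(n)
    z2 = (rng.random(n) < 0.6).astype(int)
    a2 = np.where(z2 == 1, 1.8, -1.8) + 0.7 * rng.standard_normal(n)
    return y, z, a1, a2


def generate(case_id: str, n: int, seed) -> Dataset:
    """A dataset (y, a, z) from one case; z is kept for evaluation only."""
    if case_id not in CASES:
        raise DataError(f"unknown case {case_id!r}")
    if n < 1:
        raise DataError("n must be >= 1")
    rng = np.random.default_rng(seed)
    y, z, a1, a2 = generate_paired(n, rng)
    return Dataset(y=y, a=a1 if case_id == "case1" else a2, z=z)


# ---------------------------------------------------------------------------
# True losses by Gauss–Hermite quadrature
# ---------------------------------------------------------------------------

def _gh_expect(fun, mean, var, n_nodes):
    """E[fun(Y)] for Y ~ N(mean, var) by Gauss–Hermite quadrature."""
    t, w = roots_hermite(n_nodes)
    ys = mean + np.sqrt(2.0 * var) * t
    return float(w @ fun(ys) / np.sqrt(np.pi))


def _loss_x_one(theta: GMM2Params, truth: TrueModel, n_nodes: int) -> float:
    val = 0.0
    for z, qz, m in ((1, truth.pi1, truth.mu1y), (0, 1.0 - truth.pi1, truth.mu2y)):
        val -= qz * _gh_expect(
            lambda ys: logdensity_x(theta, ys, np.full(ys.shape, z)),
            m, truth.sigma_y2, n_nodes,
        )
    return val


def true_loss_x(
    theta: GMM2Params,
    truth: TrueModel = TrueModel(),
    n_nodes: int = 64,
    align: bool = True,
) -> float:
    """Expected complete-data negative log-density -E_q[log p(y, z; theta)].

    With ``align`` (the default) the minimum over the two component-label
    assignments is returned, resolving mixture label switching.
    """
    v1 = _loss_x_one(theta.theta(), truth, n_nodes)
    if not align:
        _check_finite(v1)
        return v1
    v2 = _loss_x_one(theta.theta().swapped(), truth, n_nodes)
    out = min(v1, v2)
    _check_finite(out)
    return out


def true_loss_y(
    theta: GMM2Params, truth: TrueModel = TrueModel(), n_nodes: int = 64
) -> float:
    """Expected observed-data negative log-density -E_q[log p(y; theta)]."""
    th = theta.theta()
    val = 0.0
    for qz, m in ((truth.pi1, truth.mu1y), (1.0 - truth.pi1, truth.mu2y)):
        val -= qz * _gh_expect(lambda ys: logdensity_y(th, ys), m, truth.sigma_y2, n_nodes)
    _check_finite(val)
    return val


def _check_finite(v: float) -> None:
    if not np.isfinite(v):
        raise EvaluationError(f"loss quadrature returned {v}")


# ---------------------------------------------------------------------------
# Replicated experiments
# ---------------------------------------------------------------------------

def _one_replicate(n, rep_ss, config: ExperimentConfig, truth: TrueModel):
    """Rows (one per case) of per-replicate criteria and losses."""
    rng = np.random.default_rng(rep_ss)
    em_seed = int(rep_ss.generate_state(1)[0])
    em = dataclasses.replace(config.em, seed=em_seed)
    y, z, a1, a2 = generate_paired(n, rng)

    data_y = Dataset(y=y)
    fit_y = fit_em(data_y, use_auxiliary=False, settings=em)
    mats_y = estimate_all(fit_y, data_y, use_auxiliary=False)
    cv_xy = aic_xy(fit_y, mats_y, data_y)
    lx_y = true_loss_x(fit_y.params, truth, config.quad_nodes)

    rows = []
    for case, a in (("case1", a1), ("case2", a2)):
        if case not in config.cases:
            continue
        data_b = Dataset(y=y, a=a)
        fit_b = fit_em(data_b, use_auxiliary=True, settings=em)
        mats_b = estimate_all(fit_b, data_b, use_auxiliary=True)
        cv_xb = aic_xb(fit_b, mats_b, data_b)
        lx_b = true_loss_x(fit_b.params, truth, config.quad_nodes)
        sel_b = cv_xb.value < cv_xy.value
        rows.append(
            {
                "n": n,
                "case": case,
                "aic_xb": cv_xb.value,
                "aic_xy": cv_xy.value,
                "d_aic": cv_xb.value - cv_xy.value,
                "sel_b": bool(sel_b),
                "lx_b": lx_b,
                "lx_y": lx_y,
                "lx_best": lx_b if sel_b else lx_y,
            }
        )
    return rows


def run_replicates(config: ExperimentConfig) -> pd.DataFrame:
    """Per-replicate criteria and losses for every (n, case) in the config.

    One master seed drives independent per-replicate substreams, so results
    are reproducible bit-for-bit regardless of execution order.  Replicates
    where a fit degenerates (rare) are recorded with NaNs and logged.
    """
    truth = TrueModel()
    master = np.random.SeedSequence(config.seed)
    per_n = master.spawn(len(config.n_per_dataset))
    all_rows = []
    for n, n_ss in zip(config.n_per_dataset, per_n):
        rep_seeds = n_ss.spawn(config.n_replicates)
        for rep, rep_ss in enumerate(rep_seeds):
            try:
                rows = _one_replicate(n, rep_ss, config, truth)
            except AuxselError as exc:
                logger.warning("replicate %d (n=%d) failed: %s", rep, n, exc)
                rows = [
                    {"n": n, "case": c, "aic_xb": np.nan, "aic_xy": np.nan,
                     "d_aic": np.nan, "sel_b": None, "lx_b": np.nan,
                     "lx_y": np.nan, "lx_best": np.nan}
                    for c in config.cases
                ]
            for r in rows:
                r["rep"] = rep
            all_rows.extend(rows)
    return pd.DataFrame(all_rows)


def _mean_se(x: np.ndarray):
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    return float(x.mean()), float(x.std(ddof=1) / np.sqrt(x.size)), x.size


def summarize_bias(df: pd.DataFrame, case: str = "case1") -> pd.DataFrame:
    """Per n: mean/SE of the criterion difference and of 2n times the loss difference."""
    rows = []
    sub_all = df[df["case"] == case]
    for n, sub in sub_all.groupby("n"):
        m_aic, se_aic, t_used = _mean_se(sub["d_aic"])
        dl = 2.0 * n * (sub["lx_b"] - sub["lx_y"])
        m_risk, se_risk, _ = _mean_se(dl)
        rows.append(
            {"n": n, "mean_d_aic": m_aic, "se_d_aic": se_aic,
             "mean_2n_d_risk": m_risk, "se_2n_d_risk": se_risk, "T": t_used}
        )
    return pd.DataFrame(rows)


def summarize_selection(df: pd.DataFrame, lx0: float) -> dict:
    """Selection counts and excess-risk tables per case and n.

    Risks are reported as 2n (mean loss - lx0), with lx0 the loss of the true
    parameters, plus standard errors; counts are scaled to a per-10^4 basis.
    """
    count_rows, risk_rows = [], []
    for (case, n), sub in df.groupby(["case", "n"]):
        ok = sub[sub["sel_b"].notna()]
        T = len(ok)
        n_sel_b = int(ok["sel_b"].sum())
        count_rows.append(
            {"case": case, "n": n, "T": T, "sel_b": n_sel_b, "sel_y": T - n_sel_b,
             "sel_b_per_1e4": 1e4 * n_sel_b / T, "sel_y_per_1e4": 1e4 * (T - n_sel_b) / T}
        )
        row = {"case": case, "n": n, "T": T}
        for est in ("b", "y", "best"):
            excess = 2.0 * n * (ok[f"lx_{est}"] - lx0)
            m, se, _ = _mean_se(excess)
            row[f"risk_{est}"] = m
            row[f"se_{est}"] = se
        risk_rows.append(row)
    return {"counts": pd.DataFrame(count_rows), "risks": pd.DataFrame(risk_rows)}


def run_bias_experiment(config: Optional[ExperimentConfig] = None) -> pd.DataFrame:
    """Unbiasedness check: E[criterion difference] vs 2n times the risk difference."""
    config = config or ExperimentConfig(cases=("case1",))
    return summarize_bias(run_replicates(config))


def run_selection_experiment(config: Optional[ExperimentConfig] = None) -> dict:
    """Selection frequencies and excess risks of the three estimators."""
    config = config or ExperimentConfig()
    df = run_replicates(config)
    lx0 = true_loss_x(TrueModel().theta0, n_nodes=config.quad_nodes, align=False)
    out = summarize_selection(df, lx0)
    out["lx0"] = lx0
    out["replicates"] = df
    return out
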