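"""Empirical information matrices for the mixture criteria.

All matrices live in a common frame over the flattened parameter vector
``beta = (theta, phi)`` — ``(d+f) x (d+f)`` for the joint model, ``d x d``
when no auxiliary variable is used.  Six matrices are estimated at a fit's
own MLE:

* ``I_b``  — minus the average Hessian of the observable-data log-density;
* ``J_b``  — the average outer product of its score;
* ``I_y``  — minus the average Hessian of the y-marginal log-density
  (phi rows/columns are zero);
* ``I_x``  — minus the average Hessian of the complete-data log-density,
  with the latent label integrated out under the fitted posterior;
* ``I_zy`` — ``I_x - I_y`` (information of the latent part given y);
* ``K_by`` — average cross product of the observable score and the
  y-marginal score (phi columns are zero).

Derivatives come from analytic per-observation scores; Hessians are
complex-step derivatives of those scores (machine-precision, no subtractive
cancellation).  A central finite-difference engine over the raw
log-densities is kept as an independent cross-check surface.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BoundaryDerivativeError, DataError, SingularInformationError
from .models import (
    Dataset,
    FitResult,
    GMM2Params,
    logdensity_joint,
    logdensity_x,
    logdensity_y,
    posterior_z,
)

__all__ = [
    "InfoMatrices",
    "grad_loglik",
    "score_b",
    "score_y",
    "score_x",
    "estimate_all",
]

_FD_STEP = float(np.cbrt(np.finfo(float).eps))  # ~6.06e-6
_CS_STEP = 1e-100
_COND_LIMIT = 1e12
_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class InfoMatrices:
    """The six empirical matrices evaluated at one MLE."""

    I_b: np.ndarray
    J_b: np.ndarray
    I_x: np.ndarray
    I_y: np.ndarray
    I_zy: np.ndarray
    K_by: np.ndarray
    eval_point: GMM2Params
    n: int

    @property
    def dim(self) -> int:
        return self.I_b.shape[0]

    def to_frame(self, which: str) -> pd.DataFrame:
        """One matrix as a labeled DataFrame for text export."""
        mat = getattr(self, which)
        names = list(self.eval_point.names)
        return pd.DataFrame(mat, index=names, columns=names)

    def export(self, path) -> None:
        """Write all six matrices to one delimited text file."""
        frames = []
        for which in ("I_b", "J_b", "I_x", "I_y", "I_zy", "K_by"):
            df = self.to_frame(which)
            df.insert(0, "matrix", which)
            frames.append(df.reset_index(names="row"))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Analytic per-observation scores (complex-step safe)
# ---------------------------------------------------------------------------

def _stable_expit(t):
    """1 / (1 + exp(-t)), elementwise, safe for complex dtype with large |Re t|."""
    t = np.asarray(t)
    out = np.empty_like(t)
    pos = t.real >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-t[pos]))
    e = np.exp(t[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _score_b_vec(beta: np.ndarray, Y: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Per-observation gradient of log p(y,a;beta); returns (n, 8).

    Works on complex ``beta`` for complex-step differentiation.
    """
    pi1, mu1y, mu2y, sy, mu1a, mu2a, sa, sya = beta
    det = sy * sa - sya**2
    # inverse covariance entries
    iyy, iaa, iya = sa / det, sy / det, -sya / det
    d1y, d1a = Y - mu1y, A - mu1a
    d2y, d2a = Y - mu2y, A - mu2a
    q1 = iyy * d1y**2 + 2.0 * iya * d1y * d1a + iaa * d1a**2
    q2 = iyy * d2y**2 + 2.0 * iya * d2y * d2a + iaa * d2a**2
    logphi1 = -_LOG_2PI - 0.5 * np.log(det) - 0.5 * q1
    logphi2 = -_LOG_2PI - 0.5 * np.log(det) - 0.5 * q2
    t = np.log(pi1) + logphi1 - np.log(1.0 - pi1) - logphi2
    r1 = _stable_expit(t)
    r2 = 1.0 - r1
    # Sigma^{-1} (b - mu_k)
    u1y = iyy * d1y + iya * d1a
    u1a = iya * d1y + iaa * d1a
    u2y = iyy * d2y + iya * d2a
    u2a = iya * d2y + iaa * d2a
    # d log phi_k / d Sigma as a full symmetric-matrix derivative M_k
    m1_yy = 0.5 * (u1y * u1y - iyy)
    m1_aa = 0.5 * (u1a * u1a - iaa)
    m1_ya = 0.5 * (u1y * u1a - iya)
    m2_yy = 0.5 * (u2y * u2y - iyy)
    m2_aa = 0.5 * (u2a * u2a - iaa)
    m2_ya = 0.5 * (u2y * u2a - iya)
    g = np.empty((Y.size, 8), dtype=np.result_type(beta, Y))
    g[:, 0] = r1 / pi1 - r2 / (1.0 - pi1)
    g[:, 1] = r1 * u1y
    g[:, 2] = r2 * u2y
    g[:, 3] = r1 * m1_yy + r2 * m2_yy
    g[:, 4] = r1 * u1a
    g[:, 5] = r2 * u2a
    g[:, 6] = r1 * m1_aa + r2 * m2_aa
    g[:, 7] = 2.0 * (r1 * m1_ya + r2 * m2_ya)
    return g


def _score_y_vec(theta: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Per-observation gradient of log p(y;theta); returns (n, 4)."""
    pi1, mu1y, mu2y, sy = theta[:4]
    d1, d2 = Y - mu1y, Y - mu2y
    logphi1 = -0.5 * (_LOG_2PI + np.log(sy) + d1**2 / sy)
    logphi2 = -0.5 * (_LOG_2PI + np.log(sy) + d2**2 / sy)
    t = np.log(pi1) + logphi1 - np.log(1.0 - pi1) - logphi2
    r1 = _stable_expit(t)
    r2 = 1.0 - r1
    g = np.empty((Y.size, 4), dtype=np.result_type(theta, Y))
    g[:, 0] = r1 / pi1 - r2 / (1.0 - pi1)
    g[:, 1] = r1 * d1 / sy
    g[:, 2] = r2 * d2 / sy
    g[:, 3] = r1 * (d1**2 / (2.0 * sy**2) - 0.5 / sy) + r2 * (
        d2**2 / (2.0 * sy**2) - 0.5 / sy
    )
    return g


def _score_x_vec(theta: np.ndarray, Y: np.ndarray, z: float) -> np.ndarray:
    """Per-observation gradient of log p(y,z;theta) at a fixed label z."""
    pi1, mu1y, mu2y, sy = theta[:4]
    d1, d2 = Y - mu1y, Y - mu2y
    g = np.zeros((Y.size, 4), dtype=np.result_type(theta, Y))
    if z == 1:
        g[:, 0] = 1.0 / pi1
        g[:, 1] = d1 / sy
        g[:, 3] = d1**2 / (2.0 * sy**2) - 0.5 / sy
    else:
        g[:, 0] = -1.0 / (1.0 - pi1)
        g[:, 2] = d2 / sy
        g[:, 3] = d2**2 / (2.0 * sy**2) - 0.5 / sy
    return g


def _pad(mat_or_scores: np.ndarray, dim: int) -> np.ndarray:
    """Zero-pad a theta-block array (rows x 4 or 4 x 4) into the full frame."""
    if mat_or_scores.ndim == 2 and mat_or_scores.shape == (4, 4) and dim > 4:
        out = np.zeros((dim, dim))
        out[:4, :4] = mat_or_scores
        return out
    if mat_or_scores.shape[1] < dim:
        out = np.zeros((mat_or_scores.shape[0], dim), dtype=mat_or_scores.dtype)
        out[:, : mat_or_scores.shape[1]] = mat_or_scores
        return out
    return mat_or_scores


def score_b(params: GMM2Params, y, a) -> np.ndarray:
    """Analytic observable-data score, (n, d+f)."""
    return np.real(
        _score_b_vec(params.to_vector(), np.atleast_1d(np.asarray(y, float)),
                     np.atleast_1d(np.asarray(a, float)))
    )


def score_y(params: GMM2Params, y, pad_to: int | None = None) -> np.ndarray:
    """Analytic y-marginal score in the theta block, optionally zero-padded."""
    g = np.real(_score_y_vec(params.to_vector()[:4], np.atleast_1d(np.asarray(y, float))))
    return _pad(g, pad_to) if pad_to else g


def score_x(params: GMM2Params, y, z, pad_to: int | None = None) -> np.ndarray:
    """Analytic complete-data score at fixed z in {0, 1}."""
    if z not in (0, 1):
        raise DataError("z must be 0 or 1")
    g = np.real(_score_x_vec(params.to_vector()[:4], np.atleast_1d(np.asarray(y, float)), z))
    return _pad(g, pad_to) if pad_to else g


# ---------------------------------------------------------------------------
# Finite-difference engine (independent cross-check of the analytic scores)
# ---------------------------------------------------------------------------

def _perturbed(params: GMM2Params, j: int, delta: float) -> GMM2Params:
    vec = params.to_vector()
    vec[j] += delta
    return GMM2Params.from_vector(vec)


def _fd_step(params: GMM2Params, j: int) -> float:
    """Central-difference step for coordinate j, shrunk at parameter boundaries."""
    vec = params.to_vector()
    h = _FD_STEP * max(1.0, abs(vec[j]))
    for _ in range(60):
        try:
            _perturbed(params, j, h).validate()
            _perturbed(params, j, -h).validate()
            return h
        except Exception:
            h *= 0.5
        if h < 1e-300:
            break
    raise BoundaryDerivativeError(
        f"cannot take a central step in coordinate {params.names[j]}"
    )


def grad_loglik(density_kind: str, params: GMM2Params, observation) -> np.ndarray:
    """Central finite-difference gradient of one log-density at one observation.

    ``density_kind`` is one of ``"b"`` (observation ``(y, a)``), ``"y"``
    (observation ``y``), ``"x"`` (observation ``(y, z)``) or ``"x-weighted"``
    (observation ``y``; the two fixed-label gradients mixed under the fitted
    posterior).  Length of the result is ``d + f`` of ``params``.
    """
    if density_kind == "b":
        y, a = observation
        fun = lambda p: logdensity_joint(p, y, a)
    elif density_kind == "y":
        fun = lambda p: logdensity_y(p, observation)
    elif density_kind == "x":
        y, z = observation
        fun = lambda p: logdensity_x(p, y, z)
    elif density_kind == "x-weighted":
        y = observation
        w = posterior_z(params, y)
        fun = lambda p: w[0] * logdensity_x(p, y, 1) + w[1] * logdensity_x(p, y, 0)
    else:
        raise ValueError(f"unknown density_kind {density_kind!r}")
    p_tot = params.n_params
    g = np.empty(p_tot)
    for j in range(p_tot):
        h = _fd_step(params, j)
        g[j] = (fun(_perturbed(params, j, h)) - fun(_perturbed(params, j, -h))) / (2.0 * h)
    return g


# ---------------------------------------------------------------------------
# Complex-step Hessians and the matrix estimator
# ---------------------------------------------------------------------------

def _avg_hessian_cs(score_fn, vec: np.ndarray, weights: np.ndarray | None = None):
    """Sample-average Hessian via complex-step differentiation of a score.

    ``score_fn(vec)`` must return the per-observation gradients (n, p) and
    accept a complex parameter vector.  Optional per-observation ``weights``
    average with those weights (used for the posterior-weighted complete-data
    Hessian); they must sum to n over the effective sample.
    """
    p = vec.size
    H = np.empty((p, p))
    base = vec.astype(complex)
    for j in range(p):
        pert = base.copy()
        pert[j] += 1j * _CS_STEP
        s = score_fn(pert)
        col = s.imag / _CS_STEP
        if weights is None:
            H[:, j] = col.mean(axis=0)
        else:
            H[:, j] = (weights[:, None] * col).sum(axis=0) / weights.sum()
    return 0.5 * (H + H.T)


def estimate_all(fit: FitResult, data: Dataset, use_auxiliary: bool) -> InfoMatrices:
    """Estimate the six matrices at the fit's MLE on its own sample.

    The latent expectation inside ``I_x`` uses the posterior of z given y at
    the fitted theta.  Raises :class:`SingularInformationError` when ``I_b``
    has condition number above 1e12.  With ``use_auxiliary=False`` the frame
    is ``d x d`` and ``I_b`` coincides with ``I_y``.
    """
    params = fit.params
    Y = data.y
    n = data.n
    theta = params.to_vector()[:4]

    if use_auxiliary:
        if not params.has_aux or data.a is None:
            raise DataError("use_auxiliary=True needs a joint fit and auxiliary data")
        A = data.a
        beta = params.to_vector()
        dim = beta.size
        Sb = np.real(_score_b_vec(beta, Y, A))
        J_b = Sb.T @ Sb / n
        I_b = -_avg_hessian_cs(lambda v: _score_b_vec(v, Y, A), beta)
        Sy = _pad(np.real(_score_y_vec(theta, Y)), dim)
        K_by = Sb.T @ Sy / n
        I_y = _pad(-_avg_hessian_cs(lambda v: _score_y_vec(v, Y), theta), dim)
    else:
        dim = 4
        Sy = np.real(_score_y_vec(theta, Y))
        J_b = Sy.T @ Sy / n
        I_b = -_avg_hessian_cs(lambda v: _score_y_vec(v, Y), theta)
        K_by = J_b.copy()
        I_y = I_b.copy()

    w = posterior_z(params.theta(), Y)  # columns [P(z=1|y), P(z=0|y)]
    H1 = _avg_hessian_cs(lambda v: _score_x_vec(v, Y, 1), theta, weights=w[:, 0])
    H0 = _avg_hessian_cs(lambda v: _score_x_vec(v, Y, 0), theta, weights=w[:, 1])
    w1bar = w[:, 0].mean()
    I_x = _pad(-(w1bar * H1 + (1.0 - w1bar) * H0), dim)
    I_zy = I_x - I_y

    cond = np.linalg.cond(I_b)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        raise SingularInformationError(cond)
    return InfoMatrices(
        I_b=I_b, J_b=J_b, I_x=I_x, I_y=I_y, I_zy=I_zy, K_by=K_by,
        eval_point=params, n=n,
    )
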