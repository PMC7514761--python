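"""Two-component Gaussian mixture candidate models with a latent label.

The latent structure is a binary label ``z`` with mixing weight ``pi1`` for
``z = 1``.  Two candidate models share the label model:

* the observed-data model of the primary variable ``y`` alone — a univariate
  two-component normal mixture with a variance shared across components
  (``d = 4`` free parameters), and
* the joint model of the observables ``b = (y, a)`` including one auxiliary
  variable ``a`` — a bivariate two-component normal mixture with a shared
  2x2 covariance (``d + f = 8`` free parameters).

Both are estimated by EM with multiple restarts; a closed-form complete-data
fit (labels observed) is provided for oracle comparisons.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import DataError, FitDegenerateError, InvalidParameterError

__all__ = [
    "Dataset",
    "GMM2Params",
    "EMSettings",
    "FitResult",
    "logdensity_joint",
    "logdensity_y",
    "logdensity_x",
    "posterior_z",
    "fit_em",
    "fit_complete",
]

_LOG_2PI = float(np.log(2.0 * np.pi))

# Flattening order of the parameter vector: theta then phi.
THETA_NAMES = ("pi1", "mu1y", "mu2y", "sigma_y2")
PHI_NAMES = ("mu1a", "mu2a", "sigma_a2", "sigma_ya")
D_THETA = 4
F_PHI = 4


@dataclass(frozen=True)
class Dataset:
    """Observed sample: primary ``y``, optional auxiliary ``a``, optional labels ``z``.

    ``z`` is used only for evaluation / oracle fits, never by the EM fits.
    """

    y: np.ndarray
    a: Optional[np.ndarray] = None
    z: Optional[np.ndarray] = None

    def __post_init__(self):
        y = np.asarray(self.y, dtype=float)
        if y.ndim != 1 or y.size < 1:
            raise DataError("y must be a non-empty 1-d sequence")
        object.__setattr__(self, "y", y)
        if self.a is not None:
            a = np.asarray(self.a, dtype=float)
            if a.shape != y.shape:
                raise DataError(f"a has length {a.size}, expected {y.size}")
            object.__setattr__(self, "a", a)
        if self.z is not None:
            z = np.asarray(self.z)
            if z.shape != y.shape:
                raise DataError(f"z has length {z.size}, expected {y.size}")
            zf = z.astype(float)
            if not np.all(np.isin(zf, (0.0, 1.0))):
                raise DataError("z must contain only 0/1 labels")
            object.__setattr__(self, "z", zf.astype(int))

    @property
    def n(self) -> int:
        return self.y.size

    def drop(self, i: int) -> "Dataset":
        """Return a copy with observation ``i`` removed (for leave-one-out)."""
        keep = np.ones(self.n, dtype=bool)
        keep[i] = False
        return Dataset(
            y=self.y[keep],
            a=None if self.a is None else self.a[keep],
            z=None if self.z is None else self.z[keep],
        )


@dataclass(frozen=True)
class GMM2Params:
    """Parameters of the two-component mixture.

    ``theta = (pi1, mu1y, mu2y, sigma_y2)`` is the primary-variable part
    (component 1 corresponds to ``z = 1``); ``phi = (mu1a, mu2a, sigma_a2,
    sigma_ya)`` extends it to the joint model of ``(y, a)`` and is absent for
    the y-only model.  The flattened vector order is theta followed by phi.
    """

    pi1: float
    mu1y: float
    mu2y: float
    sigma_y2: float
    mu1a: Optional[float] = None
    mu2a: Optional[float] = None
    sigma_a2: Optional[float] = None
    sigma_ya: Optional[float] = None

    def __post_init__(self):
        aux = [self.mu1a, self.mu2a, self.sigma_a2, self.sigma_ya]
        n_set = sum(v is not None for v in aux)
        if n_set not in (0, len(aux)):
            raise InvalidParameterError(
                "auxiliary fields must be all present or all absent"
            )
        self.validate()

    def validate(self) -> None:
        if not (0.0 < self.pi1 < 1.0):
            raise InvalidParameterError(f"pi1 must be in (0,1), got {self.pi1}")
        if not (self.sigma_y2 > 0.0 and np.isfinite(self.sigma_y2)):
            raise InvalidParameterError(f"sigma_y2 must be > 0, got {self.sigma_y2}")
        if self.has_aux:
            det = self.sigma_y2 * self.sigma_a2 - self.sigma_ya**2
            if not (self.sigma_a2 > 0.0 and det > 0.0):
                raise InvalidParameterError(
                    "covariance [[sigma_y2, sigma_ya], [sigma_ya, sigma_a2]] "
                    f"is not positive definite (det={det})"
                )

    @property
    def has_aux(self) -> bool:
        return self.mu1a is not None

    @property
    def d(self) -> int:
        return D_THETA

    @property
    def f(self) -> int:
        return F_PHI if self.has_aux else 0

    @property
    def n_params(self) -> int:
        return self.d + self.f

    @property
    def names(self) -> tuple:
        return THETA_NAMES + PHI_NAMES if self.has_aux else THETA_NAMES

    @property
    def cov(self) -> np.ndarray:
        """Shared 2x2 covariance of (y, a); joint model only."""
        if not self.has_aux:
            raise InvalidParameterError("no auxiliary fields: covariance is scalar sigma_y2")
        return np.array(
            [[self.sigma_y2, self.sigma_ya], [self.sigma_ya, self.sigma_a2]]
        )

    def theta(self) -> "GMM2Params":
        """The primary-variable part, dropping phi."""
        return GMM2Params(self.pi1, self.mu1y, self.mu2y, self.sigma_y2)

    def swapped(self) -> "GMM2Params":
        """Exchange the two component labels."""
        if self.has_aux:
            return GMM2Params(
                1.0 - self.pi1, self.mu2y, self.mu1y, self.sigma_y2,
                self.mu2a, self.mu1a, self.sigma_a2, self.sigma_ya,
            )
        return GMM2Params(1.0 - self.pi1, self.mu2y, self.mu1y, self.sigma_y2)

    def to_vector(self) -> np.ndarray:
        vals = [self.pi1, self.mu1y, self.mu2y, self.sigma_y2]
        if self.has_aux:
            vals += [self.mu1a, self.mu2a, self.sigma_a2, self.sigma_ya]
        return np.array(vals, dtype=float)

    @classmethod
    def from_vector(cls, vec: Sequence[float]) -> "GMM2Params":
        vec = np.asarray(vec, dtype=float)
        if vec.size == D_THETA:
            return cls(*vec)
        if vec.size == D_THETA + F_PHI:
            return cls(*vec)
        raise InvalidParameterError(f"parameter vector must have 4 or 8 entries, got {vec.size}")


# ---------------------------------------------------------------------------
# Log-densities
# ---------------------------------------------------------------------------

def _log_normal(y, mu, var):
    return -0.5 * (_LOG_2PI + np.log(var) + (y - mu) ** 2 / var)


def _log_binormal(y, a, muy, mua, params: GMM2Params):
    sy, sa, sya = params.sigma_y2, params.sigma_a2, params.sigma_ya
    det = sy * sa - sya**2
    dy = y - muy
    da = a - mua
    quad = (sa * dy**2 - 2.0 * sya * dy * da + sy * da**2) / det
    return -_LOG_2PI - 0.5 * np.log(det) - 0.5 * quad


def logdensity_joint(params: GMM2Params, y, a):
    """log p(y, a; beta) of the bivariate two-component mixture."""
    if not params.has_aux:
        raise InvalidParameterError("logdensity_joint requires auxiliary fields")
    params.validate()
    y = np.asarray(y, dtype=float)
    a = np.asarray(a, dtype=float)
    t1 = np.log(params.pi1) + _log_binormal(y, a, params.mu1y, params.mu1a, params)
    t2 = np.log1p(-params.pi1) + _log_binormal(y, a, params.mu2y, params.mu2a, params)
    out = logsumexp(np.stack([t1, t2], axis=0), axis=0)
    return float(out) if out.ndim == 0 else out


def logdensity_y(params: GMM2Params, y):
    """log p(y; theta) of the univariate mixture (phi fields ignored)."""
    params.validate()
    y = np.asarray(y, dtype=float)
    t1 = np.log(params.pi1) + _log_normal(y, params.mu1y, params.sigma_y2)
    t2 = np.log1p(-params.pi1) + _log_normal(y, params.mu2y, params.sigma_y2)
    out = logsumexp(np.stack([t1, t2], axis=0), axis=0)
    return float(out) if out.ndim == 0 else out


def logdensity_x(params: GMM2Params, y, z):
    """log p(y, z; theta) for the complete primary vector x = (y, z)."""
    params.validate()
    y = np.asarray(y, dtype=float)
    z = np.asarray(z)
    if not np.all(np.isin(z.astype(float), (0.0, 1.0))):
        raise DataError("z must be 0 or 1")
    z = z.astype(float)
    t1 = np.log(params.pi1) + _log_normal(y, params.mu1y, params.sigma_y2)
    t2 = np.log1p(-params.pi1) + _log_normal(y, params.mu2y, params.sigma_y2)
    out = z * t1 + (1.0 - z) * t2
    return float(out) if out.ndim == 0 else out


def posterior_z(params: GMM2Params, y, a=None) -> np.ndarray:
    """Posterior probabilities of the latent label given the observables.

    Returns an array whose last axis has two entries ``[P(z=1|.), P(z=0|.)]``;
    conditions on ``(y, a)`` under the joint model when ``a`` is given, on
    ``y`` alone otherwise.
    """
    params.validate()
    y = np.asarray(y, dtype=float)
    if a is None:
        t1 = np.log(params.pi1) + _log_normal(y, params.mu1y, params.sigma_y2)
        t2 = np.log1p(-params.pi1) + _log_normal(y, params.mu2y, params.sigma_y2)
    else:
        if not params.has_aux:
            raise InvalidParameterError("posterior given (y, a) requires auxiliary fields")
        a = np.asarray(a, dtype=float)
        t1 = np.log(params.pi1) + _log_binormal(y, a, params.mu1y, params.mu1a, params)
        t2 = np.log1p(-params.pi1) + _log_binormal(y, a, params.mu2y, params.mu2a, params)
    stacked = np.stack([t1, t2], axis=-1)
    out = np.exp(stacked - logsumexp(stacked, axis=-1, keepdims=True))
    return out


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

@dataclass
class EMSettings:
    """Fitting configuration for :func:`fit_em`.

    ``tol`` is the relative change in average log-likelihood declaring
    convergence; ``variance_floor`` is the smallest admissible eigenvalue of
    the shared covariance (a restart hitting it is discarded as degenerate).
    """

    tol: float = 1e-10
    max_iter: int = 2000
    n_restarts: int = 5
    variance_floor: float = 1e-8
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "EMSettings":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise DataError(f"unknown EM settings: {sorted(unknown)}")
        return cls(**d)


@dataclass
class FitResult:
    """An MLE with its diagnostics.

    ``objective`` records which likelihood was maximized: ``"b"`` for the
    joint observables (y, a), ``"y"`` for the marginal, ``"x"`` for the
    complete-data fit.  ``loglik_per_obs`` is the maximized average
    log-likelihood of that objective.  ``responsibilities`` holds the
    posterior label probabilities at the fitted parameters, columns
    ``[P(z=1|.), P(z=0|.)]``.
    """

    params: GMM2Params
    loglik_per_obs: float
    responsibilities: np.ndarray
    n_iter: int
    converged: bool
    n_restarts_used: int
    best_restart_logliks: list = field(default_factory=list)
    objective: str = "b"
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))


def _eig_min_2x2(sy, sa, sya):
    tr = 0.5 * (sy + sa)
    disc = np.sqrt(max(0.25 * (sy - sa) ** 2 + sya**2, 0.0))
    return tr - disc


def _estep_joint(B, p: GMM2Params):
    t1 = np.log(p.pi1) + _log_binormal(B[:, 0], B[:, 1], p.mu1y, p.mu1a, p)
    t2 = np.log1p(-p.pi1) + _log_binormal(B[:, 0], B[:, 1], p.mu2y, p.mu2a, p)
    m = np.maximum(t1, t2)
    lse = m + np.log(np.exp(t1 - m) + np.exp(t2 - m))
    return np.exp(t1 - lse), float(lse.mean())


def _mstep_joint(B, r):
    n = B.shape[0]
    w1 = r.sum()
    w2 = n - w1
    mu1 = r @ B / w1
    mu2 = (1.0 - r) @ B / w2
    d1 = B - mu1
    d2 = B - mu2
    S = (d1.T @ (d1 * r[:, None]) + d2.T @ (d2 * (1.0 - r)[:, None])) / n
    return mu1, mu2, S, w1 / n


def _estep_y(Y, p: GMM2Params):
    t1 = np.log(p.pi1) + _log_normal(Y, p.mu1y, p.sigma_y2)
    t2 = np.log1p(-p.pi1) + _log_normal(Y, p.mu2y, p.sigma_y2)
    m = np.maximum(t1, t2)
    lse = m + np.log(np.exp(t1 - m) + np.exp(t2 - m))
    return np.exp(t1 - lse), float(lse.mean())


def _em_run(data: Dataset, use_auxiliary: bool, init: GMM2Params, settings: EMSettings):
    """Single EM run.  Returns (params, loglik, trace, n_iter, converged, degenerate)."""
    Y = data.y
    B = np.column_stack([data.y, data.a]) if use_auxiliary else None
    p = init
    trace = []
    converged = False
    degenerate = False
    n_iter = 0
    r = None
    for it in range(settings.max_iter + 1):
        if use_auxiliary:
            r, ll = _estep_joint(B, p)
        else:
            r, ll = _estep_y(Y, p)
        trace.append(ll)
        if it > 0 and abs(ll - trace[-2]) <= settings.tol * max(1.0, abs(ll)):
            converged = True
            break
        if it == settings.max_iter:
            break
        # M-step
        pi_new = float(np.clip(r.mean(), 1e-12, 1.0 - 1e-12))
        if use_auxiliary:
            mu1, mu2, S, _ = _mstep_joint(B, r)
            if _eig_min_2x2(S[0, 0], S[1, 1], S[0, 1]) < settings.variance_floor:
                degenerate = True
                break
            p = GMM2Params(
                pi_new, mu1[0], mu2[0], S[0, 0], mu1[1], mu2[1], S[1, 1], S[0, 1]
            )
        else:
            w1 = r.sum()
            mu1 = float(r @ Y / w1)
            mu2 = float((1.0 - r) @ Y / (Y.size - w1))
            var = float((r @ (Y - mu1) ** 2 + (1.0 - r) @ (Y - mu2) ** 2) / Y.size)
            if var < settings.variance_floor:
                degenerate = True
                break
            p = GMM2Params(pi_new, mu1, mu2, var)
        n_iter += 1
    resp = np.column_stack([r, 1.0 - r])
    return p, trace[-1], np.asarray(trace), n_iter, converged, degenerate


def _moment_init(data: Dataset, use_auxiliary: bool, split_on: str) -> GMM2Params:
    """Moment initialization from a median split of one observed column."""
    col = data.y if split_on == "y" else data.a
    mask = col <= np.median(col)
    # guard against ties putting everything on one side
    if mask.all() or not mask.any():
        mask = np.arange(data.n) < data.n // 2
    if split_on == "a":
        # component 1 carries the larger auxiliary mean by convention of the
        # illustrative truth; the label orientation is immaterial to the fit
        mask = ~mask
    y1, y2 = data.y[mask], data.y[~mask]
    pi1 = float(mask.mean())
    if not use_auxiliary:
        var = float((np.sum((y1 - y1.mean()) ** 2) + np.sum((y2 - y2.mean()) ** 2)) / data.n)
        return GMM2Params(pi1, y1.mean(), y2.mean(), max(var, 1e-6))
    B = np.column_stack([data.y, data.a])
    b1, b2 = B[mask], B[~mask]
    m1, m2 = b1.mean(axis=0), b2.mean(axis=0)
    S = ((b1 - m1).T @ (b1 - m1) + (b2 - m2).T @ (b2 - m2)) / data.n
    S[0, 0] = max(S[0, 0], 1e-6)
    S[1, 1] = max(S[1, 1], 1e-6)
    if S[0, 0] * S[1, 1] - S[0, 1] ** 2 <= 0:
        S[0, 1] = 0.0
    return GMM2Params(pi1, m1[0], m2[0], S[0, 0], m1[1], m2[1], S[1, 1], S[0, 1])


def _random_init(data: Dataset, use_auxiliary: bool, rng: np.random.Generator) -> GMM2Params:
    """Random restart: two distinct observations as means, marginal covariance."""
    i, j = rng.choice(data.n, size=2, replace=False)
    pi1 = float(rng.uniform(0.25, 0.75))
    if not use_auxiliary:
        var = float(np.var(data.y))
        return GMM2Params(pi1, data.y[i], data.y[j], max(var, 1e-6))
    B = np.column_stack([data.y, data.a])
    S = np.cov(B, rowvar=False, ddof=0)
    S[0, 0] = max(S[0, 0], 1e-6)
    S[1, 1] = max(S[1, 1], 1e-6)
    if S[0, 0] * S[1, 1] - S[0, 1] ** 2 <= 0:
        S[0, 1] = 0.0
    return GMM2Params(pi1, B[i, 0], B[j, 0], S[0, 0], B[i, 1], B[j, 1], S[1, 1], S[0, 1])


def fit_em(
    data: Dataset,
    use_auxiliary: bool,
    settings: Optional[EMSettings] = None,
    init: Optional[GMM2Params] = None,
) -> FitResult:
    """Maximize the observed-data likelihood by EM with restarts.

    With ``use_auxiliary`` the joint (y, a) model is fitted (objective
    ``"b"``), otherwise the y-only model (objective ``"y"``).  Restart 0
    starts from moments of a median split of y; restart 1 (joint model only)
    splits on the auxiliary column, which reaches modes separated along
    ``a``; remaining restarts are randomized from ``settings.seed``.  The run
    with the best final log-likelihood wins; runs hitting the degeneracy
    floor are discarded.  Passing ``init`` performs a single warm-started run
    instead (used by leave-one-out refitting).
    """
    settings = settings or EMSettings()
    if data.n < 5:
        raise DataError(f"need at least 5 observations, got {data.n}")
    if use_auxiliary and data.a is None:
        raise DataError("use_auxiliary=True requires an auxiliary column")

    if init is not None:
        inits = [init]
    else:
        inits = [_moment_init(data, use_auxiliary, "y")]
        if use_auxiliary and settings.n_restarts >= 2:
            inits.append(_moment_init(data, use_auxiliary, "a"))
        rng = np.random.default_rng(settings.seed)
        while len(inits) < settings.n_restarts:
            inits.append(_random_init(data, use_auxiliary, rng))

    best = None
    restart_logliks = []
    for p0 in inits:
        p, ll, trace, n_iter, converged, degenerate = _em_run(
            data, use_auxiliary, p0, settings
        )
        restart_logliks.append(float("nan") if degenerate else ll)
        if degenerate:
            continue
        if best is None or ll > best[1]:
            best = (p, ll, trace, n_iter, converged)
    if best is None:
        raise FitDegenerateError("all EM restarts hit the degeneracy floor")
    p, ll, trace, n_iter, converged = best
    if use_auxiliary:
        resp = posterior_z(p, data.y, data.a)
    else:
        resp = posterior_z(p, data.y)
    return FitResult(
        params=p,
        loglik_per_obs=ll,
        responsibilities=resp,
        n_iter=n_iter,
        converged=converged,
        n_restarts_used=len(inits),
        best_restart_logliks=restart_logliks,
        objective="b" if use_auxiliary else "y",
        loglik_trace=trace,
    )


def fit_complete(data: Dataset, settings: Optional[EMSettings] = None) -> FitResult:
    """Closed-form MLE of theta using the labels z as if observed.

    ``pi1`` is the label frequency, the means are per-label sample means of
    y, and ``sigma_y2`` is the pooled within-label variance with divisor n.
    """
    settings = settings or EMSettings()
    if data.z is None:
        raise DataError("fit_complete requires the latent label column z")
    z = data.z.astype(bool)
    if z.all() or not z.any():
        raise DataError("both label classes must be non-empty")
    y1, y2 = data.y[z], data.y[~z]
    pi1 = float(z.mean())
    mu1, mu2 = float(y1.mean()), float(y2.mean())
    var = float((np.sum((y1 - mu1) ** 2) + np.sum((y2 - mu2) ** 2)) / data.n)
    if var < settings.variance_floor:
        raise FitDegenerateError(
            f"pooled within-label variance {var} below floor {settings.variance_floor}"
        )
    params = GMM2Params(pi1, mu1, mu2, var)
    ll = float(np.mean(logdensity_x(params, data.y, data.z)))
    resp = np.column_stack([data.z.astype(float), 1.0 - data.z])
    return FitResult(
        params=params,
        loglik_per_obs=ll,
        responsibilities=resp,
        n_iter=0,
        converged=True,
        n_restarts_used=1,
        best_restart_logliks=[ll],
        objective="x",
        loglik_trace=np.array([ll]),
    )
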