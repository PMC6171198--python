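"""Detection functions and the maximum-likelihood SCR estimator.

The model: packs have latent activity centres s on a discrete habitat mask;
a Bernoulli encounter of pack i at trap j on occasion k occurs with
probability p(d(s_i, x_j)) that decays with distance.  Two detection kernels
are supported,

* half-normal (HN):            k(d) = exp(-d² / (2 σ²))
* negative exponential (NE):   k(d) = exp(-d / σ)

under two parameterizations of the zero-distance encounter level,

* direct:   p = g0 · k(d)
* cloglog:  p = 1 - exp(-λ0 · k(d))   (λ0 = expected encounter rate at d=0)

optionally with a trap-specific behavioural response ("TRAP"): after a
pack's first capture at a given trap, the zero-distance parameter switches
to a post-first-capture value at that trap.

Density D (packs per 100 km²) enters through the full (unconditional)
likelihood: the number of detected packs is Poisson(D·A·p̄/100) with p̄ the
mask-average probability of being detected at least once, and each observed
history contributes its mask-marginal probability conditional on detection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp

from .capture_history import CaptureHistory
from .io_formats import TrapDeployment, activity_matrix, trap_coords
from .statespace import StateSpace, distance_matrix

_PMIN = 1e-300
_PCLIP = 1e-12


@dataclass
class DetectionParams:
    """Detection-function parameters.

    Exactly one of ``g0`` (direct) or ``lambda0`` (cloglog) is used,
    depending on the model's parameterization; ``*_post`` are the
    post-first-capture levels for TRAP-response models.
    """

    sigma: float
    g0: Optional[float] = None
    lambda0: Optional[float] = None
    g0_post: Optional[float] = None
    lambda0_post: Optional[float] = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.g0 is not None and not (0 < self.g0 < 1):
            raise ValueError("g0 must be in (0, 1)")
        if self.lambda0 is not None and self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")


@dataclass
class ModelSpec:
    """Detection model structure: kernel, behavioural response, link."""

    detfn: str = "HN"  # "HN" | "NE"
    response: Optional[str] = None  # None | "TRAP"
    parameterization: str = "cloglog"  # "direct" | "cloglog"

    def __post_init__(self) -> None:
        if self.detfn not in ("HN", "NE"):
            raise ValueError("detfn must be 'HN' or 'NE'")
        if self.response not in (None, "TRAP"):
            raise ValueError("response must be None or 'TRAP'")
        if self.parameterization not in ("direct", "cloglog"):
            raise ValueError("parameterization must be 'direct' or 'cloglog'")

    @property
    def name(self) -> str:
        return f"{self.detfn}_{'TP' if self.response == 'TRAP' else 'NULL'}"

    @property
    def n_detection_params(self) -> int:
        return 3 if self.response == "TRAP" else 2


@dataclass
class MLFit:
    """Maximum-likelihood fit: density, detection parameters, uncertainty."""

    D_hat: float  # packs per 100 km²
    params: DetectionParams
    se: dict
    ci95: dict
    loglik: float
    aicc: float
    n_detected: int
    spec: ModelSpec
    converged: bool
    session_id: str = ""
    theta: np.ndarray = field(default=None, repr=False)
    vcov: np.ndarray = field(default=None, repr=False)


def kernel(d, sigma: float, detfn: str = "HN"):
    """Distance-decay kernel, 1 at d=0 and strictly decreasing."""
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be non-negative")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if detfn == "HN":
        return np.exp(-(d**2) / (2.0 * sigma**2))
    if detfn == "NE":
        return np.exp(-d / sigma)
    raise ValueError("detfn must be 'HN' or 'NE'")


def encounter_prob(d, params: DetectionParams, spec: ModelSpec):
    """Per-occasion encounter probability at distance d (pre-first-capture)."""
    k = kernel(d, params.sigma, spec.detfn)
    if spec.parameterization == "direct":
        if params.g0 is None:
            raise ValueError("direct parameterization requires g0")
        return params.g0 * k
    if params.lambda0 is None:
        raise ValueError("cloglog parameterization requires lambda0")
    return -np.expm1(-params.lambda0 * k)


def _prob_pair(d, params: DetectionParams, spec: ModelSpec):
    """(p_pre, p_post) arrays; p_post == p_pre for NULL models."""
    k = kernel(d, params.sigma, spec.detfn)
    if spec.parameterization == "direct":
        p1 = params.g0 * k
        base_post = params.g0_post if params.g0_post is not None else params.g0
        p2 = base_post * k if spec.response == "TRAP" else p1
    else:
        p1 = -np.expm1(-params.lambda0 * k)
        lam_post = (
            params.lambda0_post if params.lambda0_post is not None else params.lambda0
        )
        p2 = -np.expm1(-lam_post * k) if spec.response == "TRAP" else p1
    return p1, p2


def history_prob(
    y_i: np.ndarray,
    s: np.ndarray,
    traps: Sequence[TrapDeployment] | np.ndarray,
    params: DetectionParams,
    spec: ModelSpec,
    activity: Optional[np.ndarray] = None,
) -> float:
    """Probability of one animal's binary history given activity centre s.

    Direct per-occasion Bernoulli product; with a TRAP response the
    pre-first-capture parameter applies up to and including the first
    capture at each trap, the post parameter afterwards (per trap).
    """
    y_i = np.asarray(y_i)
    if isinstance(traps, np.ndarray):
        coords = np.atleast_2d(traps)
        if activity is None:
            activity = np.ones(y_i.shape, dtype=np.int8)
    else:
        coords = trap_coords(traps)
        if activity is None:
            activity = activity_matrix(traps)
    d = np.sqrt(((coords - np.asarray(s, dtype=float)) ** 2).sum(axis=1))
    p1, p2 = _prob_pair(d, params, spec)
    prob = 1.0
    J, K = y_i.shape
    for j in range(J):
        seen = False
        for k in range(K):
            if activity[j, k] == 0:
                continue
            p = p2[j] if seen else p1[j]
            prob *= p if y_i[j, k] else (1.0 - p)
            if y_i[j, k]:
                seen = True
    return prob


# ---------------------------------------------------------------------------
# Sufficient statistics and vectorized log-likelihood over the mask
# ---------------------------------------------------------------------------


def _suffstats(y: np.ndarray, activity: np.ndarray):
    """Per animal x trap counts summarizing Bernoulli histories.

    Returns (pre0, first, post1, post0, effort) where, per animal i and
    trap j: ``first`` is 1 if captured; ``pre0`` counts active occasions
    before the first capture (all zeros); ``post1``/``post0`` count
    captures/non-captures after the first capture; ``effort`` is the
    per-trap number of active occasions.  For NULL models first+post1 = Y
    and pre0+post0 = effort - Y, so the same four matrices drive both
    model families.
    """
    y = np.asarray(y, dtype=np.int8)
    act = np.asarray(activity, dtype=np.int8)
    n, J, K = y.shape
    if (y * (1 - act[None, :, :])).any():
        raise ValueError("captures recorded at inactive trap-occasions")
    effort = act.sum(axis=1).astype(float)  # (J,)
    Y = y.sum(axis=2).astype(float)  # (n, J)
    anycap = Y > 0
    first_idx = np.argmax(y, axis=2)  # (n, J), valid where anycap
    cumact = np.cumsum(act, axis=1)  # (J, K)
    pre_incl = cumact[np.arange(J)[None, :], first_idx].astype(float)  # (n, J)
    pre0 = np.where(anycap, pre_incl - 1.0, effort[None, :])
    first = anycap.astype(float)
    post1 = np.where(anycap, Y - 1.0, 0.0)
    post0 = np.where(anycap, effort[None, :] - pre_incl - post1, 0.0)
    return pre0, first, post1, post0, effort


def _log_prob_pair(dmat, params, spec):
    """log p1, log(1-p1), log p2, log(1-p2) on the mask x trap grid."""
    p1, p2 = _prob_pair(dmat, params, spec)
    p1 = np.clip(p1, _PMIN, 1.0 - _PCLIP)
    p2 = np.clip(p2, _PMIN, 1.0 - _PCLIP)
    return np.log(p1), np.log1p(-p1), np.log(p2), np.log1p(-p2)


def _detected_logprob(stats, logs):
    """(n, P) log Pr(y_i | s) for all detected animals and mask points."""
    pre0, first, post1, post0, _ = stats
    lp1, lq1, lp2, lq2 = logs
    return pre0 @ lq1.T + first @ lp1.T + post1 @ lp2.T + post0 @ lq2.T


def marginal_loglik(
    history: CaptureHistory,
    space: StateSpace,
    traps: Sequence[TrapDeployment],
    params: DetectionParams,
    spec: ModelSpec,
    D: float,
    _cache: Optional[dict] = None,
) -> float:
    """Full SCR log-likelihood with homogeneous density D over the mask.

    ``p·(s) = 1 - Π_{j,k active}(1 - p1(s,j))`` is the probability of being
    detected at least once from centre s; n ~ Poisson(D·A·p̄/100) and each
    detected history contributes ``log[(1/P)·Σ_s Pr(y_i|s)] - log p̄``.
    """
    if D <= 0:
        raise ValueError("density must be positive")
    if _cache is not None:
        dmat = _cache["dmat"]
        stats = _cache["stats"]
    else:
        dmat = distance_matrix(space, trap_coords(traps))
        stats = _suffstats(history.y, activity_matrix(traps))
    logs = _log_prob_pair(dmat, params, spec)
    effort = stats[4]
    log_p0 = logs[1] @ effort  # (P,) log Pr(all-zero | s)
    pdot = -np.expm1(log_p0)
    pbar = float(pdot.mean())
    if pbar <= 0:
        raise ValueError("no detectable configuration (pbar = 0)")
    P = dmat.shape[0]
    n = history.n_animals
    A = space.total_area_km2
    mu = D * A / 100.0 * pbar
    ll = n * math.log(mu) - mu - float(gammaln(n + 1))
    log_py = _detected_logprob(stats, logs)  # (n, P)
    ll += float((logsumexp(log_py, axis=1) - math.log(P) - math.log(pbar)).sum())
    return ll


def aicc(loglik: float, k_params: int, n: int) -> float:
    """Akaike information criterion with small-sample correction."""
    if n <= k_params + 1:
        raise ValueError("AICc undefined: n must exceed k_params + 1")
    return -2.0 * loglik + 2.0 * k_params + 2.0 * k_params * (k_params + 1) / (n - k_params - 1)


# ---------------------------------------------------------------------------
# ML estimation
# ---------------------------------------------------------------------------


def _logit(p):
    return math.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + math.exp(-x))


def _theta_to_params(theta: np.ndarray, spec: ModelSpec):
    """theta = [log D, log sigma, link(base), (link(post))]."""
    D = math.exp(theta[0])
    sigma = math.exp(theta[1])
    if spec.parameterization == "direct":
        base = _expit(theta[2])
        post = _expit(theta[3]) if spec.response == "TRAP" else None
        params = DetectionParams(sigma=sigma, g0=base, g0_post=post)
    else:
        base = math.exp(theta[2])
        post = math.exp(theta[3]) if spec.response == "TRAP" else None
        params = DetectionParams(sigma=sigma, lambda0=base, lambda0_post=post)
    return D, params


def _default_start(history, space, traps, spec):
    from .capture_history import mmdm as _mmdm

    m = _mmdm(history, traps)
    if m.defined and m.mean > 0:
        sigma0 = m.mean / 2.0
    else:
        coords = trap_coords(traps)
        span = np.ptp(coords, axis=0)
        sigma0 = max(float(np.hypot(*span)) / 4.0, space.spacing_m)
    A = space.total_area_km2
    D0 = max(history.n_animals / A * 100.0 / 0.7, 1e-3)
    base0 = 0.1
    theta = [math.log(D0), math.log(sigma0)]
    theta.append(_logit(base0) if spec.parameterization == "direct" else math.log(base0))
    if spec.response == "TRAP":
        theta.append(theta[2])
    return np.array(theta)


def _numeric_hessian(f, x, eps=1e-4):
    """Central-difference Hessian of scalar f at x."""
    p = len(x)
    H = np.empty((p, p))
    h = eps * (1.0 + np.abs(x))
    for a in range(p):
        for b in range(a, p):
            ea = np.zeros(p); ea[a] = h[a]
            eb = np.zeros(p); eb[b] = h[b]
            H[a, b] = H[b, a] = (
                f(x + ea + eb) - f(x + ea - eb) - f(x - ea + eb) + f(x - ea - eb)
            ) / (4.0 * h[a] * h[b])
    return H


def fit_ml(
    history: CaptureHistory,
    space: StateSpace,
    traps: Sequence[TrapDeployment],
    spec: ModelSpec,
    start: Optional[np.ndarray] = None,
    n_starts: int = 3,
    seed: int = 0,
) -> MLFit:
    """Maximize the full SCR likelihood over (D, detection parameters).

    Estimation is on transformed scales (log D, log sigma, logit g0 or
    log lambda0) with quasi-Newton optimization from a few jittered starting
    points; standard errors come from the inverse observed information and
    95% CIs are Wald intervals on the estimation scale, back-transformed.
    """
    if history.n_animals < 2:
        raise ValueError("need at least 2 detected animals to fit")
    n_multi = sum(
        1 for i in range(history.n_animals)
        if (history.y[i].sum(axis=1) > 0).sum() > 1
    )
    if n_multi == 0:
        warnings.warn(
            "no spatial recaptures: sigma is weakly identified", UserWarning,
            stacklevel=2,
        )
    cache = {
        "dmat": distance_matrix(space, trap_coords(traps)),
        "stats": _suffstats(history.y, activity_matrix(traps)),
    }

    def nll(theta):
        try:
            D, params = _theta_to_params(theta, spec)
        except (OverflowError, ValueError):
            return 1e12
        try:
            return -marginal_loglik(history, space, traps, params, spec, D, _cache=cache)
        except (ValueError, FloatingPointError, OverflowError):
            return 1e12

    theta0 = np.asarray(start, dtype=float) if start is not None else _default_start(
        history, space, traps, spec
    )
    rng = np.random.default_rng(seed)
    best = None
    for trial in range(max(1, n_starts)):
        t0 = theta0 if trial == 0 else theta0 + rng.normal(0.0, 0.3, size=len(theta0))
        res = minimize(nll, t0, method="L-BFGS-B",
                       options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-8})
        if best is None or res.fun < best.fun - 1e-10:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e11:
        raise RuntimeError(f"SCR ML fit did not converge: {best}")

    theta_hat = best.x
    H = _numeric_hessian(nll, theta_hat)
    try:
        vcov = np.linalg.inv(H)
        if (np.diag(vcov) <= 0).any():
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        warnings.warn("observed information not positive definite; using pseudo-inverse",
                      UserWarning, stacklevel=2)
        vcov = np.linalg.pinv(H)
    se_link = np.sqrt(np.abs(np.diag(vcov)))

    D_hat, params = _theta_to_params(theta_hat, spec)
    names = ["D", "sigma", "g0" if spec.parameterization == "direct" else "lambda0"]
    if spec.response == "TRAP":
        names.append("g0_post" if spec.parameterization == "direct" else "lambda0_post")
    back = []
    for idx, nm in enumerate(names):
        est_link = theta_hat[idx]
        lo, hi = est_link - 1.96 * se_link[idx], est_link + 1.96 * se_link[idx]
        if nm.startswith("g0"):
            back.append((_expit(est_link), (_expit(lo), _expit(hi))))
        else:
            back.append((math.exp(est_link), (math.exp(lo), math.exp(hi))))
    se = {nm: back[i][0] * se_link[i] if not nm.startswith("g0")
          else back[i][0] * (1 - back[i][0]) * se_link[i]
          for i, nm in enumerate(names)}  # delta method on natural scale
    ci95 = {nm: back[i][1] for i, nm in enumerate(names)}

    loglik = -best.fun
    k = len(theta_hat)
    try:
        fit_aicc = aicc(loglik, k, history.n_animals)
    except ValueError:
        warnings.warn("AICc undefined for this few detected animals",
                      UserWarning, stacklevel=2)
        fit_aicc = math.nan
    return MLFit(
        D_hat=D_hat,
        params=params,
        se=se,
        ci95=ci95,
        loglik=loglik,
        aicc=fit_aicc,
        n_detected=history.n_animals,
        spec=spec,
        converged=bool(best.success),
        session_id=history.session_id,
        theta=theta_hat,
        vcov=vcov,
    )
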