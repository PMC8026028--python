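"""Value-of-information features and the linear value-of-computation proxy.

Three nested features quantify how much a hypothetical gain in information
would improve the immediately chosen item's expected utility, relative to
choosing now:

* ``voi_myopic(b, i)`` -- one more sample from item i, then choose.
* ``voi_item(b, i)``   -- learn item i's true value exactly, then choose.
* ``voi_full(b)``      -- learn every item's true value, then choose.

All three reduce to expected-maximum computations over Gaussian beliefs.
For a single uncertain quantity against a known constant we use the closed
form  E[max(X, m)] = m Phi((m-mu)/s) + mu Phi((mu-m)/s) + s phi((m-mu)/s)
with X ~ Normal(mu, s^2).  The expected maximum of N independent normals
is closed-form for N = 2 and N = 3 (the latter via bivariate-normal
orthant probabilities and Stein's identity); N >= 4 falls back to
panelled Gauss-Legendre quadrature.

The value-of-computation proxy is a convex combination of the three
features minus the sampling cost and a constant future-cost offset:

    voc_hat(b, c) = w1 VOI_myopic + w2 VOI_item + w3 VOI_full
                    - (cost(b, c) + w4),          voc_hat(b, TERMINATE) = 0.

Array-valued variants (suffix ``_arr``) operate on batches of beliefs,
``mu`` and ``lam`` of shape (B, N), and are the work-horses of the
vectorized episode engine.  A Monte-Carlo oracle (:func:`mc_voi_oracle`)
estimates each feature by direct simulation of the hypothetical future
belief and is used to validate the closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, owens_t

from .core_mdp import TERMINATE, BeliefState, ModelParams, computation_cost

__all__ = [
    "VOCWeights",
    "voi_myopic",
    "voi_item",
    "voi_full",
    "voc_hat",
    "mc_voi_oracle",
]

_SQRT_2PI = math.sqrt(2.0 * math.pi)

# Gauss-Legendre rule reused (per panel) for every expected-max quadrature.
_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(24)
_Z_RANGE = 8.0  # integration range in standard-normal units


@dataclass(frozen=True)
class VOCWeights:
    """Feature weights of the linear VOC proxy.

    ``w1..w3`` form a convex combination over the three VOI features;
    ``w4 >= 0`` is a constant offset approximating expected future
    sampling costs (in value units).
    """

    w1: float
    w2: float
    w3: float
    w4: float

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ValueError("weights must be nonnegative")
        if abs((self.w1 + self.w2 + self.w3) - 1.0) > 1e-12:
            raise ValueError("w1 + w2 + w3 must equal 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.w1, self.w2, self.w3, self.w4], dtype=float)

    @classmethod
    def from_array(cls, w: np.ndarray) -> "VOCWeights":
        return cls(float(w[0]), float(w[1]), float(w[2]), float(w[3]))


def _phi(z: np.ndarray) -> np.ndarray:
    return np.exp(-0.5 * np.square(z)) / _SQRT_2PI


def emax_normal_const(mu, s, m):
    """E[max(X, m)] for X ~ Normal(mu, s^2), elementwise; exact at s == 0."""
    mu = np.asarray(mu, dtype=float)
    s = np.asarray(s, dtype=float)
    m = np.asarray(m, dtype=float)
    out = np.maximum(mu, m)  # degenerate s == 0
    pos = s > 0
    if np.any(pos):
        mu_p, s_p, m_p = (
            np.broadcast_to(mu, out.shape)[pos],
            np.broadcast_to(s, out.shape)[pos],
            np.broadcast_to(m, out.shape)[pos],
        )
        z = (m_p - mu_p) / s_p
        out[pos] = m_p * ndtr(z) + mu_p * ndtr(-z) + s_p * _phi(z)
    return out


def _best_and_rival(mu: np.ndarray):
    """Per row: overall max and, for each item, the max over the *other* items."""
    order = np.sort(mu, axis=1)
    top1 = order[:, -1]
    top2 = order[:, -2]
    imax = np.argmax(mu, axis=1)
    rival = np.broadcast_to(top1[:, None], mu.shape).copy()
    rival[np.arange(mu.shape[0]), imax] = top2
    return top1, rival


def voi_myopic_arr(mu: np.ndarray, lam: np.ndarray, sigma_x: float) -> np.ndarray:
    """Myopic VOI for every item; shapes (B, N) -> (B, N)."""
    tau = sigma_x ** -2
    # Preposterior variance of the post-sample mean.
    s2 = 1.0 / lam - 1.0 / (lam + tau)
    top1, rival = _best_and_rival(mu)
    val = emax_normal_const(mu, np.sqrt(s2), rival) - top1[:, None]
    return np.clip(val, 0.0, None)


def voi_item_arr(mu: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Perfect-knowledge-of-one-item VOI for every item; (B, N) -> (B, N)."""
    top1, rival = _best_and_rival(mu)
    val = emax_normal_const(mu, np.sqrt(1.0 / lam), rival) - top1[:, None]
    return np.clip(val, 0.0, None)


def _owens_t_ext(h: np.ndarray, a: np.ndarray) -> np.ndarray:
    """Owen's T function extended to a = +/-inf: T(h, inf) = Phi(-|h|)/2."""
    finite = np.isfinite(a)
    out = np.where(
        finite,
        owens_t(h, np.where(finite, a, 0.0)),
        np.sign(a) * 0.5 * ndtr(-np.abs(h)),
    )
    return out


def _bvn_cdf(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Standard bivariate normal CDF P(Z1 <= h, Z2 <= k), |rho| < 1.

    Owen's (1956) formula:  Phi2 = (Phi(h) + Phi(k))/2 - T(h, a_h)
    - T(k, a_k) - delta, with the h = 0 / k = 0 limits taken explicitly.
    """
    h = np.asarray(h, dtype=float)
    k = np.asarray(k, dtype=float)
    rho = np.asarray(rho, dtype=float)
    r = np.sqrt(np.clip(1.0 - rho**2, 1e-300, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        ah = (k - rho * h) / (h * r)
        ak = (h - rho * k) / (k * r)
    signed_inf_k = np.where(k > 0, np.inf, np.where(k < 0, -np.inf, 0.0))
    signed_inf_h = np.where(h > 0, np.inf, np.where(h < 0, -np.inf, 0.0))
    ah = np.where(h == 0, signed_inf_k, ah)
    ak = np.where(k == 0, signed_inf_h, ak)
    delta = np.where((h * k < 0) | ((h * k == 0) & (h + k < 0)), 0.5, 0.0)
    out = 0.5 * (ndtr(h) + ndtr(k)) - _owens_t_ext(h, ah) - _owens_t_ext(k, ak) - delta
    both_zero = (h == 0) & (k == 0)
    if np.any(both_zero):
        out = np.where(both_zero, 0.25 + np.arcsin(np.clip(rho, -1, 1)) / (2 * np.pi), out)
    return np.clip(out, 0.0, 1.0)


def _emax3_exact(mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """Exact E[max(U1, U2, U3)] for independent normals (all sd > 0).

    E[max] = sum_i E[U_i 1(U_i = max)]; each term expands by Stein's
    identity into mu_i * P(U_i is max) -- a bivariate normal orthant
    probability -- plus sd_i^2 times two Gaussian-product integrals with
    closed forms.
    """
    var = sd**2
    out = np.zeros(mu.shape[0])
    for i in range(3):
        j, k = [x for x in range(3) if x != i]
        s_ij = np.sqrt(var[:, i] + var[:, j])
        s_ik = np.sqrt(var[:, i] + var[:, k])
        h = (mu[:, i] - mu[:, j]) / s_ij
        g = (mu[:, i] - mu[:, k]) / s_ik
        rho = var[:, i] / (s_ij * s_ik)
        p_max = _bvn_cdf(h, g, rho)
        # E[(1/s_j) phi((X-mu_j)/s_j) Phi((X-mu_k)/s_k)] over X ~ N(mu_i, sd_i)
        def cross(jj, kk, s_ijj):
            zz = (mu[:, i] - mu[:, jj]) / s_ijj
            m = (mu[:, i] * var[:, jj] + mu[:, jj] * var[:, i]) / s_ijj**2
            v = var[:, i] * var[:, jj] / s_ijj**2
            return (_phi(zz) / s_ijj) * ndtr(
                (m - mu[:, kk]) / np.sqrt(v + var[:, kk])
            )
        out += mu[:, i] * p_max + var[:, i] * (cross(j, k, s_ij) + cross(k, j, s_ik))
    return out


def emax_independent_normals(mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    """E[max_i U_i] for independent U_i ~ Normal(mu_i, sd_i^2), rowwise.

    Closed forms for two and three items (the three-item case via
    bivariate-normal orthant probabilities and Stein's identity).  For
    N >= 4 the expectation is split as E[max] = sum_i E[U_i 1(U_i max)]
    and each term integrated by panelled Gauss-Legendre quadrature with
    panel boundaries at the other items' means, where the competing CDF
    factors can turn step-like.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    sd = np.atleast_2d(np.asarray(sd, dtype=float))
    n = mu.shape[1]
    if n == 2:
        d = mu[:, 0] - mu[:, 1]
        theta = np.sqrt(sd[:, 0] ** 2 + sd[:, 1] ** 2)
        z = d / np.where(theta > 0, theta, 1.0)
        return np.where(
            theta > 0,
            mu[:, 0] * ndtr(z) + mu[:, 1] * ndtr(-z) + theta * _phi(z),
            np.maximum(mu[:, 0], mu[:, 1]),
        )
    if n == 3 and np.all(sd > 0):
        return _emax3_exact(mu, sd)
    B = mu.shape[0]
    out = np.zeros(B)
    safe_sd = np.where(sd > 0, sd, 1.0)
    for i in range(n):
        sd_i = np.where(sd[:, i] > 0, sd[:, i], 1e-300)
        # breakpoints (other items' means) in item i's standard units
        brk = (np.delete(mu, i, axis=1) - mu[:, i, None]) / sd_i[:, None]
        brk = np.clip(np.sort(brk, axis=1), -_Z_RANGE, _Z_RANGE)
        edges = np.concatenate(
            [np.full((B, 1), -_Z_RANGE), brk, np.full((B, 1), _Z_RANGE)], axis=1
        )  # (B, P+1)
        half = 0.5 * (edges[:, 1:] - edges[:, :-1])          # (B, P)
        mid = 0.5 * (edges[:, 1:] + edges[:, :-1])
        z = mid[:, :, None] + half[:, :, None] * _GL_NODES   # (B, P, K)
        t = mu[:, i, None, None] + sd[:, i, None, None] * z
        prob = np.ones_like(t)
        for j in range(n):
            if j == i:
                continue
            zj = (t - mu[:, j, None, None]) / safe_sd[:, j, None, None]
            cdf = np.where(sd[:, j, None, None] > 0, ndtr(zj),
                           t >= mu[:, j, None, None])
            prob *= cdf
        integ = (t * _phi(z) * prob) @ _GL_WEIGHTS           # (B, P)
        out += np.sum(half * integ, axis=1)
    return out


def voi_full_arr(mu: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Full-revelation VOI; shapes (B, N) -> (B,)."""
    val = emax_independent_normals(mu, np.sqrt(1.0 / lam)) - np.max(mu, axis=1)
    return np.clip(val, 0.0, None)


# ---------------------------------------------------------------------------
# Scalar API over BeliefState

def voi_myopic(b: BeliefState, item: int, sigma_x: float) -> float:
    """Expected choice improvement from one more sample of ``item``."""
    return float(voi_myopic_arr(b.mu[None, :], b.lam[None, :], sigma_x)[0, item])


def voi_item(b: BeliefState, item: int) -> float:
    """Expected choice improvement from learning ``item``'s value exactly."""
    return float(voi_item_arr(b.mu[None, :], b.lam[None, :])[0, item])


def voi_full(b: BeliefState) -> float:
    """Expected choice improvement from learning every item's value."""
    return float(voi_full_arr(b.mu[None, :], b.lam[None, :])[0])


def voc_hat(
    b: BeliefState, c: int, w: VOCWeights, params: ModelParams
) -> float:
    """Linear VOC proxy for computation ``c``; exactly 0 for TERMINATE."""
    if c == TERMINATE:
        return 0.0
    gain = (
        w.w1 * voi_myopic(b, c, params.sigma_x)
        + w.w2 * voi_item(b, c)
        + w.w3 * voi_full(b)
    )
    return gain - (computation_cost(b, c, params) + w.w4)


def mc_voi_oracle(
    b: BeliefState,
    item: int,
    mode: str,
    n_draws: int,
    rng: np.random.Generator,
    sigma_x: float | None = None,
) -> tuple[float, float]:
    """Monte-Carlo estimate of a VOI feature by simulating future beliefs.

    Returns ``(estimate, standard_error)``.  ``mode`` is one of
    ``{"myopic", "item", "full"}``; ``sigma_x`` is required for the myopic
    mode.  Each draw simulates the hypothetical information gain directly
    (true value from the current belief, then the sample / revelation) and
    scores the resulting best-mean choice against choosing now.
    """
    if n_draws < 10_000:
        raise ValueError("n_draws must be at least 1e4 for a stable oracle")
    mu, lam = b.mu, b.lam
    base = float(np.max(mu))
    rival = float(np.max(np.delete(mu, item))) if mu.size > 1 else -np.inf
    if mode == "item":
        x = mu[item] + rng.standard_normal(n_draws) / math.sqrt(lam[item])
        vals = np.maximum(x, rival) - base
    elif mode == "myopic":
        if sigma_x is None:
            raise ValueError("sigma_x required for myopic mode")
        tau = sigma_x ** -2
        u = mu[item] + rng.standard_normal(n_draws) / math.sqrt(lam[item])
        x = u + sigma_x * rng.standard_normal(n_draws)
        post_mean = (tau * x + lam[item] * mu[item]) / (lam[item] + tau)
        vals = np.maximum(post_mean, rival) - base
    elif mode == "full":
        u = mu[None, :] + rng.standard_normal((n_draws, mu.size)) / np.sqrt(lam)[None, :]
        vals = np.max(u, axis=1) - base
    else:
        raise ValueError(f"unknown mode {mode!r}")
    est = float(np.mean(vals))
    se = float(np.std(vals, ddof=1) / math.sqrt(n_draws))
    return est, se
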