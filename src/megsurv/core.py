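"""Mixture likelihood for mutual exclusivity of a candidate gene set.

A candidate set of ``m`` genes across ``N`` patients is modelled as a
two-component mixture: with probability ``gamma`` (the *coverage*) a patient
carries the exclusivity mechanism and exactly one member gene mutates, gene
``k`` with probability ``p_k = pi_k / sum_j pi_j``; otherwise the member
genes mutate independently at their background rates ``pi_k``.  The
relative frequencies ``P`` are never free parameters — they are tied to the
background rates by the proportionality assumption, so the free parameters
are ``(gamma, pi_1..pi_m)``.

The null hypothesis of no exclusivity is ``gamma = 0``.  Because the null
value sits on the boundary of the parameter space, the likelihood-ratio
statistic ``S`` is asymptotically distributed as the mixture
``0.5*chi2_0 + 0.5*chi2_1``: a point mass at zero with weight one half and
a chi-square with one degree of freedom otherwise.

The per-patient likelihood depends on the patient's row only through its
0/1 pattern, so all fitting internally collapses the ``N x m`` matrix to
unique patterns with counts; with ``m <= 5`` that is at most 32 weighted
terms regardless of ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MegsaFit",
    "LrtResult",
    "log_likelihood",
    "fit_null",
    "fit_alternative",
    "lrt",
]

# Parameters are kept strictly inside the open unit interval; the likelihood
# at an exact boundary is defined by its limit.
EPS = 1e-6
# Log-likelihood differences below this are treated as exactly zero.
S_TOL = 1e-8
# Sentinel for log(0): a degenerate configuration (gamma=1 with an all-zero
# patient row) has zero likelihood.
NEG_INF_SENTINEL = -1e308


@dataclass
class MegsaFit:
    """Fitted mixture parameters for one candidate gene set."""

    gene_set: list[str]
    gamma: float
    pi: np.ndarray
    loglik: float
    loglik_null: float
    degenerate: bool = False

    @property
    def rel_freq(self) -> np.ndarray:
        """Relative mutation frequencies p_k = pi_k / sum(pi); sum to 1."""
        return self.pi / self.pi.sum()


@dataclass
class LrtResult:
    """Likelihood-ratio test of gamma=0 against gamma>0."""

    statistic: float
    p_value: float
    fit: MegsaFit


def _validate_params(gamma: float, pi: np.ndarray) -> None:
    if not 0.0 <= gamma <= 1.0:
        raise ValueError(f"gamma must lie in [0, 1], got {gamma}")
    if np.any(pi <= 0.0) or np.any(pi >= 1.0):
        raise ValueError("background rates pi must lie strictly in (0, 1)")


def _as_matrix(submatrix) -> np.ndarray:
    A = np.asarray(submatrix, dtype=float)
    if A.ndim == 1:
        A = A[None, :]
    return A


def aggregate_patterns(A: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Collapse rows to unique 0/1 patterns with multiplicities."""
    U, w = np.unique(np.asarray(A, dtype=np.int8), axis=0, return_counts=True)
    return U.astype(float), w.astype(float)


def _mixture_density(U: np.ndarray, gamma: float, pi: np.ndarray):
    """Per-pattern mixture density and its components.

    Returns (mix, bg, excl) where for pattern ``u`` the background density is
    ``prod_k pi_k^u_k (1-pi_k)^(1-u_k)`` and the exclusive density is
    ``bg * (#mutated genes in u) / sum(pi)`` — each term of the exclusive sum
    over mutated ``k`` reduces to the background product itself, because the
    dropped factor ``pi_k^1`` is put back by the leading ``pi_k``.
    """
    log_bg = U @ np.log(pi) + (1.0 - U) @ np.log1p(-pi)
    bg = np.exp(log_bg)
    excl = bg * U.sum(axis=1) / pi.sum()
    return (1.0 - gamma) * bg + gamma * excl, bg, excl


def _loglik_agg(U: np.ndarray, w: np.ndarray, gamma: float, pi: np.ndarray) -> float:
    mix, _, _ = _mixture_density(U, gamma, pi)
    if np.any(mix <= 0.0):
        return NEG_INF_SENTINEL
    return float(w @ np.log(mix))


def log_likelihood(submatrix, gamma: float, pi) -> float:
    """Total log-likelihood of a binary N x m matrix under the mixture.

    The exclusive component places no mass on the all-zero row (its sum over
    mutated genes is empty), so a patient with no mutated member contributes
    ``log((1-gamma) * prod_k (1-pi_k))``; at ``gamma=1`` such a row has zero
    likelihood and the sentinel ``-1e308`` is returned.
    """
    A = _as_matrix(submatrix)
    pi = np.asarray(pi, dtype=float)
    _validate_params(gamma, pi)
    U, w = aggregate_patterns(A)
    return _loglik_agg(U, w, gamma, pi)


def _neg_ll_and_grad(theta: np.ndarray, U: np.ndarray, w: np.ndarray):
    """Negative aggregated log-likelihood and gradient, natural scale."""
    g = theta[0]
    pi = theta[1:]
    mix, bg, excl = _mixture_density(U, g, pi)
    if np.any(mix <= 0.0):
        return 1e300, np.zeros_like(theta)
    inv_mix = w / mix
    ll = float(w @ np.log(mix))

    # d bg / d pi_k = bg * (u_k - pi_k) / (pi_k (1 - pi_k))
    # d excl / d pi_k = excl * [(u_k - pi_k)/(pi_k(1-pi_k)) - 1/sum(pi)]
    frac = (U - pi) / (pi * (1.0 - pi))           # (patterns, m)
    common = ((1.0 - g) * bg + g * excl)[:, None] * frac
    d_pi = inv_mix @ (common - (g * excl / pi.sum())[:, None])

    grad = np.empty_like(theta)
    grad[0] = -float(inv_mix @ (excl - bg))
    grad[1:] = -d_pi
    return -ll, grad


def fit_null(submatrix, gene_set: list[str] | None = None) -> MegsaFit:
    """Closed-form fit under gamma=0: pi_k is the column mean, clipped."""
    A = _as_matrix(submatrix)
    pi_hat = np.clip(A.mean(axis=0), EPS, 1.0 - EPS)
    U, w = aggregate_patterns(A)
    ll = _loglik_agg(U, w, 0.0, pi_hat)
    labels = gene_set if gene_set is not None else [f"g{k}" for k in range(A.shape[1])]
    return MegsaFit(gene_set=list(labels), gamma=0.0, pi=pi_hat,
                    loglik=ll, loglik_null=ll)


_GAMMA_STARTS = (0.0, 0.25, 0.5, 0.75, 0.95)


def _fit_alternative_agg(U: np.ndarray, w: np.ndarray, pi0: np.ndarray,
                         ll_null: float, n_starts: int):
    best_ll, best_gamma, best_pi = ll_null, 0.0, pi0
    m = len(pi0)
    bounds = [(EPS, 1.0 - EPS)] * (m + 1)
    for g0 in _GAMMA_STARTS[: max(1, n_starts)]:
        x0 = np.concatenate(([max(g0, EPS)], pi0))
        res = optimize.minimize(_neg_ll_and_grad, x0, args=(U, w), jac=True,
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 200, "ftol": 1e-12})
        ll = -res.fun
        if np.isfinite(ll) and ll > best_ll:
            best_ll = ll
            best_gamma = float(res.x[0])
            best_pi = np.clip(res.x[1:], EPS, 1.0 - EPS)
    return best_ll, best_gamma, np.asarray(best_pi, dtype=float)


def fit_alternative(submatrix, n_starts: int = 5,
                    gene_set: list[str] | None = None) -> MegsaFit:
    """Maximum-likelihood fit over (gamma, pi) with gamma free in [0, 1).

    Runs bounded quasi-Newton maximization from ``n_starts`` start points
    (gamma in {0, 0.25, 0.5, 0.75, 0.95}, pi at the column means) on the
    logit scale with analytic gradients, and returns the best local maximum.
    Including gamma=0 as a start guarantees the fitted log-likelihood is
    never below the null's.
    """
    A = _as_matrix(submatrix)
    N, m = A.shape
    if N < 2 or m < 2:
        raise ValueError("fit_alternative requires N >= 2 patients and m >= 2 genes")
    U, w = aggregate_patterns(A)
    null_fit = fit_null(A, gene_set)
    ll, g, pi = _fit_alternative_agg(U, w, null_fit.pi, null_fit.loglik, n_starts)
    # The likelihood can be flat in gamma (under independence the mixture
    # reproduces the same cell probabilities for a ridge of (gamma, pi)
    # values), leaving the raw maximizer's gamma arbitrary.  Report the
    # smallest coverage attaining the maximum within tolerance.
    if g > 1e-3:
        g, pi = _minimal_gamma_representative(U, w, g, pi, ll, null_fit.pi)
    labels = gene_set if gene_set is not None else [f"g{k}" for k in range(m)]
    return MegsaFit(gene_set=list(labels), gamma=g, pi=pi,
                    loglik=ll, loglik_null=null_fit.loglik)


def _profile_pi(U, w, gamma, pi0):
    """Maximize the likelihood over pi at fixed gamma."""
    bounds = [(EPS, 1.0 - EPS)] * len(pi0)

    def neg(p):
        th = np.concatenate(([gamma], p))
        f, gr = _neg_ll_and_grad(th, U, w)
        return f, gr[1:]

    res = optimize.minimize(neg, pi0, jac=True, method="L-BFGS-B",
                            bounds=bounds, options={"maxiter": 200,
                                                    "ftol": 1e-12})
    return -res.fun, np.clip(res.x, EPS, 1.0 - EPS)


def _minimal_gamma_representative(U, w, gamma, pi, best_ll, pi0,
                                  tol: float = 1e-8):
    """Smallest gamma whose profile likelihood stays within tol of the max."""
    lo, hi, pi_hi = 0.0, gamma, pi
    ll0, _ = _profile_pi(U, w, EPS, pi0)
    if ll0 >= best_ll - tol:
        return 0.0 if ll0 >= best_ll - S_TOL / 2 else EPS, pi0
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        ll_mid, pi_mid = _profile_pi(U, w, mid, pi_hi)
        if ll_mid >= best_ll - tol:
            hi, pi_hi = mid, pi_mid
        else:
            lo = mid
        if hi - lo < 1e-3:
            break
    return hi, pi_hi


def _lrt_from_loglik(ll_alt: float, ll_null: float) -> tuple[float, float]:
    S = 2.0 * (ll_alt - ll_null)
    if S < S_TOL:
        return 0.0, 1.0
    return S, 0.5 * float(stats.chi2.sf(S, df=1))


def lrt(submatrix, gene_set: list[str] | None = None, n_starts: int = 5) -> LrtResult:
    """LRT of exclusivity: S = 2*(alt - null) with boundary-mixture p-value.

    ``p = 0.5 * Pr(chi2_1 >= S)`` when ``S > 0``; the point-mass convention
    ``p = 1`` applies at ``S = 0``.
    """
    alt = fit_alternative(submatrix, n_starts=n_starts, gene_set=gene_set)
    S, p = _lrt_from_loglik(alt.loglik, alt.loglik_null)
    return LrtResult(statistic=S, p_value=p, fit=alt)


def _expit_clip(x):
    return np.clip(1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float))), EPS, 1.0 - EPS)


def _logit_clip(p):
    p = np.clip(np.asarray(p, dtype=float), EPS, 1.0 - EPS)
    return np.log(p / (1.0 - p))
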