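"""Bivariate binomial model for correlated short- and long-term binary endpoints.

Each subject in a group contributes a pair of Bernoulli responses: a
short-term response with marginal probability ``xi`` and a long-term
response with marginal probability ``pi``, with Pearson correlation
``rho`` between the two.  The construction is hierarchical: the long-term
response is Bernoulli(pi), and the short-term response is Bernoulli with
probability ``(beta + alpha) / (1 + alpha)`` for long-term responders and
``beta / (1 + alpha)`` for non-responders, where ``alpha`` is a dependence
parameter and ``beta = xi + alpha * (xi - pi)``.  Aggregated over ``n``
independent subjects the short-term count given the long-term count ``y``
is the convolution Bin(y, p1) + Bin(n - y, p0), and both marginal counts
are binomial with the nominal probabilities.

The module provides the parameterization, feasibility rules, exact pmfs,
a per-subject sampler (which also tracks the dual-responder count needed
by the Rao-Blackwell estimator), and likelihood-based estimation of rho.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

__all__ = [
    "EndpointModel",
    "SubjectCounts",
    "InfeasibleModelError",
    "alpha_from_rho",
    "is_feasible",
    "rho_max",
    "clamp_probability",
    "clamp_rho",
    "cond_pmf_x_given_y",
    "cond_pmf_matrix",
    "joint_pmf_xy",
    "joint_pmf_matrix",
    "cell_probs",
    "counts_pmf",
    "sample_counts",
    "loglik_rho",
    "profile_rho_mle",
    "pearson_rho",
]

#: numerical slack used in feasibility comparisons
_EPS = 1e-12

#: plug-in estimates of rho are kept this far inside the feasible range
_RHO_MARGIN = 1e-9


class InfeasibleModelError(ValueError):
    """Raised when (xi, pi, rho) lies outside the model's admissible range."""


def _log_comb(n, k):
    """log C(n, k), vectorized, -inf outside 0 <= k <= n."""
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    valid = (k >= 0) & (k <= n) & (n >= 0)
    nn = np.where(valid, n, 0.0)
    kk = np.where(valid, k, 0.0)
    out = gammaln(nn + 1.0) - gammaln(kk + 1.0) - gammaln(nn - kk + 1.0)
    return np.where(valid, out, -np.inf)


def _binom_logpmf(k, n, p):
    """log Bin(n, p) pmf, vectorized, handling p in {0, 1} exactly."""
    k = np.asarray(k, dtype=float)
    p = np.asarray(p, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(np.maximum(p, 1e-300)), -np.inf)
        logq = np.where(p < 1, np.log(np.maximum(1 - p, 1e-300)), -np.inf)
        term_p = np.where(k == 0, 0.0, k * logp)
        term_q = np.where(n - k == 0, 0.0, (n - k) * logq)
    return _log_comb(n, k) + term_p + term_q


def binom_pmf_vector(n: int, p: float) -> np.ndarray:
    """Bin(n, p) pmf on 0..n as a dense vector (cheap gammaln evaluation)."""
    k = np.arange(n + 1)
    return np.exp(_binom_logpmf(k, n, p))


def _alpha_candidates(xi: float, pi: float, rho: float) -> tuple[float, float]:
    """The two readings of the dependence-parameter closed form.

    The first, ``rho / (sqrt(pi(1-pi)/xi(1-xi)) - rho)``, is the one under
    which the per-subject construction has Pearson correlation exactly
    ``rho`` (moment identity: rho = r * alpha / (1 + alpha) with
    r = sqrt(pi(1-pi)/xi(1-xi))).  The second swaps the variance ratio.
    They coincide when xi == pi.
    """
    r = math.sqrt(pi * (1.0 - pi) / (xi * (1.0 - xi)))
    if rho >= min(r, 1.0 / r) - _EPS:
        raise InfeasibleModelError(
            f"rho={rho} exceeds the admissible dependence range for "
            f"xi={xi}, pi={pi}"
        )
    return rho / (r - rho), rho / (1.0 / r - rho)


def _beta_ok(xi: float, pi: float, alpha: float) -> bool:
    beta = xi + alpha * (xi - pi)
    if not (-_EPS <= beta <= 1.0 + _EPS):
        return False
    p1 = (beta + alpha) / (1.0 + alpha)
    p0 = beta / (1.0 + alpha)
    return (-_EPS <= p1 <= 1.0 + _EPS) and (-_EPS <= p0 <= 1.0 + _EPS)


def is_feasible(xi: float, pi: float, rho: float) -> bool:
    """Whether (xi, pi, rho) lies in the model's admissible range.

    The admissible range requires the dependence parameter to yield valid
    probability parameters under both orientations of the variance-ratio
    term.  This is stricter than validity of the generating construction
    alone; the extra constraint pins the boundary at, e.g., rho ~ 0.55 for
    (xi, pi) = (0.7, 0.5), so rho = 0.5 is admissible there but 0.6 is not.
    See docs/methods.md for the rationale.
    """
    if not (0.0 < xi < 1.0 and 0.0 < pi < 1.0 and 0.0 <= rho < 1.0):
        return False
    if rho == 0.0:
        return True
    try:
        a_main, a_alt = _alpha_candidates(xi, pi, rho)
    except InfeasibleModelError:
        return False
    return _beta_ok(xi, pi, a_main) and _beta_ok(xi, pi, a_alt)


def alpha_from_rho(xi: float, pi: float, rho: float) -> float:
    """Dependence parameter alpha solving the moment identity for rho.

    Raises :class:`InfeasibleModelError` when (xi, pi, rho) is outside the
    admissible range.  ``rho = 0`` gives ``alpha = 0`` (independence).
    """
    if not (0.0 < xi < 1.0 and 0.0 < pi < 1.0):
        raise InfeasibleModelError(f"marginals must be interior: xi={xi}, pi={pi}")
    if not (0.0 <= rho < 1.0):
        raise InfeasibleModelError(f"rho={rho} outside [0, 1)")
    if rho == 0.0:
        return 0.0
    if not is_feasible(xi, pi, rho):
        raise InfeasibleModelError(
            f"(xi={xi}, pi={pi}, rho={rho}) outside the admissible range"
        )
    return _alpha_candidates(xi, pi, rho)[0]


def rho_max(xi: float, pi: float) -> float:
    """Largest admissible rho for the marginal pair (xi, pi), by bisection."""
    lo, hi = 0.0, 1.0 - 1e-9
    if is_feasible(xi, pi, hi):
        return hi
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if is_feasible(xi, pi, mid):
            lo = mid
        else:
            hi = mid
    return lo


def clamp_probability(p: float, n: int) -> float:
    """Clamp an estimated probability to [0.5/n, 1 - 0.5/n] for plug-in use."""
    lo = 0.5 / n
    return min(max(p, lo), 1.0 - lo)


def clamp_rho(rho: float, xi: float, pi: float) -> float:
    """Clamp an estimated correlation into the admissible range for (xi, pi)."""
    if rho <= 0.0:
        return 0.0
    hi = rho_max(xi, pi) - _RHO_MARGIN
    return min(rho, max(hi, 0.0))


@dataclass(frozen=True)
class EndpointModel:
    """Endpoint model for one group: marginals, correlation, group size."""

    xi: float
    pi: float
    rho: float
    n: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be a positive integer")
        # raises InfeasibleModelError for inadmissible triples
        alpha_from_rho(self.xi, self.pi, self.rho)

    @property
    def alpha(self) -> float:
        return alpha_from_rho(self.xi, self.pi, self.rho)

    @property
    def beta(self) -> float:
        a = self.alpha
        return self.xi + a * (self.xi - self.pi)

    @property
    def p_short_given_responder(self) -> float:
        """Per-subject short-term response probability given long-term response."""
        a = self.alpha
        return (self.beta + a) / (1.0 + a)

    @property
    def p_short_given_nonresponder(self) -> float:
        a = self.alpha
        return self.beta / (1.0 + a)


@dataclass(frozen=True)
class SubjectCounts:
    """Aggregated responder counts for one group of n subjects."""

    x: int  # short-term responders
    y: int  # long-term responders
    z: int  # dual responders
    n: int

    def __post_init__(self):
        if not (0 <= self.x <= self.n and 0 <= self.y <= self.n):
            raise ValueError("x and y must lie in [0, n]")
        if not (max(0, self.x + self.y - self.n) <= self.z <= min(self.x, self.y)):
            raise ValueError("z must satisfy max(0, x+y-n) <= z <= min(x, y)")


def _conditional_probs(xi, pi, rho):
    a = alpha_from_rho(xi, pi, rho)
    beta = xi + a * (xi - pi)
    p1 = min(max((beta + a) / (1.0 + a), 0.0), 1.0)
    p0 = min(max(beta / (1.0 + a), 0.0), 1.0)
    return p1, p0


def cond_pmf_x_given_y(x: int, y: int, model: EndpointModel) -> float:
    """Pr(X = x | Y = y): convolution Bin(y, p1) + Bin(n - y, p0)."""
    p1, p0 = _conditional_probs(model.xi, model.pi, model.rho)
    n = model.n
    z = np.arange(max(0, x + y - n), min(x, y) + 1)
    if z.size == 0:
        return 0.0
    lp = _binom_logpmf(z, y, p1) + _binom_logpmf(x - z, n - y, p0)
    return float(np.exp(logsumexp(lp)))


def cond_pmf_matrix(model: EndpointModel) -> np.ndarray:
    """Matrix M with M[y, x] = Pr(X = x | Y = y) for all 0 <= x, y <= n."""
    p1, p0 = _conditional_probs(model.xi, model.pi, model.rho)
    n = model.n
    k = np.arange(n + 1)
    # row y of the convolution: pmf of Bin(y, p1) (length y+1) conv pmf of
    # Bin(n-y, p0) (length n-y+1) -> length n+1; done via outer z-sum
    y = k[:, None, None]          # (n+1, 1, 1)
    x = k[None, :, None]          # (1, n+1, 1)
    z = k[None, None, :]          # (1, 1, n+1)
    lp = _binom_logpmf(z, y, p1) + _binom_logpmf(x - z, n - y, p0)
    with np.errstate(over="ignore"):
        m = np.exp(lp)
    m[~np.isfinite(lp)] = 0.0
    return m.sum(axis=2)


def joint_pmf_xy(x: int, y: int, model: EndpointModel) -> float:
    """Pr(X = x, Y = y) = Bin(n, pi)(y) * Pr(X = x | Y = y)."""
    ly = _binom_logpmf(y, model.n, model.pi)
    return float(np.exp(ly)) * cond_pmf_x_given_y(x, y, model)


def joint_pmf_matrix(model: EndpointModel) -> np.ndarray:
    """Matrix J with J[y, x] = Pr(X = x, Y = y)."""
    py = binom_pmf_vector(model.n, model.pi)
    return py[:, None] * cond_pmf_matrix(model)


def cell_probs(model: EndpointModel) -> tuple[float, float, float, float]:
    """Per-subject cell probabilities (p11, p10, p01, p00).

    Cells are indexed (short, long): p11 dual responder, p10 short-only,
    p01 long-only, p00 neither.
    """
    p1 = model.p_short_given_responder
    p0 = model.p_short_given_nonresponder
    pi = model.pi
    p11 = pi * p1
    p01 = pi * (1.0 - p1)
    p10 = (1.0 - pi) * p0
    p00 = (1.0 - pi) * (1.0 - p0)
    return p11, p10, p01, p00


def counts_pmf(x: int, y: int, z: int, model: EndpointModel) -> float:
    """Pr(X = x, Y = y, Z = z): multinomial over the four per-subject cells."""
    n = model.n
    if not (0 <= z <= min(x, y) and z >= x + y - n and 0 <= x <= n and 0 <= y <= n):
        return 0.0
    p11, p10, p01, p00 = cell_probs(model)
    counts = np.array([z, x - z, y - z, n - x - y + z], dtype=float)
    probs = np.array([p11, p10, p01, p00])
    if np.any((probs == 0.0) & (counts > 0)):
        return 0.0
    logcoef = gammaln(n + 1.0) - gammaln(counts + 1.0).sum()
    logterm = np.where(counts > 0, counts * np.log(np.maximum(probs, 1e-300)), 0.0).sum()
    return float(np.exp(logcoef + logterm))


def sample_counts(model: EndpointModel, rng: np.random.Generator,
                  size: int | None = None):
    """Per-subject simulation aggregated to (x, y, z) counts.

    With ``size=None`` returns a single :class:`SubjectCounts`; with an
    integer ``size`` returns arrays ``(x, y, z)`` of that length (one
    replicate per row, n subjects each).
    """
    p1 = model.p_short_given_responder
    p0 = model.p_short_given_nonresponder
    m = 1 if size is None else size
    y_subj = rng.random((m, model.n)) < model.pi
    u = rng.random((m, model.n))
    x_subj = np.where(y_subj, u < p1, u < p0)
    x = x_subj.sum(axis=1)
    y = y_subj.sum(axis=1)
    z = (x_subj & y_subj).sum(axis=1)
    if size is None:
        return SubjectCounts(int(x[0]), int(y[0]), int(z[0]), model.n)
    return x, y, z


def loglik_rho(counts: SubjectCounts, xi: float, pi: float, rho) -> np.ndarray:
    """Log-likelihood of rho given the aggregated cell counts, margins fixed.

    The n subjects are iid over the four response cells (dual, short-only,
    long-only, neither), so up to a rho-free multinomial coefficient the
    log-likelihood is the sum of cell counts times log cell probabilities.
    The dual-responder count z carries essentially all the information
    about rho — the (x, y) margins alone leave the correlation nearly
    unidentified in a single trial.  Vectorized over a rho grid.
    """
    rho = np.atleast_1d(np.asarray(rho, dtype=float))
    x, y, z, n = counts.x, counts.y, counts.z, counts.n
    r = math.sqrt(pi * (1.0 - pi) / (xi * (1.0 - xi)))
    a = rho / (r - rho)
    beta = xi + a * (xi - pi)
    p1 = np.clip((beta + a) / (1.0 + a), 0.0, 1.0)
    p0 = np.clip(beta / (1.0 + a), 0.0, 1.0)
    cells = np.stack([pi * p1, (1.0 - pi) * p0, pi * (1.0 - p1),
                      (1.0 - pi) * (1.0 - p0)])
    cnts = np.array([z, x - z, y - z, n - x - y + z], dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(cnts == 0, 0.0,
                         cnts * np.log(np.maximum(cells, 1e-300)))
    return terms.sum(axis=0)


def profile_rho_mle(counts: SubjectCounts, xi_fixed: float, pi_fixed: float,
                    grid_size: int = 200) -> float:
    """Profile-likelihood estimate of rho with margins held fixed.

    Maximizes the bivariate binomial log-likelihood of the observed totals
    over the admissible rho interval: a dense grid pre-search (to avoid
    flat/boundary local maxima) followed by bounded scalar refinement to
    tolerance 1e-6.  Degenerate counts (x or y at 0 or n) make the
    likelihood rho-flat or boundary-attained; the maximizer is still
    returned (typically 0).
    """
    n = counts.n
    xi = clamp_probability(xi_fixed, n)
    pi = clamp_probability(pi_fixed, n)
    hi = rho_max(xi, pi) - _RHO_MARGIN
    if hi <= 0.0:
        return 0.0
    grid = np.linspace(0.0, hi, grid_size)
    ll = loglik_rho(counts, xi, pi, grid)
    best = int(np.argmax(ll))
    lo_b = grid[max(best - 1, 0)]
    hi_b = grid[min(best + 1, grid_size - 1)]
    if hi_b - lo_b < 1e-12:
        return float(grid[best])
    res = minimize_scalar(
        lambda r: -float(loglik_rho(counts, xi, pi, np.array([r]))[0]),
        bounds=(lo_b, hi_b), method="bounded",
        options={"xatol": 1e-6},
    )
    cand = float(res.x)
    if float(loglik_rho(counts, xi, pi, np.array([cand]))[0]) >= ll[best]:
        return cand
    return float(grid[best])


def pearson_rho(counts: SubjectCounts) -> float:
    """Pearson correlation of the per-subject binary pairs from aggregates.

    Returns 0 when either margin is degenerate (x or y in {0, n}), a
    neutral plug-in that keeps downstream computations defined.
    """
    n = counts.n
    px = counts.x / n
    py = counts.y / n
    var = px * (1.0 - px) * py * (1.0 - py)
    if var <= 0.0:
        return 0.0
    return (counts.z / n - px * py) / math.sqrt(var)
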