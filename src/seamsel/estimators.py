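"""Estimators of the endpoint probabilities under treatment selection.

Three families are provided for the short-term probability xi, the
long-term probability pi, and the endpoint correlation rho:

* **MLE** — the naive pooled proportion (stage 1 + stage 2) for the
  control and selected groups and the stage-1 proportion for the
  unselected groups, with Pearson's correlation on pooled counts.  It
  ignores the selection event and is conditionally biased upward for the
  selected group.
* **CMAE** — conditional mean-adjusted estimator: the MLE minus a plug-in
  estimate of its selection-conditional bias, the bias being available in
  closed form given the selection rule (sums of binomial and bivariate
  binomial probabilities weighted by selection probabilities).
* **UMVCUE** — the Rao-Blackwell estimator: the conditional expectation
  of the stage-2 proportion (which is unbiased because stage-2 data are
  untouched by the interim analysis) given the selection event and the
  sufficient statistics, yielding an exactly conditionally unbiased
  estimator for the control and selected groups.

For CMAE and UMVCUE the correlation is re-estimated by profiling the
bivariate binomial likelihood at the corresponding margin estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import bivbin
from .bivbin import (SubjectCounts, binom_pmf_vector, clamp_probability,
                     clamp_rho, pearson_rho, profile_rho_mle)
from .design import (DesignSpec, TrialData, ensure_continued, prob_select,
                     prob_select_given_count_vector)

__all__ = [
    "EstimateSet",
    "mle",
    "cmae_bias_xi",
    "cmae_bias_pi",
    "cmae",
    "umvcue_xi",
    "umvcue_pi",
    "umvcue",
    "estimate",
]


@dataclass(frozen=True)
class EstimateSet:
    """Estimates produced by one method for one trial realization.

    ``xi_hat`` covers every group (unselected groups fall back to their
    stage-1 MLE under UMVCUE); ``pi_hat`` and ``rho_hat`` are keyed by
    group index and populated for the control and selected groups.
    """

    method: str
    s: int
    xi_hat: tuple[float, ...]
    pi_hat: dict[int, float]
    rho_hat: dict[int, float]

    def __post_init__(self):
        if any(not 0.0 <= v <= 1.0 for v in self.xi_hat):
            raise ValueError("xi_hat entries must lie in [0, 1]")
        if any(not 0.0 <= v <= 1.0 for v in self.pi_hat.values()):
            raise ValueError("pi_hat entries must lie in [0, 1]")


def _mle_xi_vector(data: TrialData, design: DesignSpec) -> list[float]:
    out = []
    for g in range(design.G + 1):
        if g in (0, data.s):
            out.append(data.x_total(g) / design.n_total(g))
        else:
            out.append(data.x1[g] / design.n1[g])
    return out


def _pearson(data: TrialData, design: DesignSpec, g: int,
             rho_fixed: float | None = None) -> float:
    if rho_fixed is not None:
        return rho_fixed
    if data.z is None:
        return 0.0
    n = design.n_total(g)
    return pearson_rho(SubjectCounts(data.x_total(g), data.y[g], data.z[g], n))


def mle(data: TrialData, design: DesignSpec,
        rho_fixed: float | None = None) -> EstimateSet:
    """Naive pooled-proportion estimates; rho by Pearson on pooled counts.

    ``rho_fixed`` substitutes an externally assumed correlation when
    dual-responder counts are unavailable.
    """
    ensure_continued(data)
    xi_hat = _mle_xi_vector(data, design)
    pi_hat = {g: data.y[g] / design.n_total(g) for g in (0, data.s)}
    rho_hat = {g: _pearson(data, design, g, rho_fixed) for g in (0, data.s)}
    return EstimateSet("MLE", data.s, tuple(xi_hat), pi_hat, rho_hat)


def cmae_bias_xi(g: int, xi, s: int, design: DesignSpec) -> float:
    """Selection-conditional bias of the short-term MLE of group g.

    For continued groups (control and selected) the estimator pools both
    stages, so the bias is the stage-1 selection-tilted mean plus the
    stage-2 contribution (n2/N) xi_g, minus xi_g.  For unselected groups
    only stage 1 exists.  The control's bias is exactly 0 under the
    treatment-only rule because selection is independent of control data.
    """
    n1 = design.n1[g]
    pmf = binom_pmf_vector(n1, xi[g])
    w = prob_select_given_count_vector(s, g, xi, design)
    if g == s:
        p_sel = float(pmf @ w)
    else:
        p_sel = prob_select(s, xi, design)
    k = np.arange(n1 + 1)
    tilted = float((k * pmf * w).sum())
    if g in (0, s):
        n_tot = design.n_total(g)
        return tilted / (n_tot * p_sel) + design.n2[g] / n_tot * xi[g] - xi[g]
    return tilted / (n1 * p_sel) - xi[g]


def cmae_bias_pi(g: int, xi, pi_g: float, rho_g: float, s: int,
                 design: DesignSpec) -> float:
    """Selection-conditional bias of the long-term MLE of group g in {0, s}.

    A double sum over the stage-1 joint law of (X_g(1), Y_g(1)) — built
    from the bivariate binomial model at plug-in (xi_g, pi_g, rho_g) —
    weighted by Pr(Q=s | X_g(1)=k), plus the stage-2 term.  When rho = 0
    the long-term data are independent of the selection and the bias is 0.
    Infeasible plug-in triples are clamped into the admissible range.
    """
    if g not in (0, s):
        raise ValueError("long-term bias defined only for continued groups")
    n1 = design.n1[g]
    n_tot = design.n_total(g)
    xi_c = clamp_probability(xi[g], n_tot)
    pi_c = clamp_probability(pi_g, n_tot)
    rho_c = clamp_rho(rho_g, xi_c, pi_c)
    model = bivbin.EndpointModel(xi_c, pi_c, rho_c, n1)
    joint = bivbin.joint_pmf_matrix(model)          # [ky, kx]
    w = prob_select_given_count_vector(s, g, xi, design)
    p_sel = prob_select(s, xi, design)
    ky = np.arange(n1 + 1)
    tilted = float(ky @ joint @ w)
    return tilted / (n_tot * p_sel) + design.n2[g] / n_tot * pi_g - pi_g


def cmae(data: TrialData, design: DesignSpec, profile_rho: bool = True,
         rho_fixed: float | None = None) -> EstimateSet:
    """Conditional mean-adjusted estimates (plug-in bias subtraction).

    The bias functions are evaluated at the MLE (including Pearson's rho),
    subtracted from the MLE, and the results clipped to [0, 1]; rho is
    re-estimated by profile likelihood at the CMAE margins when
    ``profile_rho`` is set, otherwise the Pearson value is carried over.
    """
    ensure_continued(data)
    s = data.s
    xi_mle = _mle_xi_vector(data, design)
    xi_hat = []
    for g in range(design.G + 1):
        b = cmae_bias_xi(g, xi_mle, s, design)
        xi_hat.append(float(np.clip(xi_mle[g] - b, 0.0, 1.0)))
    pi_hat, rho_hat = {}, {}
    for g in (0, s):
        pi_mle = data.y[g] / design.n_total(g)
        rho_mle = _pearson(data, design, g, rho_fixed)
        b = cmae_bias_pi(g, xi_mle, pi_mle, rho_mle, s, design)
        pi_hat[g] = float(np.clip(pi_mle - b, 0.0, 1.0))
        if profile_rho and data.z is not None:
            n = design.n_total(g)
            counts = SubjectCounts(data.x_total(g), data.y[g], data.z[g], n)
            rho_hat[g] = profile_rho_mle(counts, xi_hat[g], pi_hat[g])
        else:
            rho_hat[g] = max(rho_mle, 0.0)
    return EstimateSet("CMAE", s, tuple(xi_hat), pi_hat, rho_hat)


def _umvcue_weights(g: int, data: TrialData, design: DesignSpec) -> np.ndarray:
    """Pr(Q=s | W1, X_g(1)=kx) over kx = 0..n1_g, up to a constant factor.

    Under the treatment-only rule, conditioning on W1 fixes every
    competitor's stage-1 count, so for g = s the weight is a deterministic
    0/1 indicator of the selection rule with the tie-break; for the
    control the weight does not depend on kx and a constant 1 is returned
    (it cancels in the estimator's ratio).
    """
    n1 = design.n1[g]
    if g != data.s:
        return np.ones(n1 + 1)
    s = data.s
    w = np.ones(n1 + 1)
    for k in range(n1 + 1):
        for h in design.selectable:
            if h == s:
                continue
            lhs, rhs = k * design.n1[h], data.x1[h] * design.n1[s]
            ok = lhs > rhs if h < s else lhs >= rhs
            if not ok:
                w[k] = 0.0
                break
    return w


def umvcue_xi(g: int, data: TrialData, design: DesignSpec) -> float:
    """Rao-Blackwell estimate of xi_g for g in {0, s}.

    Conditional expectation of X_g(2)/N_g(2) given the selection and the
    sufficient statistic: a ratio of hypergeometric-type sums over the
    unobserved stage-1 split, weighted by the selection indicator.  For
    the control the weights are constant and the estimator collapses to
    the pooled MLE X_g/N_g.
    """
    if g not in (0, data.s):
        raise ValueError("UMVCUE defined only for continued groups")
    n1, n2 = design.n1[g], design.n2[g]
    if n2 == 0:
        raise ValueError("UMVCUE undefined without stage-2 subjects")
    x_tot = data.x_total(g)
    kx = np.arange(n1 + 1)
    logc = bivbin._log_comb(n1, kx) + bivbin._log_comb(n2, x_tot - kx)
    w = _umvcue_weights(g, data, design)
    terms = np.exp(logc - logc[np.isfinite(logc)].max()) * w
    denom = terms.sum()
    mean_k1 = float((kx * terms).sum() / denom)
    return (x_tot - mean_k1) / n2


def umvcue_pi(g: int, data: TrialData, design: DesignSpec) -> float:
    """Rao-Blackwell estimate of pi_g for g in {0, s}.

    Conditional expectation of Y_g(2)/N_g(2) given the selection and the
    sufficient statistic (which includes the dual-responder totals).  The
    stage split of the per-subject response cells is multivariate
    hypergeometric given the totals, giving a parameter-free triple sum
    over (kx, ky, kz) with coefficient

        c = C(n1, ky) C(n2, Y-ky) C(ky, kz) C(n1-ky, kx-kz)
            * C(Y-ky, Z-kz) C(n2-Y+ky, X-kx-Z+kz)

    weighted by the selection indicator in kx; out-of-range triples
    contribute zero through the C(a, b) = 0 convention.
    """
    if g not in (0, data.s):
        raise ValueError("UMVCUE defined only for continued groups")
    n1, n2 = design.n1[g], design.n2[g]
    if n2 == 0:
        raise ValueError("UMVCUE undefined without stage-2 subjects")
    x_tot, y_tot, z_tot = data.x_total(g), data.y_total(g), data.z_total(g)
    k = np.arange(n1 + 1)
    kx = k[:, None, None]
    ky = k[None, :, None]
    kz = k[None, None, :]
    logc = (bivbin._log_comb(n1, ky)
            + bivbin._log_comb(n2, y_tot - ky)
            + bivbin._log_comb(ky, kz)
            + bivbin._log_comb(n1 - ky, kx - kz)
            + bivbin._log_comb(y_tot - ky, z_tot - kz)
            + bivbin._log_comb(n2 - y_tot + ky, x_tot - kx - z_tot + kz))
    w = _umvcue_weights(g, data, design)[:, None, None]
    finite = np.isfinite(logc)
    if not finite.any():
        raise ValueError("empty support in UMVCUE sum (inconsistent counts)")
    c = np.exp(logc - logc[finite].max())
    c[~finite] = 0.0
    terms = c * w
    denom = terms.sum()
    mean_ky1 = float((terms * k[None, :, None]).sum() / denom)
    return (y_tot - mean_ky1) / n2


def umvcue(data: TrialData, design: DesignSpec,
           profile_rho: bool = True) -> EstimateSet:
    """Rao-Blackwell estimates for the continued groups, MLE elsewhere."""
    ensure_continued(data)
    s = data.s
    xi_mle = _mle_xi_vector(data, design)
    xi_hat = list(xi_mle)
    for g in (0, s):
        xi_hat[g] = umvcue_xi(g, data, design)
    pi_hat, rho_hat = {}, {}
    for g in (0, s):
        pi_hat[g] = umvcue_pi(g, data, design)
        if profile_rho and data.z is not None:
            n = design.n_total(g)
            counts = SubjectCounts(data.x_total(g), data.y[g], data.z[g], n)
            rho_hat[g] = profile_rho_mle(counts, xi_hat[g], pi_hat[g])
        else:
            rho_hat[g] = max(_pearson(data, design, g), 0.0)
    return EstimateSet("UMVCUE", s, tuple(xi_hat), pi_hat, rho_hat)


_METHODS = {"MLE": mle, "CMAE": cmae, "UMVCUE": umvcue}


def estimate(method: str, data: TrialData, design: DesignSpec,
             **kw) -> EstimateSet:
    """Dispatch by method name ('MLE', 'CMAE', 'UMVCUE')."""
    try:
        fn = _METHODS[method.upper()]
    except KeyError:
        raise ValueError(f"unknown method {method!r}") from None
    if method.upper() == "MLE":
        kw.pop("profile_rho", None)
    return fn(data, design, **kw)
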