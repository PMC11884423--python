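"""Trial design, treatment-selection rules, and selection probabilities.

A two-stage seamless phase II/III trial randomizes subjects to a control
group (index 0) and G treatment groups (indices 1..G).  At the interim
analysis the treatment with the highest stage-1 short-term response RATE
is selected (smallest index on ties, i.e. the lowest dose for safety);
optionally the control group can be included in the rule, in which case a
control "win" stops the trial for lack of benefit.  Stage 2 enrolls
additional subjects only in the control and selected groups.

Selection probabilities Pr(Q=s) and Pr(Q=s | X_g(1)=k) are computed in
closed form by products of binomial CDFs on the rate scale, with all rate
comparisons done in exact integer arithmetic so that the smallest-index
tie-break is honored even with unequal stage-1 sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .bivbin import binom_pmf_vector

__all__ = [
    "DesignSpec",
    "TrialData",
    "TrialStopped",
    "select_treatment",
    "selection_weights",
    "prob_select_given_count",
    "prob_select_given_count_vector",
    "prob_select",
    "expected_selected_value",
]

TREATMENT_RULE = "treatment"
CONTROL_RULE = "control-inclusive"


class TrialStopped(RuntimeError):
    """Raised when the control-inclusive rule selects the control group."""


def ensure_continued(data) -> None:
    """Refuse final-analysis computations for an early-stopped trial.

    The control-inclusive rule can select the control (Q = 0), meaning
    the trial stops for lack of benefit; estimation and testing are only
    defined for trials that continued with a selected treatment.
    """
    if data.s == 0:
        raise TrialStopped(
            "control group won the interim comparison; no final-analysis "
            "inference is defined for a stopped trial")


@dataclass(frozen=True)
class DesignSpec:
    """Design of a two-stage trial with G treatment groups plus control.

    ``n1[g]`` and ``n2[g]`` are the stage-1 and stage-2 sample sizes of
    group g (index 0 = control).  ``n2`` is only consumed for groups that
    continue to stage 2 (control and the selected treatment).
    """

    G: int
    n1: tuple[int, ...]
    n2: tuple[int, ...]
    rule: str = TREATMENT_RULE
    level: float = 0.025

    def __post_init__(self):
        if self.G < 1:
            raise ValueError("G must be >= 1")
        object.__setattr__(self, "n1", tuple(int(v) for v in self.n1))
        object.__setattr__(self, "n2", tuple(int(v) for v in self.n2))
        if len(self.n1) != self.G + 1 or len(self.n2) != self.G + 1:
            raise ValueError("n1 and n2 need one entry per group incl. control")
        if any(v <= 0 for v in self.n1):
            raise ValueError("all stage-1 sizes must be positive")
        if self.rule not in (TREATMENT_RULE, CONTROL_RULE):
            raise ValueError(f"unknown selection rule {self.rule!r}")
        if not (0.0 < self.level < 0.5):
            raise ValueError("one-sided level must lie in (0, 0.5)")

    @classmethod
    def from_total(cls, G: int, N: int, tau: float, **kw) -> "DesignSpec":
        """Equal per-group total N with information fraction tau."""
        if not (0.0 < tau < 1.0):
            raise ValueError("tau must lie in (0, 1)")
        n1 = int(round(tau * N))
        if n1 <= 0 or n1 >= N:
            raise ValueError("tau * N must round to an interior stage split")
        return cls(G=G, n1=(n1,) * (G + 1), n2=(N - n1,) * (G + 1), **kw)

    @property
    def selectable(self) -> range:
        """Group indices participating in the selection rule."""
        return range(0 if self.rule == CONTROL_RULE else 1, self.G + 1)

    def n_total(self, g: int) -> int:
        return self.n1[g] + self.n2[g]


@dataclass
class TrialData:
    """Observed counts of one trial realization.

    ``x1`` holds stage-1 short-term counts for every group.  Stage-2
    short-term counts ``x2`` and long-term / dual-responder totals ``y``
    and ``z`` are dictionaries keyed by group index, populated only for
    the groups that continued (control and selected).  The per-stage
    long-term splits ``y1``/``z1`` are recorded when known (simulation)
    but no estimator or test consumes them — only totals and stage sizes
    enter the formulas.  ``z`` may be omitted (real data sets often do not
    report dual responders); estimators that need it then refuse.
    """

    s: int
    x1: tuple[int, ...]
    x2: dict[int, int]
    y: dict[int, int]
    z: dict[int, int] | None = None
    y1: dict[int, int] | None = None
    z1: dict[int, int] | None = None

    def validate(self, design: DesignSpec) -> None:
        if len(self.x1) != design.G + 1:
            raise ValueError("x1 needs one entry per group incl. control")
        for g, k in enumerate(self.x1):
            if not 0 <= k <= design.n1[g]:
                raise ValueError(f"x1[{g}]={k} outside [0, {design.n1[g]}]")
        if self.s not in range(0, design.G + 1):
            raise ValueError(f"selected index s={self.s} out of range")
        chosen = select_treatment(self.x1, design)
        if chosen != self.s:
            raise ValueError(
                f"s={self.s} inconsistent with selection rule (expected {chosen})"
            )
        for g in (0, self.s):
            if g not in self.x2 or g not in self.y:
                raise ValueError(f"stage-2 record missing for group {g}")
            if not 0 <= self.x2[g] <= design.n2[g]:
                raise ValueError(f"x2[{g}] outside [0, {design.n2[g]}]")
            n = design.n_total(g)
            if not 0 <= self.y[g] <= n:
                raise ValueError(f"y[{g}] outside [0, {n}]")
            if self.z is not None:
                x, y, z = self.x_total(g), self.y[g], self.z[g]
                if not max(0, x + y - n) <= z <= min(x, y):
                    raise ValueError(
                        f"z[{g}]={z} violates max(0, x+y-n) <= z <= min(x, y)"
                    )

    def x_total(self, g: int) -> int:
        return self.x1[g] + self.x2[g]

    def y_total(self, g: int) -> int:
        return self.y[g]

    def z_total(self, g: int) -> int:
        if self.z is None:
            raise ValueError("dual-responder counts z are not available")
        return self.z[g]

    @property
    def t(self) -> int:
        """Total long-term responders T = Y0 + Ys."""
        return self.y[0] + self.y[self.s]


def select_treatment(x1, design: DesignSpec) -> int:
    """Index selected by the rule: argmax response rate, smallest index wins ties.

    Rates are compared by exact cross-multiplication, never floats, so
    ties are detected exactly with unequal stage-1 sizes.  Under the
    control-inclusive rule the returned index may be 0, which downstream
    analyses treat as an early stop.
    """
    best = None
    for g in design.selectable:
        if best is None or x1[g] * design.n1[best] > x1[best] * design.n1[g]:
            best = g
    return best


def _beat_prob_vector(s: int, h: int, xi_h: float,
                      design: DesignSpec) -> np.ndarray:
    """Pr(group h loses to s at rate k/n1_s) for k = 0..n1_s.

    The count of losing values j of X_h(1) — #{j : j/n1_h < (or <=, by
    the tie-break) k/n1_s} — is computed in exact integer arithmetic.
    """
    n_s, n_h = design.n1[s], design.n1[h]
    k = np.arange(n_s + 1)
    thr = k * n_h
    if h < s:  # h would win ties: s must be strictly larger
        cnt = np.where(thr > 0, (thr - 1) // n_s + 1, 0)
    else:
        cnt = thr // n_s + 1
    cnt = np.minimum(cnt, n_h + 1)
    cdf = np.concatenate([[0.0], np.cumsum(binom_pmf_vector(n_h, xi_h))])
    return cdf[cnt]


@lru_cache(maxsize=512)
def _selection_weights_cached(s: int, xi: tuple, design: DesignSpec):
    w = np.ones(design.n1[s] + 1)
    for h in design.selectable:
        if h != s:
            w *= _beat_prob_vector(s, h, xi[h], design)
    w.setflags(write=False)
    return w


def selection_weights(s: int, xi, design: DesignSpec) -> np.ndarray:
    """Vector over k = 0..n1_s of Pr(Q = s | X_s(1) = k)."""
    if s not in design.selectable:
        raise ValueError(f"group {s} is not selectable under rule {design.rule!r}")
    return _selection_weights_cached(s, tuple(float(v) for v in xi), design)


def prob_select(s: int, xi, design: DesignSpec) -> float:
    """Unconditional selection probability Pr(Q = s)."""
    w = selection_weights(s, xi, design)
    pmf = binom_pmf_vector(design.n1[s], xi[s])
    return float(pmf @ w)


@lru_cache(maxsize=512)
def _competitor_weights_cached(s: int, g: int, xi: tuple,
                               design: DesignSpec) -> np.ndarray:
    """Pr(Q=s | X_g(1)=k) over k = 0..n1_g for a competing group g.

    Sums the selected group's count j out against the remaining groups:
    A[j] = Pr(X_s(1)=j) * prod_{h not in {g, s}} Pr(h loses at j); the
    condition "s beats g at (j, k)" is a threshold in j, so the vector
    over k is a suffix sum of A.
    """
    n_s, n_g = design.n1[s], design.n1[g]
    a = binom_pmf_vector(n_s, xi[s])
    for h in design.selectable:
        if h not in (g, s):
            a = a * _beat_prob_vector(s, h, xi[h], design)
    k = np.arange(n_g + 1)
    if g < s:  # s must be strictly larger: j * n_g > k * n_s
        j_min = k * n_s // n_g + 1
    else:      # j * n_g >= k * n_s
        j_min = (k * n_s + n_g - 1) // n_g
    suffix = np.concatenate([np.cumsum(a[::-1])[::-1], [0.0]])
    out = suffix[np.clip(j_min, 0, n_s + 1)]
    out.setflags(write=False)
    return out


def prob_select_given_count(s: int, g: int, k: int, xi,
                            design: DesignSpec) -> float:
    """Pr(Q = s | X_g(1) = k).

    For g = s this is the closed-form product of competitor CDFs; for a
    group outside the rule's set (the control under the treatment-only
    rule) selection is independent of X_g(1) and the unconditional
    probability is returned; for a competing group the joint law of the
    remaining groups is summed out.
    """
    if g == s:
        return float(selection_weights(s, xi, design)[k])
    if g not in design.selectable:
        return prob_select(s, xi, design)
    xi_t = tuple(float(v) for v in xi)
    return float(_competitor_weights_cached(s, g, xi_t, design)[k])


def prob_select_given_count_vector(s: int, g: int, xi,
                                   design: DesignSpec) -> np.ndarray:
    """Vector of Pr(Q = s | X_g(1) = k) over k = 0..n1_g."""
    xi_t = tuple(float(v) for v in xi)
    if g == s:
        return selection_weights(s, xi, design)
    if g not in design.selectable:
        p = prob_select(s, xi, design)
        return np.full(design.n1[g] + 1, p)
    return _competitor_weights_cached(s, g, xi_t, design)


def expected_selected_value(values, xi, design: DesignSpec) -> float:
    """E over the selection rule of a per-treatment quantity.

    ``values`` has one entry per treatment group (index 1..G accepted
    either as a length-G sequence or a length-(G+1) sequence whose entry 0
    is ignored).  Returns sum_s values[s] * Pr(Q = s) by exact
    enumeration — no simulation.  Only defined for the treatment-only rule
    (where the selection probabilities sum to 1 over treatments).
    """
    vals = list(values)
    if len(vals) == design.G:
        vals = [None] + vals
    if len(vals) != design.G + 1:
        raise ValueError("need one value per treatment group")
    return float(sum(vals[s] * prob_select(s, xi, design)
                     for s in design.selectable if s != 0))
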