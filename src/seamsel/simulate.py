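"""Scenario definitions and operating-characteristics simulation engine.

Scenarios follow a standard five-family grid for a seamless phase II/III
study with G treatment groups and one control, total per-group size N,
information fraction tau and common endpoint correlation rho:

1. global null, all probabilities equal (baseline in {0.1, 0.5, 0.7});
2. null with different short- and long-term baselines (xi in {0.3, 0.7},
   pi = 0.5; rho restricted to the admissible range);
3. only the last treatment effective: 0.5 + delta * 1(g = G);
4. linear dose effect: 0.5 + g * delta / G;
5. all treatments effective: 0.5 + delta,

with effect size delta = 0.280 for N = 50 and 0.145 for N = 200 (the
short- and long-term probabilities move together except in scenario 2).

``run_study`` simulates R replicate trials, applies the requested
estimators, tests and confidence intervals to each, and aggregates the
operating characteristics: mean and RMSE of the selected-group estimates
against the realized selected group's true values, rejection rates,
and coverage of the true log-odds difference, each with Monte Carlo
standard errors.  Results are bit-reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bivbin
from .bivbin import EndpointModel, InfeasibleModelError, is_feasible
from .design import DesignSpec, TrialData, expected_selected_value
from .estimators import estimate
from .inference import confidence_interval, p_values

__all__ = ["Scenario", "SimResult", "scenario_params", "simulate_trial",
           "simulate_trials", "run_study"]

_DELTA_BY_N = {50: 0.280, 200: 0.145}


@dataclass(frozen=True)
class Scenario:
    """One cell of the simulation grid."""

    id: int
    G: int
    N: int
    tau: float
    rho: float
    baseline: float = 0.5       # scenarios 1-2: common (short-term) baseline
    delta: float | None = None  # scenarios 3-5; default keyed on N

    def __post_init__(self):
        if self.id not in (1, 2, 3, 4, 5):
            raise ValueError("scenario id must be 1..5")
        if self.id >= 3 and self.delta is None:
            if self.N not in _DELTA_BY_N:
                raise ValueError(f"no default delta for N={self.N}; pass delta=")
            object.__setattr__(self, "delta", _DELTA_BY_N[self.N])

    def design(self, **kw) -> DesignSpec:
        return DesignSpec.from_total(self.G, self.N, self.tau, **kw)


def scenario_params(scenario: Scenario) -> tuple[np.ndarray, np.ndarray]:
    """Per-group (xi, pi) vectors (index 0 = control) with feasibility check."""
    G, d = scenario.G, scenario.delta
    g = np.arange(G + 1)
    if scenario.id == 1:
        xi = np.full(G + 1, scenario.baseline)
        pi = xi.copy()
    elif scenario.id == 2:
        xi = np.full(G + 1, scenario.baseline)
        pi = np.full(G + 1, 0.5)
    elif scenario.id == 3:
        xi = 0.5 + d * (g == G)
        pi = xi.copy()
    elif scenario.id == 4:
        xi = 0.5 + g * d / G
        pi = xi.copy()
    else:
        xi = 0.5 + d * (g >= 1)
        pi = xi.copy()
    for gg in range(G + 1):
        if not is_feasible(float(xi[gg]), float(pi[gg]), scenario.rho):
            raise InfeasibleModelError(
                f"(xi={xi[gg]}, pi={pi[gg]}, rho={scenario.rho}) is outside "
                "the admissible correlation range of the bivariate binomial "
                "model; choose a smaller rho for this scenario"
            )
    return xi, pi


def _split_counts(xi, pi, rho, n, rng, reps):
    """Per-subject draws for `reps` replicates of one group-stage."""
    model = EndpointModel(float(xi), float(pi), float(rho), n)
    return bivbin.sample_counts(model, rng, size=reps)


def simulate_trials(scenario: Scenario, design: DesignSpec,
                    rng: np.random.Generator, reps: int) -> list[TrialData]:
    """Simulate `reps` trials: stage-1 for all groups, selection, stage-2
    for control and selected group only (per-subject generation, so dual
    responder counts are exact)."""
    xi, pi = scenario_params(scenario)
    G = scenario.G
    x1 = np.empty((reps, G + 1), dtype=int)
    y1 = np.empty((reps, G + 1), dtype=int)
    z1 = np.empty((reps, G + 1), dtype=int)
    for g in range(G + 1):
        x1[:, g], y1[:, g], z1[:, g] = _split_counts(
            xi[g], pi[g], scenario.rho, design.n1[g], rng, reps)
    # exact rate comparison with first-index tie-break: scale counts to a
    # common denominator (integer), then argmax (np.argmax returns the
    # first maximizer)
    n1 = np.array(design.n1)
    L = math.lcm(*design.n1[1:]) if G >= 1 else 1
    keys = x1[:, 1:] * (L // n1[1:])[None, :]
    sel = keys.argmax(axis=1) + 1
    x2 = np.zeros((reps, G + 1), dtype=int)
    y2 = np.zeros((reps, G + 1), dtype=int)
    z2 = np.zeros((reps, G + 1), dtype=int)
    # control continues in every replicate
    x2[:, 0], y2[:, 0], z2[:, 0] = _split_counts(
        xi[0], pi[0], scenario.rho, design.n2[0], rng, reps)
    for g in range(1, G + 1):
        mask = sel == g
        m = int(mask.sum())
        if m == 0:
            continue
        x2[mask, g], y2[mask, g], z2[mask, g] = _split_counts(
            xi[g], pi[g], scenario.rho, design.n2[g], rng, m)
    out = []
    for r in range(reps):
        s = int(sel[r])
        out.append(TrialData(
            s=s,
            x1=tuple(int(v) for v in x1[r]),
            x2={0: int(x2[r, 0]), s: int(x2[r, s])},
            y={0: int(y1[r, 0] + y2[r, 0]), s: int(y1[r, s] + y2[r, s])},
            z={0: int(z1[r, 0] + z2[r, 0]), s: int(z1[r, s] + z2[r, s])},
            y1={0: int(y1[r, 0]), s: int(y1[r, s])},
            z1={0: int(z1[r, 0]), s: int(z1[r, s])},
        ))
    return out


def simulate_trial(scenario: Scenario, design: DesignSpec,
                   rng: np.random.Generator) -> TrialData:
    """Single simulated trial realization."""
    return simulate_trials(scenario, design, rng, 1)[0]


@dataclass
class SimResult:
    """Aggregated operating characteristics of one simulation setting."""

    scenario: Scenario
    R: int
    seed: int
    estimates: pd.DataFrame          # method, parameter, mean, rmse, mc_se_mean
    tests: pd.DataFrame              # method, test, reject_pct, mc_se_pct
    coverage: pd.DataFrame           # method, variant, cp_pct, mc_se_pct
    e_pi_s: float = math.nan         # analytic E[pi_s] (enumeration)
    e_xi_s: float = math.nan

    def to_frame(self) -> pd.DataFrame:
        """Long-format table of every aggregate, CSV-ready."""
        rows = []
        meta = dict(scenario=self.scenario.id, G=self.scenario.G,
                    N=self.scenario.N, tau=self.scenario.tau,
                    rho=self.scenario.rho, R=self.R, seed=self.seed)
        for _, r in self.estimates.iterrows():
            rows.append({**meta, "method": r["method"], "test": "",
                         "quantity": f"mean_{r['parameter']}",
                         "value": r["mean"], "mc_se": r["mc_se_mean"]})
            rows.append({**meta, "method": r["method"], "test": "",
                         "quantity": f"rmse_{r['parameter']}",
                         "value": r["rmse"], "mc_se": np.nan})
        for _, r in self.tests.iterrows():
            rows.append({**meta, "method": r["method"], "test": r["test"],
                         "quantity": "reject_pct", "value": r["reject_pct"],
                         "mc_se": r["mc_se_pct"]})
        for _, r in self.coverage.iterrows():
            rows.append({**meta, "method": r["method"], "test": r["variant"],
                         "quantity": "coverage_pct", "value": r["cp_pct"],
                         "mc_se": r["mc_se_pct"]})
        rows.append({**meta, "method": "", "test": "", "quantity": "E_pi_s",
                     "value": self.e_pi_s, "mc_se": np.nan})
        rows.append({**meta, "method": "", "test": "", "quantity": "E_xi_s",
                     "value": self.e_xi_s, "mc_se": np.nan})
        return pd.DataFrame(rows)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def run_study(scenario: Scenario,
              R: int,
              seed: int,
              methods: tuple[str, ...] = ("MLE", "CMAE", "UMVCUE"),
              tests: tuple[str, ...] = ("exact", "midp"),
              ci: tuple[tuple[str, str], ...] | None = None,
              design: DesignSpec | None = None,
              progress=None) -> SimResult:
    """Simulate R trials and aggregate operating characteristics.

    ``tests`` selects p-value variants (computed for every method in
    ``methods``); ``ci`` is a tuple of (method, variant) pairs for which
    confidence intervals and coverage are computed — default: every
    requested method crossed with every requested test variant.
    Profile-likelihood rho estimation runs only for methods that feed a
    test or interval (the estimator means do not involve rho).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    design = design or scenario.design()
    methods = tuple(m.upper() for m in methods)
    tests = tuple(tests)
    if ci is None:
        ci = tuple((m, v) for m in methods for v in tests)
    ci = tuple((m.upper(), v) for m, v in ci)
    xi, pi = scenario_params(scenario)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    trials = simulate_trials(scenario, design, rng, R)

    needs_rho = {m for m in methods if tests or any(c[0] == m for c in ci)}
    est_rows = {m: {"xi": [], "pi": [], "xi_true": [], "pi_true": []}
                for m in methods}
    rej = {(m, t): 0 for m in methods for t in tests}
    cover = {c: 0 for c in ci}

    for i, trial in enumerate(trials):
        s = trial.s
        d_true = _logit(float(pi[s])) - _logit(float(pi[0]))
        for m in methods:
            kw = {}
            if m in ("CMAE", "UMVCUE"):
                kw["profile_rho"] = m in needs_rho
            es = estimate(m, trial, design, **kw)
            est_rows[m]["xi"].append(es.xi_hat[s])
            est_rows[m]["pi"].append(es.pi_hat[s])
            est_rows[m]["xi_true"].append(float(xi[s]))
            est_rows[m]["pi_true"].append(float(pi[s]))
            if tests:
                tr = p_values(trial, es, design)
                if "exact" in tests and tr.reject_exact:
                    rej[(m, "exact")] += 1
                if "midp" in tests and tr.reject_midp:
                    rej[(m, "midp")] += 1
            for (cm, cv) in ci:
                if cm != m:
                    continue
                interval = confidence_interval(trial, es, design,
                                               level=0.95, variant=cv)
                if interval.contains(d_true):
                    cover[(cm, cv)] += 1
        if progress is not None and (i + 1) % 500 == 0:
            progress(i + 1, R)

    est_records = []
    for m in methods:
        for par in ("xi", "pi"):
            vals = np.array(est_rows[m][par])
            truth = np.array(est_rows[m][f"{par}_true"])
            est_records.append({
                "method": m, "parameter": f"{par}_s",
                "mean": float(vals.mean()),
                "rmse": float(np.sqrt(((vals - truth) ** 2).mean())),
                "mc_se_mean": float(vals.std(ddof=1) / math.sqrt(R)),
            })
    test_records = []
    for (m, t), cnt in rej.items():
        p = cnt / R
        test_records.append({"method": m, "test": t,
                             "reject_pct": 100.0 * p,
                             "mc_se_pct": 100.0 * math.sqrt(p * (1 - p) / R)})
    cov_records = []
    for (m, v), cnt in cover.items():
        p = cnt / R
        cov_records.append({"method": m, "variant": v,
                            "cp_pct": 100.0 * p,
                            "mc_se_pct": 100.0 * math.sqrt(p * (1 - p) / R)})
    e_pi = expected_selected_value(list(pi[1:]), xi, design)
    e_xi = expected_selected_value(list(xi[1:]), xi, design)
    return SimResult(
        scenario=scenario, R=R, seed=seed,
        estimates=pd.DataFrame(est_records),
        tests=pd.DataFrame(test_records,
                           columns=["method", "test", "reject_pct", "mc_se_pct"]),
        coverage=pd.DataFrame(cov_records,
                              columns=["method", "variant", "cp_pct",
                                       "mc_se_pct"]),
        e_pi_s=e_pi, e_xi_s=e_xi,
    )
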