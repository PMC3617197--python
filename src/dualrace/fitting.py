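"""Simulation-based maximum-likelihood fitting.

The data enter the fit as a joint histogram of raw processing time
(35 ms bins) by correctness.  For a candidate parameter vector the model
is simulated at the subject's observed designs (gaps resampled with
replacement) and the resulting cell frequencies, smoothed with a small
pseudo-count, define a multinomial likelihood of the observed counts.
Common random numbers — one set of base draws reused for every
evaluation — make the likelihood surface deterministic and smooth in
the parameters for a fixed seed, so a derivative-free optimizer
(Nelder–Mead with Latin-hypercube multi-starts in a transformed,
unconstrained space) can maximize it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit
from scipy.stats import qmc
from sklearn.base import BaseEstimator

from .comparison import ModelSpec, get_model
from .params import RESPONSE_THRESHOLD

__all__ = [
    "RPTHistogram",
    "FitResult",
    "bin_rpt",
    "estimate_log_likelihood",
    "information_criteria",
    "ModelFitter",
    "fit_subject",
]


@dataclass(frozen=True)
class RPTHistogram:
    """Joint histogram of raw processing time by correctness.

    Uniform bins aligned to zero (an edge falls on rPT = 0) spanning the
    observed range.
    """

    bin_edges: np.ndarray
    counts_correct: np.ndarray
    counts_error: np.ndarray

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def n_total(self) -> int:
        return int(self.counts_correct.sum() + self.counts_error.sum())


def bin_rpt(trials: pd.DataFrame, bin_width: float = 35.0) -> RPTHistogram:
    """Bin trials into the (rPT bin × correctness) histogram.

    ``trials`` needs columns ``rpt_ms`` and ``correct``.
    """
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    rpt = trials["rpt_ms"].to_numpy(dtype=float)
    correct = trials["correct"].to_numpy(dtype=bool)
    lo = np.floor(rpt.min() / bin_width) * bin_width
    hi = np.ceil(rpt.max() / bin_width) * bin_width
    if hi <= rpt.max():  # max exactly on an edge: keep it in the last bin
        hi += bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    cc, _ = np.histogram(rpt[correct], bins=edges)
    ce, _ = np.histogram(rpt[~correct], bins=edges)
    return RPTHistogram(bin_edges=edges, counts_correct=cc, counts_error=ce)


def information_criteria(logL: float, p: int, n: int) -> tuple[float, float]:
    """AIC and BIC for ``p`` free parameters and ``n`` observations:
    ``AIC = 2p - 2 logL``; ``BIC = p ln n - 2 logL``."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    aic = 2.0 * p - 2.0 * logL
    bic = p * np.log(n) - 2.0 * logL
    return float(aic), float(bic)


def _predicted_cell_logprobs(
    sim_rpt: np.ndarray,
    sim_correct: np.ndarray,
    hist: RPTHistogram,
    smoothing: float,
    pool_correctness: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Smoothed log cell probabilities from simulated trials.

    Simulated mass falling outside the observed range (including
    censored never-finishing trials at +inf) stays in the normalizer, so
    parameter values that push predicted responses off the observed
    support are penalized rather than ignored.
    """
    edges = hist.bin_edges
    finite = np.isfinite(sim_rpt)
    n_sim = len(sim_rpt)
    if pool_correctness:
        counts, _ = np.histogram(sim_rpt[finite], bins=edges)
        n_cells = len(counts)
        denom = n_sim + smoothing * n_cells
        logp = np.log((counts + smoothing) / denom)
        return logp, logp
    cc, _ = np.histogram(sim_rpt[finite & sim_correct], bins=edges)
    ce, _ = np.histogram(sim_rpt[finite & ~sim_correct], bins=edges)
    n_cells = 2 * len(cc)
    denom = n_sim + smoothing * n_cells
    return (
        np.log((cc + smoothing) / denom),
        np.log((ce + smoothing) / denom),
    )


def estimate_log_likelihood(
    model: ModelSpec | str,
    params: dict[str, float],
    designs: pd.DataFrame,
    observed: RPTHistogram,
    n_sim: int = 20_000,
    seed: int = 0,
    smoothing: float = 0.5,
    pool_correctness: bool = False,
    base: dict | None = None,
    design_idx: np.ndarray | None = None,
) -> float:
    """Simulated multinomial log-likelihood of an observed histogram.

    ``base``/``design_idx`` allow a caller to supply pre-drawn base
    randomness and design resampling indices (common random numbers);
    otherwise both are drawn from ``seed``.
    """
    if isinstance(model, str):
        model = get_model(model)
    if n_sim < 1000:
        raise ValueError("n_sim must be >= 1000 for a usable likelihood")
    rng = np.random.default_rng(seed)
    if design_idx is None:
        design_idx = rng.integers(0, len(designs), size=n_sim)
    if base is None:
        base = model.sample_base(rng, n_sim)
    gap = designs["gap_ms"].to_numpy(dtype=float)[design_idx]
    target = designs["target_side"].to_numpy(dtype="U1")[design_idx]
    if "more_frequent_side" in designs.columns:
        mfs = designs["more_frequent_side"].to_numpy(dtype=object)[design_idx]
    else:
        mfs = np.full(n_sim, None, dtype=object)
    sim_rpt, sim_correct = model.solve_rpt(params, base, gap, target, mfs)
    logp_c, logp_e = _predicted_cell_logprobs(
        sim_rpt, sim_correct, observed, smoothing, pool_correctness
    )
    return float(
        observed.counts_correct @ logp_c + observed.counts_error @ logp_e
    )


# ------------------------------------------------------------ transforms

def _to_unconstrained(kind: str, value: float) -> float:
    if kind == "identity":
        return value
    if kind == "log":
        return float(np.log(value))
    if kind == "logit":
        return float(logit(value))
    if kind == "logit_threshold":
        return float(logit(value / RESPONSE_THRESHOLD))
    if kind == "atanh":
        return float(np.arctanh(value))
    raise ValueError(f"unknown transform {kind!r}")


def _from_unconstrained(kind: str, value: float) -> float:
    if kind == "identity":
        return value
    if kind == "log":
        return float(np.exp(value))
    if kind == "logit":
        return float(expit(value))
    if kind == "logit_threshold":
        return float(RESPONSE_THRESHOLD * expit(value))
    if kind == "atanh":
        return float(np.tanh(value))
    raise ValueError(f"unknown transform {kind!r}")


@dataclass
class FitResult:
    """Outcome of one subject-level fit."""

    model: str
    params: dict[str, float]
    logL: float
    aic: float
    bic: float
    n_trials: int
    n_sim_per_eval: int
    converged: bool
    restarts: int
    seed: int
    restart_logLs: list[float] = field(default_factory=list)

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": self.model,
            "params": self.params,
            "logL": self.logL,
            "aic": self.aic,
            "bic": self.bic,
            "n_trials": self.n_trials,
            "n_sim_per_eval": self.n_sim_per_eval,
            "converged": self.converged,
            "restarts": self.restarts,
            "seed": self.seed,
            "restart_logLs": self.restart_logLs,
        }


class ModelFitter(BaseEstimator):
    """Subject-level simulated maximum-likelihood fitter.

    scikit-learn style estimator: ``fit(trials)`` consumes a trial table
    (columns ``gap_ms``, ``rt_ms`` or ``rpt_ms``, ``correct``,
    ``target_side``, optionally ``more_frequent_side``) and exposes the
    fitted parameter dictionary and information criteria as trailing-
    underscore attributes.

    Parameters
    ----------
    model : str
        Registered model name (``hybrid``, ``independent_race``,
        ``stanford_simplified``, ``ddm``, ``ou``).
    bias : bool
        Fit the internal-choice bias parameter (biased designs).
    n_sim : int
        Simulated trials per likelihood evaluation.
    restarts : int
        Latin-hypercube multi-starts of the Nelder–Mead search.
    maxfev : int
        Function-evaluation cap per restart.
    polish_factor : int
        After the restarts, the best restart endpoints are refined with
        ``polish_factor * n_sim`` simulated trials per evaluation.  The
        coarse surface is piecewise constant (counts move between
        histogram cells in quanta of ``1/n_sim``), which stalls the
        simplex; re-running Nelder–Mead from the incumbent with a fresh
        simplex on the finer surface escapes those plateaus.  0 disables
        polishing.
    polish_candidates, polish_rounds : int
        How many restart endpoints to polish and how many fresh simplex
        rounds each receives.
    """

    def __init__(
        self,
        model: str = "hybrid",
        bias: bool = False,
        bin_width: float = 35.0,
        n_sim: int = 20_000,
        restarts: int = 8,
        maxfev: int = 600,
        polish_factor: int = 5,
        polish_maxfev: int = 400,
        polish_candidates: int = 3,
        polish_rounds: int = 2,
        seed: int = 0,
        smoothing: float = 0.5,
        pool_correctness: bool = False,
        min_trials_warn: int = 100,
        warm_start: dict[str, float] | None = None,
        ramp: str = "linear",
    ) -> None:
        self.model = model
        self.bias = bias
        self.bin_width = bin_width
        self.n_sim = n_sim
        self.restarts = restarts
        self.maxfev = maxfev
        self.polish_factor = polish_factor
        self.polish_maxfev = polish_maxfev
        self.polish_candidates = polish_candidates
        self.polish_rounds = polish_rounds
        self.seed = seed
        self.smoothing = smoothing
        self.pool_correctness = pool_correctness
        self.min_trials_warn = min_trials_warn
        self.warm_start = warm_start
        self.ramp = ramp

    # -- helpers -----------------------------------------------------
    def _vector_to_params(self, spec: ModelSpec, names, x) -> dict[str, float]:
        params = {
            name: _from_unconstrained(spec.transforms[name], float(v))
            for name, v in zip(names, x)
        }
        if self.ramp != "linear":
            params["ramp"] = self.ramp  # stage-2 transition form (hybrid)
        return params

    def fit(self, trials: pd.DataFrame, y: None = None) -> "ModelFitter":
        import warnings

        spec = get_model(self.model)
        names = spec.param_names_with_bias(self.bias)
        trials = trials.copy()
        if "rpt_ms" not in trials.columns:
            trials["rpt_ms"] = trials["rt_ms"] - trials["gap_ms"]
        n_trials = len(trials)
        if n_trials < self.min_trials_warn:
            warnings.warn(
                f"only {n_trials} trials; fits below "
                f"{self.min_trials_warn} trials are poorly constrained",
                stacklevel=2,
            )
        observed = bin_rpt(trials, bin_width=self.bin_width)

        rng = np.random.default_rng(self.seed)
        base = spec.sample_base(rng, self.n_sim)
        design_idx = rng.integers(0, n_trials, size=self.n_sim)

        def objective(x: np.ndarray) -> float:
            params = self._vector_to_params(spec, names, x)
            return -estimate_log_likelihood(
                spec,
                params,
                trials,
                observed,
                n_sim=self.n_sim,
                smoothing=self.smoothing,
                pool_correctness=self.pool_correctness,
                base=base,
                design_idx=design_idx,
            )

        sampler = qmc.LatinHypercube(d=len(names), seed=rng)
        unit = sampler.random(n=self.restarts)
        lo = np.array([spec.start_ranges[n][0] for n in names])
        hi = np.array([spec.start_ranges[n][1] for n in names])
        starts_nat = list(lo + unit * (hi - lo))
        if self.warm_start is not None:
            # e.g. a fitted nested model mapped into this model's space,
            # guaranteeing the fit does at least as well as the nested one
            starts_nat.append(
                np.array([self.warm_start[n] for n in names])
            )

        endpoints: list[tuple[float, np.ndarray]] = []
        restart_logLs: list[float] = []
        any_success = False
        for start in starts_nat:
            x0 = np.array(
                [
                    _to_unconstrained(spec.transforms[n], v)
                    for n, v in zip(names, start)
                ]
            )
            res = minimize(
                objective,
                x0,
                method="Nelder-Mead",
                options={"maxfev": self.maxfev, "xatol": 1e-3, "fatol": 1e-3},
            )
            restart_logLs.append(-float(res.fun))
            any_success = any_success or bool(res.success)
            endpoints.append((float(res.fun), res.x))

        endpoints.sort(key=lambda e: e[0])
        best_fun, best_x = endpoints[0]
        if self.polish_factor > 0:
            n_polish = self.polish_factor * self.n_sim
            base_p = spec.sample_base(rng, n_polish)
            idx_p = rng.integers(0, n_trials, size=n_polish)

            def objective_polish(x: np.ndarray) -> float:
                params = self._vector_to_params(spec, names, x)
                return -estimate_log_likelihood(
                    spec, params, trials, observed,
                    n_sim=n_polish, smoothing=self.smoothing,
                    pool_correctness=self.pool_correctness,
                    base=base_p, design_idx=idx_p,
                )

            best_fun, best_x = np.inf, endpoints[0][1]
            for _, x_start in endpoints[: max(self.polish_candidates, 1)]:
                x_cur = x_start
                f_cur = np.inf
                for _ in range(max(self.polish_rounds, 1)):
                    res = minimize(
                        objective_polish, x_cur, method="Nelder-Mead",
                        options={"maxfev": self.polish_maxfev,
                                 "xatol": 1e-4, "fatol": 1e-4},
                    )
                    x_cur, f_cur = res.x, float(res.fun)
                    any_success = any_success or bool(res.success)
                if f_cur < best_fun:
                    best_fun, best_x = f_cur, x_cur

        self.params_ = self._vector_to_params(spec, names, best_x)
        self.log_likelihood_ = -best_fun
        self.n_params_ = len(names)
        self.aic_, self.bic_ = information_criteria(
            self.log_likelihood_, self.n_params_, n_trials
        )
        self.n_trials_ = n_trials
        self.converged_ = any_success
        self.restart_log_likelihoods_ = restart_logLs
        return self

    def result_(self) -> FitResult:
        return FitResult(
            model=self.model,
            params=self.params_,
            logL=self.log_likelihood_,
            aic=self.aic_,
            bic=self.bic_,
            n_trials=self.n_trials_,
            n_sim_per_eval=self.n_sim,
            converged=self.converged_,
            restarts=self.restarts,
            seed=self.seed,
            restart_logLs=self.restart_log_likelihoods_,
        )


def fit_subject(
    model: str, trials: pd.DataFrame, config: dict[str, Any] | None = None
) -> FitResult:
    """Functional wrapper over :class:`ModelFitter` (non-convergence is
    reported in the result's ``converged`` flag, never raised)."""
    fitter = ModelFitter(model=model, **(config or {}))
    fitter.fit(trials)
    return fitter.result_()
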