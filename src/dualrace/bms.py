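"""Group-level random-effects Bayesian model selection.

Given per-subject model evidence (log model evidence approximated by
``-AIC/2`` or ``-BIC/2``), model identities are treated as random
effects across subjects: subject ``n`` uses model ``k`` with unknown
population frequencies ``r ~ Dirichlet(alpha)``.  A variational update
iterates posterior model assignments and Dirichlet counts from a uniform
``Dirichlet(1, ..., 1)`` prior.  The *exceedance probability* of model
``k`` is the posterior probability that ``r_k`` exceeds every other
frequency, estimated by sampling the posterior Dirichlet.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import digamma
from sklearn.base import BaseEstimator

__all__ = ["BMSResult", "DirichletBMS", "variational_bms", "exceedance_probability"]


@dataclass(frozen=True)
class BMSResult:
    """Group model-selection output."""

    dirichlet_alpha: np.ndarray
    expected_frequencies: np.ndarray
    exceedance_prob: np.ndarray
    n_subjects: int
    evidence_kind: str = "aic"


def _variational_alpha(
    log_evidence: np.ndarray, prior: float = 1.0, tol: float = 1e-6,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, np.ndarray]:
    """Variational posterior Dirichlet parameters and per-subject model
    assignment probabilities."""
    ev = np.asarray(log_evidence, dtype=float)
    if ev.ndim != 2:
        raise ValueError("log_evidence must be a (subjects x models) matrix")
    n_sub, n_mod = ev.shape
    if n_sub < 1 or n_mod < 1:
        raise ValueError("need at least one subject and one model")
    if not np.isfinite(ev).all():
        raise ValueError("log_evidence entries must be finite")

    alpha = np.full(n_mod, prior, dtype=float)
    g = np.full((n_sub, n_mod), 1.0 / n_mod)
    for _ in range(max_iter):
        log_u = ev + digamma(alpha) - digamma(alpha.sum())
        log_u -= log_u.max(axis=1, keepdims=True)
        u = np.exp(log_u)
        g = u / u.sum(axis=1, keepdims=True)
        alpha_new = prior + g.sum(axis=0)
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            break
        alpha = alpha_new
    return alpha, g


def exceedance_probability(
    alpha: np.ndarray,
    n_samples: int = 1_000_000,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Monte-Carlo exceedance probabilities of a Dirichlet posterior.

    ``P(r_k > r_j for all j != k)``; single-model input returns [1].
    """
    alpha = np.asarray(alpha, dtype=float)
    if (alpha <= 0).any():
        raise ValueError("Dirichlet parameters must be positive")
    if alpha.size == 1:
        return np.array([1.0])
    rng = rng or np.random.default_rng()
    samples = rng.dirichlet(alpha, size=n_samples)
    winners = np.argmax(samples, axis=1)
    return np.bincount(winners, minlength=alpha.size) / n_samples


class DirichletBMS(BaseEstimator):
    """Random-effects group model selection over an evidence matrix.

    ``fit(X)`` takes ``X`` of shape (n_subjects, n_models) holding log
    model evidence (use ``-AIC/2`` or ``-BIC/2``) and exposes
    ``dirichlet_alpha_``, ``expected_frequencies_`` and
    ``exceedance_prob_``.
    """

    def __init__(
        self,
        prior: float = 1.0,
        tol: float = 1e-6,
        n_exceedance_samples: int = 1_000_000,
        seed: int = 0,
        evidence_kind: str = "aic",
    ) -> None:
        self.prior = prior
        self.tol = tol
        self.n_exceedance_samples = n_exceedance_samples
        self.seed = seed
        self.evidence_kind = evidence_kind

    def fit(self, X: np.ndarray, y: None = None) -> "DirichletBMS":
        alpha, g = _variational_alpha(X, prior=self.prior, tol=self.tol)
        self.dirichlet_alpha_ = alpha
        self.assignment_probs_ = g
        self.expected_frequencies_ = alpha / alpha.sum()
        self.exceedance_prob_ = exceedance_probability(
            alpha,
            n_samples=self.n_exceedance_samples,
            rng=np.random.default_rng(self.seed),
        )
        self.n_subjects_ = X.shape[0]
        return self

    def result_(self) -> BMSResult:
        return BMSResult(
            dirichlet_alpha=self.dirichlet_alpha_,
            expected_frequencies=self.expected_frequencies_,
            exceedance_prob=self.exceedance_prob_,
            n_subjects=self.n_subjects_,
            evidence_kind=self.evidence_kind,
        )


def variational_bms(
    log_evidence: np.ndarray,
    evidence_kind: str = "aic",
    n_exceedance_samples: int = 1_000_000,
    seed: int = 0,
) -> BMSResult:
    """Functional wrapper over :class:`DirichletBMS`."""
    est = DirichletBMS(
        n_exceedance_samples=n_exceedance_samples,
        seed=seed,
        evidence_kind=evidence_kind,
    )
    est.fit(np.asarray(log_evidence, dtype=float))
    return est.result_()
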