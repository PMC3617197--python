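"""Behavioral analyses for the gap paradigm.

Raw processing time (rPT = RT − gap) measures how long target
information was available before the choice response.  The *tachometric
curve* (accuracy versus rPT) separates guess-driven from stimulus-driven
responses: accuracy sits at chance below a critical rPT and rises
quickly to ceiling above it.  In the biased design, the congruent and
incongruent rPT distributions are not directly observable (the internal
decision is latent) but can be recovered from the more-frequent-side /
less-frequent-side distributions by inverting the known mixture matrix
``[[alpha, 1-alpha], [1-alpha, alpha]]``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit
from sklearn.base import BaseEstimator

__all__ = [
    "compute_rpt",
    "exclude_rt_outliers",
    "TachometricCurve",
    "tachometric_curve",
    "SigmoidTachometric",
    "estimate_critical_rpt",
    "rt_gap_regression",
    "rt_gap_slopes",
    "CongruencyDistributions",
    "deconvolve_congruency",
    "density_on_grid",
    "peak_location",
]


def compute_rpt(rt_ms, gap_ms):
    """Raw processing time: ``rPT = RT - gap``.  Positive when the
    response followed target onset, negative when it preceded it."""
    return np.asarray(rt_ms, dtype=float) - np.asarray(gap_ms, dtype=float)


def exclude_rt_outliers(trials: pd.DataFrame, k: float = 4.0) -> pd.DataFrame:
    """Drop trials whose RT deviates more than ``k`` standard deviations
    from the mean.

    Single pass; when a ``subject`` column is present the mean/sd are
    computed per subject on the unfiltered data.  A degenerate sd of 0
    excludes nothing.
    """
    if len(trials) < 2:
        raise ValueError("need at least two trials")

    if not np.isfinite(k):
        return trials
    rt = trials["rt_ms"]
    if "subject" in trials.columns:
        grp = trials.groupby("subject")["rt_ms"]
        mean, sd = grp.transform("mean"), grp.transform("std")
    else:
        mean, sd = rt.mean(), rt.std(ddof=1)
    keep = ((rt - mean).abs() <= k * sd) | (sd == 0) | ~np.isfinite(sd)
    return trials[np.asarray(keep, dtype=bool)]


@dataclass(frozen=True)
class TachometricCurve:
    """Per-bin accuracy as a function of raw processing time."""

    bin_centers: np.ndarray
    accuracy: np.ndarray
    n_per_bin: np.ndarray
    bin_width: float
    low_count_flag: np.ndarray


def tachometric_curve(
    trials: pd.DataFrame, bin_width: float = 35.0, min_n: int = 10
) -> TachometricCurve:
    """Bin trial-level correctness by rPT (bins aligned to zero).

    Bins with fewer than ``min_n`` trials are flagged (accuracy NaN-safe
    but noisy)."""
    if len(trials) == 0:
        raise ValueError("trials must be non-empty")
    rpt = trials["rpt_ms"].to_numpy(dtype=float)
    correct = trials["correct"].to_numpy(dtype=float)
    lo = np.floor(rpt.min() / bin_width) * bin_width
    hi = np.ceil(rpt.max() / bin_width) * bin_width
    if hi <= rpt.max():
        hi += bin_width
    edges = np.arange(lo, hi + 0.5 * bin_width, bin_width)
    n, _ = np.histogram(rpt, bins=edges)
    n_correct, _ = np.histogram(rpt[correct.astype(bool)], bins=edges)
    with np.errstate(invalid="ignore", divide="ignore"):
        acc = np.where(n > 0, n_correct / np.maximum(n, 1), np.nan)
    return TachometricCurve(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        accuracy=acc,
        n_per_bin=n,
        bin_width=bin_width,
        low_count_flag=n < min_n,
    )


def _sigmoid_p(x, floor, ceiling, center, width):
    return floor + (ceiling - floor) * expit((x - center) / width)


def _piecewise_p(x, floor, ceiling, onset, width):
    frac = np.clip((x - onset) / width, 0.0, 1.0)
    return floor + (ceiling - floor) * frac


class SigmoidTachometric(BaseEstimator):
    """Maximum-likelihood fit of the accuracy-vs-rPT transition.

    Fits a 4-parameter curve (floor, ceiling, center, width) to
    trial-level correctness by Bernoulli maximum likelihood.  The
    *critical rPT* is the fitted center — accuracy midway between floor
    and ceiling (for the ``piecewise`` shape: the midpoint of the linear
    ramp from chance to ceiling).  The standard error of the center
    comes from a nonparametric bootstrap over trials.

    Attributes (after ``fit``): ``floor_``, ``ceiling_``, ``center_``,
    ``width_``, ``se_center_`` (NaN when ``n_boot == 0``), ``failed_``
    (True when the curve never leaves chance).
    """

    def __init__(
        self,
        shape: str = "sigmoid",
        n_boot: int = 1000,
        seed: int = 0,
        min_rise: float = 0.1,
    ) -> None:
        self.shape = shape
        self.n_boot = n_boot
        self.seed = seed
        self.min_rise = min_rise

    def _fit_once(self, rpt: np.ndarray, correct: np.ndarray):
        pfun = _sigmoid_p if self.shape == "sigmoid" else _piecewise_p
        span = rpt.max() - rpt.min()

        def nll(x):
            floor, ceiling, center, logw = x
            p = pfun(rpt, floor, ceiling, center, np.exp(logw))
            p = np.clip(p, 1e-9, 1 - 1e-9)
            return -np.sum(np.where(correct, np.log(p), np.log1p(-p)))

        best = None
        for center0 in (np.percentile(rpt, 50), np.percentile(rpt, 70), 200.0):
            x0 = np.array([0.5, 0.98, center0, np.log(30.0)])
            res = minimize(
                nll,
                x0,
                method="L-BFGS-B",
                bounds=[
                    (1e-3, 1 - 1e-3),
                    (1e-3, 1 - 1e-3),
                    (rpt.min() - span, rpt.max() + span),
                    (np.log(0.5), np.log(max(span, 1.0))),
                ],
            )
            if best is None or res.fun < best.fun:
                best = res
        floor, ceiling, center, logw = best.x
        if self.shape == "piecewise":
            # report the ramp midpoint so both shapes return the
            # half-rise point
            center = center + 0.5 * np.exp(logw)
        return float(floor), float(ceiling), float(center), float(np.exp(logw))

    def fit(self, rpt, correct) -> "SigmoidTachometric":
        rpt = np.asarray(rpt, dtype=float)
        correct = np.asarray(correct, dtype=bool)
        floor, ceiling, center, width = self._fit_once(rpt, correct)
        self.floor_, self.ceiling_ = floor, ceiling
        self.center_, self.width_ = center, width
        self.failed_ = abs(ceiling - floor) < self.min_rise
        if self.n_boot > 0 and not self.failed_:
            rng = np.random.default_rng(self.seed)
            centers = np.empty(self.n_boot)
            n = len(rpt)
            for b in range(self.n_boot):
                idx = rng.integers(0, n, size=n)
                centers[b] = self._fit_once(rpt[idx], correct[idx])[2]
            self.se_center_ = float(np.std(centers, ddof=1))
            self.bootstrap_centers_ = centers
        else:
            self.se_center_ = float("nan")
        return self

    def predict_proba(self, rpt):
        pfun = _sigmoid_p if self.shape == "sigmoid" else _piecewise_p
        center = self.center_
        if self.shape == "piecewise":
            center = center - 0.5 * self.width_
        return pfun(np.asarray(rpt, float), self.floor_, self.ceiling_,
                    center, self.width_)


def estimate_critical_rpt(
    trials: pd.DataFrame,
    shape: str = "sigmoid",
    n_boot: int = 1000,
    seed: int = 0,
) -> tuple[float, float]:
    """Critical rPT (transition midpoint of the tachometric curve) and
    its bootstrap standard error.  Raises when the curve never leaves
    chance (flat accuracy)."""
    est = SigmoidTachometric(shape=shape, n_boot=n_boot, seed=seed)
    est.fit(trials["rpt_ms"].to_numpy(), trials["correct"].to_numpy())
    if est.failed_:
        raise RuntimeError(
            "tachometric curve never leaves chance; critical rPT undefined"
        )
    return est.center_, est.se_center_


def rt_gap_regression(trials: pd.DataFrame) -> tuple[float, tuple[float, float]]:
    """Ordinary least-squares slope of RT on gap with a 95% CI.

    Slopes below 1 indicate that subjects did not simply wait for the
    target (a pure wait-then-react strategy gives slope 1)."""
    gap = trials["gap_ms"].to_numpy(dtype=float)
    if len(np.unique(gap)) < 2:
        raise ValueError("need at least two distinct gaps")
    rt = trials["rt_ms"].to_numpy(dtype=float)
    model = sm.OLS(rt, sm.add_constant(gap)).fit()
    slope = float(model.params[1])
    lo, hi = model.conf_int(alpha=0.05)[1]
    return slope, (float(lo), float(hi))


def rt_gap_slopes(trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject RT-on-gap slopes (requires a ``subject`` column)."""
    rows = []
    for subject, df in trials.groupby("subject"):
        slope, (lo, hi) = rt_gap_regression(df)
        rows.append({"subject": subject, "slope": slope,
                     "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CongruencyDistributions:
    """Deconvolved congruent / incongruent rPT densities."""

    congruent: np.ndarray
    incongruent_correct: np.ndarray
    incongruent_error: np.ndarray | None
    alpha: float
    artifact_flag: bool  # any deconvolved cell below -0.02


def deconvolve_congruency(
    hist_more: np.ndarray,
    hist_less: np.ndarray,
    alpha: float,
    error_density: np.ndarray | None = None,
    clip_negative: bool = False,
) -> CongruencyDistributions:
    """Recover congruent / incongruent-correct rPT densities from the
    more-frequent-side and less-frequent-side densities.

    The observable densities are mixtures
    ``[M; L] = [[alpha, 1-alpha], [1-alpha, alpha]] @ [C; I]``:
    conditional on the target appearing on the cued (more frequent)
    side, a trial is congruent with probability ``alpha``; on the other
    side with probability ``1 - alpha``.  The weights are exact when the
    per-side densities are built from all trials (restricting to
    correct trials skews them, because incongruent trials are not
    always correct).  The mixture matrix is invertible only for
    ``alpha != 0.5`` (at 0.5 both rows are equal, making the linear
    transformation impossible — the unbiased design cannot separate the
    two classes).

    Error trials are necessarily incongruent (the external variable
    always codes the correct side), so the pooled error density can be
    passed through unchanged as ``error_density``.

    Sampling noise may produce small negative cells; they are reported
    as-is (``clip_negative=True`` clips to 0 and renormalizes) and
    flagged when any cell drops below -0.02.
    """
    hist_more = np.asarray(hist_more, dtype=float)
    hist_less = np.asarray(hist_less, dtype=float)
    if hist_more.shape != hist_less.shape:
        raise ValueError("input densities must have the same shape")
    if alpha == 0.5:
        raise ValueError(
            "alpha = 0.5 makes the mixture matrix singular (alpha = 1 - alpha); "
            "the linear transformation is impossible"
        )
    det = 2.0 * alpha - 1.0
    congruent = (alpha * hist_more - (1.0 - alpha) * hist_less) / det
    incongruent = (alpha * hist_less - (1.0 - alpha) * hist_more) / det
    artifact = bool(min(congruent.min(), incongruent.min()) < -0.02)
    if clip_negative:
        congruent = np.clip(congruent, 0.0, None)
        incongruent = np.clip(incongruent, 0.0, None)
        if congruent.sum() > 0:
            congruent = congruent / congruent.sum()
        if incongruent.sum() > 0:
            incongruent = incongruent / incongruent.sum()
    return CongruencyDistributions(
        congruent=congruent,
        incongruent_correct=incongruent,
        incongruent_error=(
            np.asarray(error_density, dtype=float)
            if error_density is not None
            else None
        ),
        alpha=float(alpha),
        artifact_flag=artifact,
    )


def density_on_grid(
    values: np.ndarray, edges: np.ndarray
) -> np.ndarray:
    """Unit-mass histogram of ``values`` on a fixed bin grid (mass
    outside the grid is dropped before normalization)."""
    counts, _ = np.histogram(np.asarray(values, dtype=float), bins=edges)
    total = counts.sum()
    if total == 0:
        raise ValueError("no values fall inside the grid")
    return counts / total


def peak_location(
    density: np.ndarray, centers: np.ndarray, interpolate: bool = True
) -> float:
    """Location of the density peak.

    With ``interpolate=True`` a quadratic through the maximal bin and
    its neighbours resolves sub-bin shifts; edge peaks fall back to the
    bin center.
    """
    density = np.asarray(density, dtype=float)
    centers = np.asarray(centers, dtype=float)
    i = int(np.argmax(density))
    if not interpolate or i == 0 or i == len(density) - 1:
        return float(centers[i])
    ym, y0, yp = density[i - 1], density[i], density[i + 1]
    denom = ym - 2.0 * y0 + yp
    if denom == 0:
        return float(centers[i])
    offset = 0.5 * (ym - yp) / denom
    width = centers[1] - centers[0]
    return float(centers[i] + offset * width)
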