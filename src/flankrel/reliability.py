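"""Test-retest reliability coefficients and related inference.

Implements the coefficients and tests used when comparing the reliability of
individual differences across independent samples:

* ICC(A,1) -- single-measure, absolute-agreement intraclass correlation
  under a two-way model (McGraw-Wong), computed from the ANOVA mean squares

      ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

  with k = 2 sessions.  Unlike a Pearson correlation it penalizes mean
  shifts between sessions.
* Pearson correlation, Fisher's z transform, the one-sided two-sample test
  for a difference between independent correlations (effect size Cohen's
  q = z1 - z2, SE = sqrt(1/(n1-3) + 1/(n2-3))) and the matching analytic
  power/sample-size solve.
* The Spearman-Brown prophecy formula and its inverse (smallest trial count
  reaching a target reliability).
* A leave-k-out leverage analysis for detecting participants whose presence
  dominates an ICC.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class ReliabilityEstimate:
    """A reliability coefficient with its provenance."""

    value: float
    kind: str                      # 'icc_abs_agreement' | 'pearson'
    n_participants: int
    source: str                    # 'test_retest' | 'split_half'
    meta: dict = field(default_factory=dict)


def _paired(x1, x2, min_n=3):
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if x1.shape != x2.shape or x1.ndim != 1:
        raise ValueError("x1 and x2 must be paired 1-D arrays")
    if len(x1) < min_n:
        raise ValueError(f"need at least {min_n} paired observations")
    return x1, x2


# ---------------------------------------------------------------------------
# Coefficients
# ---------------------------------------------------------------------------

def icc_value(x1, x2) -> float:
    """ICC(A,1) for two sessions, as a bare float (NaN with a warning when
    there is no between-participant variance)."""
    x1, x2 = _paired(x1, x2)
    n = len(x1)
    k = 2
    x = np.stack([x1, x2], axis=1)
    grand = x.mean()
    row = x.mean(axis=1)
    col = x.mean(axis=0)
    msr = k * np.sum((row - grand) ** 2) / (n - 1)
    msc = n * np.sum((col - grand) ** 2) / (k - 1)
    resid = x - row[:, None] - col[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0 or (msr == 0 and mse == 0 and msc == 0):
        warnings.warn("ICC undefined: no variance in scores", RuntimeWarning)
        return float("nan")
    return float((msr - mse) / denom)


def icc_absolute_agreement(x1, x2) -> ReliabilityEstimate:
    """Single-measure absolute-agreement ICC between two sessions."""
    x1, x2 = _paired(x1, x2)
    return ReliabilityEstimate(
        value=icc_value(x1, x2),
        kind="icc_abs_agreement",
        n_participants=len(x1),
        source="test_retest",
        meta={"model": "two-way, single measure, absolute agreement"},
    )


def icc_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized ICC(A,1): ``x``/``y`` are (reps, participants) session
    score matrices; returns one ICC per row."""
    n = x.shape[1]
    k = 2
    c1 = x.mean(axis=1)
    c2 = y.mean(axis=1)
    grand = (c1 + c2) / 2
    row = (x + y) / 2
    msr = k * ((row - grand[:, None]) ** 2).sum(axis=1) / (n - 1)
    msc = n * ((c1 - grand) ** 2 + (c2 - grand) ** 2) / (k - 1)
    r1 = x - row - c1[:, None] + grand[:, None]
    r2 = y - row - c2[:, None] + grand[:, None]
    mse = (r1**2 + r2**2).sum(axis=1) / (n - 1)
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (msr - mse) / denom
    out[denom <= 0] = np.nan
    return out


def pearson_rows(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized Pearson correlation along rows of (reps, participants)."""
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = (xc * yc).sum(axis=1)
    den = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den


def pearson(x1, x2) -> ReliabilityEstimate:
    """Pearson correlation between two sessions' scores."""
    x1, x2 = _paired(x1, x2)
    if np.std(x1) == 0 or np.std(x2) == 0:
        warnings.warn("Pearson undefined: zero variance", RuntimeWarning)
        r = float("nan")
    else:
        r = float(stats.pearsonr(x1, x2).statistic)
    return ReliabilityEstimate(value=r, kind="pearson",
                               n_participants=len(x1), source="test_retest")


# ---------------------------------------------------------------------------
# Fisher z machinery
# ---------------------------------------------------------------------------

def fisher_z(r: float) -> float:
    """z = atanh(r); rejects |r| >= 1 (the transform diverges)."""
    r = float(r)
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 for the Fisher z transform")
    return math.atanh(r)


def fisher_z_inverse(z: float) -> float:
    return math.tanh(float(z))


def compare_correlations(r1: float, n1: int, r2: float, n2: int,
                         alternative: str = "greater") -> dict:
    """One-sided (or two-sided) z-test for a difference between two
    correlations from independent samples.

    Returns ``{'q': Cohen's q, 'z': test statistic, 'p': p-value,
    'alternative': ...}`` with ``q = atanh(r1) - atanh(r2)`` and
    ``z = q / sqrt(1/(n1-3) + 1/(n2-3))``.  ``alternative='greater'`` tests
    r1 > r2.
    """
    if n1 < 4 or n2 < 4:
        raise ValueError("need n >= 4 in each sample")
    q = fisher_z(r1) - fisher_z(r2)
    se = math.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = q / se
    if alternative == "greater":
        p = float(stats.norm.sf(z))
    elif alternative == "less":
        p = float(stats.norm.cdf(z))
    elif alternative == "two-sided":
        p = float(2 * stats.norm.sf(abs(z)))
    else:
        raise ValueError("alternative must be 'greater', 'less' or 'two-sided'")
    return {"q": q, "z": z, "p": p, "alternative": alternative,
            "n1": n1, "n2": n2}


def required_n_per_group(q_effect: float, alpha: float, power: float) -> int:
    """Smallest equal-group n giving at least ``power`` for the one-sided
    two-sample Fisher-z test at effect size ``q_effect``.

    Analytic: SE = sqrt(2/(n-3)), so n = ceil(2 ((z_{1-a} + z_{power}) /
    q)^2 + 3).
    """
    if not (0 < alpha < 1 and 0 < power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if q_effect <= 0:
        raise ValueError("q_effect must be > 0")
    zsum = stats.norm.ppf(1 - alpha) + stats.norm.ppf(power)
    zsum = max(zsum, 0.0)
    return math.ceil(2.0 * (zsum / q_effect) ** 2 + 3.0)


# ---------------------------------------------------------------------------
# Spearman-Brown prophecy
# ---------------------------------------------------------------------------

def spearman_brown(rho_full: float, n_ratio) -> float | np.ndarray:
    """Predicted reliability of a test of ``n_ratio`` times the full length:
    ``n rho / (1 + (n - 1) rho)``."""
    n_ratio = np.asarray(n_ratio, dtype=float)
    if np.any(n_ratio <= 0):
        raise ValueError("n_ratio must be > 0")
    rho = float(rho_full)
    out = n_ratio * rho / (1.0 + (n_ratio - 1.0) * rho)
    return float(out) if out.ndim == 0 else out


def sb_required_length(rho_full: float, rho_target: float,
                       full_trials: int) -> int:
    """Smallest integer trial count t with SB-predicted reliability at
    ``t / full_trials`` of at least ``rho_target``."""
    if full_trials < 1:
        raise ValueError("full_trials must be >= 1")
    if not 0 <= rho_full < 1:
        raise ValueError("rho_full must be in [0, 1)")
    if rho_target >= 1 or rho_full <= 0:
        if rho_target <= 0:
            return 1
        raise ValueError("target reliability unreachable at any finite length")
    if rho_target <= 0:
        return 1
    n_needed = (rho_target * (1 - rho_full)) / (rho_full * (1 - rho_target))
    t = math.ceil(n_needed * full_trials - 1e-12)
    # guard against float slop on the boundary
    while t > 1 and spearman_brown(rho_full, (t - 1) / full_trials) >= rho_target:
        t -= 1
    while spearman_brown(rho_full, t / full_trials) < rho_target:
        t += 1
    return t


# ---------------------------------------------------------------------------
# Leverage analysis
# ---------------------------------------------------------------------------

def flag_score_outliers(x1, x2, z_threshold: float = 15.0) -> np.ndarray:
    """Indices of participants whose score has |z| above threshold in either
    session (z over the supplied scores)."""
    x1, x2 = _paired(x1, x2)
    flags = np.zeros(len(x1), dtype=bool)
    for x in (x1, x2):
        sd = x.std(ddof=1)
        if sd > 0:
            flags |= np.abs(x - x.mean()) / sd > z_threshold
    return np.nonzero(flags)[0]


def leverage_analysis(x1, x2, k_exclude: int = 2, n_reps: int = 10_000,
                      protected_pair=None, seed: int = 0,
                      z_threshold: float = 15.0) -> dict:
    """Leave-k-out sensitivity of the test-retest ICC to individual
    participants.

    For each replication, ``k_exclude`` random participants -- never members
    of ``protected_pair`` -- are dropped and the ICC recomputed.  Returns the
    maximum ICC over replications (``max_icc_without_pair``), the ICC with
    exactly the protected participants dropped (``icc_excluding_pair``), the
    full-sample ICC, and the indices flagged by the |z| rule.  A protected
    pair whose removal yields a far higher ICC than any random removal is a
    high-leverage outlier pair.
    """
    x1, x2 = _paired(x1, x2)
    n = len(x1)
    if k_exclude < 0:
        raise ValueError("k_exclude must be >= 0")
    if n <= k_exclude + 3:
        raise ValueError("need n > k_exclude + 3")
    protected = np.array(sorted(protected_pair), dtype=int) if protected_pair \
        else np.array([], dtype=int)
    if protected.size and (protected.min() < 0 or protected.max() >= n):
        raise ValueError("protected_pair indices out of range")

    rng = np.random.default_rng(seed)
    pool = np.setdiff1d(np.arange(n), protected)
    full_icc = icc_value(x1, x2)

    if k_exclude == 0:
        max_icc = full_icc
    else:
        iccs = np.empty(n_reps)
        for i in range(n_reps):
            drop = rng.choice(pool, size=k_exclude, replace=False)
            keep = np.ones(n, dtype=bool)
            keep[drop] = False
            iccs[i] = icc_value(x1[keep], x2[keep])
        max_icc = float(np.nanmax(iccs))

    if protected.size:
        keep = np.ones(n, dtype=bool)
        keep[protected] = False
        icc_excl = icc_value(x1[keep], x2[keep])
    else:
        icc_excl = full_icc

    return {
        "max_icc_without_pair": max_icc,
        "icc_excluding_pair": float(icc_excl),
        "full_icc": float(full_icc),
        "flagged_participants": flag_score_outliers(x1, x2, z_threshold).tolist(),
        "n_reps": n_reps if k_exclude else 0,
    }
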