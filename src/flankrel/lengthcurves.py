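"""Reliability as a function of task length, with Spearman-Brown curve fits.

Shortened tasks are built by stratified subsampling (without replacement,
condition x direction strata) of each participant-session's valid trials:
a 40-trial task draws 10 trials per stratum, and the full 320-trial task is
the valid trial set in randomized order.  Per replication and length a
single reliability coefficient is computed -- a test-retest ICC (or Pearson)
across independently subsampled sessions, or a split-half estimate from one
fresh split of the subsample -- and coefficients are averaged over
replications.

The resulting curve is compared against the family of Spearman-Brown
prophecy curves anchored at 101 candidate full-length reliabilities
(0.00, 0.01, ..., 1.00): the best-fitting curve minimizes the sum of squared
differences over test lengths, ties broken toward the smaller candidate.
A curve that tracks its best-fitting prophecy curve closely behaves like a
lengthened/shortened parallel test; Monte Carlo split-half curves typically
do not, because overlapping halves keep short-task estimates high.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scoring
from .reliability import icc_rows, pearson_rows, spearman_brown
from .splithalf import (SplitSpec, _split_effect_pairs, _stratum_classes,
                        _valid_trials, _aggregate)

DEFAULT_LENGTHS = tuple(range(40, 321, 40))
SB_GRID = np.round(np.arange(0, 101) / 100.0, 2)


@dataclass
class LengthCurve:
    """Aggregated reliability estimates indexed by total trial count."""

    lengths: tuple
    estimates: np.ndarray
    method: str                       # 'test_retest' | 'permutated' | 'monte_carlo'
    n_replications: int
    coefficient: str                  # 'icc' | 'pearson' for test_retest
    full_length: int
    best_fit_rho: float | None = None
    sse: float | None = None
    meta: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"method": self.method, "length": self.lengths,
                             "estimate": self.estimates})


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

def subsample_trials(trials: pd.DataFrame, total_length: int, seed: int,
                     stratify_by=("condition", "direction"),
                     strict: bool = True) -> pd.DataFrame:
    """Stratified random subsample of one participant-session's trials.

    Draws ``total_length / n_strata`` trials per stratum without replacement
    and returns them in randomized order.  ``total_length`` must divide
    evenly over the strata.  With ``strict`` (default) a stratum with too
    few trials raises; otherwise the draw is capped at the stratum size, so
    requesting the full length returns a permutation of the input.
    """
    n_strata = 1
    for col in stratify_by:
        n_strata *= trials[col].nunique()
    if total_length % n_strata:
        raise ValueError(
            f"total_length {total_length} not divisible by {n_strata} strata")
    per = total_length // n_strata
    rng = np.random.default_rng(seed)
    picks = []
    for key, g in trials.groupby(list(stratify_by), sort=True):
        m = len(g)
        if m < per:
            if strict:
                raise ValueError(
                    f"stratum {key} has {m} trials, need {per}")
            k = m
        else:
            k = per
        picks.append(g.index.to_numpy()[rng.permutation(m)[:k]])
    ix = np.concatenate(picks)
    return trials.loc[ix[rng.permutation(len(ix))]]


# ---------------------------------------------------------------------------
# Curves
# ---------------------------------------------------------------------------

def _test_retest_rows(classes1, classes2, n_participants, n_reps, rng,
                      subsample, coefficient, chunk=256):
    """Per-replication test-retest coefficients at a subsampled length:
    independent stratified subsamples per session per replication."""
    out = []
    done = 0
    P = n_participants
    while done < n_reps:
        c = min(chunk, n_reps - done)
        effs = []
        for classes in (classes1, classes2):
            s = np.zeros((c, P, 2))
            cnt = np.zeros((c, P, 2))
            for m, vals, part_ix, cond_ix in classes:
                k = min(subsample, m)
                x = np.repeat(vals[None, :, :], c, axis=0)
                rng.permuted(x, axis=-1, out=x)
                sk = x[..., :k].astype(np.float64, copy=False).sum(axis=-1)
                col = (slice(None), part_ix, cond_ix)
                np.add.at(s, col, sk)
                np.add.at(cnt, col, np.full((c, len(part_ix)), float(k)))
            mean = s / cnt
            effs.append(mean[:, :, 1] - mean[:, :, 0])
        if coefficient == "icc":
            out.append(icc_rows(effs[0], effs[1]))
        else:
            out.append(pearson_rows(effs[0], effs[1]))
        done += c
    return np.concatenate(out)


def reliability_curve(trials: pd.DataFrame, method: str,
                      lengths=DEFAULT_LENGTHS,
                      n_replications: int = 10_000,
                      seed: int = 0,
                      coefficient: str = "icc",
                      adjust: str = "spearman_brown",
                      aggregate: str = "mean",
                      session: int = 1,
                      stratify_by=("condition", "direction"),
                      config: scoring.ScoringConfig | None = None,
                      full_length: int | None = None) -> LengthCurve:
    """Reliability estimates at each task length.

    ``method='test_retest'`` draws independent per-session subsamples each
    replication and computes the coefficient across participants;
    ``'permutated'``/``'monte_carlo'`` draw one subsample and one fresh
    split per replication (split coefficients are SB-adjusted to the
    subsample's length when ``adjust='spearman_brown'``).
    """
    if method not in ("test_retest", "permutated", "monte_carlo"):
        raise ValueError("unknown method " + repr(method))
    lengths = tuple(int(x) for x in lengths)
    if sorted(lengths) != list(lengths) or len(set(lengths)) != len(lengths):
        raise ValueError("lengths must be strictly increasing")
    if "excluded_reason" not in trials.columns:
        trials = scoring.flag_rt_exclusions(trials, config=config)
    full_length = full_length or max(lengths)
    n_strata = 1
    for colname in stratify_by:
        n_strata *= trials[colname].nunique()
    rng = np.random.default_rng(seed)

    if method == "test_retest":
        v1 = _valid_trials(trials[trials["session"] == 1])
        v2 = _valid_trials(trials[trials["session"] == 2])
        common = sorted(set(v1["participant"]).intersection(v2["participant"]))
        if len(common) < 3:
            raise ValueError("need >= 3 participants with both sessions")
        classes1 = _stratum_classes(v1, stratify_by, common)
        classes2 = _stratum_classes(v2, stratify_by, common)
        estimates = []
        for L in lengths:
            coefs = _test_retest_rows(classes1, classes2, len(common),
                                      n_replications, rng, L // n_strata,
                                      coefficient)
            coefs = coefs[np.isfinite(coefs)]
            estimates.append(_aggregate(coefs, aggregate))
        meta = {"n_participants": len(common), "session": "both"}
    else:
        spec = SplitSpec(seed=seed, method=method, stratify_by=tuple(stratify_by),
                         n_replications=n_replications, adjust=adjust,
                         aggregate=aggregate, session=session)
        sess = trials[trials["session"] == session]
        valid = _valid_trials(sess)
        sizes = valid.groupby(["participant"] + list(stratify_by), sort=True).size()
        min_per = sizes.groupby("participant").min()
        nstr = sizes.groupby("participant").size()
        need = 2 if method == "permutated" else 1
        ok = (min_per >= need) & (nstr == nstr.max())
        common = list(min_per.index[ok])
        if len(common) < 3:
            raise ValueError("need >= 3 splittable participants")
        classes = _stratum_classes(valid, stratify_by, common)
        estimates = []
        for L in lengths:
            rs = []
            for eff_a, eff_b in _split_effect_pairs(
                    classes, len(common), n_replications, rng, method,
                    subsample=L // n_strata, mc_half_size=spec.mc_half_size):
                rs.append(pearson_rows(eff_a, eff_b))
            r = np.concatenate(rs)
            r = r[np.isfinite(r)]
            coefs = 2 * r / (1 + r) if adjust == "spearman_brown" else r
            estimates.append(_aggregate(coefs, aggregate))
        meta = {"n_participants": len(common), "session": session,
                "skipped_participants": list(min_per.index[~ok])}

    return LengthCurve(lengths=lengths, estimates=np.asarray(estimates),
                       method=method, n_replications=n_replications,
                       coefficient=coefficient if method == "test_retest" else "pearson",
                       full_length=full_length, meta={**meta, "seed": seed,
                                                      "adjust": adjust,
                                                      "aggregate": aggregate})


# ---------------------------------------------------------------------------
# Spearman-Brown grid fit
# ---------------------------------------------------------------------------

def fit_spearman_brown_curve(curve: LengthCurve,
                             grid=SB_GRID) -> tuple[float, float]:
    """Best-fitting Spearman-Brown prophecy curve over the candidate grid.

    Candidate rho's predicted value at length L is ``SB(rho, L /
    full_length)``; the winner minimizes the sum of squared differences over
    lengths (ties -> smaller rho).  Sets ``curve.best_fit_rho`` and
    ``curve.sse`` and returns them.
    """
    if len(curve.lengths) < 2:
        raise ValueError("need a curve over at least 2 lengths")
    ratios = np.asarray(curve.lengths, dtype=float) / curve.full_length
    grid = np.asarray(grid, dtype=float)
    preds = np.empty((len(grid), len(ratios)))
    for i, rho in enumerate(grid):
        preds[i] = spearman_brown(rho, ratios)
    sse = ((preds - curve.estimates[None, :]) ** 2).sum(axis=1)
    best = int(np.argmin(sse))          # first minimum = smallest rho
    curve.best_fit_rho = float(grid[best])
    curve.sse = float(sse[best])
    return curve.best_fit_rho, curve.sse
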