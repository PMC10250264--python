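"""Trial-level flanker-task simulation with known ground-truth reliability.

The generator emulates a two-session arrow-flanker study.  Each session has
one 8-trial practice block and two main blocks of 160 trials; every main
block crosses target direction (left/right), congruency
(congruent/incongruent) and 10 fixation durations (500, 550, ..., 950 ms)
exactly four times, so a session presents 160 congruent and 160 incongruent
main trials.  Trial order is a seeded uniform shuffle within each block.

Between-participant structure follows a simple trait model:

* baseline speed ``b_i ~ Normal(mu_congruent, sd_between)``,
* a stable congruency effect ``d_i`` with mean ``mu_effect`` and SD
  ``sd_effect``, correlated ``effect_baseline_corr`` with the baseline
  (slower participants tend to show larger interference, which is what
  produces the near-unity correlation between per-participant congruent and
  incongruent mean RTs seen in real flanker data),
* right-skewed ex-Gaussian trial noise (``Normal(0, sigma)`` plus
  ``Exponential(tau)``), so the observed mean RT is roughly
  ``mu_congruent + tau``,
* a small contaminant mixture: with probability ``contaminant_rate`` a trial
  is shifted ``contaminant_shift`` ms slower, producing the few-percent slow
  tail that the 3*MAD rule removes in real data,
* a pure mean speed-up of ``session2_speedup`` ms in session 2 (practice
  effects shift both conditions equally; the effect itself is stable),
* per-condition error rates, with more errors on incongruent trials.

Both sessions share ``b_i`` and ``d_i``, so the only sources of test-retest
disagreement are trial noise and the exclusion pipeline.  That makes the
ground-truth reliability of the flanker difference score available in closed
form: ``rho(L) = sd_effect^2 / (sd_effect^2 + var_e(L))`` where ``var_e(L)``
is the error variance of a difference score computed from ``L`` trials per
condition.  Because the scoring pipeline trims the slow tail (3*MAD rule)
and drops error trials, ``var_e`` is evaluated by a deterministic Monte
Carlo pass through the actual scoring code (`effect_error_variance`) rather
than from the raw noise variance; a ``trial_variance`` override gives the
textbook closed form ``var_e = 2 * trial_variance / L``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

FIXATIONS_MS = tuple(range(500, 1000, 50))
CONDITIONS = ("congruent", "incongruent")
DIRECTIONS = ("left", "right")
PRACTICE_BLOCK = "practice"
MAIN_BLOCKS = ("main1", "main2")

TRIAL_COLUMNS = [
    "participant", "group", "session", "block", "trial",
    "condition", "direction", "fixation_ms", "rt_ms", "correct",
]


@dataclass(frozen=True)
class GenerativeParams:
    """Population- and trial-level parameters of the synthetic flanker model.

    All RT quantities are in milliseconds.  Defaults emulate the statistical
    profile of a diverse online sample on keyboard devices: correct mean RTs
    around 520-570 ms, a flanker effect of ~40 ms (between-person SD ~15 ms),
    congruent-incongruent mean-RT correlation ~0.98, well under 2% errors and
    a 3-6% slow tail caught by the 3*MAD rule.
    """

    seed: int
    n_participants: int = 150
    mu_congruent: float = 450.0
    sd_between: float = 50.0
    mu_effect: float = 40.0
    sd_effect: float = 15.0
    sigma: float = 80.0                 # ex-Gaussian normal SD
    tau: float = 60.0                   # ex-Gaussian exponential mean
    session2_speedup: float = 12.0
    error_rate_congruent: float = 0.003
    error_rate_incongruent: float = 0.010
    contaminant_rate: float = 0.01
    contaminant_shift: float = 300.0
    effect_baseline_corr: float = 0.9
    n_outlier_participants: int = 0
    outlier_effect_sd_multiplier: float = 1.0

    def validate(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        for name in ("sd_between", "sd_effect", "sigma", "tau",
                     "contaminant_shift", "outlier_effect_sd_multiplier"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("error_rate_congruent", "error_rate_incongruent",
                     "contaminant_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.error_rate_incongruent < self.error_rate_congruent:
            raise ValueError(
                "error_rate_incongruent must be >= error_rate_congruent "
                "(congruency effect on errors)")
        if not -1.0 <= self.effect_baseline_corr <= 1.0:
            raise ValueError("effect_baseline_corr must be in [-1, 1]")
        if self.n_outlier_participants < 0:
            raise ValueError("n_outlier_participants must be >= 0")
        if self.n_outlier_participants > self.n_participants:
            raise ValueError("n_outlier_participants exceeds n_participants")


@dataclass(frozen=True)
class TrueReliability:
    """Closed-form reliability of the difference score at a given length."""

    length_trials_per_condition: int
    value: float


def load_params(path: str | Path) -> GenerativeParams:
    """Read generative parameters from a YAML or JSON config file.

    The ``seed`` key is mandatory: every simulated dataset must be tied to an
    explicit seed.
    """
    import yaml

    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping of parameter names")
    if "seed" in raw:
        raw["seed"] = int(raw["seed"])
    else:
        raise ValueError(f"{path}: a 'seed' entry is required")
    known = {f.name for f in dataclasses.fields(GenerativeParams)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown parameter(s) {sorted(unknown)}")
    params = GenerativeParams(**raw)
    params.validate()
    return params


# ---------------------------------------------------------------------------
# Trial schedule
# ---------------------------------------------------------------------------

def _main_block_cells() -> pd.DataFrame:
    """The 40 direction x condition x fixation cells, four times each."""
    cells = [
        (d, c, f)
        for d in DIRECTIONS
        for c in CONDITIONS
        for f in FIXATIONS_MS
    ]
    cells = cells * 4
    return pd.DataFrame(cells, columns=["direction", "condition", "fixation_ms"])


def _practice_cells(rng: np.random.Generator) -> pd.DataFrame:
    # 8 trials balancing direction and condition: 2 per cell; fixation drawn
    # uniformly from the 10 task durations.
    cells = [(d, c) for d in DIRECTIONS for c in CONDITIONS] * 2
    df = pd.DataFrame(cells, columns=["direction", "condition"])
    df["fixation_ms"] = rng.choice(FIXATIONS_MS, size=len(df))
    return df


def make_schedule(seed: int) -> pd.DataFrame:
    """One session's trial schedule: 8 practice + 2 x 160 main trials.

    Returns a DataFrame with columns ``block, trial, condition, direction,
    fixation_ms``; ``trial`` is the running index within the session.  The
    order is a seeded uniform shuffle within each block.
    """
    rng = np.random.default_rng(seed)
    blocks = []
    prac = _practice_cells(rng).sample(frac=1.0, random_state=np.random.RandomState(
        rng.integers(0, 2**31)))
    prac.insert(0, "block", PRACTICE_BLOCK)
    blocks.append(prac)
    for name in MAIN_BLOCKS:
        cells = _main_block_cells()
        cells = cells.iloc[rng.permutation(len(cells))]
        cells.insert(0, "block", name)
        blocks.append(cells)
    out = pd.concat(blocks, ignore_index=True)
    out.insert(1, "trial", np.arange(len(out)))
    return out


# ---------------------------------------------------------------------------
# Dataset simulation
# ---------------------------------------------------------------------------

def _draw_traits(params: GenerativeParams, rng: np.random.Generator):
    p = params
    n = p.n_participants
    zb = rng.standard_normal(n)
    zd = rng.standard_normal(n)
    b = p.mu_congruent + p.sd_between * zb
    rho = p.effect_baseline_corr if p.sd_between > 0 else 0.0
    d = p.mu_effect + p.sd_effect * (rho * zb + np.sqrt(1.0 - rho**2) * zd)
    # per-session effects: identical (stable trait) except for injected
    # high-leverage participants, whose effect is redrawn per session with
    # inflated variance -- extreme *and* inconsistent scores, the behaviour
    # whose removal raises a test-retest ICC
    d_sessions = np.stack([d, d], axis=1)
    if p.n_outlier_participants:
        k = p.n_outlier_participants
        d_sessions[-k:, :] = p.mu_effect + (
            p.sd_effect * p.outlier_effect_sd_multiplier
            * rng.standard_normal((k, 2)))
    return b, d_sessions


def _trial_noise(rng: np.random.Generator, n: int, params: GenerativeParams):
    p = params
    noise = np.zeros(n)
    if p.sigma > 0:
        noise += rng.normal(0.0, p.sigma, n)
    if p.tau > 0:
        noise += rng.exponential(p.tau, n)
    if p.contaminant_rate > 0:
        noise += (rng.random(n) < p.contaminant_rate) * p.contaminant_shift
    return noise


def simulate_dataset(params: GenerativeParams, group: str = "synthetic") -> pd.DataFrame:
    """Simulate a two-session trial-level flanker dataset.

    One row per trial, long format, columns `TRIAL_COLUMNS`.  Both sessions
    share each participant's baseline and effect (a stable trait); session 2
    is uniformly faster by ``session2_speedup``.  Same params (incl. seed)
    give a bit-identical table.
    """
    params.validate()
    p = params
    rng = np.random.default_rng(p.seed)
    b, d = _draw_traits(p, rng)

    # Schedules are built vectorized: per participant-session, a seeded
    # uniform shuffle of the fixed cell multiset within each block (same
    # construction as make_schedule, batched for speed).
    n_ps = p.n_participants * 2          # participant-sessions
    main = _main_block_cells()
    m_dir = main["direction"].to_numpy()
    m_cond = main["condition"].to_numpy()
    m_fix = main["fixation_ms"].to_numpy()
    prac_cells = [(dd, cc) for dd in DIRECTIONS for cc in CONDITIONS] * 2
    p_dir = np.array([c[0] for c in prac_cells])
    p_cond = np.array([c[1] for c in prac_cells])

    perm_prac = rng.permuted(np.tile(np.arange(8), (n_ps, 1)), axis=1)
    fix_prac = rng.choice(FIXATIONS_MS, size=(n_ps, 8))
    perm_m1 = rng.permuted(np.tile(np.arange(160), (n_ps, 1)), axis=1)
    perm_m2 = rng.permuted(np.tile(np.arange(160), (n_ps, 1)), axis=1)

    n_session_trials = 8 + 2 * 160
    direction = np.concatenate(
        [p_dir[perm_prac], m_dir[perm_m1], m_dir[perm_m2]], axis=1).ravel()
    condition = np.concatenate(
        [p_cond[perm_prac], m_cond[perm_m1], m_cond[perm_m2]], axis=1).ravel()
    fixation = np.concatenate(
        [fix_prac, m_fix[perm_m1], m_fix[perm_m2]], axis=1).ravel()
    block = np.tile(np.repeat([PRACTICE_BLOCK, *MAIN_BLOCKS], [8, 160, 160]), n_ps)
    trial = np.tile(np.arange(n_session_trials), n_ps)
    # participant-session rows ordered: all of session 1, then session 2
    part = np.tile(np.repeat(np.arange(1, p.n_participants + 1),
                             n_session_trials), 2)
    session = np.repeat([1, 2], p.n_participants * n_session_trials)

    df = pd.DataFrame({
        "participant": part,
        "group": group,
        "session": session,
        "block": block,
        "trial": trial,
        "condition": condition,
        "direction": direction,
        "fixation_ms": fixation,
    })

    part_ix = part - 1
    inc = (df["condition"] == "incongruent").to_numpy()
    sess2 = (df["session"] == 2).to_numpy()
    n = len(df)
    rt = (b[part_ix] + inc * d[part_ix, sess2.astype(int)]
          - sess2 * p.session2_speedup + _trial_noise(rng, n, p))
    df["rt_ms"] = np.maximum(rt, 1.0)
    err = np.where(inc, p.error_rate_incongruent, p.error_rate_congruent)
    df["correct"] = rng.random(n) >= err
    assert len(df) == 2 * p.n_participants * n_session_trials
    return df[TRIAL_COLUMNS]


def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    """Write the long-format trial CSV (header required, RT in ms)."""
    trials.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Ground-truth reliability
# ---------------------------------------------------------------------------

def _pseudo_session_effects(params: GenerativeParams, effect: float,
                            trials_per_condition: int, n_sim: int,
                            rng: np.random.Generator, config) -> np.ndarray:
    """Scored flanker effects of ``n_sim`` pseudo participant-sessions with a
    fixed true effect (trait variation off); one array of length n_sim."""
    from . import scoring

    p = params
    m = trials_per_condition
    n = n_sim * 2 * m
    part = np.repeat(np.arange(n_sim), 2 * m)
    inc = np.tile(np.repeat([False, True], m), n_sim)
    rt = p.mu_congruent + inc * effect + _trial_noise(rng, n, p)
    err = np.where(inc, p.error_rate_incongruent, p.error_rate_congruent)
    df = pd.DataFrame({
        "participant": part,
        "group": "mc",
        "session": 1,
        "block": "main1",
        "trial": np.tile(np.arange(2 * m), n_sim),
        "condition": np.where(inc, "incongruent", "congruent"),
        "direction": "left",
        "fixation_ms": 500,
        "rt_ms": np.maximum(rt, 1.0),
        "correct": rng.random(n) >= err,
    })
    flagged = scoring.flag_rt_exclusions(df, config=config)
    scores, _ = scoring.score_dataset(flagged, config=config)
    return scores["flanker_effect"].to_numpy()


def effect_error_variance(params: GenerativeParams,
                          trials_per_condition: int = 160,
                          n_sim: int = 4000,
                          mc_seed: int = 0,
                          config=None) -> float:
    """Error variance of the scored flanker effect for one session.

    Simulates ``n_sim`` pseudo participant-sessions with trait variation
    switched off (fixed baseline and effect), runs them through the actual
    exclusion + scoring pipeline, and returns the variance of the resulting
    difference scores.  This is the measurement-error variance of a
    ``trials_per_condition``-trial flanker effect under the generative model,
    including the consequences of the 3*MAD trim, the 100 ms floor, error
    removal and threshold-estimation noise.  Deterministic given arguments
    (``mc_seed`` is independent of ``params.seed``).
    """
    params.validate()
    if trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    rng = np.random.default_rng(mc_seed)
    effects = _pseudo_session_effects(params, params.mu_effect,
                                      trials_per_condition, n_sim, rng, config)
    return float(np.var(effects, ddof=1))


def effect_attenuation(params: GenerativeParams,
                       trials_per_condition: int = 160,
                       n_sim: int = 4000,
                       mc_seed: int = 0,
                       config=None,
                       delta: float = 10.0) -> float:
    """Attenuation slope of the scored effect with respect to the true effect.

    With the default pooled (per participant-session) MAD threshold, a larger
    true effect pushes more of the incongruent distribution over the shared
    cut and holds back more of the congruent tail, so the scored effect grows
    slower than the true one (slope < 1, typically ~0.88 under the default
    noise profile).  Per-condition thresholds remove the dependence (slope
    ~1).  Estimated as a central difference of the mean scored effect at
    ``mu_effect +/- delta``.
    """
    rng = np.random.default_rng(mc_seed + 1)
    lo = _pseudo_session_effects(params, params.mu_effect - delta,
                                 trials_per_condition, n_sim, rng, config)
    hi = _pseudo_session_effects(params, params.mu_effect + delta,
                                 trials_per_condition, n_sim, rng, config)
    return float((hi.mean() - lo.mean()) / (2 * delta))


def true_reliability(params: GenerativeParams,
                     trials_per_condition: int,
                     trial_variance: float | None = None,
                     n_sim: int = 4000,
                     mc_seed: int = 0) -> TrueReliability:
    """Ground-truth reliability of the flanker effect at a given task length.

    ``rho = (a * sd_effect)^2 / ((a * sd_effect)^2 + var_e(L))`` where ``a``
    is the scoring pipeline's attenuation slope (see `effect_attenuation`).
    If ``trial_variance`` is supplied, the textbook closed form is used
    instead: error variance ``2 * trial_variance / L`` (two condition means
    of ``L`` trials each) and no attenuation; otherwise both ``var_e`` and
    ``a`` are measured from the scoring pipeline by deterministic Monte
    Carlo.
    """
    if trials_per_condition < 1:
        raise ValueError("trials_per_condition must be >= 1")
    s2 = params.sd_effect**2
    if s2 == 0:
        return TrueReliability(trials_per_condition, 0.0)
    if trial_variance is not None:
        var_e = 2.0 * trial_variance / trials_per_condition
        a2 = 1.0
    elif params.sigma == 0 and params.tau == 0 and params.contaminant_rate == 0:
        var_e = 0.0
        a2 = 1.0
    else:
        var_e = effect_error_variance(params, trials_per_condition,
                                      n_sim=n_sim, mc_seed=mc_seed)
        a2 = effect_attenuation(params, trials_per_condition,
                                n_sim=n_sim, mc_seed=mc_seed) ** 2
    return TrueReliability(trials_per_condition, a2 * s2 / (a2 * s2 + var_e))


def with_true_reliability(params: GenerativeParams,
                          target: float,
                          trials_per_condition: int = 160,
                          n_sim: int = 4000,
                          mc_seed: int = 0) -> GenerativeParams:
    """Return params with ``sd_effect`` set so the ground-truth reliability at
    ``trials_per_condition`` equals ``target``.

    Neither the error variance nor the attenuation slope depends on
    ``sd_effect``, so the calibration is a direct solve:
    ``sd_effect = sqrt(target / (1-target) * var_e(L)) / a``.
    """
    if not 0.0 < target < 1.0:
        raise ValueError("target reliability must be in (0, 1)")
    var_e = effect_error_variance(params, trials_per_condition,
                                  n_sim=n_sim, mc_seed=mc_seed)
    a = effect_attenuation(params, trials_per_condition,
                           n_sim=n_sim, mc_seed=mc_seed)
    sd = float(np.sqrt(target / (1.0 - target) * var_e) / a)
    return dataclasses.replace(params, sd_effect=sd)
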