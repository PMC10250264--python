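"""Exclusion rules and flanker-effect scoring for trial-level RT data.

The pipeline follows the standard analysis of a two-condition interference
task scored as a difference of condition means:

1. practice trials are flagged and never scored;
2. main-block RTs below 100 ms are flagged (anticipations);
3. main-block RTs more than ``3 * MAD`` above each participant-session's
   median are flagged (slow tail), with the median and the unscaled MAD
   (median of absolute deviations, no 1.4826 consistency factor) computed
   once on the pre-exclusion trial set -- flags never trigger re-flagging;
4. incorrect responses are excluded from RT means but counted in accuracy;
5. the flanker effect is ``mean RT(incongruent) - mean RT(congruent)`` over
   correct, unflagged main trials;
6. participants with accuracy below 60% in either session are excluded.

Two conventions that published descriptions of this rule leave open are
exposed as config switches: whether the MAD is computed per
participant-session pooled across conditions (default) or per condition, and
whether error trials enter the threshold-defining set (default: correct
trials only, since error RTs come from a different process).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import PRACTICE_BLOCK, TRIAL_COLUMNS

REASON_NONE = "none"
REASON_PRACTICE = "practice"
REASON_RT_LT_100 = "rt_lt_100"
REASON_RT_GT_3MAD = "rt_gt_3mad"
REASON_INCORRECT = "incorrect"

SCORE_COLUMNS = [
    "participant", "group", "session",
    "mean_rt_congruent", "mean_rt_incongruent", "flanker_effect",
    "accuracy", "n_valid_congruent", "n_valid_incongruent",
    "pct_3mad_congruent", "pct_3mad_incongruent",
    "pct_lt100_congruent", "pct_lt100_incongruent",
    "pct_incorrect_congruent", "pct_incorrect_incongruent",
]


@dataclass(frozen=True)
class ScoringConfig:
    """Tunable parts of the exclusion pipeline.

    min_rt_ms            fast-guess floor (ms); RTs below it are flagged.
    mad_multiplier       slow-tail cut: rt - median > mad_multiplier * MAD.
    mad_scope            'session' pools both conditions when computing the
                         participant-session median/MAD; 'condition' computes
                         them per condition.
    mad_on_correct_only  threshold set excludes error trials (default True).
    accuracy_threshold   participants below this in either session are
                         excluded ('below' is strict: exactly 60% is kept).
    """

    min_rt_ms: float = 100.0
    mad_multiplier: float = 3.0
    mad_scope: str = "session"
    mad_on_correct_only: bool = True
    accuracy_threshold: float = 0.60

    def __post_init__(self):
        if self.mad_scope not in ("session", "condition"):
            raise ValueError("mad_scope must be 'session' or 'condition'")


DEFAULT_CONFIG = ScoringConfig()


class TrialDataError(ValueError):
    """Raised when a trial CSV fails validation; messages name row numbers."""


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format trial CSV (the dialect written by
    :func:`flankrel.synthetic.write_trials`)."""
    df = pd.read_csv(path)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise TrialDataError(f"{path}: missing column(s) {missing}")

    def rows(mask):  # header is line 1
        return [int(i) + 2 for i in df.index[mask][:10]]

    bad = ~df["condition"].isin(["congruent", "incongruent"])
    if bad.any():
        raise TrialDataError(f"{path}: invalid condition at rows {rows(bad)}")
    bad = ~df["session"].isin([1, 2])
    if bad.any():
        raise TrialDataError(f"{path}: session must be 1 or 2 at rows {rows(bad)}")
    rt = pd.to_numeric(df["rt_ms"], errors="coerce")
    bad = ~(rt > 0)
    if bad.any():
        raise TrialDataError(f"{path}: rt_ms must be > 0 at rows {rows(bad)}")
    df["rt_ms"] = rt.astype(float)
    if df["correct"].dtype != bool:
        vals = df["correct"].astype(str).str.lower()
        ok = vals.isin(["true", "false", "0", "1"])
        if not ok.all():
            raise TrialDataError(
                f"{path}: correct must be boolean at rows {rows(~ok)}")
        df["correct"] = vals.isin(["true", "1"])
    return df


# ---------------------------------------------------------------------------
# Trial-level exclusion flags
# ---------------------------------------------------------------------------

def flag_rt_exclusions(trials: pd.DataFrame,
                       config: ScoringConfig | None = None) -> pd.DataFrame:
    """Set per-trial exclusion flags; returns a copy with extra columns
    ``rt_lt_100``, ``rt_gt_3mad`` (booleans over main trials) and
    ``excluded_reason``.

    The median/MAD threshold is computed per participant-session (pooled
    across conditions by default) on the pre-exclusion set; a trial is
    slow-flagged iff ``rt - median > mad_multiplier * MAD``.  Raises if any
    threshold set has fewer than 4 trials (MAD too unstable to define a cut).
    """
    cfg = config or DEFAULT_CONFIG
    df = trials.copy()
    n_groups = df.groupby("participant")["group"].nunique()
    if (n_groups > 1).any():
        dup = n_groups.index[n_groups > 1].tolist()[:5]
        raise ValueError(
            f"participant id(s) appear in more than one group: {dup}; "
            "ids must be unique across groups")
    main = (df["block"] != PRACTICE_BLOCK).to_numpy()

    keys = ["participant", "session"]
    if cfg.mad_scope == "condition":
        keys = keys + ["condition"]
    thr_mask = main & (df["correct"].to_numpy() if cfg.mad_on_correct_only
                       else True)
    sub = df.loc[thr_mask, keys + ["rt_ms"]]
    sizes = sub.groupby(keys, sort=False).size()
    # participant-sessions with *no* threshold trials must fail the check too
    main_keys = pd.MultiIndex.from_frame(df.loc[main, keys].drop_duplicates())
    sizes = sizes.reindex(main_keys, fill_value=0)
    if (sizes < 4).any():
        small = sizes[sizes < 4].index.tolist()[:5]
        raise ValueError(
            f"MAD undefined: fewer than 4 threshold trials for {small}")
    med = sub.groupby(keys, sort=False)["rt_ms"].transform("median")
    mad = (sub["rt_ms"] - med).abs().groupby(
        [sub[k] for k in keys], sort=False).transform("median")
    table = pd.DataFrame({"_med": med, "_mad": mad}, index=sub.index)
    table = pd.concat([sub[keys], table], axis=1).drop_duplicates(subset=keys)

    merged = df[keys].merge(table, on=keys, how="left")
    med_all = merged["_med"].to_numpy()
    mad_all = merged["_mad"].to_numpy()

    rt = df["rt_ms"].to_numpy(dtype=float)
    lt = main & (rt < cfg.min_rt_ms)
    with np.errstate(invalid="ignore"):
        gt = main & ((rt - med_all) > cfg.mad_multiplier * mad_all)
    df["rt_lt_100"] = lt
    df["rt_gt_3mad"] = gt
    correct = df["correct"].to_numpy(dtype=bool)
    df["excluded_reason"] = np.select(
        [~main, lt, gt, ~correct],
        [REASON_PRACTICE, REASON_RT_LT_100, REASON_RT_GT_3MAD, REASON_INCORRECT],
        default=REASON_NONE,
    )
    return df


def _require_flags(trials: pd.DataFrame) -> None:
    if "excluded_reason" not in trials.columns:
        raise ValueError(
            "trials are not exclusion-flagged; call flag_rt_exclusions first")


# ---------------------------------------------------------------------------
# Participant-session scores
# ---------------------------------------------------------------------------

def score_dataset(trials: pd.DataFrame,
                  config: ScoringConfig | None = None
                  ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every participant-session.

    Returns ``(scores, dropped)``: one row per participant-session with
    condition means over correct unflagged main trials, the flanker effect,
    accuracy over all main trials, per-condition exclusion percentages and
    valid-trial counts.  Participant-sessions with zero valid trials in a
    condition are undefined; they are reported in ``dropped`` and omitted
    from ``scores``.
    """
    if "excluded_reason" not in trials.columns:
        trials = flag_rt_exclusions(trials, config=config)
    df = trials[trials["block"] != PRACTICE_BLOCK].copy()
    keys = ["participant", "session"]

    grp_cond = df.groupby(keys + ["condition"], sort=True)
    valid = df[df["excluded_reason"] == REASON_NONE]
    means = valid.groupby(keys + ["condition"], sort=True)["rt_ms"].mean()
    nvalid = valid.groupby(keys + ["condition"], sort=True).size()
    pct = grp_cond.agg(
        pct_3mad=("rt_gt_3mad", "mean"),
        pct_lt100=("rt_lt_100", "mean"),
        pct_incorrect=("correct", "mean"),
    ) * 100.0
    pct["pct_incorrect"] = 100.0 - pct["pct_incorrect"]

    wide = pct.unstack("condition")
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    wide["mean_rt_congruent"] = means.unstack("condition").get("congruent")
    wide["mean_rt_incongruent"] = means.unstack("condition").get("incongruent")
    nv = nvalid.unstack("condition").reindex(wide.index).fillna(0).astype(int)
    wide["n_valid_congruent"] = nv.get("congruent", 0)
    wide["n_valid_incongruent"] = nv.get("incongruent", 0)
    acc = df.groupby(keys, sort=True)["correct"].mean()
    wide["accuracy"] = acc
    wide["flanker_effect"] = (wide["mean_rt_incongruent"]
                              - wide["mean_rt_congruent"])
    first_group = df.groupby(keys, sort=True)["group"].first()
    wide["group"] = first_group

    wide = wide.reset_index()
    undefined = (wide["n_valid_congruent"] == 0) | (wide["n_valid_incongruent"] == 0)
    dropped = wide.loc[undefined, keys + ["group", "n_valid_congruent",
                                          "n_valid_incongruent"]].copy()
    scores = wide.loc[~undefined, SCORE_COLUMNS].reset_index(drop=True)
    return scores, dropped.reset_index(drop=True)


def score_participant(trials: pd.DataFrame,
                      config: ScoringConfig | None = None) -> pd.Series:
    """Score a single participant-session; raises if a condition has zero
    valid trials (the score is undefined)."""
    ps = trials[["participant", "session"]].drop_duplicates()
    if len(ps) != 1:
        raise ValueError("score_participant expects one participant-session")
    scores, dropped = score_dataset(trials, config=config)
    if len(scores) == 0:
        raise ValueError(
            f"score undefined (zero valid trials in a condition) for "
            f"{ps.iloc[0].to_dict()}")
    return scores.iloc[0]


# ---------------------------------------------------------------------------
# Participant-level exclusion and descriptives
# ---------------------------------------------------------------------------

def exclude_participants(scores: pd.DataFrame,
                         config: ScoringConfig | None = None
                         ) -> tuple[list, pd.DataFrame]:
    """Apply the accuracy rule: retained iff accuracy >= threshold in both
    sessions ('below 60%' excludes only strictly-below scores).

    Returns ``(retained_ids, report)`` where the report lists every
    participant with per-session accuracy and a status of ``retained``,
    ``low_accuracy`` or ``incomplete`` (a missing session).
    """
    cfg = config or DEFAULT_CONFIG
    acc = scores.pivot_table(index="participant", columns="session",
                             values="accuracy", aggfunc="first")
    acc = acc.reindex(columns=[1, 2])
    a1, a2 = acc[1], acc[2]
    complete = a1.notna() & a2.notna()
    ok = complete & (a1 >= cfg.accuracy_threshold) & (a2 >= cfg.accuracy_threshold)
    status = np.where(~complete, "incomplete",
                      np.where(ok, "retained", "low_accuracy"))
    report = pd.DataFrame({
        "participant": acc.index,
        "accuracy_session1": a1.to_numpy(),
        "accuracy_session2": a2.to_numpy(),
        "status": status,
    }).reset_index(drop=True)
    retained = report.loc[report["status"] == "retained", "participant"].tolist()
    return retained, report


def pivot_effects(scores: pd.DataFrame) -> pd.DataFrame:
    """Participants x sessions table of flanker effects (complete cases)."""
    wide = scores.pivot_table(index="participant", columns="session",
                              values="flanker_effect", aggfunc="first")
    wide = wide.reindex(columns=[1, 2]).dropna()
    wide.columns = ["session1", "session2"]
    return wide


def group_descriptives(scores: pd.DataFrame) -> dict:
    """Descriptive summary per group x session, mirroring the usual flanker
    reporting: medians of exclusion percentages, means/SDs of condition mean
    RTs and of the flanker effect, and the Pearson correlation between
    congruent and incongruent mean RTs.

    Single-participant cells report SDs and the correlation as None.
    Summaries are order-invariant.
    """
    out: dict = {}
    for (group, session), g in scores.groupby(["group", "session"], sort=True):
        n = len(g)
        con, inc = g["mean_rt_congruent"], g["mean_rt_incongruent"]
        if n >= 2 and con.std() > 0 and inc.std() > 0:
            corr = float(np.corrcoef(con, inc)[0, 1])
        else:
            corr = None
        entry = {
            "n": int(n),
            "median_pct_3mad": {
                "congruent": float(g["pct_3mad_congruent"].median()),
                "incongruent": float(g["pct_3mad_incongruent"].median()),
            },
            "median_pct_incorrect": {
                "congruent": float(g["pct_incorrect_congruent"].median()),
                "incongruent": float(g["pct_incorrect_incongruent"].median()),
            },
            "mean_rt": {"congruent": float(con.mean()),
                        "incongruent": float(inc.mean())},
            "sd_rt": {"congruent": float(con.std(ddof=1)) if n > 1 else None,
                      "incongruent": float(inc.std(ddof=1)) if n > 1 else None},
            "corr_congruent_incongruent": corr,
            "mean_flanker_effect": float(g["flanker_effect"].mean()),
            "sd_flanker_effect": (float(g["flanker_effect"].std(ddof=1))
                                  if n > 1 else None),
        }
        out.setdefault(str(group), {})[str(int(session))] = entry
    return out
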