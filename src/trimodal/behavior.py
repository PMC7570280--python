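"""Motor-behavior aggregation and baseline normalization.

Trial-level scores from the open-field grid, horizontal ladder and grip
strength tests are aggregated to one weekly score per animal and test
(fastest 3 of 5 ladder crossings per session, mean of 3 grip pulls,
grid metrics as recorded; the two weekly sessions averaged), then
normalized to each animal's presurgery baseline (week 0) as

    % change in performance = (weekly - baseline) / baseline * (-100)

so a value below zero means the raw score rose above baseline. Slip
counts are left raw: their baselines are near zero, which makes the
percent-change rule unstable (and Table-style analyses use them raw).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import EQ1_NORMALIZED_TESTS, RAW_COUNT_TESTS

LADDER_FASTEST_N = 3
LADDER_TRIALS = 5


def _session_score(test: str, values: np.ndarray) -> float:
    if test == "ladder_time":
        v = np.sort(values)
        if len(v) < LADDER_FASTEST_N:
            warnings.warn(
                f"ladder session has {len(v)} < {LADDER_FASTEST_N} trials; "
                "using all")
            return float(v.mean())
        return float(v[:LADDER_FASTEST_N].mean())
    return float(np.mean(values))


def aggregate_week(trials: pd.DataFrame) -> pd.DataFrame:
    """Weekly raw scores per animal/test from a trial table.

    Expects columns ``animal_id, test, week, session, trial_index,
    value``; week 0 is the presurgery baseline and is aggregated by the
    same rules. Returns ``animal_id, week, test, score``.
    """
    required = {"animal_id", "test", "week", "session", "value"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"trial table lacks columns {sorted(missing)}")
    per_session = (
        trials.groupby(["animal_id", "test", "week", "session"])["value"]
        .apply(lambda s: _session_score(s.name[1], s.to_numpy()))
        .rename("score").reset_index())
    weekly = (per_session.groupby(["animal_id", "test", "week"],
                                  as_index=False)["score"].mean())
    return weekly[["animal_id", "week", "test", "score"]]


def percent_change(weekly: float | np.ndarray,
                   baseline: float) -> float | np.ndarray:
    """(weekly - baseline) / baseline * (-100); undefined at zero baseline."""
    if baseline == 0:
        raise ZeroDivisionError("percent change undefined for zero baseline")
    return (np.asarray(weekly, dtype=float) - baseline) / baseline * (-100.0)


def normalize_to_baseline(weekly: pd.DataFrame,
                          eq1_tests=EQ1_NORMALIZED_TESTS) -> pd.DataFrame:
    """Add ``pct_change`` and the per-test ``analysis_value`` column.

    ``pct_change`` is the baseline-normalized percent change for tests in
    ``eq1_tests`` (NaN-flagged where the baseline is zero or absent);
    raw-count tests keep NaN there. ``analysis_value`` is what enters the
    correlation network and regressions: ``pct_change`` for normalized
    tests, the raw weekly score for slip counts.
    """
    out = weekly.copy()
    base = (out[out.week == 0].set_index(["animal_id", "test"])["score"])
    pct = np.full(len(out), np.nan)
    for i, r in enumerate(out.itertuples()):
        if r.test not in eq1_tests:
            continue
        b = base.get((r.animal_id, r.test), np.nan)
        if pd.isna(b) or b == 0:
            if b == 0:
                warnings.warn(
                    f"zero baseline for {r.animal_id}/{r.test}; "
                    "percent change flagged missing")
            continue
        pct[i] = float(percent_change(r.score, b))
    out["pct_change"] = pct
    # bracket access: DataFrame.pct_change is a pandas method name
    out["analysis_value"] = np.where(
        out.test.isin(list(RAW_COUNT_TESTS)), out["score"], out["pct_change"])
    return out


def behavior_weekly(trials: pd.DataFrame) -> pd.DataFrame:
    """Full behavior stage: aggregate trials, then normalize to baseline."""
    return normalize_to_baseline(aggregate_week(trials))
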