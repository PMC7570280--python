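"""Assembly of the three modalities into the analysis tables.

Merges recording metrics, weekly behavior and endpoint histology into
the longitudinal/cross-sectional tables the correlation network and the
regressions consume, and validates the observation accounting of the
default design: 480 channel-level recording rows (6 animals x 10 kept
channels x 8 weeks), 54 weekly behavior rows per test (6 animals x
[baseline + 8 weeks]), and 6 endpoint histology measurements per
marker/bin (one per animal).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    BEHAVIOR_VARS,
    HISTOLOGY_VAR_OF,
    HISTOLOGY_VARS,
    RECORDING_VARS,
    StudyConfig,
    VARIABLES,
)


@dataclass
class AnalysisTables:
    """The assembled study, keyed and validated.

    ``recording_channel``: one row per animal x kept channel x week
    (weekly mean unit count) — the basis of the units-per-channel
    outcome. ``recording_weekly``: per animal x week outcomes.
    ``behavior``: per animal x week (incl. baseline week 0) x test.
    ``histology``: per animal x marker x distance bin.
    """

    config: StudyConfig
    recording_channel: pd.DataFrame
    recording_weekly: pd.DataFrame
    behavior: pd.DataFrame
    histology: pd.DataFrame
    registry: tuple[str, ...] = VARIABLES

    def manifest(self) -> dict:
        return {
            "recording_channel_rows": int(len(self.recording_channel)),
            "recording_weekly_rows": int(len(self.recording_weekly)),
            "behavior_rows_per_test": {
                t: int((self.behavior.test == t).sum())
                for t in BEHAVIOR_VARS},
            "histology_rows_per_model": {
                f"{m}/{b}": int(((self.histology.marker == m)
                                 & (self.histology.distance_bin == b)).sum())
                for m, b in HISTOLOGY_VAR_OF},
            "variables": list(self.registry),
        }

    # -- variable access ------------------------------------------------

    def longitudinal_series(self, variable: str) -> pd.Series:
        """Per-(animal, week) values of a longitudinal registry variable."""
        if variable in RECORDING_VARS:
            col = ("pct_active" if variable == "pct_channels_active"
                   else "units_per_channel")
            df = self.recording_weekly
            return df.set_index(["animal_id", "week"])[col].rename(variable)
        if variable in BEHAVIOR_VARS:
            df = self.behavior[self.behavior.test == variable]
            return (df.set_index(["animal_id", "week"])["analysis_value"]
                    .rename(variable))
        raise KeyError(f"{variable!r} is not a longitudinal variable")

    def animal_series(self, variable: str) -> pd.Series:
        """Per-animal value: endpoint histology, or the per-animal mean of
        a longitudinal variable (post-implant weeks)."""
        if variable in HISTOLOGY_VARS:
            inv = {v: k for k, v in HISTOLOGY_VAR_OF.items()}
            m, b = inv[variable]
            df = self.histology[(self.histology.marker == m)
                                & (self.histology.distance_bin == b)]
            return df.set_index("animal_id")["value"].rename(variable)
        s = self.longitudinal_series(variable)
        s = s[s.index.get_level_values("week") >= 1]
        return s.groupby("animal_id").mean().rename(variable)

    def is_longitudinal(self, variable: str) -> bool:
        return variable not in HISTOLOGY_VARS


def assemble(config: StudyConfig,
             channel_metrics: pd.DataFrame,
             recording_weekly: pd.DataFrame,
             behavior_weekly: pd.DataFrame,
             histology: pd.DataFrame) -> AnalysisTables:
    """Merge the three modalities, checking keys and row accounting.

    All inputs must cover the same animals; an animal present in only
    some modalities is an error (missing values inside a modality are
    carried as NaN flags, never imputed).
    """
    sets = {
        "recording": set(channel_metrics.animal_id) | set(
            recording_weekly.animal_id),
        "behavior": set(behavior_weekly.animal_id),
        "histology": set(histology.animal_id),
    }
    all_animals = set.union(*sets.values())
    orphans = {
        name: sorted(all_animals - s) for name, s in sets.items()
        if all_animals - s}
    if orphans:
        raise ValueError(
            "animals missing from some modalities: "
            + "; ".join(f"{k} lacks {v}" for k, v in orphans.items()))

    for df, keys in ((channel_metrics, ["animal_id", "channel_id", "week"]),
                     (recording_weekly, ["animal_id", "week"]),
                     (behavior_weekly, ["animal_id", "week", "test"]),
                     (histology, ["animal_id", "marker", "distance_bin"])):
        if df.duplicated(subset=keys).any():
            raise ValueError(f"duplicated keys {keys} in an input table")

    canon = lambda df, keys: df.sort_values(keys, ignore_index=True)
    return AnalysisTables(
        config=config,
        recording_channel=canon(channel_metrics,
                                ["animal_id", "channel_id", "week"]),
        recording_weekly=canon(recording_weekly, ["animal_id", "week"]),
        behavior=canon(behavior_weekly, ["animal_id", "test", "week"]),
        histology=canon(histology, ["animal_id", "marker", "distance_bin"]),
    )


def regression_frame(tables: AnalysisTables, distance_bin: str,
                     level: str = "channel") -> pd.DataFrame:
    """Long-format design table for the regression stage.

    One row per channel-week (``level='channel'``, units-per-channel
    outcome) or per animal-week (``level='animal'``, percent-active
    outcome), post-implant weeks only, with the weekly behavior analysis
    values joined on (animal, week) and the chosen distance bin's
    histology values broadcast as time-constant per-animal covariates.
    """
    if level == "channel":
        df = tables.recording_channel.rename(columns={"n_units": "y"}).copy()
    elif level == "animal":
        df = tables.recording_weekly.rename(
            columns={"pct_active": "y"})[["animal_id", "week", "y"]].copy()
    else:
        raise ValueError("level must be 'channel' or 'animal'")
    df["time"] = df.week.astype(float)

    beh = tables.behavior[tables.behavior.week >= 1]
    wide = beh.pivot_table(index=["animal_id", "week"], columns="test",
                           values="analysis_value", aggfunc="first")
    df = df.merge(wide.reset_index(), on=["animal_id", "week"], how="left")

    hist = tables.histology[tables.histology.distance_bin == distance_bin]
    hw = hist.pivot_table(index="animal_id", columns="marker",
                          values="value", aggfunc="first")
    hw = hw.rename(columns={"IgG": "bbb_permeability",
                            "CD68": "microglia",
                            "GFAP": "astrocyte",
                            "NeuN": "neuron_density"})
    return df.merge(hw.reset_index(), on="animal_id", how="left")


# ---------------------------------------------------------------------------
# Round-trippable on-disk form
# ---------------------------------------------------------------------------

_TABLE_FILES = {
    "recording_channel": "recording_channel.csv",
    "recording_weekly": "recording_metrics.csv",
    "behavior": "behavior_weekly.csv",
    "histology": "histology.csv",
}


def write_tables(tables: AnalysisTables, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for attr, fname in _TABLE_FILES.items():
        getattr(tables, attr).to_csv(out / fname, index=False)
    (out / "manifest.json").write_text(
        json.dumps(tables.manifest(), indent=2))


def read_tables(in_dir: str | Path,
                config: StudyConfig | None = None) -> AnalysisTables:
    src = Path(in_dir)
    frames = {attr: pd.read_csv(src / fname)
              for attr, fname in _TABLE_FILES.items()}
    return AnalysisTables(config=config or StudyConfig(), **frames)
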