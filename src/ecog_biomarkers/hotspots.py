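"""Hotspot selection and edge-list export for external tractography.

A channel is a hotspot at a given stage when its stage-averaged biomarker
value is at least ``k`` SD (default 3) above the slow-wave-sleep reference
mean ("at least", so the boundary value is included).  The reference mean/SD
are computed across the pooled normative-channel SWS stage values (group
reference).  Selected sites are exported as an unordered pair list for
white-matter streamline software; streamline tracking itself is out of scope.
"""

from __future__ import annotations

import csv
import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass
class HotspotSet:
    stage: str
    biomarker: str
    members: pd.Series  # channel label -> value, hotspot channels only
    sws_mean: float
    sws_sd: float
    threshold_sd: float = 3.0

    @property
    def labels(self) -> list[str]:
        return list(self.members.index)


def select_hotspots(
    stage_values: pd.Series,
    sws_mean: float,
    sws_sd: float,
    k: float = 3.0,
    stage: str = "",
    biomarker: str = "",
) -> HotspotSet:
    """Channels whose value is >= sws_mean + k * sws_sd (boundary included)."""
    if sws_sd <= 0:
        raise ValueError("reference SD must be positive")
    cut = sws_mean + k * sws_sd
    vals = stage_values.dropna()
    members = vals[vals >= cut]
    return HotspotSet(stage, biomarker, members, float(sws_mean), float(sws_sd), float(k))


def export_edges(
    hs: HotspotSet,
    path: str | Path,
    coords: dict[str, tuple[float, float, float]] | None = None,
) -> Path:
    """Write all unordered hotspot pairs as a CSV edge list.

    Columns: channel_a, channel_b, value_a, value_b, stage, biomarker, plus
    xyz coordinates per member when supplied.  Fewer than 2 members produces
    a header-only file with a warning.
    """
    path = Path(path)
    fields = ["channel_a", "channel_b", "value_a", "value_b", "stage", "biomarker"]
    if coords is not None:
        fields += ["xa", "ya", "za", "xb", "yb", "zb"]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(fields)
        if len(hs.members) < 2:
            warnings.warn(
                f"hotspot set {hs.biomarker}@{hs.stage} has {len(hs.members)} member(s); "
                "empty edge list written"
            )
            return path
        for a, b in itertools.combinations(hs.labels, 2):
            row = [a, b, hs.members[a], hs.members[b], hs.stage, hs.biomarker]
            if coords is not None:
                row += list(coords[a]) + list(coords[b])
            writer.writerow(row)
    return path


def reference_stats(table: pd.DataFrame, biomarker: str, stage: str = "SWS") -> tuple[float, float]:
    """Pooled normative-channel mean/SD of a biomarker at the reference stage."""
    df = table[
        (table["biomarker"] == biomarker)
        & (table["stage"] == stage)
        & table["is_normative"]
    ]["value"].dropna()
    if df.empty:
        raise ValueError(f"no normative {biomarker} rows at stage {stage}")
    return float(df.mean()), float(df.std(ddof=1))


def stage_channel_means(table: pd.DataFrame, biomarker: str, stage: str) -> pd.Series:
    """Per-channel stage value: biomarker averaged over the stage's analysis epochs."""
    df = table[(table["biomarker"] == biomarker) & (table["stage"] == stage)]
    out = df.groupby("channel_label")["value"].mean()
    return out.dropna()


def hotspots_from_table(
    table: pd.DataFrame,
    biomarker: str,
    stage: str,
    reference_stage: str = "SWS",
    k: float = 3.0,
) -> HotspotSet:
    """Group-referenced hotspot selection straight from a biomarker table."""
    mean, sd = reference_stats(table, biomarker, reference_stage)
    vals = stage_channel_means(table, biomarker, stage)
    return select_hotspots(vals, mean, sd, k=k, stage=stage, biomarker=biomarker)


def hotspot_zscores(values: pd.Series, sws_mean: float, sws_sd: float) -> pd.Series:
    """Channel values re-expressed as SDs above the reference mean."""
    if sws_sd <= 0:
        raise ValueError("reference SD must be positive")
    return (values - sws_mean) / sws_sd
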