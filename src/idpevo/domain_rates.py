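"""Substitution and indel tallies between ancestral and descendant domains.

Counts differences between a sequence and its evolutionary predecessor in
shared alignment coordinates and accumulates per-domain normalized change
fractions along a lineage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GAP = "-"
MASK = "X"


@dataclass(frozen=True)
class DomainWindow:
    """Master-alignment column window (1-based, inclusive)."""

    name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError("window requires 1 <= start <= end")

    def slice(self) -> slice:
        return slice(self.start - 1, self.end)


@dataclass(frozen=True)
class LineagePath:
    """Ordered ancestor-to-descendant node labels with ages (Myr before present)."""

    nodes: tuple[str, ...]
    ages: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.ages):
            raise ValueError("one age per node required")
        if len(self.nodes) < 2:
            raise ValueError("a lineage needs at least two nodes")
        if any(a < b for a, b in zip(self.ages, self.ages[1:])):
            raise ValueError("node ages must be nonincreasing (oldest first)")

    def plotting_ages(self, equal_age_offset: float = 0.0) -> np.ndarray:
        """Ages for plotting; consecutive equal ages are separated by
        ``equal_age_offset`` Myr (an arbitrary display convention)."""
        ages = np.array(self.ages, dtype=float)
        if equal_age_offset > 0:
            for i in range(1, len(ages)):
                if ages[i] >= ages[i - 1]:
                    ages[i] = ages[i - 1] - equal_age_offset
        return ages


def count_changes(
    seq_a: str, seq_b: str, indel_mode: str = "events"
) -> dict[str, int]:
    """Count substitutions and indels between two aligned sequences.

    Substitutions are columns where both sequences carry (unmasked)
    residues that differ; columns containing ``X`` in either sequence are
    excluded.  An indel is a maximal run of consecutive columns gapped in
    exactly one of the two sequences; with ``indel_mode="columns"`` each
    such column counts individually.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    if indel_mode not in ("events", "columns"):
        raise ValueError("indel_mode must be 'events' or 'columns'")
    substitutions = 0
    indels = 0
    prev_state = 0  # 0 = none, 1 = gap in a only, 2 = gap in b only
    for ca, cb in zip(seq_a, seq_b):
        gap_a, gap_b = ca == GAP, cb == GAP
        if gap_a != gap_b:
            state = 1 if gap_a else 2
            if indel_mode == "columns" or state != prev_state:
                indels += 1
            prev_state = state
        else:
            prev_state = 0
            if not gap_a and ca != cb and MASK not in (ca, cb):
                substitutions += 1
    return {"substitutions": substitutions, "indel_events": indels}


def _domain_length(descendant: str, ancestor: str) -> int:
    """Residue count of the descendant domain, excluding masked columns."""
    return sum(
        1
        for ca, cd in zip(ancestor, descendant)
        if cd != GAP and MASK not in (ca, cd)
    )


def cumulative_profile(
    path: LineagePath,
    window: DomainWindow,
    sequences: dict[str, str],
    indel_mode: str = "events",
    equal_age_offset: float = 0.0,
) -> pd.DataFrame:
    """Accumulated normalized sequence change along a lineage.

    For each consecutive ancestor/descendant pair the windowed
    subsequences are compared; the change fraction is
    ``(substitutions + indels) / domain_length`` with ``domain_length``
    the descendant's non-gap residue count in the window.  The cumulative
    sum is reported against node ages.

    Returns a tidy frame with one row per lineage step.
    """
    for label in path.nodes:
        if label not in sequences:
            raise KeyError(f"no sequence for lineage node {label!r}")
        if len(sequences[label]) < window.end:
            raise ValueError(f"sequence for {label!r} does not cover the window")
    ages = path.plotting_ages(equal_age_offset)
    rows = []
    cumulative = 0.0
    for (old, young), age in zip(zip(path.nodes, path.nodes[1:]), ages[1:]):
        sub_a = sequences[old][window.slice()]
        sub_b = sequences[young][window.slice()]
        tally = count_changes(sub_a, sub_b, indel_mode=indel_mode)
        length = _domain_length(sub_b, sub_a)
        if length == 0:
            raise ValueError(
                f"descendant {young!r} has no residues in window {window.name!r}"
            )
        normalized = (tally["substitutions"] + tally["indel_events"]) / length
        cumulative += normalized
        rows.append(
            {
                "domain": window.name,
                "from_node": old,
                "to_node": young,
                "age_Myr": age,
                "substitutions": tally["substitutions"],
                "indels": tally["indel_events"],
                "domain_length": length,
                "normalized": normalized,
                "cumulative": cumulative,
            }
        )
    return pd.DataFrame(rows)


def lineage_table(
    paths: dict[str, LineagePath],
    windows: list[DomainWindow],
    sequences: dict[str, str],
    indel_mode: str = "events",
    equal_age_offset: float = 0.0,
) -> pd.DataFrame:
    """Cumulative profiles for every (lineage, domain) combination."""
    frames = []
    for lineage_name, path in paths.items():
        for window in windows:
            df = cumulative_profile(
                path, window, sequences, indel_mode, equal_age_offset
            )
            df.insert(0, "lineage", lineage_name)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
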