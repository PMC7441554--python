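"""Stall-site mapping from per-position coverage of stalled products.

Stalled-product read coverage along an insert drops sharply where the
polymerase dissociates. Each replicate profile is normalized by its own
maximum and replicates are averaged position-wise; the stall position
is the first downward crossing of relative coverage 0.5, linearly
interpolated between flanking positions. The travel distance at time t
is the stall position at t minus the position at the first time point
(0.5 min), measuring how far the polymerase progressed into the repeat
before stalling.

Coordinates are 0-based offsets from the first repeat base; distances
are in nucleotides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BASELINE_TIME = 0.5


def normalize_coverage(replicate_profiles: list[np.ndarray]) -> np.ndarray:
    """Divide each replicate by its own maximum, then average position-wise."""
    if not replicate_profiles:
        raise ValueError("no replicate profiles")
    normed = []
    for raw in replicate_profiles:
        raw = np.asarray(raw, dtype=float)
        peak = raw.max()
        if peak <= 0:
            raise ValueError("all-zero coverage profile")
        normed.append(raw / peak)
    return np.mean(normed, axis=0)


def stall_position(profile: np.ndarray, level: float = 0.5) -> float:
    """First downward crossing of *level*, linearly interpolated.

    Returns NaN when the profile never crosses the level (no stall
    transition within the insert). The first crossing is used because
    the earliest stall site dominates the stalled fraction.
    """
    prof = np.asarray(profile, dtype=float)
    for i in range(len(prof) - 1):
        if prof[i] >= level > prof[i + 1]:
            return i + (prof[i] - level) / (prof[i] - prof[i + 1])
    return float("nan")


def travel_distance(positions_by_time: dict[float, float]) -> dict[float, float]:
    """distance(t) = stall position(t) - stall position(0.5 min)."""
    if BASELINE_TIME not in positions_by_time or not np.isfinite(
        positions_by_time[BASELINE_TIME]
    ):
        raise ValueError("baseline (0.5 min) stall position undefined")
    base = positions_by_time[BASELINE_TIME]
    return {
        t: (pos - base if np.isfinite(pos) else float("nan"))
        for t, pos in positions_by_time.items()
    }


@dataclass
class CoverageProfile:
    entry_id: str
    time_min: float
    relative_coverage: np.ndarray
    stall_position: float


def profiles_from_table(coverage: pd.DataFrame) -> list[CoverageProfile]:
    """Build normalized profiles from a long-format coverage table.

    Expects columns entry_id/time_min/position/count, optionally
    replicate. Positions must be contiguous from 0.
    """
    has_rep = "replicate" in coverage.columns
    out = []
    for (entry_id, t), grp in coverage.groupby(["entry_id", "time_min"]):
        if has_rep:
            reps = [
                g.sort_values("position")["count"].to_numpy()
                for _, g in grp.groupby("replicate")
            ]
        else:
            reps = [grp.sort_values("position")["count"].to_numpy()]
        rel = normalize_coverage(reps)
        out.append(
            CoverageProfile(
                entry_id=entry_id,
                time_min=float(t),
                relative_coverage=rel,
                stall_position=stall_position(rel),
            )
        )
    return out


def travel_table(profiles: list[CoverageProfile]) -> pd.DataFrame:
    """Per-entry travel distances relative to the 0.5-min stall position."""
    rows = []
    by_entry: dict[str, dict[float, float]] = {}
    for p in profiles:
        by_entry.setdefault(p.entry_id, {})[p.time_min] = p.stall_position
    for entry_id, positions in by_entry.items():
        try:
            distances = travel_distance(positions)
        except ValueError:
            continue
        for t in sorted(positions):
            rows.append(
                {
                    "entry_id": entry_id,
                    "time_min": t,
                    "stall_position": positions[t],
                    "travel_distance": distances[t],
                }
            )
    return pd.DataFrame(rows)
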