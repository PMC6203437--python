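"""Per-animal behavioral and morphometric phenotype derivation.

Covers the novel-object-recognition discrimination index with its
exclusion rules, the rotarod per-animal summary, and the stereological
arithmetic that turns raw counts into cell numbers and volumes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: ceiling of a rotarod trial in seconds (test stopped at five minutes)
ROTAROD_MAX_S = 300.0


class BehaviorDataError(ValueError):
    """Raised for behavioral records that violate the data contract."""


def discrimination_index(new: float, old: float) -> float:
    """Novel-object discrimination index DI = (new - old) / (new + old).

    ``new`` and ``old`` are the exploration times (seconds) of the novel
    and the familiar object.  DI ranges from -1 (only the old object was
    explored) through 0 (no preference) to +1 (only the new object).  The
    index is scale-invariant, so seconds and proportions of trial time
    give the same value.

    Raises
    ------
    BehaviorDataError
        If both times are zero: the index is undefined and the animal must
        be handled by the exclusion rule, never silently scored 0.
    """
    if new < 0 or old < 0:
        raise BehaviorDataError("exploration times must be >= 0")
    total = new + old
    if total == 0:
        raise BehaviorDataError(
            "discrimination index undefined: no object exploration in trial 3"
        )
    return (new - old) / total


@dataclass(frozen=True)
class NorPartition:
    """Outcome of the novel-object-recognition exclusion rule."""

    included: tuple[str, ...]
    excluded: tuple[str, ...]
    #: animals with incomplete trial records — a data error, not an exclusion
    flagged: tuple[str, ...]

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def apply_nor_exclusions(
    records: pd.DataFrame, threshold: float = 0.0
) -> NorPartition:
    """Partition animals into included/excluded for the discrimination index.

    ``records`` has one row per (animal, trial) with columns
    ``animal_id, trial, time_object_A, time_object_B``; in trial 3 the two
    columns hold the new and the old object time.  An animal is excluded
    iff it did not explore object A in either of the first two trials, or
    did not explore any object in trial 3.  "Did not explore" means an
    exploration time of at most ``threshold`` seconds (default exactly 0).

    Animals with a missing trial record are flagged as data errors rather
    than auto-excluded, and appear in neither partition side.
    """
    required = {"animal_id", "trial", "time_object_A", "time_object_B"}
    if not required.issubset(records.columns):
        raise BehaviorDataError(f"records must have columns {sorted(required)}")
    if (records[["time_object_A", "time_object_B"]] < 0).any().any():
        raise BehaviorDataError("exploration times must be >= 0")

    included, excluded, flagged = [], [], []
    for animal, g in records.groupby("animal_id", sort=True):
        by_trial = g.set_index("trial")
        if not {1, 2, 3}.issubset(by_trial.index):
            flagged.append(str(animal))
            continue
        no_object_a = (
            by_trial.loc[1, "time_object_A"] <= threshold
            and by_trial.loc[2, "time_object_A"] <= threshold
        )
        trial3_total = (
            by_trial.loc[3, "time_object_A"] + by_trial.loc[3, "time_object_B"]
        )
        if no_object_a or trial3_total <= threshold:
            excluded.append(str(animal))
        else:
            included.append(str(animal))
    if excluded:
        logger.warning("NOR exclusion rule removed %d animals: %s", len(excluded), excluded)
    if flagged:
        logger.warning("NOR records incomplete for %d animals: %s", len(flagged), flagged)
    return NorPartition(tuple(included), tuple(excluded), tuple(flagged))


def summarize_rotarod(latencies) -> float:
    """Per-animal rotarod summary: the mean latency over non-missing trials.

    ``latencies`` are fall latencies in seconds, one per trial (typically
    9 = 3 days x 3 trials), each capped at the 300 s trial ceiling.
    Missing trials are ignored rather than imputed as a fall at t = 0; if
    every trial is missing the summary itself is missing (NaN).
    """
    arr = np.asarray(latencies, dtype=float)
    valid = arr[~np.isnan(arr)]
    if valid.size == 0:
        return float("nan")
    if np.any(valid < 0) or np.any(valid > ROTAROD_MAX_S):
        raise BehaviorDataError(
            f"rotarod latencies must lie in [0, {ROTAROD_MAX_S:g}] s"
        )
    return float(valid.mean())


def derive_cell_counts(total_brdu: float, fraction: float) -> float:
    """Number of new cells of one identity: total BrdU+ count x co-label fraction.

    The fraction comes from phenotyping a sample of BrdU-positive cells for
    a marker (e.g. NeuN for neurons, S100B for astrocytes); the product is
    reported unrounded.
    """
    if not 0.0 <= fraction <= 1.0:
        raise BehaviorDataError("co-labeling fraction must lie in [0, 1]")
    if total_brdu < 0:
        raise BehaviorDataError("total cell count must be >= 0")
    return total_brdu * fraction


@dataclass(frozen=True)
class VolumeEstimate:
    """Cavalieri volume estimate from stereological point counting."""

    point_count: int
    grid_spacing: float  # length units, e.g. 25 um
    section_interval: float  # distance between sampled sections, e.g. 240 um
    volume: float


def cavalieri_volume(
    point_count: int, grid_spacing: float = 25.0, section_interval: float = 240.0
) -> VolumeEstimate:
    """Cavalieri estimator: volume = points x grid-cell area x section interval.

    Each counted grid point represents an area of ``grid_spacing**2`` on a
    section, and each sampled section represents a slab of thickness
    ``section_interval`` along the cutting axis.  Units follow the inputs
    (microns give cubic microns).
    """
    if point_count < 0:
        raise BehaviorDataError("point_count must be >= 0")
    if grid_spacing <= 0 or section_interval <= 0:
        raise BehaviorDataError("grid spacing and section interval must be > 0")
    return VolumeEstimate(
        point_count=int(point_count),
        grid_spacing=grid_spacing,
        section_interval=section_interval,
        volume=point_count * grid_spacing**2 * section_interval,
    )


def discrimination_table(records: pd.DataFrame, threshold: float = 0.0) -> pd.DataFrame:
    """Discrimination index per included animal.

    Applies the exclusion rule, then computes DI from the trial-3 record
    (``time_object_A`` = new object, ``time_object_B`` = old object).
    Output columns: ``animal_id, di``; excluded and flagged animals are
    absent (not NaN-padded), mirroring how exclusions drop animals from
    the index calculation entirely.
    """
    part = apply_nor_exclusions(records, threshold=threshold)
    t3 = records[records["trial"] == 3].set_index(records[records["trial"] == 3]["animal_id"].astype(str))
    rows = [
        {
            "animal_id": a,
            "di": discrimination_index(
                float(t3.loc[a, "time_object_A"]), float(t3.loc[a, "time_object_B"])
            ),
        }
        for a in part.included
    ]
    return pd.DataFrame(rows, columns=["animal_id", "di"])
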