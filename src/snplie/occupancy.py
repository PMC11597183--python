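"""Interaction-occupancy profiling from per-frame contact event tables.

An interaction profiler run over a trajectory yields, per frame, the set of
residue-level contacts (hydrogen bonds, hydrophobic contacts, salt bridges,
...) between ligand and receptor.  The occupancy of a contact is the
fraction of frames in which it is present.  Replicas are pooled
frame-weighted by default; per-replica occupancies are retained so that an
alternative "any replica above threshold" filter can be applied where the
per-simulation reading is preferred.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

__all__ = [
    "INTERACTION_TYPES",
    "InteractionEvent",
    "OccupancyRecord",
    "ProfileDiff",
    "compute_occupancy",
    "filter_occupancy",
    "diff_interaction_profiles",
]

#: Recognised interaction categories.  Water bridges and halogen bonds are
#: accepted on input but are typically folded into a catch-all category in
#: rendered reports.
INTERACTION_TYPES = (
    "hydrogen_bond",
    "hydrophobic",
    "salt_bridge",
    "pi_stacking",
    "pi_cation",
    "halogen_bond",
    "water_bridge",
)


class InteractionEvent(NamedTuple):
    """Presence of one residue-level contact in one frame of one replica."""

    system_id: str
    replica: int
    frame: int
    residue_name: str
    residue_number: int
    interaction_type: str


@dataclass(frozen=True)
class OccupancyRecord:
    """Occupancy of one (residue, interaction type) contact.

    ``pooled_occupancy`` is the frame-weighted mean across replicas:
    total event frames divided by total frames.
    """

    residue_number: int
    residue_name: str
    interaction_type: str
    per_replica_occupancy: tuple
    pooled_occupancy: float

    @property
    def key(self) -> tuple[int, str]:
        return (self.residue_number, self.interaction_type)


class ProfileDiff(NamedTuple):
    gained: frozenset
    lost: frozenset
    shared: frozenset


def compute_occupancy(
    events: Sequence[InteractionEvent],
    frames_per_replica: Mapping[int, int],
) -> list[OccupancyRecord]:
    """Aggregate per-frame contact events into occupancy records.

    One record is produced per (residue_number, interaction_type) key,
    ordered by residue number then interaction type.  Per-replica
    occupancies follow the sorted replica order of ``frames_per_replica``.

    Raises
    ------
    ValueError
        For events referencing an unknown replica, an out-of-range frame,
        an unknown interaction type, or a duplicated
        (replica, frame, residue, type) event.
    """
    for rep, n in frames_per_replica.items():
        if n < 1:
            raise ValueError(f"replica {rep} has a non-positive frame count {n}")
    replicas = sorted(frames_per_replica)
    total_frames = sum(frames_per_replica.values())

    counts: dict[tuple[int, str], dict[int, int]] = defaultdict(
        lambda: {r: 0 for r in replicas}
    )
    names: dict[tuple[int, str], str] = {}
    seen: set[tuple[int, int, int, str]] = set()
    for ev in events:
        if ev.replica not in frames_per_replica:
            raise ValueError(f"event references unknown replica {ev.replica}")
        if not 0 <= ev.frame < frames_per_replica[ev.replica]:
            raise ValueError(
                f"event frame {ev.frame} out of range for replica {ev.replica} "
                f"({frames_per_replica[ev.replica]} frames)"
            )
        if ev.interaction_type not in INTERACTION_TYPES:
            raise ValueError(f"unknown interaction type {ev.interaction_type!r}")
        dedup = (ev.replica, ev.frame, ev.residue_number, ev.interaction_type)
        if dedup in seen:
            raise ValueError(
                f"duplicate event for residue {ev.residue_number} "
                f"{ev.interaction_type} at replica {ev.replica} frame {ev.frame}"
            )
        seen.add(dedup)
        key = (ev.residue_number, ev.interaction_type)
        counts[key][ev.replica] += 1
        names.setdefault(key, ev.residue_name)

    records = []
    for key in sorted(counts):
        per_replica = tuple(
            counts[key][r] / frames_per_replica[r] for r in replicas
        )
        pooled = sum(counts[key].values()) / total_frames
        records.append(
            OccupancyRecord(
                residue_number=key[0],
                residue_name=names[key],
                interaction_type=key[1],
                per_replica_occupancy=per_replica,
                pooled_occupancy=pooled,
            )
        )
    return records


def filter_occupancy(
    records: Sequence[OccupancyRecord],
    threshold: float = 0.25,
    mode: str = "pooled",
) -> list[OccupancyRecord]:
    """Keep contacts at or above the occupancy threshold (inclusive).

    ``mode="pooled"`` (default) compares the frame-weighted pooled
    occupancy; ``mode="any_replica"`` keeps a contact if any single
    replica reaches the threshold.  Output order is stable: residue
    number, then interaction type.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if mode == "pooled":
        kept = [r for r in records if r.pooled_occupancy >= threshold]
    elif mode == "any_replica":
        kept = [
            r for r in records if any(o >= threshold for o in r.per_replica_occupancy)
        ]
    else:
        raise ValueError(f"unknown filter mode {mode!r}")
    return sorted(kept, key=lambda r: r.key)


def diff_interaction_profiles(
    a: Sequence[OccupancyRecord], b: Sequence[OccupancyRecord]
) -> ProfileDiff:
    """Set difference of two filtered profiles of the same ligand.

    Relative to baseline ``a``: ``gained`` keys appear only in ``b``,
    ``lost`` only in ``a``, ``shared`` in both.
    """
    keys_a = frozenset(r.key for r in a)
    keys_b = frozenset(r.key for r in b)
    return ProfileDiff(
        gained=keys_b - keys_a, lost=keys_a - keys_b, shared=keys_a & keys_b
    )
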