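"""Canonical kinematic channel registry for the spike coordination analysis.

The analysis operates on 32 whole-body channels: the 3D centre-of-mass
coordinates, six lower-limb flexion-extension angles, eight upper-limb
angles (shoulder 3-DOF plus elbow, both sides) and fifteen trunk/neck/head
segment angles.  Every matrix in the pipeline is column-ordered by this
registry, and limb-subset analyses (lower / upper) slice it by group tag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

ChannelGroup = Literal["com", "lower", "upper", "trunk_head"]
ChannelKind = Literal["angle_deg", "position_m"]

#: number of channels in the canonical registry
N_CHANNELS = 32


@dataclass(frozen=True)
class Channel:
    """A single named kinematic channel."""

    name: str
    group: ChannelGroup
    kind: ChannelKind


@dataclass(frozen=True)
class ChannelRegistry:
    """Ordered collection of the 32 canonical channels.

    Invariants: exactly 32 uniquely-named entries with group counts
    com=3, lower=6, upper=8, trunk_head=15.
    """

    entries: tuple[Channel, ...]

    def __post_init__(self) -> None:
        names = [c.name for c in self.entries]
        if len(self.entries) != N_CHANNELS:
            raise ValueError(f"registry must have {N_CHANNELS} channels, got {len(self.entries)}")
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        counts = {"com": 3, "lower": 6, "upper": 8, "trunk_head": 15}
        for group, expected in counts.items():
            got = sum(1 for c in self.entries if c.group == group)
            if got != expected:
                raise ValueError(f"group {group!r}: expected {expected} channels, got {got}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [c.name for c in self.entries]

    def indices(self, group: str) -> list[int]:
        """Column indices of a channel group; ``whole`` returns all 32."""
        if group == "whole":
            return list(range(len(self.entries)))
        valid = {"com", "lower", "upper", "trunk_head"}
        if group not in valid:
            raise ValueError(f"unknown channel group {group!r}; expected one of {sorted(valid) + ['whole']}")
        return [i for i, c in enumerate(self.entries) if c.group == group]


def build_channel_registry() -> ChannelRegistry:
    """Return the canonical 32-channel registry.

    Order: CoM x/y/z; left then right hip/knee/ankle flexion; left then
    right shoulder (ab/adduction, horizontal ab/adduction, int/ext
    rotation) and elbow flexion; pelvis, spine, thorax, neck, head 3-DOF
    each.
    """
    entries: list[Channel] = []
    for axis in "XYZ":
        entries.append(Channel(f"CoM{axis}", "com", "position_m"))
    for side in "LR":
        for joint in ("hip", "knee", "ankle"):
            entries.append(Channel(f"{side}{joint}X", "lower", "angle_deg"))
    for side in "LR":
        for axis in "XYZ":
            entries.append(Channel(f"{side}shoulder{axis}", "upper", "angle_deg"))
        entries.append(Channel(f"{side}elbowX", "upper", "angle_deg"))
    for segment in ("Pelvis", "Spine", "Thorax", "Neck", "Head"):
        for axis in "XYZ":
            entries.append(Channel(f"{segment}{axis}", "trunk_head", "angle_deg"))
    return ChannelRegistry(tuple(entries))
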