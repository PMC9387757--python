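"""Anatomical labeling of contacts from an integer segmentation volume.

Each contact samples the segmentation in a small world-mm ball around its
position; the fraction of sampled voxels per label gives a soft assignment,
and the highest-fraction label is the contact's dominant anatomical region.
For an sEEG shaft, ordering contacts by their number (1 = deepest, at the
electrode tip) yields the deep-to-superficial sequence of regions the shaft
passes through.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import FormatError, KindError, NameError_, StateError
from .imagespace import Volume3D, world_to_voxel
from .localization import Montage

__all__ = [
    "LabelTable",
    "ContactLabels",
    "read_lut",
    "labels_at_positions",
    "shaft_label_sequence",
]

logger = logging.getLogger(__name__)


@dataclass
class LabelTable:
    """FreeSurfer-style color lookup table: id -> (name, RGBA)."""

    entries: dict = field(default_factory=dict)

    def __post_init__(self):
        if 0 not in self.entries:
            self.entries[0] = ("Unknown", (0, 0, 0, 0))

    def name(self, label_id: int) -> str:
        return self.entries.get(int(label_id), self.entries[0])[0]

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ContactLabels:
    """Per-contact soft label assignment.

    ``fractions`` maps each contact name to a list of (label name, fraction)
    sorted by descending fraction (ties broken by ascending label id); the
    fractions sum to 1.
    """

    fractions: dict = field(default_factory=dict)

    def dominant(self, name: str) -> str:
        return self.fractions[name][0][0]


def read_lut(path) -> LabelTable:
    """Parse a whitespace-delimited LUT: ``id name R G B A``, ``#`` comments."""
    entries: dict[int, tuple[str, tuple]] = {}
    first_line: dict[int, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 6:
                raise FormatError(f"{path}:{lineno}: expected 'id name R G B A', got {line!r}")
            lid = int(parts[0])
            if lid in entries:
                raise FormatError(
                    f"{path}:{lineno}: duplicate label id {lid} "
                    f"(first defined on line {first_line[lid]})"
                )
            entries[lid] = (parts[1], tuple(int(v) for v in parts[2:6]))
            first_line[lid] = lineno
    return LabelTable(entries)


def labels_at_positions(
    seg: Volume3D, lut: LabelTable, positions, radius: float = 2.0, names=None
) -> ContactLabels:
    """Sample segmentation labels in a ball of ``radius`` mm at each position.

    ``radius=0`` takes the single nearest voxel. Positions outside the grid
    are labeled Unknown with fraction 1. Fractions are voxel counts over
    the total sampled; ties in the sort are broken by lower label id.
    """
    if seg.kind != "label":
        raise KindError("labels_at_positions requires a label-kind volume")
    if radius < 0:
        raise ValueError("radius must be >= 0")
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    if names is None:
        names = [f"P{i}" for i in range(len(positions))]
    shape = np.array(seg.shape)
    out = {}
    for name, pos in zip(names, positions):
        vox = world_to_voxel(seg, pos)
        counts: dict[int, int] = {}
        if np.any(vox < -0.5) or np.any(vox > shape - 0.5):
            counts[0] = 1
        elif radius == 0:
            nearest = np.clip(np.round(vox).astype(int), 0, shape - 1)
            counts[int(seg.data[tuple(nearest)])] = 1
        else:
            idx, _ = _ball(seg, pos, radius)
            if len(idx) == 0:
                nearest = np.clip(np.round(vox).astype(int), 0, shape - 1)
                counts[int(seg.data[tuple(nearest)])] = 1
            else:
                vals = seg.data[idx[:, 0], idx[:, 1], idx[:, 2]]
                ids, cnt = np.unique(vals, return_counts=True)
                counts = {int(i): int(c) for i, c in zip(ids, cnt)}
        total = sum(counts.values())
        pairs = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        out[name] = [(lut.name(i), c / total) for i, c in pairs]
    return ContactLabels(out)


def _ball(seg: Volume3D, center_mm: np.ndarray, radius: float):
    from .localization import _ball_voxels

    return _ball_voxels(seg, center_mm, radius)


_SHAFT_RE = re.compile(r"^(?P<prefix>.*?)(?P<num>\d+)$")


def shaft_label_sequence(
    seg: Volume3D, lut: LabelTable, m: Montage, shaft: str, radius: float = 2.0
) -> list[tuple[str, str]]:
    """Ordered deep→superficial (ascending contact number) dominant labels.

    ``shaft`` is the channel-name prefix; contacts must be named
    ``<prefix><positive integer>`` and all located. Contact 1 is the
    deepest (the electrode tip). Gaps in numbering are allowed with a
    logged notice.
    """
    members = []
    for c in m.contacts:
        if not c.name.startswith(shaft):
            continue
        suffix = c.name[len(shaft):]
        if not suffix:
            continue
        if not suffix.isdigit():
            raise NameError_(f"contact {c.name!r} in shaft {shaft!r} has a non-numeric suffix")
        if c.status != "located":
            raise StateError(f"contact {c.name!r} is not located")
        members.append((int(suffix), c))
    if not members:
        raise NameError_(f"no contacts match shaft prefix {shaft!r}")
    members.sort(key=lambda t: t[0])
    nums = [n for n, _ in members]
    if nums != list(range(nums[0], nums[0] + len(nums))):
        logger.info("shaft %s has gaps in contact numbering: %s", shaft, nums)
    positions = np.array([c.position for _, c in members])
    labels = labels_at_positions(
        seg, lut, positions, radius=radius, names=[c.name for _, c in members]
    )
    return [(c.name, labels.dominant(c.name)) for _, c in members]
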