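"""Electrode montage handling: the 64-channel 10-10 layout, its spatial
grouping into wedges, anatomical region masks, and channel-reduction layouts.

Coordinates are a 2-D azimuthal projection of the scalp onto the unit disc
with the vertex (Cz) at the origin; only relative positions matter — they
drive the angular grouping, the farthest-point reduction layouts, and the
volume-conduction surrogate in the synthetic generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "Montage",
    "GroupScheme",
    "RegionMask",
    "ReductionLayout",
    "REGION_NAMES",
    "REDUCTION_SIZES",
    "load_montage",
    "assign_groups",
    "region_mask",
    "remove_region",
    "reduce_channels",
    "normalize_label",
]

REGION_NAMES = ("frontal", "central", "parietal", "occipital", "temporal")

#: Channel counts of the shipped uniform-reduction layouts.
REDUCTION_SIZES = (56, 48, 40, 32, 24, 16)

# Label prefixes defining the five overlapping scalp regions. Compound
# prefixes (FC, CP, PO, FT, TP) sit on a boundary and belong to both
# neighbouring regions; Iz (inion) is grouped with the occipital channels.
_REGION_PREFIXES = {
    "frontal": ("fp", "af", "f", "fc", "ft"),
    "central": ("c", "fc", "cp"),
    "parietal": ("p", "cp", "po", "tp"),
    "occipital": ("o", "po", "i"),
    "temporal": ("t", "ft", "tp"),
}

# Longest prefixes first so "fc5" matches "fc" before "f".
_PREFIX_ORDER = sorted(
    {p for ps in _REGION_PREFIXES.values() for p in ps}, key=len, reverse=True
)


def normalize_label(label: str) -> str:
    """Canonical channel-label key: lowercase, stripped of dots/whitespace.

    PhysioNet EDF headers pad labels with trailing dots ("Fc5." etc.);
    this makes "Fc5.", "FC5" and "fc5" compare equal.
    """
    return label.strip().replace(".", "").lower()


@dataclass(frozen=True)
class Montage:
    """An ordered electrode layout with 2-D scalp-disc coordinates."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n, 2) float

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if pos.shape != (len(self.labels), 2):
            raise ValueError(
                f"positions shape {pos.shape} does not match "
                f"{len(self.labels)} labels"
            )
        if not np.all(np.isfinite(pos)):
            raise ValueError("montage positions must be finite")
        keys = [normalize_label(l) for l in self.labels]
        if len(set(keys)) != len(keys):
            dupes = sorted({k for k in keys if keys.count(k) > 1})
            raise ValueError(f"duplicate channel labels: {dupes}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        key = normalize_label(label)
        for i, lab in enumerate(self.labels):
            if normalize_label(lab) == key:
                return i
        raise KeyError(f"channel {label!r} not in montage")

    def subset(self, indices: "np.ndarray | list[int]") -> "Montage":
        idx = np.asarray(indices, dtype=int)
        return Montage(
            labels=tuple(self.labels[i] for i in idx),
            positions=self.positions[idx],
        )


@dataclass(frozen=True)
class GroupScheme:
    """Partition of montage channels into g spatial groups."""

    group_of: tuple[int, ...]  # channel index -> group id
    g: int

    def __post_init__(self) -> None:
        gids = set(self.group_of)
        if gids and (min(gids) < 0 or max(gids) >= self.g):
            raise ValueError("group ids out of range")

    @property
    def n_channels(self) -> int:
        return len(self.group_of)

    def members(self, gid: int) -> list[int]:
        return [i for i, g in enumerate(self.group_of) if g == gid]

    def sizes(self) -> list[int]:
        return [len(self.members(g)) for g in range(self.g)]


@dataclass(frozen=True)
class RegionMask:
    """A named, possibly overlapping set of channels (anatomical region)."""

    region_name: str
    channels: frozenset[int]


@dataclass(frozen=True)
class ReductionLayout:
    """An ordered subset of montage channels retained after ablation."""

    kept: tuple[int, ...]
    k: int = field(default=-1)

    def __post_init__(self) -> None:
        if self.k == -1:
            object.__setattr__(self, "k", len(self.kept))
        if len(self.kept) != self.k:
            raise ValueError(f"layout declares k={self.k} but keeps {len(self.kept)}")
        if len(set(self.kept)) != len(self.kept):
            raise ValueError("duplicate channels in layout")


def _builtin_path(name: str) -> Path:
    return Path(str(resources.files("vnfc.data").joinpath(name)))


def load_montage(path_or_builtin: "str | Path" = "physionet64") -> Montage:
    """Load a montage from a builtin name or a delimited text file.

    The file format is tab- or comma-separated with a header line and
    columns ``label, x, y``. The builtin ``"physionet64"`` is the
    64-electrode 10-10 layout used by the PhysioNet motor imagery records.
    """
    if str(path_or_builtin) == "physionet64":
        path = _builtin_path("physionet64.tsv")
    else:
        path = Path(path_or_builtin)
    if not path.exists():
        raise FileNotFoundError(f"montage file not found: {path}")
    labels: list[str] = []
    xs: list[list[float]] = []
    with open(path) as f:
        header = f.readline()
        sep = "\t" if "\t" in header else ","
        for line in f:
            line = line.strip()
            if not line:
                continue
            parts = line.split(sep)
            if len(parts) < 3:
                raise ValueError(f"malformed montage line: {line!r}")
            labels.append(parts[0])
            xs.append([float(parts[1]), float(parts[2])])
    montage = Montage(labels=tuple(labels), positions=np.asarray(xs))
    if str(path_or_builtin) == "physionet64" and montage.n_channels != 64:
        raise ValueError("builtin physionet64 montage must have 64 channels")
    return montage


def _azimuth(positions: np.ndarray) -> np.ndarray:
    """Angle of each channel around the vertex; exactly-central channels
    (radius ~ 0, i.e. Cz) get angle 0 by convention."""
    x, y = positions[:, 0], positions[:, 1]
    ang = np.arctan2(y, x)
    ang[np.hypot(x, y) < 1e-9] = 0.0
    return ang


def assign_groups(montage: Montage, g: int = 8, strategy: str = "angular") -> GroupScheme:
    """Partition channels into ``g`` balanced angular wedges around the vertex.

    Channels are sorted by azimuth (ties broken by label) and split into g
    consecutive runs whose sizes differ by at most one; for the default
    64-channel montage and g=8 every group has exactly 8 channels. The
    result is deterministic for a fixed montage and strategy.
    """
    n = montage.n_channels
    if g < 1:
        raise ValueError("g must be >= 1")
    if g > n:
        raise ValueError(f"g={g} exceeds channel count {n}")
    if strategy != "angular":
        raise ValueError(f"unknown grouping strategy {strategy!r}")

    ang = _azimuth(montage.positions)
    order = sorted(range(n), key=lambda i: (ang[i], normalize_label(montage.labels[i])))
    # balanced chunk sizes: first (n % g) groups get one extra channel
    base, extra = divmod(n, g)
    group_of = [0] * n
    pos = 0
    for gid in range(g):
        size = base + (1 if gid < extra else 0)
        for i in order[pos : pos + size]:
            group_of[i] = gid
        pos += size
    return GroupScheme(group_of=tuple(group_of), g=g)


def region_mask(montage: Montage, region: str) -> RegionMask:
    """Channel set of one of the five overlapping 10-10 scalp regions.

    Membership is by label prefix; boundary prefixes (FC, CP, PO, FT, TP)
    belong to both adjacent regions, so masks overlap as the montage's
    region scheme intends.
    """
    if region not in REGION_NAMES:
        raise ValueError(f"unknown region {region!r}; expected one of {REGION_NAMES}")
    wanted = _REGION_PREFIXES[region]
    chans = set()
    for i, lab in enumerate(montage.labels):
        key = normalize_label(lab)
        for prefix in _PREFIX_ORDER:
            if key.startswith(prefix) and key[len(prefix) :].lstrip("z1234567890") == "":
                if prefix in wanted:
                    chans.add(i)
                break
    return RegionMask(region_name=region, channels=frozenset(chans))


def remove_region(montage: Montage, region: str) -> ReductionLayout:
    """Layout retaining every channel outside the named region."""
    mask = region_mask(montage, region)
    kept = tuple(i for i in range(montage.n_channels) if i not in mask.channels)
    return ReductionLayout(kept=kept)


def _farthest_point_order(positions: np.ndarray) -> list[int]:
    """Greedy farthest-point ordering, seeded at the channel nearest the
    vertex. Prefixes of this ordering are nested spatially-uniform subsets."""
    n = len(positions)
    radii = np.hypot(positions[:, 0], positions[:, 1])
    start = int(np.argmin(radii))
    chosen = [start]
    dist = np.linalg.norm(positions - positions[start], axis=1)
    for _ in range(n - 1):
        dist[chosen] = -1.0
        nxt = int(np.argmax(dist))  # ties: lowest index
        chosen.append(nxt)
        dist = np.minimum(dist, np.linalg.norm(positions - positions[nxt], axis=1))
    return chosen


def load_group_scheme(path: "str | Path", montage: Montage) -> GroupScheme:
    """User-supplied grouping file: JSON map of channel label -> group id."""
    with open(path) as f:
        table = json.load(f)
    table = {normalize_label(k): int(v) for k, v in table.items()}
    group_of = []
    for lab in montage.labels:
        key = normalize_label(lab)
        if key not in table:
            raise ValueError(f"grouping file does not cover channel {lab!r}")
        group_of.append(table[key])
    return GroupScheme(group_of=tuple(group_of), g=max(group_of) + 1)


def reduce_channels(montage: Montage, k: int) -> ReductionLayout:
    """Spatially uniform thinning of the montage to ``k`` channels.

    The kept set is the first k channels of a deterministic greedy
    farthest-point ordering, so the shipped layouts for 16/24/32/40/48/56
    are nested by construction. For the default montage the layouts are
    frozen in ``data/reduction_layouts.json``; other montages (or other k)
    are computed on the fly with the same rule.
    """
    n = montage.n_channels
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    if k == n:
        return ReductionLayout(kept=tuple(range(n)), k=k)

    if n == 64 and k in REDUCTION_SIZES:
        path = _builtin_path("reduction_layouts.json")
        if path.exists():
            with open(path) as f:
                table = json.load(f)
            keep_labels = table[str(k)]
            try:
                kept = tuple(montage.index_of(lab) for lab in keep_labels)
                return ReductionLayout(kept=tuple(sorted(kept)), k=k)
            except KeyError:
                pass  # custom 64-ch montage with different labels

    order = _farthest_point_order(montage.positions)
    return ReductionLayout(kept=tuple(sorted(order[:k])), k=k)
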