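"""Geometry and topology of the Humphrey 24-2 test pattern.

The 24-2 pattern places 54 stimuli on a 6 degree lattice offset 3 degrees
from both meridians, covering the central 24 degrees of field plus two
extra nasal locations at 27 degrees.  Two locations fall on the physiologic
blind spot (15 degrees temporal, +/-3 degrees vertical) and are excluded
from all deviation analyses, leaving the 52 analysed test locations.

Conventions used throughout the package:

* Coordinates are degrees of visual angle, ``x`` temporal-positive,
  ``y`` superior-positive.  A left-eye (OS) grid is the x-mirror of the
  right-eye (OD) grid; because locations are enumerated temporal-to-nasal
  the *index* of a location is laterality-invariant, so masks, sectors and
  hemifield-zone tables defined on indices apply to either eye unchanged.
* Indices are 1-based, row-major, superior-to-inferior and
  temporal-to-nasal; the blind spot occupies indices 20 and 29.
* Sectors follow a Garway-Heath-style structure-function grouping:
  superior temporal (ST), superior nasal (SN), inferior temporal (IT),
  inferior nasal (IN), temporal (T), nasal (N) and central.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set

import pandas as pd

__all__ = [
    "GridLocation",
    "Grid24_2",
    "build_grid",
    "neighbors",
    "find_clusters",
    "sector_of",
    "mirror_grid",
    "grid_from_table",
    "write_grid_table",
    "feature_name_to_index",
    "SECTORS",
]

# Row layout for a right eye: (y, x values temporal -> nasal).
# Rows at |y| = 3 carry the extra nasal-step location at -27 degrees.
_OD_ROWS: Sequence[tuple[int, Sequence[int]]] = (
    (21, (9, 3, -3, -9)),
    (15, (15, 9, 3, -3, -9, -15)),
    (9, (21, 15, 9, 3, -3, -9, -15, -21)),
    (3, (21, 15, 9, 3, -3, -9, -15, -21, -27)),
    (-3, (21, 15, 9, 3, -3, -9, -15, -21, -27)),
    (-9, (21, 15, 9, 3, -3, -9, -15, -21)),
    (-15, (15, 9, 3, -3, -9, -15)),
    (-21, (9, 3, -3, -9)),
)

_BLIND_SPOT_XY = {(15, 3), (15, -3)}

# Locations flanking the blind spot vertically; excluded from "non-edge"
# cluster rules in addition to the rim (configurable via Grid24_2.edge).
_BLIND_SPOT_FLANKS = (12, 38)

SECTORS = ("ST", "SN", "IT", "IN", "T", "N", "central")


def _sector_for(x: int, y: int) -> str:
    """Garway-Heath-style sector from temporal-positive field coordinates."""
    if abs(y) == 3:
        if x >= 15:
            return "T"
        if abs(x) <= 9:
            return "central"
        if x <= -21:
            return "N"
        # x == -15: part of the arcuate/nasal bundle of its hemifield
        return "SN" if y > 0 else "IN"
    if y > 0:
        return "ST" if x > 0 else "SN"
    return "IT" if x > 0 else "IN"


@dataclass(frozen=True)
class GridLocation:
    """One stimulus location of the 24-2 pattern."""

    index: int
    x: int
    y: int
    is_blind_spot: bool
    is_edge: bool
    hemifield: str  # "superior" | "inferior"
    sector: str


@dataclass
class Grid24_2:
    """The 24-2 pattern of one eye: locations plus 8- or 4-connectivity."""

    locations: List[GridLocation]
    adjacency: Dict[int, FrozenSet[int]]
    laterality: str
    connectivity: int = 8

    def __post_init__(self) -> None:
        self._by_index = {loc.index: loc for loc in self.locations}

    def location(self, index: int) -> GridLocation:
        try:
            return self._by_index[index]
        except KeyError:
            raise KeyError(f"no 24-2 location with index {index}") from None

    @property
    def test_indices(self) -> List[int]:
        """The 52 non-blind-spot indices, ascending."""
        return [l.index for l in self.locations if not l.is_blind_spot]

    @property
    def blind_spot_indices(self) -> List[int]:
        return [l.index for l in self.locations if l.is_blind_spot]

    @property
    def edge_indices(self) -> Set[int]:
        return {l.index for l in self.locations if l.is_edge and not l.is_blind_spot}


def _build_locations(laterality: str, edge_override: Iterable[int] | None = None) -> List[GridLocation]:
    sign = 1 if laterality == "OD" else -1
    coords: List[tuple[int, int]] = []
    for y, xs in _OD_ROWS:
        for x in xs:
            coords.append((x, y))
    coord_set = set(coords)

    def is_edge_xy(x: int, y: int) -> bool:
        # rim = any missing 4-neighbour on the 6-degree lattice
        return not all(
            (x + dx, y + dy) in coord_set
            for dx, dy in ((6, 0), (-6, 0), (0, 6), (0, -6))
        )

    edge_override = set(edge_override) if edge_override is not None else None
    locations = []
    for i, (x, y) in enumerate(coords, start=1):
        blind = (x, y) in _BLIND_SPOT_XY
        if edge_override is not None:
            edge = i in edge_override
        else:
            edge = blind or is_edge_xy(x, y) or i in _BLIND_SPOT_FLANKS
        locations.append(
            GridLocation(
                index=i,
                x=sign * x,
                y=y,
                is_blind_spot=blind,
                is_edge=edge,
                hemifield="superior" if y > 0 else "inferior",
                sector=_sector_for(x, y),
            )
        )
    return locations


def _build_adjacency(locations: Sequence[GridLocation], connectivity: int) -> Dict[int, FrozenSet[int]]:
    test = [l for l in locations if not l.is_blind_spot]
    adj: Dict[int, Set[int]] = {l.index: set() for l in test}
    for a in test:
        for b in test:
            if a.index >= b.index:
                continue
            dx, dy = abs(a.x - b.x), abs(a.y - b.y)
            if connectivity == 8:
                touching = dx <= 6 and dy <= 6 and (dx or dy)
            else:
                touching = (dx == 6 and dy == 0) or (dx == 0 and dy == 6)
            if touching:
                adj[a.index].add(b.index)
                adj[b.index].add(a.index)
    return {k: frozenset(v) for k, v in adj.items()}


def build_grid(laterality: str = "OD", connectivity: int = 8,
               edge_indices: Iterable[int] | None = None) -> Grid24_2:
    """Build the 24-2 grid of one eye.

    Parameters
    ----------
    laterality : {"OD", "OS"}
        Right or left eye; OS is the x-mirror of OD.
    connectivity : {8, 4}
        Contiguity scheme used by :func:`neighbors` / :func:`find_clusters`.
        8-connectivity (diagonals count) is the common reading of
        "contiguous points" in HFA cluster criteria.
    edge_indices
        Optional explicit replacement for the default edge set (pattern rim
        plus the two locations vertically flanking the blind spot).
    """
    if laterality not in ("OD", "OS"):
        raise ValueError(f"laterality must be 'OD' or 'OS', got {laterality!r}")
    if connectivity not in (8, 4):
        raise ValueError(f"connectivity must be 8 or 4, got {connectivity!r}")
    locations = _build_locations(laterality, edge_indices)
    return Grid24_2(
        locations=locations,
        adjacency=_build_adjacency(locations, connectivity),
        laterality=laterality,
        connectivity=connectivity,
    )


def mirror_grid(grid: Grid24_2) -> Grid24_2:
    """The fellow-eye grid (x negated, indices and topology unchanged)."""
    return build_grid(
        "OS" if grid.laterality == "OD" else "OD",
        connectivity=grid.connectivity,
    )


def neighbors(grid: Grid24_2, index: int) -> FrozenSet[int]:
    """Non-blind-spot locations within one lattice step of ``index``."""
    loc = grid.location(index)
    if loc.is_blind_spot:
        raise ValueError(f"index {index} is a blind-spot location")
    return grid.adjacency[index]


def find_clusters(
    flags: Mapping[int, bool],
    grid: Grid24_2,
    non_edge_only: bool = False,
    same_hemifield: bool = False,
) -> List[FrozenSet[int]]:
    """Maximal connected components of flagged locations.

    ``flags`` maps non-blind-spot indices to booleans.  With
    ``non_edge_only`` edge locations are dropped before the component
    search; with ``same_hemifield`` adjacency across the horizontal
    meridian is severed.  Components are returned sorted by size
    descending, ties by smallest member index.
    """
    active = set()
    for idx, on in flags.items():
        if not on:
            continue
        loc = grid.location(idx)
        if loc.is_blind_spot:
            raise ValueError(f"flag on blind-spot index {idx}")
        if non_edge_only and loc.is_edge:
            continue
        active.add(idx)

    seen: Set[int] = set()
    comps: List[FrozenSet[int]] = []
    for start in sorted(active):
        if start in seen:
            continue
        comp = {start}
        frontier = [start]
        seen.add(start)
        while frontier:
            cur = frontier.pop()
            cur_hemi = grid.location(cur).hemifield
            for nb in grid.adjacency[cur]:
                if nb not in active or nb in seen:
                    continue
                if same_hemifield and grid.location(nb).hemifield != cur_hemi:
                    continue
                seen.add(nb)
                comp.add(nb)
                frontier.append(nb)
        comps.append(frozenset(comp))
    comps.sort(key=lambda c: (-len(c), min(c)))
    return comps


def sector_of(grid: Grid24_2, index: int) -> str:
    """Sector label of a non-blind-spot location."""
    loc = grid.location(index)
    if loc.is_blind_spot:
        raise ValueError(f"index {index} is a blind-spot location")
    return loc.sector


def feature_name_to_index(name: str) -> int:
    """Map a deviation feature name like ``'td11'`` or ``'pd34'`` to a grid index.

    The numbering frame is the raw 54-point grid (blind spots at 20 and 29
    have no feature and are rejected).  This is a best-effort reconstruction
    of the naming used in permutation-importance reports; names outside
    1..54 cannot be placed on the 24-2 pattern and are rejected.
    """
    prefix, digits = name[:2].lower(), name[2:]
    if prefix not in ("td", "pd", "s_") and not (name[0].lower() == "s" and name[1:].isdigit()):
        if prefix not in ("td", "pd"):
            raise ValueError(f"unrecognised feature name {name!r}")
    if not digits.isdigit():
        raise ValueError(f"unrecognised feature name {name!r}")
    idx = int(digits)
    if not 1 <= idx <= 54:
        raise ValueError(f"feature {name!r} does not map onto the 54-point 24-2 frame")
    if idx in (20, 29):
        raise ValueError(f"feature {name!r} addresses a blind-spot location")
    return idx


def write_grid_table(grid: Grid24_2, path) -> None:
    """Serialize the grid as the documented plain-text table."""
    df = pd.DataFrame(
        {
            "index": [l.index for l in grid.locations],
            "x": [l.x for l in grid.locations],
            "y": [l.y for l in grid.locations],
            "is_blind_spot": [int(l.is_blind_spot) for l in grid.locations],
            "is_edge": [int(l.is_edge) for l in grid.locations],
            "hemifield": [l.hemifield for l in grid.locations],
            "sector": [l.sector for l in grid.locations],
        }
    )
    df.to_csv(path, index=False)


def grid_from_table(path, laterality: str = "OD", connectivity: int = 8) -> Grid24_2:
    """Load a (possibly user-modified) grid/sector table written by
    :func:`write_grid_table`."""
    df = pd.read_csv(path)
    locations = [
        GridLocation(
            index=int(r["index"]),
            x=int(r["x"]),
            y=int(r["y"]),
            is_blind_spot=bool(r["is_blind_spot"]),
            is_edge=bool(r["is_edge"]),
            hemifield=str(r["hemifield"]),
            sector=str(r["sector"]),
        )
        for _, r in df.iterrows()
    ]
    return Grid24_2(
        locations=locations,
        adjacency=_build_adjacency(locations, connectivity),
        laterality=laterality,
        connectivity=connectivity,
    )


def packaged_grid_table() -> pd.DataFrame:
    """The grid/sector table shipped with the package."""
    with resources.files("vfstack.data").joinpath("grid24_2.csv").open() as fh:
        return pd.read_csv(fh)
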