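"""Compact self-avoiding walks (Hamiltonian paths) on a W x H grid.

A compact lattice-protein structure is a directed Hamiltonian path of the grid
graph, serialized as a move string over {U, D, L, R} (R = +x, L = -x, U = +y,
D = -y).  Structures are reduced under the lattice point group; by default a
walk and its N-to-C reversal count as *different* structures (reversal-distinct
convention), mirroring the directionality retained in RNA structures.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Callable, Iterator, Sequence

import numpy as np

MOVE_STEPS = {"U": (0, 1), "D": (0, -1), "L": (-1, 0), "R": (1, 0)}
#: Explicit letter order used for all lexicographic comparisons: U < D < L < R.
MOVE_ORDER = {"U": 0, "D": 1, "L": 2, "R": 3}
_FLIP = str.maketrans("UDLR", "DURL")


def _move_key(moves: str) -> tuple[int, ...]:
    return tuple(MOVE_ORDER[m] for m in moves)


def coords_from_moves(moves: str) -> tuple[tuple[int, int], ...]:
    """Walk coordinates starting from the move string, translated so min x = min y = 0."""
    x = y = 0
    pts = [(0, 0)]
    for m in moves:
        try:
            dx, dy = MOVE_STEPS[m]
        except KeyError:
            raise ValueError(f"invalid move letter {m!r}") from None
        x, y = x + dx, y + dy
        pts.append((x, y))
    minx = min(p[0] for p in pts)
    miny = min(p[1] for p in pts)
    return tuple((px - minx, py - miny) for px, py in pts)


def moves_from_coords(coords: Sequence[tuple[int, int]]) -> str:
    steps = {v: k for k, v in MOVE_STEPS.items()}
    out = []
    for (x0, y0), (x1, y1) in zip(coords, coords[1:]):
        try:
            out.append(steps[(x1 - x0, y1 - y0)])
        except KeyError:
            raise ValueError("consecutive coordinates are not unit steps") from None
    return "".join(out)


def reverse_moves(moves: str) -> str:
    """Move string of the same walk traversed C-to-N."""
    return moves[::-1].translate(_FLIP)


@dataclass(frozen=True)
class LatticeConformation:
    """A compact self-avoiding walk on a W x H grid."""

    moves: str
    coords: tuple[tuple[int, int], ...]
    canonical_id: int | None = None
    orbit_size: int | None = None

    @classmethod
    def from_moves(cls, moves: str, canonical_id: int | None = None,
                   orbit_size: int | None = None) -> "LatticeConformation":
        coords = coords_from_moves(moves)
        if len(set(coords)) != len(coords):
            raise ValueError("walk is not self-avoiding")
        w = max(p[0] for p in coords) + 1
        h = max(p[1] for p in coords) + 1
        if w * h != len(coords):
            raise ValueError(f"walk does not tile its {w}x{h} bounding box (not compact)")
        return cls(moves, coords, canonical_id, orbit_size)

    @property
    def length(self) -> int:
        return len(self.coords)

    @property
    def width(self) -> int:
        return max(p[0] for p in self.coords) + 1

    @property
    def height(self) -> int:
        return max(p[1] for p in self.coords) + 1

    def reversed(self) -> "LatticeConformation":
        return LatticeConformation.from_moves(reverse_moves(self.moves))


@dataclass(frozen=True)
class ContactSet:
    """Lattice-adjacent, chain-nonadjacent residue pairs of a conformation."""

    pairs: frozenset[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.pairs))


def enumerate_directed_paths(width: int, height: int) -> list[str]:
    """Every directed Hamiltonian path of the W x H grid graph, as move strings.

    Deterministic: the result is sorted lexicographically under U < D < L < R.
    """
    if width < 1 or height < 1 or width * height < 2:
        raise ValueError("degenerate grid: need width*height >= 2")
    total = width * height
    visited = [[False] * height for _ in range(width)]
    path: list[str] = []
    results: list[str] = []

    def dfs(x: int, y: int, depth: int) -> None:
        if depth == total:
            results.append("".join(path))
            return
        for m in "UDLR":
            dx, dy = MOVE_STEPS[m]
            nx, ny = x + dx, y + dy
            if 0 <= nx < width and 0 <= ny < height and not visited[nx][ny]:
                visited[nx][ny] = True
                path.append(m)
                dfs(nx, ny, depth + 1)
                path.pop()
                visited[nx][ny] = False

    for sx, sy in itertools.product(range(width), range(height)):
        visited[sx][sy] = True
        dfs(sx, sy, 1)
        visited[sx][sy] = False
    results.sort(key=_move_key)
    return results


def _symmetry_ops(width: int, height: int) -> list[Callable[[int, int], tuple[int, int]]]:
    """Point-group maps of the W x H rectangle onto itself.

    8 elements for square grids; the 4 axis-preserving elements otherwise
    (90-degree rotations do not preserve a non-square rectangle).
    """
    w1, h1 = width - 1, height - 1
    ops = [
        lambda x, y: (x, y),
        lambda x, y: (w1 - x, y),
        lambda x, y: (x, h1 - y),
        lambda x, y: (w1 - x, h1 - y),
    ]
    if width == height:
        ops += [
            lambda x, y: (y, x),
            lambda x, y: (w1 - y, x),
            lambda x, y: (y, h1 - x),
            lambda x, y: (w1 - y, h1 - x),
        ]
    return ops


def symmetry_images(moves: str, distinguish_reversal: bool = True) -> set[str]:
    """Move strings of all point-group images of the walk (plus reversal images
    when reversal-distinct mode is off)."""
    coords = coords_from_moves(moves)
    w = max(p[0] for p in coords) + 1
    h = max(p[1] for p in coords) + 1
    walks = [coords] if distinguish_reversal else [coords, coords[::-1]]
    images: set[str] = set()
    for walk in walks:
        for op in _symmetry_ops(w, h):
            images.add(moves_from_coords([op(x, y) for x, y in walk]))
    return images


def canonicalize(conf: LatticeConformation | str,
                 distinguish_reversal: bool = True) -> tuple[str, int]:
    """Canonical move string (lexicographic minimum over symmetry images under
    U < D < L < R) and the orbit size (number of distinct images)."""
    moves = conf.moves if isinstance(conf, LatticeConformation) else conf
    LatticeConformation.from_moves(moves)  # validate
    images = symmetry_images(moves, distinguish_reversal)
    return min(images, key=_move_key), len(images)


def contacts(conf: LatticeConformation) -> ContactSet:
    """Residue pairs adjacent on the lattice but not along the chain."""
    index = {p: i for i, p in enumerate(conf.coords)}
    pairs = set()
    for (x, y), i in index.items():
        for dx, dy in ((1, 0), (0, 1)):
            j = index.get((x + dx, y + dy))
            if j is not None and abs(i - j) > 1:
                pairs.add((min(i, j), max(i, j)))
    return ContactSet(frozenset(pairs))


def contact_count_closed_form(width: int, height: int) -> int:
    """|contacts| of any compact W x H conformation: grid edges minus chain edges."""
    return width * (height - 1) + (width - 1) * height - (width * height - 1)


@dataclass
class StructureCatalogue:
    """The reduced catalogue of compact structures on a W x H grid.

    Structure ids are assigned by sorting canonical move strings under the
    U < D < L < R order, so ids are reproducible across runs.
    """

    width: int
    height: int
    distinguish_reversal: bool
    conformations: list[LatticeConformation]
    contact_sets: list[ContactSet]

    @property
    def n(self) -> int:
        return len(self.conformations)

    @property
    def L(self) -> int:
        return self.width * self.height

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, i: int) -> LatticeConformation:
        return self.conformations[i]

    def subset(self, ids: Sequence[int]) -> "StructureCatalogue":
        """A catalogue restricted to the given structure ids (for crafted systems)."""
        return StructureCatalogue(
            self.width, self.height, self.distinguish_reversal,
            [self.conformations[i] for i in ids],
            [self.contact_sets[i] for i in ids],
        )

    def contact_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Flattened (i, j, ptr) CSR-style contact pairs for vectorized kernels."""
        ii, jj, ptr = [], [], [0]
        for cs in self.contact_sets:
            for i, j in cs:
                ii.append(i)
                jj.append(j)
            ptr.append(len(ii))
        return (np.asarray(ii, dtype=np.int64), np.asarray(jj, dtype=np.int64),
                np.asarray(ptr, dtype=np.int64))

    def reversal_map(self) -> np.ndarray:
        """id -> id of the reversed structure's canonical class."""
        lookup = {c.moves: c.canonical_id for c in self.conformations}
        out = np.empty(self.n, dtype=np.int64)
        for c in self.conformations:
            canon, _ = canonicalize(reverse_moves(c.moves), self.distinguish_reversal)
            out[c.canonical_id] = lookup[canon]
        return out


def build_catalogue(width: int, height: int,
                    distinguish_reversal: bool = True) -> StructureCatalogue:
    """Enumerate all directed compact walks and reduce them to canonical classes."""
    paths = enumerate_directed_paths(width, height)
    orbits: dict[str, int] = {}  # canonical move string -> orbit size
    seen: set[str] = set()
    for moves in paths:
        if moves in seen:
            continue
        images = symmetry_images(moves, distinguish_reversal)
        orbits[min(images, key=_move_key)] = len(images)
        seen |= images
    if sum(orbits.values()) != len(paths):
        raise AssertionError("orbit bookkeeping mismatch during catalogue build")
    canon_set = sorted(orbits, key=_move_key)
    confs = [
        LatticeConformation.from_moves(m, canonical_id=i, orbit_size=orbits[m])
        for i, m in enumerate(canon_set)
    ]
    return StructureCatalogue(width, height, distinguish_reversal,
                              confs, [contacts(c) for c in confs])
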