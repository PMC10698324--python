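"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written from scratch against the definitions
(depth-first path search, direct energy summation, mutate-and-fold loops)
and stays independent of the code paths it validates.
"""
from __future__ import annotations

import itertools
import math

# step -> move letter, written independently of the package's tables
_STEP_LETTER = {(1, 0): "R", (-1, 0): "L", (0, 1): "U", (0, -1): "D"}


def dfs_directed_paths(width: int, height: int) -> set[str]:
    """All directed Hamiltonian paths as move strings, via plain recursion
    over an adjacency map."""
    cells = [(x, y) for x in range(width) for y in range(height)]
    adj = {
        c: [d for d in ((c[0] + 1, c[1]), (c[0] - 1, c[1]),
                        (c[0], c[1] + 1), (c[0], c[1] - 1))
            if 0 <= d[0] < width and 0 <= d[1] < height]
        for c in cells
    }
    paths: set[str] = set()

    def extend(path: list[tuple[int, int]], used: set[tuple[int, int]]) -> None:
        if len(path) == len(cells):
            moves = "".join(
                _STEP_LETTER[(b[0] - a[0], b[1] - a[1])]
                for a, b in zip(path, path[1:]))
            paths.add(moves)
            return
        for nxt in adj[path[-1]]:
            if nxt not in used:
                used.add(nxt)
                path.append(nxt)
                extend(path, used)
                path.pop()
                used.remove(nxt)

    for start in cells:
        extend([start], {start})
    return paths


# --- symmetry reduction acting on move letters directly -----------------------

_LETTER_MAPS = {
    "identity": str.maketrans("", ""),
    "flip_x": str.maketrans("LR", "RL"),
    "flip_y": str.maketrans("UD", "DU"),
    "rot180": str.maketrans("UDLR", "DURL"),
    "transpose": str.maketrans("UDLR", "RLDU"),       # (x,y) -> (y,x)
    "rot90": str.maketrans("UDLR", "LRDU"),           # (x,y) -> (-y,x)
    "rot270": str.maketrans("UDLR", "RLUD"),          # (x,y) -> (y,-x)
    "anti_transpose": str.maketrans("UDLR", "LRUD"),  # (x,y) -> (-y,-x)
}
_SQUARE_OPS = list(_LETTER_MAPS)
_RECT_OPS = ["identity", "flip_x", "flip_y", "rot180"]
_ORDER = {"U": 0, "D": 1, "L": 2, "R": 3}


def reduce_by_symmetry(paths: set[str], square: bool,
                       distinguish_reversal: bool = True) -> dict[str, int]:
    """Canonical move string -> orbit size, computed purely on letter strings."""
    ops = _SQUARE_OPS if square else _RECT_OPS
    classes: dict[str, int] = {}
    seen: set[str] = set()
    for moves in paths:
        if moves in seen:
            continue
        images = {moves.translate(_LETTER_MAPS[op]) for op in ops}
        if not distinguish_reversal:
            rev = moves[::-1].translate(_LETTER_MAPS["rot180"])
            images |= {rev.translate(_LETTER_MAPS[op]) for op in ops}
        canon = min(images, key=lambda m: [_ORDER[c] for c in m])
        classes[canon] = len(images)
        seen |= images
    return classes


# --- direct HP energetics -----------------------------------------------------

def contacts_from_coords(coords) -> set[tuple[int, int]]:
    pairs = set()
    for (i, a), (j, b) in itertools.combinations(enumerate(coords), 2):
        if abs(a[0] - b[0]) + abs(a[1] - b[1]) == 1 and abs(i - j) > 1:
            pairs.add((min(i, j), max(i, j)))
    return pairs


def hp_energy_direct(seq: str, coords) -> int:
    return -sum(1 for i, j in contacts_from_coords(coords)
                if seq[i] == "H" and seq[j] == "H")


def fold_direct(seq: str, catalogue) -> int:
    """Per-sequence argmin with explicit tie handling; -1 on a tie."""
    energies = [hp_energy_direct(seq, conf.coords) for conf in catalogue.conformations]
    emin = min(energies)
    winners = [c for c, e in enumerate(energies) if e == emin]
    return winners[0] if len(winners) == 1 else -1


def ensemble_direct(seq: str, catalogue, kBT: float) -> list[float]:
    """Unshifted direct Boltzmann summation."""
    weights = [math.exp(-hp_energy_direct(seq, conf.coords) / kBT)
               for conf in catalogue.conformations]
    z = sum(weights)
    return [w / z for w in weights]


def all_hp_sequences(L: int):
    for bits in itertools.product("PH", repeat=L):
        yield "".join(bits)


def phi_direct(p: int, catalogue) -> tuple[dict[int, float], int]:
    """Mutate-and-fold phi row over the exact neutral set; returns (phi, x)."""
    L = catalogue.L
    neutral = [s for s in all_hp_sequences(L) if fold_direct(s, catalogue) == p]
    counts: dict[int, int] = {}
    for seq in neutral:
        for i in range(L):
            mutant = seq[:i] + ("H" if seq[i] == "P" else "P") + seq[i + 1:]
            q = fold_direct(mutant, catalogue)
            counts[q] = counts.get(q, 0) + 1
    denom = len(neutral) * L
    return {q: c / denom for q, c in counts.items()}, len(neutral)


def pqp_direct(p: int, catalogue, kBT: float) -> list[float]:
    """Loop-over-neutral-set mean Boltzmann frequency of every structure."""
    L = catalogue.L
    neutral = [s for s in all_hp_sequences(L) if fold_direct(s, catalogue) == p]
    sums = [0.0] * catalogue.n
    for seq in neutral:
        for q, f in enumerate(ensemble_direct(seq, catalogue, kBT)):
            sums[q] += f
    return [s / len(neutral) for s in sums]


# --- RNA structure enumeration ------------------------------------------------

def enumerate_structures(L: int, min_hairpin: int = 3):
    """Every dot-bracket string of length L with nested pairs, hairpin loops of
    at least ``min_hairpin`` and no isolated base pairs."""

    def pairs_ok(pairs: frozenset[tuple[int, int]]) -> bool:
        for i, j in pairs:
            if not ((i + 1, j - 1) in pairs or (i - 1, j + 1) in pairs):
                return False
        return True

    def gen(lo: int, hi: int) -> list[frozenset]:
        # structures over positions [lo, hi)
        if hi - lo < 2 + min_hairpin:
            return [frozenset()]
        out = list(gen(lo + 1, hi))  # lo unpaired
        for j in range(lo + 1 + min_hairpin, hi):
            for inner in gen(lo + 1, j):
                for rest in gen(j + 1, hi):
                    out.append(frozenset({(lo, j)}) | inner | rest)
        return out

    seen = set()
    for pairs in gen(0, L):
        if pairs in seen or not pairs_ok(pairs):
            continue
        seen.add(pairs)
        db = ["."] * L
        for i, j in pairs:
            db[i], db[j] = "(", ")"
        yield "".join(db)


def stacks_from_pairs(db: str) -> int:
    """Stack count via an explicit pair-list scan."""
    stack, pairs = [], []
    for i, c in enumerate(db):
        if c == "(":
            stack.append(i)
        elif c == ")":
            pairs.append((stack.pop(), i))
    pairs.sort()
    pairset = set(pairs)
    return sum(1 for i, j in pairs if (i - 1, j + 1) not in pairset)
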