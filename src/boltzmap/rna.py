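"""RNA secondary-structure backend behind a pluggable folding-engine contract.

An engine exposes one call, ``subopt(seq, delta)``, returning every structure
within ``delta`` kcal/mol of the sequence's minimum free energy as
(dot-bracket, energy) pairs.  Two engines are provided: a deterministic
fixture-backed mock (used by all tests) and an adapter to the ViennaRNA
``RNAsubopt`` command-line tool when it is installed.

Unique-mfe determination exploits the 0.1 kcal/mol energy quantization of
nearest-neighbour models: querying a 0.02 kcal/mol window returns exactly one
structure iff the mfe structure is unique.  Boltzmann ensembles are built from
a wider suboptimal window (15 kcal/mol by default); frequencies are normalized
over the truncated list, and the maximal frequency any excluded structure
could carry, exp(-cutoff/kBT), is recorded alongside.
"""
from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass, field
from typing import Mapping, Protocol, Sequence

import numpy as np

from .core import RNA_ALPHABET, PredictorScores
from .hp_thermo import BoltzmannEnsemble

#: Boltzmann constant in kcal/(mol*K).
KB_KCAL_PER_MOL_K = 0.0019872
#: Uniqueness window; energies are quantized in 0.1 kcal/mol steps, so a
#: window this narrow contains only structures tied with the minimum.
UNIQUENESS_WINDOW = 0.02
#: Default ensemble truncation depth above the mfe, kcal/mol.
ENSEMBLE_CUTOFF = 15.0
DEFAULT_TEMPERATURE_C = 37.0


class EngineError(RuntimeError):
    """A folding engine failed or was asked about an unknown sequence."""


class FoldingEngine(Protocol):
    def subopt(self, seq: str, delta: float) -> list[tuple[str, float]]:
        """All structures with free energy within delta kcal/mol of the minimum,
        sorted by ascending energy."""


def kBT_from_temperature(t_celsius: float) -> float:
    """Thermal energy kB*T in kcal/mol (~0.62 at 37 C)."""
    t_kelvin = t_celsius + 273.15
    if t_kelvin < 0:
        raise ValueError(f"nonphysical temperature {t_celsius} C")
    return KB_KCAL_PER_MOL_K * t_kelvin


# ---------------------------------------------------------------------------
# dot-bracket utilities

def pair_table(dotbracket: str) -> list[int]:
    """Partner index per position (-1 if unpaired); raises on unbalanced input."""
    table = [-1] * len(dotbracket)
    stack: list[int] = []
    for i, ch in enumerate(dotbracket):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            table[j] = i
            table[i] = j
        elif ch != ".":
            raise ValueError(f"invalid dot-bracket character {ch!r}")
    if stack:
        raise ValueError(f"unclosed '(' at position {stack[-1]}")
    return table


def validate_structure(dotbracket: str) -> None:
    """Reject unbalanced strings, hairpin loops < 3 and isolated base pairs."""
    table = pair_table(dotbracket)
    for i, j in enumerate(table):
        if j <= i:
            continue
        if j - i - 1 < 3 and all(table[k] == -1 for k in range(i + 1, j)):
            raise ValueError(f"hairpin loop shorter than 3 at pair ({i},{j})")
        inner = i + 1 < len(table) and table[i + 1] == j - 1
        outer = i > 0 and j + 1 < len(table) and table[i - 1] == j + 1
        if not (inner or outer):
            raise ValueError(f"isolated base pair ({i},{j})")


def dotbracket_from_pair_table(table: Sequence[int]) -> str:
    out = []
    for i, j in enumerate(table):
        out.append("." if j < 0 else ("(" if j > i else ")"))
    return "".join(out)


def count_stacks(dotbracket: str) -> int:
    """Number of maximal runs of chain-adjacent nested base pairs (helices)."""
    table = pair_table(dotbracket)
    n = 0
    for i, j in enumerate(table):
        if j > i and not (i > 0 and table[i - 1] == j + 1):
            n += 1  # outermost pair of a stack
    return n


# ---------------------------------------------------------------------------
# suboptimal lists and truncated ensembles

@dataclass
class SuboptList:
    """Structures within ``cutoff`` kcal/mol of a sequence's minimum energy.

    Entries are sorted ascending by energy (ties by dot-bracket string);
    engines report energies quantized to 0.1 kcal/mol.
    """

    entries: list[tuple[str, float]]
    cutoff: float

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("empty suboptimal list")
        self.entries = sorted(self.entries, key=lambda e: (e[1], e[0]))

    @property
    def min_energy(self) -> float:
        return self.entries[0][1]


def mfe_unique(seq: str, engine: FoldingEngine,
               window: float = UNIQUENESS_WINDOW) -> tuple[str, bool]:
    """(mfe structure, uniqueness flag) via a narrow suboptimal window.

    Sequences with several structures inside the window are degenerate and
    treated as non-folding downstream.
    """
    try:
        entries = engine.subopt(seq, window)
    except EngineError:
        raise
    except Exception as exc:  # attach the sequence to engine failures
        raise EngineError(f"engine failed on sequence {seq!r}: {exc}") from exc
    if not entries:
        raise EngineError(f"engine returned no structure for {seq!r}")
    entries = sorted(entries, key=lambda e: (e[1], e[0]))
    return entries[0][0], len(entries) == 1


def boltzmann_from_subopt(sub: SuboptList | Sequence[tuple[str, float]],
                          kBT: float, cutoff: float | None = None) -> BoltzmannEnsemble:
    """Truncated Boltzmann ensemble from a suboptimal-structure list.

    Frequencies are normalized over the listed structures; any structure
    excluded by the cutoff would have had frequency at most exp(-cutoff/kBT),
    recorded as ``exclusion_bound``.
    """
    if kBT <= 0:
        raise ValueError("kBT must be positive")
    if not isinstance(sub, SuboptList):
        sub = SuboptList(list(sub), cutoff if cutoff is not None else ENSEMBLE_CUTOFF)
    energies = np.array([e for _, e in sub.entries])
    w = np.exp(-(energies - energies.min()) / kBT)
    w /= w.sum()
    freqs: dict[str, float] = {}
    for (db, _), f in zip(sub.entries, w):
        freqs[db] = freqs.get(db, 0.0) + float(f)
    return BoltzmannEnsemble(freqs=freqs, kBT=kBT, truncated=True,
                             exclusion_bound=float(np.exp(-sub.cutoff / kBT)))


def subopt_ensemble(seq: str, engine: FoldingEngine, kBT: float,
                    cutoff: float = ENSEMBLE_CUTOFF) -> BoltzmannEnsemble:
    """Truncated ensemble of one sequence straight from the engine."""
    entries = engine.subopt(seq, cutoff)
    return boltzmann_from_subopt(SuboptList(entries, cutoff), kBT)


# ---------------------------------------------------------------------------
# engines

class MockRNAEngine:
    """Deterministic fixture-backed engine: a table sequence -> [(structure, energy)].

    Suboptimal queries filter the table rows within ``delta`` of the row minimum.
    """

    def __init__(self, table: Mapping[str, Sequence[tuple[str, float]]],
                 validate: bool = True):
        self.table = {}
        for seq, entries in table.items():
            entries = sorted(entries, key=lambda e: (e[1], e[0]))
            if validate:
                for db, _ in entries:
                    if any(c in "()" for c in db):
                        validate_structure(db)
            self.table[seq] = entries

    def subopt(self, seq: str, delta: float) -> list[tuple[str, float]]:
        try:
            entries = self.table[seq]
        except KeyError:
            raise EngineError(f"mock engine has no fixture for sequence {seq!r}") from None
        emin = entries[0][1]
        return [(db, e) for db, e in entries if e <= emin + delta + 1e-9]


class ViennaRNAEngine:
    """Adapter to the ViennaRNA ``RNAsubopt`` command-line tool.

    Runs with no isolated base pairs and the package's default 37 C parameters,
    matching the conventions used throughout this package.  Optional at
    runtime; tests rely on the mock engine.
    """

    def __init__(self, executable: str = "RNAsubopt"):
        path = shutil.which(executable)
        if path is None:
            raise EngineError(f"{executable} not found on PATH")
        self.executable = path

    def subopt(self, seq: str, delta: float) -> list[tuple[str, float]]:
        cmd = [self.executable, "--noLP", "-e", f"{delta:.4f}", "-s"]
        try:
            proc = subprocess.run(cmd, input=seq + "\n", capture_output=True,
                                  text=True, check=True)
        except subprocess.CalledProcessError as exc:
            raise EngineError(f"RNAsubopt failed on {seq!r}: {exc.stderr}") from exc
        out = []
        for line in proc.stdout.splitlines():
            parts = line.split()
            if len(parts) == 2 and set(parts[0]) <= {".", "(", ")"}:
                out.append((parts[0], float(parts[1])))
        if not out:
            raise EngineError(f"RNAsubopt returned no structures for {seq!r}")
        return sorted(out, key=lambda e: (e[1], e[0]))


def get_engine(name: str, **kw) -> FoldingEngine:
    if name == "vienna":
        return ViennaRNAEngine(**kw)
    raise ValueError(f"unknown engine {name!r} (mock engines are built from fixture tables)")


# ---------------------------------------------------------------------------
# sampled phenotypic frequencies

def random_sequences(n: int, L: int, rng: np.random.Generator) -> list[str]:
    codes = rng.integers(0, 4, size=(n, L))
    letters = np.array(list(RNA_ALPHABET))
    return ["".join(row) for row in letters[codes]]


def estimate_fq_by_sampling(n: int, L: int, engine: FoldingEngine,
                            seed: int = 1) -> PredictorScores:
    """Phenotypic frequencies from folding n uniform random sequences.

    The frequency of each unique-mfe structure is its sample fraction.
    Structures observed fewer than 5 times are flagged unreliable (the
    fq >= 5/n plotting convention).
    """
    if n < 1:
        raise ValueError("need n >= 1 sequences")
    rng = np.random.default_rng(seed)
    counts: dict[str, int] = {}
    n_unfolded = 0
    for seq in random_sequences(n, L, rng):
        db, unique = mfe_unique(seq, engine)
        if unique:
            counts[db] = counts.get(db, 0) + 1
        else:
            n_unfolded += 1
    scores = {db: c / n for db, c in counts.items()}
    unreliable = {db for db, c in counts.items() if c < 5}
    return PredictorScores(scores=scores, kind="fq", sample_size=n, seed=seed,
                           f_unfolded=n_unfolded / n, unreliable=unreliable)
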