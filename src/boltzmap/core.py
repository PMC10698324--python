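"""Shared primitives: phenotype sentinel, alphabets, sequence codes, result containers.

Phenotypes are identified by small integers (HP lattice structures, toy-landscape
structures) or by dot-bracket strings (RNA).  Sequences that have no unique
minimum-energy structure are assigned the :data:`UNFOLDED` sentinel.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np

#: Sentinel phenotype for degenerate (non-folding) sequences.  Kept as a plain
#: integer so it stores directly in flat int32 assignment arrays and sorts/hashes
#: alongside integer phenotype ids.
UNFOLDED: int = -1

HP_ALPHABET: tuple[str, ...] = ("P", "H")
RNA_ALPHABET: tuple[str, ...] = ("A", "C", "G", "U")


def seq_to_code(seq: str, alphabet: Sequence[str]) -> int:
    """Encode ``seq`` as an integer in base ``len(alphabet)``, site 0 least significant.

    With the HP alphabet ("P", "H") this makes bit ``i`` of the code 1 iff residue
    ``i`` is hydrophobic.
    """
    index = {s: i for i, s in enumerate(alphabet)}
    a = len(alphabet)
    code = 0
    for i, sym in enumerate(seq):
        try:
            code += index[sym] * a**i
        except KeyError:
            raise ValueError(f"symbol {sym!r} not in alphabet {alphabet}") from None
    return code


def code_to_seq(code: int, length: int, alphabet: Sequence[str]) -> str:
    a = len(alphabet)
    out = []
    for _ in range(length):
        out.append(alphabet[code % a])
        code //= a
    return "".join(out)


def all_codes(length: int, alphabet: Sequence[str]) -> np.ndarray:
    """All sequence codes of the given length, in numeric order."""
    return np.arange(len(alphabet) ** length, dtype=np.int64)


@dataclass
class PredictorScores:
    """Per-phenotype scores used for ranking and correlation.

    kind is one of ``fq`` (phenotypic frequency), ``pqp`` (neutral-set mean
    Boltzmann frequency, with ``context`` the initial phenotype p), ``pq``
    (mean Boltzmann frequency over arbitrary sequences) or ``pq_excluding_mfe``.
    """

    scores: dict[Hashable, float]
    kind: str
    context: Hashable | None = None
    sample_size: int | None = None
    seed: int | None = None
    f_unfolded: float | None = None
    unreliable: set = field(default_factory=set)

    def __getitem__(self, q: Hashable) -> float:
        return self.scores.get(q, 0.0)

    def items(self):
        return self.scores.items()


@dataclass
class TransitionRow:
    """Phenotypic mutation probabilities out of one initial structure p.

    ``phi[q]`` is the fraction of the x*y single-site substitutions applied to
    p's neutral set (x sequences, y mutants each) whose mutant folds into q.
    The row includes q = p (mutational robustness) and UNFOLDED, so it sums to 1.
    """

    p: Hashable
    phi: dict[Hashable, float]
    x: int
    y: int
    counts: dict[Hashable, int] | None = None
    provenance: str = "exact"
    seed: int | None = None
    unreliable: set = field(default_factory=set)

    def __getitem__(self, q: Hashable) -> float:
        return self.phi.get(q, 0.0)

    def total(self) -> float:
        return float(sum(self.phi.values()))


@dataclass
class ComparisonResult:
    """Scores of the two predictors of phi for one initial phenotype p."""

    p: Hashable
    k: int
    captured_fq: int
    captured_pqp: int
    pearson_fq: float | None
    pearson_pqp: float | None
    n_pairs_fq: int
    n_pairs_pqp: int


class DegenerateSequenceError(ValueError):
    """Raised when a unique-mfe operation is applied to a degenerate sequence."""


class EmptyNeutralSetError(ValueError):
    """Raised when an operation requires a phenotype with a nonempty neutral set."""
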