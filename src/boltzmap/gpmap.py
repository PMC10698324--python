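"""Sequence -> phenotype tables, neutral sets, phenotypic frequencies and phi rows.

The phenotypic mutation probability phi_qp is the fraction of all single-site
substitutions applied to the neutral set of p (x sequences, y = (a-1)*L
substitutions each) whose mutant folds into q.  Rows include q = p (mutational
robustness) and the UNFOLDED outcome, so each row partitions the x*y mutations
and sums to one.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Hashable, Sequence

import numpy as np

from .core import (HP_ALPHABET, UNFOLDED, EmptyNeutralSetError, PredictorScores,
                   TransitionRow, seq_to_code)
from .hp_thermo import fold_codes
from .lattice import StructureCatalogue

#: Refuse to materialize exact maps bigger than this many sequences.
DEFAULT_SIZE_CEILING = 1 << 26


@dataclass
class GPMapTable:
    """A genotype-phenotype assignment over a full sequence space (or a sample).

    ``assignment[code]`` is the phenotype id of the sequence with that code,
    or UNFOLDED (-1).  ``n_phenotypes`` is the size of the phenotype universe
    (the structure catalogue), which may exceed the number of ids realized.
    """

    assignment: np.ndarray
    L: int
    alphabet: tuple[str, ...]
    n_phenotypes: int
    provenance: str = "exact"

    @property
    def a(self) -> int:
        return len(self.alphabet)

    @property
    def n_sequences(self) -> int:
        return len(self.assignment)

    def neutral_set(self, p: int) -> np.ndarray:
        """Codes of all sequences folding into p (exact mode)."""
        return np.flatnonzero(self.assignment == p).astype(np.int64)

    def neutral_set_sizes(self) -> np.ndarray:
        """Counts per phenotype id 0..n_phenotypes-1 (UNFOLDED excluded)."""
        sizes = np.bincount(self.assignment[self.assignment != UNFOLDED],
                            minlength=self.n_phenotypes)
        return sizes

    def folding_phenotypes(self) -> np.ndarray:
        return np.flatnonzero(self.neutral_set_sizes() > 0)


def build_full_gpmap(catalogue: StructureCatalogue,
                     size_ceiling: int = DEFAULT_SIZE_CEILING,
                     method: str = "auto") -> GPMapTable:
    """Exact mfe assignment of every HP sequence on the catalogue's lattice.

    ``method`` selects the dense numpy path ("numpy", fine up to ~2^18
    sequences), the blocked numba kernel ("kernel", used automatically for
    larger spaces), or "auto".
    """
    L = catalogue.L
    n_seq = 1 << L
    if n_seq > size_ceiling:
        raise ValueError(
            f"2^{L} sequences exceeds the ceiling of {size_ceiling}; "
            "use sampling (neutral walks / random draws) instead of a full build")
    if method == "auto":
        method = "numpy" if n_seq <= (1 << 18) else "kernel"
    if method == "numpy":
        assignment = fold_codes(np.arange(n_seq, dtype=np.int64), catalogue)
    elif method == "kernel":
        from ._kernel import assign_all_sequences

        assignment = assign_all_sequences(catalogue)
    else:
        raise ValueError(f"unknown method {method!r}")
    return GPMapTable(assignment=assignment.astype(np.int32), L=L,
                      alphabet=HP_ALPHABET, n_phenotypes=catalogue.n,
                      provenance="exact")


def phenotypic_frequencies(gp: GPMapTable) -> PredictorScores:
    """fq = neutral-set size / sequence-space size, plus the unfolded fraction."""
    if gp.n_sequences == 0:
        raise ValueError("empty GP map table")
    sizes = gp.neutral_set_sizes()
    n = gp.n_sequences
    scores = {int(q): sizes[q] / n for q in range(gp.n_phenotypes)}
    f_unfolded = float((gp.assignment == UNFOLDED).sum() / n)
    return PredictorScores(scores=scores, kind="fq", f_unfolded=f_unfolded)


def point_mutants(seq: str, alphabet: Sequence[str]) -> list[str]:
    """All (a-1)*L single-site substitutions, position-major then symbol order."""
    symbols = list(alphabet)
    for s in seq:
        if s not in symbols:
            raise ValueError(f"symbol {s!r} not in alphabet {alphabet}")
    out = []
    for i, cur in enumerate(seq):
        for sym in symbols:
            if sym != cur:
                out.append(seq[:i] + sym + seq[i + 1:])
    return out


def mutant_codes(codes: np.ndarray, L: int, a: int) -> np.ndarray:
    """Codes of all single-site substitutions, shape (len(codes), (a-1)*L)."""
    codes = np.asarray(codes, dtype=np.int64)
    cols = []
    place = 1
    for i in range(L):
        digit = (codes // place) % a
        for d in range(a):
            delta = (d - digit) * place
            col = codes + delta
            cols.append(np.where(digit == d, -1, col))
        place *= a
    m = np.stack([c for c in cols], axis=1)
    return m[m >= 0].reshape(len(codes), (a - 1) * L)


def phi_row(gp: GPMapTable, p: int) -> TransitionRow:
    """Exact phi_qp over all outcomes q for initial phenotype p."""
    ns = gp.neutral_set(p)
    x = len(ns)
    if x == 0:
        raise EmptyNeutralSetError(f"phenotype {p} has an empty neutral set")
    y = (gp.a - 1) * gp.L
    mut = mutant_codes(ns, gp.L, gp.a)
    outcomes = gp.assignment[mut.ravel()]
    counts = np.bincount(outcomes + 1, minlength=gp.n_phenotypes + 1)
    denom = x * y
    count_dict = {UNFOLDED: int(counts[0])}
    for q in range(gp.n_phenotypes):
        if counts[q + 1] or q == p:
            count_dict[q] = int(counts[q + 1])
    phi = {q: c / denom for q, c in count_dict.items()}
    return TransitionRow(p=p, phi=phi, x=x, y=y, counts=count_dict,
                         provenance="exact")


def phi_row_sampled(sample: Sequence[str], fold: Callable[[str], Hashable],
                    p: Hashable, alphabet: Sequence[str],
                    seed: int | None = None) -> TransitionRow:
    """phi_qp estimated from a sample of neutral-set sequences.

    Every sequence in the sample must fold to p; the denominator is
    len(sample) * y.  Estimates below 10/(x*y) are flagged unreliable.
    """
    if not sample:
        raise EmptyNeutralSetError("empty sample")
    y = (len(alphabet) - 1) * len(sample[0])
    counts: dict[Hashable, int] = {p: 0, UNFOLDED: 0}
    for seq in sample:
        if fold(seq) != p:
            raise ValueError(f"sample sequence {seq!r} does not fold to {p!r}")
        for mut in point_mutants(seq, alphabet):
            q = fold(mut)
            counts[q] = counts.get(q, 0) + 1
    x = len(sample)
    denom = x * y
    phi = {q: c / denom for q, c in counts.items()}
    floor = 10 / denom
    unreliable = {q for q, v in phi.items() if 0 < v < floor}
    return TransitionRow(p=p, phi=phi, x=x, y=y, counts=counts,
                         provenance="sampled", seed=seed, unreliable=unreliable)


def count_folding_structures(gp: GPMapTable) -> int:
    """Number of distinct structures with at least one uniquely-folding sequence."""
    return int(len(gp.folding_phenotypes()))
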