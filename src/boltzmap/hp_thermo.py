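"""HP-model energies and Boltzmann ensembles over a compact structure catalogue.

The HP energy of a sequence threaded onto a conformation is minus the number
of contacts whose two residues are both hydrophobic (one stabilising unit per
H-H contact, nothing otherwise).  The Boltzmann frequency of structure p for
sequence s is

    F_p = exp(-G_p / kBT) / sum_q exp(-G_q / kBT)

with the sum over the whole compact catalogue; kBT is the reduced temperature
in units of the HP interaction strength.  A sequence whose minimum energy is
attained by two or more structures is degenerate and treated as non-folding.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Sequence

import numpy as np

from .core import HP_ALPHABET, UNFOLDED, DegenerateSequenceError, seq_to_code
from .lattice import ContactSet, StructureCatalogue


@dataclass
class BoltzmannEnsemble:
    """Structure -> equilibrium frequency for one sequence.

    Frequencies sum to 1 for exact (full-catalogue) ensembles; for truncated
    ensembles built from a suboptimal-structure list the sum is over the list
    and ``exclusion_bound`` records the maximal frequency a dropped structure
    could have had.
    """

    freqs: dict[Hashable, float]
    kBT: float
    truncated: bool = False
    exclusion_bound: float | None = None

    def __getitem__(self, p: Hashable) -> float:
        return self.freqs.get(p, 0.0)

    def total(self) -> float:
        return float(sum(self.freqs.values()))


def _as_code(seq: str | int, L: int) -> int:
    if isinstance(seq, str):
        if len(seq) != L:
            raise ValueError(f"sequence length {len(seq)} != lattice length {L}")
        return seq_to_code(seq, HP_ALPHABET)
    code = int(seq)
    if not 0 <= code < (1 << L):
        raise ValueError("sequence code out of range")
    return code


def hp_energy(seq: str | int, cs: ContactSet, L: int | None = None) -> int:
    """Contact energy (<= 0) of a sequence threaded on a conformation's contacts."""
    if isinstance(seq, str):
        L = len(seq)
        code = seq_to_code(seq, HP_ALPHABET)
    else:
        if L is None:
            raise ValueError("L required when passing a sequence code")
        code = _as_code(seq, L)
    e = 0
    for i, j in cs:
        if i >= L or j >= L or i < 0:
            raise IndexError(f"contact ({i},{j}) out of range for L={L}")
        if (code >> i) & (code >> j) & 1:
            e -= 1
    return e


def contact_count_matrix(codes: np.ndarray, catalogue: StructureCatalogue) -> np.ndarray:
    """H-H contact counts, shape (n_sequences, n_structures); energy is -counts."""
    codes = np.asarray(codes, dtype=np.int64)
    out = np.zeros((codes.size, catalogue.n), dtype=np.int16)
    for c, cs in enumerate(catalogue.contact_sets):
        acc = out[:, c]
        for i, j in cs:
            acc += ((codes >> i) & (codes >> j) & 1).astype(np.int16)
    return out


def frequency_matrix(codes: np.ndarray, catalogue: StructureCatalogue,
                     kBT: float) -> np.ndarray:
    """Exact Boltzmann frequencies for each code over the whole catalogue.

    Rows sum to 1; computed with a max-shift so the partition sum never
    overflows.
    """
    if kBT <= 0:
        raise ValueError("kBT must be positive")
    cnt = contact_count_matrix(codes, catalogue).astype(np.float64)
    cnt -= cnt.max(axis=1, keepdims=True)
    w = np.exp(cnt / kBT)
    return w / w.sum(axis=1, keepdims=True)


def ensemble(seq: str | int, catalogue: StructureCatalogue,
             kBT: float) -> BoltzmannEnsemble:
    """Boltzmann ensemble of one sequence over the full compact catalogue."""
    if catalogue.n == 0:
        raise ValueError("catalogue is empty")
    code = _as_code(seq, catalogue.L)
    f = frequency_matrix(np.asarray([code]), catalogue, kBT)[0]
    return BoltzmannEnsemble({c: float(f[c]) for c in range(catalogue.n)}, kBT)


def fold_codes(codes: np.ndarray, catalogue: StructureCatalogue) -> np.ndarray:
    """Unique-mfe structure id per code, UNFOLDED (-1) on ties; vectorized."""
    cnt = contact_count_matrix(codes, catalogue)
    best = cnt.max(axis=1)
    is_best = cnt == best[:, None]
    ids = is_best.argmax(axis=1).astype(np.int32)
    ids[is_best.sum(axis=1) > 1] = UNFOLDED
    return ids


def assign_mfe(seq: str | int, catalogue: StructureCatalogue) -> int:
    """The unique energy-minimizing structure id, or UNFOLDED if tied."""
    if catalogue.n == 0:
        raise ValueError("catalogue is empty")
    code = _as_code(seq, catalogue.L)
    return int(fold_codes(np.asarray([code]), catalogue)[0])


def ground_state_frequency(seq: str | int, catalogue: StructureCatalogue,
                           kBT: float) -> float:
    """Boltzmann frequency of the (unique) mfe structure of ``seq``."""
    code = _as_code(seq, catalogue.L)
    p = assign_mfe(code, catalogue)
    if p == UNFOLDED:
        raise DegenerateSequenceError(
            "ground_state_frequency requires a sequence with a unique mfe structure")
    return float(frequency_matrix(np.asarray([code]), catalogue, kBT)[0, p])


def mfe_frequencies(codes: np.ndarray, catalogue: StructureCatalogue,
                    kBT: float) -> tuple[np.ndarray, np.ndarray]:
    """(mfe ids, ground-state frequencies) for many codes at once.

    Degenerate codes get id UNFOLDED and frequency nan.
    """
    codes = np.asarray(codes, dtype=np.int64)
    ids = fold_codes(codes, catalogue)
    freqs = np.full(codes.size, np.nan)
    mask = ids != UNFOLDED
    if mask.any():
        f = frequency_matrix(codes[mask], catalogue, kBT)
        freqs[mask] = f[np.arange(mask.sum()), ids[mask]]
    return ids, freqs
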