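"""Neutral-set and whole-map averages of Boltzmann frequencies.

p_qp is the mean Boltzmann frequency of structure q over sequences whose
unique mfe structure is p — the neutral-set generalization of plastogenetic
congruence.  p_q is the same average taken over arbitrary sequences.  Both
can be computed exactly on enumerable maps or by seeded sampling (the HP
analyses use 10^3 with-replacement draws per neutral set for p_qp and 10^5
random sequences for p_q).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import UNFOLDED, EmptyNeutralSetError, PredictorScores
from .gpmap import GPMapTable
from .hp_thermo import fold_codes, frequency_matrix, mfe_frequencies
from .lattice import StructureCatalogue


def _scores_from_vector(vec: np.ndarray, kind: str, **kw) -> PredictorScores:
    return PredictorScores(scores={int(q): float(v) for q, v in enumerate(vec)},
                           kind=kind, **kw)


def pqp_exact(gp: GPMapTable, p: int, catalogue: StructureCatalogue,
              kBT: float) -> PredictorScores:
    """Mean Boltzmann frequency of every structure over the full neutral set of p."""
    ns = gp.neutral_set(p)
    if len(ns) == 0:
        raise EmptyNeutralSetError(f"phenotype {p} has an empty neutral set")
    mean = frequency_matrix(ns, catalogue, kBT).mean(axis=0)
    return _scores_from_vector(mean, "pqp", context=int(p))


def pqp_all_exact(gp: GPMapTable, catalogue: StructureCatalogue,
                  kBT: float, block: int = 1 << 16) -> np.ndarray:
    """Exact p_qp matrix, rows = initial p, cols = q; nan rows for empty sets.

    Streams the sequence space in blocks and accumulates per-phenotype sums,
    so only one block's frequency matrix is in memory at a time.
    """
    S = catalogue.n
    sums = np.zeros((S, S))
    counts = np.zeros(S, dtype=np.int64)
    n = gp.n_sequences
    for start in range(0, n, block):
        codes = np.arange(start, min(start + block, n), dtype=np.int64)
        ids = gp.assignment[codes]
        mask = ids != UNFOLDED
        if not mask.any():
            continue
        f = frequency_matrix(codes[mask], catalogue, kBT)
        np.add.at(sums, ids[mask], f)
        counts += np.bincount(ids[mask], minlength=S)
    out = np.full((S, S), np.nan)
    nz = counts > 0
    out[nz] = sums[nz] / counts[nz, None]
    return out


def pqp_sampled(gp: GPMapTable, p: int, catalogue: StructureCatalogue, kBT: float,
                n: int = 1000, seed: int = 1, replace: bool = True) -> PredictorScores:
    """p_qp from n draws (with replacement by default) from the neutral set of p."""
    if n < 1:
        raise ValueError("need n >= 1 draws")
    ns = gp.neutral_set(p)
    if len(ns) == 0:
        raise EmptyNeutralSetError(f"phenotype {p} has an empty neutral set")
    rng = np.random.default_rng(seed)
    if replace:
        draw = rng.choice(ns, size=n, replace=True)
    else:
        if n > len(ns):
            raise ValueError("cannot draw more than the neutral set without replacement")
        draw = rng.choice(ns, size=n, replace=False)
    mean = frequency_matrix(draw, catalogue, kBT).mean(axis=0)
    return _scores_from_vector(mean, "pqp", context=int(p), sample_size=n, seed=seed)


def pq_random(catalogue: StructureCatalogue, kBT: float, n: int = 100_000,
              seed: int = 1, include_mfe: bool = True,
              block: int = 1 << 14) -> PredictorScores:
    """Mean Boltzmann frequency of each structure over n uniform random sequences.

    With ``include_mfe`` off, each uniquely-folding sequence's own mfe structure
    contributes zero for that sequence (degenerate sequences keep all terms).
    """
    if n < 1:
        raise ValueError("need n >= 1 draws")
    rng = np.random.default_rng(seed)
    S = catalogue.n
    sums = np.zeros(S)
    done = 0
    while done < n:
        m = min(block, n - done)
        codes = rng.integers(0, 1 << catalogue.L, size=m, dtype=np.int64)
        f = frequency_matrix(codes, catalogue, kBT)
        if not include_mfe:
            ids = fold_codes(codes, catalogue)
            mask = ids != UNFOLDED
            f[np.flatnonzero(mask), ids[mask]] = 0.0
        sums += f.sum(axis=0)
        done += m
    kind = "pq" if include_mfe else "pq_excluding_mfe"
    return _scores_from_vector(sums / n, kind, sample_size=n, seed=seed)


def pq_exact(gp: GPMapTable, catalogue: StructureCatalogue, kBT: float,
             include_mfe: bool = True, block: int = 1 << 16) -> PredictorScores:
    """Exact whole-map average Boltzmann frequency of each structure."""
    S = catalogue.n
    sums = np.zeros(S)
    n = gp.n_sequences
    for start in range(0, n, block):
        codes = np.arange(start, min(start + block, n), dtype=np.int64)
        f = frequency_matrix(codes, catalogue, kBT)
        if not include_mfe:
            ids = gp.assignment[codes]
            mask = ids != UNFOLDED
            f[np.flatnonzero(mask), ids[mask]] = 0.0
        sums += f.sum(axis=0)
    kind = "pq" if include_mfe else "pq_excluding_mfe"
    return _scores_from_vector(sums / n, kind)


@dataclass
class GroundStateStats:
    """Distribution summary of ground-state Boltzmann frequencies (fractions)."""

    median: float
    q25: float
    q75: float
    fraction_folding: float
    n: int
    kBT: float
    seed: int


def ground_state_stats(catalogue: StructureCatalogue, kBT: float, n: int = 2000,
                       seed: int = 1) -> GroundStateStats:
    """Ground-state occupancy statistics over uniform random folding sequences.

    Draws n uniform sequences, discards degenerate ones and summarizes the
    distribution of the mfe structure's Boltzmann frequency.
    """
    if n < 1:
        raise ValueError("need n >= 1 draws")
    rng = np.random.default_rng(seed)
    codes = rng.integers(0, 1 << catalogue.L, size=n, dtype=np.int64)
    ids, freqs = mfe_frequencies(codes, catalogue, kBT)
    folding = freqs[ids != UNFOLDED]
    if folding.size == 0:
        raise EmptyNeutralSetError("no uniquely folding sequence found in the sample")
    q25, med, q75 = np.percentile(folding, [25, 50, 75])
    return GroundStateStats(median=float(med), q25=float(q25), q75=float(q75),
                            fraction_folding=float(folding.size / n),
                            n=n, kBT=kBT, seed=seed)
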