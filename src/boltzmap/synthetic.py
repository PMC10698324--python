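"""Self-contained test worlds: random-field toy landscapes, mock RNA engines,
and the exact small-lattice suite.

The toy landscape is an abstract GP map with additive per-site,
per-structure random-field energies: E(s in q) = sum_i eps[q, i, s_i] with
eps drawn once from N(0, sigma^2) under a fixed seed.  It exposes the same
fold/ensemble contract as the HP model, so every downstream stage (phi rows,
Boltzmann averages, predictor comparison) runs unchanged on it.  The ratio
sigma/kBT tunes how strongly ensembles concentrate on the ground state, i.e.
how much plastogenetic congruence the landscape exhibits.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core import UNFOLDED, PredictorScores, code_to_seq, seq_to_code
from .gpmap import GPMapTable
from .hp_thermo import BoltzmannEnsemble
from .lattice import StructureCatalogue, build_catalogue
from .rna import MockRNAEngine

TOY_SIZE_CEILING = 1 << 20
_LETTERS = "ABCDEFGH"


@dataclass
class ToyLandscape:
    """Additive random-field GP map over an a-letter alphabet of length n."""

    a: int
    n: int
    S: int
    sigma: float
    kBT: float
    seed: int
    eps: np.ndarray  # (S, n, a) site energies

    @property
    def alphabet(self) -> tuple[str, ...]:
        return tuple(_LETTERS[: self.a])

    def _digits(self, codes: np.ndarray) -> np.ndarray:
        codes = np.asarray(codes, dtype=np.int64)
        digits = np.empty((codes.size, self.n), dtype=np.int64)
        c = codes.copy()
        for i in range(self.n):
            digits[:, i] = c % self.a
            c //= self.a
        return digits

    def energy_matrix(self, codes: np.ndarray) -> np.ndarray:
        """E(s in q) for each code, shape (len(codes), S)."""
        digits = self._digits(codes)
        out = np.zeros((digits.shape[0], self.S))
        for i in range(self.n):
            out += self.eps[:, i, :].T[digits[:, i]]
        return out

    def fold_codes(self, codes: np.ndarray) -> np.ndarray:
        e = self.energy_matrix(codes)
        best = e.min(axis=1)
        is_best = e == best[:, None]
        ids = is_best.argmax(axis=1).astype(np.int32)
        ids[is_best.sum(axis=1) > 1] = UNFOLDED
        return ids

    def fold(self, seq: str) -> int:
        return int(self.fold_codes(np.asarray([seq_to_code(seq, self.alphabet)]))[0])

    def frequency_matrix(self, codes: np.ndarray) -> np.ndarray:
        e = self.energy_matrix(codes)
        w = np.exp(-(e - e.min(axis=1, keepdims=True)) / self.kBT)
        return w / w.sum(axis=1, keepdims=True)

    def ensemble(self, seq: str) -> BoltzmannEnsemble:
        f = self.frequency_matrix(np.asarray([seq_to_code(seq, self.alphabet)]))[0]
        return BoltzmannEnsemble({q: float(v) for q, v in enumerate(f)}, self.kBT)

    def build_gpmap(self) -> GPMapTable:
        codes = np.arange(self.a**self.n, dtype=np.int64)
        return GPMapTable(assignment=self.fold_codes(codes), L=self.n,
                          alphabet=self.alphabet, n_phenotypes=self.S,
                          provenance="exact")


def make_toy_landscape(a: int, n: int, S: int, sigma: float, kBT: float,
                       seed: int) -> ToyLandscape:
    """A toy landscape regenerated bit-identically from (seed, a, n, S, sigma)."""
    if a**n > TOY_SIZE_CEILING:
        raise ValueError(f"{a}^{n} sequences exceeds the toy ceiling {TOY_SIZE_CEILING}")
    if a < 2 or a > len(_LETTERS):
        raise ValueError("alphabet size out of range")
    rng = np.random.default_rng(seed)
    eps = sigma * rng.standard_normal((S, n, a))
    return ToyLandscape(a=a, n=n, S=S, sigma=sigma, kBT=kBT, seed=seed, eps=eps)


def make_mock_rna_engine(table: Mapping[str, Sequence[tuple[str, float]]],
                         validate: bool = True) -> MockRNAEngine:
    """A fixture-backed engine satisfying the folding-engine contract."""
    return MockRNAEngine(table, validate=validate)


SMALL_LATTICE_GRIDS = [(1, 2), (2, 2), (2, 3), (3, 3), (2, 4), (4, 4)]


def small_lattice_suite(grids: Sequence[tuple[int, int]] | None = None,
                        cache_dir: str | Path | None = None
                        ) -> dict[tuple[int, int], tuple[StructureCatalogue, GPMapTable]]:
    """Exact catalogues and GP maps for the small-lattice test grids.

    With ``cache_dir`` set, assignments are cached to disk and verified by
    checksum on reload; corrupted caches are rebuilt.
    """
    from .gpmap import build_full_gpmap

    out = {}
    for w, h in grids if grids is not None else SMALL_LATTICE_GRIDS:
        cat = build_catalogue(w, h)
        gp = None
        cache = None
        if cache_dir is not None:
            cache = Path(cache_dir) / f"gpmap_{w}x{h}.npy"
            meta = cache.with_suffix(".json")
            if cache.exists() and meta.exists():
                arr = np.load(cache)
                digest = hashlib.sha256(arr.tobytes()).hexdigest()
                stored = json.loads(meta.read_text())
                if stored.get("sha256") == digest and stored.get("n_phenotypes") == cat.n:
                    gp = GPMapTable(assignment=arr, L=cat.L, alphabet=("P", "H"),
                                    n_phenotypes=cat.n, provenance="exact")
        if gp is None:
            gp = build_full_gpmap(cat)
            if cache is not None:
                cache.parent.mkdir(parents=True, exist_ok=True)
                np.save(cache, gp.assignment)
                cache.with_suffix(".json").write_text(json.dumps({
                    "sha256": hashlib.sha256(gp.assignment.tobytes()).hexdigest(),
                    "n_phenotypes": cat.n, "width": w, "height": h,
                }))
        out[(w, h)] = (cat, gp)
    return out
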