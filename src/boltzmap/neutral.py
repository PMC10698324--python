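"""Site-scanning random-walk sampling of neutral sets.

For sequence spaces too large to enumerate, the neutral set of a phenotype p
is sampled by random walks that scan sites cyclically, at each visited site
proposing a random substitution and accepting it only if the mutant still
folds into p.  Every 50th state (accepted or retained) is emitted, and many
independently seeded walks are pooled (defaults: 100 walks of 10^5 steps,
subsampling one in 50).  For RNA, sites paired in p can instead propose a
swap of the whole base pair to another complementary pair, which improves
mixing across neutral-network components; this is a documented variant of the
cited site-scanning scheme, not a bit-identical reimplementation.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Hashable, Sequence

import numpy as np

from .core import UNFOLDED, PredictorScores, TransitionRow
from .gpmap import phi_row_sampled
from .rna import pair_table

#: Complementary (including wobble) RNA pairs available to basepair-swap moves.
COMPLEMENTARY_PAIRS = [("A", "U"), ("U", "A"), ("C", "G"), ("G", "C"),
                       ("G", "U"), ("U", "G")]


@dataclass
class WalkConfig:
    """Schedule of the neutral-set sampler.

    The expected pooled sample size is n_walks * steps_per_walk / subsample
    (2 x 10^5 at the defaults).
    """

    p: Hashable
    seed: int
    n_walks: int = 100
    steps_per_walk: int = 100_000
    subsample: int = 50
    basepair_swaps: bool = False

    def __post_init__(self) -> None:
        if min(self.n_walks, self.steps_per_walk, self.subsample) < 1:
            raise ValueError("walk counts must be positive")

    @property
    def expected_sample_size(self) -> int:
        return self.n_walks * (self.steps_per_walk // self.subsample)


def find_neutral_start(p: Hashable, fold: Callable[[str], Hashable], L: int,
                       alphabet: Sequence[str], seed: int,
                       max_tries: int = 100_000) -> str:
    """A sequence folding to p, found by folding uniform random sequences."""
    rng = np.random.default_rng(seed)
    letters = list(alphabet)
    for _ in range(max_tries):
        seq = "".join(rng.choice(letters, size=L))
        if fold(seq) == p:
            return seq
    raise RuntimeError(f"no sequence folding to {p!r} found in {max_tries} draws")


def _one_walk(start: str, fold: Callable[[str], Hashable], cfg: WalkConfig,
              rng: np.random.Generator, partners: list[int] | None,
              alphabet: Sequence[str]) -> list[str]:
    letters = list(alphabet)
    a = len(letters)
    current = list(start)
    L = len(current)
    out = []
    site = 0
    for step in range(cfg.steps_per_walk):
        proposal = current.copy()
        if (cfg.basepair_swaps and partners is not None and partners[site] >= 0):
            j = partners[site]
            pa, pb = COMPLEMENTARY_PAIRS[rng.integers(0, len(COMPLEMENTARY_PAIRS))]
            proposal[site], proposal[j] = pa, pb
        else:
            cur = current[site]
            alt = letters[rng.integers(0, a - 1)]
            if alt == cur:  # map the drawn index past the current symbol
                alt = letters[a - 1]
            proposal[site] = alt
        if fold("".join(proposal)) == cfg.p:
            current = proposal
        site = (site + 1) % L
        if (step + 1) % cfg.subsample == 0:
            out.append("".join(current))
    return out


def neutral_walk(start: str | Sequence[str], fold: Callable[[str], Hashable],
                 cfg: WalkConfig, alphabet: Sequence[str],
                 structure: str | None = None) -> list[str]:
    """Pooled site-scanning sample of the neutral set of cfg.p.

    ``start`` may be a single sequence (reused by every walk) or one start per
    walk.  ``structure`` (dot-bracket of p) enables basepair-swap proposals
    when cfg.basepair_swaps is on.  Every emitted sequence folds to p.
    """
    starts = [start] * cfg.n_walks if isinstance(start, str) else list(start)
    if len(starts) != cfg.n_walks:
        raise ValueError(f"need {cfg.n_walks} start sequences, got {len(starts)}")
    for s in starts:
        if fold(s) != cfg.p:
            raise ValueError(f"start sequence {s!r} does not fold to {cfg.p!r}")
    partners = None
    if cfg.basepair_swaps:
        if structure is None:
            raise ValueError("basepair swaps need the dot-bracket structure of p")
        partners = pair_table(structure)
    sample: list[str] = []
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_walks)
    for s, ss in zip(starts, seeds):
        sample.extend(_one_walk(s, fold, cfg, np.random.default_rng(ss),
                                partners, alphabet))
    return sample


def sample_phi_and_pqp(p: Hashable, cfg: WalkConfig,
                       fold: Callable[[str], Hashable],
                       ensemble: Callable[[str], "object"],
                       alphabet: Sequence[str],
                       start: str | Sequence[str],
                       structure: str | None = None
                       ) -> tuple[TransitionRow, PredictorScores]:
    """Two independent neutral-set samples routed to phi and p_qp estimates.

    The two samples use distinct sub-seeds derived from cfg.seed so the
    estimates are independent.  phi values below 10/(x*y) and p_qp values
    below 10/x are flagged unreliable (the ~1e-4 floor at the default
    schedule).
    """
    seed_phi, seed_pqp = np.random.SeedSequence(cfg.seed).spawn(2)
    cfg_phi = WalkConfig(p=p, seed=int(seed_phi.generate_state(1)[0] % (2**31)),
                         n_walks=cfg.n_walks, steps_per_walk=cfg.steps_per_walk,
                         subsample=cfg.subsample, basepair_swaps=cfg.basepair_swaps)
    cfg_pqp = WalkConfig(p=p, seed=int(seed_pqp.generate_state(1)[0] % (2**31)),
                         n_walks=cfg.n_walks, steps_per_walk=cfg.steps_per_walk,
                         subsample=cfg.subsample, basepair_swaps=cfg.basepair_swaps)
    sample_phi = neutral_walk(start, fold, cfg_phi, alphabet, structure)
    sample_pqp = neutral_walk(start, fold, cfg_pqp, alphabet, structure)

    phi = phi_row_sampled(sample_phi, fold, p, alphabet, seed=cfg_phi.seed)

    sums: dict[Hashable, float] = {}
    for seq in sample_pqp:
        ens = ensemble(seq)
        freqs = ens.freqs if hasattr(ens, "freqs") else ens
        for q, f in freqs.items():
            sums[q] = sums.get(q, 0.0) + f
    n = len(sample_pqp)
    scores = {q: v / n for q, v in sums.items()}
    floor = 10 / n
    pqp = PredictorScores(scores=scores, kind="pqp", context=p, sample_size=n,
                          seed=cfg_pqp.seed,
                          unreliable={q for q, v in scores.items() if 0 < v < floor})
    return phi, pqp
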