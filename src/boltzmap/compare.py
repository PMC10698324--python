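"""Scoring the two predictors of phenotypic mutation probabilities.

For each initial structure p the transitions phi_qp (q != p, folded outcomes
only) are compared against two predictors of the new structure q: the
phenotypic frequency f_q and the neutral-set Boltzmann average p_qp.  Two
metrics are used: how many of the top-k phi outcomes each predictor's own
top-k captures (set intersection, k = 30 by default), and the Pearson
correlation of log phi against log score over strictly positive pairs.
"""
from __future__ import annotations

import logging
from typing import Hashable, Iterable, Mapping

import numpy as np
from scipy import stats

from .core import UNFOLDED, ComparisonResult, PredictorScores, TransitionRow
from .gpmap import GPMapTable, phenotypic_frequencies, phi_row
from .boltzmann_stats import pqp_all_exact, pqp_sampled
from .lattice import StructureCatalogue

logger = logging.getLogger(__name__)


def _score_map(scores) -> Mapping[Hashable, float]:
    if isinstance(scores, PredictorScores):
        return scores.scores
    if isinstance(scores, TransitionRow):
        return scores.phi
    return scores


def rank_top_k(scores, k: int, exclude: Iterable[Hashable] = ()) -> list:
    """Top-k phenotypes by descending score, ties broken by ascending id.

    Zero- and negative-score phenotypes never rank, so fewer than k items are
    returned when fewer positive candidates exist.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    excl = set(exclude)
    items = [(q, v) for q, v in _score_map(scores).items()
             if q not in excl and v > 0]
    items.sort(key=lambda t: (-t[1], t[0]))
    return [q for q, _ in items[:k]]


def top_k_capture(phi: TransitionRow, predictor, k: int = 30) -> int:
    """|top-k by phi  ∩  top-k by predictor|, both excluding p and UNFOLDED."""
    exclude = (phi.p, UNFOLDED)
    top_phi = rank_top_k(phi, k, exclude)
    top_pred = rank_top_k(predictor, k, exclude)
    return len(set(top_phi) & set(top_pred))


def loglog_pearson(phi: TransitionRow, predictor) -> tuple[float | None, int]:
    """Pearson r of (log phi_qp, log score_q) over pairs with both positive.

    q = p and UNFOLDED are excluded.  Returns (None, n_pairs) when fewer than
    3 positive pairs remain (too few for a meaningful correlation).
    """
    pred = _score_map(predictor)
    xs, ys = [], []
    for q, v in phi.phi.items():
        if q == phi.p or q == UNFOLDED or v <= 0:
            continue
        s = pred.get(q, 0.0)
        if s > 0:
            xs.append(np.log(v))
            ys.append(np.log(s))
    n = len(xs)
    if n < 3:
        return None, n
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return None, n
    r, _ = stats.pearsonr(xs, ys)
    return float(r), n


def compare_predictors(phi: TransitionRow, fq: PredictorScores,
                       pqp: PredictorScores, k: int = 30) -> ComparisonResult:
    r_fq, n_fq = loglog_pearson(phi, fq)
    r_pqp, n_pqp = loglog_pearson(phi, pqp)
    return ComparisonResult(
        p=phi.p, k=k,
        captured_fq=top_k_capture(phi, fq, k),
        captured_pqp=top_k_capture(phi, pqp, k),
        pearson_fq=r_fq, pearson_pqp=r_pqp,
        n_pairs_fq=n_fq, n_pairs_pqp=n_pqp,
    )


def compare_all(gp: GPMapTable, catalogue: StructureCatalogue, kBT: float,
                k: int = 30, pqp_mode: str = "exact", pqp_n: int = 1000,
                seed: int = 1) -> list[ComparisonResult]:
    """Both predictors scored against exact phi for every folding initial p.

    Initial structures whose phi row has no positive candidate outcome
    (q != p, folded) are logged and skipped.
    """
    fq = phenotypic_frequencies(gp)
    results = []
    pqp_matrix = None
    if pqp_mode == "exact":
        pqp_matrix = pqp_all_exact(gp, catalogue, kBT)
    elif pqp_mode != "sampled":
        raise ValueError(f"unknown pqp_mode {pqp_mode!r}")
    rng = np.random.default_rng(seed)
    for p in gp.folding_phenotypes():
        p = int(p)
        phi = phi_row(gp, p)
        if not rank_top_k(phi, k, exclude=(p, UNFOLDED)):
            logger.info("skipping p=%d: no folded candidate outcomes", p)
            continue
        if pqp_matrix is not None:
            pqp = PredictorScores(
                scores={int(q): float(v) for q, v in enumerate(pqp_matrix[p])},
                kind="pqp", context=p)
        else:
            pqp = pqp_sampled(gp, p, catalogue, kBT, n=pqp_n,
                              seed=int(rng.integers(0, 2**31 - 1)))
        results.append(compare_predictors(phi, fq, pqp, k))
    return results


def summarize(results: list[ComparisonResult]) -> dict[str, float]:
    """Mean capture scores and mean log-log Pearson r across initial structures."""
    if not results:
        raise ValueError("no comparison results to summarize")
    cap_fq = float(np.mean([r.captured_fq for r in results]))
    cap_pqp = float(np.mean([r.captured_pqp for r in results]))
    r_fq = [r.pearson_fq for r in results if r.pearson_fq is not None]
    r_pqp = [r.pearson_pqp for r in results if r.pearson_pqp is not None]
    return {
        "n_structures": len(results),
        "mean_capture_fq": cap_fq,
        "mean_capture_pqp": cap_pqp,
        "mean_pearson_fq": float(np.mean(r_fq)) if r_fq else float("nan"),
        "mean_pearson_pqp": float(np.mean(r_pqp)) if r_pqp else float("nan"),
    }
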