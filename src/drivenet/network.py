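"""Mutual-predictability scoring on the weighted functional-linkage network.

A gene's direct neighbors, ranked by edge weight, form a retrieval list; the
AUC of that list against a positive gene set (tie-corrected Mann–Whitney form,
identical to the ROC area swept over weight cutoffs) measures how well the
gene's neighborhood recovers the set. A driver×DRG pair is scored by the
geometric mean of the two directional AUCs — the driver's neighborhood
recovering the DRG set, and the DRG's neighborhood recovering the driver set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)


@dataclass
class NeighborRanking:
    """A gene's direct neighbors sorted by edge weight (descending)."""

    center: str
    neighbors: list[str]
    weights: np.ndarray


@dataclass
class PairScore:
    driver: str
    drg: str
    category: str
    auc_driver: float  # driver's neighborhood recovering the DRG set
    auc_drg: float  # DRG's neighborhood recovering the driver set
    score: float  # geometric mean


def neighbor_ranking(net: nx.Graph, gene: str) -> NeighborRanking:
    """Weight-descending ranking of a gene's direct neighbors.

    Ties are broken by gene id for reproducible output; the AUC downstream is
    order-independent given midranks.
    """
    if gene not in net:
        raise KeyError(f"gene {gene!r} not in network")
    items = sorted(
        ((nb, float(net[gene][nb]["weight"])) for nb in net.neighbors(gene)),
        key=lambda it: (-it[1], it[0]),
    )
    return NeighborRanking(
        center=gene,
        neighbors=[nb for nb, _ in items],
        weights=np.array([w for _, w in items], dtype=float),
    )


def auc_recovery(ranking: NeighborRanking, positives) -> float | None:
    """Tie-corrected Mann–Whitney AUC of the ranking for the positive set.

    Positives are restricted to the neighbor set. Returns None (undefined)
    when the neighborhood contains no positive or no negative.
    """
    pos = np.array([nb in positives for nb in ranking.neighbors], dtype=bool)
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(ranking.weights)  # midranks, ascending
    rank_sum = ranks[pos].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def auc_cutoff_sweep(ranking: NeighborRanking, positives) -> float | None:
    """ROC-trapezoid AUC computed explicitly at every distinct weight cutoff.

    Definitionally equivalent to :func:`auc_recovery`; kept as an independent
    route for verification.
    """
    pos = np.array([nb in positives for nb in ranking.neighbors], dtype=bool)
    n_pos = int(pos.sum())
    n_neg = len(pos) - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    w = ranking.weights
    cutoffs = np.unique(w)[::-1]
    tpr = [0.0]
    fpr = [0.0]
    for c in cutoffs:
        above = w >= c
        tpr.append(float((above & pos).sum()) / n_pos)
        fpr.append(float((above & ~pos).sum()) / n_neg)
    return float(np.trapezoid(tpr, fpr))


def mutual_predictability(net: nx.Graph, driver: str, drg: str,
                          driver_set, drg_set,
                          leave_one_out: bool = False,
                          category: str = "") -> PairScore | None:
    """Geometric-mean mutual-predictability score of one driver×DRG pair.

    By default the full DRG set (including the partner) and the full driver
    set are the positives for the two directional AUCs; ``leave_one_out``
    removes the partner gene from its positive set for sensitivity analysis.
    Returns None when either AUC is undefined.
    """
    if driver not in driver_set:
        raise ValueError(f"{driver!r} not in driver set")
    if drg not in drg_set:
        raise ValueError(f"{drg!r} not in DRG set")
    drg_pos = set(drg_set) - ({drg} if leave_one_out else set())
    drv_pos = set(driver_set) - ({driver} if leave_one_out else set())
    auc_d = auc_recovery(neighbor_ranking(net, driver), drg_pos)
    auc_r = auc_recovery(neighbor_ranking(net, drg), drv_pos)
    if auc_d is None or auc_r is None:
        return None
    return PairScore(
        driver=driver,
        drg=drg,
        category=category,
        auc_driver=auc_d,
        auc_drg=auc_r,
        score=float(np.sqrt(auc_d * auc_r)),
    )


def top_pairs(net: nx.Graph, driver_genes, drg_genes, category: str = "",
              k: int = 100, leave_one_out: bool = False) -> list[PairScore]:
    """Top-k driver×DRG pairs of one category by mutual-predictability score.

    Scores the full Cartesian product, drops undefined pairs, and sorts by
    (score desc, AUC sum desc, driver id, drg id) for a stable, reproducible
    ranking.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    drivers = sorted(set(driver_genes) & set(net.nodes))
    drgs = sorted(set(drg_genes) & set(net.nodes))
    if not drivers or not drgs:
        logger.warning("empty driver or DRG set for category %r", category)
        return []
    drv_set, drg_set = set(drivers), set(drgs)

    if leave_one_out:
        scores = [
            s
            for d in drivers
            for r in drgs
            if (s := mutual_predictability(net, d, r, drv_set, drg_set,
                                           leave_one_out=True, category=category))
            is not None
        ]
    else:
        # without leave-one-out the directional AUCs factor per gene
        auc_of_driver = {
            d: auc_recovery(neighbor_ranking(net, d), drg_set) for d in drivers
        }
        auc_of_drg = {
            r: auc_recovery(neighbor_ranking(net, r), drv_set) for r in drgs
        }
        scores = [
            PairScore(d, r, category, a, b, float(np.sqrt(a * b)))
            for d in drivers
            for r in drgs
            if (a := auc_of_driver[d]) is not None
            and (b := auc_of_drg[r]) is not None
        ]
    scores.sort(key=lambda s: (-s.score, -(s.auc_driver + s.auc_drg), s.driver, s.drg))
    return scores[:k]


def pair_scores_frame(scores: list[PairScore]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "driver": [s.driver for s in scores],
            "drg": [s.drg for s in scores],
            "category": [s.category for s in scores],
            "auc_driver": [s.auc_driver for s in scores],
            "auc_drg": [s.auc_drg for s in scores],
            "score": [s.score for s in scores],
            "rank": np.arange(1, len(scores) + 1),
        }
    )
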