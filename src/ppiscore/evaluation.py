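"""Assessment statistics for scored decoy ensembles.

Implements Spearman's rank correlation between scores and DockQ, ROC AUC
at a DockQ cutoff (and over a range of cutoffs), the dataset-level hit rate
h(R), the per-target effective hit rate h_k(R) under repeated subsampling,
and the negative-dominance fraction mu: the fraction of models that are
negative (DockQ < cutoff) yet rank strictly better than every positive.

Score orientation is always explicit: energy-like scores are lower-better
(and correlate negatively with DockQ); predicted-quality scores such as the
SVR score are higher-better.  Spearman's rho is reported signed and never
auto-flipped.  Both hit rates follow the "fraction of draws/targets with at
least one positive in the top R" semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from .sampling import POSITIVE_CUTOFF, ScoredModelSet

__all__ = [
    "EvalSummary",
    "spearman_rho",
    "roc_auc",
    "auc_curve",
    "hit_rate",
    "effective_hit_rate",
    "negative_dominance_mu",
    "evaluate_scores",
]


@dataclass(frozen=True)
class EvalSummary:
    rho: float
    auc_by_cutoff: dict[float, float]
    mu: float
    hit_rate_curve: np.ndarray | None = None


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson on average ranks)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("inputs must have equal length")
    if len(x) < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rank correlation undefined for a constant input")
    return float(stats.spearmanr(x, y).statistic)


def _oriented(scores: np.ndarray, lower_is_better: bool) -> np.ndarray:
    return -scores if lower_is_better else scores


def roc_auc(
    scores: Sequence[float],
    dockq: Sequence[float],
    cutoff: float = POSITIVE_CUTOFF,
    lower_is_better: bool = False,
) -> float:
    """Probability that a random positive outranks a random negative.

    Ties in score contribute 1/2.  Positives are models with
    DockQ >= cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(dockq, dtype=float) >= cutoff
    if labels.all() or not labels.any():
        raise ValueError("both classes must be nonempty for AUC")
    return float(roc_auc_score(labels, _oriented(scores, lower_is_better)))


def auc_curve(
    model_set: ScoredModelSet,
    score_name: str,
    cutoffs: Sequence[float] | None = None,
    lower_is_better: bool = False,
) -> dict[float, float]:
    """AUC at each DockQ cutoff (default 0.2 to 0.8 in steps of 0.1)."""
    if cutoffs is None:
        cutoffs = np.round(np.arange(0.2, 0.8 + 1e-9, 0.1), 10)
    s = model_set.scores(score_name)
    q = model_set.dockq
    return {
        float(c): roc_auc(s, q, cutoff=float(c), lower_is_better=lower_is_better)
        for c in cutoffs
    }


def _rank_order(scores: np.ndarray, lower_is_better: bool) -> np.ndarray:
    """Indices ordered best-first; ties keep stable input order."""
    key = scores if lower_is_better else -scores
    return np.argsort(key, kind="stable")


def hit_rate(
    model_sets: Sequence[ScoredModelSet],
    score_name: str,
    R_max: int = 100,
    cutoff: float = POSITIVE_CUTOFF,
    lower_is_better: bool = False,
) -> np.ndarray:
    """h(R): fraction of targets with >= 1 positive in their top R models.

    Returns an array of length R_max where entry R-1 is h(R); the curve is
    nondecreasing in R.
    """
    if not model_sets:
        raise ValueError("at least one target is required")
    first_hits = []
    for ms in model_sets:
        order = _rank_order(ms.scores(score_name), lower_is_better)
        pos = ms.labels(cutoff)[order]
        hits = np.flatnonzero(pos)
        first_hits.append(hits[0] + 1 if len(hits) else np.inf)
    first_hits = np.asarray(first_hits, dtype=float)
    ranks = np.arange(1, R_max + 1)
    return (first_hits[None, :] <= ranks[:, None]).mean(axis=1)


def effective_hit_rate(
    model_set: ScoredModelSet,
    score_name: str,
    Nm: int,
    Ns: int = 1000,
    R_max: int = 100,
    cutoff: float = POSITIVE_CUTOFF,
    lower_is_better: bool = False,
    seed: int = 0,
) -> np.ndarray:
    """h_k(R): fraction of Ns random size-Nm draws with a positive in top R.

    Each draw is taken without replacement from the target's models and
    ranked by the given score.
    """
    Nt = len(model_set)
    if not 1 <= Nm <= Nt:
        raise ValueError("Nm must satisfy 1 <= Nm <= number of models")
    rng = np.random.default_rng(seed)
    order = _rank_order(model_set.scores(score_name), lower_is_better)
    # position of each model in the full best-first ranking
    position = np.empty(Nt, dtype=int)
    position[order] = np.arange(Nt)
    pos_label = model_set.labels(cutoff)
    first_hits = np.empty(Ns)
    for l in range(Ns):
        chosen = rng.choice(Nt, size=Nm, replace=False)
        chosen_pos_sorted = np.sort(position[chosen])
        is_pos = pos_label[order[chosen_pos_sorted]]
        hits = np.flatnonzero(is_pos)
        first_hits[l] = hits[0] + 1 if len(hits) else np.inf
    ranks = np.arange(1, R_max + 1)
    return (first_hits[None, :] <= ranks[:, None]).mean(axis=1)


def negative_dominance_mu(
    model_set: ScoredModelSet,
    score_name: str,
    cutoff: float = POSITIVE_CUTOFF,
    lower_is_better: bool = False,
) -> float:
    """Fraction of models that are negative and outrank every positive."""
    s = _oriented(model_set.scores(score_name), lower_is_better)
    labels = model_set.labels(cutoff)
    if not labels.any():
        raise ValueError("at least one positive model is required")
    best_positive = s[labels].max()
    dominating = (~labels) & (s > best_positive)
    return float(dominating.mean())


def evaluate_scores(
    model_set: ScoredModelSet,
    score_name: str,
    lower_is_better: bool = False,
    cutoff: float = POSITIVE_CUTOFF,
    auc_cutoffs: Sequence[float] | None = None,
) -> EvalSummary:
    """Convenience bundle: rho, AUC-vs-cutoff curve, and mu for one score."""
    rho = spearman_rho(model_set.scores(score_name), model_set.dockq)
    aucs = auc_curve(model_set, score_name, auc_cutoffs, lower_is_better)
    mu = negative_dominance_mu(model_set, score_name, cutoff, lower_is_better)
    return EvalSummary(rho=rho, auc_by_cutoff=aucs, mu=mu)
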