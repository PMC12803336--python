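"""DockQ-uniform subsampling and class balancing of scored decoy sets.

Docking engines produce vastly more low-quality than near-native models,
which distorts rank- and classification-based assessment.  The remedy used
here: sort models into 20 evenly spaced DockQ bins, keep at most 50 per bin,
top up with extra negatives (DockQ < 0.23), and finally trim the majority
class at random so positives (DockQ >= 0.23) and negatives are balanced 1:1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScoredModelSet",
    "POSITIVE_CUTOFF",
    "bin_models",
    "uniform_subsample",
    "balance_classes",
]

POSITIVE_CUTOFF = 0.23
DEFAULT_N_BINS = 20
DEFAULT_PER_BIN = 50
DEFAULT_EXTRA_NEGATIVES = 1000


@dataclass
class ScoredModelSet:
    """Per-model table of DockQ plus zero or more scores.

    Backed by a DataFrame with columns ``model_id``, ``dockq``, and one
    column per score; the unit of all evaluation statistics.
    """

    df: pd.DataFrame
    positive_cutoff: float = POSITIVE_CUTOFF

    def __post_init__(self):
        for col in ("model_id", "dockq"):
            if col not in self.df.columns:
                raise ValueError(f"missing required column {col!r}")
        d = self.df["dockq"].to_numpy()
        if len(d) and (np.nanmin(d) < 0 or np.nanmax(d) > 1):
            raise ValueError("dockq values must lie in [0, 1]")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def score_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("model_id", "dockq")]

    @property
    def dockq(self) -> np.ndarray:
        return self.df["dockq"].to_numpy(dtype=float)

    def scores(self, name: str) -> np.ndarray:
        if name not in self.score_names:
            raise KeyError(f"unknown score {name!r}")
        return self.df[name].to_numpy(dtype=float)

    def labels(self, cutoff: float | None = None) -> np.ndarray:
        cutoff = self.positive_cutoff if cutoff is None else cutoff
        return self.dockq >= cutoff

    @classmethod
    def from_records(cls, records, positive_cutoff: float = POSITIVE_CUTOFF):
        """Build from (model_id, dockq, {score: value}) tuples."""
        rows = []
        for model_id, q, scores in records:
            rows.append({"model_id": model_id, "dockq": q, **scores})
        return cls(pd.DataFrame(rows), positive_cutoff=positive_cutoff)

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, positive_cutoff: float = POSITIVE_CUTOFF):
        return cls(pd.read_csv(path, sep="\t"), positive_cutoff=positive_cutoff)


def bin_models(model_set: ScoredModelSet, n_bins: int = DEFAULT_N_BINS) -> np.ndarray:
    """Evenly spaced DockQ bin index per record.

    Bin k covers [k/n_bins, (k+1)/n_bins); the last bin is right-closed so
    DockQ = 1 lands in bin n_bins - 1.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    idx = np.floor(model_set.dockq * n_bins).astype(int)
    return np.minimum(idx, n_bins - 1)


def uniform_subsample(
    model_set: ScoredModelSet,
    per_bin: int = DEFAULT_PER_BIN,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
) -> ScoredModelSet:
    """Keep at most *per_bin* records per DockQ bin, uniformly at random."""
    if per_bin < 1:
        raise ValueError("per_bin must be >= 1")
    rng = np.random.default_rng(seed)
    bins = bin_models(model_set, n_bins)
    keep: list[int] = []
    for b in range(n_bins):
        members = np.flatnonzero(bins == b)
        if len(members) > per_bin:
            members = rng.choice(members, size=per_bin, replace=False)
        keep.extend(members.tolist())
    keep = sorted(keep)
    return ScoredModelSet(
        model_set.df.iloc[keep], positive_cutoff=model_set.positive_cutoff
    )


def balance_classes(
    selected: ScoredModelSet,
    pool: ScoredModelSet | None = None,
    cutoff: float = POSITIVE_CUTOFF,
    n_extra_negatives: int = DEFAULT_EXTRA_NEGATIVES,
    seed: int = 0,
) -> ScoredModelSet:
    """Top up negatives from *pool*, then trim to an exact 1:1 class ratio.

    Up to *n_extra_negatives* negatives whose model ids are not already
    selected are added, after which the majority class is randomly trimmed
    so positives and negatives are equally numerous.
    """
    rng = np.random.default_rng(seed)
    df = selected.df.copy()
    if pool is not None and n_extra_negatives > 0:
        have = set(df["model_id"])
        pool_df = pool.df
        candidates = pool_df[
            (pool_df["dockq"] < cutoff) & (~pool_df["model_id"].isin(have))
        ]
        take = min(n_extra_negatives, len(candidates))
        if take > 0:
            picked = rng.choice(candidates.index.to_numpy(), size=take, replace=False)
            df = pd.concat([df, pool_df.loc[sorted(picked)]], ignore_index=True)
    labels = df["dockq"].to_numpy() >= cutoff
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be nonempty to balance")
    target = min(n_pos, n_neg)
    keep = np.ones(len(df), dtype=bool)
    majority = np.flatnonzero(labels) if n_pos > n_neg else np.flatnonzero(~labels)
    if len(majority) > target:
        drop = rng.choice(majority, size=len(majority) - target, replace=False)
        keep[drop] = False
    return ScoredModelSet(df[keep], positive_cutoff=cutoff)
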