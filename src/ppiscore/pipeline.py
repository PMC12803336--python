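"""End-to-end assessment runs over one or more targets.

A "target" bundles a native dimer, optionally its decoy structures, and a
scored-model pool.  ``run_assessment`` applies the standard protocol per
target — DockQ-uniform subsampling, class balancing, Spearman rho / AUC /
mu per score, native interface features (Nc, S), and the landscape
anisotropy kappa^2 when decoy structures are available — and aggregates
mean correlations per target and per score.  ``run_interpolation_assessment``
evaluates score-DockQ correlations image by image along bound-to-unbound
monomer paths, normalizing each score's rho by its bound-image value.

Every stage draws its randomness from the run seed, so reports are pure
functions of (inputs, config, seed).  Per-target failures are logged to
standard error and skipped; remaining targets continue.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation, landscape, sampling, svr_score
from .structio import DimerStructure

__all__ = ["RunConfig", "TargetData", "run_assessment", "run_interpolation_assessment"]

logger = logging.getLogger("ppiscore")
if not logger.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)


@dataclass
class RunConfig:
    """Assessment settings; defaults are the protocol's standard constants."""

    n_bins: int = 20
    per_bin: int = 50
    positive_cutoff: float = 0.23
    contact_cutoff: float = 4.5
    n_extra_negatives: int = 1000
    n_images: int = 6
    svr_C: float = 1.0
    svr_epsilon: float = 0.1
    seed: int = 0
    # score name -> True when lower values mean better models
    score_orientations: dict = field(default_factory=dict)

    def lower_is_better(self, score_name: str) -> bool:
        return bool(self.score_orientations.get(score_name, True))

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for key, value in asdict(self).items():
                if key == "score_orientations":
                    for name, flag in value.items():
                        fh.write(f"orientation.{name}={'lower' if flag else 'higher'}\n")
                else:
                    fh.write(f"{key}={value}\n")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        kwargs: dict = {}
        orientations: dict = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                key, value = key.strip(), value.strip()
                if key.startswith("orientation."):
                    orientations[key.removeprefix("orientation.")] = value == "lower"
                elif key in ("n_bins", "per_bin", "n_extra_negatives", "n_images", "seed"):
                    kwargs[key] = int(value)
                else:
                    kwargs[key] = float(value)
        return cls(score_orientations=orientations, **kwargs)


@dataclass
class TargetData:
    name: str
    native: DimerStructure
    scores: sampling.ScoredModelSet
    decoys: Sequence[DimerStructure] | None = None


def _assess_one(config: RunConfig, target: TargetData) -> dict:
    selected = sampling.uniform_subsample(
        target.scores,
        per_bin=config.per_bin,
        n_bins=config.n_bins,
        seed=config.seed,
    )
    balanced = sampling.balance_classes(
        selected,
        pool=target.scores,
        cutoff=config.positive_cutoff,
        n_extra_negatives=config.n_extra_negatives,
        seed=config.seed,
    )
    row: dict = {"target": target.name, "n_models": len(balanced)}
    rhos = []
    for name in balanced.score_names:
        summary = evaluation.evaluate_scores(
            balanced,
            name,
            lower_is_better=config.lower_is_better(name),
            cutoff=config.positive_cutoff,
        )
        row[f"rho_{name}"] = summary.rho
        row[f"auc_{name}"] = summary.auc_by_cutoff.get(
            min(summary.auc_by_cutoff, key=lambda c: abs(c - config.positive_cutoff))
        )
        row[f"mu_{name}"] = summary.mu
        rhos.append(summary.rho)
    row["mean_rho"] = float(np.mean(rhos)) if rhos else float("nan")
    feats = svr_score.featurize(
        target.native, contact_cutoff=config.contact_cutoff, seed=config.seed
    )
    row["n_contacts"] = feats.n_contacts
    row["separability"] = feats.separability
    if target.decoys is not None:
        id_to_q = dict(
            zip(target.scores.df["model_id"], target.scores.df["dockq"])
        )
        qs = [id_to_q.get(f"decoy_{i:04d}") for i in range(len(target.decoys))]
        qs = None if any(v is None for v in qs) else qs
        _, inertia = landscape.landscape_summary(target.decoys, target.native, qs)
        row["kappa2"] = inertia.kappa2
    return row


def run_assessment(
    config: RunConfig, targets: Sequence[TargetData]
) -> tuple[pd.DataFrame, dict]:
    """Per-target report plus aggregate per-score mean correlations."""
    if not targets:
        raise ValueError("at least one target is required")
    rows = []
    for target in targets:
        try:
            rows.append(_assess_one(config, target))
            logger.info("assessed target %s", target.name)
        except Exception as exc:
            logger.warning("target %s skipped: %s", target.name, exc)
    report = pd.DataFrame(rows)
    aggregate: dict = {"n_targets": len(report)}
    for col in report.columns:
        if col.startswith("rho_"):
            aggregate[f"mean_{col}"] = float(report[col].mean())
    if "mean_rho" in report:
        aggregate["mean_rho"] = float(report["mean_rho"].mean())
    return report, aggregate


def run_interpolation_assessment(
    config: RunConfig,
    image_tables: Sequence[tuple[float, float, dict[str, sampling.ScoredModelSet]]],
) -> pd.DataFrame:
    """rho-vs-iRMSD* table along an interpolation path.

    *image_tables* holds, per image in path order, its iRMSD, iRMSD*, and a
    scored-model set per score name.  Each score's Spearman correlation is
    normalized by its value at the bound image (first entry).
    """
    if not image_tables:
        raise ValueError("at least one image is required")
    rows = []
    bound_rho: dict[str, float] = {}
    for idx, (irmsd, irmsd_star, tables) in enumerate(image_tables):
        row: dict = {"image": idx, "irmsd": irmsd, "irmsd_star": irmsd_star}
        for name, model_set in tables.items():
            rho = evaluation.spearman_rho(model_set.scores(name), model_set.dockq)
            if idx == 0:
                bound_rho[name] = rho
            row[f"rho_{name}"] = rho
            row[f"rho_norm_{name}"] = (
                rho / bound_rho[name] if bound_rho.get(name) else float("nan")
            )
        norm_cols = [v for k, v in row.items() if k.startswith("rho_norm_")]
        row["mean_rho_norm"] = float(np.mean(norm_cols)) if norm_cols else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
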