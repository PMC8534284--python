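"""Exhaustive-subset random-forest screening of a metabolite signature.

Every non-empty subset of the consensus signature is evaluated as a
random-forest classifier of case vs control over repeated class-balanced
train/test splits; performance is the mean held-out ROC AUC with a
normal-approximation 95% confidence interval over repeats.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from ._forest import forest_vote_fractions
from .containers import FeatureMatrix, SampleMetadata, SubsetModelResult

__all__ = ["ScreenConfig", "enumerate_subsets", "evaluate_subset", "screen_signature", "rank_models"]


@dataclass
class ScreenConfig:
    """Protocol for the subset screen.

    n_repeats        : balanced subsampling repeats per subset (default 50)
    n_trees          : trees per forest (default 500)
    train_fraction   : per-class train draw as a fraction of the minority
                       class size (default 0.8)
    max_subset_size  : guard against combinatorial blowup (default 16)
    """

    n_repeats: int = 50
    n_trees: int = 500
    train_fraction: float = 0.8
    max_subset_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("n_repeats must be >= 2")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")


def enumerate_subsets(signature: Sequence[str], max_size: int = 16) -> List[Tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically."""
    members = sorted(set(signature))
    if not members:
        raise ValueError("signature is empty")
    if len(members) > max_size:
        raise ValueError(
            f"signature has {len(members)} metabolites; exhaustive enumeration "
            f"is limited to {max_size} (2^{max_size} - 1 subsets)"
        )
    out: List[Tuple[str, ...]] = []
    for size in range(1, len(members) + 1):
        out.extend(combinations(members, size))
    return out


def _balanced_split(
    labels: np.ndarray, train_fraction: float, rng: np.random.Generator
) -> Tuple[np.ndarray, np.ndarray]:
    """Class-balanced train indices; the held-out remainder is the test set."""
    classes, counts = np.unique(labels, return_counts=True)
    n_train_per_class = max(int(np.floor(train_fraction * counts.min())), 1)
    train_idx = []
    for c in classes:
        idx = np.flatnonzero(labels == c)
        train_idx.append(rng.choice(idx, size=n_train_per_class, replace=False))
    train = np.concatenate(train_idx)
    test = np.setdiff1d(np.arange(labels.size), train)
    return train, test


def evaluate_subset(
    matrix: FeatureMatrix,
    metadata: SampleMetadata,
    subset: Sequence[str],
    config: ScreenConfig,
    is_full_model: bool = False,
) -> SubsetModelResult:
    """Mean held-out ROC AUC of a forest on one metabolite subset.

    Per repeat: draw a class-balanced train split, fit a random forest on
    the subset columns, score the held-out samples by the fraction of
    trees voting case, and compute the ROC AUC. The 95% CI is
    mean +/- 1.96 sd / sqrt(n_repeats), clipped to [0, 1].
    """
    subset = tuple(sorted(subset))
    missing = [f for f in subset if f not in matrix.feature_ids]
    if missing:
        raise ValueError(f"subset features not in matrix: {missing}")
    y = (metadata.table.loc[matrix.sample_ids, "group"] == "case").to_numpy(dtype=int)
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 5:
        raise ValueError("both classes must be present with >= 5 samples")
    X = matrix.values[list(subset)].to_numpy(dtype=float)
    ss = np.random.SeedSequence([config.seed, len(subset), *map(hash_name, subset)])
    child_seeds = ss.generate_state(config.n_repeats * 2)
    aucs: List[float] = []
    y64 = y.astype(np.int64)
    for r in range(config.n_repeats):
        rng = np.random.default_rng(child_seeds[2 * r])
        train, test = _balanced_split(y, config.train_fraction, rng)
        prob_case = forest_vote_fractions(
            X[train], y64[train], X[test], config.n_trees,
            int(child_seeds[2 * r + 1] % (2**31 - 1)),
        )
        aucs.append(float(roc_auc_score(y[test], prob_case)))
    mean = float(np.mean(aucs))
    sd = float(np.std(aucs, ddof=1))
    half = 1.96 * sd / np.sqrt(config.n_repeats)
    return SubsetModelResult(
        subset=subset,
        auc=mean,
        ci_low=max(0.0, min(mean, mean - half)),
        ci_high=min(1.0, max(mean, mean + half)),
        n_repeats=config.n_repeats,
        per_repeat_aucs=aucs,
        is_full_model=is_full_model,
    )


def hash_name(name: str) -> int:
    """Stable non-negative 32-bit hash of a feature name (process-independent)."""
    h = 2166136261
    for ch in name.encode():
        h = ((h ^ ch) * 16777619) % (2**32)
    return h


def screen_signature(
    matrix: FeatureMatrix,
    metadata: SampleMetadata,
    signature: Sequence[str],
    config: Optional[ScreenConfig] = None,
) -> List[SubsetModelResult]:
    """Evaluate every non-empty subset of the signature."""
    config = config or ScreenConfig()
    subsets = enumerate_subsets(signature, max_size=config.max_subset_size)
    full = subsets[-1]
    return [
        evaluate_subset(matrix, metadata, s, config, is_full_model=(s == full))
        for s in subsets
    ]


def rank_models(results: Sequence[SubsetModelResult]) -> List[SubsetModelResult]:
    """Sort by mean AUC descending; ties go to smaller, then lexicographically
    earlier, subsets."""
    if not results:
        raise ValueError("no models to rank")
    return sorted(results, key=lambda r: (-r.auc, len(r.subset), r.subset))


def models_table(results: Sequence[SubsetModelResult]) -> pd.DataFrame:
    """Ranked models as a tidy frame (subset, auc, ci_low, ci_high, n_repeats)."""
    ranked = rank_models(results)
    return pd.DataFrame(
        {
            "subset": ["+".join(r.subset) for r in ranked],
            "subset_size": [len(r.subset) for r in ranked],
            "auc": [r.auc for r in ranked],
            "ci_low": [r.ci_low for r in ranked],
            "ci_high": [r.ci_high for r in ranked],
            "n_repeats": [r.n_repeats for r in ranked],
            "is_full_model": [r.is_full_model for r in ranked],
        }
    )
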