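"""Cleaning and feature selection ahead of graph construction.

Pipeline order is fixed: low-quality filtering -> correlation-based feature
selection -> min-max normalization.  All statistics (zero/missing fractions,
imputation medians, selection scores, min/max) are computed on training
samples only and then applied to the full cohort, so no test information
leaks into the selected set or the scaling.

Correlation-based feature selection (CFS) is implemented as one-vs-rest
Pearson ranking: a feature's score is the largest absolute correlation
between its column and any class-indicator vector.  The kept count is
k = min(ceil(feature_fraction * p_clean), feature_cap) — by default 25% of
the post-filter features, capped at 5,000 per view.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import LabelSet, OmicsView

logger = logging.getLogger(__name__)

__all__ = [
    "SelectionResult",
    "filter_low_quality",
    "normalize_minmax",
    "cfs_scores",
    "cfs_select",
    "rename_methylation_features",
    "Preprocessor",
]


@dataclass
class SelectionResult:
    view_name: str
    kept_feature_names: list[str]
    scores: pd.Series  # score per (post-filter) feature, original order
    k: int

    def __post_init__(self):
        if len(self.kept_feature_names) != self.k:
            raise ValueError("kept feature list does not match k")


def filter_low_quality(view: OmicsView, max_zero_fraction: float = 0.2,
                       max_missing_fraction: float = 0.2,
                       stat_rows: Sequence[int] | None = None) -> OmicsView:
    """Drop noisy features; impute surviving missing entries by the median.

    A feature is dropped when its zero fraction exceeds ``max_zero_fraction``
    or its missing fraction exceeds ``max_missing_fraction``.  Fractions and
    imputation medians are computed over ``stat_rows`` (default: all rows),
    which the model pipeline sets to the training rows.
    """
    rows = np.arange(view.n_samples) if stat_rows is None else np.asarray(stat_rows)
    X = view.values
    sub = X[rows]
    miss = np.isnan(sub)
    n = len(rows)
    zero_frac = np.where(miss, False, sub == 0.0).sum(axis=0) / n
    miss_frac = miss.sum(axis=0) / n
    keep = (zero_frac <= max_zero_fraction) & (miss_frac <= max_missing_fraction)
    if not keep.any():
        raise ValueError(
            f"view {view.view_name!r}: all {view.n_features} features dropped; "
            f"relax max_zero_fraction ({max_zero_fraction}) or "
            f"max_missing_fraction ({max_missing_fraction})")
    dropped = [f for f, k in zip(view.feature_names, keep) if not k]
    if dropped:
        logger.info("filter_low_quality[%s]: dropped %d/%d features",
                    view.view_name, len(dropped), view.n_features)
    Xk = X[:, keep].copy()
    with np.errstate(all="ignore"):
        med = np.nanmedian(sub[:, keep], axis=0)
    med = np.where(np.isnan(med), 0.0, med)
    nan_pos = np.isnan(Xk)
    Xk[nan_pos] = np.broadcast_to(med, Xk.shape)[nan_pos]
    names = [f for f, k in zip(view.feature_names, keep) if k]
    return OmicsView(view.view_name, list(view.sample_ids), names, Xk)


def normalize_minmax(train_view: OmicsView,
                     apply_to: OmicsView | None = None) -> OmicsView:
    """Scale each feature to [0,1] with training-set min/max.

    Constant features map to 0; out-of-range values in ``apply_to`` are
    clipped so every output entry lies in [0,1].
    """
    if apply_to is None:
        apply_to = train_view
    if train_view.feature_names != apply_to.feature_names:
        raise ValueError("feature sets differ between train and apply views")
    lo = train_view.values.min(axis=0)
    hi = train_view.values.max(axis=0)
    span = hi - lo
    safe = np.where(span > 0, span, 1.0)
    X = (apply_to.values - lo) / safe
    X[:, span == 0] = 0.0
    X = np.clip(X, 0.0, 1.0)
    return OmicsView(apply_to.view_name, list(apply_to.sample_ids),
                     list(apply_to.feature_names), X)


def cfs_scores(values: np.ndarray, codes: np.ndarray, C: int) -> np.ndarray:
    """One-vs-rest correlation score per feature column.

    score_j = max_c | corr(x_j, 1[y == c]) |, with 0 for zero-variance
    columns or indicators (undefined correlations).
    """
    n, p = values.shape
    if n < 3:
        raise ValueError("correlation selection needs n >= 3 samples")
    Xc = values - values.mean(axis=0)
    sx = np.sqrt((Xc ** 2).sum(axis=0))
    Y = np.zeros((n, C))
    Y[np.arange(n), codes] = 1.0
    Yc = Y - Y.mean(axis=0)
    sy = np.sqrt((Yc ** 2).sum(axis=0))
    num = Xc.T @ Yc  # p x C
    denom = np.outer(sx, sy)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    return np.abs(corr).max(axis=1)


def cfs_select(view: OmicsView, labels: LabelSet,
               feature_fraction: float = 0.25,
               feature_cap: int = 5000) -> SelectionResult:
    """Rank features by one-vs-rest correlation and keep the top k.

    Ties in score are broken by feature name so the kept set is deterministic
    regardless of input column order.
    """
    if view.sample_ids != labels.sample_ids:
        raise ValueError("view and labels must be aligned")
    scores = cfs_scores(view.values, labels.class_codes, labels.C)
    p_clean = view.n_features
    k = min(math.ceil(feature_fraction * p_clean), feature_cap)
    order = sorted(range(p_clean),
                   key=lambda j: (-scores[j], view.feature_names[j]))
    kept = [view.feature_names[j] for j in order[:k]]
    return SelectionResult(view.view_name, kept,
                           pd.Series(scores, index=view.feature_names), k)


def rename_methylation_features(view: OmicsView,
                                mapping: Mapping[str, str]) -> OmicsView:
    """Rename probe-level features (CpG sites) to gene names via a table.

    Unmapped features are dropped.  When several probes map to one gene, the
    probe with the highest variance survives; the rest are dropped and the
    collisions logged.
    """
    if not mapping:
        raise ValueError("empty CpG->gene mapping")
    var = np.var(np.nan_to_num(view.values), axis=0)
    best: dict[str, int] = {}
    collided = []
    for j, f in enumerate(view.feature_names):
        gene = mapping.get(f)
        if gene is None:
            continue
        if gene in best:
            collided.append(gene)
            if var[j] > var[best[gene]]:
                best[gene] = j
        else:
            best[gene] = j
    if collided:
        logger.info("rename_methylation_features[%s]: %d collision(s): %s",
                    view.view_name, len(collided),
                    ", ".join(sorted(set(collided))[:10]))
    if not best:
        raise ValueError("mapping covers none of the view's features")
    genes = sorted(best, key=lambda g: best[g])  # preserve column order
    idx = [best[g] for g in genes]
    return OmicsView(view.view_name, list(view.sample_ids), genes,
                     view.values[:, idx])


class Preprocessor:
    """Train-fitted filter -> select -> normalize for a set of views."""

    def __init__(self, max_zero_fraction: float = 0.2,
                 max_missing_fraction: float = 0.2,
                 feature_fraction: float = 0.25, feature_cap: int = 5000):
        self.max_zero_fraction = max_zero_fraction
        self.max_missing_fraction = max_missing_fraction
        self.feature_fraction = feature_fraction
        self.feature_cap = feature_cap
        self.selections_: dict[str, SelectionResult] = {}
        self._train_stats: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    def fit_transform(self, views: Sequence[OmicsView], labels: LabelSet,
                      train_ids: Sequence[str]) -> list[OmicsView]:
        """Fit on the training rows, return the transformed full views."""
        train_set = set(train_ids)
        out = []
        for view in views:
            rows = np.array([i for i, s in enumerate(view.sample_ids)
                             if s in train_set])
            filtered = filter_low_quality(view, self.max_zero_fraction,
                                          self.max_missing_fraction,
                                          stat_rows=rows)
            train_view = filtered.subset_samples(
                [s for s in filtered.sample_ids if s in train_set])
            sel = cfs_select(train_view, labels.subset(train_view.sample_ids),
                             self.feature_fraction, self.feature_cap)
            self.selections_[view.view_name] = sel
            kept_full = filtered.subset_features(sel.kept_feature_names)
            kept_train = train_view.subset_features(sel.kept_feature_names)
            lo = kept_train.values.min(axis=0)
            hi = kept_train.values.max(axis=0)
            med = np.median(kept_train.values, axis=0)
            self._train_stats[view.view_name] = (lo, hi, med)
            out.append(normalize_minmax(kept_train, kept_full))
        return out

    def transform_new(self, view: OmicsView) -> OmicsView:
        """Apply a fitted pipeline to new samples of one view."""
        sel = self.selections_.get(view.view_name)
        if sel is None:
            raise KeyError(f"no fitted state for view {view.view_name!r}")
        lo, hi, med = self._train_stats[view.view_name]
        pos = {f: j for j, f in enumerate(view.feature_names)}
        missing = [f for f in sel.kept_feature_names if f not in pos]
        if missing:
            raise ValueError(f"new samples lack feature(s): {missing[:5]}")
        X = view.values[:, [pos[f] for f in sel.kept_feature_names]].copy()
        nan_pos = np.isnan(X)
        X[nan_pos] = np.broadcast_to(med, X.shape)[nan_pos]
        span = hi - lo
        safe = np.where(span > 0, span, 1.0)
        X = (X - lo) / safe
        X[:, span == 0] = 0.0
        X = np.clip(X, 0.0, 1.0)
        return OmicsView(view.view_name, list(view.sample_ids),
                         list(sel.kept_feature_names), X)
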