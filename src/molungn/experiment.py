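"""Evaluation protocol: stratified 70/30 splits repeated ten times,
loss bookkeeping, ablation orchestration and stage-pair binarization.

``run_experiment`` is the published protocol: for each repeat a fresh
stratified split, train-fitted preprocessing, per-view graphs, joint
training, and held-out metrics; the result aggregates mean and standard
deviation per metric.  View-subset ablations (the seven omics combinations)
and the no-fusion ablation are plain config edits (``views=...``,
``use_vcdn=False``).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
import json
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .config import RunConfig
from .io import LabelSet, OmicsView
from .metrics import MetricsReport
from .model import MultiOmicsGAT

__all__ = ["split", "total_loss", "cross_entropy", "RunResult",
           "run_experiment", "view_combinations", "stage_pair_datasets"]

_SCALARS = ("accuracy", "recall_weighted", "f1_weighted", "f1_macro")


def split(labels: LabelSet, train_fraction: float = 0.7,
          seed: int = 0) -> tuple[list[str], list[str]]:
    """Stratified random train/test split of the cohort.

    Train size is round(train_fraction * n) up to stratification rounding;
    the returned id lists are sorted so downstream order never depends on the
    shuffle.  A class with fewer than 2 samples cannot be stratified and
    raises.
    """
    n = labels.n_samples
    codes = labels.class_codes
    counts = np.bincount(codes, minlength=labels.C)
    present = counts[np.unique(codes)]
    if (present < 2).any():
        bad = [labels.class_names[c] for c in np.unique(codes)
               if counts[c] < 2]
        raise ValueError(f"class(es) with < 2 samples cannot be split: {bad}")
    n_train = int(round(train_fraction * n))
    n_train = min(max(n_train, len(present)), n - len(present))
    train, test = train_test_split(labels.sample_ids, train_size=n_train,
                                   stratify=codes, random_state=int(seed))
    return sorted(train), sorted(test)


def cross_entropy(probs: Sequence[float], true_class: int) -> float:
    """-log p(true class), floored at 1e-12 for finiteness."""
    probs = np.asarray(probs, dtype=float)
    if not 0 <= int(true_class) < probs.size:
        raise ValueError(f"class code {true_class} out of range")
    return float(-np.log(max(probs[int(true_class)], 1e-12)))


def total_loss(branch_losses: Sequence[float], fusion_loss: float,
               delta: float = 1.0) -> float:
    """L = sum_i L_Ci + delta * L_MOVCDN."""
    branch_losses = [float(x) for x in branch_losses]
    if any(x < 0 for x in branch_losses) or fusion_loss < 0:
        raise ValueError("cross-entropy losses cannot be negative")
    return float(sum(branch_losses) + delta * float(fusion_loss))


@dataclass
class RunResult:
    """Per-repeat metrics plus aggregates for one experiment configuration."""

    reports: list[MetricsReport]
    config: RunConfig
    seeds: list[int]

    @property
    def table(self) -> pd.DataFrame:
        return pd.DataFrame([{k: getattr(r, k) for k in _SCALARS}
                             for r in self.reports])

    def mean(self) -> dict[str, float]:
        return self.table.mean().to_dict()

    def std(self) -> dict[str, float]:
        return self.table.std(ddof=1).to_dict()

    def summary(self) -> str:
        mu, sd = self.mean(), self.std()
        lines = [f"{len(self.reports)} repeats "
                 f"(train fraction {self.config.train_fraction})"]
        for k in _SCALARS:
            lines.append(f"{k:<16s} {mu[k]:.4f} +- {sd[k]:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "config": self.config.to_dict(),
            "seeds": self.seeds,
            "repeats": [r.to_dict() for r in self.reports],
            "mean": self.mean(),
            "std": self.std(),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def run_experiment(views: Sequence[OmicsView], labels: LabelSet,
                   config: RunConfig | None = None) -> RunResult:
    """The full protocol: repeated stratified splits, fit, held-out metrics.

    Each repeat draws its split and training seed from an independent
    substream of ``config.seed``, so repeats are reproducible individually
    and adding repeats never changes earlier ones.
    """
    config = config or RunConfig()
    model = MultiOmicsGAT(views, labels, config)
    states = np.random.SeedSequence(config.seed).generate_state(
        2 * config.num_repeats) % (2 ** 31)
    reports, seeds = [], []
    for r in range(config.num_repeats):
        split_seed = int(states[2 * r])
        fit_seed = int(states[2 * r + 1])
        try:
            train_ids, _ = split(model.labels, config.train_fraction,
                                 split_seed)
            res = model.fit(train_ids=train_ids, seed=fit_seed)
            reports.append(res.metrics())
        except Exception as exc:
            raise RuntimeError(f"repeat {r} failed: {exc}") from exc
        seeds.append(fit_seed)
    return RunResult(reports, config, seeds)


def view_combinations(view_names: Sequence[str]) -> list[tuple[str, ...]]:
    """All nonempty view subsets — 7 combinations for three omics types."""
    names = list(view_names)
    out: list[tuple[str, ...]] = []
    for r in range(1, len(names) + 1):
        out.extend(combinations(names, r))
    return out


def stage_pair_datasets(labels: LabelSet) -> list[tuple[str, LabelSet]]:
    """Binary label sets for each adjacent stage pair.

    Stage order follows the (sorted) class-name order of the label set; for
    stages S1..SK this yields K-1 restricted datasets with codes {0, 1}
    (lower stage -> 0).
    """
    if labels.C < 2:
        raise ValueError("need at least two stages")
    out = []
    for t in range(labels.C - 1):
        name_lo, name_hi = labels.class_names[t], labels.class_names[t + 1]
        keep = [(s, c) for s, c in zip(labels.sample_ids, labels.class_codes)
                if c in (t, t + 1)]
        ids = [s for s, _ in keep]
        codes = np.array([0 if c == t else 1 for _, c in keep], dtype=np.int64)
        pair = LabelSet(ids, codes, [name_lo, name_hi])
        out.append((f"{name_lo}-{name_hi}", pair))
    return out
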