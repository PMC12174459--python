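"""Feature-importance ranking and stage-pair biomarker discovery.

The primary importance definition is masking/ablation importance: the drop
in held-out weighted F1 when one feature's (post-normalization) column is
replaced by zeros, the in-domain floor after min-max scaling.  Features that
preprocessing dropped never enter the network and score exactly 0.  A
gradient x input score is available behind ``method="gradient_input"`` and
is reported alongside, never silently substituted.

Stage-pair discovery converts the K-stage problem into K-1 adjacent binary
tasks (Stage_t vs Stage_{t+1}); each pair gets the full train -> mask ->
rank pipeline and its own importance table, so a biomarker specific to one
stage transition surfaces only in that pair's table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .autodiff import Tensor
from .config import RunConfig
from .experiment import split, stage_pair_datasets
from .io import LabelSet, OmicsView
from .metrics import compute_metrics
from .model import MultiOmicsGAT, MultiOmicsGATResults

logger = logging.getLogger(__name__)

__all__ = ["ImportanceTable", "masking_importance", "top_biomarkers",
           "stage_pair_biomarkers"]


@dataclass
class ImportanceTable:
    """Rows of (view, feature, importance, rank) plus run metadata.

    Within each view, ranks run 1..p with no gaps, ordered by descending
    importance with ties broken by feature name.
    """

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"view_name", "feature_name", "importance", "rank"}
        if not required.issubset(self.frame.columns):
            raise ValueError(f"importance table needs columns {sorted(required)}")

    def view(self, view_name: str) -> pd.DataFrame:
        sub = self.frame[self.frame.view_name == view_name]
        return sub.sort_values("rank").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False,
                          columns=["view_name", "feature_name", "importance",
                                   "rank"])


def _rank_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    parts = []
    for _, sub in df.groupby("view_name", sort=False):
        sub = sub.sort_values(["importance", "feature_name"],
                              ascending=[False, True], kind="mergesort")
        sub = sub.assign(rank=np.arange(1, len(sub) + 1))
        parts.append(sub)
    return pd.concat(parts, ignore_index=True)


def _eval_f1(results: MultiOmicsGATResults, probs: list[np.ndarray],
             test_pos: np.ndarray, y_test: np.ndarray) -> float:
    fused = results._fuse(probs)
    pred = fused[test_pos].argmax(axis=1)
    return compute_metrics(y_test, pred, results.model.labels.C).f1_weighted


def masking_importance(results: MultiOmicsGATResults, repeats: int = 1,
                       seed: int = 0,
                       method: str = "masking") -> ImportanceTable:
    """Score every raw input feature of a fitted model.

    masking: importance(f) = baseline test F1_weighted minus the F1_weighted
    with f's column zeroed, averaged over ``repeats`` evaluations (the
    forward pass is deterministic, so repeats matter only for stochastic
    heads; the parameter is kept for contract stability).

    gradient_input: mean over test samples of |d log p(predicted class) / dx
    * x|, a saliency-style alternative.
    """
    if not results.test_ids:
        raise ValueError("importance needs a nonempty held-out test set")
    if method not in ("masking", "gradient_input"):
        raise ValueError(f"unknown importance method {method!r}")
    node_pos = {s: i for i, s in enumerate(results.node_ids)}
    test_pos = np.array([node_pos[s] for s in results.test_ids])
    y_test = results.model.labels.subset(results.test_ids).class_codes

    base_probs = [results._branch_probs(i)
                  for i in range(len(results.branches))]
    baseline = _eval_f1(results, base_probs, test_pos, y_test)

    rows: list[dict] = []
    for vi, raw in enumerate(results.model.views):
        vname = raw.view_name
        kept = results.preprocessor.selections_[vname].kept_feature_names
        kept_pos = {f: j for j, f in enumerate(kept)}
        proc = results.processed[vi].subset_samples(results.node_ids)
        if method == "gradient_input":
            scores = _gradient_input_scores(results, vi, proc, test_pos)
        for fname in raw.feature_names:
            if fname not in kept_pos:
                imp = 0.0  # never entered the network
            elif method == "gradient_input":
                imp = scores[kept_pos[fname]]
            else:
                j = kept_pos[fname]
                drops = []
                for _ in range(max(int(repeats), 1)):
                    X = proc.values.copy()
                    X[:, j] = 0.0
                    probs = list(base_probs)
                    probs[vi] = results._branch_probs(vi, X_override=X)
                    drops.append(baseline -
                                 _eval_f1(results, probs, test_pos, y_test))
                imp = float(np.mean(drops))
            rows.append({"view_name": vname, "feature_name": fname,
                         "importance": imp})
    frame = _rank_frame(rows)
    meta = {"method": method, "baseline_f1_weighted": baseline,
            "repeats": int(repeats), "seed": int(seed),
            "n_test": len(results.test_ids)}
    return ImportanceTable(frame, meta)


def _gradient_input_scores(results: MultiOmicsGATResults, vi: int,
                           proc: OmicsView,
                           test_pos: np.ndarray) -> np.ndarray:
    X = Tensor(proc.values)
    g = results.graphs[vi]
    logits = results.branches[vi](X, g.neighbor_mask)
    logp = ad.log_softmax(logits, axis=-1)
    pred = logp.value.argmax(axis=1)
    picked = ad.gather_rc(ad.take(logp, test_pos, axis=0),
                          np.arange(len(test_pos)), pred[test_pos])
    ad.tsum(picked).backward()
    sal = np.abs(X.grad * proc.values)[test_pos]
    return sal.mean(axis=0)


def top_biomarkers(table: ImportanceTable, k: int) -> pd.DataFrame:
    """Top-k features per view, in rank order (ties already name-broken)."""
    if k < 0:
        raise ValueError("k must be >= 0")
    parts = []
    for vname, sub in table.frame.groupby("view_name", sort=False):
        if k > len(sub):
            logger.warning("top_biomarkers: k=%d exceeds %d features in "
                           "view %r; clipping", k, len(sub), vname)
        parts.append(sub.sort_values("rank").head(k))
    if not parts:
        return table.frame.head(0)
    return pd.concat(parts, ignore_index=True)


def stage_pair_biomarkers(views: Sequence[OmicsView], labels: LabelSet,
                          config: RunConfig | None = None,
                          seed: int | None = None,
                          repeats: int = 1,
                          method: str = "masking"
                          ) -> list[tuple[str, ImportanceTable]]:
    """One importance table per adjacent stage pair.

    Each pair is a fresh binary problem: stratified split, joint training,
    masking importance on the held-out samples.
    """
    config = config or RunConfig()
    if seed is None:
        seed = config.seed
    states = np.random.SeedSequence(seed).generate_state(
        2 * max(labels.C - 1, 1)) % (2 ** 31)
    out = []
    for t, (pair_name, pair_labels) in enumerate(stage_pair_datasets(labels)):
        train_ids, _ = split(pair_labels, config.train_fraction,
                             int(states[2 * t]))
        model = MultiOmicsGAT(views, pair_labels, config)
        # split ids may include samples dropped during view alignment
        train_ids = [s for s in train_ids if s in model.sample_ids]
        res = model.fit(train_ids=train_ids, seed=int(states[2 * t + 1]))
        table = masking_importance(res, repeats=repeats, seed=seed,
                                   method=method)
        table.metadata["stage_pair"] = pair_name
        out.append((pair_name, table))
    return out
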