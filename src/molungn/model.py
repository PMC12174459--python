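"""The multi-omics graph-attention classifier, statsmodels-style.

:class:`MultiOmicsGAT` is built from data (per-view feature tables plus a
label set) and a :class:`~molungn.config.RunConfig`; ``fit()`` runs the joint
end-to-end optimization of every omics branch plus the fusion head and
returns a :class:`MultiOmicsGATResults` carrying the trained parameters, the
per-epoch loss log, predictions, metrics and a ``summary()`` table.

Training minimizes

    L = sum_i L_Ci + delta * L_MOVCDN        (delta = 1 by default)

where each L_Ci is the mean cross-entropy of branch i on the training nodes
and L_MOVCDN is the mean cross-entropy of the fused output.  All parameters
are updated together by Adam at the configured learning rate; losses are
averaged over training samples so the rate is independent of cohort size.

Graph handling is transductive by default: the patient-similarity network is
built over train+test samples jointly, but only training nodes contribute to
the loss.  An inductive mode trains on a training-only graph and attaches
held-out samples by cosine similarity at prediction time, without rebuilding
the adjacency or retraining.
"""

from __future__ import annotations

import json
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import autodiff as ad
from .config import RunConfig
from .fusion import FusionHead, cross_tensor_flat
from .gat import EdgeSet, OSGATBranch
from .graph import PatientGraph, attach_new_samples, build_graph
from .io import LabelSet, OmicsView, align_views
from .metrics import MetricsReport, compute_metrics
from .preprocess import Preprocessor

logger = logging.getLogger(__name__)

__all__ = ["Adam", "MultiOmicsGAT", "MultiOmicsGATResults"]


class Adam:
    """First-order adaptive optimizer over a flat parameter list."""

    def __init__(self, params, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class MultiOmicsGAT:
    """Multi-omics cancer-stage classifier over patient-similarity networks.

    Parameters
    ----------
    views : sequence of OmicsView
        Raw (unpreprocessed) per-omics feature tables.
    labels : LabelSet
        Stage labels; views and labels are aligned on construction.
    config : RunConfig, optional
        Hyperparameters; defaults reproduce the published settings.
    """

    def __init__(self, views: Sequence[OmicsView], labels: LabelSet,
                 config: RunConfig | None = None):
        self.config = config or RunConfig()
        if self.config.views is not None:
            wanted = list(self.config.views)
            by_name = {v.view_name: v for v in views}
            unknown = [w for w in wanted if w not in by_name]
            if unknown:
                raise ValueError(f"unknown view name(s) in config: {unknown}")
            views = [by_name[w] for w in wanted]
        self.views, self.labels = align_views(list(views), labels)
        self.view_names = [v.view_name for v in self.views]

    @classmethod
    def from_dataframes(cls, frames: Mapping[str, pd.DataFrame],
                        labels: pd.Series,
                        config: RunConfig | None = None) -> "MultiOmicsGAT":
        views = [OmicsView.from_frame(df, name) for name, df in frames.items()]
        return cls(views, LabelSet.from_series(labels), config)

    @property
    def sample_ids(self) -> list[str]:
        return self.labels.sample_ids

    # -- fitting ----------------------------------------------------------
    def fit(self, train_ids: Sequence[str] | None = None,
            seed: int | None = None) -> "MultiOmicsGATResults":
        """Jointly train all branches and the fusion head.

        ``train_ids`` defaults to every sample (pure transductive fit with no
        held-out set).  ``seed`` drives parameter initialization and dropout;
        identical seeds give bitwise-identical results.
        """
        cfg = self.config
        if seed is None:
            seed = cfg.seed
        if train_ids is None:
            train_ids = list(self.sample_ids)
        train_ids = [str(s) for s in train_ids]
        train_set = set(train_ids)
        unknown = train_set - set(self.sample_ids)
        if unknown:
            raise ValueError(f"train ids not in the cohort: {sorted(unknown)[:5]}")
        test_ids = [s for s in self.sample_ids if s not in train_set]

        pre = Preprocessor(cfg.max_zero_fraction, cfg.max_missing_fraction,
                           cfg.feature_fraction, cfg.feature_cap)
        processed = pre.fit_transform(self.views, self.labels, train_ids)

        train_pos = [i for i, s in enumerate(self.sample_ids) if s in train_set]
        if cfg.graph_mode == "inductive":
            node_ids = list(train_ids)
        else:
            node_ids = list(self.sample_ids)
        node_views = [v.subset_samples(node_ids) for v in processed]
        graphs = [build_graph(v, cfg.avg_degree) for v in node_views]
        train_graphs = [build_graph(v.subset_samples(
            [s for s in v.sample_ids if s in train_set]), cfg.avg_degree)
            for v in processed]

        node_pos = {s: i for i, s in enumerate(node_ids)}
        train_rows = np.array([node_pos[s] for s in train_ids
                               if s in node_pos])
        y = self.labels.subset(node_ids).class_codes
        y_train = y[train_rows]

        root = np.random.SeedSequence(seed)
        init_ss, drop_ss = root.spawn(2)
        init_rng = np.random.default_rng(init_ss)
        drop_rng = np.random.default_rng(drop_ss)

        C = self.labels.C
        m = len(self.views)
        dtype = np.dtype(cfg.compute_dtype).type
        branches = [OSGATBranch(v.n_features, C, init_rng,
                                hidden_dims=cfg.hidden_dims,
                                num_heads=cfg.num_heads,
                                attention_layers=cfg.attention_layers,
                                fc_dims=cfg.fc_dims, dropout=cfg.dropout,
                                slope=cfg.leaky_slope, dtype=dtype)
                    for v in node_views]
        use_fusion = cfg.use_vcdn and m >= 2
        head = FusionHead(C, m, cfg.vcdn_features, init_rng,
                          cfg.leaky_slope, dtype=dtype) if use_fusion else None

        params = [p for b in branches for p in b.parameters()]
        if head is not None:
            params += head.parameters()
        opt = Adam(params, cfg.learning_rate)

        X_nodes = [v.values.astype(dtype) for v in node_views]
        masks = [EdgeSet(g.neighbor_mask) for g in graphs]
        log_rows = []
        total_epochs = cfg.pretrain_epochs + cfg.num_epochs
        for epoch in range(total_epochs):
            opt.zero_grad()
            branch_losses = []
            probs = []
            for X, mask, branch in zip(X_nodes, masks, branches):
                logits = branch(X, mask, train_rng=drop_rng)
                logp = ad.log_softmax(logits, axis=-1)
                picked = ad.gather_rc(ad.take(logp, train_rows, axis=0),
                                      np.arange(len(train_rows)), y_train)
                branch_losses.append(ad.mul(ad.tmean(picked), -1.0))
                probs.append(ad.exp(logp))
            loss = branch_losses[0]
            for bl in branch_losses[1:]:
                loss = ad.add(loss, bl)
            fusion_loss_val = np.nan
            if head is not None and epoch >= cfg.pretrain_epochs:
                flat = cross_tensor_flat(probs)
                flogits = head(flat)
                flogp = ad.log_softmax(flogits, axis=-1)
                fpicked = ad.gather_rc(ad.take(flogp, train_rows, axis=0),
                                       np.arange(len(train_rows)), y_train)
                floss = ad.mul(ad.tmean(fpicked), -1.0)
                fusion_loss_val = float(floss.value)
                loss = ad.add(loss, ad.mul(floss, cfg.delta))
            total = float(loss.value)
            if not np.isfinite(total):
                raise FloatingPointError(
                    f"training loss became non-finite at epoch {epoch}")
            loss.backward()
            opt.step()
            log_rows.append({"epoch": epoch,
                             **{f"loss_{v}": float(bl.value)
                                for v, bl in zip(self.view_names, branch_losses)},
                             "loss_fusion": fusion_loss_val,
                             "loss_total": total})
        training_log = pd.DataFrame(log_rows)
        return MultiOmicsGATResults(self, pre, processed, graphs, train_graphs,
                                    branches, head, train_ids, test_ids,
                                    seed, training_log)


class MultiOmicsGATResults:
    """Fitted-model container: predictions, metrics, diagnostics, summary."""

    def __init__(self, model: MultiOmicsGAT, preprocessor: Preprocessor,
                 processed: list[OmicsView], graphs: list[PatientGraph],
                 train_graphs: list[PatientGraph],
                 branches: list[OSGATBranch], head: FusionHead | None,
                 train_ids: list[str], test_ids: list[str], seed: int,
                 training_log: pd.DataFrame):
        self.model = model
        self.config = model.config
        self.preprocessor = preprocessor
        self.processed = processed
        self.graphs = graphs
        self.train_graphs = train_graphs
        self.branches = branches
        self.head = head
        self.train_ids = train_ids
        self.test_ids = test_ids
        self.seed = seed
        self.training_log = training_log
        self._cache: dict | None = None

    # -- forward evaluation ------------------------------------------------
    @property
    def node_ids(self) -> list[str]:
        return self.graphs[0].sample_ids

    def _branch_probs(self, view_idx: int,
                      X_override: np.ndarray | None = None) -> np.ndarray:
        g = self.graphs[view_idx]
        if not hasattr(self, "_edge_sets"):
            self._edge_sets = [EdgeSet(gr.neighbor_mask) for gr in self.graphs]
        X = self.processed[view_idx].subset_samples(g.sample_ids).values \
            if X_override is None else X_override
        X = X.astype(self.branches[view_idx].head.W.value.dtype, copy=False)
        logits = self.branches[view_idx](X, self._edge_sets[view_idx])
        return np.exp(ad.log_softmax(logits, axis=-1).value)

    def _fuse(self, probs: list[np.ndarray]) -> np.ndarray:
        if self.head is None:
            return np.mean(probs, axis=0)
        flat = cross_tensor_flat(probs)
        return np.exp(ad.log_softmax(self.head(flat), axis=-1).value)

    def _evaluate(self) -> dict:
        if self._cache is None:
            probs = [self._branch_probs(i) for i in range(len(self.branches))]
            self._cache = {"view_probs": probs, "fused": self._fuse(probs)}
        return self._cache

    # -- public surface ----------------------------------------------------
    def view_probabilities(self) -> dict[str, pd.DataFrame]:
        ev = self._evaluate()
        names = self.model.labels.class_names
        return {v: pd.DataFrame(p, index=self.node_ids, columns=names)
                for v, p in zip(self.model.view_names, ev["view_probs"])}

    def predict_proba(self, mode: str = "transductive") -> pd.DataFrame:
        """Final class distribution per sample.

        In transductive mode (default) every node of the fitted graph is
        scored.  ``mode='inductive'`` re-scores the held-out samples by
        attaching them to the training graph instead.
        """
        names = self.model.labels.class_names
        if mode == "transductive":
            ev = self._evaluate()
            return pd.DataFrame(ev["fused"], index=self.node_ids, columns=names)
        if mode != "inductive":
            raise ValueError("mode must be 'transductive' or 'inductive'")
        held = [v.subset_samples(self.test_ids) for v in self.processed]
        return self.predict_proba_inductive(held, preprocessed=True)

    def predict_proba_inductive(self, new_views: Sequence[OmicsView],
                                preprocessed: bool = False) -> pd.DataFrame:
        """Score unseen samples against the training nodes only."""
        by_name = {v.view_name: v for v in new_views}
        probs = []
        new_ids = None
        for vi, vname in enumerate(self.model.view_names):
            if vname not in by_name:
                raise ValueError(f"missing view {vname!r} for inductive "
                                 "prediction")
            nv = by_name[vname]
            if not preprocessed:
                nv = self.preprocessor.transform_new(nv)
            new_ids = nv.sample_ids
            tg = self.train_graphs[vi]
            train_X = self.processed[vi].subset_samples(tg.sample_ids).values
            combined = attach_new_samples(tg, train_X, nv.values, nv.sample_ids)
            logits = self.branches[vi](np.vstack([train_X, nv.values]),
                                       combined.neighbor_mask)
            p = np.exp(ad.log_softmax(logits, axis=-1).value)
            probs.append(p[len(tg.sample_ids):])
        fused = self._fuse(probs)
        return pd.DataFrame(fused, index=new_ids,
                            columns=self.model.labels.class_names)

    def predict(self, ids: Sequence[str] | None = None,
                mode: str = "transductive") -> pd.Series:
        """Predicted class codes; argmax ties resolve to the lowest code."""
        proba = self.predict_proba(mode=mode)
        if ids is not None:
            proba = proba.loc[list(ids)]
        codes = proba.to_numpy().argmax(axis=1)
        return pd.Series(codes, index=proba.index, name="predicted_code")

    def metrics(self, ids: Sequence[str] | None = None) -> MetricsReport:
        """Metrics on ``ids`` (default: the held-out test set)."""
        if ids is None:
            ids = self.test_ids if self.test_ids else self.node_ids
        ids = list(ids)
        pred = self.predict(ids).to_numpy()
        truth = self.model.labels.subset(ids).class_codes
        return compute_metrics(truth, pred, self.model.labels.C)

    def feature_importance(self, method: str = "masking", repeats: int = 1,
                           seed: int = 0):
        from .biomarker import masking_importance
        return masking_importance(self, repeats=repeats, seed=seed,
                                  method=method)

    def summary(self) -> str:
        cfg = self.config
        lines = [
            "Multi-omics graph-attention classifier".center(60),
            "=" * 60,
            f"views:            {', '.join(self.model.view_names)}",
            f"classes (C):      {self.model.labels.C} "
            f"({', '.join(self.model.labels.class_names)})",
            f"samples:          {len(self.node_ids)} "
            f"(train {len(self.train_ids)}, test {len(self.test_ids)})",
            f"fusion:           {'MOVCDN tensor head' if self.head else 'branch average'}",
            f"epochs/lr:        {cfg.num_epochs} @ {cfg.learning_rate}",
            f"heads/hidden:     {cfg.num_heads}/{cfg.hidden_dims}",
            f"seed:             {self.seed}",
        ]
        if len(self.training_log):
            lines += ["-" * 60,
                      f"final total loss: "
                      f"{self.training_log['loss_total'].iloc[-1]:.4f}"]
        if self.test_ids:
            rep = self.metrics()
            lines += ["-" * 60, "held-out metrics:", rep.summary()]
        return "\n".join(lines)

    def plot_training(self, ax=None):
        """Loss curves per branch and for the fusion head."""
        import matplotlib.pyplot as plt
        if ax is None:
            _, ax = plt.subplots()
        for col in self.training_log.columns:
            if col.startswith("loss_"):
                ax.plot(self.training_log["epoch"], self.training_log[col],
                        label=col[5:])
        ax.set_xlabel("epoch")
        ax.set_ylabel("cross-entropy")
        ax.legend()
        return ax

    # -- persistence -------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: parameter arrays + JSON metadata."""
        arrays = {}
        for vi, b in enumerate(self.branches):
            for pi, p in enumerate(b.parameters()):
                arrays[f"branch{vi}_p{pi}"] = p.value
        if self.head is not None:
            for pi, p in enumerate(self.head.parameters()):
                arrays[f"head_p{pi}"] = p.value
        meta = {
            "config": self.config.to_dict(),
            "seed": self.seed,
            "train_ids": self.train_ids,
            "class_names": self.model.labels.class_names,
            "view_names": self.model.view_names,
            "kept_features": {v: s.kept_feature_names
                              for v, s in self.preprocessor.selections_.items()},
        }
        arrays["_meta"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path, views: Sequence[OmicsView],
             labels: LabelSet) -> "MultiOmicsGATResults":
        """Rebuild a fitted model from a checkpoint plus the original data."""
        with np.load(path) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            arrays = {k: data[k] for k in data.files if k != "_meta"}
        config = RunConfig.from_dict(meta["config"])
        # build the identical structure without optimizing, then restore weights
        model = MultiOmicsGAT(views, labels,
                              config.updated(num_epochs=0, pretrain_epochs=0))
        res = model.fit(train_ids=meta["train_ids"], seed=meta["seed"])
        model.config = config
        res.config = config
        for vi, b in enumerate(res.branches):
            for pi, p in enumerate(b.parameters()):
                p.value = arrays[f"branch{vi}_p{pi}"]
        if res.head is not None:
            for pi, p in enumerate(res.head.parameters()):
                p.value = arrays[f"head_p{pi}"]
        res._cache = None
        return res
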