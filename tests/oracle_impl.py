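"""Independent straight-line oracles used by the test suite.

Everything here is deliberately written as plain loops over nodes, heads and
edges — no shared code with the package's vectorized/fused implementations —
so agreement between the two is evidence of correctness, not tautology.
"""

import numpy as np


def oracle_layer_norm(x, eps=1e-5):
    out = np.empty_like(x, dtype=float)
    for i in range(x.shape[0]):
        row = x[i]
        out[i] = (row - row.mean()) / np.sqrt(row.var() + eps)
    return out


def oracle_branch_forward(X, mask, branch):
    """Re-derive the whole branch with scalar-ish numpy: FC reducer,
    multi-head attention layers (concat then averaged), class head, softmax.
    """
    H = np.asarray(X, dtype=float)
    # -- reducer: affine -> ReLU -> layer norm, three times, no dropout
    for lin in branch.reducer.layers:
        H = np.maximum(H @ lin.W.value + lin.b.value, 0.0)
        H = oracle_layer_norm(H)
    # -- attention layers
    for layer in branch.layers:
        K, F = layer.heads, layer.out_dim
        n = H.shape[0]
        W = layer.head_weights          # (K, in, F)
        a = layer.a.value               # (K, 2F, 1)
        head_outs = np.zeros((K, n, F))
        for k in range(K):
            Wh = H @ W[k]
            for i in range(n):
                neigh = [j for j in range(n) if mask[i, j]]
                scores = []
                for j in neigh:
                    concat = np.concatenate([Wh[i], Wh[j]])
                    s = float(concat @ a[k][:, 0])
                    scores.append(s if s > 0 else layer.slope * s)
                scores = np.array(scores)
                w = np.exp(scores - scores.max())
                w = w / w.sum()
                head_outs[k, i] = sum(w[t] * Wh[j]
                                      for t, j in enumerate(neigh))
        if layer.concat_heads:
            H = head_outs.transpose(1, 0, 2).reshape(n, K * F)
        else:
            H = head_outs.mean(axis=0)
        if layer.activation == "elu":
            H = np.where(H > 0, H, np.expm1(np.minimum(H, 0.0)))
    logits = H @ branch.head.W.value + branch.head.b.value
    probs = np.empty_like(logits)
    for i in range(logits.shape[0]):
        z = np.exp(logits[i] - logits[i].max())
        probs[i] = z / z.sum()
    return probs


def oracle_metrics(y_true, y_pred, C):
    """Brute-force confusion-matrix metrics with explicit loops."""
    n = len(y_true)
    cm = [[0] * C for _ in range(C)]
    for t, p in zip(y_true, y_pred):
        cm[t][p] += 1
    acc = sum(cm[i][i] for i in range(C)) / n
    recalls, precisions, f1s, supports = [], [], [], []
    for i in range(C):
        support = sum(cm[i])
        predicted = sum(cm[j][i] for j in range(C))
        rec = cm[i][i] / support if support else 0.0
        prec = cm[i][i] / predicted if predicted else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
        recalls.append(rec)
        precisions.append(prec)
        f1s.append(f1)
        supports.append(support)
    rec_w = sum(supports[i] / n * recalls[i] for i in range(C))
    f1_macro = sum(f1s) / C
    f1_w = sum(supports[i] / n * f1s[i] for i in range(C))
    return {"accuracy": acc, "recall_weighted": rec_w,
            "f1_macro": f1_macro, "f1_weighted": f1_w}


def oracle_fusion_forward(tensor, head):
    """Two-layer fusion head by hand: affine, LeakyReLU, affine, softmax."""
    x = np.asarray(tensor, dtype=float).ravel()
    h = x @ head.fc1.W.value + head.fc1.b.value
    h = np.where(h > 0, h, head.slope * h)
    z = h @ head.fc2.W.value + head.fc2.b.value
    e = np.exp(z - z.max())
    return e / e.sum()
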