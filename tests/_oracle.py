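"""Literal per-node double-loop reference of the link-aware attention pass.

Transcribes the propagation rule one node at a time with plain Python loops
and float arithmetic — no batching, no shared code with the package's
vectorized forward — so it can serve as an independent oracle: for every
(depth, position) in the sampled tree, compute inner-product attention
logits against the partner-drug query, normalize, aggregate, apply
LeakyReLU(0.1), and repeat for H rounds.
"""

import math

import numpy as np


def _leaky(x, alpha=0.1):
    return np.where(x >= 0, x, alpha * x)


def _side(sub, partner_root, params, sentinel):
    cfg = params.config
    E = params["embedding"].data
    H, K = cfg.hop, cfg.neighbor_samples
    q = E[partner_root].copy()
    nodes = {(0, 0): int(sub.root)}
    for t in range(1, H + 1):
        for p, n in enumerate(sub.layers[t - 1].reshape(-1)):
            nodes[(t, p)] = int(n)
    z = {key: E[n].copy() for key, n in nodes.items()}
    roots = [z[(0, 0)].copy()]
    for h in range(1, H + 1):
        new = {}
        for t in range(H - h + 1):
            for p in range(K**t):
                neigh_keys = [(t + 1, p * K + j) for j in range(K)]
                nbr_nodes = [nodes[key] for key in neigh_keys]
                nbr_vecs = [z[key] for key in neigh_keys]
                mask = [n != sentinel for n in nbr_nodes]
                if cfg.attention == "gat_const":
                    cnt = sum(mask)
                    w = [(1.0 / cnt if m else 0.0) for m in mask] if cnt else [0.0] * K
                else:
                    logits = [float(q @ v) for v in nbr_vecs]
                    if cfg.raw_attention:
                        w = [l if m else 0.0 for l, m in zip(logits, mask)]
                    else:
                        live = [l for l, m in zip(logits, mask) if m]
                        mx = max(live) if live else 0.0
                        es = [
                            math.exp(l - mx) if m else 0.0
                            for l, m in zip(logits, mask)
                        ]
                        s = sum(es)
                        w = [(e / s if s > 0 else 0.0) for e in es]
                z_n = np.zeros(cfg.dim)
                for wi, vi in zip(w, nbr_vecs):
                    z_n = z_n + wi * vi
                W, b = params.agg_weight(h - 1)
                if cfg.aggregator == "concat":
                    pre = np.concatenate([z[(t, p)], z_n]) @ W.data + b.data
                else:
                    pre = z_n @ W.data + b.data
                new[(t, p)] = _leaky(pre)
        z = new
        roots.append(z[(0, 0)].copy())
    return np.concatenate(roots) if cfg.layer_agg else roots[-1]


def reference_forward(pair, sub_u, sub_v, params, sentinel):
    """Return (z_u, z_v, score) computed by the literal double-loop rule."""
    cfg = params.config
    z_u = _side(sub_u, pair[1], params, sentinel)
    z_v = _side(sub_v, pair[0], params, sentinel)
    if cfg.num_classes == 2:
        score = 1.0 / (1.0 + math.exp(-float(z_u @ z_v)))
    else:
        feats = np.concatenate([z_u, z_v])
        hidden = _leaky(feats @ params["head_W1"].data + params["head_b1"].data)
        logits = hidden @ params["head_W2"].data + params["head_b2"].data
        e = np.exp(logits - logits.max())
        score = e / e.sum()
    return z_u, z_v, score
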