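"""Brute-force loop oracles shared by the acceptance checks.

Deliberately written with explicit Python loops and none of the package's
vectorised code paths."""

import numpy as np


def prs_loop_oracle(values, prs):
    out = []
    for row in values:
        s = prs.intercept
        for i, w in enumerate(prs.additive_weights):
            s += w * row[i]
        for t in prs.interactions:
            ga, gb = row[t.index_a], row[t.index_b]
            if t.mode == "product":
                s += t.weight * ga * gb
            elif round(ga) == t.required_state_a and round(gb) == t.required_state_b:
                s += t.weight
        out.append(s)
    return np.array(out)


def forward_loop_oracle(net, X):
    acts = net.spec.activations
    out = []
    for x in X:
        v = list(x)
        for l, (W, b) in enumerate(zip(net.weights, net.biases)):
            if net.spec.skip_input_to_last_hidden and l == net.n_layers - 1:
                v = v + list(x)
            z = []
            for j in range(W.shape[1]):
                acc = b[j]
                for i in range(W.shape[0]):
                    acc += v[i] * W[i, j]
                z.append(acc)
            if acts[l] == "relu":
                v = [max(0.0, u) for u in z]
            elif acts[l] == "linear":
                v = z
            else:
                v = [2.0 / (1.0 + np.exp(-u)) for u in z]
        out.append(v)
    return np.array(out)


def auc_pairwise_oracle(pos, neg):
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _ranks(v):
    ranks = []
    for x in v:
        less = sum(1 for u in v if u < x)
        equal = sum(1 for u in v if u == x)
        ranks.append(less + (equal + 1) / 2.0)
    return np.array(ranks)


def spearman_rank_oracle(a, b):
    ra, rb = _ranks(list(a)), _ranks(list(b))
    ra = ra - ra.mean()
    rb = rb - rb.mean()
    return float(np.sum(ra * rb) / np.sqrt(np.sum(ra**2) * np.sum(rb**2)))
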