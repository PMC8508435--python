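"""Pure-loop reference implementations of the capsule arithmetic.

Deliberately slow, scalar-level implementations used as independent
oracles by the test suite and the ``routing-selftest`` command.  They
share no code path with :mod:`melcaps.capsule_core` beyond numpy scalars.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["squash_loop", "votes_loop", "dynamic_routing_loop", "mcc_loop", "auc_pairs"]


def squash_loop(s: np.ndarray) -> np.ndarray:
    s = np.asarray(s, dtype=float)
    out = np.zeros_like(s)
    for i in range(s.shape[0]):
        n2 = sum(float(x) * float(x) for x in s[i])
        n = math.sqrt(n2)
        if n == 0.0:
            continue
        for d in range(s.shape[1]):
            out[i, d] = (n2 / (1.0 + n2)) * (s[i, d] / n)
    return out


def votes_loop(u: np.ndarray, W: np.ndarray) -> np.ndarray:
    n_in, n_out, d_in, d_out = W.shape
    votes = np.zeros((n_in, n_out, d_out))
    for i in range(n_in):
        for j in range(n_out):
            for e in range(d_out):
                acc = 0.0
                for d in range(d_in):
                    acc += W[i, j, d, e] * u[i, d]
                votes[i, j, e] = acc
    return votes


def dynamic_routing_loop(votes: np.ndarray, iterations: int):
    """Routing-by-agreement with explicit loops: softmax over output
    capsules, weighted aggregation, squash, agreement update b += u_hat.v
    on every iteration but the last."""
    n_in, n_out, d_out = votes.shape
    b = np.zeros((n_in, n_out))
    v = np.zeros((n_out, d_out))
    c = np.zeros((n_in, n_out))
    for r in range(iterations):
        for i in range(n_in):
            mx = max(b[i, j] for j in range(n_out))
            exps = [math.exp(b[i, j] - mx) for j in range(n_out)]
            tot = sum(exps)
            for j in range(n_out):
                c[i, j] = exps[j] / tot
        s = np.zeros((n_out, d_out))
        for j in range(n_out):
            for e in range(d_out):
                s[j, e] = sum(c[i, j] * votes[i, j, e] for i in range(n_in))
        v = squash_loop(s)
        if r < iterations - 1:
            for i in range(n_in):
                for j in range(n_out):
                    b[i, j] += sum(votes[i, j, e] * v[j, e] for e in range(d_out))
    return v, c


def mcc_loop(tp: int, tn: int, fp: int, fn: int) -> float:
    num = tp * tn - fp * fn
    den = math.sqrt(tp + fp) * math.sqrt(tp + fn) * math.sqrt(tn + fp) * math.sqrt(tn + fn)
    if den == 0:
        return 0.0
    return num / den


def auc_pairs(y_true, scores) -> float:
    """AUC by explicit pair counting: concordant pairs count 1, ties 1/2."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = scores[y_true == 1]
    neg = scores[y_true == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes required")
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
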