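"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written by a different route than the
package code: exhaustive enumeration, direct definitions, and a plain
einsum/loop forward pass for the network.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMP = str.maketrans("ACGT", "TGCA")


def rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


def is_pal(sub: str, mode: str) -> bool:
    """Direct definition: equality with the reverse complement."""
    n = len(sub)
    if n % 2 == 0:
        return n > 0 and sub == rc(sub)
    if mode != "center-gapped":
        return False
    h = n // 2
    return sub[:h] == rc(sub[h + 1 :])


def all_palindromic_spans(s: str, mode: str) -> set[tuple[int, int]]:
    """Every palindromic substring span, by vectorized all-substrings scan."""
    a = np.frombuffer(s.encode(), dtype=np.uint8)
    comp = np.frombuffer(rc(s)[::-1].encode(), dtype=np.uint8)  # complement, unreversed
    n = a.size
    spans: set[tuple[int, int]] = set()
    for length in range(2, n + 1):
        if mode == "strict" and length % 2:
            continue
        sub = sliding_window_view(a, length)
        sub_rc = sliding_window_view(comp, length)[:, ::-1]
        if length % 2 == 0:
            ok = (sub == sub_rc).all(axis=1)
        else:
            h = length // 2
            ok = (sub[:, :h] == sub_rc[:, :h]).all(axis=1)
        for i in np.flatnonzero(ok):
            spans.add((int(i), int(i) + length))
    return spans


def brute_maximal_palindromes(s: str, min_len: int, mode: str) -> list[tuple[int, int]]:
    """Maximal palindromic substrings ≥ min_len via exhaustive enumeration.

    A span is maximal when extending it by one base on both ends leaves the
    sequence or breaks the palindrome predicate.
    """
    spans = all_palindromic_spans(s, mode)
    out = [
        (a, b)
        for (a, b) in spans
        if b - a >= min_len and not (a > 0 and b < len(s) and (a - 1, b + 1) in spans)
    ]
    return sorted(out)


def auc_pair_counting(preds, labels) -> float:
    """AUC as the Mann–Whitney pair statistic, ties counting one half."""
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = preds[labels == 1]
    neg = preds[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (pos.size * neg.size)


def ap_direct(preds, labels) -> float:
    """Average precision as Σ (Rₙ − Rₙ₋₁)·Pₙ down the ranked list."""
    preds = np.asarray(preds, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-preds, kind="stable")
    y = labels[order]
    p_total = y.sum()
    ap = 0.0
    prev_recall = 0.0
    tp = 0
    # group by distinct thresholds (tied predictions are one operating point)
    sorted_preds = preds[order]
    i = 0
    n = y.size
    while i < n:
        j = i
        while j < n and sorted_preds[j] == sorted_preds[i]:
            j += 1
        tp += y[i:j].sum()
        precision = tp / j
        recall = tp / p_total
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return float(ap)


def delong_permutation_p(preds_a, preds_b, labels, n_reps: int = 10000, seed: int = 0) -> float:
    """Paired permutation test of equal AUCs: per sample, the two models'
    predictions are exchanged with probability 1/2 under the null."""
    preds = np.stack([np.asarray(preds_a, float), np.asarray(preds_b, float)])
    labels = np.asarray(labels, dtype=int)

    def auc(p):
        return auc_rank(p, labels)

    observed = abs(auc(preds[0]) - auc(preds[1]))
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_reps):
        flip = rng.integers(0, 2, size=labels.size).astype(bool)
        a = np.where(flip, preds[1], preds[0])
        b = np.where(flip, preds[0], preds[1])
        if abs(auc(a) - auc(b)) >= observed - 1e-12:
            count += 1
    return count / n_reps


def auc_rank(preds, labels) -> float:
    from scipy.stats import rankdata

    preds = np.asarray(preds, float)
    labels = np.asarray(labels, int)
    r = rankdata(preds)
    m = int(labels.sum())
    n = labels.size - m
    return float((r[labels == 1].sum() - m * (m + 1) / 2) / (m * n))


# ---------------------------------------------------------------------------
# independent network forward pass


def _conv1d_direct(x: np.ndarray, w: np.ndarray, b: np.ndarray, kernel: int,
                   pad: tuple[int, int]) -> np.ndarray:
    """Direct einsum convolution: x (L, C), w (k*C, F) -> (L_out, F)."""
    xp = np.pad(x, (pad, (0, 0)))
    l_out = xp.shape[0] - kernel + 1
    wk = w.reshape(kernel, -1, w.shape[1])  # (k, C, F)
    out = np.zeros((l_out, w.shape[1]))
    for j in range(kernel):
        out += np.einsum("lc,cf->lf", xp[j : j + l_out], wk[j])
    return out + b


def _bn_inference(x, layer):
    return layer.gamma * (x - layer.running_mean) / np.sqrt(layer.running_var + layer.eps) \
        + layer.beta


def masked_forward_oracle(model, x_one: np.ndarray, mask: np.ndarray) -> float:
    """Inference-mode forward pass with stem occlusion, recomputed outside
    the model object from its raw weights (float64, direct loops)."""
    spec = model.spec
    k = spec.kernel_width
    h = _conv1d_direct(x_one.astype(np.float64), model.stem_conv.w.astype(np.float64),
                       model.stem_conv.b.astype(np.float64), k, (0, 0))
    h = np.maximum(_bn_inference(h, model.stem_bn), 0)
    h = h.copy()
    h[np.asarray(mask, bool)] = 0.0
    pad = ((k - 1) // 2, k // 2)
    for block in model.blocks:
        g = _conv1d_direct(h, block.conv1.w.astype(np.float64),
                           block.conv1.b.astype(np.float64), k, pad)
        g = np.maximum(_bn_inference(g, block.bn1), 0)
        g = _conv1d_direct(g, block.conv2.w.astype(np.float64),
                           block.conv2.b.astype(np.float64), k, pad)
        g = np.maximum(_bn_inference(g, block.bn2), 0)
        h = g + h if block.skip else g
    flat = h.reshape(-1)
    d = np.maximum(flat @ model.dense1.w.astype(np.float64) + model.dense1.b, 0)
    z = float((d @ model.head.w.astype(np.float64) + model.head.b)[0])
    return 1.0 / (1.0 + np.exp(-z))
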