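"""Independent loop-level oracles shared by the test modules."""

import numpy as np


def oracle_fusion(member_arrays, include_self=True):
    """Direct translation of the 4-step ensemble combination rule.

    Explicit loops throughout; kept independent of the package implementation.
    """
    K = len(member_arrays)
    flat = [np.asarray(m, float).ravel() for m in member_arrays]
    corr = np.full((K, K), np.nan)
    for i in range(K):
        for j in range(K):
            si, sj = np.std(flat[i]), np.std(flat[j])
            tol_i = 1e-12 * max(1.0, np.abs(flat[i]).max())
            tol_j = 1e-12 * max(1.0, np.abs(flat[j]).max())
            if si > tol_i and sj > tol_j:
                corr[i, j] = np.mean(
                    (flat[i] - flat[i].mean()) * (flat[j] - flat[j].mean())
                ) / (si * sj)
    off = [corr[i, j] for i in range(K) for j in range(K) if i != j and np.isfinite(corr[i, j])]
    thr = min(0.8, 0.9 * max(off)) if off else 0.8
    n = np.zeros(K, dtype=int)
    for i in range(K):
        if not np.isfinite(corr[i, i]):
            continue
        for j in range(K):
            if not include_self and i == j:
                continue
            if np.isfinite(corr[i, j]) and corr[i, j] > thr:
                n[i] += 1
    total = n.sum()
    if total == 0:
        valid = np.array([np.isfinite(corr[i, i]) for i in range(K)])
        w = valid / max(valid.sum(), 1)
    else:
        w = n / total
    fused_prob = sum(wi * m for wi, m in zip(w, member_arrays))
    return w, n, fused_prob >= 0.5
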