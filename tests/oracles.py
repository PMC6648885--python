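"""Independent brute-force reference implementations for the texture stage.

Everything here is written as plain nested loops over voxels, deliberately
sharing no code with the package's vectorized implementations, so agreement
on random inputs is a meaningful check.
"""

from __future__ import annotations

import numpy as np


def _in_bounds(idx, shape):
    return all(0 <= i < n for i, n in zip(idx, shape))


def _neighbors26(idx):
    x, y, z = idx
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if dx == dy == dz == 0:
                    continue
                yield (x + dx, y + dy, z + dz)


def brute_glcm(levels, mask, ng, offset):
    """Symmetrized co-occurrence counts by exhaustive ordered-pair scan."""
    P = np.zeros((ng, ng))
    shape = mask.shape
    for idx in np.argwhere(mask):
        j = tuple(idx + np.array(offset))
        i = tuple(idx)
        if _in_bounds(j, shape) and mask[j]:
            P[levels[i] - 1, levels[j] - 1] += 1
    return P + P.T


def brute_glrlm(levels, mask, ng, offset):
    """Run-length counts by walking each line voxel by voxel."""
    off = np.array(offset)
    shape = mask.shape
    runs = []
    for idx in np.argwhere(mask):
        prev = tuple(idx - off)
        cur = tuple(idx)
        # run starts where the predecessor is outside the VOI or differs
        if (
            _in_bounds(prev, shape)
            and mask[prev]
            and levels[prev] == levels[cur]
        ):
            continue
        length = 1
        nxt = tuple(idx + off)
        while _in_bounds(nxt, shape) and mask[nxt] and levels[nxt] == levels[cur]:
            length += 1
            nxt = tuple(np.array(nxt) + off)
        runs.append((levels[cur] - 1, length))
    max_len = max((l for _, l in runs), default=1)
    P = np.zeros((ng, max_len))
    for lv, l in runs:
        P[lv, l - 1] += 1
    return P


def brute_glszm(levels, mask, ng):
    """Size-zone counts by explicit flood fill with 26-connectivity."""
    seen = np.zeros(mask.shape, dtype=bool)
    zones = []
    for start in map(tuple, np.argwhere(mask)):
        if seen[start]:
            continue
        level = levels[start]
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            cur = stack.pop()
            size += 1
            for nb in _neighbors26(cur):
                if (
                    _in_bounds(nb, mask.shape)
                    and mask[nb]
                    and not seen[nb]
                    and levels[nb] == level
                ):
                    seen[nb] = True
                    stack.append(nb)
        zones.append((level - 1, size))
    max_size = max((s for _, s in zones), default=1)
    P = np.zeros((ng, max_size))
    for lv, s in zones:
        P[lv, s - 1] += 1
    return P


def brute_gldm(levels, mask, ng):
    """Dependence counts: equal-level in-VOI 26-neighbours per voxel."""
    deps = []
    for idx in map(tuple, np.argwhere(mask)):
        dep = 0
        for nb in _neighbors26(idx):
            if _in_bounds(nb, mask.shape) and mask[nb] and levels[nb] == levels[idx]:
                dep += 1
        deps.append((levels[idx] - 1, dep))
    max_dep = max((d for _, d in deps), default=0)
    P = np.zeros((ng, max_dep + 1))
    for lv, d in deps:
        P[lv, d] += 1
    return P


def brute_ngtdm(levels, mask, ng):
    """Per-level (s_i, n_i) by direct neighbour averaging."""
    s = np.zeros(ng)
    n = np.zeros(ng)
    for idx in map(tuple, np.argwhere(mask)):
        nb_levels = [
            levels[nb]
            for nb in _neighbors26(idx)
            if _in_bounds(nb, mask.shape) and mask[nb]
        ]
        if not nb_levels:
            continue
        lv = levels[idx]
        s[lv - 1] += abs(lv - sum(nb_levels) / len(nb_levels))
        n[lv - 1] += 1
    return s, n


def brute_pairwise_auc(scores, truth):
    """AUC as the fraction of concordant positive/negative pairs."""
    pos = [s for s, t in zip(scores, truth) if t == 1]
    neg = [s for s, t in zip(scores, truth) if t == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))
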