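"""Brute-force reference implementations used as independent oracles.

Everything here is deliberately naive — direct loops and exhaustive
enumeration — and must stay independent of the package code paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def flood_fill_label(mask: np.ndarray, connectivity: int = 2) -> np.ndarray:
    """Connected-component labelling by explicit stack-based flood fill."""
    mask = np.asarray(mask, dtype=bool)
    labels = np.zeros(mask.shape, dtype=np.int32)
    if connectivity == 2:
        neigh = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                 if (dr, dc) != (0, 0)]
    else:
        neigh = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    current = 0
    h, w = mask.shape
    for r0 in range(h):
        for c0 in range(w):
            if mask[r0, c0] and labels[r0, c0] == 0:
                current += 1
                stack = [(r0, c0)]
                labels[r0, c0] = current
                while stack:
                    r, c = stack.pop()
                    for dr, dc in neigh:
                        rr, cc = r + dr, c + dc
                        if 0 <= rr < h and 0 <= cc < w and mask[rr, cc] \
                                and labels[rr, cc] == 0:
                            labels[rr, cc] = current
                            stack.append((rr, cc))
    return labels


def partition_sets(labels: np.ndarray) -> set[frozenset[tuple[int, int]]]:
    """A label map as a set of pixel-coordinate sets (label-id agnostic)."""
    out: dict[int, set[tuple[int, int]]] = {}
    for r, c in zip(*np.nonzero(labels)):
        out.setdefault(int(labels[r, c]), set()).add((int(r), int(c)))
    return {frozenset(s) for s in out.values()}


def ball_heights(radius: float) -> tuple[np.ndarray, np.ndarray]:
    """Ball structuring element: heights and boolean footprint."""
    r_int = int(np.ceil(radius))
    yy, xx = np.mgrid[-r_int : r_int + 1, -r_int : r_int + 1]
    d2 = (yy**2 + xx**2).astype(float)
    foot = d2 <= radius**2
    heights = np.zeros_like(d2)
    heights[foot] = np.sqrt(radius**2 - d2[foot])
    return heights, foot


def brute_rolling_ball_subtract(img: np.ndarray, radius: float) -> np.ndarray:
    """Rolling-ball subtraction via direct min/max double loops.

    Border handling clamps indices to the image (edge replication), the
    same convention as scipy's ``mode="nearest"``.
    """
    arr = np.asarray(img, dtype=float)
    heights, foot = ball_heights(radius)
    r_int = heights.shape[0] // 2
    h, w = arr.shape

    def clamped(r: int, c: int) -> float:
        return arr[min(max(r, 0), h - 1), min(max(c, 0), w - 1)]

    eroded = np.zeros_like(arr)
    for r in range(h):
        for c in range(w):
            vals = [
                clamped(r + dr, c + dc) - heights[dr + r_int, dc + r_int]
                for dr in range(-r_int, r_int + 1)
                for dc in range(-r_int, r_int + 1)
                if foot[dr + r_int, dc + r_int]
            ]
            eroded[r, c] = min(vals)
    background = np.zeros_like(arr)
    for r in range(h):
        for c in range(w):
            vals = [
                (eroded[min(max(r + dr, 0), h - 1), min(max(c + dc, 0), w - 1)]
                 + heights[dr + r_int, dc + r_int])
                for dr in range(-r_int, r_int + 1)
                for dc in range(-r_int, r_int + 1)
                if foot[dr + r_int, dc + r_int]
            ]
            background[r, c] = max(vals)
    return np.clip(arr - background, 0.0, None)


def nearest_marker_partition(
    mask: np.ndarray, markers: list[tuple[int, int]]
) -> np.ndarray:
    """Assign every foreground pixel to its Euclidean-nearest marker."""
    mask = np.asarray(mask, dtype=bool)
    out = np.zeros(mask.shape, dtype=np.int32)
    for r, c in zip(*np.nonzero(mask)):
        dists = [np.hypot(r - mr, c - mc) for mr, mc in markers]
        out[r, c] = int(np.argmin(dists)) + 1
    return out


def exhaustive_max_matching(
    detected: list[tuple[float, float]],
    truth: list[tuple[float, float, float]],
) -> int:
    """Maximum one-to-one matching (detected centroid within the truth
    radius) by exhaustive enumeration; only feasible for tiny inputs."""
    n_det, n_true = len(detected), len(truth)
    eligible = [
        [
            np.hypot(d[0] - t[0], d[1] - t[1]) <= t[2]
            for t in truth
        ]
        for d in detected
    ]
    best = 0
    idx_true = list(range(n_true))
    for k in range(min(n_det, n_true), 0, -1):
        for det_subset in itertools.combinations(range(n_det), k):
            for true_perm in itertools.permutations(idx_true, k):
                if all(eligible[d][t] for d, t in zip(det_subset, true_perm)):
                    return k
    return best


def hand_anova_f(groups: list[np.ndarray]) -> float:
    """One-way ANOVA F from explicit sums of squares."""
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_between = len(groups) - 1
    df_within = len(all_vals) - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)


def hand_kruskal_h(groups: list[np.ndarray]) -> float:
    """Kruskal–Wallis H from the rank formula (no-tie case)."""
    all_vals = np.concatenate(groups)
    order = np.argsort(all_vals)
    ranks = np.empty_like(order, dtype=float)
    ranks[order] = np.arange(1, len(all_vals) + 1)
    n = len(all_vals)
    start, h = 0, 0.0
    for g in groups:
        rbar = ranks[start : start + len(g)].mean()
        h += len(g) * (rbar - (n + 1) / 2.0) ** 2
        start += len(g)
    return 12.0 / (n * (n + 1)) * h


def brute_percentile(values: np.ndarray, q: float) -> float:
    """Percentile by sorted-order linear interpolation between closest ranks."""
    s = np.sort(np.asarray(values, dtype=float))
    if len(s) == 1:
        return float(s[0])
    pos = q / 100.0 * (len(s) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return float(s[lo] * (1 - frac) + s[hi] * frac)
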