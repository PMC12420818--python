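"""Independent brute-force oracles used by the test suite.

Each function recomputes a pipeline primitive by direct enumeration or
a closed formula, deliberately sharing no code with the implementation
it checks.
"""

import numpy as np


def disk_offsets(radius: int) -> list[tuple[int, int]]:
    return [
        (dy, dx)
        for dy in range(-radius, radius + 1)
        for dx in range(-radius, radius + 1)
        if dy * dy + dx * dx <= radius * radius
    ]


def brute_force_opening(image: np.ndarray, radius: int) -> np.ndarray:
    """Grayscale opening by a disc: erosion (min) then dilation (max),
    computed pixel-by-pixel with edge replication."""
    offs = disk_offsets(radius)
    H, W = image.shape
    padded = np.pad(image, radius, mode="edge")

    def min_filter(img):
        out = np.empty_like(img, dtype=np.float64)
        p = np.pad(img, radius, mode="edge")
        for y in range(H):
            for x in range(W):
                out[y, x] = min(p[y + radius + dy, x + radius + dx] for dy, dx in offs)
        return out

    def max_filter(img):
        out = np.empty_like(img, dtype=np.float64)
        p = np.pad(img, radius, mode="edge")
        for y in range(H):
            for x in range(W):
                out[y, x] = max(p[y + radius + dy, x + radius + dx] for dy, dx in offs)
        return out

    del padded
    return max_filter(min_filter(np.asarray(image, dtype=np.float64)))


def brute_force_tophat(image: np.ndarray, radius: int) -> np.ndarray:
    return np.asarray(image, dtype=np.float64) - brute_force_opening(image, radius)


def intermeans_fixed_point(values: np.ndarray, tol: float = 1e-10) -> float:
    """Intermeans threshold by scanning: the fixed point t* satisfying
    t* = (mean(v <= t*) + mean(v > t*)) / 2, located by checking every
    inter-sample midpoint interval."""
    v = np.sort(np.asarray(values, dtype=np.float64).ravel())
    candidates = np.unique(v)
    # between consecutive distinct values the two class means are constant,
    # so the fixed point can be found per interval
    for i in range(len(candidates)):
        lo = v[v <= candidates[i]]
        hi = v[v > candidates[i]]
        if hi.size == 0:
            continue
        t = (lo.mean() + hi.mean()) / 2.0
        # consistency: t must fall in the interval that produced this split
        upper = candidates[i + 1] if i + 1 < len(candidates) else np.inf
        if candidates[i] <= t < upper or abs(t - candidates[i]) < tol:
            return float(t)
    raise AssertionError("no intermeans fixed point found")


def brute_force_background(
    raster_center: tuple[float, float],
    roi_pixels: set,
    mask: np.ndarray,
    target: int,
) -> list[tuple[int, int]]:
    """Sort every image pixel by (distance from center, y, x); keep the
    first ``target`` outside the ROI and the mask."""
    cy, cx = raster_center
    H, W = mask.shape
    cand = sorted(
        ((y - cy) ** 2 + (x - cx) ** 2, y, x)
        for y in range(H)
        for x in range(W)
    )
    out = []
    for _, y, x in cand:
        if (y, x) in roi_pixels or mask[y, x]:
            continue
        out.append((y, x))
        if len(out) == target:
            return out
    raise AssertionError("brute-force oracle: not enough eligible pixels")


def kruskal_h(groups: list[np.ndarray]) -> float:
    """Kruskal–Wallis H from the rank formula with tie correction:
    H = [12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2] / (1 - sum(t^3-t)/(N^3-N))."""
    pooled = np.concatenate(groups)
    N = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(N)
    sorted_v = pooled[order]
    i = 0
    pos = np.arange(1, N + 1, dtype=np.float64)
    while i < N:
        j = i
        while j < N and sorted_v[j] == sorted_v[i]:
            j += 1
        ranks[order[i:j]] = pos[i:j].mean()  # mid-ranks
        i = j
    rbar = (N + 1) / 2.0
    start = 0
    h = 0.0
    for g in groups:
        r_i = ranks[start : start + g.size].mean()
        h += g.size * (r_i - rbar) ** 2
        start += g.size
    h *= 12.0 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float(np.sum(counts**3 - counts)) / (N**3 - N)
    return h / correction


def dunn_z_pair(groups: dict, pair: tuple[str, str]) -> float:
    """Dunn's z for one pair from first principles."""
    names = list(groups)
    arrays = [np.asarray(groups[k], dtype=np.float64) for k in names]
    pooled = np.concatenate(arrays)
    N = pooled.size
    from scipy.stats import rankdata

    ranks = rankdata(pooled)
    means = {}
    start = 0
    for k, a in zip(names, arrays):
        means[k] = ranks[start : start + a.size].mean()
        start += a.size
    _, counts = np.unique(pooled, return_counts=True)
    ties = np.sum(counts**3 - counts)
    i, j = pair
    ni, nj = len(groups[i]), len(groups[j])
    se = np.sqrt((N * (N + 1) / 12.0 - ties / (12.0 * (N - 1))) * (1.0 / ni + 1.0 / nj))
    return (means[i] - means[j]) / se
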