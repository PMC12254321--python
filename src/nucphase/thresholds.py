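"""Histogram thresholding: Otsu and Renyi-entropy, 256-bin dialect.

Both operate on a 256-bin histogram built after min-max scaling of the image
(the ImageJ convention), so results are bit-compatible with the common
ImageJ/Fiji implementations. The Renyi method follows the Sahoo et al.
formulation used by Fiji's "RenyiEntropy": maximum-entropy thresholds at
Renyi orders 1/2, 1 (Shannon limit) and 2, combined with the three-threshold
weighting rule.
"""

from __future__ import annotations

import numpy as np

N_BINS = 256


def histogram256(image: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, float]:
    """256-bin histogram after min-max scaling.

    Returns (counts, per-pixel bin indices, vmin, vmax).
    """
    img = np.asarray(image, dtype=float)
    vmin, vmax = float(img.min()), float(img.max())
    if vmax <= vmin:
        raise ValueError("constant image has no histogram contrast")
    idx = np.minimum(
        ((img - vmin) / (vmax - vmin) * N_BINS).astype(int), N_BINS - 1
    )
    counts = np.bincount(idx.ravel(), minlength=N_BINS)
    return counts, idx, vmin, vmax


def otsu_index(hist: np.ndarray) -> int:
    """Otsu threshold bin: maximize between-class variance.

    Background = bins <= t. First maximum wins on ties.
    """
    h = np.asarray(hist, dtype=float)
    total = h.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    p = h / total
    bins = np.arange(len(h))
    w0 = np.cumsum(p)
    mu = np.cumsum(p * bins)
    mu_t = mu[-1]
    w1 = 1.0 - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        var_between = (mu_t * w0 - mu) ** 2 / (w0 * w1)
    var_between[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(var_between[:-1]))


def _renyi_entropy_curve(p: np.ndarray, order: float) -> np.ndarray:
    """Total fore+background Renyi entropy for every candidate threshold t.

    order == 1 is the Shannon (Kapur maximum-entropy) limit. Candidates with
    an empty class get -inf.
    """
    P1 = np.cumsum(p)
    P2 = 1.0 - P1
    n = len(p)
    out = np.full(n, -np.inf)
    valid = (P1 > 0) & (P2 > 0)
    if order == 1.0:
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log(p), 0.0)
        c = np.cumsum(plogp)
        tot = c[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            hb = np.log(P1) - c / P1
            hw = np.log(P2) - (tot - c) / P2
        out[valid] = hb[valid] + hw[valid]
    else:
        q = p**order
        cq = np.cumsum(q)
        tot = cq[-1]
        inv = 1.0 / (1.0 - order)
        # an empty class has zero q-mass: exclude it, otherwise the sign of
        # inv turns log(0) into +inf for orders > 1
        valid = valid & (cq > 0) & ((tot - cq) > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            hb = inv * np.log(cq / P1**order)
            hw = inv * np.log((tot - cq) / P2**order)
        out[valid] = hb[valid] + hw[valid]
    return out


def renyi_index(hist: np.ndarray) -> int:
    """Renyi-entropy threshold bin (Sahoo three-order combination rule)."""
    h = np.asarray(hist, dtype=float)
    total = h.sum()
    if total <= 0:
        raise ValueError("empty histogram")
    nonzero = np.flatnonzero(h)
    if len(nonzero) < 2:
        raise ValueError("histogram needs at least two occupied bins")
    p = h / total
    P1 = np.cumsum(p)
    P2 = 1.0 - P1

    t1 = int(np.argmax(_renyi_entropy_curve(p, 0.5)))
    t2 = int(np.argmax(_renyi_entropy_curve(p, 1.0)))
    t3 = int(np.argmax(_renyi_entropy_curve(p, 2.0)))
    t_star1, t_star2, t_star3 = sorted((t1, t2, t3))

    if abs(t_star1 - t_star2) <= 5:
        if abs(t_star2 - t_star3) <= 5:
            beta = (1, 2, 1)
        else:
            beta = (0, 1, 3)
    else:
        if abs(t_star2 - t_star3) <= 5:
            beta = (3, 1, 0)
        else:
            beta = (1, 2, 1)
    omega = P1[t_star3] - P1[t_star1]
    opt = (
        t_star1 * (P1[t_star1] + 0.25 * omega * beta[0])
        + 0.25 * t_star2 * omega * beta[1]
        + t_star3 * (P2[t_star3] + 0.25 * omega * beta[2])
    )
    return int(opt)


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu intensity threshold; foreground = image > value."""
    counts, _, vmin, vmax = histogram256(image)
    t = otsu_index(counts)
    return vmin + (t + 1) * (vmax - vmin) / N_BINS


def renyi_threshold(image: np.ndarray) -> float:
    """Renyi-entropy intensity threshold; foreground = image > value."""
    counts, _, vmin, vmax = histogram256(image)
    t = renyi_index(counts)
    return vmin + (t + 1) * (vmax - vmin) / N_BINS
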