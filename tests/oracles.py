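"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity by the most literal route available —
exhaustive grid minimisation for the two-centre fuzzy clustering
objective, direct python-set enumeration for the overlap evaluation
rules, a double loop for windowed means — deliberately sharing no code
with the implementations under test.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, label

EIGHT = np.ones((3, 3), dtype=int)


def fcm_two_center_cost(data: np.ndarray, v1: float, v2: float) -> float:
    """J(U*, {v1, v2}) for m = 2 with memberships optimal for the centres.

    For fixed centres the quadratic membership problem has the closed
    form u_i = d2 / (d1 + d2), giving J_i = d1*d2 / (d1 + d2).
    """
    d1 = (data - v1) ** 2
    d2 = (data - v2) ** 2
    s = d1 + d2
    out = np.where(s > 0, d1 * d2 / np.where(s > 0, s, 1.0), 0.0)
    return float(out.sum())


def fcm_two_center_oracle(data, coarse: int = 201, refine_step: float = 5e-4):
    """Exhaustive two-centre minimisation of the clustering cost.

    Coarse pair-grid over the data range followed by a fine local grid;
    returns the two optimal centres sorted ascending.
    """
    data = np.asarray(data, dtype=np.float64).ravel()
    lo, hi = data.min(), data.max()
    if hi - lo < 1e-12:
        return np.array([lo, lo])
    grid = np.linspace(lo, hi, coarse)
    d = (data[:, None] - grid[None, :]) ** 2  # n x g
    best = (np.inf, lo, hi)
    for a in range(coarse):
        da = d[:, a][:, None]
        s = da + d
        with np.errstate(invalid="ignore"):
            j = np.where(s > 0, da * d / np.where(s > 0, s, 1.0), 0.0).sum(axis=0)
        b = int(np.argmin(j))
        if j[b] < best[0]:
            best = (float(j[b]), grid[a], grid[b])

    step = grid[1] - grid[0]
    span = np.arange(-step, step + refine_step / 2, refine_step)
    g1 = np.clip(best[1] + span, lo, hi)
    g2 = np.clip(best[2] + span, lo, hi)
    fine_best = (np.inf, best[1], best[2])
    for v1 in g1:
        for v2 in g2:
            j = fcm_two_center_cost(data, v1, v2)
            if j < fine_best[0]:
                fine_best = (j, v1, v2)
    return np.sort(np.array(fine_best[1:]))


def overlap_eval_oracle(detected, truth, sigma, domain=None):
    """Literal set enumeration of the sigma-overlap TP/FP/FN/TN rules.

    Materialises the detected/ground-truth component sets and the three
    pixel sets exactly as written: TP from the union of the intersection
    and the promoted components (ratio strictly greater than sigma), FP
    and FN from the disjoint components plus the under-sigma remainders,
    TN as everything else.
    """
    detected = np.asarray(detected, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    d_lab, nd = label(detected, structure=EIGHT)
    g_lab, ng = label(truth, structure=EIGHT)
    d_comps = [set(zip(*np.where(d_lab == k))) for k in range(1, nd + 1)]
    g_comps = [set(zip(*np.where(g_lab == k))) for k in range(1, ng + 1)]
    D = set(zip(*np.where(detected)))
    G = set(zip(*np.where(truth)))

    tp = D & G
    for comp in d_comps:
        if len(comp & G) / len(comp) > sigma:
            tp |= comp
    for comp in g_comps:
        if len(comp & D) / len(comp) > sigma:
            tp |= comp

    fp: set = set()
    for comp in d_comps:
        if not comp & G:
            fp |= comp
        elif len(comp & G) / len(comp) <= sigma:
            fp |= comp - G
    fn: set = set()
    for comp in g_comps:
        if not comp & D:
            fn |= comp
        elif len(comp & D) / len(comp) <= sigma:
            fn |= comp - D

    if domain is None:
        universe = detected.size
        in_dom = lambda s: len(s)  # noqa: E731
    else:
        dom = set(zip(*np.where(np.asarray(domain, dtype=bool))))
        universe = len(dom)
        in_dom = lambda s: len(s & dom)  # noqa: E731
    n_tp, n_fp, n_fn = in_dom(tp), in_dom(fp), in_dom(fn)
    return n_tp, n_fp, n_fn, universe - n_tp - n_fp - n_fn


def box_mean_oracle(values, window, mask=None):
    """Double-loop windowed mean over the valid part of each window."""
    values = np.asarray(values, dtype=np.float64)
    h, w = values.shape
    wr, wc = window
    out = np.zeros_like(values)
    for r in range(h):
        for c in range(w):
            r0, r1 = max(0, r - wr // 2), min(h, r - wr // 2 + wr)
            c0, c1 = max(0, c - wc // 2), min(w, c - wc // 2 + wc)
            block = values[r0:r1, c0:c1]
            if mask is not None:
                sel = np.asarray(mask, dtype=bool)[r0:r1, c0:c1]
                out[r, c] = block[sel].mean() if sel.any() else 0.0
            else:
                out[r, c] = block.mean()
    return out


def make_random_mask(rng: np.random.Generator, shape=(64, 64),
                     scale: float = 3.0, density: float = 0.15) -> np.ndarray:
    """A random blobby binary mask (smoothed noise thresholded at a
    quantile), giving components of varied size and shape."""
    field = gaussian_filter(rng.normal(size=shape), scale)
    return field > np.quantile(field, 1.0 - density)
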