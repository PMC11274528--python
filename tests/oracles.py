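"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately re-derive quantities by the most direct route available
(exhaustive enumeration, textbook formulas in high-precision arithmetic,
rank statistics) and share no code with the implementation paths they
check.
"""

from __future__ import annotations

from decimal import Decimal, getcontext
from fractions import Fraction

import numpy as np

getcontext().prec = 50


# ---------------------------------------------------------------------------
# exhaustive W / PW search on a label volume


def brute_force_w(labels: np.ndarray, spacing2, tol: float = 0.10):
    """Exhaustive longest-compliant-chord search over all axial slices.

    Enumerates every pair of tumor boundary pixels in every slice, computes
    the crossing fraction by dense sampling, and returns
    ``(W_mm, slice_index, endpoints, crossing)`` for the longest chord with
    crossing <= tol (falling back to the global minimal-crossing chord).
    Same caliper and sampling conventions as the implementation; the
    independence is in the exhaustive search order.
    """
    spacing2 = np.asarray(spacing2, dtype=float)
    best = None          # (length, z, (p,q), crossing)
    fallback = None      # (crossing, -length, z, (p,q))
    for z in range(labels.shape[2]):
        sl = labels[:, :, z]
        tumor = sl == 1
        if not tumor.any():
            continue
        pts = _boundary(tumor)
        for a in range(len(pts)):
            for b in range(a + 1, len(pts)):
                p, q = pts[a], pts[b]
                frac = _crossing(sl, p, q)
                length = _caliper(p, q, spacing2)
                if frac <= tol:
                    if best is None or length > best[0]:
                        best = (length, z, (tuple(p), tuple(q)), frac)
                else:
                    cand = (frac, -length, z, (tuple(p), tuple(q)))
                    if fallback is None or cand[:2] < fallback[:2]:
                        fallback = cand
    if best is not None:
        return best
    frac, neglen, z, ep = fallback
    return (-neglen, z, ep, frac)


def brute_force_pw(labels: np.ndarray, spacing2, w_endpoints, w_slice: int,
                   tol: float = 0.10, angle_tol_deg: float = 5.0):
    """Exhaustive perpendicular-width search in the W slice."""
    spacing2 = np.asarray(spacing2, dtype=float)
    sl = labels[:, :, w_slice]
    pts = _boundary(sl == 1)
    wd = (np.asarray(w_endpoints[1], float)
          - np.asarray(w_endpoints[0], float)) * spacing2
    wd /= np.linalg.norm(wd)
    best = None
    for a in range(len(pts)):
        for b in range(a + 1, len(pts)):
            p, q = pts[a], pts[b]
            seg = (q - p) * spacing2
            seglen = np.linalg.norm(seg)
            if seglen == 0:
                continue
            if abs(float(seg @ wd)) / seglen > np.sin(
                    np.deg2rad(angle_tol_deg)):
                continue
            if _crossing(sl, p, q) > tol:
                continue
            length = _caliper(p, q, spacing2)
            if best is None or length > best:
                best = length
    return best


def _boundary(tumor: np.ndarray) -> np.ndarray:
    interior = np.zeros_like(tumor)
    interior[1:-1, 1:-1] = (tumor[1:-1, 1:-1] & tumor[:-2, 1:-1]
                            & tumor[2:, 1:-1] & tumor[1:-1, :-2]
                            & tumor[1:-1, 2:])
    return np.argwhere(tumor & ~interior)


def _crossing(sl, p, q) -> float:
    # fixed sample count: the crossing fraction is then a deterministic
    # function of the endpoints, matching the measured convention
    t = np.linspace(0.0, 1.0, 257)
    samples = p + t[:, None] * (q - p)
    ij = np.rint(samples).astype(int)
    return float((sl[ij[:, 0], ij[:, 1]] != 1).mean())


def _caliper(p, q, spacing2) -> float:
    d = (np.asarray(q, float) - np.asarray(p, float))
    n_mm = float(np.linalg.norm(d * spacing2))
    if n_mm == 0:
        return float(np.linalg.norm(spacing2))
    u = d / np.linalg.norm(d)
    return n_mm + float(np.linalg.norm(u * spacing2))


# ---------------------------------------------------------------------------
# statistics oracles


def ccc_decimal(x, y) -> float:
    """Lin's CCC by direct Decimal evaluation of the defining formula."""
    n = len(x)
    xs = [Decimal(repr(v)) for v in x]
    ys = [Decimal(repr(v)) for v in y]
    mx = sum(xs) / n
    my = sum(ys) / n
    sxx = sum((v - mx) ** 2 for v in xs) / n
    syy = sum((v - my) ** 2 for v in ys) / n
    sxy = sum((u - mx) * (v - my) for u, v in zip(xs, ys)) / n
    return float(2 * sxy / (sxx + syy + (mx - my) ** 2))


def bland_altman_decimal(x, y):
    """Mean difference and 1.96-sd limits by Decimal arithmetic."""
    n = len(x)
    ds = [Decimal(repr(a)) - Decimal(repr(b)) for a, b in zip(x, y)]
    mean = sum(ds) / n
    var = sum((d - mean) ** 2 for d in ds) / (n - 1)
    sd = var.sqrt()
    k = Decimal("1.96")
    return float(mean), float(mean - k * sd), float(mean + k * sd)


def auc_mann_whitney(changes, truth) -> float:
    """AUC as the normalized Mann–Whitney U statistic (ties count 1/2)."""
    c = np.asarray(changes, dtype=float)
    t = np.asarray(truth, dtype=bool)
    pos = c[t]
    neg = c[~t]
    wins = sum(Fraction(1) if a > b else Fraction(1, 2) if a == b
               else Fraction(0) for a in pos for b in neg)
    return float(wins / (len(pos) * len(neg)))


def crosstab_by_counting(predicted, truth):
    """2x2 diagnostics recomputed by plain counting with Fractions."""
    tp = sum(1 for p, t in zip(predicted, truth) if p and t)
    fp = sum(1 for p, t in zip(predicted, truth) if p and not t)
    tn = sum(1 for p, t in zip(predicted, truth) if not p and not t)
    fn = sum(1 for p, t in zip(predicted, truth) if not p and t)
    out = {}
    out["sens"] = float(100 * Fraction(tp, tp + fn)) if tp + fn else None
    out["spec"] = float(100 * Fraction(tn, tn + fp)) if tn + fp else None
    out["ppv"] = float(100 * Fraction(tp, tp + fp)) if tp + fp else None
    out["npv"] = float(100 * Fraction(tn, tn + fn)) if tn + fn else None
    return out
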