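"""Independent brute-force re-implementations used as test oracles.

Everything here is written with explicit loops, straight from the
processing rules, and deliberately shares no code with the package so
that agreement is evidence, not tautology.
"""

from __future__ import annotations

import math

import numpy as np


def jump_flags_oracle(x, y, valid, k):
    """Forward-walk jump rejection, recomputed from scratch."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    valid = list(np.asarray(valid, bool))
    disps = []
    for f in range(len(x) - 1):
        if valid[f] and valid[f + 1]:
            disps.append(math.hypot(x[f + 1] - x[f], y[f + 1] - y[f]))
    sd = float(np.std(disps)) if disps else 0.0
    if sd == 0.0:
        return np.asarray(valid, bool)
    thr = k * sd
    out = list(valid)
    anchor = None
    for f in range(len(x)):
        if not valid[f]:
            continue
        if anchor is None:
            anchor = f
            continue
        if math.hypot(x[f] - x[anchor], y[f] - y[anchor]) > thr * (f - anchor):
            out[f] = False
        else:
            anchor = f
    return np.asarray(out, bool)


def fill_gaps_oracle(x, y, valid, max_gap):
    """Rule-by-rule gap filling."""
    x, y = list(map(float, x)), list(map(float, y))
    valid = list(np.asarray(valid, bool))
    n = len(valid)
    usable = list(valid)
    filled = [False] * n
    f = 0
    while f < n:
        if valid[f]:
            f += 1
            continue
        g = f
        while g < n and not valid[g]:
            g += 1
        # invalid run [f, g)
        if f > 0 and g < n and (g - f) <= max_gap:
            for h in range(f, g):
                x[h] = (x[f - 1] + x[g]) / 2.0
                y[h] = (y[f - 1] + y[g]) / 2.0
                usable[h] = True
                filled[h] = True
        f = g
    return np.array(x), np.array(y), np.array(usable), np.array(filled)


def smooth_oracle(values, usable, window):
    """Centred moving mean with half-weight end taps for even windows,
    truncated at span edges, via direct per-frame summation."""
    values = np.asarray(values, float)
    usable = np.asarray(usable, bool)
    n = len(values)
    if window == 1:
        return values.copy()
    if window % 2 == 1:
        offsets = [(o, 1.0) for o in range(-(window // 2), window // 2 + 1)]
    else:
        h = window // 2
        offsets = [(-h, 0.5)] + [(o, 1.0) for o in range(-h + 1, h)] + [(h, 0.5)]
    # span id per frame
    span = [-1] * n
    sid = -1
    for f in range(n):
        if usable[f] and (f == 0 or not usable[f - 1]):
            sid += 1
        if usable[f]:
            span[f] = sid
    out = values.copy()
    for f in range(n):
        if not usable[f]:
            continue
        num = den = 0.0
        for o, w in offsets:
            g = f + o
            if 0 <= g < n and span[g] == span[f]:
                num += w * values[g]
                den += w
        out[f] = num / den
    return out


def local_extrema_oracle(v, a, b):
    """Interior local maxima/minima indices of v[a:b], by inspection."""
    maxima, minima = [], []
    for f in range(a + 1, b - 1):
        if v[f] > v[f - 1] and v[f] >= v[f + 1]:
            maxima.append(f)
        if v[f] < v[f - 1] and v[f] <= v[f + 1]:
            minima.append(f)
    return maxima, minima


def candidates_oracle(v_out, threshold, min_frames, spans, zero_band=0.0):
    """Exhaustive extremum-pair scan over the outward-velocity signal."""
    n = len(v_out)
    raw = []
    for s0, s1 in spans:
        a, b = s0, min(s1 - 1, n)
        if b - a < 2:
            continue
        maxima, minima = local_extrema_oracle(v_out, a, b)
        maxima = [m for m in maxima if v_out[m] >= threshold]
        minima = [m for m in minima if v_out[m] <= -threshold]
        for m in maxima:
            nmins = [q for q in minima if q > m]
            if not nmins:
                continue
            q = min(nmins)
            w0 = m
            while w0 > a and v_out[w0 - 1] > zero_band:
                w0 -= 1
            w1 = q
            while w1 < b - 1 and v_out[w1 + 1] < -zero_band:
                w1 += 1
            raw.append((w0, w1 + 2, m))
    raw.sort()
    merged = []
    for w0, w1, m in raw:
        if merged and w0 <= merged[-1][1]:
            p0, p1, pm = merged[-1]
            best = pm if abs(v_out[pm]) >= abs(v_out[m]) else m
            merged[-1] = (p0, max(p1, w1), best)
        else:
            merged.append((w0, w1, m))
    return [(w0, w1, m) for (w0, w1, m) in merged if w1 - w0 >= min_frames]


def nearest_well_oracle(point, centers):
    """1-based nearest well by scanning all eight distances."""
    best, best_d = None, float("inf")
    for i, (cx, cy) in enumerate(centers):
        d = math.hypot(point[0] - cx, point[1] - cy)
        if d < best_d:  # strict: ties keep the lowest index
            best, best_d = i + 1, d
    return best, best_d


def removal_runs_oracle(prob, threshold, debounce):
    """Below-threshold runs of at least debounce frames (start frames)."""
    n = len(prob)
    starts = []
    f = 0
    while f < n:
        if prob[f] >= threshold:
            f += 1
            continue
        g = f
        while g < n and prob[g] < threshold:
            g += 1
        if g - f >= debounce:
            starts.append(f)
        f = g
    return starts
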