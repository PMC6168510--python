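"""Independent plain-Python reference for the allowed-range procedure.

Re-derived directly from the published step list (smooth, threshold the
derivative, extend against the running boundary, merge, discard minima
and terminal intervals) using explicit loops and Python lists — no
numpy, no code shared with the package implementation.  Used as the
oracle the fast implementation is checked against.
"""


def smooth(values, window=3, passes=5):
    v = list(values)
    half = window // 2
    for _ in range(passes):
        out = []
        for k in range(len(v)):
            lo = max(0, k - half)
            hi = min(len(v), k + half + 1)
            out.append(sum(v[lo:hi]) / (hi - lo))
        v = out
    return v


def derivative(v):
    d = []
    for k in range(len(v)):
        if k == 0:
            d.append(v[1] - v[0])
        elif k == len(v) - 1:
            d.append(v[-1] - v[-2])
        else:
            d.append((v[k + 1] - v[k - 1]) / 2.0)
    return d


def reference_allowed_ranges(raw, window=3, passes=5,
                             derivative_threshold=0.5, divisor=20.0,
                             rescale_min=-20.0):
    """1-based (start, end) allowed cut intervals for a raw profile."""
    v = smooth(raw, window, passes)
    factor = 1.0
    if rescale_min != 0 and min(v) < 0:
        factor = abs(rescale_min) / abs(min(v))
    v = [x * factor for x in v]
    d = derivative(v)
    e_min = min(v)
    e_tr = abs(e_min) / divisor

    # step B: group flat cuts (0-based inclusive here)
    intervals = []
    k = 0
    while k < len(v):
        if abs(d[k]) < derivative_threshold:
            j = k
            while j < len(v) and abs(d[j]) < derivative_threshold:
                j += 1
            intervals.append([k, j - 1])
            k = j
        else:
            k += 1

    # step C: extend while the adjacent value is within e_tr of the
    # running boundary value
    for iv in intervals:
        while iv[0] > 0 and abs(v[iv[0] - 1] - v[iv[0]]) < e_tr:
            iv[0] -= 1
        while iv[1] < len(v) - 1 and abs(v[iv[1] + 1] - v[iv[1]]) < e_tr:
            iv[1] += 1
    intervals.sort()
    merged = []
    for iv in intervals:
        if merged and iv[0] <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], iv[1])
        else:
            merged.append(iv)

    # step D: drop terminal-touching intervals, then basins
    kept = []
    for s, e in merged:
        if s == 0 or e == len(v) - 1:
            continue
        if v[s - 1] > v[s] and v[e + 1] > v[e]:
            continue
        kept.append((s + 1, e + 1))
    return kept
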