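"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately re-derive each quantity by exhaustive enumeration or
direct evaluation, independent of the library implementations they check.
"""

import numpy as np


def oracle_peak_indices(x, prominence_min):
    """Strict local maxima above the baseline (0) with prominence computed
    by direct extension to the nearest higher terrain on each side."""
    hits = []
    for i in range(1, len(x) - 1):
        if not (x[i] > x[i - 1] and x[i] > x[i + 1]):
            continue
        left_min = x[i]
        j = i - 1
        while j >= 0 and x[j] <= x[i]:
            left_min = min(left_min, x[j])
            j -= 1
        right_min = x[i]
        j = i + 1
        while j < len(x) and x[j] <= x[i]:
            right_min = min(right_min, x[j])
            j += 1
        prom = x[i] - max(left_min, right_min)
        if x[i] > 0 and prom >= prominence_min:
            hits.append(i)
    return hits


def oracle_cell_label(x, t, bw=(-50.0, 0.0), cw=(15.0, 38.0), k=0.5):
    """Direct three-branch Increase/Decrease/Nonresponse evaluation,
    sample by sample."""
    b = x[(t >= bw[0]) & (t < bw[1])]
    mu, sd = b.mean(), b.std()
    up = down = False
    zmax, zmin = -np.inf, np.inf
    for ti, xi in zip(t, x):
        if cw[0] <= ti < cw[1]:
            z = (xi - mu) / sd
            zmax, zmin = max(zmax, z), min(zmin, z)
            if z > k:
                up = True
            if z < -k:
                down = True
    if up and down:
        return "Increase" if zmax >= -zmin else "Decrease"
    if up:
        return "Increase"
    if down:
        return "Decrease"
    return "Nonresponse"


def oracle_count_peaks(x, fs, t_inj, baseline=30.0, peak_sd=2.0,
                       noise_sd=5.0, refractory=1e-3):
    """Exhaustive threshold + local-max + refractory peak counting;
    returns (counted indices, excluded indices)."""
    t = np.arange(len(x)) / fs - t_inj
    seg = x[(t >= -baseline) & (t < 0)]
    med, sd = np.median(seg), seg.std()
    lower, upper = med + peak_sd * sd, med + noise_sd * sd
    cand = [i for i in range(1, len(x) - 1)
            if x[i] > x[i - 1] and x[i] > x[i + 1] and x[i] > lower]
    dist = max(int(round(refractory * fs)), 1)
    order = sorted(cand, key=lambda i: x[i], reverse=True)
    removed = set()
    for i in order:
        if i in removed:
            continue
        for j in cand:
            if j != i and abs(j - i) < dist and j not in removed:
                if x[j] <= x[i]:
                    removed.add(j)
    kept = [i for i in cand if i not in removed]
    counted = [i for i in kept if x[i] <= upper]
    excluded = [i for i in kept if x[i] > upper]
    return counted, excluded
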