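"""Independent brute-force peak-finding oracle.

Re-derives local maxima, prominences, greedy distance filtering and
interpolated half-prominence widths from first principles; used to
cross-check events.find_peaks.
"""

import numpy as np


def _local_maxima(x):
    out = []
    i = 1
    n = len(x)
    while i < n - 1:
        if x[i - 1] < x[i]:
            j = i
            while j < n - 1 and x[j + 1] == x[j]:
                j += 1
            if j < n - 1 and x[j + 1] < x[j]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def _prominence(x, peak):
    h = x[peak]
    left_min = h
    i = peak - 1
    while i >= 0 and x[i] <= h:
        left_min = min(left_min, x[i])
        i -= 1
    right_min = h
    i = peak + 1
    while i < len(x) and x[i] <= h:
        right_min = min(right_min, x[i])
        i += 1
    left_base = left_min
    right_base = right_min
    return h - max(left_base, right_base)


def _width(x, peak, prominence):
    # linear interpolation of the crossings at half-prominence height
    h = x[peak] - 0.5 * prominence
    i = peak
    while i > 0 and x[i - 1] > h:
        i -= 1
    if i > 0:
        left_ip = (i - 1) + (h - x[i - 1]) / (x[i] - x[i - 1])
    else:
        left_ip = 0.0
    i = peak
    while i < len(x) - 1 and x[i + 1] > h:
        i += 1
    if i < len(x) - 1:
        right_ip = (i + 1) - (h - x[i + 1]) / (x[i] - x[i + 1])
    else:
        right_ip = float(len(x) - 1)
    return right_ip - left_ip


def brute_force_peaks(x, distance, min_prominence, min_width, max_width):
    """Exhaustive scan applying the same definitions as find_peaks."""
    x = np.asarray(x, float)
    peaks = _local_maxima(x)
    # greedy distance filter: highest peak claims its neighborhood first
    peaks = np.asarray(peaks)
    if len(peaks) and distance > 1:
        keep = np.ones(len(peaks), bool)
        for k in np.argsort(x[peaks])[::-1]:
            if not keep[k]:
                continue
            close = np.abs(peaks - peaks[k]) < distance
            close[k] = False
            keep[close] = False
        peaks = peaks[keep]
    result = []
    for p in peaks:
        prom = _prominence(x, p)
        if prom < min_prominence:
            continue
        w = _width(x, p, prom)
        if not (min_width <= w <= max_width):
            continue
        result.append(int(p))
    return result


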