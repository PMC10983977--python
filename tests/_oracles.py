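"""Independent brute-force oracles shared across test modules.

These deliberately re-derive quantities from first principles (definition
-level scans, exhaustive enumeration) and must stay independent of the
implementation paths they check.
"""

import numpy as np


def oracle_local_maxima(d):
    """Indices of local maxima, plateaus reported at their midpoint."""
    peaks = []
    i = 1
    n = len(d)
    while i < n - 1:
        if d[i - 1] < d[i]:
            j = i
            while j < n - 1 and d[j + 1] == d[i]:
                j += 1
            if j < n - 1 and d[j + 1] < d[i]:
                peaks.append(i + (j - i) // 2)
            i = j + 1
        else:
            i += 1
    return peaks


def oracle_prominence(d, peak):
    """Topographic prominence by definition: height minus the higher of the
    two interval minima toward the nearest higher ground (or signal edge)."""
    height = d[peak]
    left = d[:peak][::-1]
    higher = np.flatnonzero(left > height)
    left_min = left[: higher[0]].min() if len(higher) else left.min()
    right = d[peak + 1 :]
    higher = np.flatnonzero(right > height)
    right_min = right[: higher[0]].min() if len(higher) else right.min()
    return height - max(left_min, right_min)


def oracle_peaks(d, prominence, distance):
    """Full peak finding by definition: local maxima passing the prominence
    bar, then greedy separation (height desc, ties to the lower index)."""
    candidates = [
        p for p in oracle_local_maxima(d)
        if oracle_prominence(d, p) >= prominence
    ]
    order = sorted(candidates, key=lambda p: (-d[p], p))
    kept = []
    for p in order:
        if all(abs(p - q) >= distance for q in kept):
            kept.append(p)
    return sorted(kept)


def centers_to_bins(centers, config):
    """Map peak locations in pA back to histogram bin indices."""
    width = (config.hist_hi - config.hist_lo) / config.n_bins
    return np.round((centers - config.hist_lo) / width - 0.5).astype(int)
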