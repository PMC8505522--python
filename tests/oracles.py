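"""Independent brute-force oracles.

Every frozen expected value asserted in the test suite is recomputed here
by the most naive possible method (plain Python loops, direct formula
transcription), deliberately sharing no code with the package
implementation they check.
"""

import math


def shares_bruteforce(probs):
    """Destination shares by naive division."""
    total = sum(probs)
    if total == 0:
        return [0.0 for _ in probs]
    return [p / total for p in probs]


def logistic_bruteforce(z, a=1.0, b=1.0):
    return 1.0 / (a + b * math.exp(-z))


def nodes_within_radius_bruteforce(coords, center, radius):
    """Epicenter membership by looping over every node."""
    out = []
    for i, (x, y) in enumerate(coords):
        if math.hypot(x - center[0], y - center[1]) <= radius:
            out.append(i)
    return out


def vrank_bruteforce(i, p, w, L, neighbor_lists, c_bar, beta_damp):
    """VRank from its definition: own bundle-cost/income ratio, damped
    geometric mean with the neighborhood aggregate ratio."""
    own = (p[i] * c_bar * L[i]) / (w[i] * L[i])
    nbrs = neighbor_lists[i]
    if not nbrs:
        return own
    num = sum(p[j] * c_bar * L[j] for j in nbrs)
    den = sum(w[j] * L[j] for j in nbrs)
    return math.sqrt(own * beta_damp * (num / den))


def bin_means_bruteforce(values_by_node, bin_by_node, n_bins):
    """Per-bin means by explicit accumulation; empty bins -> None."""
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for node, v in values_by_node.items():
        b = bin_by_node[node]
        sums[b] += v
        counts[b] += 1
    return [sums[b] / counts[b] if counts[b] else None for b in range(n_bins)]


def shoelace_bruteforce(points):
    """Signed polygon area, term by term."""
    n = len(points)
    acc = 0.0
    for k in range(n):
        x1, y1 = points[k]
        x2, y2 = points[(k + 1) % n]
        acc += x1 * y2 - x2 * y1
    return acc / 2.0
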