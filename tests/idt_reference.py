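"""Independent brute-force reference for dispersion-threshold segmentation.

Pure-Python, quadratic-time re-implementation of the greedy window rule,
kept deliberately naive (full dispersion recomputation at every step) so it
shares no code path with the package implementation.
"""

import math


def brute_force_diameter(points) -> float:
    """Max pairwise Euclidean distance by full enumeration."""
    best = 0.0
    pts = list(points)
    for i in range(len(pts)):
        for j in range(i + 1, len(pts)):
            d = math.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
            if d > best:
                best = d
    return best


def idt_reference(
    x, y, t_s, threshold, min_samples, max_duration=None
) -> list[tuple[int, int]]:
    """Greedy dispersion-threshold fixation spans, exhaustively recomputed.

    Returns inclusive (start, end) index pairs.  At each position a seed
    window of ``min_samples`` is tested; if within threshold it is grown
    while the full-window dispersion stays within threshold (and, when
    ``max_duration`` is set, the window time span within that), emitted,
    and the scan restarts after it; otherwise the window slides by one.
    """
    n = len(x)
    pts = list(zip(x, y))

    def ok(a, b):  # window a..b inclusive admissible?
        if max_duration is not None and t_s[b] - t_s[a] > max_duration:
            return False
        return brute_force_diameter(pts[a : b + 1]) <= threshold

    spans = []
    i = 0
    while i + min_samples <= n:
        if ok(i, i + min_samples - 1):
            j = i + min_samples - 1
            while j + 1 < n and ok(i, j + 1):
                j += 1
            spans.append((i, j))
            i = j + 1
        else:
            i += 1
    return spans
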