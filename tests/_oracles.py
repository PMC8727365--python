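"""Independent brute-force oracles shared by the test suite.

These deliberately avoid the library code paths they check: plain-Python
dynamic programming for edit distance, entropy arithmetic for the
Jensen-Shannon distance, and an O(n^2) exhaustive scan for the first low
ebb of an RPUP histogram.
"""

from __future__ import annotations

import math


def dp_edit_distance(a: str, b: str) -> int:
    """Textbook Wagner-Fischer Levenshtein distance."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[-1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _entropy2(p) -> float:
    return -sum(x * math.log2(x) for x in p if x > 0)


def jsd_oracle(p, q) -> float:
    """Jensen-Shannon distance, base 2, from the entropy definition."""
    ps, qs = sum(p), sum(q)
    p = [x / ps for x in p]
    q = [x / qs for x in q]
    m = [(x + y) / 2 for x, y in zip(p, q)]
    div = _entropy2(m) - 0.5 * (_entropy2(p) + _entropy2(q))
    return math.sqrt(max(div, 0.0))


def mh_oracle(x, y) -> float:
    X, Y = sum(x), sum(y)
    num = 2 * sum(a * b for a, b in zip(x, y))
    den = (sum(a * a for a in x) / X**2 + sum(b * b for b in y) / Y**2) * X * Y
    return num / den


def ebb_oracle(counts: dict[int, int], fallback: int = 2) -> int:
    """Exhaustive first-local-minimum scan with the plateau rule."""
    r_max = max(counts)
    arr = [0.0] * (r_max + 1)
    for r, c in counts.items():
        arr[r] = c
    for r in range(2, r_max):
        if arr[r] > arr[r - 1]:
            continue
        if r > 2 and arr[r] == arr[r - 1] and arr[r - 1] <= arr[r - 2]:
            continue  # interior of a plateau that started earlier
        nxt = next((arr[j] for j in range(r + 1, r_max + 1) if arr[j] != arr[r]), None)
        if nxt is not None and nxt > arr[r]:
            return r
    return fallback
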