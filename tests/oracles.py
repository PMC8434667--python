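"""Independent brute-force oracles for the entropy kernels.

Deliberately naive O(N^2) / dictionary-counting implementations, kept
free of any code shared with the package so they can serve as
independent references.
"""

import math


def brute_force_sampen(x, m, tol):
    """Direct double-loop template counting, Chebyshev distance, strict <."""
    n = len(x)
    nt = n - m
    a = b = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            d_m = max(abs(x[i + k] - x[j + k]) for k in range(m))
            if d_m < tol:
                b += 1
                if max(d_m, abs(x[i + m] - x[j + m])) < tol:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def brute_force_pe(x, D, delay):
    """Ordinal-pattern counting with stable (earlier-index-first) ranks."""
    n_vec = len(x) - (D - 1) * delay
    counts = {}
    for i in range(n_vec):
        window = [x[i + k * delay] for k in range(D)]
        pattern = tuple(sorted(range(D), key=lambda k: (window[k], k)))
        counts[pattern] = counts.get(pattern, 0) + 1
    return -sum((c / n_vec) * math.log2(c / n_vec) for c in counts.values())
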