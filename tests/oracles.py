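"""Independent brute-force reference implementations used only by tests.

These are deliberately naive O(N^2) double loops written straight from the
defining formulas (Pincus ApEn with self-matches, Richman-Moorman SampEn
without), so they share no code path with the package's vectorized
estimators.
"""

import numpy as np


def apen_brute(x, m=2, r=0.2):
    x = np.asarray(x, dtype=float)
    n = len(x)
    r_abs = r * x.std()

    def phi(mm):
        n_templ = n - mm + 1
        templates = [x[i : i + mm] for i in range(n_templ)]
        total = 0.0
        for i in range(n_templ):
            count = sum(
                1 for j in range(n_templ)
                if np.max(np.abs(templates[i] - templates[j])) <= r_abs
            )
            total += np.log(count / n_templ)
        return total / n_templ

    return phi(m) - phi(m + 1)


def sampen_brute(x, m=2, r=0.2):
    x = np.asarray(x, dtype=float)
    n = len(x)
    r_abs = r * x.std()

    def pairs(mm):
        n_templ = n - m
        templates = [x[i : i + mm] for i in range(n_templ)]
        return sum(
            1
            for i in range(n_templ)
            for j in range(i + 1, n_templ)
            if np.max(np.abs(templates[i] - templates[j])) <= r_abs
        )

    return -np.log(pairs(m + 1) / pairs(m))


def lz76_brute(bits):
    """Pattern count by explicit exhaustive-history parsing: repeatedly take
    the shortest prefix of the remainder that is NOT a substring of the
    history extended by all but its last symbol."""
    s = "".join("1" if b else "0" for b in bits)
    words = 0
    start = 0
    n = len(s)
    while start < n:
        length = 1
        while start + length <= n:
            word = s[start : start + length]
            history_ext = s[: start + length - 1]
            if word in history_ext:
                length += 1
            else:
                break
        words += 1
        start += length
    return words
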