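"""Independent brute-force oracles used to cross-check the main implementations.

These deliberately share no code with the package: the LZ76 parser uses
naive Python substring search on strings, and the sample-entropy counter
uses explicit O(n^2 * m) loops.
"""

from __future__ import annotations

import math


def lz76_brute(bits) -> int:
    """Naive LZ76 exhaustive-history phrase count via substring containment.

    Extend the current phrase while it occurs as a substring of all
    preceding material plus the phrase minus its last symbol; close at first
    novelty; a final still-reproducible suffix counts as one phrase.
    """
    s = "".join(str(int(b)) for b in bits)
    n = len(s)
    if n == 0:
        raise ValueError("empty input")
    count = 0
    i = 0
    while i < n:
        length = 1
        while i + length <= n and s[i : i + length] in s[: i + length - 1]:
            length += 1
        if i + length > n:
            length = n - i
        count += 1
        i += length
    return count


def sampen_brute(series, m: int = 2, r_coef: float = 0.3):
    """O(n^2) sample-entropy counter returning (B, A, value).

    B counts ordered pairs (i != j) of m-length templates within Chebyshev
    distance r = r_coef * population-sd; A the same for (m+1)-length
    templates over the same index range.
    """
    x = [float(v) for v in series]
    n = len(x)
    mean = sum(x) / n
    sd = math.sqrt(sum((v - mean) ** 2 for v in x) / n)
    r = r_coef * sd

    def cheb(i, j, length):
        return max(abs(x[i + k] - x[j + k]) for k in range(length))

    n_templates = n - m
    b = a = 0
    for i in range(n_templates):
        for j in range(n_templates):
            if i == j:
                continue
            if cheb(i, j, m) <= r:
                b += 1
            if cheb(i, j, m + 1) <= r:
                a += 1
    if b == 0:
        value = float("nan")
    elif a == 0:
        value = float("inf")
    else:
        value = -math.log(a / b)
    return b, a, value
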