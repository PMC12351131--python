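"""Independent brute-force oracles for the moment features.

Deliberately naive: sort-based median and explicit Python loops, sharing
no code with the package implementation.
"""

import math


def oracle_median(xs):
    s = sorted(xs)
    n = len(s)
    if n % 2 == 1:
        return float(s[n // 2])
    return (s[n // 2 - 1] + s[n // 2]) / 2.0


def oracle_median_variance(xs):
    eta = oracle_median(xs)
    total = 0.0
    for x in xs:
        total += (x - eta) ** 2
    return total / len(xs)


def oracle_median_std(xs):
    return math.sqrt(oracle_median_variance(xs))


def oracle_median_skewness(xs, raw=False):
    eta = oracle_median(xs)
    sd = oracle_median_std(xs)
    total = 0.0
    for x in xs:
        total += (x - eta) ** 3
    out = total / sd ** 3
    return out if raw else out / len(xs)


def oracle_median_kurtosis(xs, raw=False):
    eta = oracle_median(xs)
    sd = oracle_median_std(xs)
    total = 0.0
    for x in xs:
        total += (x - eta) ** 4
    out = total / sd ** 4
    return out if raw else out / len(xs)


def oracle_classical(xs):
    n = len(xs)
    m = sum(xs) / n
    v = sum((x - m) ** 2 for x in xs) / n
    sd = math.sqrt(v)
    skew = sum((x - m) ** 3 for x in xs) / n / sd ** 3
    kurt = sum((x - m) ** 4 for x in xs) / n / sd ** 4
    return m, v, skew, kurt
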