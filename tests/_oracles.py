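"""Independent brute-force oracles used by the tests.

These deliberately avoid the package's code paths (and scipy's pmf):
binomial probabilities come from math.comb and plain powers, posteriors
from direct enumeration in probability space.
"""

from math import comb, log, sqrt


def mixture_p(m: int, k: int, f: float, eps: float) -> float:
    p = (1 - f) * m / 2 + f * k / 2
    return p * (1 - eps) + (1 - p) * eps


def binom_pmf(x: int, n: int, p: float) -> float:
    return comb(n, x) * p**x * (1 - p) ** (n - x)


def binom_log_pmf(x: int, n: int, p: float) -> float:
    return log(binom_pmf(x, n, p))


def posterior_enumeration(alt, depth, m, f, eps, prior=(1 / 3, 1 / 3, 1 / 3)):
    weights = [
        prior[k] * binom_pmf(alt, depth, mixture_p(m, k, f, eps)) for k in (0, 1, 2)
    ]
    total = sum(weights)
    return [w / total for w in weights]


def gaussian_log_density(x: float, mu: float, sigma: float) -> float:
    return -0.5 * ((x - mu) / sigma) ** 2 - log(sigma * sqrt(2 * 3.141592653589793))


def pearson_r2_textbook(xs, ys) -> float:
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy * sxy / (sxx * syy)
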