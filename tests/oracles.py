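"""Independent brute-force oracles used only by the test suite."""

from fractions import Fraction
from functools import lru_cache
from math import factorial


@lru_cache(maxsize=None)
def _hypergeom_dist(r1: int, r2: int, c1: int):
    """All tables with margins (r1, r2, c1): list of (x, exact probability)
    where x is the top-left cell, via the factorial formula."""
    n = r1 + r2
    c2 = n - c1
    out = []
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        prob = Fraction(
            factorial(r1) * factorial(r2) * factorial(c1) * factorial(c2),
            factorial(n)
            * factorial(x)
            * factorial(r1 - x)
            * factorial(c1 - x)
            * factorial(r2 - c1 + x),
        )
        out.append((x, prob))
    return tuple(out)


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact rationals:
    sum the probabilities of all tables no more probable than the observed."""
    dist = _hypergeom_dist(a + b, c + d, a + c)
    p_obs = dict(dist)[a]
    return float(sum(p for _, p in dist if p <= p_obs))


def pearson_r_oracle(xs, ys) -> float:
    """Textbook product-moment formula, plain Python."""
    n = len(xs)
    mx = sum(xs) / n
    my = sum(ys) / n
    sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
    sxx = sum((x - mx) ** 2 for x in xs)
    syy = sum((y - my) ** 2 for y in ys)
    return sxy / (sxx * syy) ** 0.5
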