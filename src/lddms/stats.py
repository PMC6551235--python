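"""Closed-form expected candidate and motif counts for random sequences.

Under a background model in which every character of every sequence is
drawn i.i.d. uniformly from Sigma — and treating the m-l+1 windows of a
sequence as independent l-mers, a standard simplification that is
inexact but empirically accurate for these counts — the expected sizes
of the candidate sets and of the final motif set have closed forms.
Writing N(Sigma, l, d) for the hamming-ball size and W = m - l + 1:

* p1 = N(Sigma,l,d1) / |Sigma|^l        chance one random window is within d1
* p2 = 1 - (1-p1)^W                     some window of one sequence is
* p3 = p2^n                             ... of every sequence
* E|C1| = |Sigma|^l p3                  expected (l,d1)-motif count
* p4, p5 as p1, p2 with radius d2;  E|C2| = |Sigma|^l (1 - (1-p5)^n)
* p6 = (N(d1) - N(d2)) / |Sigma|^l      one window lands in the annulus (d2, d1]
* p7 = sum_{k>=1} C(W,k) p6^k (1-p4-p6)^(W-k)
                                        some window in the annulus, none within d2
* p8 = sum_{i=1}^{n} C(n,i) p5^i p7^(n-i)
                                        every sequence within d1, at least one within d2
* E|O| = |Sigma|^l p8                   expected (l,d1,d2)-motif count

The module also quantifies the motivation for the two-radius model: if
each of n species independently accumulates a uniform number of
mutations on {0, ..., l/2}, the expected minimum and maximum mutation
counts (E[Y], E[Z]) spread far apart as n grows, and the probability
that at least one species stays within a tight radius d2 approaches one.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, lgamma, log

import numpy as np
from scipy.special import logsumexp

from .hamming import neighborhood_size

__all__ = [
    "ModelParams",
    "ExpectedCounts",
    "expected_counts",
    "mutation_spread_expectations",
    "validity_probability",
]


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the random-sequence model.

    ``sigma`` is the alphabet size, ``l`` the motif length, ``d1``/``d2``
    the loose/tight radii, ``m`` the sequence length and ``n`` the number
    of sequences.
    """

    sigma: int
    l: int
    d1: int
    d2: int
    m: int
    n: int

    def __post_init__(self) -> None:
        if self.sigma < 2:
            raise ValueError("alphabet size must be at least 2")
        if not 0 <= self.d2 < self.d1 <= self.l <= self.m:
            raise ValueError(
                f"parameters must satisfy 0 <= d2 < d1 <= l <= m "
                f"(got d2={self.d2}, d1={self.d1}, l={self.l}, m={self.m})"
            )
        if self.n < 1:
            raise ValueError("need at least one sequence")


@dataclass(frozen=True)
class ExpectedCounts:
    """Probabilities p1..p8 and the expected counts E|C1|, E|C2|, E|O|."""

    p1: float
    p2: float
    p3: float
    p4: float
    p5: float
    p6: float
    p7: float
    p8: float
    c1: float
    c2: float
    o: float


def _log_comb(a: int, b: int) -> float:
    return lgamma(a + 1) - lgamma(b + 1) - lgamma(a - b + 1)


def expected_counts(params: ModelParams) -> ExpectedCounts:
    """Evaluate the closed-form expected counts for ``params``.

    The p7 binomial sum is evaluated in log space (large W makes the
    individual binomial coefficients overflow long before the sum does).
    """
    sigma, l, d1, d2, m, n = (
        params.sigma,
        params.l,
        params.d1,
        params.d2,
        params.m,
        params.n,
    )
    w = m - l + 1
    total = sigma**l  # exact integer; converted to float only in ratios
    n_d1 = neighborhood_size(sigma, l, d1)
    n_d2 = neighborhood_size(sigma, l, d2)

    p1 = n_d1 / total
    p2 = 1.0 - (1.0 - p1) ** w
    p3 = p2**n
    c1 = total * p3

    p4 = n_d2 / total
    p5 = 1.0 - (1.0 - p4) ** w
    c2 = total * (1.0 - (1.0 - p5) ** n)

    p6 = (n_d1 - n_d2) / total

    # p7: at least one window in the annulus (d2, d1], none within d2
    rest = 1.0 - p4 - p6
    if p6 <= 0.0:
        p7 = 0.0
    else:
        log_terms = []
        for k in range(1, w + 1):
            if rest <= 0.0 and k < w:
                continue
            t = _log_comb(w, k) + k * log(p6)
            if w - k > 0:
                t += (w - k) * log(rest)
            log_terms.append(t)
        p7 = float(np.exp(logsumexp(log_terms))) if log_terms else 0.0

    p8 = 0.0
    for i in range(1, n + 1):
        p8 += comb(n, i) * p5**i * p7 ** (n - i)
    o = total * p8

    return ExpectedCounts(p1, p2, p3, p4, p5, p6, p7, p8, c1, c2, o)


def mutation_spread_expectations(l: int, n: int) -> tuple[float, float]:
    """Expected minimum and maximum of n i.i.d. uniform mutation counts.

    Each of ``n`` species draws its mutation count uniformly from
    ``{0, 1, ..., l/2}``.  Returns ``(E[Y], E[Z])`` for the minimum Y and
    maximum Z, from the exact tail sums

        E[Y] = sum_k k [ (h-k+1)^n - (h-k)^n ] / (h+1)^n,
        E[Z] = sum_k k [ (k+1)^n  - k^n     ] / (h+1)^n,   h = l/2.

    Requires ``l`` even so the support {0..l/2} is integral.
    """
    if l <= 0 or l % 2:
        raise ValueError("motif length l must be positive and even")
    if n < 1:
        raise ValueError("need at least one species")
    h = l // 2
    denom = (h + 1) ** n
    ey = sum(k * ((h - k + 1) ** n - (h - k) ** n) for k in range(1, h + 1)) / denom
    ez = sum(k * ((k + 1) ** n - k**n) for k in range(1, h + 1)) / denom
    return ey, ez


def validity_probability(n: int, l: int, d2: int) -> float:
    """Chance that at least one of n species mutated at most d2 times.

    With per-species mutation counts i.i.d. uniform on ``{0, ..., l/2}``,
    a single species stays within ``d2`` with probability
    ``(d2+1)/(l/2+1)``, so the result is ``1 - (1 - (d2+1)/(l/2+1))^n``.
    """
    if l <= 0 or l % 2:
        raise ValueError("motif length l must be positive and even")
    if n < 1:
        raise ValueError("need at least one species")
    h = l // 2
    if not 0 <= d2 <= h:
        raise ValueError(f"d2={d2} must lie in [0, l/2={h}]")
    return 1.0 - (1.0 - (d2 + 1) / (h + 1)) ** n
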