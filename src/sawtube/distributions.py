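"""Distributional summaries of walk size.

A census records, for each walk length ``N``, the histogram of squared
end-to-end distances over all ``c_N`` walks.  This module turns one such
histogram into the discrete probability distribution of ``omega^2`` (the
squared end-to-end distance in walk-step units), its cumulative form, the
exact mean, and the characteristic ratio ``<omega^2>/N`` — the quantities
used to compare chain expansion across tube sizes and origin types.

Probabilities and means are exact rationals; the support is bounded by
``1 <= omega^2 <= N^2`` (a single step at minimum, a fully extended walk at
maximum).  A two-parameter gamma CDF can be least-squares fitted to the
empirical CDF as a smooth summary of its shape.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import optimize, stats

from .enumeration import WalkCensus
from .lattice import get_lattice

__all__ = ["E2EDistribution", "summarize", "gamma_cdf_fit", "median"]


@dataclass(frozen=True)
class E2EDistribution:
    """Discrete distribution of squared end-to-end distance at one length."""

    n: int
    support: tuple[Fraction, ...]
    pmf: tuple[Fraction, ...]
    cdf: tuple[Fraction, ...]
    mean_sq_e2e: Fraction
    char_ratio: Fraction


def summarize(census: WalkCensus, n: int) -> E2EDistribution:
    """Exact pmf/cdf/mean of ``omega^2`` at length ``n`` from a census."""
    if n not in census.counts:
        raise ValueError(f"length {n} is not covered by the census (n_max={census.n_max})")
    scale = get_lattice(census.lattice_name).internal_to_physical_sq
    c_n = census.counts[n]
    items = sorted(census.e2e_hist[n].items())
    support = tuple(d2 * scale for d2, _ in items)
    pmf = tuple(Fraction(c, c_n) for _, c in items)
    cdf_vals = []
    acc = Fraction(0)
    for p in pmf:
        acc += p
        cdf_vals.append(acc)
    mean = sum(s * p for s, p in zip(support, pmf))
    return E2EDistribution(
        n=n,
        support=support,
        pmf=pmf,
        cdf=tuple(cdf_vals),
        mean_sq_e2e=mean,
        char_ratio=mean / n,
    )


def median(dist: E2EDistribution) -> Fraction:
    """Smallest support value whose cumulative probability reaches 1/2."""
    for s, c in zip(dist.support, dist.cdf):
        if c >= Fraction(1, 2):
            return s
    raise AssertionError("cdf never reaches 1/2")  # impossible for a pmf


def gamma_cdf_fit(dist: E2EDistribution) -> tuple[float, float, float]:
    """Fit a two-parameter gamma CDF to the empirical CDF.

    Unweighted least squares of ``GammaCDF(x; shape, scale)`` against the
    empirical cumulative probabilities at the support points.  Returns
    ``(shape, scale, sse)``.

    Raises
    ------
    ValueError
        If the distribution has fewer than 3 support points.
    """
    if len(dist.support) < 3:
        raise ValueError("gamma fit requires at least 3 support points")
    x = np.array([float(s) for s in dist.support])
    y = np.array([float(c) for c in dist.cdf])
    mean = float(dist.mean_sq_e2e)
    var = float(
        sum(p * (s - dist.mean_sq_e2e) ** 2 for s, p in zip(dist.support, dist.pmf))
    )
    # moment-matched start; var > 0 because there are >= 3 support points
    shape0 = mean * mean / var
    scale0 = var / mean

    def resid(params: np.ndarray) -> np.ndarray:
        shape, scale = params
        return stats.gamma.cdf(x, shape, scale=scale) - y

    sol = optimize.least_squares(
        resid, x0=[shape0, scale0], bounds=([1e-12, 1e-12], [np.inf, np.inf])
    )
    shape, scale = sol.x
    return float(shape), float(scale), float(np.sum(sol.fun**2))
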