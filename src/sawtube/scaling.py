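"""Scaling-law fits and confinement summaries.

Walk counts and walk size are conjectured to follow the asymptotic laws

    c_N ~ A mu^N N^(gamma - 1),        <omega_N^2> ~ D N^(2 nu),

with ``mu`` the connective constant, ``gamma`` the entropic exponent and
``nu`` the size exponent.  Both laws are linear in log space, so the fits
here are ordinary least squares of ``ln c_N`` on ``(1, N, ln N)`` and of
``ln <omega^2>`` on ``(1, ln N)``.  For confined walks the size law is
anomalous at small ``N`` (the tube stretches short chains), so size fits
default to the late-``N`` half of the data; the count law holds over the
whole range and is fitted over it by default.

The module also provides the cross-origin summaries used to characterise a
tube as a whole: the multiplicity-weighted average connective constant, the
``log c_N(i) / log c_N(1)`` convergence ratio between origin types, and
walk counts rescaled by the origin's overlap ratio (which collapses, to
first order, the spread between origin types).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .enumeration import WalkCensus
from .origins import OriginClass

__all__ = [
    "ScalingFit",
    "fit_counts",
    "fit_e2e",
    "weighted_mu",
    "log_count_ratio",
    "overlap_scaled_counts",
]


@dataclass(frozen=True)
class ScalingFit:
    """Coefficients of one scaling-law fit.

    ``kind == "counts"`` populates ``(A, mu, gamma)``; ``kind == "e2e"``
    populates ``(D, nu)``.  ``residual`` is the sum of squared log-space
    residuals over the fit range.
    """

    kind: str
    fit_range: tuple[int, int]
    residual: float
    A: float | None = None
    mu: float | None = None
    gamma: float | None = None
    D: float | None = None
    nu: float | None = None


def _fit_window(census: WalkCensus, n_lo: int, n_hi: int | None) -> list[int]:
    n_hi = census.n_max if n_hi is None else n_hi
    ns = [n for n in range(n_lo, n_hi + 1) if n in census.counts]
    if len(ns) < 4:
        raise ValueError("scaling fits require at least 4 lengths in the fit range")
    return ns


def fit_counts(census: WalkCensus, n_lo: int = 1, n_hi: int | None = None) -> ScalingFit:
    """OLS fit of ``ln c_N = ln A + N ln mu + (gamma - 1) ln N``.

    Defaults to the full available range; the count law is accurate down to
    ``N = 1`` even under confinement.
    """
    ns = _fit_window(census, n_lo, n_hi)
    narr = np.array(ns, dtype=float)
    y = np.array([math.log(census.counts[n]) for n in ns])
    X = np.column_stack([np.ones_like(narr), narr, np.log(narr)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = float(np.sum((X @ coef - y) ** 2))
    return ScalingFit(
        kind="counts",
        fit_range=(ns[0], ns[-1]),
        residual=resid,
        A=math.exp(coef[0]),
        mu=math.exp(coef[1]),
        gamma=coef[2] + 1.0,
    )


def fit_e2e(census: WalkCensus, n_lo: int | None = None, n_hi: int | None = None) -> ScalingFit:
    """OLS fit of ``ln <omega^2> = ln D + 2 nu ln N``.

    ``n_lo`` defaults to ``ceil(n_max / 2)``: under confinement the size law
    only sets in at late ``N``, so short lengths are excluded by default.
    """
    if n_lo is None:
        n_lo = -(-census.n_max // 2)
    ns = _fit_window(census, n_lo, n_hi)
    larr = np.log(np.array(ns, dtype=float))
    y = np.array([math.log(census.mean_sq_e2e(n)) for n in ns])
    X = np.column_stack([np.ones_like(larr), larr])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = float(np.sum((X @ coef - y) ** 2))
    return ScalingFit(
        kind="e2e",
        fit_range=(ns[0], ns[-1]),
        residual=resid,
        D=math.exp(coef[0]),
        nu=coef[1] / 2.0,
    )


def weighted_mu(
    classes: Sequence[OriginClass], fits: Sequence[ScalingFit | float]
) -> float:
    """Multiplicity-weighted average connective constant over origin classes.

    ``fits`` may hold :class:`ScalingFit` objects or plain ``mu`` values,
    ordered to match ``classes``.
    """
    if len(classes) != len(fits):
        raise ValueError("need exactly one fit per origin class")
    mus = [f.mu if isinstance(f, ScalingFit) else float(f) for f in fits]
    if any(m is None for m in mus):
        raise ValueError("all fits must carry a connective constant")
    total = sum(c.multiplicity for c in classes)
    return sum(c.multiplicity * m for c, m in zip(classes, mus)) / total


def log_count_ratio(census_i: WalkCensus, census_1: WalkCensus, n: int) -> float:
    """Convergence ratio ``ln c_N(i) / ln c_N(1)`` between two origins."""
    if n not in census_i.counts or n not in census_1.counts:
        raise ValueError(f"length {n} is not covered by both censuses")
    return math.log(census_i.counts[n]) / math.log(census_1.counts[n])


def overlap_scaled_counts(
    census: WalkCensus, origin_class: OriginClass
) -> dict[int, Fraction]:
    """Counts rescaled by the origin's overlap ratio: ``N -> c_N / r_i``.

    Exact rationals: the overlap is an exact fraction and the counts are
    exact integers, so nothing is lost to floating point.
    """
    if census.origin not in origin_class.sites:
        raise ValueError("census origin does not belong to the given origin class")
    r = origin_class.overlap
    return {n: Fraction(c) / r for n, c in census.counts.items()}
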