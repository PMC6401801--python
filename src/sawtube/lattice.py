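"""Simple-cubic and face-centered-cubic lattices in exact integer coordinates.

Both lattices are represented on an integer grid chosen so that every
nearest-neighbour step and every squared distance is an exact integer:

* **SC** — the conventional cubic cell has edge 1; nearest neighbours are the
  six ``±e_i`` offsets and the squared nearest-neighbour distance is 1.
* **FCC** — coordinates are doubled so that the conventional cubic cell has
  edge 2 and lattice sites are the integer triples with *even* coordinate
  sum.  Nearest neighbours are the twelve permutations of ``(±1, ±1, 0)``
  and the squared nearest-neighbour distance is 2 in internal units.

Physical distances are expressed in units of the walk step length (nearest
neighbours are 1 step apart on either lattice), so internal squared
distances convert to physical ones by the factor
:attr:`Lattice.internal_to_physical_sq` (1 for SC, 1/2 for FCC).  All
conversions use :class:`fractions.Fraction`; no floating point enters any
geometric predicate.

The tube confinement region restricts the two transverse coordinates
``x2, x3`` to ``0 <= x2, x3 <= B`` while the axial coordinate ``x1`` runs
over all integers.  ``B`` is the tube size in internal units: ``B = n`` for
an ``n x n`` SC tube and ``B = 2n`` for an ``n sqrt2 x n sqrt2`` FCC tube,
with ``n`` the tube size in conventional-cell units.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterator

__all__ = [
    "Lattice",
    "TubeRegion",
    "Site",
    "SC",
    "FCC",
    "get_lattice",
    "on_lattice",
    "neighbors",
    "in_region",
    "physical_sq_e2e",
]

#: A lattice site in internal integer coordinates; ``x1`` is the tube axis.
Site = tuple[int, int, int]


@dataclass(frozen=True)
class Lattice:
    """A Bravais lattice with exact integer step vectors.

    Attributes
    ----------
    name:
        ``"SC"`` or ``"FCC"``.
    steps:
        Ordered tuple of neighbour displacement vectors in internal units.
        The ordering is fixed and documented so that depth-first traversals
        are reproducible; it is closed under negation.
    step_sq_internal:
        Squared nearest-neighbour distance in internal units.
    internal_to_physical_sq:
        Factor converting an internal squared distance to squared walk-step
        units (exact rational).
    """

    name: str
    steps: tuple[Site, ...]
    step_sq_internal: int
    internal_to_physical_sq: Fraction

    @property
    def coordination(self) -> int:
        """Number of nearest neighbours (6 for SC, 12 for FCC)."""
        return len(self.steps)


def _sc_steps() -> tuple[Site, ...]:
    return (
        (1, 0, 0), (-1, 0, 0),
        (0, 1, 0), (0, -1, 0),
        (0, 0, 1), (0, 0, -1),
    )


def _fcc_steps() -> tuple[Site, ...]:
    # All permutations of (+-1, +-1, 0); axial pairs first, then transverse.
    out = []
    for a in (1, -1):
        for b in (1, -1):
            out.append((a, b, 0))
            out.append((a, 0, b))
    for a in (1, -1):
        for b in (1, -1):
            out.append((0, a, b))
    return tuple(out)


SC = Lattice("SC", _sc_steps(), 1, Fraction(1))
FCC = Lattice("FCC", _fcc_steps(), 2, Fraction(1, 2))

_LATTICES = {"SC": SC, "FCC": FCC}


def get_lattice(name: str) -> Lattice:
    """Look up a lattice by name (case-insensitive)."""
    try:
        return _LATTICES[name.upper()]
    except KeyError:
        raise ValueError(f"unknown lattice {name!r}; expected 'SC' or 'FCC'") from None


def on_lattice(site: Site, lattice: Lattice) -> bool:
    """True iff ``site`` is a point of ``lattice`` (parity check for FCC)."""
    if lattice.name == "FCC":
        return (site[0] + site[1] + site[2]) % 2 == 0
    return True


def neighbors(site: Site, lattice: Lattice) -> list[Site]:
    """Nearest neighbours of ``site`` in the fixed step order.

    Raises
    ------
    ValueError
        If ``site`` violates the FCC parity constraint.
    """
    if not on_lattice(site, lattice):
        raise ValueError(f"site {site} is not on the {lattice.name} lattice")
    x1, x2, x3 = site
    return [(x1 + s1, x2 + s2, x3 + s3) for s1, s2, s3 in lattice.steps]


@dataclass(frozen=True)
class TubeRegion:
    """A square-cross-section tube along the ``x1`` axis, or no confinement.

    Parameters
    ----------
    lattice:
        The underlying lattice.
    n:
        Tube size in conventional-cell units (an ``n x n`` tube).  Positive
        integers for SC; positive multiples of 1/2 for FCC.  ``None`` means
        unrestricted (the full lattice).
    """

    lattice: Lattice
    n: Fraction | None

    def __post_init__(self) -> None:
        if self.n is None:
            return
        n = Fraction(self.n)
        object.__setattr__(self, "n", n)
        if n <= 0:
            raise ValueError("tube size must be positive")
        if self.lattice.name == "SC" and n.denominator != 1:
            raise ValueError("SC tube size must be a positive integer")
        if self.lattice.name == "FCC" and (2 * n).denominator != 1:
            raise ValueError("FCC tube size must be a positive multiple of 0.5")

    @property
    def restricted(self) -> bool:
        return self.n is not None

    @property
    def side_internal(self) -> int:
        """Transverse bound B in internal units (sites satisfy 0 <= x <= B)."""
        if self.n is None:
            raise ValueError("unrestricted region has no transverse bound")
        b = self.n if self.lattice.name == "SC" else 2 * self.n
        return int(b)

    @property
    def side_physical_sq(self) -> Fraction:
        """Squared tube side L^2 in walk-step units (L = n for SC, n*sqrt2 for FCC)."""
        if self.n is None:
            raise ValueError("unrestricted region has no side")
        scale = 1 if self.lattice.name == "SC" else 2
        return Fraction(self.n) ** 2 * scale

    def __contains__(self, site: Site) -> bool:
        return in_region(site, self)

    def label(self) -> str:
        if self.n is None:
            return "unrestricted"
        n = self.n
        ns = str(int(n)) if n.denominator == 1 else str(float(n))
        return f"{ns}x{ns}" if self.lattice.name == "SC" else f"{ns}sqrt2x{ns}sqrt2"


def in_region(site: Site, region: TubeRegion) -> bool:
    """Tube membership: parity plus ``0 <= x2, x3 <= B`` (``x1`` unbounded)."""
    if not on_lattice(site, region.lattice):
        return False
    if not region.restricted:
        return True
    b = region.side_internal
    return 0 <= site[1] <= b and 0 <= site[2] <= b


def cross_section_count(region: TubeRegion) -> int:
    """Number of lattice sites in the cross-section plane ``x1 = 0``."""
    return sum(1 for _ in _iter_cross_section(region))


def _iter_cross_section(region: TubeRegion) -> Iterator[Site]:
    if not region.restricted:
        raise ValueError("cross section is undefined for an unrestricted region")
    b = region.side_internal
    for x2 in range(b + 1):
        for x3 in range(b + 1):
            site = (0, x2, x3)
            if on_lattice(site, region.lattice):
                yield site


def physical_sq_e2e(a: Site, b: Site, lattice: Lattice) -> Fraction:
    """Squared Euclidean distance between two sites in walk-step units."""
    d2 = sum((p - q) ** 2 for p, q in zip(a, b))
    return d2 * lattice.internal_to_physical_sq
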