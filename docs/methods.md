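# Methods

## Model

A self-avoiding walk (SAW) of length `N` on a lattice is an ordered sequence
of sites `ω(0), ω(1), …, ω(N)` in which consecutive sites are nearest
neighbours and no site occurs twice. With the step length as the unit of
length, the squared end-to-end distance `ω² = |ω(N) − ω(0)|²` is bounded by
`1 ≤ ω² ≤ N²`. SAWs are the minimal model of an excluded-volume polymer;
here they model hard-sphere chains packed in a square nanochannel, where the
ordered phases seen in off-lattice simulations sit on (nearly) perfect SC or
FCC crystals with a cube axis along the channel. The number `c_N` of
distinct `N`-step walks from a given origin is, up to a constant, the
conformational entropy of a confined chain — the quantity that drives phase
behaviour in athermal systems.

## Coordinates and confinement

Both lattices live on an integer grid so that the depth-first search and
every histogram key are exact:

* **SC** — conventional cell edge 1; steps `±e_i`; internal squared
  distances are already in step units.
* **FCC** — coordinates doubled (conventional cell edge 2); sites are the
  integer triples of even coordinate sum; steps are the 12 permutations of
  `(±1, ±1, 0)`; internal squared distances convert to step units by a
  factor 1/2.

A tube of size `n` (conventional-cell units) along the `x1` axis admits the
sites with `0 ≤ x2, x3 ≤ B`, where `B = n` (SC) or `B = 2n` (FCC); the
physical side is `L = n` (SC) or `L = n√2` (FCC). The corner-anchored
*inclusive* bound is a deliberate design choice: it is the unique reading of
the square-channel geometry that reproduces the published cross-section
populations for all nine studied tube sizes (e.g. 16 sites for the 3×3 SC
tube splitting 4/8/4, 25 sites for the 3√2 FCC tube splitting 4/8/4/4/4/1).
A strict centered inequality does not.

## Origin classification

Confinement breaks the cubic symmetry; cross-section sites split into orbits
of the dihedral group of the square (8 elements) acting on `(x2, x3)` about
the cross-section centre. This operational classification stands in for the
full tetragonal space-group treatment: for FCC tubes with odd `B`, half of
an orbit's images have odd coordinate sum — those are sites of the adjacent
`x1 = ±1` planes, and are excluded from the `x1 = 0` multiplicity. The
construction reproduces every published multiplicity; no studied size shows
sites that are space-group equivalent but dihedral-inequivalent.

Each class carries an overlap ratio

    r = (1/2 + min(a, L−a)/L) · (1/2 + min(b, L−b)/L),

the fraction of an `L×L` square centred at the origin lying inside the
cross section, computed as an exact `Fraction` (it reduces to the
dimensionless ratios `x/B`, so one formula serves both lattices). Classes
are labelled 1, 2, … by ascending overlap; type 1 is always the corner
class with `r = 1/4`. Equal overlaps between distinct orbits would be
broken by lexicographically smallest representative with a warning; none
occur for the studied sizes.

## Enumeration

Counting is exhaustive depth-first backtracking over a fixed, documented
step order; no symmetry reduction of the search is applied (origin sites on
walls break most of it, and correctness is the priority). Visited sites
live in a dense occupancy array over the reachable box
`[−N, N] × [0, B]²` — the transverse extent is tiny and the axial extent
bounded by the walk length, so the array is small and constant-time.

Two engines share one contract and are asserted equal in the tests: a
recursive pure-Python reference with arbitrary-precision integers, and an
iterative numba-JIT kernel with `int64` accumulators (exact up to
9.2×10¹⁸, far above any count reachable by direct enumeration — the largest
published value is ~4.7×10¹¹). An independent oracle generates all `z^N`
step sequences and filters violations in a separate pass; it is guarded to
`N ≤ 6` and exists only for testing.

The search can be partitioned by first step and the partial censuses merged
(`census_merge`), which is bit-identical to a monolithic run and enables
parallel or resumable long jobs. The tool contains no randomness; identical
configurations give identical outputs.

Validation: the enumerator reproduces the published unrestricted series
(SC: 6, 30, 150, 726, 3534; FCC: 12, 132, 1404, 14700, 152532) and, in a
one-off long run (~4 min), the published count `c_17 = 9 239 393 494` for
the corner origin of the 3×3 SC tube.

## Distributions

For each length the histogram of internal squared end-to-end distances is
converted to an exact rational pmf/cdf; means and characteristic ratios
`⟨ω²⟩/N` are exact. The median of a discrete cdf is the smallest support
value with cumulative probability ≥ 1/2 (deterministic by construction).
A two-parameter gamma CDF can be least-squares fitted to the empirical CDF
at the support points (unweighted, moment-matched start, positive-parameter
bounds); the gamma is a smoothing summary only — no comparison to published
fitted curves is attempted, since their objective is not stated.

Under strong confinement the characteristic-ratio medians drift upward with
`N` rather than sitting at a constant: for the 2×2 SC tube, corner origin,
the medians at `N = 11, 13, 15, 17` are 1.00, 1.00, 1.13, 1.24 under the
smallest-support rule — only the longest walks reach the ~1.25 plateau, so
the plateau test is asserted at `N = 17` together with the qualitative
collapse of the `1/N`-scaled curves.

## Scaling fits

Counts follow `c_N ~ A μ^N N^(γ−1)`; size follows `⟨ω²⟩ ~ D N^{2ν}`. Both
are fitted by ordinary least squares in log space — `ln c_N` on
`(1, N, ln N)` and `ln⟨ω²⟩` on `(1, ln N)` — with no weighting and no
differential approximants: the aim is moderate-length correlations, not
high-accuracy exponents. Defaults: the count law is fitted over the full
range `N ∈ [1, N_max]` (it holds down to `N = 1` even under confinement);
the size law over the late half `N ≥ ⌈N_max/2⌉`, because confinement makes
short walks anomalously rod-like. Both ranges are overridable.
Fitted-coefficient comparisons to published tables are tolerance-based
(±0.05 on μ): the published fit ranges are unstated, and across plausible
ranges our μ for the 1×1 SC tube varies over ~2.32–2.41.

The per-tube summaries are: the multiplicity-weighted average connective
constant `Σ|O_i|μ_i / Σ|O_i|`; the convergence ratio
`ln c_N(i) / ln c_N(1)` between origin types (→ 1 as `N` grows, since long
walks forget their origin); and overlap-scaled counts `c_N / r_i`, which
collapse the spread between origin types to first order (exact rationals).

## Problem sizes

The default test and acceptance runs use the desk-scale configurations: the
1×1 SC tube to `N = 17` (~5×10⁷ search nodes, under a second in the JIT
engine), the 0.5√2 FCC tube to `N = 12` (~2×10⁶ nodes), the 2×2 SC tube to
`N = 17` for the distribution checks, and `N ≤ 10` enumerations elsewhere.
The widest tubes at the published maximum lengths (3×3 SC at `N = 17`
unrestricted, FCC at `N = 13`) are hour-to-day scale and are left to
explicit long runs via first-step partitioning; one such run was used to
validate the enumerator against the published 3×3 count above.

## Limitations

* Tube axes other than a cube axis ⟨100⟩, non-square cross sections,
  periodic transverse boundaries and the BCC lattice are out of scope.
* The dihedral classification is operational, not a space-group orbit
  computation; it is verified against the studied sizes only.
* Fitted exponents are effective, fit-range-sensitive values for moderate
  `N`, not estimates of universal critical exponents.
* The gamma fit summarises shape; its parameters have no claimed physical
  meaning.
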